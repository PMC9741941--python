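# Methods

## Acoustic model of the channel-data synthesizer

The synthesizer emulates pulse-echo acquisition of point scatterers under
steered plane-wave transmits on a 2-D linear array:

- **Transmit**: an ideal plane wave with direction `(sin θ, cos θ)` whose
  wavefront crosses the array center `(0, 0)` at `t = 0`. The transmit field
  carries no spreading loss and no aperture sampling, so transmit grating
  lobes are not modeled; all grating-lobe behavior studied here originates
  on receive, where the beamforming subaperture samples the field at the
  element pitch.
- **Scattering**: linear, single scattering from point targets with real
  reflectivity amplitudes.
- **Receive**: each element records the pulse at the round-trip delay
  `τ = (x sin θ + z cos θ)/c0 + √((x − x_e)² + z²)/c0`, weighted by 1/r
  spherical spreading and a hard-baffle far-field element factor
  `sinc(a·sin φ/λ)·cos φ` with `a` the element width (default 0.9 × pitch;
  the kerf is not specified for the modeled probe) and `φ` the angle off the
  element normal.
- **Pulse**: a Gaussian-modulated sinusoid at the probe center frequency
  with −6 dB fractional bandwidth 0.8 (default), truncated at its −60 dB
  envelope extent. The pulse object is supported on `[0, duration]`; the
  synthesizer aligns its evaluation so the envelope *peak* arrives at τ,
  which is the convention every delay-accuracy check in the test suite
  relies on. Samples are evaluated exactly at sample instants (no
  fractional-delay interpolation on synthesis), so superposition and
  amplitude linearity hold to machine precision.
- **Noise**: white Gaussian, scaled so that the prescribed raw-data SNR
  holds over the *entire* raw array (all times, elements and angles), and
  generated from an explicit integer seed.

The default study configuration is a broadband 128-element array with
0.3048 mm pitch, 7.82 MHz center frequency (λ ≈ 197 µm, so the first
receive grating lobe sits near ±40°), 31.28 MHz sampling (4 × f0), sound
speed 1540 m/s, and a recording window sized to cover every delay the
beamforming grid can request.

What the synthesizer does **not** model: transmit aperture diffraction,
attenuation and dispersion, nonlinear propagation, multiple scattering,
reverberation, elevational (out-of-plane) effects, and element-to-element
sensitivity mismatch. Passing tests therefore demonstrate the *mechanism*
of NSI grating-lobe suppression and the correct relative behavior of the
methods, not the absolute dB levels a physical acquisition would produce.
In particular the absolute grating-lobe levels depend on the pulse
surrogate: with a measured two-way impulse response they would differ in
detail, which is why the simulation studies are read as tolerance-banded
quantities and orderings.

## Beamforming conventions

- **Subaperture**: N = round(z / (F# · pitch)) rounded *up* to even (even N
  keeps the ±1 zero-mean split exact), minimum 2, fixed F-number 1.5 by
  default. When the subaperture runs off the array it is zero-padded, not
  renormalized; asymmetric clipping at the edges is accepted and logged.
- **Scan lines at element midpoints.** An even-length subaperture cannot be
  centered on an element. Placing scan lines on element centers leaves the
  aperture center half a pitch off the line, which visibly destroys the
  zero-mean aperture's broadside null (the NSI mechanism) — measured on the
  wire study, the null disappears entirely and NSI cancellation collapses
  to ~12 dB. Default scan lines therefore sit at the 127 element midpoints
  (including x = 0), where the even aperture is exactly symmetric about the
  line; any other line placement is still accepted, with the subaperture
  anchored to the nearest lattice position.
- **Delays**: linear interpolation between RF samples (default); a
  nearest-sample mode is kept because the brute-force DAS oracle in the
  test suite is defined at integer sample delays. Delays outside the
  recorded window contribute zero.
- **Hann window**: the symmetric (N+2)-point raised cosine with its zero
  endpoints dropped, so all N weights are strictly positive (the textbook
  N-point window is identically zero at N = 2, which would null shallow
  pixels).
- **dc-offset algebra**: DAS is linear in the receive weights, so the
  zero-mean and uniform ("ones") beamformed datasets form a basis:
  `dc1 = zm + c·ones`, `dc2 = −zm + c·ones`. Sweeps over the dc offset
  reuse one pair of beamformed datasets; the identity is asserted against
  directly beamformed dc apertures in the tests.

## NSI combination and display

`E_NSI = (E_dc1 + E_dc2)/2 − E_ZM` is computed on envelope amplitudes
(magnitude of the depth-axis analytic signal). Where the subtraction is
nonpositive the result is clamped to a relative floor of 1e−12 × the image
maximum — display is logarithmic, so the floor only has to keep the
compression defined; floored pixels sit ~240 dB down, far below any
dynamic range of interest. Log compression normalizes to the image maximum
(0 dB) exactly.

With c = 0 the two dc apertures degenerate to ±the zero-mean aperture and
the combination cancels everywhere (the floor); increasing c widens the NSI
main lobe and raises residuals, which is the resolution/speckle trade-off
the dc offset controls. Exposed defaults are c = 0.1 (resolution-oriented)
and c = 1.0 (contrast-oriented, Hann-like speckle).

## Angular low-pass filter (IC-NSI)

A linear-phase equiripple FIR low-pass designed by the Parks–McClellan
exchange with normalized passband edge 0.3, stopband edge 0.8 and ≥ 60 dB
single-pass stopband attenuation; the order is grown from a length estimate
until the designed response verifiably meets the attenuation (11 taps for
the default band edges). It is applied along the steering-angle axis
forward-backward (zero phase) with symmetric-reflection end padding, so the
filtered angles stay registered for the per-angle NSI subtraction. C-NSI is
unfiltered by default: filtering before a coherent sum makes no appreciable
difference, since the coherent sum is itself the DC component of the angle
axis.

When the angle axis is shorter than the minimum-order design (e.g. 3–9
angle sequences), a shorter forced-order design is substituted and a
warning is logged; its attenuation is best-effort. One consequence,
verified in the sweep study: the IC-NSI grating-lobe reduction is no longer
strictly monotone in the number of compounded angles, because the effective
filter changes with the axis length. The monotone "more angles, less
reduction" trend is asserted for C-NSI, which has no filter.

## GCF baseline

Per pixel and per angle, the delayed, Hann-apodized subaperture vector is
Fourier-transformed across the aperture (spectrum length = subaperture
length, no zero padding) and the DAS output is weighted by the energy
fraction in the bins |k| ≤ M0 (DC plus M0 bins each side, counted modulo
the spectrum length, so M0 ≥ N/2 degenerates to weight 1). The weight is 0
for an all-zero vector. GCF is applied before coherent compounding — each
transmit's aperture coherence is what the construction models — and M0 = 2
is the empirical default. The weight lies in [0, 1], is scale-invariant,
and is non-decreasing in M0.

## Metrics

- **Lateral profile of axially integrated power**: P(x) = Σ_z E(z, x)²,
  in dB re its maximum, floored at −120 dB. Grating-lobe energy smears
  axially, so the axial integral captures it robustly.
- **Grating-lobe level**: max of the profile inside the grating windows
  minus the max inside the main-lobe window. Default windows for the wire
  study: main = scatterer x ± 1 mm; grating = ±1 mm bands around
  x_s + z_s·tan(θ_g) with θ_g = arcsin(±λ/d) (≈ ±4.2 mm at 5 mm depth).
  Reduction = GL_Hann − GL_method on the same windows and compounding.
- **CNR** = |μ_t − μ_b| / √(σ_t² + σ_b²) on linear envelope amplitudes
  (pass a dB image for the dB-domain variant); ROIs must cover ≥ 25 px.
- **Speckle SNR** = mean/SD of envelope amplitude in a homogeneous ROI
  (≥ 100 px); 1.91 for fully developed (Rayleigh) speckle.
- **Beamwidth**: width of the contiguous region above (peak − 6 dB) with
  linear-interpolated crossings. −6 dB is the package's convention; the
  threshold is an argument.

## Study sizes and seeds

The bundled studies use the full 128-element configuration with a
6 mm-deep, 127-line grid sampled at λ/8 axially (≈ 31k pixels), chosen so
each simulation completes in seconds while the grating windows and main
lobe are fully resolved. The speckle study uses 120 scatterers/mm² (≈ 11
per resolution cell at 6.5 mm depth — fully developed), a hyperechoic
circular inclusion, and the full 33-angle sequence so the designed angular
filter (not the fallback) is exercised. Every stochastic step (noise,
scatterer placement) takes an explicit integer seed; replicate seeds are
derived arithmetically from a base seed.

## Known limitations

- Absolute grating-lobe levels inherit the pulse surrogate; the best-case
  reduction over the bundled dc/angle sweep computes to ≈ 50 dB here,
  whereas measured broadband systems can reach higher values. The residual
  is set by the quadrature component between the odd (zero-mean) and even
  (dc) aperture responses inside the grating windows, which envelope
  subtraction cannot cancel; it shrinks proportionally with the dc offset.
- The 2-D model ignores the elevational focus (recorded in the probe
  configuration but unused).
- GCF image formation is the slowest path (per-pixel aperture spectra);
  it is vectorized over depth groups but not parallelized.
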