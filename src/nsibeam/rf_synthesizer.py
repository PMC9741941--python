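"""Synthetic pulse-echo RF channel data for steered plane-wave transmits.

A point-scatterer acoustic model: each transmit is an ideal steered plane
wave (no transmit aperture sampling, no spreading loss on transmit), each
scatterer re-radiates the broadband pulse, and each receive element records
the echo with hard-baffle element directivity and 1/r spherical spreading.
Linear, single-scattering, lossless propagation — deterministic given its
inputs, with optional seeded additive white Gaussian noise at a prescribed
raw-data SNR.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.signal import gausspulse

from .probe_model import (
    ImagingGrid,
    PlaneWaveSequence,
    ProbeGeometry,
    element_positions,
    wavelength,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-modulated sinusoid pulse surrogate.

    The pulse is supported on [0, duration] with its (unit-magnitude) peak
    at duration/2; ``fractional_bandwidth`` is the -6 dB bandwidth over the
    center frequency. ``duration`` defaults to the -60 dB envelope extent.
    """

    center_frequency: float
    fractional_bandwidth: float = 0.8
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        if self.duration is None:
            tc = gausspulse(
                "cutoff",
                fc=self.center_frequency,
                bw=self.fractional_bandwidth,
                tpr=-60,
            )
            object.__setattr__(self, "duration", 2.0 * tc)
        elif self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def peak_time(self) -> float:
        return self.duration / 2.0

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        val = gausspulse(
            t - self.peak_time,
            fc=self.center_frequency,
            bw=self.fractional_bandwidth,
        )
        return np.where((t >= 0.0) & (t <= self.duration), val, 0.0)

    @classmethod
    def for_probe(cls, geometry: ProbeGeometry) -> "PulseModel":
        return cls(geometry.center_frequency, geometry.fractional_bandwidth)


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers: positions (S, 2) as (x, z) in m, linear amplitudes."""

    positions: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (S, 2)")
        if pos.shape[0] == 0:
            raise ValueError("scatterer field must contain at least one scatterer")
        if amp.shape != (pos.shape[0],):
            raise ValueError("amplitudes must have one value per scatterer")
        if np.any(pos[:, 1] <= 0):
            raise ValueError("all scatterer depths z must be > 0")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(amp))):
            raise ValueError("positions and amplitudes must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_scatterers(self) -> int:
        return int(self.amplitudes.size)


@dataclass(frozen=True)
class ChannelData:
    """Per-element, per-angle RF time series.

    ``samples`` is indexed [time, element, angle]; ``t0`` is the time of the
    first sample relative to the transmit wavefront crossing (0, 0).
    """

    samples: np.ndarray
    t0: float
    sampling_frequency: float
    sequence: PlaneWaveSequence
    geometry: ProbeGeometry

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 3:
            raise ValueError("samples must be indexed [time, element, angle]")
        if s.shape[1] != self.geometry.n_elements:
            raise ValueError("element axis must match geometry.n_elements")
        if s.shape[2] != self.sequence.n_angles:
            raise ValueError("angle axis must match the sequence length")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def scaled(self, k: float) -> "ChannelData":
        return dataclasses.replace(self, samples=self.samples * k)

    # -- HDF5 container -----------------------------------------------------
    def save(self, path) -> None:
        g = self.geometry
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("rf", data=self.samples.astype(np.float32))
            ds.attrs["t0"] = self.t0
            ds.attrs["fs"] = self.sampling_frequency
            ds.attrs["angles_deg"] = np.asarray(self.sequence.angles_deg)
            ds.attrs["n_elements"] = g.n_elements
            ds.attrs["pitch_m"] = g.pitch
            ds.attrs["f0_hz"] = g.center_frequency
            ds.attrs["fs_probe_hz"] = g.sampling_frequency
            ds.attrs["c0_m_s"] = g.sound_speed
            ds.attrs["fractional_bandwidth"] = g.fractional_bandwidth
            ds.attrs["element_width_m"] = g.element_width

    @classmethod
    def load(cls, path) -> "ChannelData":
        with h5py.File(path, "r") as fh:
            ds = fh["rf"]
            samples = np.asarray(ds[...], dtype=float)
            a = ds.attrs
            geometry = ProbeGeometry(
                n_elements=int(a["n_elements"]),
                pitch=float(a["pitch_m"]),
                center_frequency=float(a["f0_hz"]),
                sampling_frequency=float(a["fs_probe_hz"]),
                sound_speed=float(a["c0_m_s"]),
                element_width=float(a["element_width_m"]),
                fractional_bandwidth=float(a["fractional_bandwidth"]),
            )
            seq = PlaneWaveSequence(np.asarray(a["angles_deg"], dtype=float))
            return cls(
                samples=samples,
                t0=float(a["t0"]),
                sampling_frequency=float(a["fs"]),
                sequence=seq,
                geometry=geometry,
            )


# ---------------------------------------------------------------------------
# Delay model
# ---------------------------------------------------------------------------

def two_way_delay(
    geometry: ProbeGeometry,
    angle_deg: float,
    scatterer_xz,
    element_index: int,
) -> float:
    """Round-trip time (s): plane-wave transmit to (x, z), echo back to one
    element.  t = 0 when the transmitted wavefront crosses the array center.
    """
    x, z = float(scatterer_xz[0]), float(scatterer_xz[1])
    if z <= 0:
        raise ValueError("scatterer depth z must be > 0")
    th = math.radians(angle_deg)
    xe = float(element_positions(geometry)[element_index])
    c0 = geometry.sound_speed
    tx = (x * math.sin(th) + z * math.cos(th)) / c0
    rx = math.hypot(x - xe, z) / c0
    return tx + rx


def _directivity(geometry: ProbeGeometry, xe: np.ndarray, xs, zs) -> np.ndarray:
    """Hard-baffle far-field element factor sinc(a sin(phi)/lambda) cos(phi)."""
    dx = xs - xe
    r = np.hypot(dx, zs)
    sin_phi = dx / r
    cos_phi = zs / r
    lam = wavelength(geometry)
    return np.sinc(geometry.element_width * sin_phi / lam) * cos_phi


def required_window(
    geometry: ProbeGeometry,
    sequence: PlaneWaveSequence,
    grid: ImagingGrid,
    pulse: PulseModel | None = None,
) -> float:
    """Recording end time covering every beamforming delay the grid needs.

    The receive half-aperture at the deepest pixel is z/(2 F#) plus one
    pitch of margin; transmit delay is maximized over grid corners and
    steering angles.
    """
    if pulse is None:
        pulse = PulseModel.for_probe(geometry)
    c0 = geometry.sound_speed
    z_max = float(grid.z[-1])
    x_abs = float(np.max(np.abs(grid.x)))
    th = np.radians(sequence.angles_deg)
    tx_max = float(np.max(x_abs * np.abs(np.sin(th)) + z_max * np.cos(th))) / c0
    half_ap = z_max / (2.0 * grid.f_number) + geometry.pitch
    rx_max = math.hypot(half_ap, z_max) / c0
    return 1.05 * (tx_max + rx_max) + pulse.duration


def synthesize(
    geometry: ProbeGeometry,
    sequence: PlaneWaveSequence,
    scatterers: ScattererField,
    pulse: PulseModel | None = None,
    t_end: float | None = None,
    chunk: int = 256,
) -> ChannelData:
    """Simulate RF channel data for every steering angle in the sequence.

    samples[t, e, a] = sum over scatterers of
        amplitude * directivity(e, s) * pulse(t - tau(e, a, s)) / r(e, s)

    where tau is ``two_way_delay`` and the pulse is aligned so its peak
    arrives at tau.  The recording window defaults to 1.2x the deepest
    round trip; scatterers whose echoes fall entirely beyond an explicit
    ``t_end`` are excluded with a logged warning.
    """
    if scatterers.n_scatterers == 0:
        raise ValueError("scatterer field must be non-empty")
    if pulse is None:
        pulse = PulseModel.for_probe(geometry)
    fs = geometry.sampling_frequency
    c0 = geometry.sound_speed
    xe = element_positions(geometry)
    xs_all = scatterers.positions[:, 0]
    zs_all = scatterers.positions[:, 1]
    th_all = np.radians(sequence.angles_deg)

    # worst-case round trip over scatterers, elements, angles
    tx_worst = np.max(
        xs_all[None, :] * np.sin(th_all)[:, None]
        + zs_all[None, :] * np.cos(th_all)[:, None]
    )
    rx_worst = np.max(np.hypot(xs_all[:, None] - xe[None, :], zs_all[:, None]))
    tau_worst = (tx_worst + rx_worst) / c0
    if t_end is None:
        t_end = 1.2 * tau_worst + pulse.duration
    n_t = int(math.ceil(t_end * fs)) + 1
    n_e = geometry.n_elements
    n_a = sequence.n_angles

    # earliest arrival per scatterer (broadside transmit lower bound)
    r_min = np.min(np.hypot(xs_all[:, None] - xe[None, :], zs_all[:, None]), axis=1)
    tau_min = (np.min(
        xs_all[None, :] * np.sin(th_all)[:, None]
        + zs_all[None, :] * np.cos(th_all)[:, None], axis=0) + r_min) / c0
    inside = tau_min - pulse.peak_time < t_end
    if not np.all(inside):
        n_out = int(np.sum(~inside))
        logger.warning(
            "%d scatterer(s) fall beyond the %0.2f us recording window; excluded",
            n_out, t_end * 1e6,
        )
        if not np.any(inside):
            raise ValueError("all scatterers fall beyond the recording window")
    keep = np.flatnonzero(inside)

    n_pulse = int(math.ceil(pulse.duration * fs)) + 2
    out = np.zeros((n_t, n_e, n_a), dtype=float)
    for a in range(n_a):
        th = th_all[a]
        acc = np.zeros(n_t * n_e, dtype=float)
        for lo in range(0, keep.size, chunk):
            sel = keep[lo : lo + chunk]
            xs, zs = xs_all[sel], zs_all[sel]
            amp = scatterers.amplitudes[sel]
            tx = (xs * math.sin(th) + zs * math.cos(th)) / c0        # (S,)
            r = np.hypot(xs[:, None] - xe[None, :], zs[:, None])     # (S, E)
            tau = tx[:, None] + r / c0
            gain = (amp[:, None] / r) * _directivity(
                geometry, xe[None, :], xs[:, None], zs[:, None]
            )
            # sample indices spanning the pulse support around each tau
            n0 = np.ceil((tau - pulse.peak_time) * fs).astype(np.int64)
            n_idx = n0[:, :, None] + np.arange(n_pulse)              # (S, E, L)
            t_rel = n_idx / fs - tau[:, :, None] + pulse.peak_time
            vals = gain[:, :, None] * pulse(t_rel)
            valid = (n_idx >= 0) & (n_idx < n_t)
            flat = (n_idx * n_e + np.arange(n_e)[None, :, None])[valid]
            acc += np.bincount(flat, weights=vals[valid], minlength=n_t * n_e)
        out[:, :, a] = acc.reshape(n_t, n_e)
    return ChannelData(
        samples=out, t0=0.0, sampling_frequency=fs,
        sequence=sequence, geometry=geometry,
    )


def add_noise(channel: ChannelData, snr_db: float | None, seed: int) -> ChannelData:
    """Add white Gaussian noise at a prescribed raw-data SNR.

    The SNR is defined over the entire raw array (all times, elements and
    angles): 10 log10(signal power / noise power) = snr_db.  ``snr_db`` of
    None (or +inf) returns the data unchanged; reproducible under a fixed
    seed.
    """
    if snr_db is None or np.isinf(snr_db):
        return dataclasses.replace(channel, samples=channel.samples.copy())
    p_sig = float(np.mean(channel.samples**2))
    if p_sig == 0.0:
        raise ValueError("SNR undefined for all-zero channel data")
    p_noise = p_sig / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, math.sqrt(p_noise), size=channel.samples.shape)
    return dataclasses.replace(channel, samples=channel.samples + noise)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def make_phantom(kind: str, **params) -> ScattererField:
    """Build a scatterer field.

    kind='single_point'   : one scatterer; params x (default 0), z (5 mm),
                            amplitude (1).
    kind='wire_grid'      : lattice of unit scatterers at the outer product
                            of x_positions and z_positions.
    kind='speckle_cyst'   : uniformly scattered diffuse medium over a
                            rectangle (center x/z, width, height) at
                            density_per_mm2, standard-normal amplitudes,
                            optionally rescaled inside circular inclusions
                            circles=[(cx, cz, radius, amplitude_scale), ...]
                            (scale 0 = anechoic); seeded.
    """
    if kind == "single_point":
        x = float(params.get("x", 0.0))
        z = float(params.get("z", 5e-3))
        amp = float(params.get("amplitude", 1.0))
        return ScattererField(np.array([[x, z]]), np.array([amp]))
    if kind == "wire_grid":
        xs = np.atleast_1d(np.asarray(params["x_positions"], dtype=float))
        zs = np.atleast_1d(np.asarray(params["z_positions"], dtype=float))
        gx, gz = np.meshgrid(xs, zs, indexing="ij")
        pos = np.column_stack([gx.ravel(), gz.ravel()])
        return ScattererField(pos, np.ones(pos.shape[0]))
    if kind == "speckle_cyst":
        cx = float(params.get("center_x", 0.0))
        cz = float(params["center_z"])
        width = float(params["width"])
        height = float(params["height"])
        density = float(params["density_per_mm2"])
        seed = int(params.get("seed", 0))
        circles = params.get("circles", [])
        area_mm2 = (width * 1e3) * (height * 1e3)
        n = int(math.ceil(density * area_mm2))
        rng = np.random.default_rng(seed)
        x = cx + (rng.random(n) - 0.5) * width
        z = cz + (rng.random(n) - 0.5) * height
        amp = rng.standard_normal(n)
        for (ccx, ccz, r, scale) in circles:
            inside = (x - ccx) ** 2 + (z - ccz) ** 2 <= r**2
            amp[inside] *= scale
        return ScattererField(np.column_stack([x, z]), amp)
    raise ValueError(f"unknown phantom kind: {kind!r}")
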