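"""Linear-array geometry, plane-wave sequences and imaging-grid conventions.

Coordinate convention used throughout the package: ``x`` is the lateral
coordinate (m) along the array, ``z`` is depth (m, positive into the medium),
the array sits at ``z = 0`` with its elements centered about ``x = 0``.
Steering angles are in degrees, positive toward +x, and the transmitted
plane wavefront crosses the array center ``(0, 0)`` at ``t = 0``.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

#: Conventional soft-tissue sound speed (m/s); used when a config omits it.
SOFT_TISSUE_SOUND_SPEED = 1540.0


@dataclass(frozen=True)
class ProbeGeometry:
    """Physical description of a linear array and its acoustic constants.

    Parameters
    ----------
    n_elements : int
        Number of array elements (>= 2).
    pitch : float
        Center-to-center element spacing (m).
    center_frequency : float
        Nominal pulse center frequency (Hz).
    sampling_frequency : float
        RF sampling rate (Hz); must be at least 4x the center frequency.
    sound_speed : float
        Medium sound speed (m/s).
    element_width : float, optional
        Physical element width (m) used for the hard-baffle directivity
        model; defaults to 0.9 * pitch (kerf of 10% of the pitch).
    fractional_bandwidth : float
        Pulse -6 dB bandwidth divided by the center frequency.
    elevational_focus : float, optional
        Elevational lens focus (m). Recorded for completeness; the 2-D
        model ignores it.
    """

    n_elements: int
    pitch: float
    center_frequency: float
    sampling_frequency: float
    sound_speed: float = SOFT_TISSUE_SOUND_SPEED
    element_width: float | None = None
    fractional_bandwidth: float = 0.8
    elevational_focus: float | None = None

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        if self.sampling_frequency < 4.0 * self.center_frequency:
            raise ValueError(
                "sampling_frequency must be >= 4x center_frequency for "
                "adequate RF sampling"
            )
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.element_width is None:
            object.__setattr__(self, "element_width", 0.9 * self.pitch)

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.center_frequency

    def element_positions(self) -> np.ndarray:
        return element_positions(self)


def element_positions(geometry: ProbeGeometry) -> np.ndarray:
    """Lateral element-center coordinates (m), symmetric about x = 0."""
    n = geometry.n_elements
    idx = np.arange(n, dtype=float)
    return (idx - (n - 1) / 2.0) * geometry.pitch


def line_positions(geometry: ProbeGeometry) -> np.ndarray:
    """Default scan-line lateral coordinates: the element midpoints.

    An even-length receive subaperture is exactly symmetric about a line
    placed midway between two elements, which centers the zero-mean
    aperture's broadside null on the scan line; for 128 elements this gives
    127 lines including x = 0.
    """
    xe = element_positions(geometry)
    return 0.5 * (xe[:-1] + xe[1:])


def wavelength(geometry: ProbeGeometry) -> float:
    """Acoustic wavelength at the probe center frequency (m)."""
    return geometry.sound_speed / geometry.center_frequency


def grating_lobe_angle(
    geometry: ProbeGeometry, steer_deg: float = 0.0
) -> tuple[float, ...]:
    """Predicted first grating-lobe directions (degrees).

    Solves ``sin(theta_g) = sin(theta_steer) +/- lambda / pitch`` and
    returns the real solutions (those with |sin| <= 1) as a sorted tuple,
    empty when the array is sampled finely enough that no grating lobe
    enters real space.
    """
    lam = wavelength(geometry)
    s0 = math.sin(math.radians(steer_deg))
    out = []
    for sgn in (-1.0, 1.0):
        s = s0 + sgn * lam / geometry.pitch
        if abs(s) <= 1.0:
            out.append(math.degrees(math.asin(s)))
    return tuple(sorted(out))


@dataclass(frozen=True)
class PlaneWaveSequence:
    """Ordered list of plane-wave steering angles (degrees).

    Each transmit is referenced so that the wavefront crosses the array
    center at t = 0.
    """

    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("angles_deg must be a non-empty 1-D sequence")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(np.abs(angles) >= 90.0):
            raise ValueError("|angle| must be < 90 degrees")
        object.__setattr__(self, "angles_deg", angles)

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)

    @classmethod
    def symmetric(cls, n_angles: int, half_span_deg: float = 16.0) -> "PlaneWaveSequence":
        """n_angles equally spaced over [-half_span, +half_span]; n = 1 -> [0]."""
        if n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if n_angles == 1:
            return cls(np.array([0.0]))
        return cls(np.linspace(-half_span_deg, half_span_deg, n_angles))


@dataclass(frozen=True)
class ImagingGrid:
    """Beamforming grid: scan-line lateral positions, depth samples, F-number.

    The receive subaperture width at depth z is z / f_number, clipped to the
    physical aperture.
    """

    x: np.ndarray
    z: np.ndarray
    f_number: float = 1.5

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if z.size == 0 or x.size == 0:
            raise ValueError("grid axes must be non-empty")
        if z[0] <= 0 or np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing with z[0] > 0")
        if self.f_number <= 0:
            raise ValueError("f_number must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)

    @property
    def n_lines(self) -> int:
        return int(self.x.size)

    @property
    def n_depths(self) -> int:
        return int(self.z.size)


# ---------------------------------------------------------------------------
# Study configuration: L14-5/38-like broadband linear array
# ---------------------------------------------------------------------------

def l14_5_38() -> ProbeGeometry:
    """The 128-element, 0.3048 mm pitch, 7.82 MHz broadband linear array
    configuration used for all bundled simulation studies.  fs = 4 * f0.
    """
    return ProbeGeometry(
        n_elements=128,
        pitch=0.3048e-3,
        center_frequency=7.82e6,
        sampling_frequency=31.28e6,
        sound_speed=SOFT_TISSUE_SOUND_SPEED,
        fractional_bandwidth=0.8,
        elevational_focus=16e-3,
    )


def study_sequence(n_angles: int = 33, half_span_deg: float = 16.0) -> PlaneWaveSequence:
    """Default compounding sequence: n angles spanning -16..+16 degrees."""
    return PlaneWaveSequence.symmetric(n_angles, half_span_deg)


def study_grid(
    geometry: ProbeGeometry,
    z_min: float = 2.5e-3,
    z_max: float = 8.5e-3,
    dz: float | None = None,
    f_number: float = 1.5,
) -> ImagingGrid:
    """Grid with scan lines at the element midpoints and lambda/8 axial
    sampling."""
    if dz is None:
        dz = wavelength(geometry) / 8.0
    z = np.arange(z_min, z_max + dz / 2, dz)
    return ImagingGrid(x=line_positions(geometry), z=z, f_number=f_number)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    geometry: ProbeGeometry
    sequence: PlaneWaveSequence
    grid: ImagingGrid


def config_from_dict(cfg: dict) -> ImagingConfig:
    probe = cfg["probe"]
    geometry = ProbeGeometry(
        n_elements=int(probe["n_elements"]),
        pitch=float(probe["pitch_m"]),
        center_frequency=float(probe["f0_hz"]),
        sampling_frequency=float(probe["fs_hz"]),
        sound_speed=float(probe.get("c0_m_s", SOFT_TISSUE_SOUND_SPEED)),
        fractional_bandwidth=float(probe.get("fractional_bandwidth", 0.8)),
        element_width=(
            float(probe["element_width_m"]) if "element_width_m" in probe else None
        ),
        elevational_focus=(
            float(probe["elevational_focus_m"])
            if "elevational_focus_m" in probe
            else None
        ),
    )
    seq = PlaneWaveSequence(np.asarray(cfg["sequence"]["angles_deg"], dtype=float))
    gridcfg = cfg.get("grid", {})
    f_number = float(gridcfg.get("f_number", 1.5))
    z_min = float(gridcfg.get("z_min", 2.5e-3))
    z_max = float(gridcfg.get("z_max", 8.5e-3))
    dz = gridcfg.get("dz")
    grid = study_grid(
        geometry, z_min=z_min, z_max=z_max,
        dz=None if dz is None else float(dz), f_number=f_number,
    )
    return ImagingConfig(geometry=geometry, sequence=seq, grid=grid)


def load_config(path) -> ImagingConfig:
    """Load probe/sequence/grid blocks from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return config_from_dict(cfg)


def config_to_dict(config: ImagingConfig) -> dict:
    g = config.geometry
    return {
        "probe": {
            "n_elements": g.n_elements,
            "pitch_m": g.pitch,
            "f0_hz": g.center_frequency,
            "fs_hz": g.sampling_frequency,
            "c0_m_s": g.sound_speed,
            "fractional_bandwidth": g.fractional_bandwidth,
            "element_width_m": g.element_width,
        },
        "sequence": {"angles_deg": [float(a) for a in config.sequence.angles_deg]},
        "grid": {
            "f_number": config.grid.f_number,
            "z_min": float(config.grid.z[0]),
            "z_max": float(config.grid.z[-1]),
            "dz": float(config.grid.z[1] - config.grid.z[0])
            if config.grid.n_depths > 1
            else None,
        },
    }
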