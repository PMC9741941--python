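"""Image-quality metrics: axially integrated lateral power profiles,
grating-lobe level and reduction, CNR, speckle SNR, and main-lobe width.

Grating-lobe level is measured on the lateral profile of axially integrated
power (the lobe energy smears axially, so integrating over depth captures
it) as the peak inside a lateral grating window minus the peak inside the
main-lobe window, in dB.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nsi_engine import BModeImage, EnvelopeImage
from .probe_model import ImagingGrid, ProbeGeometry, grating_lobe_angle

#: dB floor applied to power profiles so plots and comparisons stay finite.
PROFILE_FLOOR_DB = -120.0


@dataclass(frozen=True)
class LateralPowerProfile:
    """Axially integrated power per scan line, dB relative to its maximum."""

    x: np.ndarray
    power_db: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        p = np.asarray(self.power_db, dtype=float)
        if x.shape != p.shape or x.ndim != 1:
            raise ValueError("x and power_db must be matching 1-D arrays")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "power_db", p)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangle or circle in (x, z) coordinates.

    kind='rect' uses bounds=(x0, x1, z0, z1); kind='circle' uses
    bounds=(cx, cz, radius).  ``role`` is a free-text label (target,
    background, grating_window, main_window).
    """

    kind: str
    bounds: tuple
    role: str = ""

    def mask(self, grid: ImagingGrid) -> np.ndarray:
        xx = grid.x[None, :]
        zz = grid.z[:, None]
        if self.kind == "rect":
            x0, x1, z0, z1 = self.bounds
            m = (xx >= x0) & (xx <= x1) & (zz >= z0) & (zz <= z1)
        elif self.kind == "circle":
            cx, cz, r = self.bounds
            m = (xx - cx) ** 2 + (zz - cz) ** 2 <= r**2
        else:
            raise ValueError(f"unknown ROI kind: {self.kind!r}")
        if not np.any(m):
            raise ValueError("ROI does not intersect the imaging grid")
        return np.broadcast_to(m, (grid.n_depths, grid.n_lines))


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of per-image metrics; fields are None where not measured."""

    grating_lobe_level_db: float | None = None
    grating_lobe_reduction_db: float | None = None
    cnr: float | None = None
    speckle_snr: float | None = None
    beamwidth_m: float | None = None


def _values(image) -> np.ndarray:
    if isinstance(image, EnvelopeImage):
        return image.values
    if isinstance(image, BModeImage):
        return image.db_values
    return np.asarray(image, dtype=float)


# ---------------------------------------------------------------------------
# Profiles and grating-lobe levels
# ---------------------------------------------------------------------------

def axial_power_profile(
    e: EnvelopeImage, floor_db: float = PROFILE_FLOOR_DB
) -> LateralPowerProfile:
    """P(x) = sum_z E(z, x)^2, expressed as 10 log10(P / Pmax)."""
    p = np.sum(e.values**2, axis=0)
    peak = float(p.max())
    if peak <= 0.0:
        raise ValueError("profile undefined for an all-zero image")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(p / peak)
    return LateralPowerProfile(x=e.grid.x.copy(), power_db=np.maximum(db, floor_db))


def _window_peak(profile: LateralPowerProfile, windows) -> float:
    if isinstance(windows, tuple) and np.isscalar(windows[0]):
        windows = [windows]
    sel = np.zeros(profile.x.size, dtype=bool)
    for lo, hi in windows:
        sel |= (profile.x >= lo) & (profile.x <= hi)
    if not np.any(sel):
        raise ValueError("window selects no profile samples")
    return float(profile.power_db[sel].max())


def grating_lobe_level(
    profile: LateralPowerProfile, main_window, grating_windows
) -> float:
    """Peak profile level in the grating window(s) minus the main-lobe peak
    (dB; negative when the grating lobes sit below the main lobe).

    Windows are (lo, hi) lateral intervals in m; ``grating_windows`` may be
    a single interval or a list of them.  Windows must not overlap.
    """
    g = grating_windows
    if isinstance(g, tuple) and np.isscalar(g[0]):
        g = [g]
    lo_m, hi_m = main_window
    for lo, hi in g:
        if lo < hi_m and hi > lo_m:
            raise ValueError("main and grating windows must be disjoint")
    return _window_peak(profile, g) - _window_peak(profile, main_window)


def grating_windows_for(
    geometry: ProbeGeometry,
    scatterer_x: float,
    depth: float,
    half_width: float = 1e-3,
) -> list[tuple[float, float]]:
    """Lateral bands around the arcsin-predicted grating-lobe positions of
    a broadside receive beam focused at (scatterer_x, depth)."""
    angles = grating_lobe_angle(geometry, 0.0)
    if not angles:
        raise ValueError("array has no real grating lobe at this wavelength")
    out = []
    for th in angles:
        x = scatterer_x + depth * math.tan(math.radians(th))
        out.append((x - half_width, x + half_width))
    return out


def main_window_for(scatterer_x: float, half_width: float = 1e-3) -> tuple[float, float]:
    return (scatterer_x - half_width, scatterer_x + half_width)


# ---------------------------------------------------------------------------
# Contrast and speckle statistics
# ---------------------------------------------------------------------------

def cnr(image, target: RoiSpec, background: RoiSpec, grid: ImagingGrid | None = None) -> float:
    """Contrast-to-noise ratio |mu_t - mu_b| / sqrt(var_t + var_b).

    Computed on linear envelope amplitudes by default (pass a BModeImage to
    use dB-domain statistics instead).  Both ROIs must cover >= 25 pixels.
    """
    if grid is None:
        grid = image.grid
    vals = _values(image)
    t = vals[target.mask(grid)]
    b = vals[background.mask(grid)]
    if t.size < 25 or b.size < 25:
        raise ValueError("CNR ROIs must each cover at least 25 pixels")
    vt, vb = float(np.var(t)), float(np.var(b))
    if vt == 0.0 and vb == 0.0:
        raise ValueError("degenerate ROIs: zero variance in both regions")
    return abs(float(np.mean(t)) - float(np.mean(b))) / math.sqrt(vt + vb)


def speckle_snr(e, roi: RoiSpec | None = None, grid: ImagingGrid | None = None) -> float:
    """Mean over standard deviation of envelope amplitude in a homogeneous
    region; 1.91 characterizes fully developed (Rayleigh) speckle.

    ``e`` may be an EnvelopeImage (with an ROI covering >= 100 pixels) or a
    plain sample array.
    """
    if isinstance(e, EnvelopeImage):
        if roi is None:
            raise ValueError("an ROI is required for image input")
        vals = e.values[roi.mask(grid or e.grid)]
    else:
        vals = np.asarray(e, dtype=float).ravel()
    if vals.size < 100:
        raise ValueError("speckle SNR needs at least 100 samples")
    sd = float(np.std(vals))
    if sd == 0.0:
        raise ValueError("zero variance: speckle SNR undefined")
    return float(np.mean(vals)) / sd


# ---------------------------------------------------------------------------
# Beamwidth
# ---------------------------------------------------------------------------

def beamwidth(profile: LateralPowerProfile, level_db: float = -6.0) -> float:
    """Width (m) of the contiguous region around the profile maximum above
    (max + level_db), with linear-interpolated crossings."""
    if level_db >= 0:
        raise ValueError("level_db must be negative")
    p = profile.power_db
    x = profile.x
    peaks = np.flatnonzero(p == p.max())
    if peaks.size != 1:
        raise ValueError("profile must have a unique global maximum")
    i = int(peaks[0])
    thr = float(p.max()) + level_db

    def cross(direction: int) -> float:
        j = i
        while 0 <= j + direction < p.size and p[j + direction] > thr:
            j += direction
        k = j + direction
        if k < 0 or k >= p.size:
            raise ValueError("profile never crosses the level within its extent")
        # linear interpolation between (x[j], p[j]) and (x[k], p[k])
        frac = (p[j] - thr) / (p[j] - p[k])
        return float(x[j] + frac * (x[k] - x[j]))

    return cross(+1) - cross(-1)
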