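"""Plane-wave delay-and-sum beamforming with translated fixed-F-number
subapertures and pluggable receive apodizations.

The NSI receive apodizations live here: the zero-mean split aperture
(first N/2 weights +1, last N/2 weights -1, broadside null), the dc-offset
aperture (zero-mean plus a constant c) and its flipped counterpart, plus the
Hann taper and a uniform ("ones") aperture used as a linear-algebra basis:
for the same subaperture, dc_offset = zero_mean + c * ones and
dc_offset_flipped = -zero_mean + c * ones, so one pair of beamformed
datasets yields every dc offset for free.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .probe_model import ImagingGrid, PlaneWaveSequence, ProbeGeometry, element_positions

logger = logging.getLogger(__name__)

APODIZATION_KINDS = ("hann", "zero_mean", "dc_offset", "dc_offset_flipped", "ones")


@dataclass(frozen=True)
class ApodizationVector:
    """Receive weights over one even-length subaperture."""

    weights: np.ndarray
    kind: str
    c: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return int(self.weights.size)


def _hann_weights(n: int) -> np.ndarray:
    # symmetric (n+2)-point raised cosine with the zero endpoints dropped,
    # so every weight is strictly positive even for n = 2
    k = np.arange(1, n + 1, dtype=float)
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * k / (n + 1))


def make_apodization(kind: str, n: int, c: float = 0.0) -> ApodizationVector:
    """Build one of the supported receive apodizations over n elements.

    n must be even so the +1/-1 zero-mean split is exact; c >= 0 is the dc
    offset added to the zero-mean window.
    """
    if n < 2 or n % 2 != 0:
        raise ValueError("subaperture size n must be even and >= 2")
    if c < 0:
        raise ValueError("dc offset c must be >= 0")
    zm = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    if kind == "zero_mean":
        w = zm
    elif kind == "dc_offset":
        w = zm + c
    elif kind == "dc_offset_flipped":
        w = (zm + c)[::-1].copy()
    elif kind == "hann":
        w = _hann_weights(n)
    elif kind == "ones":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown apodization kind: {kind!r}")
    return ApodizationVector(weights=w, kind=kind, c=c)


# ---------------------------------------------------------------------------
# Subaperture bookkeeping
# ---------------------------------------------------------------------------

def subaperture_size(z: float, f_number: float, pitch: float) -> int:
    """N = round(z / (F# * pitch)), rounded up to even, at least 2."""
    n = int(round(z / (f_number * pitch)))
    if n % 2 != 0:
        n += 1
    return max(n, 2)


@dataclass(frozen=True)
class SubapertureSpan:
    """Element index range [start, stop) plus zero-pad counts on each side."""

    start: int
    stop: int
    pad_left: int
    pad_right: int

    @property
    def n(self) -> int:
        return self.stop - self.start + self.pad_left + self.pad_right


def _first_index(x_line: float, xe0: float, pitch: float, n_sub: int) -> int:
    # window whose geometric center is nearest the line; an even-N window is
    # exactly symmetric when the line sits midway between two elements (the
    # default grid), and lands half a pitch off for element-centered lines
    center_f = (x_line - xe0) / pitch
    return int(math.floor(center_f - (n_sub - 1) / 2.0 + 0.5))


def subaperture(
    grid: ImagingGrid,
    geometry: ProbeGeometry,
    line_index: int,
    depth_index: int,
) -> SubapertureSpan:
    """Element span of the fixed-F-number subaperture for one pixel.

    Indices falling outside the physical array are reported as zero-pad
    counts (the weights there contribute nothing and are not renormalized).
    """
    z = float(grid.z[depth_index])
    n_sub = subaperture_size(z, grid.f_number, geometry.pitch)
    xe = element_positions(geometry)
    first = _first_index(float(grid.x[line_index]), xe[0], geometry.pitch, n_sub)
    start = max(first, 0)
    stop = min(first + n_sub, geometry.n_elements)
    if stop < start:  # subaperture entirely off the array
        start = stop = min(max(first, 0), geometry.n_elements)
    return SubapertureSpan(
        start=start,
        stop=stop,
        pad_left=start - first,
        pad_right=(first + n_sub) - stop,
    )


# ---------------------------------------------------------------------------
# Beamformed container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamformedRF:
    """Beamformed RF indexed [depth, line, angle].

    ``angles_deg`` is None after coherent compounding (single summed angle).
    """

    data: np.ndarray
    grid: ImagingGrid
    kind: str
    c: float = 0.0
    angles_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("data must be indexed [depth, line, angle]")
        if d.shape[0] != self.grid.n_depths or d.shape[1] != self.grid.n_lines:
            raise ValueError("data shape inconsistent with grid")
        if not np.all(np.isfinite(d)):
            raise ValueError("beamformed data must be finite")
        object.__setattr__(self, "data", d)
        if self.angles_deg is not None:
            a = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
            if a.size != d.shape[2]:
                raise ValueError("angles_deg must match the angle axis")
            object.__setattr__(self, "angles_deg", a)

    @property
    def n_angles(self) -> int:
        return int(self.data.shape[2])

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("rf", data=self.data.astype(np.float32))
            ds.attrs["kind"] = self.kind
            ds.attrs["c"] = self.c
            ds.attrs["f_number"] = self.grid.f_number
            fh.create_dataset("x", data=self.grid.x)
            fh.create_dataset("z", data=self.grid.z)
            if self.angles_deg is not None:
                fh.create_dataset("angles_deg", data=self.angles_deg)

    @classmethod
    def load(cls, path) -> "BeamformedRF":
        with h5py.File(path, "r") as fh:
            ds = fh["rf"]
            grid = ImagingGrid(
                x=np.asarray(fh["x"]),
                z=np.asarray(fh["z"]),
                f_number=float(ds.attrs["f_number"]),
            )
            angles = (
                np.asarray(fh["angles_deg"]) if "angles_deg" in fh else None
            )
            return cls(
                data=np.asarray(ds[...], dtype=float),
                grid=grid,
                kind=str(ds.attrs["kind"]),
                c=float(ds.attrs["c"]),
                angles_deg=angles,
            )


# ---------------------------------------------------------------------------
# Delay-and-sum core
# ---------------------------------------------------------------------------

def _gather(
    channel, angle_index: int, x_line: float, z: np.ndarray, interp: str
) -> np.ndarray:
    """Delay-aligned channel samples for one scan line and angle, indexed
    [depth, element]; delays outside the recorded window contribute 0."""
    g = channel.geometry
    xe = element_positions(g)
    th = math.radians(float(channel.sequence.angles_deg[angle_index]))
    c0 = g.sound_speed
    tx = (x_line * math.sin(th) + z * math.cos(th)) / c0           # (nz,)
    rx = np.hypot(x_line - xe[None, :], z[:, None]) / c0           # (nz, E)
    f = (tx[:, None] + rx - channel.t0) * channel.sampling_frequency
    rf = channel.samples[:, :, angle_index]                        # (T, E)
    n_t = rf.shape[0]
    e_idx = np.arange(g.n_elements)[None, :]
    if interp == "linear":
        i0 = np.floor(f).astype(np.int64)
        frac = f - i0
        valid = (i0 >= 0) & (i0 + 1 < n_t)
        i0c = np.clip(i0, 0, n_t - 2)
        vals = (1.0 - frac) * rf[i0c, e_idx] + frac * rf[i0c + 1, e_idx]
    elif interp == "nearest":
        i0 = np.rint(f).astype(np.int64)
        valid = (i0 >= 0) & (i0 < n_t)
        i0c = np.clip(i0, 0, n_t - 1)
        vals = rf[i0c, e_idx]
    else:
        raise ValueError("interp must be 'linear' or 'nearest'")
    vals = np.where(valid, vals, 0.0)
    return vals


def _weight_mask(
    kind: str,
    c: float,
    n_sub: np.ndarray,
    first: np.ndarray,
    n_elements: int,
) -> np.ndarray:
    """Per-depth receive weights expanded onto the full element axis,
    indexed [depth, element]; zero outside the (clipped) subaperture."""
    pos = np.arange(n_elements)[None, :] - first[:, None]          # (nz, E)
    nn = n_sub[:, None]
    inside = (pos >= 0) & (pos < nn)
    if kind == "hann":
        w = 0.5 - 0.5 * np.cos(2.0 * np.pi * (pos + 1) / (nn + 1))
    elif kind == "zero_mean":
        w = np.where(pos < nn // 2, 1.0, -1.0)
    elif kind == "ones":
        w = np.ones_like(pos, dtype=float)
    elif kind == "dc_offset":
        w = np.where(pos < nn // 2, 1.0, -1.0) + c
    elif kind == "dc_offset_flipped":
        w = -np.where(pos < nn // 2, 1.0, -1.0) + c
    else:
        raise ValueError(f"unknown apodization kind: {kind!r}")
    return np.where(inside, w, 0.0)


def _line_geometry(grid: ImagingGrid, geometry: ProbeGeometry, line_index: int):
    """(n_sub(z), first(z)) index arrays for one scan line."""
    n_sub = np.array(
        [subaperture_size(z, grid.f_number, geometry.pitch) for z in grid.z],
        dtype=np.int64,
    )
    xe0 = float(element_positions(geometry)[0])
    x_line = float(grid.x[line_index])
    first = np.array(
        [_first_index(x_line, xe0, geometry.pitch, int(n)) for n in n_sub],
        dtype=np.int64,
    )
    return n_sub, first


def das_line(
    channel,
    grid: ImagingGrid,
    line_index: int,
    angle_index: int,
    kind: str = "hann",
    c: float = 0.0,
    interp: str = "linear",
) -> np.ndarray:
    """One delay-and-sum scan line (RF over depth) for one steering angle."""
    n_sub, first = _line_geometry(grid, channel.geometry, line_index)
    vals = _gather(channel, angle_index, float(grid.x[line_index]), grid.z, interp)
    w = _weight_mask(kind, c, n_sub, first, channel.geometry.n_elements)
    return np.sum(w * vals, axis=1)


def beamform_multi(
    channel,
    grid: ImagingGrid,
    specs: Sequence[tuple[str, float]],
    interp: str = "linear",
) -> list[BeamformedRF]:
    """Beamform all lines and angles for several apodizations at once,
    sharing the delay/interpolation work across apodizations."""
    g = channel.geometry
    n_a = channel.sequence.n_angles
    outs = [np.zeros((grid.n_depths, grid.n_lines, n_a)) for _ in specs]
    clipped = 0
    for li in range(grid.n_lines):
        n_sub, first = _line_geometry(grid, g, li)
        masks = [
            _weight_mask(kind, c, n_sub, first, g.n_elements) for kind, c in specs
        ]
        if np.any(first < 0) or np.any(first + n_sub > g.n_elements):
            clipped += 1
        x_line = float(grid.x[li])
        for a in range(n_a):
            vals = _gather(channel, a, x_line, grid.z, interp)
            for m, out in zip(masks, outs):
                out[:, li, a] = np.sum(m * vals, axis=1)
    if clipped:
        logger.debug(
            "subaperture clipped (zero-padded, not renormalized) on %d/%d lines",
            clipped, grid.n_lines,
        )
    return [
        BeamformedRF(
            data=out, grid=grid, kind=kind, c=c,
            angles_deg=channel.sequence.angles_deg,
        )
        for out, (kind, c) in zip(outs, specs)
    ]


def beamform(
    channel,
    grid: ImagingGrid,
    kind: str = "hann",
    c: float = 0.0,
    interp: str = "linear",
) -> BeamformedRF:
    """Delay-and-sum all scan lines for all angles with one apodization."""
    return beamform_multi(channel, grid, [(kind, c)], interp=interp)[0]


def coherent_compound(bf: BeamformedRF) -> BeamformedRF:
    """Sample-wise sum of beamformed RF across the angle axis."""
    if bf.n_angles < 1:
        raise ValueError("need at least one angle")
    summed = bf.data.sum(axis=2, keepdims=True)
    return dataclasses.replace(bf, data=summed, angles_deg=None)
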