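"""Generalized coherence factor (GCF) weighting of DAS output.

The GCF of a delayed, apodized subaperture vector is the fraction of its
discrete aperture-spectrum energy within the low-frequency bins |k| <= M0:
a coherent (focused) target concentrates energy near DC and keeps its DAS
value, while incoherent clutter spreads energy across the spectrum and is
suppressed.  Applied per pixel and per angle before coherent compounding.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .das_beamformer import _gather, _line_geometry, _weight_mask
from .nsi_engine import BModeImage, EnvelopeImage, envelope, log_compress
from .probe_model import ImagingGrid


@dataclass(frozen=True)
class GCFConfig:
    """M0 is the spectral cutoff in aperture-spectrum bins (DC plus M0 bins
    on each side); 2 is the empirical default for the bundled studies."""

    m0: int = 2

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise ValueError("M0 must be a nonnegative integer")


def _low_bins(n: int, m0: int) -> np.ndarray:
    """Unique DFT bin indices with |k| <= m0 modulo the spectrum length."""
    k = np.arange(-m0, m0 + 1)
    return np.unique(k % n)


def gcf_weight(samples, config: GCFConfig = GCFConfig()) -> float:
    """Spectral-energy ratio of one aperture vector, in [0, 1].

    w = sum_{|k| <= M0} |S(k)|^2 / sum_k |S(k)|^2 over the DFT S of the
    delayed, apodized subaperture samples; 0 when the vector has no energy.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("samples must be a non-empty 1-D vector")
    spec = np.fft.fft(s)
    power = np.abs(spec) ** 2
    total = float(power.sum())
    if total == 0.0:
        return 0.0
    return float(power[_low_bins(s.size, config.m0)].sum() / total)


def _gcf_weights_line(values: np.ndarray, n_sub: np.ndarray, first: np.ndarray,
                      n_elements: int, m0: int) -> np.ndarray:
    """Per-depth GCF weights for one line/angle given the already-apodized,
    delay-aligned element samples ``values`` [depth, element]."""
    nz = values.shape[0]
    w = np.zeros(nz)
    for n in np.unique(n_sub):
        rows = np.flatnonzero(n_sub == n)
        # the clipped subaperture keeps its nominal length n: out-of-array
        # positions are zero-padded, matching the DAS edge rule
        sub = np.zeros((rows.size, int(n)))
        for i, r in enumerate(rows):
            lo = int(first[r])
            a0, a1 = max(lo, 0), min(lo + int(n), n_elements)
            if a1 > a0:
                sub[i, a0 - lo : a1 - lo] = values[r, a0:a1]
        spec = np.fft.fft(sub, axis=1)
        power = np.abs(spec) ** 2
        total = power.sum(axis=1)
        low = power[:, _low_bins(int(n), m0)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0.0, low / np.maximum(total, 1e-300), 0.0)
        w[rows] = ratio
    return w


def gcf_envelope(
    channel, grid: ImagingGrid, config: GCFConfig = GCFConfig()
) -> EnvelopeImage:
    """GCF-weighted Hann-DAS envelope image.

    Per pixel and angle, the DAS (Hann) sum is multiplied by the GCF of the
    same Hann-apodized, delay-aligned subaperture; angles are then
    coherently compounded and the envelope detected.
    """
    g = channel.geometry
    n_a = channel.sequence.n_angles
    out = np.zeros((grid.n_depths, grid.n_lines))
    for li in range(grid.n_lines):
        n_sub, first = _line_geometry(grid, g, li)
        mask = _weight_mask("hann", 0.0, n_sub, first, g.n_elements)
        x_line = float(grid.x[li])
        acc = np.zeros(grid.n_depths)
        for a in range(n_a):
            vals = mask * _gather(channel, a, x_line, grid.z, "linear")
            das = vals.sum(axis=1)
            w = _gcf_weights_line(vals, n_sub, first, g.n_elements, config.m0)
            acc += w * das
        out[:, li] = acc
    return EnvelopeImage(values=envelope(out, axis=0), grid=grid)


def gcf_image(
    channel,
    grid: ImagingGrid,
    config: GCFConfig = GCFConfig(),
    dynamic_range: float = 60.0,
) -> BModeImage:
    """GCF-weighted B-mode image (max-normalized log compression)."""
    return log_compress(gcf_envelope(channel, grid, config), dynamic_range)
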