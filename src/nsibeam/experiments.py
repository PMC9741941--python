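"""Reproduction drivers for the bundled simulation studies.

These helpers wire the full pipeline together for the single-scatterer
grating-lobe studies: a wire-like point target at 5 mm depth under the
128-element, 0.3048 mm pitch, 7.82 MHz configuration, beamformed at
F-number 1.5.  They are what the command-line ``experiment`` subcommand and
the acceptance script run.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nsi_engine
from .das_beamformer import beamform_multi, coherent_compound
from .gcf_beamformer import GCFConfig, gcf_envelope
from .image_metrics import (
    axial_power_profile,
    beamwidth,
    grating_lobe_level,
    grating_windows_for,
    main_window_for,
)
from .nsi_engine import (
    AngularFilterSpec,
    EnvelopeImage,
    cnsi_envelope_from_basis,
    envelope_image,
    icnsi_envelope_from_basis,
    log_compress,
    nsi_basis,
)
from .probe_model import ImagingGrid, PlaneWaveSequence, l14_5_38, study_grid, study_sequence
from .rf_synthesizer import (
    ChannelData,
    PulseModel,
    add_noise,
    make_phantom,
    required_window,
    synthesize,
)

logger = logging.getLogger(__name__)

SCATTERER_DEPTH = 5e-3


def single_scatterer_channel(
    n_angles: int = 1,
    snr_db: float | None = None,
    seed: int = 0,
    geometry=None,
    grid: ImagingGrid | None = None,
    depth: float = SCATTERER_DEPTH,
) -> tuple[ChannelData, ImagingGrid]:
    """Simulate the single-scatterer study: one point target at (0, depth),
    n equally spaced steering angles over -16..+16 degrees, optional seeded
    additive noise at the given raw-data SNR."""
    if geometry is None:
        geometry = l14_5_38()
    if grid is None:
        grid = study_grid(geometry)
    sequence = study_sequence(n_angles)
    phantom = make_phantom("single_point", x=0.0, z=depth)
    pulse = PulseModel.for_probe(geometry)
    t_end = required_window(geometry, sequence, grid, pulse)
    channel = synthesize(geometry, sequence, phantom, pulse, t_end=t_end)
    if snr_db is not None:
        channel = add_noise(channel, snr_db, seed)
    return channel, grid


def gl_level_of(e: EnvelopeImage, geometry, scatterer_x: float = 0.0,
                depth: float = SCATTERER_DEPTH) -> float:
    """Grating-lobe level (dB re main lobe) of one envelope image using the
    default arcsin-predicted grating windows and +/-1 mm main window."""
    profile = axial_power_profile(e)
    return grating_lobe_level(
        profile,
        main_window_for(scatterer_x),
        grating_windows_for(geometry, scatterer_x, depth),
    )


def gl_study(
    dc_offsets=(0.1, 1.0),
    angle_counts=(1,),
    methods=("cnsi", "icnsi"),
    snr_db: float | None = None,
    seed: int = 0,
    geometry=None,
    grid: ImagingGrid | None = None,
) -> pd.DataFrame:
    """Grating-lobe levels and reductions over a dc-offset x angle-count
    sweep, against the Hann baseline with the same compounding.

    Returns a tidy frame with columns method, dc, n_angles, snr_db,
    gl_hann_db, gl_nsi_db, reduction_db.
    """
    if geometry is None:
        geometry = l14_5_38()
    if grid is None:
        grid = study_grid(geometry)
    rows = []
    for n_angles in angle_counts:
        channel, _ = single_scatterer_channel(
            n_angles=n_angles, snr_db=snr_db, seed=seed,
            geometry=geometry, grid=grid,
        )
        b_zm, b_ones = nsi_basis(channel, grid)
        b_hann = beamform_multi(channel, grid, [("hann", 0.0)])[0]
        gl_hann = gl_level_of(envelope_image(coherent_compound(b_hann)), geometry)
        for method, c in itertools.product(methods, dc_offsets):
            if method == "cnsi":
                e = cnsi_envelope_from_basis(b_zm, b_ones, c)
            elif method == "icnsi":
                e = icnsi_envelope_from_basis(b_zm, b_ones, c)
            else:
                raise ValueError(f"unknown NSI method: {method!r}")
            gl_nsi = gl_level_of(e, geometry)
            rows.append(
                dict(
                    method=method, dc=c, n_angles=n_angles, snr_db=snr_db,
                    seed=seed, gl_hann_db=gl_hann, gl_nsi_db=gl_nsi,
                    reduction_db=gl_hann - gl_nsi,
                )
            )
    return pd.DataFrame(rows)


def noisy_gl_study(
    snr_db_values=(0.0, 6.0, 12.0, 24.0),
    n_replicates: int = 3,
    dc: float = 1.0,
    base_seed: int = 0,
    n_angles: int = 1,
    geometry=None,
    grid: ImagingGrid | None = None,
) -> pd.DataFrame:
    """Grating-lobe reduction of C-NSI (fixed dc) versus raw-data SNR,
    replicated over seeds derived from ``base_seed``."""
    frames = []
    for snr in snr_db_values:
        for rep in range(n_replicates):
            seed = (base_seed * 1000 + int(round(snr)) * 10 + rep) % (2**31)
            frames.append(
                gl_study(
                    dc_offsets=(dc,), angle_counts=(n_angles,),
                    methods=("cnsi",), snr_db=snr, seed=seed,
                    geometry=geometry, grid=grid,
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Generic experiment runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one simulation experiment."""

    phantom_kind: str = "single_point"
    phantom_params: dict = field(default_factory=dict)
    angle_counts: tuple = (1,)
    methods: tuple = ("hann", "cnsi", "icnsi", "gcf")
    dc_offsets: tuple = (1.0,)
    m0: int = 2
    snr_db_values: tuple = (None,)
    seeds: tuple = (0,)
    dynamic_range: float = 60.0
    out_dir: str | None = None


def _method_envelope(method, channel, grid, c, m0):
    if method == "hann":
        return nsi_engine.das_envelope(channel, grid, "hann")
    if method == "cnsi":
        return nsi_engine.cnsi_envelope(channel, grid, c)
    if method == "icnsi":
        return nsi_engine.icnsi_envelope(channel, grid, c)
    if method == "gcf":
        return gcf_envelope(channel, grid, GCFConfig(m0))
    raise ValueError(f"unknown method: {method!r}")


def run_experiment(spec: ExperimentSpec, geometry=None, grid=None) -> pd.DataFrame:
    """Run every (angle count, SNR, seed, method, dc) combination of the
    spec; returns a tidy metrics table and, when ``out_dir`` is set, writes
    channel data, images and the table there.

    Deterministic given the spec's seeds.
    """
    if geometry is None:
        geometry = l14_5_38()
    if grid is None:
        grid = study_grid(geometry)
    out_dir = Path(spec.out_dir) if spec.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for n_angles, snr, seed in itertools.product(
        spec.angle_counts, spec.snr_db_values, spec.seeds
    ):
        logger.info(
            "stage=simulate phantom=%s angles=%d snr=%s seed=%d",
            spec.phantom_kind, n_angles, snr, seed,
        )
        sequence = study_sequence(n_angles)
        phantom = make_phantom(spec.phantom_kind, **spec.phantom_params)
        pulse = PulseModel.for_probe(geometry)
        t_end = required_window(geometry, sequence, grid, pulse)
        channel = synthesize(geometry, sequence, phantom, pulse, t_end=t_end)
        if snr is not None:
            channel = add_noise(channel, snr, seed)
        if out_dir:
            channel.save(out_dir / f"chan_a{n_angles}_snr{snr}_s{seed}.h5")
        hann_env = None
        for method in spec.methods:
            dcs = spec.dc_offsets if method in ("cnsi", "icnsi") else (np.nan,)
            for c in dcs:
                logger.info("stage=image method=%s dc=%s", method, c)
                env = _method_envelope(
                    method, channel, grid, c if np.isfinite(c) else 1.0, spec.m0
                )
                if method == "hann":
                    hann_env = env
                row = dict(
                    method=method, dc=c, n_angles=n_angles,
                    snr_db=snr, seed=seed,
                )
                if spec.phantom_kind == "single_point":
                    depth = float(spec.phantom_params.get("z", SCATTERER_DEPTH))
                    x0 = float(spec.phantom_params.get("x", 0.0))
                    gl = gl_level_of(env, geometry, x0, depth)
                    row["gl_level_db"] = gl
                    row["beamwidth_m"] = beamwidth(axial_power_profile(env))
                    if hann_env is not None and method != "hann":
                        row["reduction_db"] = (
                            gl_level_of(hann_env, geometry, x0, depth) - gl
                        )
                rows.append(row)
                if out_dir:
                    img = log_compress(env, spec.dynamic_range)
                    tag = f"{method}_dc{c}_a{n_angles}_snr{snr}_s{seed}"
                    np.save(out_dir / f"img_{tag}.npy", img.db_values)
    table = pd.DataFrame(rows)
    if out_dir:
        table.to_csv(out_dir / "metrics.csv", index=False)
    return table
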