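"""Shared fixtures: the single-scatterer study, its beamformed bases, the
dc/angle grating-lobe sweep, the noisy-channel sweep, and a speckle/cyst
phantom.  All simulation inputs are generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

import nsibeam as nb
from nsibeam.das_beamformer import beamform_multi, coherent_compound
from nsibeam.image_metrics import RoiSpec
from nsibeam.nsi_engine import (
    cnsi_envelope_from_basis,
    das_envelope,
    envelope_image,
    icnsi_envelope_from_basis,
    nsi_basis,
)
from nsibeam.probe_model import ImagingGrid, line_positions, study_grid, study_sequence
from nsibeam.rf_synthesizer import PulseModel, make_phantom, required_window, synthesize


@pytest.fixture(scope="session")
def geometry():
    return nb.l14_5_38()


@pytest.fixture(scope="session")
def point_study(geometry):
    """Noise-free single scatterer at (0, 5 mm), one 0-degree plane wave."""
    channel, grid = nb.single_scatterer_channel(n_angles=1)
    return channel, grid


@pytest.fixture(scope="session")
def point_basis(point_study):
    """Beamformed zero-mean/ones bases plus the Hann baseline and its
    envelope/grating-lobe level for the single-scatterer study."""
    channel, grid = point_study
    b_zm, b_ones = nsi_basis(channel, grid)
    b_hann = beamform_multi(channel, grid, [("hann", 0.0)])[0]
    e_hann = envelope_image(coherent_compound(b_hann))
    gl_hann = nb.experiments.gl_level_of(e_hann, channel.geometry)
    return dict(
        channel=channel, grid=grid, b_zm=b_zm, b_ones=b_ones,
        b_hann=b_hann, e_hann=e_hann, gl_hann=gl_hann,
    )


@pytest.fixture(scope="session")
def gl_sweep():
    """Noise-free grating-lobe reduction sweep: dc offsets x angle counts,
    both C-NSI and IC-NSI."""
    return nb.gl_study(
        dc_offsets=(1.0, 0.5, 0.1, 0.05),
        angle_counts=(1, 3, 9),
        methods=("cnsi", "icnsi"),
    )


@pytest.fixture(scope="session")
def noisy_sweep():
    """Seeded noisy-channel sweep at dc = 1.0 over raw-data SNRs."""
    return nb.noisy_gl_study(
        snr_db_values=(0.0, 6.0, 12.0, 24.0), n_replicates=3, dc=1.0, base_seed=1
    )


@pytest.fixture(scope="session")
def speckle_images(geometry):
    """Fully developed speckle with a hyperechoic circular inclusion,
    imaged with the 33-angle sequence: Hann, C-NSI and IC-NSI envelopes
    plus target/background ROIs."""
    phantom = make_phantom(
        "speckle_cyst",
        center_z=6.5e-3, width=7e-3, height=4e-3, density_per_mm2=120,
        circles=[(0.0, 6.5e-3, 1.2e-3, 3.0)], seed=7,
    )
    sequence = study_sequence(33)
    z = study_grid(geometry, z_min=5e-3, z_max=8e-3).z
    xs = line_positions(geometry)
    grid = ImagingGrid(x=xs[np.abs(xs) < 4e-3], z=z, f_number=1.5)
    pulse = PulseModel.for_probe(geometry)
    channel = synthesize(
        geometry, sequence, phantom, pulse,
        t_end=required_window(geometry, sequence, grid, pulse),
    )
    b_zm, b_ones = nsi_basis(channel, grid)
    return dict(
        hann=das_envelope(channel, grid, "hann"),
        cnsi=cnsi_envelope_from_basis(b_zm, b_ones, 1.0),
        icnsi=icnsi_envelope_from_basis(b_zm, b_ones, 1.0),
        background=RoiSpec("rect", (1.8e-3, 3.8e-3, 5.5e-3, 7.5e-3), "background"),
        target=RoiSpec("circle", (0.0, 6.5e-3, 0.9e-3), "target"),
    )
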