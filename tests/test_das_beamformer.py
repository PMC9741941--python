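"""Apodizations, subapertures, and the delay-and-sum engine."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nsibeam as nb
from nsibeam.das_beamformer import (
    beamform,
    beamform_multi,
    coherent_compound,
    das_line,
    make_apodization,
    subaperture,
    subaperture_size,
)
from nsibeam.nsi_engine import envelope
from nsibeam.probe_model import ImagingGrid, PlaneWaveSequence, ProbeGeometry
from nsibeam.rf_synthesizer import ChannelData, ScattererField, synthesize, two_way_delay


class TestApodizations:
    def test_zero_mean_split(self):
        a = make_apodization("zero_mean", 8)
        np.testing.assert_array_equal(a.weights, [1, 1, 1, 1, -1, -1, -1, -1])
        assert a.weights.sum() == 0.0

    def test_dc_offset_and_flip(self):
        d1 = make_apodization("dc_offset", 4, c=0.1)
        d2 = make_apodization("dc_offset_flipped", 4, c=0.1)
        np.testing.assert_allclose(d1.weights, [1.1, 1.1, -0.9, -0.9])
        np.testing.assert_allclose(d2.weights, d1.weights[::-1])
        assert np.mean(d1.weights) == pytest.approx(0.1)

    def test_hann_positive_and_symmetric(self):
        w = make_apodization("hann", 6).weights
        assert np.all(w > 0)
        np.testing.assert_allclose(w, w[::-1])
        assert np.all(make_apodization("hann", 2).weights > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_apodization("zero_mean", 7)
        with pytest.raises(ValueError):
            make_apodization("tukey", 8)
        with pytest.raises(ValueError):
            make_apodization("dc_offset", 4, c=-0.5)

    @given(
        st.integers(min_value=1, max_value=32).map(lambda k: 2 * k),
        st.floats(min_value=0.0, max_value=2.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_exact_mean_properties(self, n, c):
        assert make_apodization("zero_mean", n).weights.sum() == 0.0
        assert np.mean(make_apodization("dc_offset", n, c).weights) == pytest.approx(
            c, abs=1e-12
        )


class TestSubaperture:
    def test_size_rule_at_5mm(self):
        # z / (F# * pitch) = 5 / (1.5 * 0.3048) = 10.94 -> 12 after the
        # round-then-even rule
        assert subaperture_size(5e-3, 1.5, 0.3048e-3) == 12

    def test_size_rounds_to_even_at_least_two(self):
        assert subaperture_size(10.2e-3, 1.5, 1e-3) == 8  # 6.8 -> 7 -> 8
        assert subaperture_size(0.1e-3, 1.5, 1e-3) == 2

    def test_centered_span_on_midpoint_line(self):
        g = nb.l14_5_38()
        grid = nb.study_grid(g)
        li = int(np.argmin(np.abs(grid.x)))  # the x = 0 line
        iz = int(np.argmin(np.abs(grid.z - 5e-3)))
        span = subaperture(grid, g, li, iz)
        assert span.pad_left == span.pad_right == 0
        assert span.stop - span.start == 12
        xe = nb.element_positions(g)
        center = 0.5 * (xe[span.start] + xe[span.stop - 1])
        assert center == pytest.approx(grid.x[li], abs=1e-12)

    def test_edge_line_is_zero_padded(self):
        g = nb.l14_5_38()
        grid = nb.study_grid(g)
        span = subaperture(grid, g, 0, grid.n_depths - 1)
        assert span.pad_left > 0
        assert span.pad_left + (span.stop - span.start) + span.pad_right == span.n


def _toy_setup(seed=0):
    probe = ProbeGeometry(
        n_elements=4, pitch=1e-3, center_frequency=2e6,
        sampling_frequency=10e6, sound_speed=1500.0,
    )
    rng = np.random.default_rng(seed)
    seq = PlaneWaveSequence(np.array([0.0]))
    chan = ChannelData(rng.standard_normal((64, 4, 1)), 0.0, 10e6, seq, probe)
    grid = ImagingGrid(x=[-0.5e-3, 0.5e-3], z=[1.5e-3, 2.2e-3, 3.1e-3], f_number=1.0)
    return probe, chan, grid


class TestDasCore:
    def test_matches_exhaustive_loop_oracle(self):
        """Nearest-sample DAS equals a per-element explicit loop built from
        subaperture(), make_apodization() and two_way_delay()."""
        probe, chan, grid = _toy_setup()
        for kind, c in [("hann", 0.0), ("zero_mean", 0.0), ("dc_offset", 0.3)]:
            for li in range(grid.n_lines):
                line = das_line(chan, grid, li, 0, kind, c, interp="nearest")
                for iz, z in enumerate(grid.z):
                    span = subaperture(grid, probe, li, iz)
                    apod = make_apodization(kind, span.n, c)
                    acc = 0.0
                    for k in range(span.n):
                        e = span.start - span.pad_left + k
                        if not (0 <= e < probe.n_elements):
                            continue
                        tau = two_way_delay(probe, 0.0, (grid.x[li], z), e)
                        i = int(round(tau * chan.sampling_frequency))
                        if 0 <= i < chan.n_samples:
                            acc += apod.weights[k] * chan.samples[i, e, 0]
                    assert line[iz] == pytest.approx(acc, rel=1e-9, abs=1e-12)

    def test_linear_in_apodization_weights(self):
        probe, chan, grid = _toy_setup(1)
        c = 0.7
        b_zm = beamform(chan, grid, "zero_mean")
        b_ones = beamform(chan, grid, "ones")
        b_dc = beamform(chan, grid, "dc_offset", c)
        b_flip = beamform(chan, grid, "dc_offset_flipped", c)
        np.testing.assert_allclose(
            b_dc.data, b_zm.data + c * b_ones.data, rtol=1e-12, atol=1e-12
        )
        np.testing.assert_allclose(
            b_flip.data, -b_zm.data + c * b_ones.data, rtol=1e-12, atol=1e-12
        )

    def test_linear_in_channel_data(self):
        probe, chan, grid = _toy_setup(2)
        doubled = dataclasses.replace(chan, samples=2.0 * chan.samples)
        a = beamform(chan, grid, "hann")
        b = beamform(doubled, grid, "hann")
        np.testing.assert_allclose(b.data, 2.0 * a.data, rtol=1e-12)

    def test_beamform_multi_matches_individual(self):
        probe, chan, grid = _toy_setup(3)
        multi = beamform_multi(chan, grid, [("hann", 0.0), ("zero_mean", 0.0)])
        np.testing.assert_array_equal(multi[0].data, beamform(chan, grid, "hann").data)
        np.testing.assert_array_equal(
            multi[1].data, beamform(chan, grid, "zero_mean").data
        )


class TestFocusingProperties:
    def test_hann_line_peaks_at_scatterer_depth(self, point_basis):
        grid = point_basis["grid"]
        e = point_basis["e_hann"].values
        li = int(np.argmin(np.abs(grid.x)))
        iz = int(np.argmax(e[:, li]))
        assert abs(grid.z[iz] - 5e-3) < 2 * (grid.z[1] - grid.z[0])

    def test_zero_mean_broadside_notch_at_least_30_db(self, point_basis):
        """The split aperture nulls the on-axis target relative to Hann."""
        grid = point_basis["grid"]
        li = int(np.argmin(np.abs(grid.x)))
        iz = int(np.argmin(np.abs(grid.z - 5e-3)))
        e_h = point_basis["e_hann"].values
        e_zm = envelope(point_basis["b_zm"].data[:, :, 0])
        # compare within a small depth neighborhood of the wire
        sl = slice(max(iz - 4, 0), iz + 5)
        peak_h = e_h[sl, li].max()
        peak_zm = e_zm[sl, li].max()
        with np.errstate(divide="ignore"):
            notch_db = 20 * np.log10(peak_zm / peak_h)
        assert notch_db <= -30.0


class TestCoherentCompound:
    def test_single_angle_unchanged(self):
        _, chan, grid = _toy_setup(4)
        bf = beamform(chan, grid, "hann")
        np.testing.assert_array_equal(coherent_compound(bf).data, bf.data)

    def test_duplicated_angle_doubles(self):
        _, chan, grid = _toy_setup(5)
        bf = beamform(chan, grid, "hann")
        two = dataclasses.replace(
            bf, data=np.concatenate([bf.data, bf.data], axis=2),
            angles_deg=np.array([0.0, 1.0]),
        )
        np.testing.assert_allclose(coherent_compound(two).data, 2.0 * bf.data)

    def test_symmetric_angles_give_symmetric_profile(self):
        """Compounding -theta and +theta for a centered scatterer yields a
        laterally symmetric envelope profile."""
        probe = ProbeGeometry(
            n_elements=32, pitch=0.3048e-3, center_frequency=7.82e6,
            sampling_frequency=31.28e6,
        )
        seq = PlaneWaveSequence(np.array([-10.0, 10.0]))
        field = ScattererField(np.array([[0.0, 4e-3]]), np.array([1.0]))
        chan = synthesize(probe, seq, field)
        xl = nb.probe_model.line_positions(probe)
        grid = ImagingGrid(x=xl, z=np.linspace(3e-3, 5e-3, 81), f_number=1.5)
        e = envelope(coherent_compound(beamform(chan, grid, "hann")).data[:, :, 0])
        profile = np.sum(e**2, axis=0)
        np.testing.assert_allclose(profile, profile[::-1], rtol=0.05, atol=1e-6)


def test_beamformed_hdf5_round_trip(tmp_path):
    _, chan, grid = _toy_setup(6)
    bf = beamform(chan, grid, "dc_offset", 0.4)
    path = tmp_path / "bf.h5"
    bf.save(path)
    loaded = nb.BeamformedRF.load(path)
    np.testing.assert_allclose(loaded.data, bf.data, rtol=1e-6, atol=1e-7)
    assert loaded.kind == "dc_offset" and loaded.c == pytest.approx(0.4)
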