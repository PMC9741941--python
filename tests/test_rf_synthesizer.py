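"""Channel-data synthesis: delays, linearity, noise calibration, phantoms."""
import math

import numpy as np
import pytest

import nsibeam as nb
from nsibeam.probe_model import PlaneWaveSequence, ProbeGeometry
from nsibeam.rf_synthesizer import (
    ChannelData,
    PulseModel,
    ScattererField,
    add_noise,
    make_phantom,
    synthesize,
    two_way_delay,
)


@pytest.fixture
def probe():
    return ProbeGeometry(
        n_elements=8, pitch=1e-3, center_frequency=2e6,
        sampling_frequency=20e6, sound_speed=1500.0,
    )


def wavefront_delay_oracle(geometry, angle_deg, xz, element_index):
    """Geometric oracle: signed distance from the scatterer to the transmit
    wavefront plane through the origin, plus the Euclidean return path."""
    th = math.radians(angle_deg)
    normal = np.array([math.sin(th), math.cos(th)])  # propagation direction
    d_tx = float(np.dot(normal, xz))
    xe = nb.element_positions(geometry)[element_index]
    d_rx = math.dist((xz[0], xz[1]), (xe, 0.0))
    return (d_tx + d_rx) / geometry.sound_speed


class TestTwoWayDelay:
    def test_broadside_on_axis_round_trip(self, probe):
        # element at x=+0.5 mm is nearest to axis; use a probe with odd
        # geometry by checking the analytic form instead
        tau = two_way_delay(probe, 0.0, (0.5e-3, 5e-3), 4)
        assert tau == pytest.approx(2 * 5e-3 / 1500.0, rel=1e-6)

    def test_three_four_five_triangle(self, probe):
        # scatterer 4 mm deep, element 3 mm off: 4 mm down + 5 mm return
        tau = two_way_delay(probe, 0.0, (0.5e-3, 4e-3), 7)  # element at +3.5mm
        d_rx = math.hypot(3e-3, 4e-3)
        assert tau == pytest.approx((4e-3 + d_rx) / 1500.0, rel=1e-9)
        assert tau == pytest.approx(6.0e-6, rel=1e-6)

    def test_steered_matches_geometric_oracle(self, probe):
        tau = two_way_delay(probe, 16.0, (2e-3, 5e-3), 0)
        assert tau == pytest.approx(
            wavefront_delay_oracle(probe, 16.0, (2e-3, 5e-3), 0), rel=1e-12
        )

    def test_mirror_reciprocity_at_broadside(self, probe):
        # mirroring both scatterer x and element x leaves tau unchanged
        a = two_way_delay(probe, 0.0, (1.2e-3, 6e-3), 1)  # element at -2.5mm
        b = two_way_delay(probe, 0.0, (-1.2e-3, 6e-3), 6)  # element at +2.5mm
        assert a == pytest.approx(b, rel=1e-14)

    def test_nonpositive_depth_rejected(self, probe):
        with pytest.raises(ValueError):
            two_way_delay(probe, 0.0, (0.0, 0.0), 0)


class TestSynthesize:
    def test_envelope_peak_time_matches_delay(self, probe):
        from scipy.signal import hilbert

        seq = PlaneWaveSequence(np.array([0.0]))
        field = ScattererField(np.array([[0.5e-3, 5e-3]]), np.array([1.0]))
        chan = synthesize(probe, seq, field)
        env = np.abs(hilbert(chan.samples[:, 4, 0]))
        t_peak = np.argmax(env) / chan.sampling_frequency
        tau = two_way_delay(probe, 0.0, (0.5e-3, 5e-3), 4)
        assert abs(t_peak - tau) <= 1.0 / chan.sampling_frequency

    def test_linearity_in_amplitude_and_superposition(self, probe):
        seq = PlaneWaveSequence(np.array([-5.0, 5.0]))
        f1 = ScattererField(np.array([[0.0, 4e-3]]), np.array([1.0]))
        f2 = ScattererField(np.array([[1e-3, 6e-3]]), np.array([0.7]))
        union = ScattererField(
            np.vstack([f1.positions, f2.positions]),
            np.concatenate([f1.amplitudes, f2.amplitudes]),
        )
        t_end = 12e-6
        c1 = synthesize(probe, seq, f1, t_end=t_end)
        c2 = synthesize(probe, seq, f2, t_end=t_end)
        cu = synthesize(probe, seq, union, t_end=t_end)
        np.testing.assert_allclose(
            cu.samples, c1.samples + c2.samples, rtol=0, atol=1e-12
        )
        # two coincident unit scatterers = exactly twice one
        double = ScattererField(
            np.repeat(f1.positions, 2, axis=0), np.ones(2)
        )
        cd = synthesize(probe, seq, double, t_end=t_end)
        np.testing.assert_allclose(cd.samples, 2.0 * c1.samples, rtol=0, atol=1e-12)

    def test_zero_amplitude_gives_zero_channel(self, probe):
        seq = PlaneWaveSequence(np.array([0.0]))
        field = ScattererField(np.array([[0.0, 4e-3]]), np.array([0.0]))
        chan = synthesize(probe, seq, field)
        assert np.all(chan.samples == 0.0)

    def test_scatterer_beyond_window_excluded_with_warning(self, probe, caplog):
        seq = PlaneWaveSequence(np.array([0.0]))
        field = ScattererField(
            np.array([[0.0, 4e-3], [0.0, 50e-3]]), np.array([1.0, 1.0])
        )
        near_only = ScattererField(np.array([[0.0, 4e-3]]), np.array([1.0]))
        with caplog.at_level("WARNING"):
            chan = synthesize(probe, seq, field, t_end=8e-6)
        assert any("excluded" in r.message for r in caplog.records)
        ref = synthesize(probe, seq, near_only, t_end=8e-6)
        np.testing.assert_allclose(chan.samples, ref.samples)

    def test_empty_field_rejected(self, probe):
        with pytest.raises(ValueError):
            ScattererField(np.empty((0, 2)), np.empty(0))


class TestAddNoise:
    def _big_channel(self, probe, seed=0):
        rng = np.random.default_rng(seed)
        seq = PlaneWaveSequence(np.linspace(-16, 16, 33))
        samples = rng.standard_normal((400, probe.n_elements, 33))
        return ChannelData(samples, 0.0, probe.sampling_frequency, seq, probe)

    def test_zero_db_matches_signal_power_within_one_percent(self, probe):
        chan = self._big_channel(probe)
        noisy = add_noise(chan, 0.0, seed=3)
        p_sig = np.mean(chan.samples**2)
        p_noise = np.mean((noisy.samples - chan.samples) ** 2)
        assert chan.samples.size >= 10**5
        assert p_noise == pytest.approx(p_sig, rel=0.01)

    def test_infinite_snr_is_identity(self, probe):
        chan = self._big_channel(probe)
        np.testing.assert_array_equal(add_noise(chan, None, 0).samples, chan.samples)
        np.testing.assert_array_equal(
            add_noise(chan, np.inf, 0).samples, chan.samples
        )

    def test_same_seed_bit_identical(self, probe):
        chan = self._big_channel(probe)
        a = add_noise(chan, 6.0, seed=11)
        b = add_noise(chan, 6.0, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = add_noise(chan, 6.0, seed=12)
        assert not np.array_equal(a.samples, c.samples)

    def test_all_zero_signal_rejected(self, probe):
        seq = PlaneWaveSequence(np.array([0.0]))
        chan = ChannelData(
            np.zeros((10, probe.n_elements, 1)), 0.0,
            probe.sampling_frequency, seq, probe,
        )
        with pytest.raises(ValueError):
            add_noise(chan, 10.0, seed=0)


class TestPhantoms:
    def test_single_point_default(self):
        f = make_phantom("single_point")
        assert f.n_scatterers == 1
        np.testing.assert_allclose(f.positions[0], [0.0, 5e-3])

    def test_anechoic_circle_zeroes_amplitudes(self):
        f = make_phantom(
            "speckle_cyst", center_z=10e-3, width=10e-3, height=10e-3,
            density_per_mm2=5, circles=[(0.0, 10e-3, 2e-3, 0.0)], seed=1,
        )
        inside = (f.positions[:, 0] ** 2 + (f.positions[:, 1] - 10e-3) ** 2
                  <= (2e-3) ** 2)
        assert inside.sum() > 0
        assert np.all(f.amplitudes[inside] == 0.0)
        outside_sd = np.std(f.amplitudes[~inside])
        assert outside_sd == pytest.approx(1.0, rel=0.1)

    def test_density_gives_ceil_count(self):
        f = make_phantom(
            "speckle_cyst", center_z=10e-3, width=3e-3, height=2e-3,
            density_per_mm2=7.3, seed=0,
        )
        assert f.n_scatterers == math.ceil(7.3 * 3.0 * 2.0)

    def test_wire_grid_lattice(self):
        f = make_phantom(
            "wire_grid", x_positions=[-1e-3, 1e-3], z_positions=[5e-3, 10e-3, 15e-3]
        )
        assert f.n_scatterers == 6
        assert np.all(f.amplitudes == 1.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_phantom("blood_vessel")


def test_channel_hdf5_round_trip(tmp_path, probe):
    seq = PlaneWaveSequence(np.array([-3.0, 0.0, 3.0]))
    field = ScattererField(np.array([[0.0, 4e-3]]), np.array([1.0]))
    chan = synthesize(probe, seq, field)
    path = tmp_path / "chan.h5"
    chan.save(path)
    loaded = nb.ChannelData.load(path)
    np.testing.assert_allclose(loaded.samples, chan.samples, rtol=1e-6, atol=1e-7)
    assert loaded.sampling_frequency == chan.sampling_frequency
    assert loaded.geometry.pitch == probe.pitch
    np.testing.assert_allclose(loaded.sequence.angles_deg, seq.angles_deg)
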