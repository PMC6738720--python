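"""EMG engine: fiber potentials, MUAPs, montage, synthesis, features."""

import numpy as np
import pytest

from emgsim.ap_source import APModel, FiberSourceParams, build_source_train
from emgsim.emg import (
    MUAP,
    EMGRecord,
    apply_montage,
    compose_muap,
    electrical_profile,
    fiber_potential,
    pickup_radius,
    signal_features,
    spike_triggered_average,
    synthesize_emg,
)
from emgsim.volume_conductor import LeadField, analytic_infinite_potential


def _straight_fiber_lead(length_mm, depth_mm, sigma=0.28, electrode_x=None):
    """Lead field of a point electrode above a straight fiber (infinite
    isotropic medium), sampled on the 0.1 mm arc grid."""
    arc = np.arange(0.0, length_mm + 0.05, 0.1)
    ex = length_mm / 2 if electrode_x is None else electrode_x
    pts = np.column_stack([arc, np.zeros_like(arc), np.full_like(arc, -depth_mm)])
    vals = analytic_infinite_potential(pts, [ex, 0.0, 0.0], 1.0, sigma)
    return LeadField("e", pts, np.atleast_1d(vals), arc_mm=arc)


class TestFiberPotential:
    def test_constant_lead_gives_zero(self):
        tr = build_source_train(30.0, 15.0)
        arc = np.arange(0.0, 30.05, 0.1)
        lead = LeadField("e", None, np.full_like(arc, 7.3), arc_mm=arc)
        w = fiber_potential(tr, lead)
        peak_cur = np.abs(tr.currents).max()
        assert np.abs(w).max() < 1e-12 * peak_cur * 7.3 * len(arc)

    def test_matches_direct_summation_oracle(self):
        # brute force: evaluate the analytic point-source potential at
        # every source position and instant, no interpolation machinery
        tr = build_source_train(30.0, 15.0)
        lead = _straight_fiber_lead(30.0, 8.0)
        w = fiber_potential(tr, lead)
        pts = np.column_stack(
            [
                tr.positions_mm,
                np.zeros_like(tr.positions_mm),
                np.full_like(tr.positions_mm, -8.0),
            ]
        )
        h_exact = np.atleast_1d(
            analytic_infinite_potential(pts, [15.0, 0.0, 0.0], 1.0, 0.28)
        )
        w_oracle = tr.currents @ h_exact
        rms = np.sqrt(np.mean((w - w_oracle) ** 2))
        assert rms < 0.005 * np.sqrt(np.mean(w_oracle**2))

    def test_doubling_velocity_halves_duration(self):
        lead = _straight_fiber_lead(30.0, 8.0)
        durations = {}
        for u in (2.0, 4.0):
            tr = build_source_train(
                30.0, 15.0, FiberSourceParams(conduction_velocity=u)
            )
            w = np.abs(fiber_potential(tr, lead))
            above = tr.times[w > 0.01 * w.max()]
            durations[u] = above.max() - above.min()
        assert abs(durations[2.0] / durations[4.0] - 2.0) < 0.1

    def test_linearity_in_source_currents(self):
        tr = build_source_train(30.0, 15.0)
        lead = _straight_fiber_lead(30.0, 8.0)
        w1 = fiber_potential(tr, lead)
        tr.currents = 3.0 * tr.currents
        np.testing.assert_allclose(fiber_potential(tr, lead), 3.0 * w1, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        tr = build_source_train(30.0, 15.0)
        lead = _straight_fiber_lead(20.0, 8.0)
        with pytest.raises(ValueError):
            fiber_potential(tr, lead)


class TestComposeMuap:
    def test_single_fiber_unit_equals_fiber_potential(self):
        tr = build_source_train(30.0, 15.0)
        lead = _straight_fiber_lead(30.0, 8.0)
        m = compose_muap([tr], [[lead]], fs=20000.0)
        w = fiber_potential(tr, lead)
        tgrid = np.arange(m.waveforms.shape[1]) / 20000.0
        np.testing.assert_allclose(
            m.waveforms[0], np.interp(tgrid, tr.times, w, left=0, right=0),
            atol=1e-18,
        )

    def test_mirror_symmetric_fibers_double_the_potential(self):
        tr1 = build_source_train(30.0, 15.0)
        tr2 = build_source_train(30.0, 15.0)
        lead = _straight_fiber_lead(30.0, 8.0)
        m1 = compose_muap([tr1], [[lead]])
        m2 = compose_muap([tr1, tr2], [[lead], [lead]])
        np.testing.assert_allclose(
            m2.waveforms, 2.0 * m1.waveforms, rtol=1e-3, atol=1e-20
        )

    def test_deep_unit_smaller_than_shallow(self):
        trs = [build_source_train(30.0, 15.0) for _ in range(5)]
        shallow = compose_muap(trs, [[_straight_fiber_lead(30.0, 4.0)]] * 5)
        deep = compose_muap(trs, [[_straight_fiber_lead(30.0, 10.0)]] * 5)
        assert deep.peak_to_peak[0] < shallow.peak_to_peak[0]


class TestMontage:
    def test_common_mode_rejection(self):
        w = np.tile(np.sin(np.linspace(0, 5, 100)), (5, 1))
        np.testing.assert_allclose(apply_montage(w), 0.0, atol=1e-15)

    def test_zero_center_passthrough(self):
        w = np.random.default_rng(0).normal(size=(5, 50))
        w[4] = 0.0
        np.testing.assert_array_equal(apply_montage(w), w[:4])

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 40)), rng.normal(size=(5, 40))
        np.testing.assert_allclose(
            apply_montage(a + b), apply_montage(a) + apply_montage(b), rtol=1e-12
        )

    def test_double_differential_option(self):
        w = np.random.default_rng(2).normal(size=(5, 30))
        dd = apply_montage(w, scheme="double_differential")
        assert dd.shape == (2, 30)
        np.testing.assert_allclose(dd[0], w[0] - 2 * w[4] + w[2], rtol=1e-12)

    def test_wrong_electrode_count_rejected(self):
        with pytest.raises(ValueError):
            apply_montage(np.zeros((4, 10)))


class TestSynthesizeEmg:
    def _toy_muap(self, n=40, amp=1.0):
        w = amp * np.sin(np.linspace(0, 2 * np.pi, n))[None, :]
        return MUAP(waveforms=w, fs=20000.0, unit_index=1)

    def test_single_spike_is_delayed_muap(self):
        m = self._toy_muap()
        t0 = 0.01
        rec = synthesize_emg(
            {1: m}, {1: np.array([t0])}, duration_s=0.05,
            noise_sigma_v=0.0, band_hz=None,
        )
        i0 = int(round(t0 * 20000))
        np.testing.assert_allclose(
            rec.channels[0, i0 : i0 + 40], m.waveforms[0], atol=1e-15
        )
        assert np.abs(rec.channels[0, :i0]).max() < 1e-12

    def test_disjoint_units_superpose_exactly(self):
        m1, m2 = self._toy_muap(), self._toy_muap(amp=2.0)
        r1 = synthesize_emg({1: m1}, {1: np.array([0.01])}, duration_s=0.1,
                            noise_sigma_v=0.0, band_hz=None)
        r2 = synthesize_emg({2: m2}, {2: np.array([0.05])}, duration_s=0.1,
                            noise_sigma_v=0.0, band_hz=None)
        r12 = synthesize_emg(
            {1: m1, 2: m2},
            {1: np.array([0.01]), 2: np.array([0.05])},
            duration_s=0.1, noise_sigma_v=0.0, band_hz=None,
        )
        np.testing.assert_allclose(
            r12.channels, r1.channels + r2.channels, atol=1e-18
        )

    def test_noise_sigma_calibration(self):
        rec = synthesize_emg(
            {1: self._toy_muap(amp=0.0)}, {1: np.array([])},
            duration_s=25.0, noise_sigma_v=4.217e-6, band_hz=None, seed=5,
        )
        assert abs(rec.channels.std() / 4.217e-6 - 1.0) < 0.02

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            synthesize_emg(
                {1: self._toy_muap()}, {1: np.array([0.01])},
                duration_s=0.1, fs=3000.0, band_hz=(20.0, 2000.0),
            )


class TestSignalFeatures:
    def test_sine_rms_and_median_frequency(self):
        fs = 20000.0
        t = np.arange(int(5 * fs)) / fs
        x = 2.0 * np.sin(2 * np.pi * 150.0 * t)
        rec = EMGRecord(channels=x[None, :], fs=fs)
        f = signal_features(rec)
        assert abs(f["rms_v"] - 2.0 / np.sqrt(2)) < 1e-3
        assert abs(f["median_frequency_hz"] - 150.0) < 2.0

    def test_white_noise_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=int(25 * 20000))
        rec = EMGRecord(channels=x[None, :], fs=20000.0)
        f = signal_features(rec)
        assert abs(f["kurtosis"] - 3.0) < 0.1
        assert abs(f["skewness"]) < 0.05

    def test_polarity_flip_only_changes_skewness_sign(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=int(2 * 20000)) ** 3  # skewed signal
        ra = EMGRecord(channels=x[None, :], fs=20000.0)
        rb = EMGRecord(channels=-x[None, :], fs=20000.0)
        fa, fb = signal_features(ra), signal_features(rb)
        assert fa["rms_v"] == pytest.approx(fb["rms_v"])
        assert fa["kurtosis"] == pytest.approx(fb["kurtosis"])
        assert fa["median_frequency_hz"] == pytest.approx(
            fb["median_frequency_hz"]
        )
        assert fa["skewness"] == pytest.approx(-fb["skewness"])

    def test_too_short_record_rejected(self):
        rec = EMGRecord(channels=np.zeros((1, 100)), fs=20000.0)
        with pytest.raises(ValueError):
            signal_features(rec)


class TestSpikeTriggeredAverage:
    def _record_with_spikes(self, muap, spikes, noise=0.0, seed=0):
        return synthesize_emg(
            {1: muap}, {1: spikes}, duration_s=float(spikes.max() + 0.1),
            noise_sigma_v=noise, band_hz=None, seed=seed,
        )

    def test_noise_free_sta_recovers_muap(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 40))[None, :]
        m = MUAP(waveforms=w, fs=20000.0)
        spikes = np.arange(0.1, 2.0, 0.137)
        rec = self._record_with_spikes(m, spikes)
        sta = spike_triggered_average(rec, {1: spikes}, 1, (0.0, 40 / 20000.0))
        np.testing.assert_allclose(sta[0], w[0], atol=1e-10)

    def test_sta_residual_scales_with_spike_count(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 40))[None, :] * 1e-5
        m = MUAP(waveforms=w, fs=20000.0)
        sigma = 2e-6

        def residual(n_spikes, seed):
            spikes = np.arange(0.1, 0.1 + 0.05 * n_spikes, 0.05)
            rec = self._record_with_spikes(m, spikes, noise=sigma, seed=seed)
            sta = spike_triggered_average(
                rec, {1: spikes}, 1, (0.0, 40 / 20000.0)
            )
            return np.sqrt(np.mean((sta[0] - w[0]) ** 2))

        r100 = np.mean([residual(100, s) for s in range(3)])
        r400 = np.mean([residual(400, s) for s in range(3, 6)])
        assert abs(r400 / r100 - 0.5) < 0.2 * 0.5 + 0.05

    def test_asynchronous_units_give_low_crosstalk(self):
        rng = np.random.default_rng(7)
        w1 = np.sin(np.linspace(0, 2 * np.pi, 40))[None, :] * 1e-5
        w2 = np.cos(np.linspace(0, 4 * np.pi, 40))[None, :] * 1e-5
        m1 = MUAP(waveforms=w1, fs=20000.0)
        m2 = MUAP(waveforms=w2, fs=20000.0)
        s1 = np.cumsum(rng.uniform(0.04, 0.06, 250)) + 0.1
        s2 = np.cumsum(rng.uniform(0.03, 0.05, 250)) + 0.1
        rec = synthesize_emg(
            {1: m1, 2: m2}, {1: s1, 2: s2},
            duration_s=float(max(s1.max(), s2.max()) + 0.1),
            noise_sigma_v=0.0, band_hz=None,
        )
        sta = spike_triggered_average(rec, {1: s1}, 1, (0.0, 40 / 20000.0))
        bias = np.sqrt(np.mean((sta[0] - w1[0]) ** 2))
        assert bias < 0.1 * np.sqrt(np.mean(w1**2))

    def test_too_few_spikes_rejected(self):
        rec = EMGRecord(channels=np.zeros((1, 1000)), fs=20000.0)
        with pytest.raises(ValueError):
            spike_triggered_average(rec, {1: np.array([0.01])}, 1, (0, 0.002))


class TestProfileMap:
    def test_profile_needs_no_extra_solves(self):
        # the map is assembled purely from existing lead-field samples
        grid = np.column_stack(
            [np.linspace(-5, 5, 21), np.zeros(21)]
        )
        pts3 = np.column_stack([grid[:, 0], grid[:, 1], -np.full(21, 6.0)])
        leads = [
            LeadField(
                f"e{k}",
                pts3,
                np.atleast_1d(
                    analytic_infinite_potential(pts3, [xk, 0, 0], 1.0, 0.28)
                ),
            )
            for k, xk in enumerate(np.linspace(-2.5, 2.5, 5))
        ]
        pmap = electrical_profile(leads, grid, np.array([0.0, 0.0]))
        assert pmap.values.max() == pytest.approx(1.0)
        # decays away from the array's projection
        d = np.abs(grid[:, 0])
        assert pmap.values[np.argmax(d)] < pmap.values[np.argmin(d)]

    def test_pickup_radius_level_bounds(self):
        grid = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
        pmap = electrical_profile(
            [LeadField("e", grid, 1.0 / (1.0 + grid[:, 0]))], grid,
            np.array([0.0, 0.0]),
        )
        with pytest.raises(ValueError):
            pickup_radius(pmap, 0.0)
        r = pickup_radius(pmap, 0.5)
        assert 0.0 < r <= 10.0
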