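"""Spiking replay model: rates, STDP, AELIF dynamics, analysis."""

import numpy as np
import pytest
from scipy import signal

from spikelapse import replay_sim as rs
from spikelapse.replay_sim import analysis as an
from spikelapse.replay_sim import network as nw
from spikelapse.replay_sim.params import INTERNEURON, PYRAMIDAL


@pytest.fixture(scope="module")
def tiny_net():
    """Small untrained network (10 pyr / 1 int per region)."""
    cfg = rs.NetworkConfig(scale=0.008)
    n = cfg.n_pyr
    pf = rs.PlaceFieldMap(centers_cm=np.full(n, np.nan))
    w0 = np.zeros((n, n))
    return nw.build_offline_network(w0, w0, cfg, pf, pf, seed=0)


class TestPlaceRates:
    def test_rate_at_field_center_reaches_lambda_max(self):
        pfm = rs.PlaceFieldMap(centers_cm=np.array([50.0]))
        t = np.linspace(0, 1 / pfm.f_theta_hz, 2000)
        rates = rs.place_rates(np.full_like(t, 50.0), t, pfm, pfm.centers_cm)
        assert rates.max() == pytest.approx(20.0, rel=1e-3)

    def test_rate_one_sigma_away_at_theta_peak(self):
        pfm = rs.PlaceFieldMap(centers_cm=np.array([50.0]))
        t = np.linspace(0, 1 / pfm.f_theta_hz, 5000)
        rates = rs.place_rates(np.full_like(t, 50.0 + pfm.sigma_cm), t, pfm,
                               pfm.centers_cm)
        assert rates.max() == pytest.approx(20.0 * np.exp(-0.5), rel=1e-3)

    def test_exploration_reproducible_and_is_off(self):
        rng = np.random.default_rng(0)
        pf3 = rs.PlaceFieldMap.random(40, rng)
        pf1 = rs.PlaceFieldMap.random(40, np.random.default_rng(1))
        a = rs.simulate_exploration(pf3, pf1, rs.IsStimConfig(mode="off"),
                                    duration_s=20.0, seed=5)
        b = rs.simulate_exploration(pf3, pf1, rs.IsStimConfig(mode="off"),
                                    duration_s=20.0, seed=5)
        assert np.array_equal(a.spikes["ca3_pyr"][0], b.spikes["ca3_pyr"][0])
        assert len(a.is_times_ms) == 0

    def test_clustered_is_near_reference(self):
        rng = np.random.default_rng(0)
        pf3 = rs.PlaceFieldMap.random(60, rng)
        pf1 = rs.PlaceFieldMap.random(60, np.random.default_rng(1))
        res = rs.simulate_exploration(pf3, pf1, rs.IsStimConfig(mode="clustered"),
                                      duration_s=60.0, seed=2)
        assert len(res.is_times_ms) > 0
        # IS occur while the virtual mouse is near |x| = 100 cm
        idx = np.searchsorted(res.t_ms, res.is_times_ms).clip(0, len(res.t_ms) - 1)
        assert np.all(np.abs(np.abs(res.x_cm[idx]) - 100.0) < 20.0)


class TestStdp:
    def test_single_pair_positive_lag(self):
        cfg = rs.CA3_CA1_STDP
        dw = rs.pair_update(cfg.tau_plus_ms, 0.5, cfg)
        assert dw == pytest.approx(cfg.lambda_step * np.exp(-1))

    def test_symmetric_rule_facilitates_negative_lag(self):
        cfg = rs.CA3_CA3_STDP
        dw = rs.pair_update(-62.5, 0.5, cfg)
        assert dw == pytest.approx(cfg.lambda_step * np.exp(-1))

    def test_asymmetric_rule_depresses_negative_lag(self):
        cfg = rs.CA3_CA1_STDP
        assert rs.pair_update(-10.0, 0.5, cfg) < 0

    def test_no_spikes_leaves_weights_unchanged(self):
        mask = np.ones((3, 3), bool)
        w0 = np.full((3, 3), 0.4)
        w = rs.train_stdp(np.array([]), np.array([], int), np.array([]),
                          np.array([], int), mask, w0, rs.CA3_CA1_STDP)
        assert np.array_equal(w, w0)

    def test_trace_updates_match_pair_rule(self):
        # one pre spike at 0, one post spike at tau_plus: single pair
        cfg = rs.CA3_CA1_STDP
        mask = np.array([[True]])
        w0 = np.array([[0.2]])
        w = rs.train_stdp(np.array([0.0]), np.array([0]),
                          np.array([cfg.tau_plus_ms]), np.array([0]),
                          mask, w0, cfg)
        assert w[0, 0] == pytest.approx(0.2 + rs.pair_update(cfg.tau_plus_ms, 0.2, cfg))

    def test_weights_stay_in_unit_interval(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 2000, 400))
        ids = rng.integers(0, 10, 400)
        mask = rng.random((10, 10)) < 0.5
        w0 = rs.initial_weights(mask, 0.3, rng)
        w = rs.train_stdp(times, ids, times, ids, mask, w0, rs.CA3_CA3_STDP,
                          recurrent=True)
        assert np.all(w >= 0.0) and np.all(w <= 1.0)
        assert np.all(w[~mask] == 0.0)


class TestAelifDynamics:
    def test_isolated_neuron_settles_at_leak_reversal(self, tiny_net):
        net = tiny_net
        net.dg_mask[:] = False
        sim = nw.simulate_offline(net, 0.5, seed=0)
        assert len(sim.spike_times_ms) == 0
        assert np.allclose(sim.lfp_mV, 0.0)

    def test_constant_current_drives_regular_spiking(self, tiny_net):
        net = tiny_net
        net.dg_mask[:] = False
        ext = np.zeros(net.n_total)
        ext[0] = 400.0  # pA onto one pyramidal cell
        iid = net.slices["ca3_int"].start
        ext[iid] = 200.0  # interneuron threshold is much lower
        sim = nw.simulate_offline(net, 1.0, seed=0, external_current_pA=ext)
        for neuron, p in ((0, PYRAMIDAL), (iid, INTERNEURON)):
            t = np.sort(sim.spike_times_ms[sim.spike_ids == neuron])
            assert len(t) >= 2
            assert np.all(np.diff(t) >= p.t_ref_ms - 1e-9)

    def test_step_size_robustness(self):
        # deterministic drive; halving dt changes per-neuron counts < 5%
        counts = {}
        for dt in (0.1, 0.01):
            cfg = rs.NetworkConfig(scale=0.008, dt_ms=dt)
            n = cfg.n_pyr
            pf = rs.PlaceFieldMap(centers_cm=np.full(n, np.nan))
            net = nw.build_offline_network(np.zeros((n, n)), np.zeros((n, n)),
                                           cfg, pf, pf, seed=0)
            net.dg_mask[:] = False
            ext = np.zeros(net.n_total)
            ext[: net.slices["ca3_pyr"].stop] = 350.0
            sim = nw.simulate_offline(net, 1.0, seed=0, external_current_pA=ext)
            counts[dt] = np.bincount(sim.spike_ids.astype(int), minlength=net.n_total)
        c1, c2 = counts[0.1], counts[0.01]
        active = c2 > 0
        assert np.all(np.abs(c1[active] - c2[active]) / c2[active] < 0.05)


class TestReplayDetection:
    def _bump(self, n, center, width=40, amp=2.0):
        x = np.zeros(n)
        t = np.arange(n)
        x += amp * np.exp(-((t - center) ** 2) / (2 * width**2))
        return x

    def test_flat_lfp_no_replays(self):
        assert an.detect_replays(np.zeros(5000)) == []

    def test_min_distance_merges_close_bumps(self):
        x = self._bump(5000, 2000) + self._bump(5000, 2100)
        assert len(an.detect_replays(x)) == 1

    def test_separated_bumps_both_detected(self):
        x = self._bump(5000, 2000) + self._bump(5000, 2300)
        assert len(an.detect_replays(x)) == 2

    def test_windows_are_300_ms(self):
        x = self._bump(5000, 2500)
        (lo, hi), = an.detect_replays(x)
        assert hi - lo == pytest.approx(0.300, abs=1e-6)


class TestDecodeAndContamination:
    def test_single_center_decoded(self):
        centers = np.array([50.0, -30.0, np.nan])
        traj = an.decode_position(np.array([0.01, 0.02]), np.array([0, 0]),
                                  centers, 0.0, 0.05)
        assert traj.x_cm[0] == 50.0

    def test_tie_breaks_toward_smaller_abs_position(self):
        centers = np.array([80.0, -20.0])
        traj = an.decode_position(np.array([0.01, 0.012]), np.array([0, 1]),
                                  centers, 0.0, 0.025)
        assert traj.x_cm[0] == -20.0

    def test_empty_bins_are_nan(self):
        centers = np.array([10.0])
        traj = an.decode_position(np.array([0.01]), np.array([0]),
                                  centers, 0.0, 0.1)
        assert not np.isnan(traj.x_cm[0]) and np.all(np.isnan(traj.x_cm[1:]))

    def test_sweeping_raster_decodes_monotone(self):
        centers = np.linspace(10, 100, 10)
        times = np.arange(10) * 0.025 + 0.01
        traj = an.decode_position(times, np.arange(10), centers, 0.0, 0.25)
        assert np.all(np.diff(traj.x_cm) > 0)

    def test_contamination_counts_uncued_arm_spikes(self):
        centers = np.array([100.0, -80.0, np.nan])
        t = np.array([0.01, 0.02, 0.03])
        ids = np.array([0, 1, 2])
        n = an.contamination(t, ids, centers, cued_arm_sign=1.0, window=(0.0, 0.05))
        assert n == 1
        assert an.contamination(t[:1], ids[:1], centers, 1.0, (0.0, 0.05)) == 0


class TestSpectra:
    def test_pure_tone_psd_peak(self):
        fs = 1000.0
        t = np.arange(0, 6.0, 1 / fs)
        x = np.sin(2 * np.pi * 150.0 * t)
        out = an.spectral_summary(x, fs)
        peak = out["psd_freqs_hz"][np.argmax(out["psd"])]
        assert peak == pytest.approx(150.0, abs=fs / 1024 + 1e-9)

    def test_parseval_band_power(self, rng):
        fs = 1000.0
        x = rng.standard_normal(8000)
        f, psd = signal.welch(x, fs=fs, nperseg=256, noverlap=32, nfft=1024)
        assert np.trapezoid(psd, f) == pytest.approx(np.var(x), rel=0.05)

    def test_cwt_band_limits(self, rng):
        out = an.spectral_summary(rng.standard_normal(6000), 1000.0)
        f = out["cwt_freqs_hz"]
        assert len(f) == 200
        assert f[0] == pytest.approx(10**1.2) and f[-1] == pytest.approx(10**2.5)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            an.spectral_summary(np.zeros(1000), 1000.0)


class TestBuildNetwork:
    def test_wrong_weight_shape_rejected(self):
        cfg = rs.NetworkConfig(scale=0.008)
        pf = rs.PlaceFieldMap(centers_cm=np.full(cfg.n_pyr, np.nan))
        with pytest.raises(ValueError):
            nw.build_offline_network(np.zeros((3, 3)), np.zeros((3, 3)), cfg, pf, pf)

    def test_cue_window_without_place_cells_rejected(self):
        cfg = rs.NetworkConfig(scale=0.008)
        pf = rs.PlaceFieldMap(centers_cm=np.full(cfg.n_pyr, np.nan))
        net = nw.build_offline_network(np.zeros((cfg.n_pyr,) * 2),
                                       np.zeros((cfg.n_pyr,) * 2), cfg, pf, pf)
        with pytest.raises(ValueError):
            nw.simulate_offline(net, 0.3, cue_center_cm=100.0)

    def test_lfp_scale_inverse_in_electrode_distance(self):
        from spikelapse.replay_sim.params import LfpProxyConfig

        a = rs.NetworkConfig(scale=0.008, lfp=LfpProxyConfig(r_um=5.0))
        b = rs.NetworkConfig(scale=0.008, lfp=LfpProxyConfig(r_um=10.0))
        sims = []
        for cfg in (a, b):
            n = cfg.n_pyr
            pf3 = rs.PlaceFieldMap.random(n, np.random.default_rng(3))
            pf1 = rs.PlaceFieldMap.random(n, np.random.default_rng(4))
            w = rs.random_connectivity(n, n, 0.5, np.random.default_rng(5)) * 0.5
            net = nw.build_offline_network(w, w, cfg, pf3, pf1, seed=0)
            sims.append(nw.simulate_offline(net, 0.5, seed=7))
        assert np.allclose(sims[0].lfp_mV, 2 * sims[1].lfp_mV, atol=1e-9)


class TestEndToEnd:
    def test_trained_control_network_produces_replays(self):
        cfg = rs.NetworkConfig(scale=0.25)
        tn = rs.train_network("control", cfg, duration_s=120.0, seed=0)
        out = rs.spontaneous_replay_summary(tn, duration_s=5.0, seed=2)
        assert out["n_replays"] > 0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            rs.train_network("unknown")
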