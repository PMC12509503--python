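"""Poisson gain models: densities, sampler, HPD, predictive checks."""

import numpy as np
import pytest
from scipy import special, stats

from spikelapse import bayes_models as bm

ZONES = np.array(["delay", "choice", "outer_arm", "reward"])
ANIMALS = np.array([f"m{i + 1}" for i in range(7)])


def make_table(rng, rho, eta, T_s=600.0, n_animals=7):
    T = np.full((n_animals, len(eta)), T_s)
    S = rng.poisson(T * np.asarray(rho)[:, None] * np.asarray(eta)[None, :])
    return bm.ZoneCountTable(animals=ANIMALS[:n_animals], zones=ZONES, S=S, T=T)


class TestLogPosteriorZone:
    def test_single_cell_poisson_term(self):
        data = bm.ZoneCountTable(animals=np.array(["a"]), zones=np.array(["z"]),
                                 S=np.array([[3.0]]), T=np.array([[10.0]]))
        got = bm.log_posterior_zone(np.array([0.3]), np.array([1.0]), data)
        pois = 3 * np.log(3.0) - 3.0 - special.gammaln(4)
        prior = (-np.log(0.3) - 0.5 * ((np.log(0.3) + 1) / 0.3) ** 2) + (-np.log(1.0) - 0.0)
        assert got == pytest.approx(pois + prior, abs=1e-10)

    def test_scale_swap_leaves_likelihood_unchanged(self, rng):
        data = make_table(rng, np.full(7, 0.5), [1, 1, 1, 2])
        m = bm.ZoneGainModel(data)
        u1 = np.concatenate([np.log(np.full(7, 0.5)), np.zeros(4)])
        u2 = np.concatenate([np.log(np.full(7, 0.25)), np.full(4, np.log(2.0))])
        assert m.log_likelihood(u1) == pytest.approx(m.log_likelihood(u2), abs=1e-8)

    def test_nonpositive_parameters_rejected(self, rng):
        data = make_table(rng, np.full(7, 0.5), [1, 1, 1, 1])
        assert bm.log_posterior_zone(np.full(7, -0.1), np.ones(4), data) == -np.inf

    @pytest.mark.parametrize("model_kind", ["zone", "state"])
    def test_gradient_matches_finite_differences(self, rng, model_kind):
        if model_kind == "zone":
            model = bm.ZoneGainModel(make_table(rng, np.full(7, 0.5), [1, 1, 1, 2]))
        else:
            P = rng.dirichlet(np.ones(3), 60)
            model = bm.StateRateModel(rng.poisson(5, 60), np.full(60, 20.0),
                                      rng.integers(0, 3, 60), P, n_animals=3)
        u = rng.normal(0, 0.3, model.ndim)
        g = model.grad_log_target(u)
        h = 1e-6
        num = np.array([
            (model.log_target(u + h * e) - model.log_target(u - h * e)) / (2 * h)
            for e in np.eye(model.ndim)
        ])
        assert np.allclose(g, num, atol=1e-4)


class TestSampler:
    def test_well_specified_fit_converges(self, rng):
        data = make_table(rng, np.full(7, 0.5), [1, 1, 1, 2])
        samp = bm.sample_posterior(bm.ZoneGainModel(data), seed=11)
        assert samp.diagnostics["rhat"].max() < 1.01
        assert samp.diagnostics["ess"].min() > 400

    def test_prior_only_run_recovers_prior(self):
        data = bm.ZoneCountTable(animals=ANIMALS[:2], zones=ZONES,
                                 S=np.zeros((2, 4)), T=np.zeros((2, 4)))
        samp = bm.sample_posterior(bm.ZoneGainModel(data), seed=12)
        assert np.median(samp.stacked("eta[reward]")) == pytest.approx(1.0, abs=0.15)
        assert np.median(samp.stacked("rho[m1]")) == pytest.approx(np.exp(-1), abs=0.06)

    def test_posterior_tracks_naive_rate_under_flat_gains(self, rng):
        # single animal, all gains 1: posterior mean of rho*eta_z ~ S/T
        data = make_table(rng, [0.5], [1, 1, 1, 1], T_s=2000.0, n_animals=1)
        samp = bm.sample_posterior(bm.ZoneGainModel(data), seed=13)
        naive = data.S.sum() / data.T.sum()
        for z in ZONES:
            prod = samp.stacked("rho[m1]") * samp.stacked(f"eta[{z}]")
            assert prod.mean() == pytest.approx(naive, rel=0.1)

    def test_calibrated_under_prior_drawn_truth(self, rng):
        """Simulation-based calibration: intervals cover prior-drawn truth."""
        hits, total = 0, 0
        for k in range(5):
            rho = np.exp(rng.normal(-1, 0.3, 7))
            eta = np.exp(rng.normal(0, 1, 4))
            data = make_table(rng, rho, eta)
            samp = bm.sample_posterior(bm.ZoneGainModel(data), seed=50 + k)
            for i, a in enumerate(ANIMALS):
                h = bm.hpd(samp.stacked(f"rho[{a}]"), null=None)
                hits += h.lower <= rho[i] <= h.upper
                total += 1
            for j, z in enumerate(ZONES):
                h = bm.hpd(samp.stacked(f"eta[{z}]"), null=None)
                hits += h.lower <= eta[j] <= h.upper
                total += 1
        assert hits / total >= 0.85

    def test_zone_relabeling_invariance(self, rng):
        data = make_table(rng, np.full(7, 0.5), [1, 1, 1, 2])
        perm = np.array([3, 0, 2, 1])
        data_p = bm.ZoneCountTable(animals=data.animals, zones=data.zones[perm],
                                   S=data.S[:, perm], T=data.T[:, perm])
        s1 = bm.sample_posterior(bm.ZoneGainModel(data), seed=14)
        s2 = bm.sample_posterior(bm.ZoneGainModel(data_p), seed=14)
        for z in ZONES:
            assert s1.mean(f"eta[{z}]") == pytest.approx(s2.mean(f"eta[{z}]"), rel=0.05)


class TestHpd:
    def test_constant_samples_point_interval(self):
        h = bm.hpd(np.full(500, 2.0))
        assert h.lower == h.upper == 2.0

    def test_standard_normal_quantiles(self, rng):
        draws = rng.standard_normal(100_000)
        h = bm.hpd(draws, coverage=0.95, null=0.0)
        assert h.lower == pytest.approx(-1.96, abs=0.05)
        assert h.upper == pytest.approx(1.96, abs=0.05)
        assert h.breach_alpha == pytest.approx(0.05)

    def test_matches_arviz_hdi(self, rng):
        import arviz as az

        draws = rng.gamma(3.0, 1.0, 20_000)
        h = bm.hpd(draws)
        lo, hi = az.hdi(draws, hdi_prob=0.95)
        assert h.lower == pytest.approx(lo, abs=0.02)
        assert h.upper == pytest.approx(hi, abs=0.02)

    def test_null_outside_sample_range_no_breach(self, rng):
        draws = 1.5 + rng.random(1000)  # uniformly above 1
        h = bm.hpd(draws, null=1.0)
        assert h.breach_alpha is None

    def test_breach_alpha_by_bisection(self, rng):
        draws = rng.normal(2.0, 0.5, 50_000)
        h = bm.hpd(draws, null=1.0)
        assert not h.contains(1.0)
        # at the breach coverage the interval just reaches the null
        assert h.breach_alpha is not None
        alpha_exact = 2 * stats.norm.cdf((1.0 - 2.0) / 0.5)
        assert h.breach_alpha == pytest.approx(alpha_exact, abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            bm.hpd(np.arange(10.0))


class TestPosteriorPredictive:
    def test_well_specified_coverage(self, rng):
        data = make_table(rng, np.full(7, 0.5), [1, 1, 1, 2])
        model = bm.ZoneGainModel(data)
        samp = bm.sample_posterior(model, seed=15)
        ppc = bm.posterior_predictive(model, samp, seed=0)
        assert ppc["obs_coverage_95"] >= 0.85

    def test_no_spurious_preference_for_full_model(self, rng):
        # data generated with all gains 1: full model should not strongly win
        data = make_table(rng, np.full(7, 0.5), [1, 1, 1, 1])
        full = bm.ZoneGainModel(data)
        clamped = bm.ZoneGainModel(data, clamp_eta=True)
        sf = bm.sample_posterior(full, seed=16)
        sc = bm.sample_posterior(clamped, seed=16)
        assert bm.aic(full, sf) >= bm.aic(clamped, sc) - 4.0


class TestStateRateModel:
    @staticmethod
    def _sharp_marginals(rng, n_trials, eta, rho=0.5, T_s=30.0):
        states = rng.integers(0, len(eta), n_trials)
        P = np.full((n_trials, len(eta)), 0.1 / (len(eta) - 1))
        P[np.arange(n_trials), states] = 0.9
        T = np.full(n_trials, T_s)
        S = rng.poisson(T * rho * (P @ np.asarray(eta)))
        return S, T, rng.integers(0, 7, n_trials), P

    def test_degenerate_marginals_reduce_to_single_gain(self, rng):
        P = np.zeros((300, 3)); P[:, 1] = 1.0
        T = np.full(300, 30.0)
        S = rng.poisson(T * 0.5 * 0.4)
        model = bm.StateRateModel(S, T, np.zeros(300, int), P, n_animals=1)
        samp = bm.sample_posterior(model, seed=17)
        prod = samp.stacked("rho[0]") * samp.stacked("eta[1]")
        assert prod.mean() == pytest.approx(0.2, rel=0.1)

    def test_suppressed_state_gain_detected(self, rng):
        S, T, aidx, P = self._sharp_marginals(rng, 500, [1.0, 0.4, 1.0])
        model = bm.StateRateModel(S, T, aidx, P, n_animals=7,
                                  state_names=["engaged", "guess", "persev"])
        samp = bm.sample_posterior(model, seed=18)
        h = bm.hpd(samp.stacked("eta[guess]"), null=1.0)
        assert not h.contains(1.0)
        assert h.upper < 1.0  # suppression, not elevation

    def test_marginals_must_sum_to_one(self, rng):
        with pytest.raises(ValueError):
            bm.StateRateModel(np.ones(5), np.ones(5), np.zeros(5, int),
                              np.full((5, 3), 0.5))

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            bm.StateRateModel(np.ones(3), np.array([1.0, 0.0, 1.0]),
                              np.zeros(3, int), np.full((3, 2), 0.5))


class TestPosteriorSamplesContainer:
    def test_long_format_round_trip(self, rng):
        data = make_table(rng, np.full(2, 0.5), [1, 1, 1, 1], n_animals=2)
        samp = bm.sample_posterior(bm.ZoneGainModel(data), n_chains=2,
                                   n_iter=200, n_warmup=200, seed=19)
        df = samp.to_frame()
        assert set(df.columns) == {"chain", "iter", "parameter", "value"}
        assert df["chain"].nunique() == 2
        assert len(df) == 2 * 200 * 6
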