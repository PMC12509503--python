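"""Hierarchical Poisson gain models for zone- and state-specific IS rates.

Two models share one structure: observed spike counts are Poisson with
mean = exposure x animal baseline rate x a positive gain,

    zone model:   S[a, z] ~ Poisson(T[a, z] * rho_a * eta_z)
    state model:  S_i     ~ Poisson(T_i * rho_a(i) * sum_s eta_s p(s_i = s))

with log-normal priors on the gains (eta ~ LogNormal(0, 1)), a log-normal
prior on the zone-model baselines (rho_a ~ LogNormal(-1, 0.3)) and a
zero-truncated Normal(0.5, 0.5) on the state-model baselines.  A gain of
1 is the neutral ("null") value; evidence for modulation is summarized by
highest-posterior-density (HPD) intervals and the tail mass at which the
interval first reaches 1.

Sampling is by gradient-based Hamiltonian Monte Carlo in unconstrained
log space: fixed-length leapfrog trajectories with the step size tuned by
dual averaging toward a 65% acceptance target and a dense metric adapted
from the warmup draws (both frozen after warmup), with split R-hat and
effective-sample-size diagnostics.  The inferential targets -- posterior
means and HPD intervals -- do not depend on the sampler brand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "ZoneCountTable",
    "ZoneGainModel",
    "StateRateModel",
    "PosteriorSamples",
    "HPDInterval",
    "log_posterior_zone",
    "sample_posterior",
    "hpd",
    "posterior_predictive",
    "aic",
]


def _poisson_logpmf(k, mu):
    return special.xlogy(k, mu) - mu - special.gammaln(k + 1)


@dataclass
class ZoneCountTable:
    """Per-animal x per-zone spike counts and occupancy seconds."""

    animals: np.ndarray          # (A,) labels
    zones: np.ndarray            # (Z,) labels
    S: np.ndarray                # (A, Z) counts
    T: np.ndarray                # (A, Z) occupancy seconds

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.S.shape != self.T.shape:
            raise ValueError("S and T must share a shape")
        if np.any(self.S < 0) or np.any(self.T < 0):
            raise ValueError("counts and occupancy must be >= 0")
        if np.any((self.S > 0) & (self.T <= 0)):
            raise ValueError("spikes observed in a zone with zero occupancy")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZoneCountTable":
        """Build from a long table with columns animal, zone, spikes, occupancy_s."""
        pivot_s = df.pivot_table(index="animal", columns="zone", values="spikes", aggfunc="sum")
        pivot_t = df.pivot_table(index="animal", columns="zone", values="occupancy_s", aggfunc="sum")
        return cls(
            animals=pivot_s.index.to_numpy(),
            zones=pivot_s.columns.to_numpy(),
            S=pivot_s.to_numpy(),
            T=pivot_t.reindex(index=pivot_s.index, columns=pivot_s.columns).to_numpy(),
        )


class ZoneGainModel:
    """Zone-gain Poisson model; parameters in log space for sampling.

    Parameter vector u = [log rho_a ..., log eta_z ...].  With the
    log-normal priors, the log-space prior is Gaussian, so the log target
    (including the Jacobian of the exp transform) is exactly

        sum_cells PoissonLogPmf(S; T e^{u_rho} e^{u_eta})
        + sum_a N(u_rho_a; -1, 0.3) + sum_z N(u_eta_z; 0, 1).
    """

    RHO_LOC, RHO_SCALE = -1.0, 0.3
    ETA_LOC, ETA_SCALE = 0.0, 1.0

    def __init__(self, data: ZoneCountTable, clamp_eta: bool = False):
        self.data = data
        self.clamp_eta = clamp_eta
        self.n_animals = len(data.animals)
        self.n_zones = len(data.zones)

    @property
    def param_names(self) -> list[str]:
        names = [f"rho[{a}]" for a in self.data.animals]
        if not self.clamp_eta:
            names += [f"eta[{z}]" for z in self.data.zones]
        return names

    @property
    def ndim(self) -> int:
        return self.n_animals + (0 if self.clamp_eta else self.n_zones)

    def _split(self, u):
        log_rho = u[: self.n_animals]
        log_eta = (np.zeros(self.n_zones) if self.clamp_eta
                   else u[self.n_animals :])
        return log_rho, log_eta

    def log_target(self, u: np.ndarray) -> float:
        if np.any(np.abs(u) > 40):  # far outside any posterior mass; reject
            return -np.inf
        log_rho, log_eta = self._split(u)
        mu = self.data.T * np.exp(log_rho[:, None] + log_eta[None, :])
        ll = _poisson_logpmf(self.data.S, mu)[self.data.T > 0].sum()
        lp = -0.5 * np.sum(((log_rho - self.RHO_LOC) / self.RHO_SCALE) ** 2)
        if not self.clamp_eta:
            lp += -0.5 * np.sum(((log_eta - self.ETA_LOC) / self.ETA_SCALE) ** 2)
        return float(ll + lp)

    def grad_log_target(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(u, -40, 40)
        log_rho, log_eta = self._split(u)
        mu = self.data.T * np.exp(log_rho[:, None] + log_eta[None, :])
        resid = np.where(self.data.T > 0, self.data.S - mu, 0.0)
        g_rho = resid.sum(axis=1) - (log_rho - self.RHO_LOC) / self.RHO_SCALE**2
        if self.clamp_eta:
            return g_rho
        g_eta = resid.sum(axis=0) - (log_eta - self.ETA_LOC) / self.ETA_SCALE**2
        return np.concatenate([g_rho, g_eta])

    def init_point(self, rng: np.random.Generator) -> np.ndarray:
        u = np.concatenate([
            np.full(self.n_animals, self.RHO_LOC),
            np.zeros(0 if self.clamp_eta else self.n_zones),
        ])
        return u + 0.1 * rng.standard_normal(self.ndim)

    def log_likelihood(self, u: np.ndarray) -> float:
        log_rho, log_eta = self._split(u)
        mu = self.data.T * np.exp(log_rho[:, None] + log_eta[None, :])
        return float(_poisson_logpmf(self.data.S, mu)[self.data.T > 0].sum())

    def predict_mean(self, u: np.ndarray) -> np.ndarray:
        log_rho, log_eta = self._split(u)
        return self.data.T * np.exp(log_rho[:, None] + log_eta[None, :])


def log_posterior_zone(rho: np.ndarray, eta: np.ndarray, data: ZoneCountTable) -> float:
    """Natural-scale log posterior density (up to a constant).

    Non-positive parameters are rejected with -inf.
    """
    rho = np.asarray(rho, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(rho <= 0) or np.any(eta <= 0):
        return -np.inf
    mu = data.T * rho[:, None] * eta[None, :]
    ll = _poisson_logpmf(data.S, mu)[data.T > 0].sum()
    # LogNormal(m, s) density includes the 1/x Jacobian on the natural scale
    lp = np.sum(
        -np.log(rho) - 0.5 * ((np.log(rho) - ZoneGainModel.RHO_LOC) / ZoneGainModel.RHO_SCALE) ** 2
    )
    lp += np.sum(
        -np.log(eta) - 0.5 * ((np.log(eta) - ZoneGainModel.ETA_LOC) / ZoneGainModel.ETA_SCALE) ** 2
    )
    return float(ll + lp)


class StateRateModel:
    """Behavioral-state gain model for delay-zone IS counts per trial.

    Likelihood per trial: Poisson(T_i * rho_a(i) * sum_s eta_s p_i[s]) with
    the state marginals p_i fixed inputs.  The baseline prior is a
    zero-truncated Normal(0.5, 0.5) (the printed max(Normal, 0) form puts
    an atom at zero; truncation keeps the density proper and positive).
    """

    ETA_LOC, ETA_SCALE = 0.0, 1.0
    RHO_MEAN, RHO_SD = 0.5, 0.5

    def __init__(self, counts, exposures, animal_idx, marginals, n_animals=None,
                 state_names=None):
        self.S = np.asarray(counts, dtype=float)
        self.T = np.asarray(exposures, dtype=float)
        self.animal_idx = np.asarray(animal_idx, dtype=int)
        self.P = np.asarray(marginals, dtype=float)
        if np.any(self.T <= 0):
            raise ValueError("per-trial exposures must be > 0")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("state marginals must sum to 1 per trial")
        self.n_animals = int(n_animals or self.animal_idx.max() + 1)
        self.n_states = self.P.shape[1]
        self.state_names = (list(state_names) if state_names is not None
                            else list(range(self.n_states)))

    @property
    def param_names(self) -> list[str]:
        return [f"rho[{a}]" for a in range(self.n_animals)] + [
            f"eta[{s}]" for s in self.state_names
        ]

    @property
    def ndim(self) -> int:
        return self.n_animals + self.n_states

    def _split(self, u):
        return u[: self.n_animals], u[self.n_animals :]

    def log_target(self, u: np.ndarray) -> float:
        if np.any(np.abs(u) > 40):
            return -np.inf
        u_rho, u_eta = self._split(u)
        rho = np.exp(u_rho)
        gain = self.P @ np.exp(u_eta)
        mu = self.T * rho[self.animal_idx] * gain
        ll = _poisson_logpmf(self.S, mu).sum()
        # truncated normal on rho, sampled through u = log rho (Jacobian e^u)
        lp = np.sum(-0.5 * ((rho - self.RHO_MEAN) / self.RHO_SD) ** 2 + u_rho)
        lp += np.sum(-0.5 * ((u_eta - self.ETA_LOC) / self.ETA_SCALE) ** 2)
        return float(ll + lp)

    def grad_log_target(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(u, -40, 40)
        u_rho, u_eta = self._split(u)
        rho = np.exp(u_rho)
        e_eta = np.exp(u_eta)
        G = self.P @ e_eta
        mu = self.T * rho[self.animal_idx] * G
        resid = self.S - mu  # d loglik / d log rho_a(i), per trial
        g_rho = np.bincount(self.animal_idx, weights=resid, minlength=self.n_animals)
        g_rho += -(rho - self.RHO_MEAN) / self.RHO_SD**2 * rho + 1.0
        g_eta = e_eta * ((self.S / G) @ self.P) - e_eta * (
            (self.T * rho[self.animal_idx]) @ self.P
        )
        g_eta += -(u_eta - self.ETA_LOC) / self.ETA_SCALE**2
        return np.concatenate([g_rho, g_eta])

    def init_point(self, rng: np.random.Generator) -> np.ndarray:
        u = np.concatenate([
            np.full(self.n_animals, np.log(self.RHO_MEAN)),
            np.zeros(self.n_states),
        ])
        return u + 0.1 * rng.standard_normal(self.ndim)

    def log_likelihood(self, u: np.ndarray) -> float:
        u_rho, u_eta = self._split(u)
        mu = self.T * np.exp(u_rho)[self.animal_idx] * (self.P @ np.exp(u_eta))
        return float(_poisson_logpmf(self.S, mu).sum())

    def predict_mean(self, u: np.ndarray) -> np.ndarray:
        u_rho, u_eta = self._split(u)
        return self.T * np.exp(u_rho)[self.animal_idx] * (self.P @ np.exp(u_eta))


@dataclass
class PosteriorSamples:
    """Posterior draws on the natural scale plus convergence diagnostics.

    ``draws`` maps parameter name to an (n_chains, n_iter) array.
    """

    draws: dict[str, np.ndarray]
    diagnostics: pd.DataFrame
    warnings: list[str]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.stacked(name).mean())

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iter, parameter, value."""
        recs = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                recs.append(pd.DataFrame({
                    "chain": c,
                    "iter": np.arange(arr.shape[1]),
                    "parameter": name,
                    "value": arr[c],
                }))
        return pd.concat(recs, ignore_index=True)

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())


def _diagnostics(draws_u: np.ndarray, names: list[str]) -> pd.DataFrame:
    import warnings as _w

    import arviz as az

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        ds = az.convert_to_dataset(draws_u)
        rhat = az.rhat(ds)["x"].to_numpy()
        ess = az.ess(ds)["x"].to_numpy()
    return pd.DataFrame({"parameter": names, "rhat": rhat, "ess": ess}).set_index("parameter")


def sample_posterior(
    model,
    n_chains: int = 4,
    n_iter: int = 1000,
    n_warmup: int = 500,
    target_accept: float = 0.65,
    seed: int = 0,
) -> PosteriorSamples:
    """Hamiltonian Monte Carlo over the model's log-space target.

    Fixed-length leapfrog trajectories (20 steps with +/-20% jitter) in a
    preconditioned space: during the first half of warmup the metric is
    identity while dual averaging tunes the step size toward
    ``target_accept``; at mid-warmup a dense metric is estimated from the
    warmup draws and dual averaging restarts.  Step size and metric are
    frozen after warmup.  Draws are reported on the natural scale; split
    R-hat and ESS are computed in sampling (log) space.
    """
    ndim = model.ndim
    n_leapfrog = 20
    all_draws = np.empty((n_chains, n_iter, ndim))
    warnings_out: list[str] = []
    n_divergent = 0
    ss = np.random.SeedSequence(seed)
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        u = model.init_point(rng)
        A = 0.1 * np.eye(ndim)  # u = A v preconditioner
        Ainv = np.linalg.inv(A)
        v = Ainv @ u
        # dual averaging state (Hoffman & Gelman schedule)
        log_eps = np.log(0.1)
        log_eps_bar, h_bar = log_eps, 0.0
        mu_da = np.log(10.0) + log_eps
        t_da = 0
        warm_draws = []
        half = n_warmup // 2

        def grad_v(vv):
            return A.T @ model.grad_log_target(A @ vv)

        logp = model.log_target(A @ v)
        for t in range(n_warmup + n_iter):
            eps = np.exp(log_eps) * rng.uniform(0.8, 1.2)
            p0 = rng.standard_normal(ndim)
            vv, pp = v.copy(), p0.copy()
            g = grad_v(vv)
            pp += 0.5 * eps * g
            for _ in range(n_leapfrog):
                vv += eps * pp
                g = grad_v(vv)
                pp += eps * g
            pp -= 0.5 * eps * g
            logp_prop = model.log_target(A @ vv)
            dH = (logp_prop - 0.5 * pp @ pp) - (logp - 0.5 * p0 @ p0)
            if not np.isfinite(dH):
                accept_prob = 0.0
                if t >= n_warmup:
                    n_divergent += 1
            else:
                accept_prob = min(1.0, np.exp(min(0.0, dH)))
            if rng.random() < accept_prob:
                v, logp = vv, logp_prop
            if t < n_warmup:
                t_da += 1
                h_bar += ((target_accept - accept_prob) - h_bar) / (t_da + 10)
                log_eps = mu_da - np.sqrt(t_da) / 0.05 * h_bar
                eta = t_da ** -0.75
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                warm_draws.append(A @ v)
                if t == half and len(warm_draws) > 10:
                    sample = np.array(warm_draws[len(warm_draws) // 2 :])
                    cov = np.cov(sample.T) + 1e-8 * np.eye(ndim)
                    A = np.linalg.cholesky(cov)
                    v = np.linalg.solve(A, warm_draws[-1])
                    logp = model.log_target(A @ v)
                    log_eps = np.log(0.5)
                    mu_da = np.log(10.0) + log_eps
                    log_eps_bar, h_bar, t_da = log_eps, 0.0, 0
                if t == n_warmup - 1:
                    log_eps = log_eps_bar
            else:
                all_draws[c, t - n_warmup] = A @ v
    if n_divergent:
        warnings_out.append(f"{n_divergent} divergent transitions")
    names = model.param_names
    diag = _diagnostics(all_draws, names)
    if (diag["rhat"] > 1.01).any():
        warnings_out.append(
            "split R-hat above 1.01 for: "
            + ", ".join(diag.index[diag["rhat"] > 1.01])
        )
    if (diag["ess"] < 400).any():
        warnings_out.append(
            "effective sample size below 400 for: "
            + ", ".join(diag.index[diag["ess"] < 400])
        )
    draws = {name: np.exp(all_draws[:, :, k]) for k, name in enumerate(names)}
    return PosteriorSamples(draws=draws, diagnostics=diag, warnings=warnings_out)


@dataclass
class HPDInterval:
    lower: float
    upper: float
    coverage: float
    breach_alpha: float | None

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _hpd_bounds(sorted_draws: np.ndarray, coverage: float) -> tuple[float, float]:
    n = len(sorted_draws)
    k = max(1, int(np.ceil(coverage * n)))
    if k >= n:
        return float(sorted_draws[0]), float(sorted_draws[-1])
    widths = sorted_draws[k:] - sorted_draws[: n - k]
    j = int(np.argmin(widths))
    return float(sorted_draws[j]), float(sorted_draws[j + k])


def hpd(
    samples: np.ndarray,
    coverage: float = 0.95,
    null: float | None = 1.0,
    tol: float = 1e-3,
) -> HPDInterval:
    """Shortest sorted-sample interval holding the requested mass.

    If the null value falls outside the interval, ``breach_alpha`` is the
    tail mass (1 - coverage) at which a widened interval first contains
    the null, found by bisection; ``None`` if no coverage below 1 does.
    """
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    if len(samples) < 100:
        raise ValueError("need >= 100 draws")
    lo, hi = _hpd_bounds(samples, coverage)
    if null is None:
        return HPDInterval(lower=lo, upper=hi, coverage=coverage, breach_alpha=None)
    breach: float | None = 1.0 - coverage
    if not (lo <= null <= hi):
        if null < samples[0] or null > samples[-1]:
            breach = None
        else:
            a, b = coverage, 1.0
            while b - a > tol:
                mid = 0.5 * (a + b)
                l2, h2 = _hpd_bounds(samples, mid)
                if l2 <= null <= h2:
                    b = mid
                else:
                    a = mid
            breach = 1.0 - b
    return HPDInterval(lower=lo, upper=hi, coverage=coverage, breach_alpha=breach)


def posterior_predictive(
    model, samples: PosteriorSamples, seed: int = 0, n_draws: int = 500
) -> dict:
    """Replicate data from posterior draws and summarize the fit.

    Returns per-datum replicate-mean quantiles, the MSE of the replicate
    means against the observed data, and the central-95% coverage of the
    observations by their replicate distributions.
    """
    rng = np.random.default_rng(seed)
    names = model.param_names
    flat = np.stack([np.log(samples.stacked(n)) for n in names], axis=1)
    pick = rng.choice(len(flat), size=min(n_draws, len(flat)), replace=False)
    mus = np.stack([model.predict_mean(flat[i]) for i in pick])
    reps = rng.poisson(mus)
    obs = model.data.S if hasattr(model, "data") else model.S
    rep_mean = mus.mean(axis=0)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    inside = (obs >= lo) & (obs <= hi)
    if hasattr(model, "data"):
        mask = model.data.T > 0
        mse = float(np.mean((rep_mean[mask] - obs[mask]) ** 2))
        coverage = float(np.mean(inside[mask]))
    else:
        mse = float(np.mean((rep_mean - obs) ** 2))
        coverage = float(np.mean(inside))
    return {
        "replicate_mean": rep_mean,
        "obs_coverage_95": coverage,
        "mse": mse,
    }


def aic(model, samples: PosteriorSamples) -> float:
    """AIC with the plug-in log-likelihood at the posterior mean.

    k counts the free parameters of the model variant.
    """
    names = model.param_names
    u_mean = np.array([np.log(samples.stacked(n)).mean() for n in names])
    return float(2 * model.ndim - 2 * model.log_likelihood(u_mean))
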