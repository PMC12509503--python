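"""Spatial statistics of interictal activity.

The spread of IS on the maze is quantified by treating the pooled IS train
as if it came from a single place cell: the maze is binned into a 15 x 15
grid and the Skaggs information rate

    I = sum_i lambda_i P(x_i) log2(lambda_i / mean_rate),   mean_rate = sum_i lambda_i P(x_i)

is computed over occupied bins, with I_spike = I / mean_rate in bits per
spike.  Session-level regressions relate I_spike to the mean path length
of BIRDs (Gamma GLMM, reciprocal link, random intercept per animal) and
task performance to I_spike (fixed-effects Gaussian GLM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "OccupancyMap",
    "build_occupancy_map",
    "spatial_information",
    "bird_distance",
    "fit_si_vs_distance",
    "fit_performance_vs_si",
]


@dataclass
class OccupancyMap:
    """Per-bin occupancy seconds and event counts on an n x n grid."""

    occupancy_s: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy_s = np.asarray(self.occupancy_s, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.occupancy_s.shape != self.counts.shape:
            raise ValueError("occupancy and counts must share a shape")
        if np.any(self.occupancy_s < 0) or np.any(self.counts < 0):
            raise ValueError("occupancy and counts must be non-negative")

    @property
    def P(self) -> np.ndarray:
        """Occupancy probability per bin (zero where unoccupied)."""
        total = self.occupancy_s.sum()
        return self.occupancy_s / total if total > 0 else self.occupancy_s

    @property
    def rate(self) -> np.ndarray:
        """Event rate per bin (Hz); zero where unoccupied."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(self.occupancy_s > 0, self.counts / self.occupancy_s, 0.0)
        return lam


def build_occupancy_map(
    traj,
    event_times_s: np.ndarray,
    n_bins: int = 15,
    bounds: tuple[float, float, float, float] | None = None,
) -> OccupancyMap:
    """Bin a trajectory and its events into an ``n_bins`` square grid."""
    x, y, t = traj.x_cm, traj.y_cm, traj.t_s
    if bounds is None:
        bounds = (x.min(), x.max(), y.min(), y.max())
    x0, x1, y0, y1 = bounds
    edges_x = np.linspace(x0, x1, n_bins + 1)
    edges_y = np.linspace(y0, y1, n_bins + 1)
    dt = traj.sample_period_s
    occ, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    occ *= dt
    ev = np.asarray(event_times_s, dtype=float)
    idx = np.clip(np.searchsorted(t, ev), 0, len(t) - 1)
    cnt, _, _ = np.histogram2d(x[idx], y[idx], bins=[edges_x, edges_y])
    return OccupancyMap(occupancy_s=occ, counts=cnt)


def spatial_information(omap: OccupancyMap) -> tuple[float, float]:
    """Information rate (bits/s) and per-spike information (bits/spike).

    Zero-rate bins contribute nothing (0 log 0 := 0); unoccupied bins are
    excluded.  Raises if no spikes occurred in any occupied bin, since
    bits/spike is then undefined.
    """
    P = omap.P
    lam = omap.rate
    mean_rate = float((lam * P).sum())
    if mean_rate <= 0:
        raise ValueError("all-zero rate map: information per spike undefined")
    mask = (P > 0) & (lam > 0)
    I = float(np.sum(lam[mask] * P[mask] * np.log2(lam[mask] / mean_rate)))
    return I, I / mean_rate


def bird_distance(positions: np.ndarray) -> float:
    """Path length (cm) along successive spike positions of one BIRD."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) == 0:
        raise ValueError("need at least one position")
    if len(positions) == 1:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(positions, axis=0), axis=1)))


def _gamma_loglik(y, mu, shape):
    # Gamma parameterized by shape k and mean mu (scale mu/k)
    return (
        (shape - 1) * np.log(y)
        - shape * y / mu
        - shape * np.log(mu / shape)
        - special.gammaln(shape)
    )


class MixedGlmFit:
    """Container for the Gamma mixed-model fit."""

    def __init__(self, coef_table, dispersion, re_sd, loglik, converged):
        self.coef_table = coef_table
        self.dispersion = dispersion
        self.re_sd = re_sd
        self.loglik = loglik
        self.converged = converged

    def __repr__(self) -> str:  # pragma: no cover
        return f"MixedGlmFit(\n{self.coef_table}\ndispersion={self.dispersion:.4g}, re_sd={self.re_sd:.4g})"


def fit_si_vs_distance(
    i_spike: np.ndarray,
    mean_bird_distance: np.ndarray,
    animal_ids: np.ndarray,
    n_quad: int = 25,
) -> MixedGlmFit:
    """Gamma GLMM: I_spike ~ 1 + <d> + (1 | animal), reciprocal link.

    Maximum likelihood with the animal random intercept integrated out by
    Gauss-Hermite quadrature.  Returns fixed-effect estimates with
    standard errors from the numerical Hessian, the Gamma dispersion
    (1 / shape), and the random-intercept SD.
    """
    y = np.asarray(i_spike, dtype=float)
    x = np.asarray(mean_bird_distance, dtype=float)
    groups = np.asarray(animal_ids)
    if np.any(y <= 0):
        raise ValueError("Gamma family requires strictly positive I_spike")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 animals")
    # hermegauss integrates against exp(-u^2/2); renormalize to N(0, 1)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(2 * np.pi)

    def nll(params):
        b0, b1, log_shape, log_sd = params
        shape = np.exp(log_shape)
        sd = np.exp(log_sd)
        total = 0.0
        for g in uniq:
            m = groups == g
            eta = b0 + b1 * x[m]  # (n_g,)
            etas = eta[:, None] + sd * nodes[None, :]  # (n_g, Q)
            if np.any(etas <= 1e-8):
                etas = np.clip(etas, 1e-8, None)
            mu = 1.0 / etas
            ll = _gamma_loglik(y[m][:, None], mu, shape).sum(axis=0)  # (Q,)
            total += special.logsumexp(ll + log_w)
        return -total

    eta0 = 1.0 / max(y.mean(), 1e-6)
    x0 = np.array([eta0, 0.0, np.log(10.0), np.log(0.5)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
    res = optimize.minimize(nll, res.x, method="BFGS", options={"gtol": 1e-8})
    # numerical Hessian for fixed-effect SEs
    eps = 1e-4
    k = len(res.x)
    H = np.zeros((k, k))
    f0 = nll(res.x)
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * eps
            ej = np.eye(k)[j] * eps
            H[i, j] = H[j, i] = (
                nll(res.x + ei + ej) - nll(res.x + ei - ej)
                - nll(res.x - ei + ej) + nll(res.x - ei - ej)
            ) / (4 * eps**2)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    b = res.x
    dof = len(y) - 2
    se = np.where(se > 0, se, np.nan)
    tstats = b[:2] / se[:2]
    pvals = 2 * stats.t.sf(np.abs(tstats), dof)
    table = pd.DataFrame(
        {
            "estimate": b[:2],
            "se": se[:2],
            "tstat": tstats,
            "pvalue": pvals,
        },
        index=["Intercept", "mean_bird_distance"],
    )
    return MixedGlmFit(
        coef_table=table,
        dispersion=float(1.0 / np.exp(b[2])),
        re_sd=float(np.exp(b[3])),
        loglik=float(-f0),
        converged=bool(res.success),
    )


def fit_performance_vs_si(performance: np.ndarray, i_spike: np.ndarray):
    """Fixed-effects regression Performance ~ 1 + I_spike.

    Gaussian GLM with dispersion estimated from the data; returns the
    statsmodels results object (coefficient table via ``.summary()``).
    """
    import statsmodels.api as sm

    y = np.asarray(performance, dtype=float)
    x = np.asarray(i_spike, dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 sessions")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: model is rank deficient")
    X = sm.add_constant(x)
    return sm.OLS(y, X).fit()
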