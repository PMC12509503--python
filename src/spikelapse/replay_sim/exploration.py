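"""Simulated exploration: clamped place-cell spiking on a two-arm track.

During the plasticity ("online") phase pyramidal spiking is clamped to an
inhomogeneous Poisson process combining place tuning and theta phase
precession:

    lambda_i(t) = lambda_max [1/2 + 1/2 cos(2 pi f_theta t
                  + (pi / sigma) sign(x_i)(x(t) - x_i))]
                  * exp(-(x(t) - x_i)^2 / (2 sigma^2))

for place cells (baseline rate for the rest).  The virtual mouse runs at
constant speed from the midpoint to the end of one arm, teleports back,
and picks the opposite arm with 90% probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import IsStimConfig, PlaceFieldMap

__all__ = ["ExplorationResult", "place_rates", "simulate_trajectory", "simulate_exploration"]


@dataclass
class ExplorationResult:
    """Clamped spike trains plus the trajectory that generated them."""

    t_ms: np.ndarray               # trajectory sample times
    x_cm: np.ndarray               # position
    arm_sign: np.ndarray           # per-sample arm (+1 right / -1 left)
    spikes: dict[str, tuple[np.ndarray, np.ndarray]]  # pop -> (times_ms, ids)
    is_times_ms: np.ndarray
    is_targets: dict[int, np.ndarray]  # spike index -> CA3 neuron ids hit


def place_rates(x: np.ndarray, t_s: np.ndarray, pfm: PlaceFieldMap,
                centers: np.ndarray) -> np.ndarray:
    """Instantaneous rate (Hz) for cells with the given field centers.

    ``x`` and ``t_s`` are (T,); ``centers`` is (C,); returns (T, C).
    """
    dx = x[:, None] - centers[None, :]
    env = np.exp(-(dx**2) / (2 * pfm.sigma_cm**2))
    phase = (2 * np.pi * pfm.f_theta_hz * t_s[:, None]
             + np.pi / pfm.sigma_cm * np.sign(centers)[None, :] * dx)
    return pfm.lambda_max_hz * (0.5 + 0.5 * np.cos(phase)) * env


def simulate_trajectory(duration_s: float, speed_cm_s: float, half_track_cm: float,
                        alternation_p: float, dt_ms: float,
                        rng: np.random.Generator):
    """Constant-speed arm traversals with teleport returns.

    Returns (t_ms, x_cm, arm_sign, trial_starts_idx, trial_arm_signs).
    """
    dt_s = dt_ms / 1e3
    n = int(round(duration_s / dt_s))
    t_ms = np.arange(n) * dt_ms
    x = np.empty(n)
    arm = np.empty(n)
    trial_starts = []
    trial_arms = []
    i = 0
    current = 1.0 if rng.random() < 0.5 else -1.0
    n_per_trial = int(round(half_track_cm / speed_cm_s / dt_s))
    while i < n:
        trial_starts.append(i)
        trial_arms.append(current)
        m = min(n_per_trial, n - i)
        frac = np.arange(m) / n_per_trial
        x[i : i + m] = current * frac * half_track_cm
        arm[i : i + m] = current
        i += m
        if rng.random() < alternation_p:
            current = -current
    return t_ms, x, arm, np.array(trial_starts), np.array(trial_arms)


def _draw_poisson_spikes(rates_hz: np.ndarray, dt_s: float, t_ms: np.ndarray,
                         rng: np.random.Generator):
    hit = rng.random(rates_hz.shape) < rates_hz * dt_s
    ti, ci = np.nonzero(hit)
    return t_ms[ti], ci


def simulate_exploration(
    pfm_ca3: PlaceFieldMap,
    pfm_ca1: PlaceFieldMap,
    is_cfg: IsStimConfig,
    duration_s: float = 600.0,
    speed_cm_s: float = 35.0,
    alternation_p: float = 0.9,
    dt_ms: float = 1.0,
    seed: int = 0,
    chunk_steps: int = 20000,
) -> ExplorationResult:
    """Draw clamped CA3/CA1 pyramidal spike trains and the IS train.

    The IS train is drawn once from the location-locked rate profile (one
    IS location per arm traversal) and merged into the CA3 trains of the
    neurons that receive each spike.
    """
    rng = np.random.default_rng(seed)
    dt_s = dt_ms / 1e3
    t_ms, x, arm, trial_starts, trial_arms = simulate_trajectory(
        duration_s, speed_cm_s, pfm_ca3.half_track_cm, alternation_p, dt_ms, rng
    )
    n = len(t_ms)
    spikes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop, pfm in (("ca3_pyr", pfm_ca3), ("ca1_pyr", pfm_ca1)):
        n_cells = len(pfm.centers_cm)
        place_idx = np.nonzero(pfm.is_place)[0]
        times_list, ids_list = [], []
        for lo in range(0, n, chunk_steps):
            hi = min(n, lo + chunk_steps)
            rates = place_rates(x[lo:hi], t_ms[lo:hi] / 1e3, pfm,
                                pfm.centers_cm[place_idx])
            tt, cc = _draw_poisson_spikes(rates, dt_s, t_ms[lo:hi], rng)
            times_list.append(tt)
            ids_list.append(place_idx[cc])
        # non-place baseline
        non_place = np.nonzero(~pfm.is_place)[0]
        if len(non_place):
            n_bg = rng.poisson(pfm.baseline_hz * duration_s * len(non_place))
            times_list.append(rng.uniform(0, duration_s * 1e3, n_bg))
            ids_list.append(rng.choice(non_place, size=n_bg))
        times = np.concatenate(times_list)
        ids = np.concatenate(ids_list)
        order = np.argsort(times, kind="stable")
        spikes[pop] = (times[order], ids[order])

    is_times = np.empty(0)
    is_targets: dict[int, np.ndarray] = {}
    if is_cfg.mode != "off":
        # per-trial IS location on the traversed arm
        x_is = np.empty(n)
        edges = list(trial_starts) + [n]
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if is_cfg.mode == "clustered":
                loc = trial_arms[k] * is_cfg.reference_cm
            else:
                loc = trial_arms[k] * rng.uniform(0.0, pfm_ca3.half_track_cm)
            x_is[lo:hi] = loc
        rate = is_cfg.lambda_max_hz * np.exp(
            -((x - x_is) ** 2) / (2 * is_cfg.sigma_cm**2)
        )
        hit = np.nonzero(rng.random(n) < rate * dt_s)[0]
        is_times = t_ms[hit]
        # delivery: each spike reaches each eligible CA3 neuron with p_deliver
        t3, i3 = spikes["ca3_pyr"]
        extra_t, extra_i = [t3], [i3]
        centers = pfm_ca3.centers_cm
        for k, step in enumerate(hit):
            if is_cfg.delivery == "broadcast":
                eligible = np.arange(len(centers))
            else:
                env = np.exp(-((x[step] - centers) ** 2) / (2 * pfm_ca3.sigma_cm**2))
                eligible = np.nonzero(pfm_ca3.is_place & (env >= is_cfg.active_threshold))[0]
            recv = eligible[rng.random(len(eligible)) < is_cfg.p_deliver]
            is_targets[k] = recv
            if len(recv):
                extra_t.append(np.full(len(recv), t_ms[step]))
                extra_i.append(recv)
        tt = np.concatenate(extra_t)
        ii = np.concatenate(extra_i)
        order = np.argsort(tt, kind="stable")
        spikes["ca3_pyr"] = (tt[order], ii[order])

    return ExplorationResult(
        t_ms=t_ms, x_cm=x, arm_sign=arm, spikes=spikes,
        is_times_ms=is_times, is_targets=is_targets,
    )
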