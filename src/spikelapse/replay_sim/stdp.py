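"""Trace-based all-pairs STDP on normalized weights.

Every pre/post spike pair contributes one update through exponentially
decaying eligibility traces: a presynaptic spike depresses (or, with
alpha < 0, facilitates) each outgoing synapse in proportion to the
postsynaptic trace with time constant tau_minus; a postsynaptic spike
potentiates each incoming synapse in proportion to the presynaptic trace
with time constant tau_plus.  Weights are clipped to [0, 1] after every
update.  Simultaneous pre/post spikes are processed pre-first, so a
coincident pair takes the potentiation branch.
"""

from __future__ import annotations

import numpy as np

from .params import StdpConfig

__all__ = ["random_connectivity", "initial_weights", "train_stdp"]


def random_connectivity(n_pre: int, n_post: int, p: float,
                        rng: np.random.Generator,
                        no_self: bool = False) -> np.ndarray:
    """Boolean (n_pre, n_post) adjacency with connection probability p."""
    mask = rng.random((n_pre, n_post)) < p
    if no_self and n_pre == n_post:
        np.fill_diagonal(mask, False)
    return mask


def initial_weights(mask: np.ndarray, loc_scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Normalized initial weights: loc_scale * LogNormal(0, 1), clipped to [0, 1].

    The log-normal has unbounded support, so values above 1 (which the
    normalized-weight bookkeeping cannot represent) are clipped.
    """
    w = np.zeros(mask.shape)
    w[mask] = np.clip(loc_scale * rng.lognormal(0.0, 1.0, mask.sum()), 0.0, 1.0)
    return w


def pair_update(dt_ms: float, w: float, cfg: StdpConfig) -> float:
    """Single-pair weight change for lag dt = t_post - t_pre (reference rule)."""
    if dt_ms > 0:
        return cfg.lambda_step * (1.0 - w) ** cfg.mu_plus * np.exp(-dt_ms / cfg.tau_plus_ms)
    return -cfg.lambda_step * cfg.alpha * w**cfg.mu_minus * np.exp(-abs(dt_ms) / cfg.tau_minus_ms)


def train_stdp(
    pre_times_ms: np.ndarray,
    pre_ids: np.ndarray,
    post_times_ms: np.ndarray,
    post_ids: np.ndarray,
    mask: np.ndarray,
    w0: np.ndarray,
    cfg: StdpConfig,
    recurrent: bool = False,
) -> np.ndarray:
    """Apply STDP over the full spike record; returns the final weights.

    For a recurrent projection pass the same spike arrays for pre and
    post (each spike then acts in both roles).  Requires mu = 0 (weight-
    independent updates), which is the configuration used throughout.
    """
    if cfg.mu_plus != 0 or cfg.mu_minus != 0:
        raise NotImplementedError("vectorized path assumes weight-independent updates")
    n_pre, n_post = mask.shape
    w = w0.copy()
    trace_pre = np.zeros(n_pre)    # decays with tau_plus; bumped by pre spikes
    trace_post = np.zeros(n_post)  # decays with tau_minus; bumped by post spikes
    if recurrent:
        events_t = np.asarray(pre_times_ms, dtype=float)
        order = np.argsort(events_t, kind="stable")
        events_t = events_t[order]
        events_i = np.asarray(pre_ids)[order]
        events_role = np.zeros(len(events_t), dtype=np.int8)  # both roles
    else:
        events_t = np.concatenate([pre_times_ms, post_times_ms]).astype(float)
        events_i = np.concatenate([pre_ids, post_ids])
        events_role = np.concatenate([
            np.ones(len(pre_times_ms), dtype=np.int8),    # 1 = pre only
            np.full(len(post_times_ms), 2, dtype=np.int8)  # 2 = post only
        ])
        # stable sort keeps pre before post at equal times -> coincident
        # pairs take the potentiation branch
        order = np.argsort(events_t, kind="stable")
        events_t, events_i, events_role = events_t[order], events_i[order], events_role[order]
    t_last = 0.0
    dp = cfg.lambda_step
    dm = -cfg.lambda_step * cfg.alpha
    for t, i, role in zip(events_t, events_i, events_role):
        dt = t - t_last
        if dt > 0:
            trace_pre *= np.exp(-dt / cfg.tau_plus_ms)
            trace_post *= np.exp(-dt / cfg.tau_minus_ms)
            t_last = t
        if role != 2:  # acts as pre: depression/facilitation on its targets
            row = mask[i]
            w[i, row] = np.clip(w[i, row] + dm * trace_post[row], 0.0, 1.0)
        if role != 1:  # acts as post: potentiation on its sources
            col = mask[:, i]
            w[col, i] = np.clip(w[col, i] + dp * trace_pre[col], 0.0, 1.0)
        if role != 2:
            trace_pre[i] += 1.0
        if role != 1:
            trace_post[i] += 1.0
    np.clip(w, 0.0, 1.0, out=w)
    w[~mask] = 0.0
    return w
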