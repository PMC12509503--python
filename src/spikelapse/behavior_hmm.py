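"""Hidden Markov model of trial-to-trial task engagement.

Choice outcomes (correct / incorrect) on a delayed alternation task are
modeled as Bernoulli emissions of a discrete latent behavioral state that
evolves as a sticky Markov chain across trials.  Sessions are independent
sequences: the chain re-initializes from the initial distribution at every
session boundary.  Fitting is by Baum-Welch expectation-maximization over
the concatenated multi-session data; decoding by Viterbi (joint MAP path)
and forward-backward (per-trial marginals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HmmParams",
    "ChoiceData",
    "StatePosterior",
    "init_params",
    "simulate_choices",
    "baum_welch",
    "viterbi",
    "forward_backward",
    "hierarchical_bootstrap",
]


@dataclass
class HmmParams:
    """Parameters of an N-state Bernoulli-emission HMM.

    Attributes
    ----------
    A : (N, N) row-stochastic transition matrix, ``A[s, s']`` the
        probability of moving from state ``s`` to ``s'`` between trials.
    alpha0 : (N,) initial state distribution used at each session start.
    p_s : (N,) per-state probability of a correct choice.
    epsilon : stickiness parameter used by :func:`init_params`.
    """

    A: np.ndarray
    alpha0: np.ndarray
    p_s: np.ndarray
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.alpha0 = np.asarray(self.alpha0, dtype=float)
        self.p_s = np.asarray(self.p_s, dtype=float)
        n = self.n_states
        if self.A.shape != (n, n):
            raise ValueError("A must be N x N")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of A must sum to 1")
        if not np.isclose(self.alpha0.sum(), 1.0, atol=1e-8):
            raise ValueError("alpha0 must sum to 1")
        if np.any(self.p_s <= 0.0) or np.any(self.p_s >= 1.0):
            raise ValueError("p_s must lie in (0, 1)")

    @property
    def n_states(self) -> int:
        return len(self.p_s)


@dataclass
class ChoiceData:
    """Concatenated per-trial correctness with session boundaries.

    ``boundaries`` holds the start index of every session; sessions
    partition ``correct`` into contiguous blocks.
    """

    correct: np.ndarray
    boundaries: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.correct = np.asarray(self.correct, dtype=int)
        if self.boundaries is None:
            self.boundaries = np.array([0])
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if len(self.correct) and (self.boundaries[0] != 0 or np.any(np.diff(self.boundaries) <= 0)):
            raise ValueError("boundaries must start at 0 and strictly increase")
        if len(self.correct) and self.boundaries[-1] >= len(self.correct) + 1:
            raise ValueError("boundary beyond data")

    def sessions(self):
        """Yield the per-session slices of the correctness vector."""
        edges = list(self.boundaries) + [len(self.correct)]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                yield self.correct[lo:hi]


@dataclass
class StatePosterior:
    viterbi_path: np.ndarray
    marginals: np.ndarray
    log_likelihood: float


def init_params(N: int, epsilon: float = 0.5) -> HmmParams:
    """Sticky initialization for Baum-Welch.

    The transition matrix is ``(I + eps * J) / (1 + N * eps)`` (J all-ones),
    which is row-stochastic, concentrates mass on the diagonal for small
    ``epsilon`` and tends to the uniform matrix as ``epsilon`` grows.  The
    initial distribution is uniform and the emission probabilities are N
    uniformly spaced values in [0.1, 0.9].
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    A = (np.eye(N) + epsilon * np.ones((N, N))) / (1.0 + N * epsilon)
    alpha0 = np.full(N, 1.0 / N)
    p_s = np.linspace(0.1, 0.9, N) if N > 1 else np.array([0.5])
    return HmmParams(A=A, alpha0=alpha0, p_s=p_s, epsilon=epsilon)


def simulate_choices(
    params: HmmParams,
    n_sessions: int,
    trials_per_session: int,
    rng: np.random.Generator,
    return_states: bool = False,
):
    """Draw choice sequences (and optionally state paths) from the model."""
    N = params.n_states
    correct = []
    states = []
    boundaries = []
    idx = 0
    for _ in range(n_sessions):
        boundaries.append(idx)
        s = rng.choice(N, p=params.alpha0)
        for _ in range(trials_per_session):
            states.append(s)
            correct.append(int(rng.random() < params.p_s[s]))
            s = rng.choice(N, p=params.A[s])
            idx += 1
    data = ChoiceData(np.array(correct), np.array(boundaries))
    if return_states:
        return data, np.array(states)
    return data


def _emission_probs(obs: np.ndarray, p_s: np.ndarray) -> np.ndarray:
    # (T, N) likelihood of each observation under each state
    return np.where(obs[:, None] == 1, p_s[None, :], 1.0 - p_s[None, :])


def _forward_backward_scaled(obs, params):
    """Scaled forward-backward for one session.

    Returns (gamma, xi_sum, log_likelihood): per-trial marginals, summed
    pairwise posteriors, and the session log-likelihood.
    """
    A, alpha0 = params.A, params.alpha0
    B = _emission_probs(obs, params.p_s)
    T, N = B.shape
    alpha = np.empty((T, N))
    c = np.empty(T)
    alpha[0] = alpha0 * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, N))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        right = B[1:] * beta[1:] / c[1:, None]
        xi_sum = (alpha[:-1].T @ right) * A
    else:
        xi_sum = np.zeros((N, N))
    return gamma, xi_sum, float(np.log(c).sum())


def log_likelihood(data: ChoiceData, params: HmmParams) -> float:
    """Total log-likelihood of the concatenated choice data."""
    return sum(_forward_backward_scaled(obs, params)[2] for obs in data.sessions())


def baum_welch(
    data: ChoiceData,
    init: HmmParams,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[HmmParams, float]:
    """EM fit over multiple independent sessions.

    Each session restarts from ``alpha0``; sufficient statistics are pooled
    across sessions.  The log-likelihood is non-decreasing per iteration
    (asserted); convergence at relative change below ``tol``.
    """
    params = init
    N = params.n_states
    prev_ll = -np.inf
    ll = prev_ll
    for _ in range(max_iter):
        gamma0 = np.zeros(N)
        xi_tot = np.zeros((N, N))
        num_p = np.zeros(N)
        den_p = np.zeros(N)
        ll = 0.0
        n_sessions = 0
        for obs in data.sessions():
            gamma, xi_sum, sess_ll = _forward_backward_scaled(obs, params)
            gamma0 += gamma[0]
            xi_tot += xi_sum
            num_p += gamma[obs == 1].sum(axis=0)
            den_p += gamma.sum(axis=0)
            ll += sess_ll
            n_sessions += 1
        if n_sessions == 0:
            raise ValueError("no non-empty sessions")
        if ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
            raise AssertionError("EM log-likelihood decreased")
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll
        A = xi_tot / np.clip(xi_tot.sum(axis=1, keepdims=True), 1e-300, None)
        # sessions of length 1 contribute no transitions; keep old rows then
        A = np.where(xi_tot.sum(axis=1, keepdims=True) > 0, A, params.A)
        alpha0 = gamma0 / gamma0.sum()
        p_s = np.clip(num_p / np.clip(den_p, 1e-300, None), 1e-6, 1 - 1e-6)
        params = HmmParams(A=A, alpha0=alpha0, p_s=p_s, epsilon=params.epsilon)
    return params, float(ll)


def viterbi(data: ChoiceData, params: HmmParams) -> np.ndarray:
    """Jointly most probable state path, computed per session in log space.

    Ties break toward the lowest state index.
    """
    paths = []
    logA = np.log(params.A)
    log_alpha0 = np.log(params.alpha0)
    for obs in data.sessions():
        logB = np.log(_emission_probs(obs, params.p_s))
        T, N = logB.shape
        delta = np.empty((T, N))
        psi = np.zeros((T, N), dtype=int)
        delta[0] = log_alpha0 + logB[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            psi[t] = np.argmax(cand, axis=0)  # argmax picks lowest index on ties
            delta[t] = cand[psi[t], np.arange(N)] + logB[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        paths.append(path)
    return np.concatenate(paths) if paths else np.empty(0, dtype=int)


def forward_backward(data: ChoiceData, params: HmmParams) -> StatePosterior:
    """Per-trial state marginals plus the Viterbi path and log-likelihood."""
    gammas = []
    ll = 0.0
    for obs in data.sessions():
        gamma, _, sess_ll = _forward_backward_scaled(obs, params)
        gammas.append(gamma)
        ll += sess_ll
    marginals = np.vstack(gammas) if gammas else np.empty((0, params.n_states))
    return StatePosterior(
        viterbi_path=viterbi(data, params),
        marginals=marginals,
        log_likelihood=float(ll),
    )


def hierarchical_bootstrap(
    values: np.ndarray,
    states: np.ndarray,
    animal_ids: np.ndarray,
    n_rep: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> dict[int, dict]:
    """State-stratified two-level bootstrap of per-trial values.

    For each state, ``n_rep`` replicate means are built by repeatedly
    drawing an animal with probability proportional to its trial count in
    that state and then one of its trials uniformly, until the replicate
    matches the stratum size.  Returns per-state mean and percentile CI.
    """
    if rng is None:
        rng = np.random.default_rng()
    values = np.asarray(values, dtype=float)
    states = np.asarray(states)
    animal_ids = np.asarray(animal_ids)
    out: dict[int, dict] = {}
    for s in np.unique(states):
        mask = states == s
        vals = values[mask]
        anims = animal_ids[mask]
        uniq, counts = np.unique(anims, return_counts=True)
        weights = counts / counts.sum()
        n = len(vals)
        by_animal = [vals[anims == a] for a in uniq]
        reps = np.empty(n_rep)
        for r in range(n_rep):
            picks = rng.choice(len(uniq), size=n, p=weights)
            reps[r] = np.mean(
                [by_animal[k][rng.integers(len(by_animal[k]))] for k in picks]
            )
        lo, hi = np.percentile(reps, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
        out[int(s)] = {"mean": float(reps.mean()), "ci": (float(lo), float(hi))}
    return out
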