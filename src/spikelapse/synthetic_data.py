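"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here: LFP traces (1/f
noise + theta band + embedded biexponential IS transients), figure-8 maze
trajectories with delay / choice / outer-arm / reward zones, trial tables
whose choice outcomes come from a sticky Bernoulli-emission HMM, IS event
times from a non-homogeneous Poisson process with zone-specific gains, and
hand-label-style windows around events.  All generators are deterministic
given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior_hmm import HmmParams, simulate_choices
from .is_detection import LabeledWindow, LfpTrace
from .maze_zones import Trajectory, ZoneMap, default_zone_map

__all__ = [
    "SynthConfig",
    "default_hmm_truth",
    "make_lfp",
    "make_behavior",
    "make_labeled_windows",
    "draw_window_widths",
]

# Biexponential IS transient: sharp rise, slower decay.
IS_RISE_MS = 2.0
IS_DECAY_MS = 15.0

# Truncated log-normal for labeled-window widths (ms): parameters solved so
# the [14, 724] ms truncated distribution has mean 100 ms and sd 92 ms.
WIDTH_LOG_MU = 4.2234092
WIDTH_LOG_SIGMA = 0.87238222
WIDTH_MIN_MS = 14.0
WIDTH_MAX_MS = 724.0

# Mean delay-zone exit latency (s past the 30 s interval) per behavioral
# state, ordered by state success rate (perseveration, guess, engaged).
EXIT_LATENCY_MEANS_S = (12.0, 7.85, 7.6)
EXIT_LATENCY_SD_S = 1.0


def default_hmm_truth() -> HmmParams:
    """Sticky 3-state ground truth: success rates 19% / 53% / 75%."""
    A = np.full((3, 3), 0.04)
    np.fill_diagonal(A, 0.92)
    return HmmParams(A=A, alpha0=np.full(3, 1 / 3), p_s=np.array([0.19, 0.53, 0.75]))


@dataclass
class SynthConfig:
    """Ground-truth configuration for all generators.

    Amplitudes are in microvolts; ``noise_rms_uV`` and ``theta_amp_uV``
    set the noise floor (the IS signal-to-noise ratio is a free choice of
    the experiment, not a measured quantity).
    """

    seed: int = 0
    fs_hz: float = 1000.0
    duration_s: float = 600.0
    theta_hz: float = 7.0
    noise_exponent: float = 1.0
    is_amp_uV: float = 1500.0
    noise_rms_uV: float = 150.0
    theta_amp_uV: float = 100.0
    zone_gains: dict = field(
        default_factory=lambda: {"delay": 1.0, "choice": 1.0, "outer_arm": 1.35, "reward": 1.9}
    )
    base_rate_hz: float = 0.5
    hmm_truth: HmmParams = field(default_factory=default_hmm_truth)
    n_sessions: int = 5
    trials_per_session: int = 20
    run_speed_cm_s: float = 20.0
    pos_fs_hz: float = 30.0
    pos_jitter_cm: float = 0.0
    reward_dwell_s: float = 4.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fs_hz and duration_s must be > 0")
        if any(g <= 0 for g in self.zone_gains.values()):
            raise ValueError("zone gains must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-rms 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _is_kernel(fs_hz: float) -> np.ndarray:
    """Unit-peak biexponential transient (2 ms rise, 15 ms decay)."""
    t = np.arange(0.0, 8 * IS_DECAY_MS / 1e3, 1.0 / fs_hz)
    k = np.exp(-t / (IS_DECAY_MS / 1e3)) - np.exp(-t / (IS_RISE_MS / 1e3))
    return k / k.max()


def make_lfp(cfg: SynthConfig, event_times: np.ndarray) -> LfpTrace:
    """Pink noise + theta sinusoid + one IS transient per event time."""
    event_times = np.asarray(event_times, dtype=float)
    if np.any(event_times < 0) or np.any(event_times > cfg.duration_s):
        raise ValueError("event times must lie within [0, duration_s]")
    n = int(round(cfg.duration_s * cfg.fs_hz))
    rng = cfg.rng(stream=1)
    trace = np.zeros(n)
    if cfg.noise_rms_uV > 0:
        trace += cfg.noise_rms_uV * _pink_noise(n, cfg.noise_exponent, rng)
    if cfg.theta_amp_uV > 0:
        t = np.arange(n) / cfg.fs_hz
        trace += cfg.theta_amp_uV * np.sin(2 * np.pi * cfg.theta_hz * t)
    if cfg.is_amp_uV != 0 and len(event_times):
        kernel = cfg.is_amp_uV * _is_kernel(cfg.fs_hz)
        for ev in event_times:
            i0 = int(round(ev * cfg.fs_hz))
            seg = kernel[: max(0, n - i0)]
            trace[i0 : i0 + len(seg)] += seg
    return LfpTrace(samples=trace, fs_hz=cfg.fs_hz)


def _trial_waypoints(zm: ZoneMap, side: str) -> list[tuple[float, float]]:
    sgn = 1.0 if side == "east" else -1.0
    x0, x1, y0, y1 = zm.bounds
    hw = x1
    h = y1
    return [
        (0.0, 30.0),              # delay center (dwell happens here)
        (0.0, h - 5.0),           # up the stem into the choice box
        (sgn * (hw - 5.0), h - 5.0),  # along the top corridor
        (sgn * (hw - 5.0), 12.5),     # down the side arm into reward
        (sgn * (hw - 7.5), 12.5),     # reward port (dwell)
        (sgn * (hw - 7.5), 5.0),      # exit reward downward
        (0.0, 5.0),               # return corridor
        (0.0, 30.0),              # back to the delay zone
    ]


def _walk(points, speed, fs, t0):
    """Constant-speed linear interpolation through waypoints, sampled at fs."""
    xs, ys, ts = [], [], []
    t = t0
    for (xa, ya), (xb, yb) in zip(points[:-1], points[1:]):
        d = float(np.hypot(xb - xa, yb - ya))
        if d == 0:
            continue
        dur = d / speed
        n = max(1, int(round(dur * fs)))
        frac = np.arange(n) / n
        xs.append(xa + frac * (xb - xa))
        ys.append(ya + frac * (yb - ya))
        ts.append(t + frac * dur)
        t += dur
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(ts), t


def make_behavior(
    cfg: SynthConfig,
    zm: ZoneMap | None = None,
    delay_interval_s: float = 30.0,
):
    """Generate trajectory, trial table, IS events, and ground truth.

    The trajectory visits delay -> stem/choice -> outer arm -> reward ->
    return per trial; choice outcomes follow the ground-truth HMM; IS event
    times are a Poisson process with rate ``base_rate_hz * gain(zone)``.

    Returns a dict with keys ``trajectory``, ``trials``, ``event_times_s``,
    ``event_zones``, ``zones`` (per-sample ground-truth zone classes),
    ``states`` (per-trial HMM states), and ``choice_data``.
    """
    if cfg.trials_per_session < 1:
        raise ValueError("trials_per_session must be >= 1")
    if zm is None:
        zm = default_zone_map()
    rng = cfg.rng(stream=2)
    choice_data, states = simulate_choices(
        cfg.hmm_truth, cfg.n_sessions, cfg.trials_per_session, rng, return_states=True
    )
    # order states by success rate so exit-latency means line up
    order = np.argsort(cfg.hmm_truth.p_s)
    rank_of_state = np.empty_like(order)
    rank_of_state[order] = np.arange(len(order))

    xs_all, ys_all, ts_all = [], [], []
    rows = []
    t = 0.0
    trial_idx = 0
    fs = cfg.pos_fs_hz
    for sess in range(cfg.n_sessions):
        prev_side = None
        for k in range(cfg.trials_per_session):
            correct = bool(choice_data.correct[trial_idx])
            state = states[trial_idx]
            if prev_side is None:
                # alternation is undefined on the first trial: count correct
                correct = True
                choice_data.correct[trial_idx] = 1
                side = "east" if rng.random() < 0.5 else "west"
            else:
                side = ({"east": "west", "west": "east"}[prev_side]
                        if correct else prev_side)
            rank = rank_of_state[state]
            latency = max(
                0.5, rng.normal(EXIT_LATENCY_MEANS_S[min(rank, 2)], EXIT_LATENCY_SD_S)
            )
            dwell = delay_interval_s + latency
            n_dwell = max(1, int(round(dwell * fs)))
            delay_entry = t
            xs_all.append(np.zeros(n_dwell))
            ys_all.append(np.full(n_dwell, 30.0))
            ts_all.append(t + np.arange(n_dwell) / fs)
            t += n_dwell / fs
            wp = _trial_waypoints(zm, side)
            # outbound to reward port
            x1, y1, tt1, t = _walk(wp[:5], cfg.run_speed_cm_s, fs, t)
            xs_all.append(x1); ys_all.append(y1); ts_all.append(tt1)
            # reward dwell
            n_rw = max(1, int(round(cfg.reward_dwell_s * fs)))
            xs_all.append(np.full(n_rw, wp[4][0]))
            ys_all.append(np.full(n_rw, wp[4][1]))
            ts_all.append(t + np.arange(n_rw) / fs)
            t += n_rw / fs
            # return leg
            x2, y2, tt2, t = _walk(wp[4:], cfg.run_speed_cm_s, fs, t)
            xs_all.append(x2); ys_all.append(y2); ts_all.append(tt2)
            rows.append(
                {
                    "session": sess,
                    "trial": k,
                    "choice": side,
                    "correct": correct,
                    "state": int(state),
                    "delay_entry_s": delay_entry,
                    "delay_exit_s": delay_entry + dwell,
                    "delay_exit_latency_s": latency,
                }
            )
            prev_side = side
            trial_idx += 1
    x = np.concatenate(xs_all)
    y = np.concatenate(ys_all)
    ts = np.concatenate(ts_all)
    if cfg.pos_jitter_cm > 0:
        x = x + rng.normal(0, cfg.pos_jitter_cm, len(x))
        y = y + rng.normal(0, cfg.pos_jitter_cm, len(y))
    traj = Trajectory(t_s=ts, x_cm=x, y_cm=y)
    zones = np.array(
        [zm.zone_class.get(zm.lookup(xi, yi), "none") for xi, yi in zip(x, y)],
        dtype=object,
    )
    # non-homogeneous Poisson events by thinning
    gains = np.array([cfg.zone_gains.get(z, 1.0) for z in zones])
    rate_max = cfg.base_rate_hz * gains.max()
    total_t = ts[-1]
    n_cand = rng.poisson(rate_max * total_t)
    cand = np.sort(rng.uniform(0, total_t, n_cand))
    idx = np.clip(np.searchsorted(ts, cand), 0, len(ts) - 1)
    accept = rng.uniform(0, rate_max, n_cand) < cfg.base_rate_hz * gains[idx]
    event_times = cand[accept]
    event_zones = zones[idx[accept]]
    trials = pd.DataFrame(rows)
    return {
        "trajectory": traj,
        "trials": trials,
        "event_times_s": event_times,
        "event_zones": event_zones,
        "zones": zones,
        "states": states,
        "choice_data": choice_data,
        "zone_map": zm,
    }


def draw_window_widths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Label-window widths (s): truncated log-normal, mean 100 ms, sd 92 ms."""
    widths = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(WIDTH_LOG_MU, WIDTH_LOG_SIGMA, size=2 * (n - filled))
        keep = draw[(draw >= WIDTH_MIN_MS) & (draw <= WIDTH_MAX_MS)]
        take = min(len(keep), n - filled)
        widths[filled : filled + take] = keep[:take]
        filled += take
    return widths / 1e3


def make_labeled_windows(
    event_times: np.ndarray,
    jitter_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[LabeledWindow]:
    """One window per event, each guaranteed to contain its event.

    The window center is the event time plus a Gaussian jitter (sd
    ``jitter_s``) clipped so the event stays inside; consecutive
    overlapping windows are clipped at the midpoint between their events.
    """
    if jitter_s < 0:
        raise ValueError("jitter_s must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    event_times = np.sort(np.asarray(event_times, dtype=float))
    widths = draw_window_widths(len(event_times), rng)
    starts = np.empty(len(event_times))
    ends = np.empty(len(event_times))
    for k, (t, w) in enumerate(zip(event_times, widths)):
        off = np.clip(rng.normal(0, jitter_s), -0.45 * w, 0.45 * w) if jitter_s > 0 else 0.0
        starts[k] = t + off - w / 2
        ends[k] = t + off + w / 2
    for k in range(1, len(event_times)):
        if starts[k] < ends[k - 1]:
            mid = 0.5 * (event_times[k - 1] + event_times[k])
            ends[k - 1] = min(ends[k - 1], mid)
            starts[k] = max(starts[k], mid)
    return [
        LabeledWindow(t_start_s=float(s), t_end_s=float(e))
        for s, e in zip(starts, ends)
        if e > s
    ]
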