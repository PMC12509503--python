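"""Interictal-spike (IS) detection, detector tuning, and event taxonomy.

Detection runs on a single LFP channel: the trace is polarity-oriented by
the sign of its skewness (so the heavy IS tail points positive),
down-sampled to 1 kHz, band-pass filtered with a zero-phase Butterworth,
and local maxima with topographic prominence above a threshold are taken
as IS times.  The detector is tuned against hand-labeled windows by
exhaustive grid search maximizing the F_{1/2} score, which weights
precision over recall.  Detected spike trains are classified into
solitary IS, BIRDs (chains with inter-spike intervals under 2 s), and
seizures (such chains lasting at least 10 s).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "LfpTrace",
    "DetectorConfig",
    "EventSeries",
    "DetectorScore",
    "LabeledWindow",
    "orient_polarity",
    "detect_spikes",
    "score_detector",
    "f_beta",
    "tune_detector",
    "default_tuning_grid",
    "classify_events",
    "detect_seizures",
    "event_statistics",
]

BIRD_ISI_S = 2.0
SEIZURE_MIN_DURATION_S = 10.0
DETECT_FS_HZ = 1000.0


@dataclass
class LfpTrace:
    """Single-channel LFP in microvolts."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs_hz


@dataclass(frozen=True)
class DetectorConfig:
    threshold_uV: float
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.threshold_uV <= 0:
            raise ValueError("threshold_uV must be > 0")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass(frozen=True)
class LabeledWindow:
    """A hand-labeled time window that may contain one IS."""

    t_start_s: float
    t_end_s: float
    contains_event: bool = True

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError("t_end_s must exceed t_start_s")


@dataclass
class EventSeries:
    """Detected IS with taxonomy labels and optional rms amplitudes.

    Labels are one of solitary / bird_first / bird_within / bird_last;
    ``bird_id`` is -1 for solitary spikes and groups BIRD members.
    """

    times_s: np.ndarray
    labels: np.ndarray
    bird_id: np.ndarray
    amplitude_rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.bird_id = np.asarray(self.bird_id, dtype=int)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        for b in np.unique(self.bird_id[self.bird_id >= 0]):
            members = self.labels[self.bird_id == b]
            if len(members) < 2:
                raise ValueError("a BIRD needs >= 2 spikes")
            if np.sum(members == "bird_first") != 1 or np.sum(members == "bird_last") != 1:
                raise ValueError("a BIRD needs exactly one first and one last spike")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class DetectorScore:
    tp: int
    fp: int
    fn: int
    beta: float = 0.5
    precision: float = field(init=False)
    recall: float = field(init=False)
    f_beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        self.f_beta = f_beta(self.precision, self.recall, self.beta)


def f_beta(precision: float, recall: float, beta: float = 0.5) -> float:
    """F_beta = (1 + beta^2) P R / (beta^2 P + R); 0 when P = R = 0."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


def orient_polarity(trace: LfpTrace) -> LfpTrace:
    """Flip the trace so its heavy (IS) tail points positive.

    Multiplies by the sign of the sample skewness; zero-skew traces are
    returned unchanged, constant traces are rejected.
    """
    if np.ptp(trace.samples) == 0:
        raise ValueError("constant trace has no polarity")
    sk = stats.skew(trace.samples)
    sign = 1.0 if sk >= 0 else -1.0
    return LfpTrace(samples=sign * trace.samples, fs_hz=trace.fs_hz)


def _resample_to(trace: LfpTrace, fs_hz: float) -> LfpTrace:
    if np.isclose(trace.fs_hz, fs_hz):
        return trace
    from fractions import Fraction

    frac = Fraction(fs_hz / trace.fs_hz).limit_denominator(1000)
    out = signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return LfpTrace(samples=out, fs_hz=fs_hz)


def detect_spikes(trace: LfpTrace, cfg: DetectorConfig) -> np.ndarray:
    """Times of band-passed local maxima with prominence >= threshold.

    The trace is resampled to 1 kHz if needed, filtered with a zero-phase
    order-3 Butterworth in [low_hz, high_hz], and peak prominences are
    evaluated topographically (scipy ``find_peaks``).
    """
    trace = _resample_to(trace, DETECT_FS_HZ)
    nyq = trace.fs_hz / 2.0
    if not (0 < cfg.low_hz < cfg.high_hz < nyq):
        raise ValueError(f"passband ({cfg.low_hz}, {cfg.high_hz}) infeasible at fs {trace.fs_hz}")
    sos = signal.butter(3, [cfg.low_hz, cfg.high_hz], btype="band", fs=trace.fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, trace.samples)
    peaks, _ = signal.find_peaks(filt, prominence=cfg.threshold_uV)
    return peaks / trace.fs_hz


def score_detector(
    detections: np.ndarray,
    windows: list[LabeledWindow],
    beta: float = 0.5,
) -> DetectorScore:
    """Score detections against non-overlapping labeled windows.

    A window with at least one detection is one TP; every additional
    detection inside a window is an FP, as is every detection outside all
    windows; a window with none is an FN.
    """
    detections = np.sort(np.asarray(detections, dtype=float))
    windows = sorted(windows, key=lambda w: w.t_start_s)
    for w1, w2 in zip(windows[:-1], windows[1:]):
        if w2.t_start_s < w1.t_end_s:
            raise ValueError("windows must be non-overlapping")
    tp = fp = fn = 0
    inside = np.zeros(len(detections), dtype=bool)
    for w in windows:
        lo = np.searchsorted(detections, w.t_start_s, side="left")
        hi = np.searchsorted(detections, w.t_end_s, side="right")
        count = hi - lo
        inside[lo:hi] = True
        if count >= 1:
            tp += 1
            fp += count - 1
        else:
            fn += 1
    fp += int(np.sum(~inside))
    return DetectorScore(tp=tp, fp=fp, fn=fn, beta=beta)


def default_tuning_grid() -> list[DetectorConfig]:
    """Thresholds 500-2500 uV (step 100), low edge {1,2,4,8,16} Hz, high {200,400} Hz."""
    return [
        DetectorConfig(threshold_uV=thr, low_hz=lo, high_hz=hi)
        for thr, lo, hi in itertools.product(
            range(500, 2600, 100), (1, 2, 4, 8, 16), (200, 400)
        )
    ]


def tune_detector(
    trace: LfpTrace,
    windows: list[LabeledWindow],
    grid: list[DetectorConfig] | None = None,
    beta: float = 0.5,
) -> tuple[DetectorConfig, DetectorScore]:
    """Exhaustive grid search maximizing F_beta.

    Ties break toward the higher threshold, then the narrower passband.
    The band-pass filter is recomputed per passband, not per threshold.
    """
    if grid is None:
        grid = default_tuning_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    trace = _resample_to(trace, DETECT_FS_HZ)
    best: tuple[float, float, float, DetectorConfig, DetectorScore] | None = None
    by_band: dict[tuple[float, float], list[DetectorConfig]] = {}
    for cfg in grid:
        by_band.setdefault((cfg.low_hz, cfg.high_hz), []).append(cfg)
    for (lo, hi), cfgs in by_band.items():
        sos = signal.butter(3, [lo, hi], btype="band", fs=trace.fs_hz, output="sos")
        filt = signal.sosfiltfilt(sos, trace.samples)
        peaks, props = signal.find_peaks(filt, prominence=0.0)
        prom = props["prominences"]
        for cfg in cfgs:
            det = peaks[prom >= cfg.threshold_uV] / trace.fs_hz
            score = score_detector(det, windows, beta=beta)
            key = (score.f_beta, cfg.threshold_uV, -(cfg.high_hz - cfg.low_hz))
            if best is None or key > best[:3]:
                best = (*key, cfg, score)
    assert best is not None
    return best[3], best[4]


def classify_events(times_s: np.ndarray) -> EventSeries:
    """Partition a sorted spike train into solitary IS and BIRDs.

    Maximal runs of consecutive inter-spike intervals below 2 s with at
    least two spikes form one BIRD with first/within/last labels; every
    other spike is solitary.
    """
    times_s = np.asarray(times_s, dtype=float)
    n = len(times_s)
    labels = np.array(["solitary"] * n, dtype=object)
    bird_id = np.full(n, -1, dtype=int)
    if n == 0:
        return EventSeries(times_s, labels, bird_id)
    isi = np.diff(times_s)
    next_bird = 0
    i = 0
    while i < n - 1:
        if isi[i] < BIRD_ISI_S:
            j = i
            while j < n - 1 and isi[j] < BIRD_ISI_S:
                j += 1
            labels[i] = "bird_first"
            labels[j] = "bird_last"
            labels[i + 1 : j] = "bird_within"
            bird_id[i : j + 1] = next_bird
            next_bird += 1
            i = j + 1
        else:
            i += 1
    return EventSeries(times_s, labels, bird_id)


def detect_seizures(times_s: np.ndarray) -> list[tuple[float, float]]:
    """Spans of sub-2 s ISI trains whose duration reaches 10 s."""
    events = classify_events(times_s)
    out = []
    for b in np.unique(events.bird_id[events.bird_id >= 0]):
        t = events.times_s[events.bird_id == b]
        if t[-1] - t[0] >= SEIZURE_MIN_DURATION_S:
            out.append((float(t[0]), float(t[-1])))
    return out


def event_statistics(events: EventSeries, session_duration_s: float) -> dict:
    """Pooled IS rate, solitary rate, BIRD onset rate, durations, sizes."""
    if session_duration_s <= 0:
        raise ValueError("session_duration_s must be > 0")
    bird_ids = np.unique(events.bird_id[events.bird_id >= 0])
    durations = []
    sizes = []
    for b in bird_ids:
        t = events.times_s[events.bird_id == b]
        durations.append(float(t[-1] - t[0]))
        sizes.append(int(len(t)))
    return {
        "is_rate_hz": len(events) / session_duration_s,
        "solitary_rate_hz": float(np.sum(events.labels == "solitary")) / session_duration_s,
        "bird_rate_hz": len(bird_ids) / session_duration_s,
        "bird_durations_s": np.array(durations),
        "spikes_per_bird": np.array(sizes),
    }


def event_amplitudes(
    trace: LfpTrace, times_s: np.ndarray, half_window_s: float = 0.1
) -> np.ndarray:
    """Per-event rms amplitude over +/-100 ms of the oriented raw trace."""
    trace = orient_polarity(trace)
    hw = int(round(half_window_s * trace.fs_hz))
    out = np.empty(len(times_s))
    for k, t in enumerate(np.asarray(times_s, dtype=float)):
        c = int(round(t * trace.fs_hz))
        seg = trace.samples[max(0, c - hw) : c + hw + 1]
        out[k] = np.sqrt(np.mean(seg**2)) if len(seg) else np.nan
    return out
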