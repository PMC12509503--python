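"""IS waveform embedding and reward-zone decoding.

Each detected IS contributes a fixed-length snippet of the single-channel
LFP (+/-100 ms around the detection time, down-sampled to 2 kHz, z-scored
per waveform).  Snippets are embedded into 2-D with t-SNE and a bagged
ensemble of decision trees is trained with stratified five-fold
cross-validation to classify whether the IS occurred in a reward zone;
pooled out-of-fold scores give one ROC per animal.  Decodability (AUC) is
then regressed against task performance, and per-animal-normalized rms
amplitudes are compared between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .is_detection import LfpTrace

__all__ = [
    "WaveformMatrix",
    "extract_waveforms",
    "embed_2d",
    "classify_reward",
    "auc_vs_performance",
    "rms_compare",
]

WAVEFORM_FS_HZ = 2000.0
HALF_WINDOW_S = 0.1
N_SAMPLES = int(round(2 * HALF_WINDOW_S * WAVEFORM_FS_HZ)) + 1  # inclusive endpoints


@dataclass
class WaveformMatrix:
    """Z-scored IS waveforms (rows) with per-event labels."""

    X: np.ndarray                  # (n_events, 401)
    labels: dict[str, np.ndarray]  # e.g. in_reward, side, correct, animal
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_SAMPLES:
            raise ValueError(f"waveform rows must have {N_SAMPLES} samples")

    def __len__(self) -> int:
        return len(self.X)


def extract_waveforms(
    trace: LfpTrace,
    event_times_s: np.ndarray,
    labels: dict[str, np.ndarray] | None = None,
) -> WaveformMatrix:
    """Extract +/-100 ms snippets at 2 kHz, z-scored per waveform.

    Events closer than 100 ms to either trace edge are dropped (with the
    matching label entries) and recorded in ``labels['n_dropped']`` -- the
    snippet would be ragged otherwise.
    """
    event_times_s = np.asarray(event_times_s, dtype=float)
    if not np.isclose(trace.fs_hz, WAVEFORM_FS_HZ):
        from fractions import Fraction

        frac = Fraction(WAVEFORM_FS_HZ / trace.fs_hz).limit_denominator(1000)
        res = signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
        trace = LfpTrace(samples=res, fs_hz=WAVEFORM_FS_HZ)
    hw = int(round(HALF_WINDOW_S * trace.fs_hz))
    centers = np.round(event_times_s * trace.fs_hz).astype(int)
    ok = (centers - hw >= 0) & (centers + hw < len(trace.samples))
    rows = np.stack([trace.samples[c - hw : c + hw + 1] for c in centers[ok]]) \
        if ok.any() else np.empty((0, N_SAMPLES))
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    out_labels = {}
    if labels:
        out_labels = {k: np.asarray(v)[ok] for k, v in labels.items()}
    out_labels["n_dropped"] = np.sum(~ok)
    return WaveformMatrix(X=(rows - mu) / sd, labels=out_labels, times_s=event_times_s[ok])


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    seed: int


def embed_2d(wm: WaveformMatrix, seed: int = 0, perplexity: float = 30.0) -> EmbeddingResult:
    """2-D t-SNE embedding of the waveform rows (default parameters)."""
    from sklearn.manifold import TSNE

    n = len(wm)
    if n < 10:
        raise ValueError("need >= 10 waveforms to embed")
    if n <= perplexity:
        raise ValueError(
            f"perplexity {perplexity} requires more than {int(perplexity)} waveforms; "
            "lower the perplexity or pool more events"
        )
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return EmbeddingResult(coords=tsne.fit_transform(wm.X), seed=seed)


def classify_reward(
    features: np.ndarray,
    in_reward: np.ndarray,
    k_folds: int = 5,
    n_estimators: int = 100,
    seed: int = 0,
):
    """Bagged-tree classification with stratified k-fold CV, pooled ROC.

    ``features`` may be the 2-D embedding or the raw waveform rows.
    Returns (auc, (fpr, tpr, thresholds), out-of-fold scores).
    """
    from sklearn.ensemble import BaggingClassifier
    from sklearn.metrics import roc_auc_score, roc_curve
    from sklearn.model_selection import StratifiedKFold
    from sklearn.tree import DecisionTreeClassifier

    X = np.asarray(features, dtype=float)
    y = np.asarray(in_reward).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for train, test in skf.split(X, y):
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=n_estimators,
            random_state=seed,
        )
        clf.fit(X[train], y[train])
        scores[test] = clf.predict_proba(X[test])[:, 1]
    auc = roc_auc_score(y, scores)
    curve = roc_curve(y, scores)
    return float(auc), curve, scores


def auc_vs_performance(auc_values: np.ndarray, performance: np.ndarray):
    """OLS of performance on per-animal AUC; returns the statsmodels fit.

    The F statistic against the constant model and coefficient table come
    from the results object (``.fvalue``, ``.params``, ``.pvalues``).
    """
    import statsmodels.api as sm

    a = np.asarray(auc_values, dtype=float)
    p = np.asarray(performance, dtype=float)
    if len(a) < 3:
        raise ValueError("need >= 3 animals")
    if np.ptp(a) == 0:
        raise ValueError("constant AUC: model is rank deficient")
    return sm.OLS(p, sm.add_constant(a)).fit()


def rms_compare(
    rms: np.ndarray,
    animal_ids: np.ndarray,
    group: np.ndarray,
) -> dict:
    """Two-sample t-test of per-animal-normalized rms amplitudes.

    Each animal's rms values are divided by that animal's rms standard
    deviation, then the two groups (boolean ``group``) are compared with
    an unpaired two-sided t-test.
    """
    rms = np.asarray(rms, dtype=float)
    animal_ids = np.asarray(animal_ids)
    group = np.asarray(group).astype(bool)
    norm = np.empty_like(rms)
    for a in np.unique(animal_ids):
        m = animal_ids == a
        sd = rms[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"animal {a} has zero rms spread")
        norm[m] = rms[m] / sd
    g1, g0 = norm[group], norm[~group]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs >= 2 events")
    t, p = stats.ttest_ind(g1, g0)
    return {
        "normalized": norm,
        "tstat": float(t),
        "pvalue": float(p),
        "mean_diff": float(g1.mean() - g0.mean()),
        "df": len(g1) + len(g0) - 2,
    }
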