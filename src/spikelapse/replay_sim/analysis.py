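"""Replay detection, position decoding, contamination, and spectra.

Replay events are detected as prominent peaks of the low-pass filtered
LFP proxy; the represented maze position is reconstructed per 25 ms bin
by the population-vector method (the place-field center collecting the
most spikes wins, ties toward the smaller |x|); contamination counts
place-cell spikes whose field centers lie on the un-cued arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "detect_replays",
    "decode_position",
    "contamination",
    "spectral_summary",
    "spectral_peak_hz",
]

REPLAY_PROMINENCE_MV = 1.0
REPLAY_MIN_DISTANCE_SAMPLES = 200
REPLAY_HALF_WINDOW_S = 0.150
LOWPASS_HZ = 200.0
LOWPASS_ORDER = 7
DECODE_BIN_S = 0.025
CWT_BAND_HZ = (10**1.2, 10**2.5)


def detect_replays(lfp_mV: np.ndarray, fs_hz: float = 1000.0) -> list[tuple[float, float]]:
    """(start_s, end_s) windows (+/-150 ms) around qualifying LFP peaks.

    Peaks need 1 mV prominence and 200-sample separation on the LFP
    low-passed at 200 Hz with a 7th-order zero-phase Butterworth.  The
    deflection sign of the proxy depends only on a scalar gain, so peaks
    are searched on the rectified-polarity signal (flipped if the mean
    deflection is negative).
    """
    x = np.asarray(lfp_mV, dtype=float)
    if len(x) < 3 * LOWPASS_ORDER:
        return []
    sos = signal.butter(LOWPASS_ORDER, LOWPASS_HZ, btype="low", fs=fs_hz, output="sos")
    filt = signal.sosfiltfilt(sos, x - x.mean())
    if np.abs(filt.min()) > np.abs(filt.max()):
        filt = -filt
    peaks, _ = signal.find_peaks(filt, prominence=REPLAY_PROMINENCE_MV,
                                 distance=REPLAY_MIN_DISTANCE_SAMPLES)
    return [
        (max(0.0, pk / fs_hz - REPLAY_HALF_WINDOW_S),
         min(len(x) / fs_hz, pk / fs_hz + REPLAY_HALF_WINDOW_S))
        for pk in peaks
    ]


@dataclass
class DecodedTrajectory:
    bin_centers_s: np.ndarray
    x_cm: np.ndarray          # nan where no place-cell spikes fell in the bin


def decode_position(
    spike_times_s: np.ndarray,
    spike_cell_ids: np.ndarray,
    centers_cm: np.ndarray,
    t_start_s: float,
    t_end_s: float,
    bin_s: float = DECODE_BIN_S,
) -> DecodedTrajectory:
    """Population-vector decoding over 25 ms bins.

    ``centers_cm`` maps cell id -> field center (nan for non-place
    cells).  Per bin the decoded position is the field center receiving
    the maximum spike count; ties break toward the smaller |x|; bins with
    no place-cell spikes decode to nan.
    """
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    spike_cell_ids = np.asarray(spike_cell_ids, dtype=int)
    sel = (spike_times_s >= t_start_s) & (spike_times_s < t_end_s)
    sel &= ~np.isnan(centers_cm[spike_cell_ids])
    edges = np.arange(t_start_s, t_end_s + bin_s / 2, bin_s)
    out = np.full(len(edges) - 1, np.nan)
    tt = spike_times_s[sel]
    cc = centers_cm[spike_cell_ids[sel]]
    which = np.digitize(tt, edges) - 1
    for b in np.unique(which):
        if b < 0 or b >= len(out):
            continue
        vals, counts = np.unique(cc[which == b], return_counts=True)
        top = counts == counts.max()
        cand = vals[top]
        out[b] = cand[np.argmin(np.abs(cand))]
    return DecodedTrajectory(bin_centers_s=0.5 * (edges[:-1] + edges[1:]), x_cm=out)


def contamination(
    spike_times_s: np.ndarray,
    spike_cell_ids: np.ndarray,
    centers_cm: np.ndarray,
    cued_arm_sign: float,
    window: tuple[float, float],
) -> int:
    """Place-cell spikes in the window whose field lies on the un-cued arm."""
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    spike_cell_ids = np.asarray(spike_cell_ids, dtype=int)
    sel = (spike_times_s >= window[0]) & (spike_times_s < window[1])
    c = centers_cm[spike_cell_ids[sel]]
    c = c[~np.isnan(c)]
    return int(np.sum(np.sign(c) == -np.sign(cued_arm_sign)))


def spectral_summary(
    lfp_mV: np.ndarray,
    fs_hz: float = 1000.0,
    replay_windows: list[tuple[float, float]] | None = None,
) -> dict:
    """Welch PSD and a Morlet wavelet map of the mean replay waveform.

    PSD: 256-sample segments, 32-sample overlap, 1024 FFT points.  CWT:
    complex Morlet (bandwidth 1.5, center frequency 1.0) at 200
    log-spaced bands between 10^1.2 and 10^2.5 Hz, applied to the mean of
    the replay-aligned windows (or the whole trace when none are given).
    """
    import pywt

    x = np.asarray(lfp_mV, dtype=float)
    if len(x) < 5 * fs_hz:
        raise ValueError("need at least 5 s of LFP for the spectral summary")
    freqs, psd = signal.welch(x, fs=fs_hz, nperseg=256, noverlap=32, nfft=1024)
    if replay_windows:
        half = int(round(REPLAY_HALF_WINDOW_S * fs_hz))
        segs = []
        for lo, hi in replay_windows:
            c = int(round((lo + hi) / 2 * fs_hz))
            if c - half >= 0 and c + half < len(x):
                segs.append(x[c - half : c + half])
        mean_wave = np.mean(segs, axis=0) if segs else x[: 2 * half]
    else:
        mean_wave = x
    cwt_freqs = np.logspace(np.log10(CWT_BAND_HZ[0]), np.log10(CWT_BAND_HZ[1]), 200)
    scales = pywt.frequency2scale("cmor1.5-1.0", cwt_freqs / fs_hz)
    coefs, _ = pywt.cwt(mean_wave - mean_wave.mean(), scales, "cmor1.5-1.0",
                        sampling_period=1.0 / fs_hz)
    return {
        "psd_freqs_hz": freqs,
        "psd": psd,
        "cwt_freqs_hz": cwt_freqs,
        "cwt_power": np.abs(coefs) ** 2,
        "mean_replay_wave": mean_wave,
    }


def spectral_peak_hz(summary: dict, band_hz: tuple[float, float] = CWT_BAND_HZ) -> float:
    """Frequency of the largest wavelet power within the analysis band."""
    power = summary["cwt_power"].mean(axis=1)
    freqs = summary["cwt_freqs_hz"]
    m = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return float(freqs[m][np.argmax(power[m])])
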