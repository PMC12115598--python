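"""Windowing and the 14-feature bank over 8 inertial channels.

Each labeled event is cut into fixed 7-s windows (70 samples at 10 Hz).
From every window, 14 time/frequency features are computed on each of the
8 signal channels — the three acceleration axes and their magnitude, the
three gyroscope axes and their magnitude — giving a 112-dimensional
feature vector per window. Acceleration channels exist in both the body
frame and the world frame; gyroscope channels are frame-independent.

Conventions (the formulas leave these open, so they are fixed here):
population (divisor N) standard deviation and central moments; Fisher
excess kurtosis; zero-variance skewness/kurtosis defined as 0; the
zero-crossing rate is computed on the mean-centered signal with exact
zeros transparent (a crossing is a sign flip between consecutive nonzero
signs); spectral features come from the mean-removed one-sided boxcar
periodogram with the DC bin excluded from the argmax and ties broken
toward the lower frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .io_dataset import POSITIVE_BEHAVIOR, EventRecording, event_id

import logging

logger = logging.getLogger(__name__)

#: channel order (acceleration axes + magnitude, gyro axes + magnitude)
CHANNELS = ("ax", "ay", "az", "amag", "wx", "wy", "wz", "wmag")

#: feature order within each channel
FEATURE_NAMES = (
    "mean", "median", "std", "zcr", "peak_to_peak", "sum", "sum_abs", "rms",
    "avg_variation", "skewness", "kurtosis", "time_between_peaks",
    "dominant_frequency", "dominant_spectral_density",
)

#: the 112 column names, `<channel>__<feature>`, in fixed order
FEATURE_COLUMNS = tuple(f"{c}__{f}" for c in CHANNELS for f in FEATURE_NAMES)

_ACCEL_SOURCE = {
    "body": ("bno_ax_body", "bno_ay_body", "bno_az_body"),
    "world": ("bno_ax_world", "bno_ay_world", "bno_az_world"),
}
_GYRO_SOURCE = ("bno_gx", "bno_gy", "bno_gz")


@dataclass
class SignalWindow:
    """Fixed-length slice of one event: 8 derived channels at 10 Hz."""

    channels: dict  # name -> 1-D array, keys == CHANNELS
    fs: float
    frame: str  # 'body' | 'world'
    event: str = ""
    index: int = 0
    behavior: str = ""

    @property
    def n(self) -> int:
        return len(self.channels["ax"])


def window_from_arrays(accel_xyz, gyro_xyz, fs=10.0, frame="body", **meta) -> SignalWindow:
    """Assemble a SignalWindow from (n,3) acceleration and gyro arrays."""
    a = np.asarray(accel_xyz, dtype=float)
    g = np.asarray(gyro_xyz, dtype=float)
    if a.shape != g.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("accel and gyro must both be (n, 3)")
    ch = {
        "ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2],
        "amag": np.linalg.norm(a, axis=1),
        "wx": g[:, 0], "wy": g[:, 1], "wz": g[:, 2],
        "wmag": np.linalg.norm(g, axis=1),
    }
    return SignalWindow(channels=ch, fs=fs, frame=frame, **meta)


def segment_windows(rec: EventRecording, frame: str, window_s: float = 7.0,
                    mode: str = "first") -> list[SignalWindow]:
    """Cut an event into fixed windows of ``window_s`` seconds.

    mode='first' keeps one window starting at sample 0 (one sample per
    labeled event); mode='tiled' keeps every non-overlapping consecutive
    window. Events shorter than the window yield an empty list with a
    logged warning.
    """
    if frame not in _ACCEL_SOURCE:
        raise ValueError(f"frame must be 'body' or 'world', got {frame!r}")
    if mode not in ("first", "tiled"):
        raise ValueError(f"unknown window mode {mode!r}")
    n_win = int(round(window_s * rec.fs))
    if rec.n_samples < n_win:
        logger.warning("event %s shorter than %.3gs window; skipped",
                       event_id(rec), window_s)
        return []
    accel = rec.data[list(_ACCEL_SOURCE[frame])].to_numpy(dtype=float)
    gyro = rec.data[list(_GYRO_SOURCE)].to_numpy(dtype=float)
    n_windows = 1 if mode == "first" else rec.n_samples // n_win
    out = []
    for k in range(n_windows):
        sl = slice(k * n_win, (k + 1) * n_win)
        out.append(window_from_arrays(
            accel[sl], gyro[sl], fs=rec.fs, frame=frame,
            event=event_id(rec), index=k, behavior=rec.behavior,
        ))
    return out


# ---------------------------------------------------------------- features

def basic_stats(x) -> tuple:
    """(mean, median, std, sum, sum_abs, peak_to_peak, rms); population std."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return (
        float(np.mean(x)),
        float(np.median(x)),
        float(np.std(x)),
        float(np.sum(x)),
        float(np.sum(np.abs(x))),
        float(np.ptp(x)),
        float(np.sqrt(np.mean(x ** 2))),
    )


def zero_crossing_rate(x) -> float:
    """Sign-flip rate of the mean-centered signal, in [0, 1].

    Exact zeros carry no sign: crossings are counted between consecutive
    nonzero signs, then divided by N - 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    s = np.sign(x - x.mean())
    nz = s[s != 0]
    if nz.size < 2:
        return 0.0
    return float(np.sum(nz[1:] != nz[:-1])) / (x.size - 1)


def avg_variation(x) -> float:
    """Mean absolute successive difference."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def shape_moments(x) -> tuple:
    """(skewness, Fisher excess kurtosis); population moments; 0 when flat."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 < 1e-24:
        return 0.0, 0.0
    skew = float(np.mean(d ** 3) / m2 ** 1.5)
    kurt = float(np.mean(d ** 4) / m2 ** 2 - 3.0)
    return skew, kurt


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima; a plateau takes its first index."""
    idx = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def time_between_peaks(x, fs: float) -> float:
    """Mean interval (s) between local maxima; 0 when fewer than 2 peaks."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    peaks = _local_maxima(x)
    if peaks.size < 2:
        return 0.0
    return float(np.mean(np.diff(peaks))) / fs


def spectral_features(x, fs: float) -> tuple:
    """(dominant frequency Hz, dominant spectral density).

    Mean-removed one-sided boxcar periodogram; the DC bin is excluded from
    the argmax and ties break toward the lower frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    freqs, pxx = periodogram(x - x.mean(), fs=fs, window="boxcar", detrend=False)
    k = int(np.argmax(pxx[1:])) + 1  # ties -> lowest frequency via argmax
    return float(freqs[k]), float(pxx[k])


def compute_channel_features(x, fs: float) -> dict:
    """All 14 features of one channel, keyed by FEATURE_NAMES."""
    mean, median, std, total, total_abs, ptp, rms = basic_stats(x)
    skew, kurt = shape_moments(x)
    dom_f, dom_d = spectral_features(x, fs)
    return {
        "mean": mean, "median": median, "std": std,
        "zcr": zero_crossing_rate(x), "peak_to_peak": ptp,
        "sum": total, "sum_abs": total_abs, "rms": rms,
        "avg_variation": avg_variation(x),
        "skewness": skew, "kurtosis": kurt,
        "time_between_peaks": time_between_peaks(x, fs),
        "dominant_frequency": dom_f, "dominant_spectral_density": dom_d,
    }


def extract_features(w: SignalWindow) -> pd.Series:
    """The 112-entry feature vector of one window, fixed name order."""
    values = {}
    for c in CHANNELS:
        feats = compute_channel_features(w.channels[c], w.fs)
        for f in FEATURE_NAMES:
            values[f"{c}__{f}"] = feats[f]
    s = pd.Series(values, index=list(FEATURE_COLUMNS), dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("non-finite feature value")
    return s


def build_design_matrix(db, frame: str, mode: str = "first",
                        window_s: float = 7.0):
    """Feature matrix over a database of events.

    Returns ``(X, y, meta)``: X a DataFrame with the 112 named columns,
    one row per window; y an int array with 1 for active mounting and 0
    for every other behavior; meta a DataFrame (event, window, behavior,
    frame) aligned with X's rows.
    """
    rows, labels, meta = [], [], []
    for rec in db:
        for w in segment_windows(rec, frame=frame, window_s=window_s, mode=mode):
            rows.append(extract_features(w))
            labels.append(1 if rec.behavior == POSITIVE_BEHAVIOR else 0)
            meta.append({"event": w.event, "window": w.index,
                         "behavior": w.behavior, "frame": frame})
    if not rows:
        raise ValueError("no usable windows in database")
    X = pd.DataFrame(rows).reset_index(drop=True)
    return X, np.asarray(labels, dtype=int), pd.DataFrame(meta)
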