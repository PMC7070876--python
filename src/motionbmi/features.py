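"""Classical per-window feature extraction for the baseline learners.

Each window is summarized by 43 hand-crafted features computed on the three
raw (pre-normalization) accelerometer axes — z-scored data would destroy the
amplitude information several features carry:

* per-axis mean (3)
* per-axis standard deviation (3)
* per-axis average absolute difference from the axis mean (3)
* average resultant acceleration, mean of sqrt(ax^2 + ay^2 + az^2) (1)
* per-axis average time between successive peaks, seconds (3)
* per-axis binned value distribution over 10 equal-width bins spanning the
  axis min-max range (30)

Peaks are local maxima above the axis mean separated by at least
``min_peak_separation_s``; a window with fewer than two peaks reports the
window duration as its peak interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Window

ACC_AXES = ("acc_x", "acc_y", "acc_z")

DEFAULT_BINS = 10
DEFAULT_MIN_PEAK_SEPARATION_S = 0.25


def feature_names(bins: int = DEFAULT_BINS) -> list[str]:
    names: list[str] = []
    names += [f"mean_{a}" for a in ACC_AXES]
    names += [f"std_{a}" for a in ACC_AXES]
    names += [f"avg_abs_diff_{a}" for a in ACC_AXES]
    names += ["avg_resultant_acc"]
    names += [f"time_between_peaks_{a}" for a in ACC_AXES]
    for a in ACC_AXES:
        names += [f"bin{b}_{a}" for b in range(bins)]
    return names


def _time_between_peaks(
    x: np.ndarray, fs: float, min_separation_s: float
) -> float:
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = find_peaks(x, height=x.mean(), distance=distance)
    if len(peaks) < 2:
        return len(x) / fs  # no measurable gait cycle: report window duration
    return float(np.diff(peaks).mean() / fs)


def _binned_distribution(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:  # constant axis: all mass in the first bin
        out = np.zeros(bins)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return counts / counts.sum()


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def featurize_window(
    win: Window,
    bins: int = DEFAULT_BINS,
    min_peak_separation_s: float = DEFAULT_MIN_PEAK_SEPARATION_S,
) -> FeatureVector:
    """Compute the 43-feature descriptor (for the default 10 bins)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if win.length_w < 3:
        raise ValueError("window too short to featurize (need >= 3 samples)")
    acc = win.data[:3]
    fs = win.sampling_rate_hz
    vals: list[float] = []
    vals += acc.mean(axis=1).tolist()
    vals += acc.std(axis=1).tolist()
    vals += np.abs(acc - acc.mean(axis=1, keepdims=True)).mean(axis=1).tolist()
    vals += [float(np.sqrt((acc**2).sum(axis=0)).mean())]
    vals += [
        _time_between_peaks(acc[i], fs, min_peak_separation_s) for i in range(3)
    ]
    for i in range(3):
        vals += _binned_distribution(acc[i], bins).tolist()
    return FeatureVector(
        values=np.asarray(vals, dtype=float), names=tuple(feature_names(bins))
    )


def featurize_dataset(
    windows: Sequence[Window],
    bins: int = DEFAULT_BINS,
    min_peak_separation_s: float = DEFAULT_MIN_PEAK_SEPARATION_S,
) -> pd.DataFrame:
    """One feature row per window, with subject id and BMI label attached."""
    names = feature_names(bins)
    if len(windows) == 0:
        return pd.DataFrame(
            columns=["subject_id", "window_index", "bmi"] + names
        )
    lengths = {w.length_w for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    rows = []
    for win in windows:
        fv = featurize_window(win, bins, min_peak_separation_s)
        rows.append(
            {
                "subject_id": win.subject_id,
                "window_index": win.window_index,
                "bmi": win.bmi_label,
                **fv.as_dict(),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "window_index", "bmi"] + names)
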