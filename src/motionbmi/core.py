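"""Domain types and the signal front-end: resampling, sliding windows, normalization.

A recording is a six-channel inertial time series (tri-axial accelerometer +
tri-axial gyroscope) sampled at a fixed rate. The front-end linearly resamples
all channels onto a common rate, cuts the recording into fixed-length windows
(the unit of labelling, filtering and prediction), and z-scores each window
per channel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

#: default window length in samples; at the default 90 Hz this spans ~1 s
DEFAULT_WINDOW = 90
#: default step between window starts (half a window: 50% overlap)
DEFAULT_STEP = 45
#: default common sampling rate after resampling, Hz
DEFAULT_RATE_HZ = 90.0


class BMICategory(enum.Enum):
    """WHO nutritional-status bands for adult BMI (kg/m^2)."""

    UNDERWEIGHT = "Underweight"
    NORMAL_WEIGHT = "NormalWeight"
    PRE_OBESITY = "PreObesity"
    OBESITY_I = "ObesityI"
    OBESITY_II = "ObesityII"
    OBESITY_III = "ObesityIII"


# half-open intervals, lower bound inclusive
_CATEGORY_BOUNDS = [
    (0.0, 18.5, BMICategory.UNDERWEIGHT),
    (18.5, 25.0, BMICategory.NORMAL_WEIGHT),
    (25.0, 30.0, BMICategory.PRE_OBESITY),
    (30.0, 35.0, BMICategory.OBESITY_I),
    (35.0, 40.0, BMICategory.OBESITY_II),
    (40.0, float("inf"), BMICategory.OBESITY_III),
]


def bmi_to_category(bmi: float) -> BMICategory:
    """Map a BMI value (kg/m^2) to its WHO band.

    Bands are half-open with inclusive lower bounds:
    [0, 18.5), [18.5, 25), [25, 30), [30, 35), [35, 40), [40, inf).
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be a positive finite number, got {bmi!r}")
    for lo, hi, cat in _CATEGORY_BOUNDS:
        if lo <= bmi < hi:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class SubjectMeta:
    """Anthropometrics for one subject; BMI = weight_kg / (height_m)^2."""

    subject_id: str
    height_cm: float
    weight_kg: float
    bmi: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.height_cm is not None and self.height_cm <= 0:
            raise ValueError("height_cm must be positive")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if self.bmi is None:
            if self.height_cm is None or self.weight_kg is None:
                raise ValueError("need bmi, or height_cm and weight_kg")
            object.__setattr__(
                self, "bmi", self.weight_kg / (self.height_cm / 100.0) ** 2
            )
        elif self.height_cm is not None and self.weight_kg is not None:
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(implied - self.bmi) > 0.1:
                raise ValueError(
                    f"bmi {self.bmi:.2f} inconsistent with height/weight "
                    f"(implies {implied:.2f}) for subject {self.subject_id}"
                )
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")

    @property
    def category(self) -> BMICategory:
        return bmi_to_category(self.bmi)


@dataclass(frozen=True)
class SensorSequence:
    """One subject's time-ordered 6-channel recording.

    ``data`` is a (6, T) float array in channel order
    (acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z).
    """

    subject_id: str
    sampling_rate_hz: float
    data: np.ndarray
    activity_label: Optional[str] = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != 6:
            raise ValueError(f"data must be (6, T), got shape {data.shape}")
        if data.shape[1] < 1:
            raise ValueError("sequence must contain at least one sample")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError(
                f"non-finite values in recording for subject {self.subject_id}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class Window:
    """A fixed-length sub-sequence cut from a recording.

    ``data`` is a (6, w) matrix; ``window_index`` is 1-based within the parent
    sequence. Each window carries its subject's (single) BMI label and the
    sampling rate, so duration-dependent features stay expressible in seconds.
    """

    subject_id: str
    window_index: int
    data: np.ndarray
    bmi_label: float
    sampling_rate_hz: float = DEFAULT_RATE_HZ
    activity_label: Optional[str] = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != 6:
            raise ValueError(f"window data must be (6, w), got {data.shape}")
        if self.window_index < 1:
            raise ValueError("window_index is 1-based and must be >= 1")
        object.__setattr__(self, "data", data)

    @property
    def length_w(self) -> int:
        return self.data.shape[1]


def resample_linear(seq: SensorSequence, target_rate_hz: float) -> SensorSequence:
    """Linearly resample all six channels onto a uniform grid at ``target_rate_hz``.

    The new grid spans the original time range [0, (T-1)/fs] inclusive of both
    endpoints; each channel is the piecewise-linear interpolant of the input.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if seq.n_samples < 2:
        raise ValueError("cannot interpolate a sequence with fewer than 2 samples")
    t_old = np.arange(seq.n_samples) / seq.sampling_rate_hz
    t_end = t_old[-1]
    # uniform grid spanning [0, t_end] with spacing as close to 1/target as an
    # endpoint-inclusive grid allows
    n_new = max(2, int(round(t_end * target_rate_hz)) + 1)
    t_new = np.linspace(0.0, t_end, n_new)
    data = np.vstack([np.interp(t_new, t_old, ch) for ch in seq.data])
    return replace(seq, sampling_rate_hz=target_rate_hz, data=data)


def slide_windows(
    seq: SensorSequence,
    w: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    bmi_label: float = float("nan"),
) -> list[Window]:
    """Cut ``seq`` into L = floor((T - w) / step) overlapping windows.

    Window k (1-based) covers samples (k-1)*step+1 .. (k-1)*step+w, so
    consecutive windows overlap by w - step samples. Note the count formula
    discards a trailing fully-valid start when (T - w) is an exact multiple of
    step; this convention is kept deliberately and documented.
    Returns an empty list when w > T.
    """
    if w < 1 or step < 1:
        raise ValueError("w and step must be positive integers")
    T = seq.n_samples
    if w > T:
        return []
    L = (T - w) // step
    out = []
    for k in range(1, L + 1):
        start = (k - 1) * step
        out.append(
            Window(
                subject_id=seq.subject_id,
                window_index=k,
                data=seq.data[:, start : start + w],
                bmi_label=bmi_label,
                sampling_rate_hz=seq.sampling_rate_hz,
                activity_label=seq.activity_label,
            )
        )
    return out


def normalize_window(win: Window, mode: str = "zscore") -> Window:
    """Normalize each channel of a window independently.

    ``zscore`` (default): (x - mean) / std per channel; a constant channel maps
    to all-zeros. ``minmax``: rescale each channel to [0, 1]; a constant
    channel maps to 0.5.
    """
    data = win.data
    if not np.all(np.isfinite(data)):
        ch, idx = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"non-finite value in channel {CHANNEL_NAMES[ch]} at sample {idx}"
        )
    if mode == "zscore":
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        out = np.where(sd > 0, (data - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    elif mode == "minmax":
        lo = data.min(axis=1, keepdims=True)
        hi = data.max(axis=1, keepdims=True)
        rng = hi - lo
        out = np.where(rng > 0, (data - lo) / np.where(rng > 0, rng, 1.0), 0.5)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(win, data=out)


def normalize_windows(
    windows: Sequence[Window], mode: str = "zscore"
) -> list[Window]:
    return [normalize_window(w, mode) for w in windows]
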