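"""Motion entropy (MEn) and entropy-based window filtering.

MEn extends sample entropy to a joint accelerometer/gyroscope statistic. Both
tri-axial sensors are collapsed to their per-sample vector magnitudes (making
the measure orientation-robust), length-``xi`` templates of consecutive
magnitude samples are compared under the Chebyshev (max-difference) distance
separately per sensor, and

    MEn = -ln( B^{xi+1} / B^{xi} )

where B^l is the average fraction of template pairs matching within the
tolerances (r_acc, r_gyro) at template length l. Low MEn means a highly
regular signal, high MEn an irregular one; the filtering strategy keeps the
central mass of the per-window MEn distribution, discarding both the most
mechanical and the noisiest windows before training.

Two interpretation knobs are exposed because the defining formulas admit two
readings each:

``match_mode``
    ``literal_average`` scores a template pair as the *average* of the two
    per-sensor match indicators (so a pair matching on one sensor only counts
    1/2); ``joint`` requires both sensors to match (logical AND).
``normalization``
    ``sampen_consistent`` (default) evaluates both template lengths over the
    pair set valid at length xi+1, which guarantees B^{xi+1} <= B^{xi} and
    hence MEn >= 0, as in classical sample entropy; ``strict_literal``
    evaluates each length over its own full pair set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .core import Window

MatchMode = Literal["literal_average", "joint"]
Normalization = Literal["sampen_consistent", "strict_literal"]
TailMode = Literal["both_tails", "lower_tail", "upper_tail"]


@dataclass(frozen=True)
class MagnitudePair:
    """Per-sample vector magnitudes of the two sensors over one window."""

    acc_mag: np.ndarray
    gyro_mag: np.ndarray

    def __post_init__(self):
        acc = np.asarray(self.acc_mag, dtype=float)
        gyro = np.asarray(self.gyro_mag, dtype=float)
        if acc.shape != gyro.shape or acc.ndim != 1:
            raise ValueError("acc_mag and gyro_mag must be 1-D and equal length")
        if np.any(acc < 0) or np.any(gyro < 0):
            raise ValueError("vector magnitudes must be non-negative")
        object.__setattr__(self, "acc_mag", acc)
        object.__setattr__(self, "gyro_mag", gyro)

    def __len__(self) -> int:
        return self.acc_mag.shape[0]


@dataclass(frozen=True)
class MEnParams:
    """Template length and matching tolerances for one MEn evaluation.

    ``psi`` records the tolerance multiplier when (r_acc, r_gyro) were
    calibrated as psi * mean magnitude standard deviation; it is informational
    once the tolerances are fixed.
    """

    xi: int = 2
    r_acc: float = 0.0
    r_gyro: float = 0.0
    psi: Optional[float] = None
    match_mode: MatchMode = "literal_average"
    normalization: Normalization = "sampen_consistent"

    def __post_init__(self):
        if self.xi < 1:
            raise ValueError("template length xi must be >= 1")
        if self.r_acc < 0 or self.r_gyro < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass(frozen=True)
class MEnResult:
    """One window's motion entropy with the probabilities behind it.

    ``value`` is +inf (with ``degenerate=True``) when no template pair matches
    at length xi+1, i.e. the conditional probability is zero.
    """

    value: float
    b_xi: float
    b_xi_plus_1: float
    params: MEnParams
    subject_id: Optional[str] = None
    window_index: Optional[int] = None

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.value)


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of the entropy-based window filter.

    ``threshold_percentile`` (theta) is the fraction trimmed from each tail of
    the empirical MEn distribution when ``tail_mode='both_tails'`` (so theta =
    0.25 keeps the central half); theta = 0 disables filtering.
    """

    threshold_percentile: float = 0.1
    psi: float = 0.05
    xi: int = 2
    tail_mode: TailMode = "both_tails"
    match_mode: MatchMode = "literal_average"
    normalization: Normalization = "sampen_consistent"

    def __post_init__(self):
        if not 0.0 <= self.threshold_percentile:
            raise ValueError("threshold_percentile must be >= 0")
        if self.tail_mode == "both_tails" and self.threshold_percentile >= 0.5:
            raise ValueError(
                "threshold_percentile must be < 0.5 with both_tails filtering"
            )
        if self.tail_mode in ("lower_tail", "upper_tail") and (
            self.threshold_percentile >= 1.0
        ):
            raise ValueError("threshold_percentile must be < 1 for one-tail modes")
        if self.psi <= 0:
            raise ValueError("psi must be positive")


def vector_magnitudes(win: Window) -> MagnitudePair:
    """Euclidean norm of each tri-axial sample, per sensor."""
    data = np.asarray(win.data, dtype=float)
    if data.shape[0] != 6:
        raise ValueError(f"expected 6 channels, got {data.shape[0]}")
    acc = np.sqrt(np.sum(data[:3] ** 2, axis=0))
    gyro = np.sqrt(np.sum(data[3:] ** 2, axis=0))
    return MagnitudePair(acc_mag=acc, gyro_mag=gyro)


def _templates(x: np.ndarray, ell: int) -> np.ndarray:
    # (n_templates, ell) view of consecutive runs
    return np.lib.stride_tricks.sliding_window_view(x, ell)


def _chebyshev_pairs(x: np.ndarray, ell: int) -> np.ndarray:
    """Pairwise Chebyshev distance between all length-``ell`` templates."""
    t = _templates(x, ell)  # (n, ell)
    # (n, n): max over offsets of |t_i - t_j|
    return np.abs(t[:, None, :] - t[None, :, :]).max(axis=2)


def _match_prob(
    m: MagnitudePair,
    ell: int,
    n_templates: int,
    r_acc: float,
    r_gyro: float,
    match_mode: MatchMode,
) -> float:
    """Average per-template match fraction at length ``ell``.

    Only the first ``n_templates`` templates participate (this is how the
    sampen_consistent normalization restricts length xi to the xi+1 pair set).
    Self-pairs are excluded; each template's fraction is over the other
    n_templates - 1 templates.
    """
    d_acc = _chebyshev_pairs(m.acc_mag, ell)[:n_templates, :n_templates]
    d_gyro = _chebyshev_pairs(m.gyro_mag, ell)[:n_templates, :n_templates]
    acc_ok = d_acc <= r_acc
    gyro_ok = d_gyro <= r_gyro
    if match_mode == "literal_average":
        score = (acc_ok.astype(float) + gyro_ok.astype(float)) / 2.0
    elif match_mode == "joint":
        score = (acc_ok & gyro_ok).astype(float)
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    np.fill_diagonal(score, 0.0)
    n = n_templates
    if n < 2:
        raise ValueError("need at least 2 templates to form a pair")
    per_template = score.sum(axis=1) / (n - 1)
    return float(per_template.mean())


def template_match_counts(
    m: MagnitudePair,
    xi: int,
    r_acc: float,
    r_gyro: float,
    match_mode: MatchMode = "literal_average",
    normalization: Normalization = "sampen_consistent",
) -> tuple[float, float]:
    """Self-similarity probabilities (B^xi, B^{xi+1}) of a magnitude pair."""
    w = len(m)
    if xi + 1 > w - 1:
        raise ValueError(
            f"template length xi={xi} too large for window length {w}"
        )
    if r_acc < 0 or r_gyro < 0:
        raise ValueError("tolerances must be non-negative")
    n_long = w - xi  # templates of length xi+1
    if normalization == "sampen_consistent":
        b_xi = _match_prob(m, xi, n_long, r_acc, r_gyro, match_mode)
    elif normalization == "strict_literal":
        b_xi = _match_prob(m, xi, w - xi + 1, r_acc, r_gyro, match_mode)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    b_xi1 = _match_prob(m, xi + 1, n_long, r_acc, r_gyro, match_mode)
    return b_xi, b_xi1


def motion_entropy(win: Window, params: MEnParams) -> MEnResult:
    """Motion entropy of one window; +inf sentinel when no xi+1 matches."""
    m = vector_magnitudes(win)
    b_xi, b_xi1 = template_match_counts(
        m,
        params.xi,
        params.r_acc,
        params.r_gyro,
        params.match_mode,
        params.normalization,
    )
    if b_xi1 <= 0.0 or b_xi <= 0.0:
        value = float("inf")
    else:
        value = float(-np.log(b_xi1 / b_xi))
    return MEnResult(
        value=value,
        b_xi=b_xi,
        b_xi_plus_1=b_xi1,
        params=params,
        subject_id=win.subject_id,
        window_index=win.window_index,
    )


def calibrate_tolerances(
    windows: Sequence[Window], psi: float
) -> tuple[float, float]:
    """Tolerances r = psi * mean per-window magnitude standard deviation.

    The mean-of-stds should be taken over the training pool only, so filter
    decisions never depend on test data.
    """
    if len(windows) == 0:
        raise ValueError("cannot calibrate tolerances on an empty window list")
    if psi <= 0:
        raise ValueError("psi must be positive")
    acc_stds = np.empty(len(windows))
    gyro_stds = np.empty(len(windows))
    for i, win in enumerate(windows):
        m = vector_magnitudes(win)
        acc_stds[i] = m.acc_mag.std()
        gyro_stds[i] = m.gyro_mag.std()
    r_acc = psi * float(acc_stds.mean())
    r_gyro = psi * float(gyro_stds.mean())
    if r_acc == 0.0 or r_gyro == 0.0:
        warnings.warn(
            "calibrated tolerance is zero (constant magnitude series); "
            "template matching will be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return r_acc, r_gyro


def compute_men(
    windows: Sequence[Window],
    cfg: FilterConfig,
    tolerances: Optional[tuple[float, float]] = None,
) -> list[MEnResult]:
    """MEn for every window, with tolerances calibrated at ``cfg.psi``.

    ``tolerances`` overrides calibration (e.g. with values fixed on a
    training split).
    """
    if tolerances is None:
        tolerances = calibrate_tolerances(windows, cfg.psi)
    r_acc, r_gyro = tolerances
    params = MEnParams(
        xi=cfg.xi,
        r_acc=r_acc,
        r_gyro=r_gyro,
        psi=cfg.psi,
        match_mode=cfg.match_mode,
        normalization=cfg.normalization,
    )
    return [motion_entropy(w, params) for w in windows]


def filter_windows(
    windows: Sequence[Window],
    cfg: FilterConfig,
    tolerances: Optional[tuple[float, float]] = None,
) -> tuple[list[Window], list[MEnResult]]:
    """Entropy-filter a window pool; returns (kept windows, all MEn results).

    With ``both_tails`` (default) the floor(theta*N) lowest-MEn and
    floor(theta*N) highest-MEn windows are removed, retaining the central
    mass in original order. Ranking uses a stable sort, so ties are resolved
    in input order; infinite MEn (no template match at length xi+1) ranks
    above every finite value and is removed first from the upper tail.
    theta = 0 returns the input unchanged.
    """
    if len(windows) == 0:
        raise ValueError("cannot filter an empty window list")
    results = compute_men(windows, cfg, tolerances)
    theta = cfg.threshold_percentile
    n = len(windows)
    if theta == 0.0:
        return list(windows), results
    values = np.array([r.value for r in results])
    order = np.argsort(values, kind="stable")  # inf sorts last
    k = int(np.floor(theta * n))
    drop = set()
    if cfg.tail_mode in ("both_tails", "lower_tail"):
        drop.update(order[:k].tolist())
    if cfg.tail_mode in ("both_tails", "upper_tail"):
        if k > 0:
            drop.update(order[-k:].tolist())
    if cfg.tail_mode in ("both_tails", "upper_tail"):
        # degenerate windows are always discarded once filtering is on
        drop.update(np.nonzero(~np.isfinite(values))[0].tolist())
    kept = [w for i, w in enumerate(windows) if i not in drop]
    return kept, results
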