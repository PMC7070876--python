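"""Leave-one-subject-out evaluation of BMI predictors.

The evaluation unit is the window: each subject's recording is cut into
windows, every window inherits the subject's BMI, and in each fold one
subject's windows form the test set while all remaining subjects' windows
train the model. Everything fitted — entropy-filter tolerances and
quantiles, the regressor itself — is computed from training windows only.

Learners: the hybrid CNN-LSTM (on per-window z-scored data) and classical
baselines on the 43-feature descriptor — k-nearest-neighbour, RBF
support-vector and decision-tree regressors — plus a train-mean straw man.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    SensorSequence,
    SubjectMeta,
    Window,
    bmi_to_category,
    normalize_windows,
    resample_linear,
    slide_windows,
)
from .features import featurize_dataset
from .men import FilterConfig, calibrate_tolerances, filter_windows
from .model import CNNLSTMRegressor, ModelConfig
from .synth import Cohort

BASELINE_LEARNERS = ("knn", "svr", "tree", "mean")


@dataclass(frozen=True)
class FoldPlan:
    fold_id: int
    test_subject: str
    train_subjects: tuple[str, ...]

    def __post_init__(self):
        if self.test_subject in self.train_subjects:
            raise ValueError("test subject must not appear in the training set")


def make_loso_folds(subjects: Sequence[str]) -> list[FoldPlan]:
    """One fold per subject, ordered deterministically by subject id."""
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    ordered = sorted(subjects)
    return [
        FoldPlan(
            fold_id=i,
            test_subject=s,
            train_subjects=tuple(t for t in ordered if t != s),
        )
        for i, s in enumerate(ordered)
    ]


def mae(y, yhat) -> float:
    """Mean absolute error (L1)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length and non-empty")
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error (L2)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def category_report(y, yhat) -> pd.DataFrame:
    """Per-WHO-band MAE and category accuracy of window-level predictions.

    Rows are grouped by the *true* BMI band; ``accuracy`` is the fraction of
    windows whose predicted BMI falls into the same band — an
    operationalization of category-level accuracy for a regression output.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    rows = []
    true_cats = np.array([bmi_to_category(v).value for v in y])
    pred_cats = np.array(
        [bmi_to_category(v).value if v > 0 else "invalid" for v in yhat]
    )
    for cat in pd.unique(true_cats):
        mask = true_cats == cat
        rows.append(
            {
                "category": cat,
                "n_windows": int(mask.sum()),
                "mae": mae(y[mask], yhat[mask]),
                "accuracy": float(np.mean(pred_cats[mask] == cat)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end experiment description: front-end, filter, learner."""

    resample_rate_hz: float = 90.0
    window: int = 90
    step: int = 45
    normalization: str = "zscore"
    filter: FilterConfig = field(default_factory=lambda: FilterConfig())
    filter_test: bool = False
    learner: str = "cnn_lstm"
    model: ModelConfig = field(default_factory=ModelConfig)
    knn_neighbors: int = 5
    aggregate_per_subject: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.learner not in ("cnn_lstm",) + BASELINE_LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")


@dataclass
class EvalReport:
    """Per-fold and aggregate LOSO metrics, plus a per-category breakdown."""

    per_fold: list[dict]
    category_table: pd.DataFrame
    config: Optional[PipelineConfig] = None

    @property
    def mae_mean(self) -> float:
        return float(np.mean([f["mae"] for f in self.per_fold]))

    @property
    def mae_std(self) -> float:
        return float(np.std([f["mae"] for f in self.per_fold]))

    @property
    def rmse_mean(self) -> float:
        return float(np.mean([f["rmse"] for f in self.per_fold]))

    @property
    def rmse_std(self) -> float:
        return float(np.std([f["rmse"] for f in self.per_fold]))

    def to_dict(self) -> dict:
        return {
            "aggregate": {
                "mae_mean": self.mae_mean,
                "mae_std": self.mae_std,
                "rmse_mean": self.rmse_mean,
                "rmse_std": self.rmse_std,
                "n_folds": len(self.per_fold),
            },
            "per_fold": self.per_fold,
            "per_category": self.category_table.to_dict(orient="records"),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Leave-one-subject-out evaluation",
            "=" * 40,
            f"folds:          {len(self.per_fold)}",
            f"MAE  (mean+-sd): {self.mae_mean:.3f} +- {self.mae_std:.3f}",
            f"RMSE (mean+-sd): {self.rmse_mean:.3f} +- {self.rmse_std:.3f}",
            "",
            "per-category (pooled windows):",
            self.category_table.to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_categories(self, ax=None):  # pragma: no cover - plotting shim
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.category_table
        ax.bar(t["category"], t["mae"])
        ax.set_ylabel("MAE (kg/m$^2$)")
        ax.tick_params(axis="x", rotation=30)
        return ax


DatasetLike = Union[Cohort, Sequence[tuple[SensorSequence, SubjectMeta]]]


def _as_pairs(dataset: DatasetLike) -> list[tuple[SensorSequence, SubjectMeta]]:
    if isinstance(dataset, Cohort):
        return list(zip(dataset.sequences, dataset.metadata))
    return list(dataset)


def _fold_seed(experiment_seed: int, fold_id: int) -> int:
    ss = np.random.SeedSequence([experiment_seed, fold_id])
    return int(ss.generate_state(1)[0] % (2**31))


class LOSOExperiment:
    """Leave-one-subject-out experiment; ``fit()`` returns an EvalReport."""

    def __init__(self, dataset: DatasetLike, config: Optional[PipelineConfig] = None):
        self.pairs = _as_pairs(dataset)
        if len(self.pairs) < 2:
            raise ValueError("need at least 2 subjects")
        self.config = config or PipelineConfig()
        import warnings as _warnings

        cats = {m.category for _, m in self.pairs}
        if len(cats) == 1:
            _warnings.warn(
                "all subjects fall in a single BMI category; per-category "
                "accuracy is degenerate",
                RuntimeWarning,
                stacklevel=2,
            )

    def _windows_by_subject(self) -> dict[str, list[Window]]:
        cfg = self.config
        out: dict[str, list[Window]] = {}
        for seq, meta in self.pairs:
            if abs(seq.sampling_rate_hz - cfg.resample_rate_hz) > 1e-9:
                seq = resample_linear(seq, cfg.resample_rate_hz)
            wins = slide_windows(seq, cfg.window, cfg.step, bmi_label=meta.bmi)
            if seq.subject_id in out:
                raise ValueError(f"duplicate subject id {seq.subject_id}")
            out[seq.subject_id] = wins
        return out

    def fit(self, verbose: bool = False) -> EvalReport:
        cfg = self.config
        by_subject = self._windows_by_subject()
        folds = make_loso_folds(list(by_subject))
        per_fold = []
        pooled_y: list[float] = []
        pooled_yhat: list[float] = []
        for plan in folds:
            train = [w for s in plan.train_subjects for w in by_subject[s]]
            test = list(by_subject[plan.test_subject])
            if not train or not test:
                raise ValueError(
                    f"fold {plan.fold_id}: empty train or test window pool"
                )
            # everything fitted below sees training windows only
            theta = cfg.filter.threshold_percentile
            if theta > 0:
                tol = calibrate_tolerances(train, cfg.filter.psi)
                train, _ = filter_windows(train, cfg.filter, tolerances=tol)
                if cfg.filter_test:
                    test, _ = filter_windows(test, cfg.filter, tolerances=tol)
                if not train:
                    raise ValueError("entropy filter removed all training windows")
            y_test = np.array([w.bmi_label for w in test])
            yhat = np.asarray(self._fit_predict(plan, train, test), dtype=float)
            if cfg.aggregate_per_subject:
                # smooth per-window noise: every window of the held-out
                # subject receives the subject-level median prediction
                yhat = np.full_like(yhat, np.median(yhat))
            fold_rec = {
                "fold_id": plan.fold_id,
                "test_subject": plan.test_subject,
                "n_test_windows": len(test),
                "n_train_windows": len(train),
                "mae": mae(y_test, yhat),
                "rmse": rmse(y_test, yhat),
            }
            per_fold.append(fold_rec)
            pooled_y.extend(y_test.tolist())
            pooled_yhat.extend(np.asarray(yhat).tolist())
            if verbose:  # pragma: no cover
                print(fold_rec)
        report = EvalReport(
            per_fold=per_fold,
            category_table=category_report(pooled_y, pooled_yhat),
            config=cfg,
        )
        return report

    def _fit_predict(
        self, plan: FoldPlan, train: list[Window], test: list[Window]
    ) -> np.ndarray:
        cfg = self.config
        y_train = np.array([w.bmi_label for w in train])
        fold_seed = _fold_seed(cfg.seed, plan.fold_id)
        if cfg.learner == "cnn_lstm":
            train_n = normalize_windows(train, cfg.normalization)
            test_n = normalize_windows(test, cfg.normalization)
            mcfg = replace(cfg.model, seed=fold_seed)
            res = CNNLSTMRegressor(train_n, y_train, mcfg).fit()
            return res.predict(test_n)
        if cfg.learner == "mean":
            return np.full(len(test), y_train.mean())
        # feature-based baselines operate on raw (unnormalized) windows
        ft_train = featurize_dataset(train)
        ft_test = featurize_dataset(test)
        feat_cols = [
            c for c in ft_train.columns
            if c not in ("subject_id", "window_index", "bmi")
        ]
        X_train = ft_train[feat_cols].to_numpy()
        X_test = ft_test[feat_cols].to_numpy()
        if cfg.learner == "knn":
            from sklearn.neighbors import KNeighborsRegressor

            est = KNeighborsRegressor(
                n_neighbors=min(cfg.knn_neighbors, len(train))
            )
        elif cfg.learner == "svr":
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler
            from sklearn.svm import SVR

            est = make_pipeline(StandardScaler(), SVR(kernel="rbf"))
        elif cfg.learner == "tree":
            from sklearn.tree import DecisionTreeRegressor

            est = DecisionTreeRegressor(random_state=fold_seed)
        else:  # pragma: no cover
            raise ValueError(cfg.learner)
        est.fit(X_train, y_train)
        return np.asarray(est.predict(X_test), dtype=float)


def run_experiment(
    dataset: DatasetLike, config: Optional[PipelineConfig] = None, **kw
) -> EvalReport:
    """Functional wrapper: ``LOSOExperiment(dataset, config).fit()``."""
    return LOSOExperiment(dataset, config).fit(**kw)
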