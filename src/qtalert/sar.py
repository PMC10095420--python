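"""SAR classifier training and evaluation.

Repeated stratified k-fold cross-validation (default five folds) of an
RBF-kernel support-vector classifier and comparison learners (logistic
regression, random forest, gradient-boosted trees), with:

* optional nested grid search for hyperparameters, performed inside the
  training folds only;
* a permutation-label negative control (``Permutation_Y``): labels are
  re-permuted independently before every iteration, so a sound pipeline
  scores at chance (balanced accuracy 0.5, MCC 0, precision equal to the
  positive-class prevalence);
* per-iteration metric panels summarized as mean ± sd;
* recall over ROR-ranked top-N drug subsets.

Margin and linear models are standardized (zero mean, unit variance,
fit on training folds only) and produce calibrated probabilities so the
stated 0.5 probability decision threshold applies; tree models consume
raw counts. Every source of randomness derives from a single seed, so
reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import DescriptorMatrix
from .disproportionality import RankedDrugList
from .metrics import METRIC_NAMES, MetricSet, metrics_from_predictions

ModelFamily = Literal["svm-rbf", "logistic", "random-forest", "gradient-boosted-trees"]

MODEL_FAMILIES: tuple[ModelFamily, ...] = (
    "svm-rbf",
    "logistic",
    "random-forest",
    "gradient-boosted-trees",
)


@dataclass
class CVConfig:
    n_folds: int = 5
    n_iterations: int = 1000
    decision_threshold: float = 0.5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class Hyperparams:
    """Model family plus fixed hyperparameters and an optional grid.

    When ``grid`` is set, each training fold runs an inner 3-fold grid
    search selecting by balanced accuracy; otherwise the fixed values
    are used directly. Grid keys address pipeline steps
    (e.g. ``model__C``, ``model__gamma``).
    """

    family: ModelFamily = "svm-rbf"
    c: float = 1.0
    gamma: float | str = "scale"
    grid: dict[str, list] | None = None
    extra: dict = field(default_factory=dict)


def default_svm_grid(step: int = 2) -> dict[str, list]:
    """Coarse log2 grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    return {
        "model__estimator__C": [2.0**e for e in range(-5, 16, step)],
        "model__estimator__gamma": [2.0**e for e in range(-15, 4, step)],
    }


def make_estimator(hp: Hyperparams, random_state: int = 0):
    """Build the (possibly grid-searched) pipeline for one model family."""
    if hp.family == "svm-rbf":
        base = SVC(C=hp.c, gamma=hp.gamma, kernel="rbf", **hp.extra)
        # Platt sigmoid calibration fit on inner training splits so the
        # 0.5 probability threshold is meaningful for a margin classifier
        model = CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
        steps = [("scale", StandardScaler()), ("model", model)]
    elif hp.family == "logistic":
        model = LogisticRegression(C=hp.c, max_iter=5000, **hp.extra)
        steps = [("scale", StandardScaler()), ("model", model)]
    elif hp.family == "random-forest":
        model = RandomForestClassifier(
            n_estimators=hp.extra.get("n_estimators", 200),
            random_state=random_state,
            **{k: v for k, v in hp.extra.items() if k != "n_estimators"},
        )
        steps = [("model", model)]
    elif hp.family == "gradient-boosted-trees":
        model = GradientBoostingClassifier(random_state=random_state, **hp.extra)
        steps = [("model", model)]
    else:
        raise ValueError(f"unknown model family {hp.family!r}")
    pipe = Pipeline(steps)
    if hp.grid:
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=random_state)
        return GridSearchCV(pipe, hp.grid, scoring="balanced_accuracy", cv=inner, n_jobs=1)
    return pipe


@dataclass
class CVSummary:
    """Per-iteration metric panels with mean ± sd summaries."""

    raw: pd.DataFrame  # one row per iteration, one column per metric
    family: ModelFamily
    config: CVConfig

    def mean(self) -> pd.Series:
        return self.raw.mean(axis=0)

    def sd(self) -> pd.Series:
        # sample sd across iterations, as reported alongside the mean
        return self.raw.std(axis=0, ddof=1).fillna(0.0)

    def sem(self) -> pd.Series:
        """Monte-Carlo standard error of each metric mean."""
        return self.sd() / np.sqrt(len(self.raw))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean(), "sd": self.sd()})

    def formatted(self) -> pd.Series:
        return pd.Series(
            {
                m: f"{self.mean()[m]:.3f} ± {self.sd()[m]:.3f}"
                for m in self.raw.columns
            }
        )


def _iteration_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-iteration substreams below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _cv_iteration(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    hp: Hyperparams,
    iteration_seed: int,
) -> MetricSet:
    """One shuffled k-fold pass: pooled out-of-fold predictions."""
    if config.stratified:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=iteration_seed
        )
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=iteration_seed)
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold lost one class entirely")
        est = make_estimator(hp, random_state=iteration_seed)
        est.fit(X[train_idx], y[train_idx])
        classes = est.classes_ if hasattr(est, "classes_") else est.best_estimator_.classes_
        pos_col = int(np.where(classes == 1)[0][0])
        oof[test_idx] = est.predict_proba(X[test_idx])[:, pos_col]
    return metrics_from_predictions(y, oof, config.decision_threshold)


def repeated_cv(matrix: DescriptorMatrix, config: CVConfig, hp: Hyperparams) -> CVSummary:
    """Repeated shuffled stratified k-fold CV; one pooled metric panel
    per iteration, summarized across iterations."""
    X, y = matrix.X(), matrix.y()
    _check_class_sizes(y, config)
    seeds = _iteration_seeds(config.seed, config.n_iterations)
    rows = [_cv_iteration(X, y, config, hp, s).as_dict() for s in seeds]
    return CVSummary(pd.DataFrame(rows, columns=list(METRIC_NAMES)), hp.family, config)


def permutation_control(
    matrix: DescriptorMatrix, config: CVConfig, hp: Hyperparams
) -> CVSummary:
    """Negative control: labels randomly permuted before every CV
    iteration. Converges to chance-level scores for any feature matrix."""
    X, y = matrix.X(), matrix.y()
    _check_class_sizes(y, config)
    seeds = _iteration_seeds(config.seed, config.n_iterations)
    rows = []
    for s in seeds:
        rng = np.random.default_rng(s)
        y_perm = rng.permutation(y)
        rows.append(_cv_iteration(X, y_perm, config, hp, s).as_dict())
    return CVSummary(pd.DataFrame(rows, columns=list(METRIC_NAMES)), hp.family, config)


def reduced_model_eval(
    matrix: DescriptorMatrix, selected: list[str], config: CVConfig, hp: Hyperparams
) -> CVSummary:
    """The repeated-CV protocol restricted to the selected columns."""
    return repeated_cv(matrix.select(selected), config, hp)


def fit_full(matrix: DescriptorMatrix, hp: Hyperparams, seed: int = 0):
    """Fit one estimator on the whole labeled matrix (for external
    validation such as ranked-recall evaluation)."""
    est = make_estimator(hp, random_state=seed)
    est.fit(matrix.X(), matrix.y())
    return est


def recall_at_top_n(
    model,
    ranked: RankedDrugList,
    matrix: DescriptorMatrix,
    step: int = 50,
    threshold: float = 0.5,
) -> list[tuple[int, float]]:
    """Recall over ROR-ranked prefixes.

    All ranked drugs are positives by construction (each has reports of
    the event), so recall at N is the fraction of the top-N drugs the
    model flags as positive. N grows by ``step`` until the whole list is
    covered.
    """
    ids = ranked.ids()
    missing = [i for i in ids if i not in matrix.values.index]
    if missing:
        raise KeyError(f"no descriptor row for ranked drug(s): {missing}")
    X = matrix.values.loc[ids].to_numpy(dtype=float)
    classes = model.classes_ if hasattr(model, "classes_") else model.best_estimator_.classes_
    pos_col = int(np.where(classes == 1)[0][0])
    proba = model.predict_proba(X)[:, pos_col]
    predicted_pos = proba > threshold
    out: list[tuple[int, float]] = []
    n = step
    while True:
        n_eff = min(n, len(ids))
        out.append((n_eff, float(predicted_pos[:n_eff].mean())))
        if n_eff == len(ids):
            break
        n += step
    return out


def _check_class_sizes(y: np.ndarray, config: CVConfig) -> None:
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ValueError("need both classes present")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{config.n_folds} folds"
        )
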