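"""Confusion-matrix metrics and repeated stratified cross-validation.

AD (patient) is the positive class throughout:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (= recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)

The evaluation protocol is a k-fold stratified cross-validation repeated
``runs`` times with fresh fold assignments.  Within each run the
validation predictions of all folds are pooled into one confusion matrix
before computing metrics (robust when the positive class contributes
only 2-3 subjects per fold); per-fold metrics are also recorded.
Aggregates are the mean and sample standard deviation over runs.

Dimensionality reduction is fit inside each training fold by default
(``pca_mode='per-fold'``), so the validation fold never influences the
component directions; ``'global'`` fits once on the full matrix, which
mimics protocols that reduce before splitting at the price of mild
information leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import pca as _pca
from .features import FeatureMatrix
from .network import TrainConfig, classify, train_scg

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVConfig",
    "CVReport",
    "metrics",
    "stratified_folds",
    "run_cv",
]

_POS, _NEG = "AD", "HC"


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fn/fp/tn with AD as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=object).astype(str)
        y_pred = np.asarray(y_pred, dtype=object).astype(str)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction/label length mismatch")
        return cls(
            tp=int(((y_true == _POS) & (y_pred == _POS)).sum()),
            fn=int(((y_true == _POS) & (y_pred == _NEG)).sum()),
            fp=int(((y_true == _NEG) & (y_pred == _POS)).sum()),
            tn=int(((y_true == _NEG) & (y_pred == _NEG)).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision and recall."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    return MetricSet(
        accuracy=_ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        sensitivity=sens,
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        precision=_ratio(counts.tp, counts.tp + counts.fp, "precision"),
        recall=sens,
    )


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of `k` stratified folds (seeded shuffle).

    Fold sizes differ by at most one, as do per-class counts across
    folds.  Classes with fewer members than `k` trigger a warning and
    appear in only some folds.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got k={k}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members for k={k}: "
            "some folds will lack that class", RuntimeWarning, stacklevel=2)
        # downgrade: deal the (seeded) shuffled members of each class
        # round-robin into folds; sizes and per-class counts still differ
        # by at most one across folds
        rng = np.random.default_rng(seed)
        assignment = np.empty(len(labels), dtype=int)
        ptr = 0
        for cls in np.unique(labels):
            idx = np.nonzero(labels == cls)[0]
            rng.shuffle(idx)
            for i in idx:
                assignment[i] = ptr % k
                ptr += 1
        return assignment
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 32))
    assignment = np.empty(len(labels), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignment[val_idx] = fold
    return assignment


@dataclass(frozen=True)
class CVConfig:
    """Settings of the repeated stratified CV pipeline."""

    runs: int = 50
    folds: int = 10
    variance_threshold: float = 0.90
    pcs_override: int | None = None
    pca_mode: str = "per-fold"          # or "global"
    hidden_units: int = 10
    threshold: float = 0.5
    balance_class_costs: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.pca_mode not in ("per-fold", "global"):
            raise ValueError(f"unknown pca_mode {self.pca_mode!r}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class CVReport:
    """Per-run metrics, their aggregates, fold assignments and settings."""

    per_run: list[dict]                  # one MetricSet dict per run
    per_fold: list[list[dict]]           # run -> fold -> metric dict
    fold_assignments: list[list[int]]    # run -> assignment vector
    mean: dict
    sd: dict
    sd_folds: dict
    seed: int
    config: dict

    def to_json(self, path=None, indent: int = 2):
        payload = {
            "seed": self.seed,
            "config": self.config,
            "mean": self.mean,
            "sd": self.sd,
            "sd_folds": self.sd_folds,
            "per_run": self.per_run,
            "per_fold": self.per_fold,
            "fold_assignments": self.fold_assignments,
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = []
        for m in ("accuracy", "sensitivity", "specificity", "precision"):
            lines.append(f"{m:>12s}: {self.mean[m] * 100:6.2f} +/- "
                         f"{self.sd[m] * 100:.2f} %")
        return "\n".join(lines)


def _class_costs(labels) -> tuple[float, float]:
    """Per-class weights inversely proportional to class frequency."""
    labels = np.asarray(labels, dtype=object).astype(str)
    n = len(labels)
    n_ad = int((labels == _POS).sum())
    n_hc = n - n_ad
    return (n / (2.0 * n_hc), n / (2.0 * n_ad))


def run_cv(matrix, labels=None, config: CVConfig = CVConfig(), seed: int = 0) -> CVReport:
    """Repeated stratified k-fold CV of the PCA + FNN pipeline.

    `matrix` may be a :class:`FeatureMatrix` (labels taken from it) or a
    plain (n, p) array with `labels` given separately.  Per-run seeds are
    spawned deterministically from `seed`, so run r is reproducible in
    isolation.
    """
    if isinstance(matrix, FeatureMatrix):
        x = matrix.values
        labels = matrix.labels
    else:
        x = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a plain array")
        labels = np.asarray(labels, dtype=object).astype(str)
    n = x.shape[0]
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    global_model = None
    if config.pca_mode == "global":
        global_model = _pca.fit_pca(x)

    root = np.random.SeedSequence(seed)
    run_seeds = [int(ss.generate_state(1)[0] % (2 ** 31)) for ss in
                 root.spawn(config.runs)]

    per_run, per_fold_all, assignments = [], [], []
    for run, rseed in enumerate(run_seeds):
        folds = stratified_folds(labels, config.folds, seed=rseed)
        y_pred = np.empty(n, dtype=object)
        fold_metrics = []
        for fold in range(config.folds):
            val = folds == fold
            train = ~val
            if len(np.unique(labels[train])) < 2:
                raise ValueError(
                    f"run {run}, fold {fold}: training folds contain a "
                    "single class"
                )
            if config.pca_mode == "per-fold":
                model = _pca.fit_pca(x[train])
            else:
                model = global_model
            if config.pcs_override is not None:
                k = min(config.pcs_override, model.k_max)
            else:
                k = _pca.select_components(model, config.variance_threshold)
            s_train = _pca.transform(model, x[train], k)
            s_val = _pca.transform(model, x[val], k)
            costs = _class_costs(labels[train]) if config.balance_class_costs else None
            tcfg = TrainConfig(
                max_iterations=config.train.max_iterations,
                mse_goal=config.train.mse_goal,
                sigma=config.train.sigma,
                lambda_init=config.train.lambda_init,
                seed=int((rseed * config.folds + fold) % (2 ** 31)),
                class_costs=costs,
                use_bias=config.train.use_bias,
            )
            t_train = (labels[train] == _POS).astype(float)
            weights, _ = train_scg(
                s_train, t_train, (k, config.hidden_units, 1), tcfg
            )
            pred = classify(weights, s_val, config.threshold)
            y_pred[val] = pred
            fold_metrics.append(
                metrics(ConfusionCounts.from_predictions(labels[val], pred)).as_dict()
            )
        counts = ConfusionCounts.from_predictions(labels, y_pred)
        assert counts.total == n
        per_run.append(metrics(counts).as_dict())
        per_fold_all.append(fold_metrics)
        assignments.append(folds.tolist())

    keys = per_run[0].keys()
    mean = {m: float(np.mean([r[m] for r in per_run])) for m in keys}
    sd = {
        m: float(np.std([r[m] for r in per_run], ddof=1)) if config.runs > 1 else 0.0
        for m in keys
    }
    flat_folds = [f for run in per_fold_all for f in run]
    sd_folds = {
        m: float(np.nanstd([f[m] for f in flat_folds], ddof=1))
        if len(flat_folds) > 1 else 0.0
        for m in keys
    }
    cfg = asdict(config)
    return CVReport(
        per_run=per_run,
        per_fold=per_fold_all,
        fold_assignments=assignments,
        mean=mean,
        sd=sd,
        sd_folds=sd_folds,
        seed=seed,
        config=cfg,
    )
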