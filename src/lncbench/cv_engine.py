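"""Gene-grouped repeated cross-validation with factorial filter application.

This is the machinery that demonstrates the middle-exclusion effect: identical
fold plans are evaluated under four filter-application modes —

* ``all``        filter both the training and the evaluation side of each fold,
* ``none``       filter nothing,
* ``train_only`` filter the training side only,
* ``eval_only``  filter the evaluation side only,

so that any difference in the reported metrics is attributable to where the
filter was applied, not to fold composition or model seeds.

Two guards are enforced, not advisory:

* gene grouping — all records of a gene land on one side of every split
  (transcript isoforms share sequence, so splitting them leaks sequence
  between training and evaluation);
* an access audit — model fitting reads training data exclusively through an
  :class:`AuditedDataset` that raises :class:`LeakageError` if any record of
  the fold's evaluation side is requested.

Model families wrap vendor implementations with default hyperparameters and
only seeds pinned; ``gbdt_default`` (LightGBM) is the benchmark model.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .localization_prep import FilterSpec, LabeledDataset, middle_exclusion

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_FAMILIES",
    "RANK_METRICS",
    "METRICS",
    "LeakageError",
    "ModelSpec",
    "FoldPlan",
    "MetricReport",
    "AuditedDataset",
    "build_model",
    "make_fold_plan",
    "compute_metrics",
    "run_condition",
    "run_factorial",
    "run_interval_sweep",
    "pooled_sd",
]

MODEL_FAMILIES = ("gbdt_default", "random_forest", "gradient_boosting", "svm_rbf", "mlp3")
METRICS = ("accuracy", "f1", "mcc", "auprc", "auroc")
RANK_METRICS = ("auprc", "auroc")


class LeakageError(RuntimeError):
    """Evaluation-fold data was requested during model construction."""


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A model family with vendor-default hyperparameters and a pinned seed."""

    family: str = "gbdt_default"
    seed: int = 0
    overrides: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def build_model(spec: ModelSpec):
    """Instantiate the estimator for a spec. Defaults untouched except the seed.

    ``mlp3`` is a three-layer perceptron (1344 -> 128 -> 64 -> 2, ReLU) with a
    fixed epoch budget and early stopping disabled: early stopping monitors a
    validation split during training, which is exactly the continuous preview
    of held-out performance the evaluation protocol forbids.
    """
    overrides = dict(spec.overrides)
    if spec.family == "gbdt_default":
        import lightgbm

        return lightgbm.LGBMClassifier(random_state=spec.seed, verbose=-1, **overrides)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **overrides)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **overrides)
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=spec.seed, **overrides)
    if spec.family == "mlp3":
        overrides.setdefault("hidden_layer_sizes", (128, 64))
        overrides.setdefault("max_iter", 60)
        return MLPClassifier(
            random_state=spec.seed, early_stopping=False, **overrides
        )
    raise AssertionError(spec.family)


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Materialized (train ids, eval ids) pairs for repeated grouped CV."""

    n_folds: int
    n_repeats: int
    holdout_fraction: float
    stratified: bool
    seed: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    holdout_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.folds)


def make_fold_plan(
    dataset: LabeledDataset,
    n_folds: int = 5,
    n_repeats: int = 2,
    holdout_fraction: float = 0.0,
    stratified: bool = True,
    seed: int = 0,
) -> FoldPlan:
    """Stratified-by-label, grouped-by-gene repeated folds, deterministic per seed.

    If ``holdout_fraction`` > 0, that fraction of genes (stratified) is removed
    first with the plan seed and never appears in any fold — mirroring a
    protocol that withholds a final test set from cross-validation. Repeats
    differ by reshuffling with derived seeds.
    """
    df = dataset.df
    ids = df.index.to_numpy()
    labels = df["label"].to_numpy(dtype=int)
    groups = df["gene"].to_numpy()

    rng = np.random.default_rng(seed)
    holdout_ids = np.array([], dtype=ids.dtype)
    if holdout_fraction > 0:
        holdout_genes = _stratified_gene_sample(ids, labels, groups, holdout_fraction, rng)
        holdout_mask = np.isin(groups, list(holdout_genes))
        holdout_ids = ids[holdout_mask]
        ids, labels, groups = ids[~holdout_mask], labels[~holdout_mask], groups[~holdout_mask]

    counts = np.bincount(labels, minlength=2)
    if (counts < n_folds).any():
        raise ValueError(
            f"each class needs >= n_folds={n_folds} members, got {tuple(counts)}"
        )

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if stratified:
            splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        else:
            order = np.random.default_rng(rep_seed).permutation(len(ids))
            ids, labels, groups = ids[order], labels[order], groups[order]
            splitter = GroupKFold(n_splits=n_folds)
        for train_idx, eval_idx in splitter.split(np.zeros_like(labels), labels, groups):
            folds.append((ids[np.sort(train_idx)], ids[np.sort(eval_idx)]))
    return FoldPlan(
        n_folds=n_folds,
        n_repeats=n_repeats,
        holdout_fraction=holdout_fraction,
        stratified=stratified,
        seed=seed,
        folds=tuple(folds),
        holdout_ids=holdout_ids,
    )


def _stratified_gene_sample(ids, labels, groups, fraction, rng) -> set:
    """Sample whole genes, stratified by each gene's (first) label."""
    import pandas as pd

    per_gene = pd.DataFrame({"gene": groups, "label": labels}).groupby("gene")["label"].first()
    chosen: list = []
    for label_value, members in per_gene.groupby(per_gene):
        genes = np.sort(members.index.to_numpy())
        n_take = int(round(fraction * len(genes)))
        chosen.extend(rng.choice(genes, size=n_take, replace=False))
    return set(chosen)


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------

class AuditedDataset:
    """Access-audited view of a dataset with a forbidden (evaluation) id set.

    Every matrix extraction goes through :meth:`take`; requesting any
    forbidden record raises :class:`LeakageError`. The engine routes all
    fitting-side access through this wrapper so the leakage guard is enforced
    by construction, not convention.
    """

    def __init__(self, dataset: LabeledDataset, forbidden_ids: Iterable):
        if dataset.features is None:
            raise ValueError("dataset must be featurized before model fitting")
        self._dataset = dataset
        self._forbidden = set(forbidden_ids)
        self.accessed: set = set()

    def take(self, record_ids: Sequence) -> tuple[np.ndarray, np.ndarray]:
        requested = set(record_ids)
        leaked = requested & self._forbidden
        if leaked:
            raise LeakageError(
                f"fit-side access to {len(leaked)} evaluation-fold record(s), "
                f"e.g. {sorted(leaked)[:3]}"
            )
        self.accessed |= requested
        sub = self._dataset.subset(record_ids)
        return sub.features, sub.labels


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, decision_threshold: float = 0.5
) -> dict:
    """Accuracy/F1/MCC from thresholded scores plus rank metrics, on the 0-100 scale.

    Positive class is cytoplasmic (1). Scores exactly at the threshold go to
    the negative class (``score > threshold`` predicts positive), so a
    constant 0.5 score on balanced labels yields 50% accuracy. With a single
    observed class the rank metrics are undefined and returned as NaN.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    preds = (scores > decision_threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division F1/MCC on degenerate folds
        out = {
            "accuracy": 100.0 * accuracy_score(labels, preds),
            "f1": 100.0 * f1_score(labels, preds, zero_division=0),
            "mcc": float(matthews_corrcoef(labels, preds)),
        }
    if len(np.unique(labels)) < 2:
        out["auprc"] = math.nan
        out["auroc"] = math.nan
    else:
        out["auprc"] = 100.0 * average_precision_score(labels, scores)
        out["auroc"] = 100.0 * roc_auc_score(labels, scores)
    out["confusion"] = {"tn": tn, "fp": fp, "fn": fn, "tp": tp}
    return out


@dataclass(frozen=True)
class MetricReport:
    """Per-fold metrics and their mean +/- sd for one evaluation condition."""

    condition: str
    per_fold: tuple[Mapping, ...]

    def values(self, metric: str) -> np.ndarray:
        return np.array([f[metric] for f in self.per_fold], dtype=float)

    def mean(self, metric: str) -> float:
        vals = self.values(metric)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else math.nan

    def sd(self, metric: str) -> float:
        vals = self.values(metric)
        vals = vals[~np.isnan(vals)]
        return float(vals.std(ddof=1)) if len(vals) > 1 else math.nan

    def n_defined(self, metric: str) -> int:
        return int((~np.isnan(self.values(metric))).sum())

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m), "n_folds": self.n_defined(m)}
            for m in METRICS
        }

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "summary": self.summary(),
            "per_fold": [dict(f) for f in self.per_fold],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------------
# Condition runs
# ---------------------------------------------------------------------------

def _filtered_ids(dataset: LabeledDataset, ids: np.ndarray, filt: FilterSpec) -> np.ndarray:
    sub = middle_exclusion(dataset.subset(ids), filt)
    return sub.df.index.to_numpy()


def _fold_metrics(model, dataset, eval_ids, n_train) -> dict:
    sub = dataset.subset(eval_ids)
    row: dict = {"n_train": int(n_train), "n_eval": int(len(sub))}
    if len(sub) == 0:
        logger.warning("empty evaluation fold after filtering; metrics undefined")
        row.update({m: math.nan for m in METRICS})
        row["confusion"] = {"tn": 0, "fp": 0, "fn": 0, "tp": 0}
        return row
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper warns about feature names on ndarray input
        warnings.simplefilter("ignore", UserWarning)
        scores = model.predict_proba(sub.features)[:, list(model.classes_).index(1)]
    metrics = compute_metrics(sub.labels, scores)
    if math.isnan(metrics["auroc"]):
        logger.warning("single-class evaluation fold: rank metrics undefined")
    row.update(metrics)
    return row


def run_condition(
    dataset: LabeledDataset,
    model: ModelSpec,
    plan: FoldPlan,
    filt: FilterSpec,
) -> MetricReport:
    """Train and score every fold under one filter-application mode.

    Per fold: apply the middle-exclusion interval to the training side iff the
    mode is ``all``/``train_only`` and to the evaluation side iff
    ``all``/``eval_only``; fit on the (possibly filtered) training fold only,
    score class-1 probabilities on the (possibly filtered) evaluation fold.
    Folds whose evaluation side degenerates to one class keep their threshold
    metrics but record NaN rank metrics, which the report excludes from means.
    """
    rows = []
    for train_ids, eval_ids in plan.folds:
        tr = _filtered_ids(dataset, train_ids, filt) if filt.applies_to_train() else train_ids
        ev = _filtered_ids(dataset, eval_ids, filt) if filt.applies_to_eval() else eval_ids
        audited = AuditedDataset(dataset, forbidden_ids=eval_ids)
        x_train, y_train = audited.take(tr)
        estimator = build_model(model)
        estimator.fit(x_train, y_train)
        rows.append(_fold_metrics(estimator, dataset, ev, len(tr)))
    return MetricReport(condition=filt.mode, per_fold=tuple(rows))


def run_factorial(
    dataset: LabeledDataset,
    model: ModelSpec,
    plan: FoldPlan,
    interval: tuple[float, float] = (-1.0, 1.0),
) -> dict[str, MetricReport]:
    """All four filter modes on identical folds and model seeds.

    Modes sharing a training set share one fit per fold (``none``/``eval_only``
    train unfiltered; ``all``/``train_only`` train filtered), which is exact
    because the model families are deterministic given data + seed; equality
    with independent :func:`run_condition` calls is part of the test suite.
    Returns ``{mode: MetricReport}`` with exactly the four modes as keys.
    """
    lower, upper = interval
    base = FilterSpec(lower=lower, upper=upper, mode="none")
    rows: dict[str, list] = {mode: [] for mode in ("all", "none", "train_only", "eval_only")}
    for train_ids, eval_ids in plan.folds:
        audited = AuditedDataset(dataset, forbidden_ids=eval_ids)
        tr_filt = _filtered_ids(dataset, train_ids, base)
        ev_filt = _filtered_ids(dataset, eval_ids, base)

        model_plain = build_model(model)
        model_plain.fit(*audited.take(train_ids))
        model_filt = build_model(model)
        model_filt.fit(*audited.take(tr_filt))

        rows["none"].append(_fold_metrics(model_plain, dataset, eval_ids, len(train_ids)))
        rows["eval_only"].append(_fold_metrics(model_plain, dataset, ev_filt, len(train_ids)))
        rows["train_only"].append(_fold_metrics(model_filt, dataset, eval_ids, len(tr_filt)))
        rows["all"].append(_fold_metrics(model_filt, dataset, ev_filt, len(tr_filt)))
    return {mode: MetricReport(mode, tuple(r)) for mode, r in rows.items()}


def run_interval_sweep(
    dataset: LabeledDataset,
    model: ModelSpec,
    plan: FoldPlan,
    half_widths: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    modes: Sequence[str] = ("all", "none", "train_only", "eval_only"),
) -> dict[float, dict[str, MetricReport]]:
    """One report per requested mode per symmetric interval [-w, w].

    The unfiltered-train fit per fold is shared across widths (it does not
    depend on the interval). When ``modes`` excludes both ``all`` and
    ``train_only`` the filtered-train fits are skipped entirely, making the
    boost curve (``eval_only`` minus ``none``) cost one fit per fold total.
    """
    unknown = set(modes) - {"all", "none", "train_only", "eval_only"}
    if unknown:
        raise ValueError(f"unknown filter modes: {sorted(unknown)}")
    need_filtered_fit = bool({"all", "train_only"} & set(modes))
    rows: dict[float, dict[str, list]] = {
        float(w): {mode: [] for mode in modes} for w in half_widths
    }
    for train_ids, eval_ids in plan.folds:
        audited = AuditedDataset(dataset, forbidden_ids=eval_ids)
        model_plain = build_model(model)
        model_plain.fit(*audited.take(train_ids))
        plain_row = _fold_metrics(model_plain, dataset, eval_ids, len(train_ids))
        for w in rows:
            filt = FilterSpec(lower=-w, upper=w, mode="none")
            ev_filt = _filtered_ids(dataset, eval_ids, filt)
            if "none" in rows[w]:
                rows[w]["none"].append(plain_row)
            if "eval_only" in rows[w]:
                rows[w]["eval_only"].append(
                    _fold_metrics(model_plain, dataset, ev_filt, len(train_ids))
                )
            if need_filtered_fit:
                tr_filt = _filtered_ids(dataset, train_ids, filt)
                model_filt = build_model(model)
                model_filt.fit(*audited.take(tr_filt))
                if "train_only" in rows[w]:
                    rows[w]["train_only"].append(
                        _fold_metrics(model_filt, dataset, eval_ids, len(tr_filt))
                    )
                if "all" in rows[w]:
                    rows[w]["all"].append(
                        _fold_metrics(model_filt, dataset, ev_filt, len(tr_filt))
                    )
    return {
        w: {mode: MetricReport(mode, tuple(r)) for mode, r in mode_rows.items()}
        for w, mode_rows in rows.items()
    }


def pooled_sd(report_a: MetricReport, report_b: MetricReport, metric: str = "auroc") -> float:
    """Root-mean of the two conditions' fold variances — the comparison yardstick."""
    va, vb = report_a.sd(metric) ** 2, report_b.sd(metric) ** 2
    return math.sqrt((va + vb) / 2.0)
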