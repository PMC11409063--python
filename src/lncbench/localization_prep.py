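"""From CNRCI matrix + sequences to a labeled, balanced per-gene dataset.

The stages, in pipeline order:

1. optional cell-line screening (drop lines whose CNRCI values correlate
   poorly with the rest — computed on training genes only, to keep evaluation
   data out of the decision),
2. aggregation of per-cell-line CNRCI values to one scalar per gene,
3. binarization against thresholds (positive = cytoplasmic = 1,
   negative = nuclear = 0),
4. (optionally, and in the CV engine per fold) the middle-exclusion filter:
   removal of records whose CNRCI lies in a central closed interval,
5. class balancing by down-sampling the majority class.

Aggregation variants
--------------------
``log2_mean_ratio`` (the benchmark default) computes
``log2( mean_c 2**CNRCI_{g,c} )`` over non-missing cell lines — the log of the
mean of the raw cytoplasmic/nuclear ratios, which has a direct abundance
interpretation. ``mean_cnrci`` averages the log-ratios themselves (the
historical protocol), and ``single_cell_line`` reads one column. By Jensen's
inequality ``log2_mean_ratio >= mean_cnrci`` for every gene, with equality
exactly on constant rows.

The middle-exclusion filter is deliberately a standalone, pure operation with
an explicit application mode (all / none / train_only / eval_only): the point
of the factorial experiment is to attribute metric changes to where the filter
is applied, so the filter itself never decides that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CnrciTable, JoinedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AGGREGATIONS",
    "FILTER_MODES",
    "LabelSpec",
    "FilterSpec",
    "ScreenResult",
    "LabeledDataset",
    "aggregate_cnrci",
    "screen_cell_lines",
    "binarize",
    "middle_exclusion",
    "downsample_majority",
    "prepare_dataset",
]

AGGREGATIONS = ("log2_mean_ratio", "mean_cnrci", "single_cell_line")
FILTER_MODES = ("all", "none", "train_only", "eval_only")


@dataclass(frozen=True)
class LabelSpec:
    """Labeling protocol: aggregation rule, excluded lines, thresholds.

    ``threshold_cyt``/``threshold_nuc`` bound the labeling gap: a gene is
    cytoplasmic (1) when its aggregate is strictly above ``threshold_cyt``,
    nuclear (0) when strictly below ``threshold_nuc``, and dropped in between
    (closed gap — an aggregate exactly at a coincident threshold of 0 is
    dropped, since the sign rule is undefined there).
    """

    aggregation: str = "log2_mean_ratio"
    cell_line: str | None = None  # required for single_cell_line
    excluded_cell_lines: tuple[str, ...] = ()
    screen_min_corr: float | None = None  # data-driven screen threshold, if set
    threshold_cyt: float = 0.0
    threshold_nuc: float = 0.0
    min_cell_lines: int = 1

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.aggregation == "single_cell_line" and not self.cell_line:
            raise ValueError("single_cell_line aggregation requires cell_line")
        if self.threshold_nuc > self.threshold_cyt:
            raise ValueError("threshold_nuc must be <= threshold_cyt")
        if self.min_cell_lines < 1:
            raise ValueError("min_cell_lines must be >= 1")


@dataclass(frozen=True)
class FilterSpec:
    """Middle-exclusion interval [lower, upper] (closed) and application mode."""

    lower: float = -1.0
    upper: float = 1.0
    mode: str = "none"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("FilterSpec: lower must be <= upper")
        if self.mode not in FILTER_MODES:
            raise ValueError(f"FilterSpec: unknown mode {self.mode!r}")

    def applies_to_train(self) -> bool:
        return self.mode in ("all", "train_only")

    def applies_to_eval(self) -> bool:
        return self.mode in ("all", "eval_only")

    def with_half_width(self, w: float) -> "FilterSpec":
        """Symmetric interval [-w, w] around zero, same mode."""
        return replace(self, lower=-w, upper=w)


# ---------------------------------------------------------------------------
# Labeled dataset container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledDataset:
    """Per-record localization data: gene, aggregate CNRCI, binary label, sequence.

    ``df`` is indexed by a unique record id (equal to the gene id in the
    standard one-record-per-gene pipeline) with columns ``gene`` (grouping key
    for splits), ``cnrci`` (kept on every record so evaluation-side filtering
    stays possible after labeling), ``label`` (1 = cytoplasmic, 0 = nuclear)
    and optionally ``sequence``. ``features`` rows align with ``df`` rows.
    """

    df: pd.DataFrame
    features: np.ndarray | None = None
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("record ids must be unique")
        for col in ("gene", "cnrci", "label"):
            if col not in self.df.columns:
                raise ValueError(f"LabeledDataset missing column {col!r}")
        if self.features is not None and len(self.features) != len(self.df):
            raise ValueError("feature matrix row count does not match records")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def record_ids(self) -> np.ndarray:
        return self.df.index.to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(n_nuclear, n_cytoplasmic)."""
        labels = self.df["label"]
        return int((labels == 0).sum()), int((labels == 1).sum())

    def subset(self, record_ids: Sequence) -> "LabeledDataset":
        idx = self.df.index.get_indexer(list(record_ids))
        if (idx < 0).any():
            missing = [r for r, i in zip(record_ids, idx) if i < 0]
            raise KeyError(f"unknown record ids: {missing[:3]}")
        feats = self.features[idx] if self.features is not None else None
        return LabeledDataset(self.df.iloc[idx], feats, self.feature_names)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_cnrci(table: CnrciTable, spec: LabelSpec) -> pd.Series:
    """One scalar per gene under the spec's aggregation rule.

    Missing entries are ignored per gene; genes with fewer than
    ``min_cell_lines`` non-missing entries (after dropping excluded lines) are
    removed with a logged count.
    """
    df = table.df.drop(columns=[c for c in spec.excluded_cell_lines if c in table.df.columns])
    if df.shape[1] == 0:
        raise ValueError("excluded_cell_lines removes every cell line")

    if spec.aggregation == "single_cell_line":
        if spec.cell_line not in df.columns:
            raise ValueError(f"cell line {spec.cell_line!r} not in table")
        values = df[spec.cell_line]
        n_obs = values.notna().astype(int)
    else:
        n_obs = df.notna().sum(axis=1)
        if spec.aggregation == "log2_mean_ratio":
            # log of the mean of the raw ratios, not the mean of the logs
            with np.errstate(invalid="ignore"):
                values = np.log2(np.exp2(df).mean(axis=1, skipna=True))
        else:  # mean_cnrci
            values = df.mean(axis=1, skipna=True)

    keep = n_obs >= spec.min_cell_lines
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "aggregate_cnrci: dropped %d genes with < %d observed cell lines",
            n_dropped, spec.min_cell_lines,
        )
    return values[keep].dropna().astype(float)


# ---------------------------------------------------------------------------
# Cell-line screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    excluded: tuple[str, ...]
    mean_correlation: pd.Series  # per cell line, mean pairwise Spearman
    n_training_genes: int


def screen_cell_lines(
    table: CnrciTable,
    min_mean_corr: float,
    training_gene_ids: Iterable[str],
) -> ScreenResult:
    """Flag cell lines whose CNRCI values correlate poorly with the others.

    Per line: the mean pairwise Spearman correlation with every other line over
    co-observed genes; lines below ``min_mean_corr`` are excluded. The
    correlation is computed on ``training_gene_ids`` only — screening on
    evaluation genes would leak the response into protocol decisions, so the
    caller must state which genes are fair game.
    """
    if len(table.cell_lines) < 3:
        raise ValueError("cell-line screen undefined with fewer than 3 lines")
    sub = table.df.loc[table.df.index.intersection(list(training_gene_ids))]
    corr = sub.corr(method="spearman", min_periods=3)
    np.fill_diagonal(corr.values, np.nan)
    mean_corr = corr.mean(axis=1, skipna=True)
    excluded = tuple(mean_corr.index[mean_corr < min_mean_corr])
    logger.info(
        "screen_cell_lines: excluded %s (threshold %.2f, %d training genes)",
        list(excluded) or "nothing", min_mean_corr, len(sub),
    )
    return ScreenResult(excluded, mean_corr, len(sub))


# ---------------------------------------------------------------------------
# Binarization, middle exclusion, balancing
# ---------------------------------------------------------------------------

def binarize(
    values: pd.Series | Mapping[str, float],
    spec: LabelSpec,
    sequences: Mapping[str, str] | None = None,
) -> LabeledDataset:
    """Assign binary labels; the labeling-gap interval is dropped with a count.

    value > threshold_cyt -> 1 (cytoplasmic); value < threshold_nuc -> 0
    (nuclear); values in [threshold_nuc, threshold_cyt] — including an exact 0
    under coincident thresholds at 0 — fall in the gap and are removed. This
    drop is part of labeling and is distinct from the middle-exclusion
    FilterSpec applied later.
    """
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    series = series.astype(float)
    label = pd.Series(np.nan, index=series.index)
    label[series > spec.threshold_cyt] = 1
    label[series < spec.threshold_nuc] = 0
    n_gap = int(label.isna().sum())
    if n_gap:
        logger.info("binarize: %d genes in the labeling gap dropped", n_gap)
    keep = label.notna()
    df = pd.DataFrame(
        {
            "gene": series.index[keep],
            "cnrci": series[keep].to_numpy(),
            "label": label[keep].to_numpy(dtype=int),
        },
        index=series.index[keep],
    )
    df.index.name = "record_id"
    if sequences is not None:
        df["sequence"] = [sequences[g] for g in df["gene"]]
    return LabeledDataset(df.sort_index())


def middle_exclusion(dataset: LabeledDataset, filt: FilterSpec) -> LabeledDataset:
    """Remove records with CNRCI in the closed interval [lower, upper]. Pure."""
    keep = ~dataset.df["cnrci"].between(filt.lower, filt.upper, inclusive="both")
    n_before, n_after = len(dataset), int(keep.sum())
    logger.debug("middle_exclusion [%g, %g]: %d -> %d records",
                 filt.lower, filt.upper, n_before, n_after)
    feats = dataset.features[keep.to_numpy()] if dataset.features is not None else None
    return LabeledDataset(dataset.df[keep], feats, dataset.feature_names)


def downsample_majority(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Balance classes exactly by down-sampling the majority without replacement.

    Deterministic per seed; sampling operates on the sorted majority ids so
    the result does not depend on input row order.
    """
    n_nuc, n_cyt = dataset.class_counts()
    if n_nuc == 0 or n_cyt == 0:
        raise ValueError("downsample_majority requires both classes non-empty")
    if n_nuc == n_cyt:
        return dataset
    majority = 0 if n_nuc > n_cyt else 1
    n_keep = min(n_nuc, n_cyt)
    maj_ids = np.sort(dataset.df.index[dataset.df["label"] == majority].to_numpy())
    rng = np.random.default_rng(seed)
    kept_maj = rng.choice(maj_ids, size=n_keep, replace=False)
    keep_ids = set(kept_maj) | set(dataset.df.index[dataset.df["label"] != majority])
    keep_sorted = sorted(keep_ids)
    logger.info("downsample_majority: (%d nuc, %d cyt) -> (%d, %d)",
                n_nuc, n_cyt, n_keep, n_keep)
    return dataset.subset(keep_sorted)


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def prepare_dataset(
    joined: JoinedDataset,
    spec: LabelSpec = LabelSpec(),
    *,
    balance_seed: int | None = None,
) -> tuple[LabeledDataset, dict]:
    """Screen (optional) -> aggregate -> binarize -> balance (optional).

    When ``spec.screen_min_corr`` is set, the data-driven screen runs over all
    joined genes (a global protocol decision made before any splitting, as in
    an explicit-exclusion-list protocol); fold-level screening is available by
    calling ``screen_cell_lines`` with the fold's training genes. Returns the
    dataset and a stage-count report.
    """
    report: dict = {"n_joined": len(joined.genes)}
    table = joined.cnrci
    excluded = list(spec.excluded_cell_lines)
    if spec.screen_min_corr is not None:
        screen = screen_cell_lines(table, spec.screen_min_corr, joined.genes)
        excluded.extend(c for c in screen.excluded if c not in excluded)
        report["screen_excluded"] = list(screen.excluded)
    spec = replace(spec, excluded_cell_lines=tuple(excluded))
    values = aggregate_cnrci(table, spec)
    report["n_aggregated"] = len(values)
    dataset = binarize(values, spec, sequences=joined.sequences)
    report["n_labeled"] = len(dataset)
    report["class_counts"] = dict(zip(("nuclear", "cytoplasmic"), dataset.class_counts()))
    if balance_seed is not None:
        dataset = downsample_majority(dataset, balance_seed)
        report["n_balanced"] = len(dataset)
    return dataset, report
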