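"""Shared fixtures: small synthetic cohorts and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import lncbench as lb


@pytest.fixture(scope="session")
def small_cohort() -> lb.SyntheticCohort:
    """A quick cohort (300 genes, short sequences) for structural tests."""
    cfg = lb.SyntheticConfig(n_genes=300, seq_len_mean=400.0, seq_len_sd=60.0, seed=11)
    return lb.generate_cohort(cfg)


def prepare_cohort(cohort: lb.SyntheticCohort, *, balance_seed: int = 42) -> lb.LabeledDataset:
    """Screen -> aggregate -> label -> balance -> featurize, the standard path."""
    screen = lb.screen_cell_lines(cohort.cnrci, 0.5, cohort.genes)
    spec = lb.LabelSpec(excluded_cell_lines=screen.excluded)
    values = lb.aggregate_cnrci(cohort.cnrci, spec)
    dataset = lb.binarize(values, spec, sequences=cohort.sequences)
    dataset = lb.downsample_majority(dataset, balance_seed)
    return lb.featurize_dataset(dataset)


@pytest.fixture(scope="session")
def small_dataset(small_cohort) -> lb.LabeledDataset:
    return prepare_cohort(small_cohort)


def brute_force_kmer_profile(sequence: str, ks=(3, 4, 5)) -> np.ndarray:
    """Independent k-mer counter: enumerate every substring into a dict."""
    blocks = []
    for k in sorted(ks):
        words = ["".join(w) for w in itertools.product("ACGT", repeat=k)]
        counts = dict.fromkeys(words, 0)
        n_valid = 0
        for i in range(len(sequence) - k + 1):
            window = sequence[i : i + k]
            if all(b in "ACGT" for b in window):
                counts[window] += 1
                n_valid += 1
        if n_valid:
            blocks.append(np.array([counts[w] / n_valid for w in words]))
        else:
            blocks.append(np.zeros(4**k))
    return np.concatenate(blocks)


def brute_force_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """All positive/negative pair comparison with tie credit 1/2."""
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def random_sequence(rng: np.random.Generator, length: int, n_rate: float = 0.0) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    if n_rate > 0:
        mask = rng.random(length) < n_rate
        bases[mask] = "N"
    return "".join(bases)


def toy_dataset(labels, cnrci, genes=None, record_ids=None) -> lb.LabeledDataset:
    """Hand-built labeled dataset (no sequences/features) for split/filter tests."""
    n = len(labels)
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n)]
    ids = list(record_ids) if record_ids is not None else [f"r{i}" for i in range(n)]
    df = pd.DataFrame(
        {"gene": genes, "cnrci": list(cnrci), "label": list(labels)},
        index=pd.Index(ids, name="record_id"),
    )
    return lb.LabeledDataset(df)
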