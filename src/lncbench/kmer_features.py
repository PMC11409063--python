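"""k-mer frequency profiles — the sole predictive features of the benchmark.

A profile concatenates, for k in {3, 4, 5}, the relative frequencies of all
4**k words counted in overlapping windows (step 1), giving a fixed
64 + 256 + 1024 = 1344-dimensional vector. Ordering is k ascending, then
lexicographic with A < C < G < T within each k-block. Frequencies (count
divided by the number of valid windows) rather than raw counts keep the
representation length-independent. Windows containing any non-ACGT symbol are
skipped from both numerator and denominator, so a long transcript with an
isolated N keeps its remaining information. No reverse-complement collapsing:
transcripts are single-stranded RNA in a fixed orientation.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .localization_prep import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_KS", "kmer_profile", "feature_names", "featurize_dataset"]

DEFAULT_KS = (3, 4, 5)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def feature_names(ks: tuple[int, ...] = DEFAULT_KS) -> tuple[str, ...]:
    """Stable column names, e.g. ``k3_AAA`` ... ``k5_TTTTT``."""
    names = []
    for k in sorted(ks):
        for word in itertools.product("ACGT", repeat=k):
            names.append(f"k{k}_{''.join(word)}")
    return tuple(names)


def kmer_profile(sequence: str, ks: tuple[int, ...] = DEFAULT_KS) -> tuple[np.ndarray, bool]:
    """Concatenated per-k frequency blocks and a validity flag.

    Returns ``(profile, ok)``. Each k-block sums to 1 when the sequence has at
    least one all-ACGT window of that width; otherwise the block is all zeros
    and ``ok`` is False (the caller decides whether to drop the record). A
    sequence shorter than max(ks) therefore yields a flagged, partly or fully
    zero profile rather than an exception.
    """
    ks = tuple(sorted(ks))
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    blocks: list[np.ndarray] = []
    ok = True
    for k in ks:
        size = 4 ** k
        if len(codes) < k:
            blocks.append(np.zeros(size))
            ok = False
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows != 255).all(axis=1)
        n_valid = int(valid.sum())
        if n_valid == 0:
            blocks.append(np.zeros(size))
            ok = False
            continue
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        indices = (windows[valid].astype(np.int64) * powers).sum(axis=1)
        counts = np.bincount(indices, minlength=size)
        blocks.append(counts / n_valid)
    return np.concatenate(blocks), ok


def featurize_dataset(
    dataset: LabeledDataset, ks: tuple[int, ...] = DEFAULT_KS
) -> LabeledDataset:
    """Attach a profile per record; records flagged too short are dropped.

    Row order follows the dataset; permuting input records permutes rows but
    not their values.
    """
    if "sequence" not in dataset.df.columns:
        raise ValueError("dataset has no sequence column to featurize")
    profiles = []
    keep = []
    for seq in dataset.df["sequence"]:
        vec, valid = kmer_profile(seq, ks)
        profiles.append(vec)
        keep.append(valid)
    keep = np.array(keep, dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("featurize_dataset: dropped %d records with too-short sequences",
                    n_dropped)
    features = np.vstack([p for p, v in zip(profiles, keep) if v]) if keep.any() else \
        np.empty((0, sum(4 ** k for k in ks)))
    return LabeledDataset(dataset.df[keep], features, feature_names(ks))
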