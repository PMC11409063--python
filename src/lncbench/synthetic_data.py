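"""Synthetic lncRNA localization cohorts with a planted, effect-size-controlled signal.

The generator emulates the structure of quantitative subcellular-localization
data without any download: a gene x cell-line matrix of CNRCI values (base-2
log cytoplasmic-to-nuclear ratios, sparse, with one decorrelated outlier cell
line) and one nucleotide sequence per gene whose k-mer composition carries a
signal monotone in the gene's latent localization.

Generative model
----------------
* Latent localization ``z_g ~ Normal(mu_z, sigma_z)`` per gene, in log2 units.
  The default ``mu_z < 0`` reproduces the nuclear-majority skew of real data.
* Observed CNRCI for a regular cell line: ``z_g + Normal(0, sigma_noise)``.
  The optional outlier line draws ``Normal(mu_z, outlier_scale)`` independent
  of ``z`` — a stand-in for a poorly correlating line that a cell-line screen
  should flag. Each entry is then masked missing with probability ``1 - p_obs``.
* Sequences are assembled from non-overlapping words of length ``k_signal``
  sampled from a multinomial over all ``4**k_signal`` words whose log-weights
  are ``+alpha * z_g`` for the cytoplasmic signal-word set, ``-alpha * z_g``
  for the nuclear set and 0 otherwise (softmax-normalized). Signal strength is
  therefore monotone in ``|z_g|`` and vanishes exactly at ``z_g = 0``, which is
  what makes genes near CNRCI = 0 inherently hard to classify — the property
  that the middle-exclusion factorial exploits.

All randomness flows through one seeded ``numpy`` Generator; identical
config + seed gives a byte-identical cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import CnrciTable

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "draw_cnrci_matrix",
    "draw_sequence",
    "write_fasta",
    "write_cnrci_csv",
    "write_truth_tsv",
]

BASES = "ACGT"
MIN_SEQ_LEN = 200  # lncRNA definition: transcripts longer than 200 nt


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort (defaults = the study conditions).

    Units: ``mu_z``, ``sigma_z``, ``sigma_noise``, ``outlier_scale`` are in
    log2 ratio units; sequence lengths in nucleotides; ``alpha`` is the
    per-log2-unit log-weight enrichment of signal words (dimensionless).
    """

    n_genes: int = 3000
    n_cell_lines: int = 15
    mu_z: float = -0.5
    sigma_z: float = 1.5
    sigma_noise: float = 0.5
    outlier_line: bool = True
    outlier_scale: float = 1.5
    p_obs: float = 0.7
    seq_len_mean: float = 1000.0
    seq_len_sd: float = 250.0
    k_signal: int = 5
    m_signal: int = 8
    alpha: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_cell_lines < 1:
            raise ValueError("n_cell_lines must be >= 1")
        if not (0 < self.p_obs <= 1):
            raise ValueError("p_obs must be in (0, 1]")
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be > 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.k_signal < 1:
            raise ValueError("k_signal must be >= 1")
        if self.m_signal < 0:
            raise ValueError("m_signal must be >= 0")
        if 2 * self.m_signal > 4 ** self.k_signal:
            raise ValueError("m_signal: signal word sets exceed the 4^k_signal vocabulary")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.seq_len_mean < MIN_SEQ_LEN:
            raise ValueError(f"seq_len_mean must be >= {MIN_SEQ_LEN}")
        if self.seq_len_sd < 0:
            raise ValueError("seq_len_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its latent truth."""

    cnrci: CnrciTable
    sequences: Mapping[str, str]
    z: pd.Series
    signal_words_cyt: frozenset[str]
    signal_words_nuc: frozenset[str]
    outlier_line_name: str | None
    config: SyntheticConfig

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)


@lru_cache(maxsize=8)
def _signal_word_indices(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint cytoplasmic / nuclear signal-word index sets, fixed per config.

    Drawn from a stream derived from (seed, k_signal, m_signal) so the word
    identities do not shift when unrelated config fields change.
    """
    rng = np.random.default_rng([config.seed, config.k_signal, config.m_signal, 91])
    perm = rng.permutation(4 ** config.k_signal)
    cyt = np.sort(perm[: config.m_signal])
    nuc = np.sort(perm[config.m_signal: 2 * config.m_signal])
    return cyt, nuc


@lru_cache(maxsize=4)
def _all_words(k: int) -> np.ndarray:
    return np.array(["".join(w) for w in itertools.product(BASES, repeat=k)])


def draw_sequence(z_g: float, config: SyntheticConfig, rng: np.random.Generator) -> str:
    """Sample one sequence whose signal-word enrichment is monotone in z_g.

    The length is Normal(seq_len_mean, seq_len_sd) floored at 200 nt; words of
    length ``k_signal`` are drawn i.i.d. from the softmax-weighted vocabulary
    and concatenated (the last word truncated to hit the drawn length).
    """
    k = config.k_signal
    length = max(MIN_SEQ_LEN, k, int(round(rng.normal(config.seq_len_mean, config.seq_len_sd))))
    cyt_idx, nuc_idx = _signal_word_indices(config)
    logw = np.zeros(4 ** k)
    logw[cyt_idx] += config.alpha * z_g
    logw[nuc_idx] -= config.alpha * z_g
    weights = np.exp(logw - logw.max())
    probs = weights / weights.sum()
    n_words = -(-length // k)  # ceil
    draws = rng.choice(4 ** k, size=n_words, p=probs)
    seq = "".join(_all_words(k)[draws])
    return seq[:length]


def draw_cnrci_matrix(
    z: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> CnrciTable:
    """Latent z plus per-line noise, an optional decorrelated outlier line, masking."""
    if len(z) != config.n_genes:
        raise ValueError("z length must equal n_genes")
    n, m = config.n_genes, config.n_cell_lines
    values = np.asarray(z, dtype=float)[:, None] + rng.normal(0.0, config.sigma_noise, (n, m))
    if config.outlier_line and m >= 1:
        values[:, m - 1] = rng.normal(config.mu_z, config.outlier_scale, n)
    mask = rng.random((n, m)) >= config.p_obs
    values[mask] = np.nan
    genes = _gene_ids(n)
    lines = _line_names(m)
    return CnrciTable(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=lines))


def _gene_ids(n: int) -> list[str]:
    return [f"SYNG{i:06d}" for i in range(n)]


def _line_names(m: int) -> list[str]:
    return [f"line{i + 1:02d}" for i in range(m)]


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort: latent z, CNRCI matrix, and sequences.

    Deterministic given the config (which includes the seed). Raises
    ``ValueError`` naming the offending field for an invalid config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    z = rng.normal(config.mu_z, config.sigma_z, config.n_genes)
    cnrci = draw_cnrci_matrix(z, config, rng)
    genes = _gene_ids(config.n_genes)
    sequences = {g: draw_sequence(z_g, config, rng) for g, z_g in zip(genes, z)}
    cyt_idx, nuc_idx = _signal_word_indices(config)
    words = _all_words(config.k_signal)
    outlier = _line_names(config.n_cell_lines)[-1] if config.outlier_line else None
    return SyntheticCohort(
        cnrci=cnrci,
        sequences=sequences,
        z=pd.Series(z, index=pd.Index(genes, name="gene_id"), name="z"),
        signal_words_cyt=frozenset(words[cyt_idx]),
        signal_words_nuc=frozenset(words[nuc_idx]),
        outlier_line_name=outlier,
        config=config,
    )


# ---------------------------------------------------------------------------
# Writers (formats the data_io readers accept)
# ---------------------------------------------------------------------------

def write_fasta(cohort: SyntheticCohort, path, width: int = 60) -> None:
    """One record per gene, header = gene id, 60-column wrapped."""
    with open(path, "w") as out:
        for gene in cohort.genes:
            seq = cohort.sequences[gene]
            out.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i: i + width] + "\n")


def write_cnrci_csv(cohort: SyntheticCohort, path) -> None:
    """Long-format CSV in the default reader dialect; missing entries as NA rows."""
    df = cohort.cnrci.df
    with open(path, "w") as out:
        out.write("ENSEMBL ID,Data Source,Data Type,Value\n")
        for gene in df.index:
            for line in df.columns:
                v = df.at[gene, line]
                cell = "NA" if pd.isna(v) else repr(float(v))
                out.write(f"{gene},{line},CNRCI,{cell}\n")


def write_truth_tsv(cohort: SyntheticCohort, path) -> None:
    """Latent truth table: gene id and z, plus the config echo in a header comment."""
    with open(path, "w") as out:
        cfg = ";".join(f"{k}={v}" for k, v in asdict(cohort.config).items())
        out.write(f"# config: {cfg}\n")
        out.write("gene_id\tz\n")
        for gene in cohort.genes:
            out.write(f"{gene}\t{cohort.z[gene]!r}\n")
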