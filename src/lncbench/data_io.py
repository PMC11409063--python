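"""Readers and validators for the three input formats of the localization pipeline.

Real data arrives as three files:

* a long-format CSV of per-gene, per-cell-line CNRCI values (the export
  dialect of the lncATLAS database: one row per gene x cell line x data type),
* transcript sequences in FASTA,
* gene annotation in GFF3 whose transcript records may carry the
  ``Ensembl_canonical`` tag marking the representative transcript per gene.

CNRCI is the base-2 log of the cytoplasmic-to-nuclear normalized abundance
ratio: positive values mean cytoplasmic preference, negative nuclear.
Everything here is pure with respect to its inputs, and ids are normalized
(Ensembl-style ``.N`` version suffixes stripped; GENCODE pipe-delimited FASTA
headers split) so that unversioned CNRCI tables join versioned annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping
from urllib.parse import unquote

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CsvDialect",
    "CnrciTable",
    "TranscriptSet",
    "CanonicalSelection",
    "JoinedDataset",
    "strip_version",
    "read_lncatlas_csv",
    "select_canonical_from_gff3",
    "read_fasta",
    "transcript_set_from_canonical",
    "transcript_set_from_gene_fasta",
    "join_gene_sequence",
]


class FormatError(ValueError):
    """An input file violates the expected format or internal consistency."""


_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(identifier: str) -> str:
    """Drop an Ensembl-style numeric version suffix (``ENSG...123.5`` -> ``ENSG...123``)."""
    return _VERSION_RE.sub("", identifier)


# ---------------------------------------------------------------------------
# CNRCI table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsvDialect:
    """Column schema of a long-format CNRCI export.

    Defaults match the public lncATLAS "all data" CSV; every name is
    overrideable because the schema is not standardized.
    """

    gene_col: str = "ENSEMBL ID"
    line_col: str = "Data Source"
    type_col: str = "Data Type"
    value_col: str = "Value"
    cnrci_tag: str = "CNRCI"


@dataclass(frozen=True)
class CnrciTable:
    """Gene x cell-line matrix of CNRCI values; NaN marks a missing entry."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in CNRCI table: {dup!r}")
        if self.df.columns.has_duplicates:
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise FormatError(f"duplicate cell-line name in CNRCI table: {dup!r}")
        values = self.df.to_numpy(dtype=float, na_value=np.nan)
        if np.isinf(values).any():
            raise FormatError("CNRCI table contains non-finite (inf) values")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_observed(self) -> int:
        return int(self.df.notna().to_numpy().sum())

    @property
    def observed_fraction(self) -> float:
        return self.n_observed / float(self.df.size)

    def drop_cell_lines(self, lines: Iterable[str]) -> "CnrciTable":
        lines = [ln for ln in lines if ln in self.df.columns]
        return CnrciTable(self.df.drop(columns=lines))

    def subset_genes(self, genes: Iterable[str]) -> "CnrciTable":
        return CnrciTable(self.df.loc[list(genes)])


def read_lncatlas_csv(path, dialect: CsvDialect = CsvDialect()) -> CnrciTable:
    """Read a long-format CNRCI CSV and pivot it to a gene x cell-line matrix.

    Rows whose data-type column differs from ``dialect.cnrci_tag`` are dropped.
    Unparseable or NA values become missing entries (counted in the log), so a
    sparse export loads without imputation. Duplicate (gene, cell line) rows
    are tolerated only if their values agree.
    """
    raw = pd.read_csv(path, dtype=str)
    required = [dialect.gene_col, dialect.line_col, dialect.type_col, dialect.value_col]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise FormatError(
            f"CNRCI CSV missing required column(s) {missing_cols}; "
            f"found columns {list(raw.columns)}"
        )

    rows = raw[raw[dialect.type_col] == dialect.cnrci_tag].copy()
    n_dropped_type = len(raw) - len(rows)
    values = pd.to_numeric(rows[dialect.value_col], errors="coerce")
    values[np.isinf(values)] = np.nan
    n_unparseable = int(values.isna().sum())
    rows["_value"] = values
    rows["_gene"] = rows[dialect.gene_col].map(strip_version)

    # Conflicting duplicates are data corruption; agreeing ones collapse.
    grouped = rows.groupby(["_gene", dialect.line_col])["_value"]
    spread = grouped.apply(lambda s: s.dropna().nunique())
    conflicts = spread[spread > 1]
    if len(conflicts):
        gene, line = conflicts.index[0]
        raise FormatError(
            f"conflicting CNRCI values for gene {gene!r} in cell line {line!r}"
        )

    # groupby/unstack keeps (gene, line) combinations whose value is missing
    table = grouped.first().unstack(dialect.line_col)
    table.index.name = "gene_id"
    table.columns.name = None
    logger.info(
        "read_lncatlas_csv: %d genes x %d cell lines (%d non-CNRCI rows dropped, "
        "%d missing/unparseable values)",
        table.shape[0], table.shape[1], n_dropped_type, n_unparseable,
    )
    return CnrciTable(table.sort_index())


# ---------------------------------------------------------------------------
# GFF3 canonical-transcript selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalSelection:
    """Canonical transcript per gene, plus the count of genes lacking the tag."""

    mapping: Mapping[str, str]
    n_genes_without_canonical: int


def _parse_gff3_attributes(text: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for part in text.strip().split(";"):
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        attrs[key.strip()] = [unquote(v) for v in value.split(",")]
    return attrs


def select_canonical_from_gff3(gff3_path) -> CanonicalSelection:
    """Scan transcript features for the ``Ensembl_canonical`` tag.

    Returns gene id -> transcript id (version-stripped). Genes whose
    transcripts all lack the tag are omitted and counted; a gene with two
    tagged transcripts is corrupt annotation and raises.
    """
    canonical: dict[str, str] = {}
    genes_seen: set[str] = set()
    with open(gff3_path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = _parse_gff3_attributes(fields[8])
            # transcript-level rows carry transcript_id (GENCODE) or an
            # ID plus a Parent gene (Ensembl); gene/exon rows are skipped
            tx_vals = attrs.get("transcript_id") or (
                attrs.get("ID") if "Parent" in attrs else None
            )
            if not tx_vals:
                continue
            gene_vals = attrs.get("gene_id") or attrs.get("Parent")
            if not gene_vals:
                continue
            gene = strip_version(gene_vals[0].removeprefix("gene:"))
            transcript = strip_version(tx_vals[0].removeprefix("transcript:"))
            if gene == transcript:  # a gene row carrying gene_id only
                continue
            genes_seen.add(gene)
            if "Ensembl_canonical" in attrs.get("tag", []):
                if gene in canonical and canonical[gene] != transcript:
                    raise FormatError(
                        f"gene {gene!r} has two canonical-tagged transcripts "
                        f"({canonical[gene]!r}, {transcript!r})"
                    )
                canonical[gene] = transcript
    n_without = len(genes_seen - set(canonical))
    logger.info(
        "select_canonical_from_gff3: %d canonical transcripts, %d genes without tag",
        len(canonical), n_without,
    )
    return CanonicalSelection(canonical, n_without)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an insertion-ordered ``{id: sequence}`` map.

    Sequences are uppercased with U mapped to T (RNA exports). The record id
    is the first whitespace token of the header; GENCODE-style pipe-delimited
    ids are split with the first field (version-stripped) used as the key.
    """
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        key = strip_version(record.id.split("|")[0])
        if key in records:
            raise FormatError(f"duplicate FASTA record id: {key!r}")
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"FASTA record {key!r} has an empty sequence")
        records[key] = seq
    if not records:
        raise FormatError(f"no FASTA records found in {path!s}")
    return records


@dataclass(frozen=True)
class TranscriptSet:
    """One representative nucleotide sequence per gene.

    ``provenance`` records, per gene, which transcript supplied the sequence
    (or ``"header"`` when the FASTA was already keyed by gene id).
    """

    sequences: Mapping[str, str]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for gene {gene!r}")


def transcript_set_from_canonical(
    fasta: Mapping[str, str], selection: CanonicalSelection
) -> TranscriptSet:
    """Join FASTA records (keyed by transcript id) to canonical picks per gene."""
    sequences: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for gene, transcript in selection.mapping.items():
        seq = fasta.get(transcript)
        if seq is None:
            continue
        sequences[gene] = seq
        provenance[gene] = transcript
    n_missing = len(selection.mapping) - len(sequences)
    if n_missing:
        logger.info(
            "transcript_set_from_canonical: %d canonical transcripts absent from FASTA",
            n_missing,
        )
    return TranscriptSet(sequences, provenance)


def transcript_set_from_gene_fasta(fasta: Mapping[str, str]) -> TranscriptSet:
    """Treat FASTA ids directly as gene ids (the synthetic writer's layout)."""
    return TranscriptSet(dict(fasta), {g: "header" for g in fasta})


# ---------------------------------------------------------------------------
# Join
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JoinedDataset:
    """Inner join of a CNRCI table with per-gene sequences, sorted by gene id."""

    cnrci: CnrciTable
    sequences: Mapping[str, str]
    n_dropped_table_only: int
    n_dropped_seq_only: int

    @property
    def genes(self) -> list[str]:
        return self.cnrci.genes


def join_gene_sequence(table: CnrciTable, seqs: TranscriptSet) -> JoinedDataset:
    """Inner-join CNRCI rows with sequences on gene id (deterministic order)."""
    table_genes = set(table.genes)
    seq_genes = set(seqs.sequences)
    shared = sorted(table_genes & seq_genes)
    if not shared:
        raise FormatError(
            "no genes shared between CNRCI table and sequences; "
            "check id normalization (version suffixes, FASTA header dialect)"
        )
    n_table_only = len(table_genes - seq_genes)
    n_seq_only = len(seq_genes - table_genes)
    logger.info(
        "join_gene_sequence: %d genes joined (%d table-only, %d sequence-only dropped)",
        len(shared), n_table_only, n_seq_only,
    )
    return JoinedDataset(
        cnrci=table.subset_genes(shared),
        sequences={g: seqs.sequences[g] for g in shared},
        n_dropped_table_only=n_table_only,
        n_dropped_seq_only=n_seq_only,
    )
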