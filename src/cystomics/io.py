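"""Readers and writers for every on-disk artifact of the pipeline.

All tables are plain TSV with a header row. Protein coordinates are 1-based
inclusive everywhere in the package and on disk. Missing abundances are
written as the empty string and accepted as "", "NA" or "NaN" on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Symbol used in flank windows where the window runs past a protein end.
GAP = "-"

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class FormatError(ValueError):
    """Raised when an input file violates the documented schema."""


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FormatError(f"sequence for {name!r} is empty")
    for i, ch in enumerate(seq):
        if ch not in _CANONICAL_SET:
            raise FormatError(
                f"non-canonical residue {ch!r} at position {i + 1} of {name!r}; "
                f"only the 20 canonical letters are accepted"
            )
    return seq


@dataclass
class ProteinDB:
    """Ordered accession -> amino-acid sequence store.

    Sequences are uppercase strings over the 20 canonical letters; ambiguous
    codes (B/J/O/U/X/Z) are rejected at construction time.
    """

    records: dict[str, str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, seq in self.records.items():
            self.records[acc] = _check_sequence(seq, acc)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __getitem__(self, accession: str) -> str:
        return self.records[accession]

    def items(self):
        return self.records.items()

    @property
    def accessions(self) -> list[str]:
        return list(self.records)


@dataclass
class PeptideRecord:
    """An identified peptide with its located protein matches.

    ``matches`` holds ``(accession, start, end)`` triples with 1-based
    inclusive coordinates, so ``protein[start-1:end] == sequence``.
    """

    peptide_id: str
    sequence: str
    matches: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _check_sequence(self.sequence, self.peptide_id)

    def validate_against(self, db: ProteinDB) -> None:
        """Check every match against the protein database; raise on mismatch."""
        for acc, start, end in self.matches:
            if acc not in db:
                raise FormatError(f"{self.peptide_id}: unknown accession {acc!r}")
            prot = db[acc]
            if not (1 <= start <= end <= len(prot)):
                raise FormatError(
                    f"{self.peptide_id}: coordinates {start}-{end} out of range "
                    f"for {acc!r} (length {len(prot)})"
                )
            if prot[start - 1 : end] != self.sequence:
                raise FormatError(
                    f"{self.peptide_id}: sequence does not match {acc!r}[{start}-{end}]"
                )


@dataclass
class QuantMatrix:
    """Feature x sample abundance matrix, the central currency of the pipeline.

    ``data`` is a DataFrame indexed by feature_id with one column per sample;
    missing measurements are NaN. ``scale`` records whether values are raw
    intensities ("linear", non-negative) or log2 intensities ("log2").
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        self.data = self.data.astype(float)
        if self.scale == "linear" and (self.data.to_numpy() < 0).any():
            raise FormatError("negative values are not allowed on the linear scale")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), self.scale)

    def to_samples_by_features(self) -> pd.DataFrame:
        """Samples x features view (the scikit-learn orientation)."""
        return self.data.T


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ProteinDB:
    """Read a protein FASTA file.

    The accession is the first whitespace-delimited token of the header; the
    full header is retained as the record description.
    """
    records: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in records:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        records[acc] = str(rec.seq)
        descriptions[acc] = rec.description
    return ProteinDB(records, descriptions)


def write_fasta(db: ProteinDB, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in db.items():
            desc = db.descriptions.get(acc, acc)
            fh.write(f">{desc}\n" if desc.startswith(acc) else f">{acc} {desc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Generic TSV
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with missing values as empty cells.
    Floats use the shortest round-trip representation, so reading the file
    back reproduces the values exactly."""
    table.to_csv(path, sep="\t", index=index, na_rep="")


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col=index_col, na_values=sorted(_MISSING_TOKENS),
        keep_default_na=False, float_precision="round_trip",
    )


# ---------------------------------------------------------------------------
# Quantitative matrix
# ---------------------------------------------------------------------------

def read_quant_table(path: str | Path, scale: str = "linear") -> QuantMatrix:
    """Read a quant.tsv (feature_id + one column per sample)."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=sorted(_MISSING_TOKENS),
        keep_default_na=False, float_precision="round_trip",
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value in {path}: {exc}") from exc
    return QuantMatrix(df, scale=scale)


def write_quant_table(m: QuantMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "feature_id"
    write_table(df, path, index=True)


# ---------------------------------------------------------------------------
# Peptide table
# ---------------------------------------------------------------------------

def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read peptides.tsv (peptide_id, sequence, accession, start, end; one row
    per match, 1-based inclusive coordinates)."""
    df = read_table(path)
    required = {"peptide_id", "sequence", "accession", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"peptides table missing columns {required - set(df.columns)}")
    records: dict[str, PeptideRecord] = {}
    for row in df.itertuples(index=False):
        rec = records.get(row.peptide_id)
        if rec is None:
            rec = PeptideRecord(row.peptide_id, row.sequence, [])
            records[row.peptide_id] = rec
        elif rec.sequence != row.sequence.upper():
            raise FormatError(
                f"peptide {row.peptide_id!r} has inconsistent sequences"
            )
        if not (isinstance(row.accession, str) and row.accession):
            continue  # unmapped peptide: row with empty match columns
        rec.matches.append((row.accession, int(row.start), int(row.end)))
    return list(records.values())


def write_peptide_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if rec.matches:
            for acc, start, end in rec.matches:
                rows.append((rec.peptide_id, rec.sequence, acc, start, end))
        else:
            rows.append((rec.peptide_id, rec.sequence, "", np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["peptide_id", "sequence", "accession", "start", "end"])
    write_table(df, path)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

DEFAULT_GROUPS = ("CA", "SCN", "MCN", "IPMN", "PC", "UNC")


def read_sample_table(
    path: str | Path, allowed_groups: Iterable[str] | None = DEFAULT_GROUPS
) -> pd.DataFrame:
    """Read samples.tsv (sample_id, group, cea_ng_ml, amylase_iu_l) indexed by
    sample_id."""
    df = read_table(path, index_col=0)
    if "group" not in df.columns:
        raise FormatError("samples table needs a 'group' column")
    if df.index.has_duplicates:
        raise FormatError("duplicate sample ids in samples table")
    if allowed_groups is not None:
        bad = set(df["group"]) - set(allowed_groups)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    df = samples.copy()
    df.index.name = "sample_id"
    write_table(df, path, index=True)


def check_samples_match(m: QuantMatrix, samples: pd.DataFrame) -> None:
    missing = set(m.sample_ids) - set(samples.index)
    if missing:
        raise FormatError(f"samples table lacks metadata for: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Annotations (feature -> term), config
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read annotations.tsv (feature_id, term) into feature -> set of terms."""
    df = read_table(path)
    if not {"feature_id", "term"}.issubset(df.columns):
        raise FormatError("annotations table needs columns feature_id, term")
    ann: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        ann.setdefault(str(row.feature_id), set()).add(str(row.term))
    return ann


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
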