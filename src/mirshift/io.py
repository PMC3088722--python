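"""Strict readers and writers for the plain-text formats the pipeline touches.

All parsers validate eagerly and raise :class:`FormatError` with a file/line
location rather than silently coercing malformed input.  Sequences are held
internally in the DNA alphabet (U is normalised to T on input) for 3'UTRs and
in the RNA alphabet for mature miRNAs, both uppercase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "UTRRecord",
    "MiRNARecord",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_utr_fasta",
    "write_utr_fasta",
    "read_mirna_table",
    "read_expression_tsv",
    "read_conservation_tsv",
    "read_gmt",
    "write_tsv",
]

_DNA = frozenset("ACGT")
_RNA = frozenset("ACGU")
#: characters accepted in a raw UTR FASTA body (before normalisation)
_UTR_OK = frozenset("ACGTUacgtu")


class FormatError(ValueError):
    """Malformed input file; the message carries the path and line number."""


@dataclass(frozen=True)
class UTRRecord:
    """One mRNA-sense 3'UTR, read 5'->3', DNA alphabet."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id!r}")
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"{self.gene_id!r}: non-DNA characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA 5'->3' (RNA alphabet) with its extracted seed.

    The seed is the hexamer at positions 2-7 (1-based, inclusive); the seed
    itself is the family key, so all miRNAs sharing one hexamer form one
    seed family.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.name!r}: sequence shorter than 8 nt "
                f"({len(self.sequence)} nt)"
            )
        if not set(self.sequence) <= _RNA:
            bad = sorted(set(self.sequence) - _RNA)
            raise ValueError(f"miRNA {self.name!r}: non-RNA characters {bad}")

    @property
    def seed(self) -> str:
        """Hexamer at miRNA positions 2-7 (1-based)."""
        return self.sequence[1:7]

    @property
    def family_key(self) -> str:
        return self.seed

    @property
    def position8(self) -> str:
        """Nucleotide at miRNA position 8 (always present: length >= 8)."""
        return self.sequence[7]


@dataclass
class ExpressionMatrix:
    """Gene x sample linear-scale intensities plus a sample->condition design.

    Values are strictly positive (readers floor at 1.0 before construction so
    logs are always finite).
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"design does not cover samples: {missing}")
        absent = [s for s in self.condition_of if s not in self.values.columns]
        if absent:
            raise ValueError(f"design samples missing from table: {absent}")
        if not (self.values.to_numpy() > 0).all():
            raise ValueError("expression values must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.condition_of[s] == condition]
        if not out:
            raise ValueError(f"condition {condition!r} has no samples")
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. from a GMT file) with free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


# ---------------------------------------------------------------------------
# FASTA


def _iter_fasta(path: str | Path):
    """Yield (header, sequence, header_lineno); strict about structure."""
    path = Path(path)
    header: str | None = None
    header_line = 0
    parts: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(parts), header_line
                header = line[1:].strip()
                header_line = lineno
                parts = []
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                parts.append(line)
    if header is not None:
        yield header, "".join(parts), header_line


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """Read a 3'UTR FASTA into :class:`UTRRecord` objects, input order kept.

    The gene id is the header token before the first whitespace.  U/u is
    normalised to T and lowercase is uppercased; any other character is a
    hard error.  Duplicate gene ids and empty sequences are hard errors.
    """
    path = Path(path)
    records: list[UTRRecord] = []
    seen: set[str] = set()
    for header, seq, lineno in _iter_fasta(path):
        gene_id = header.split()[0]
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        if not seq:
            raise FormatError(f"{path}:{lineno}: empty sequence for {gene_id!r}")
        bad = set(seq) - _UTR_OK
        if bad:
            raise FormatError(
                f"{path}:{lineno}: {gene_id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        records.append(UTRRecord(gene_id, seq.upper().replace("U", "T")))
    return records


def write_utr_fasta(records: Iterable[UTRRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_mirna_table(path: str | Path) -> list[MiRNARecord]:
    """Read mature miRNAs from FASTA or a 2-column TSV (name, sequence).

    Sequences are normalised to uppercase RNA (T -> U); sequences shorter
    than 8 nt and duplicate names are hard errors.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    entries: list[tuple[str, str, int]] = []
    if first.startswith(">"):
        for header, seq, lineno in _iter_fasta(path):
            entries.append((header.split()[0], seq, lineno))
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = [f.strip() for f in line.replace(",", "\t").split("\t") if f.strip()]
                if len(fields) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 fields (name, sequence), "
                        f"got {len(fields)}"
                    )
                entries.append((fields[0], fields[1], lineno))
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    for name, seq, lineno in entries:
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate miRNA name {name!r}")
        seen.add(name)
        try:
            records.append(MiRNARecord(name, seq.upper().replace("T", "U")))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# TSV


def read_expression_tsv(
    path: str | Path, design: Mapping[str, str], floor: float = 1.0
) -> ExpressionMatrix:
    """Read a genes x samples TSV of linear-scale intensities.

    First column holds gene ids, header row holds sample ids.  Values below
    ``floor`` (default 1.0) are floored so every log is finite.  The design
    must cover every sample column and name no absent samples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    values = numeric.astype(float).clip(lower=floor)
    return ExpressionMatrix(values, dict(design))


def read_conservation_tsv(path: str | Path) -> pd.Series:
    """Read per-gene conservation scores (columns: gene_id, score)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns gene_id, score")
    ser = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="score",
    )
    if ser.isna().any():
        bad = ser.index[ser.isna()][0]
        raise FormatError(f"{path}: non-numeric score for gene {bad!r}")
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return ser


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then member gene ids."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with '#'-prefixed header lines carrying run provenance."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
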