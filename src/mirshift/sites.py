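"""Seed extraction, canonical site patterns, UTR scanning, target annotation.

Canonical site types on the mRNA, in decreasing hierarchy of efficacy:

* ``8mer``     reverse complement of miRNA positions 2-8, followed by an A
  (opposite miRNA position 1);
* ``7mer-m8``  reverse complement of miRNA positions 2-8;
* ``7mer-A1``  reverse complement of positions 2-7 followed by an A
  (the "T1A" convention);
* ``6mer``     reverse complement of positions 2-7 only.

Scanning walks a UTR left to right; wherever any pattern matches, exactly one
site of the highest-priority matching type is emitted and the scan resumes at
the nucleotide after that site's 6-nt seed core, so one core is never counted
as two sites (an 8mer is not additionally a 7mer and a 6mer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import MiRNARecord, UTRRecord

__all__ = [
    "SITE_TYPES",
    "SitePattern",
    "SeedSite",
    "FamilyRule",
    "extract_seed",
    "reverse_complement",
    "compile_patterns",
    "scan_utr",
    "scan_collection",
    "build_target_annotations",
    "select_conserved",
]

#: site types in priority order (best first)
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    return dna.translate(_RC)[::-1]


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SitePattern:
    """One canonical site type with the exact DNA string the mRNA must contain."""

    site_type: str
    match_string: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")

    @property
    def length(self) -> int:
        return len(self.match_string)

    @property
    def core_offset(self) -> int:
        """Start of the 6-nt seed core within the match string."""
        return 1 if self.site_type in ("8mer", "7mer-m8") else 0


@dataclass(frozen=True, order=True)
class SeedSite:
    """One predicted site: 0-based half-open interval on the UTR."""

    gene_id: str
    start: int
    end: int
    site_type: str
    family_key: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class FamilyRule:
    """Inclusion/exclusion rule for one miRNA member or seed family.

    ``family_key`` is matched against both miRNA names and seed hexamers.
    ``mode`` is ``include`` (default behaviour), ``exclude_family`` (drop the
    member's sites entirely) or ``exclude_site_types`` (drop only the named
    site types for that member).
    """

    family_key: str
    mode: str = "include"
    excluded_types: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mode not in ("include", "exclude_family", "exclude_site_types"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if (self.mode == "exclude_site_types") != bool(self.excluded_types):
            raise ValueError("excluded_types must be non-empty iff mode is "
                             "exclude_site_types")
        bad = set(self.excluded_types) - set(SITE_TYPES)
        if bad:
            raise ValueError(f"unknown site types {sorted(bad)}")


def extract_seed(mirna_sequence: str) -> str:
    """Hexamer at miRNA positions 2-7 (1-based, inclusive), RNA alphabet."""
    seq = mirna_sequence.strip().upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(f"miRNA sequence too short ({len(seq)} nt, need >= 8)")
    return seq[1:7]


def compile_patterns(seed: str, position8: str | None = None) -> tuple[SitePattern, ...]:
    """Build the canonical site patterns for one seed, in priority order.

    With ``position8`` (the miRNA's position-8 nucleotide) all four types are
    produced; without it only the 7mer-A1 and 6mer (the m8-extended types need
    position 8).
    """
    seed_dna = _to_dna(seed)
    if len(seed_dna) != 6 or not set(seed_dna) <= set("ACGT"):
        raise ValueError(f"invalid seed {seed!r}")
    core = reverse_complement(seed_dna)
    patterns: list[SitePattern] = []
    if position8:
        p8 = _to_dna(position8)
        if len(p8) != 1 or p8 not in "ACGT":
            raise ValueError(f"invalid position-8 nucleotide {position8!r}")
        m8 = reverse_complement(seed_dna + p8)
        patterns.append(SitePattern("8mer", m8 + "A"))
        patterns.append(SitePattern("7mer-m8", m8))
    patterns.append(SitePattern("7mer-A1", core + "A"))
    patterns.append(SitePattern("6mer", core))
    return tuple(patterns)


def scan_utr(
    utr: UTRRecord,
    patterns: Sequence[SitePattern],
    family_key: str = "",
) -> list[SeedSite]:
    """Scan one UTR with the patterns of one seed family.

    At each offset where any pattern matches, exactly one site of the
    highest-priority matching type is emitted; scanning resumes at the
    nucleotide after that site's 6-nt seed core.  Sites come back sorted by
    start.  Patterns containing only {A,C,G,T} never match an ambiguous base.
    """
    seq = utr.sequence
    ordered = sorted(patterns, key=lambda p: SITE_TYPES.index(p.site_type))
    # offset -> best-priority pattern matching there
    best: dict[int, SitePattern] = {}
    for pat in ordered:
        pos = seq.find(pat.match_string)
        while pos != -1:
            best.setdefault(pos, pat)
            pos = seq.find(pat.match_string, pos + 1)
    sites: list[SeedSite] = []
    resume = 0
    for off in sorted(best):
        if off < resume:
            continue
        pat = best[off]
        sites.append(SeedSite(utr.gene_id, off, off + pat.length, pat.site_type,
                              family_key))
        resume = off + pat.core_offset + 6  # nucleotide after the seed core
    return sites


def _rule_for(mirna: MiRNARecord, rules: Sequence[FamilyRule]) -> FamilyRule | None:
    for rule in rules:
        if rule.family_key in (mirna.name, mirna.family_key):
            return rule
    return None


def scan_collection(
    utrs: Iterable[UTRRecord],
    mirnas: Sequence[MiRNARecord],
    rules: Sequence[FamilyRule] = (),
) -> pd.DataFrame:
    """Scan every UTR with every miRNA member, applying family rules.

    Sites are classified with the member's full pattern set first; under an
    ``exclude_site_types`` rule sites of the excluded types are then dropped
    (not reclassified to a lower type).  Returns a tidy frame with columns
    gene_id, start, end, site_type, family, member.
    """
    names = {m.name for m in mirnas} | {m.family_key for m in mirnas}
    for rule in rules:
        if rule.family_key not in names:
            warnings.warn(
                f"rule for {rule.family_key!r} matches no miRNA; ignored",
                stacklevel=2,
            )
    rows: list[tuple] = []
    utrs = list(utrs)
    for mirna in mirnas:
        rule = _rule_for(mirna, rules)
        if rule is not None and rule.mode == "exclude_family":
            continue
        patterns = compile_patterns(mirna.seed, mirna.position8)
        dropped = rule.excluded_types if rule is not None else frozenset()
        for utr in utrs:
            for site in scan_utr(utr, patterns, mirna.family_key):
                if site.site_type in dropped:
                    continue
                rows.append((site.gene_id, site.start, site.end, site.site_type,
                             site.family_key, mirna.name))
    df = pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "site_type", "family", "member"]
    )
    return df.sort_values(["gene_id", "start", "member"], kind="mergesort").reset_index(
        drop=True
    )


def build_target_annotations(
    utrs: Iterable[UTRRecord],
    mirnas: Sequence[MiRNARecord],
    rules: Sequence[FamilyRule] = (),
    conservation: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene site counts and target calls over the union of family members.

    Sites identical in (gene, interval, type) contributed by several members
    are counted once.  Returns a frame indexed by gene_id with one count
    column per site type, ``n_sites``, ``is_target`` and (if supplied)
    ``conservation_score``.
    """
    utrs = list(utrs)
    sites = scan_collection(utrs, mirnas, rules)
    unique = sites.drop_duplicates(["gene_id", "start", "end", "site_type"])
    genes = pd.Index([u.gene_id for u in utrs], name="gene_id")
    counts = (
        unique.pivot_table(index="gene_id", columns="site_type", values="start",
                           aggfunc="count", fill_value=0)
        .reindex(genes, fill_value=0)
        .reindex(columns=list(SITE_TYPES), fill_value=0)
        .astype(int)
    )
    counts.columns = [f"n_{t}" for t in counts.columns]
    counts["n_sites"] = counts.sum(axis=1)
    counts["is_target"] = counts["n_sites"] > 0
    if conservation is not None:
        ser = pd.Series(conservation, dtype=float)
        counts["conservation_score"] = ser.reindex(genes).to_numpy()
    else:
        counts["conservation_score"] = float("nan")
    return counts


def select_conserved(annotations: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """Top-``fraction`` of scored targets by conservation score.

    Returns the ceil(fraction * n_scored_targets) targets with the highest
    score; ties at the cutoff are broken by lexicographic gene id so the set
    is deterministic.  Unscored targets never enter.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    scored = annotations[annotations["is_target"]
                         & annotations["conservation_score"].notna()]
    if scored.empty:
        raise ValueError("no target has a conservation score")
    k = math.ceil(fraction * len(scored))
    order = scored.sort_values(
        ["conservation_score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return set(order.index[:k])
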