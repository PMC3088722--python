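"""Covariate-matched control gene selection with balance diagnostics.

Controls are non-target genes chosen to resemble the target set in expression
level (log2 mean WT intensity), 3'UTR length (log10) and dinucleotide
composition (16 overlapping-dinucleotide frequencies), so that a shift in the
targets' LFC distribution can be attributed to the seed sites rather than to
these covariates.  Matching is greedy nearest-neighbour without replacement on
z-scored covariates, with the 16 composition dimensions down-weighted by
1/sqrt(16) so the three covariate blocks contribute equally to squared
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import UTRRecord

__all__ = [
    "DINUCLEOTIDES",
    "CovariateTable",
    "ControlMatchSet",
    "build_covariates",
    "match_controls",
    "balance_report",
]

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

#: a CovariateTable is a DataFrame indexed by gene_id with these columns
CovariateTable = pd.DataFrame
COVARIATE_COLUMNS = ("expr_log2", "log10_utr_length") + tuple(
    f"dinuc_{d}" for d in DINUCLEOTIDES
)


def _dinucleotide_frequencies(sequence: str) -> np.ndarray:
    """Overlapping dinucleotide counts over (length - 1), as 16 frequencies."""
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    pairs = codes[:-1] * 4 + codes[1:]
    return np.bincount(pairs, minlength=16) / (len(sequence) - 1)


def build_covariates(utrs: Iterable[UTRRecord], gene_stats: pd.DataFrame) -> CovariateTable:
    """Covariates for every gene having both a UTR and an expression record.

    UTRs shorter than 2 nt cannot yield dinucleotide frequencies and are
    dropped with a warning.
    """
    utrs = list(utrs)
    short = [u.gene_id for u in utrs if u.length < 2]
    if short:
        warnings.warn(f"dropping {len(short)} UTRs shorter than 2 nt", stacklevel=2)
    usable = [u for u in utrs if u.length >= 2]
    genes = [u.gene_id for u in usable if u.gene_id in gene_stats.index]
    if not genes:
        raise ValueError("no gene has both a UTR and an expression record")
    by_id = {u.gene_id: u for u in usable}
    dinuc = np.vstack([_dinucleotide_frequencies(by_id[g].sequence) for g in genes])
    table = pd.DataFrame(dinuc, index=pd.Index(genes, name="gene_id"),
                         columns=[f"dinuc_{d}" for d in DINUCLEOTIDES])
    table.insert(0, "log10_utr_length", [np.log10(by_id[g].length) for g in genes])
    table.insert(0, "expr_log2", gene_stats.loc[genes, "mean_log2_wt"].to_numpy())
    return table[list(COVARIATE_COLUMNS)]


@dataclass
class ControlMatchSet:
    """Target-to-control pairing; ``pairs`` has columns target, control, distance."""

    pairs: pd.DataFrame
    unmatched: list[str] = field(default_factory=list)

    @property
    def control_genes(self) -> list[str]:
        return list(self.pairs["control"])

    @property
    def target_genes(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["target"]))


def match_controls(
    targets: Iterable[str],
    covariates: CovariateTable,
    rng_seed: int = 0,
    pool: Sequence[str] | None = None,
    n_controls: int = 1,
) -> ControlMatchSet:
    """Greedy nearest-neighbour control matching without replacement.

    Every covariate is z-scored over pool plus targets; composition columns
    are down-weighted by 1/sqrt(16).  Targets are visited in an order shuffled
    by ``rng_seed`` (fixed seed gives an identical pairing); each takes its
    ``n_controls`` nearest still-available pool genes.  Targets absent from
    the covariate table are reported in ``unmatched``, never silently dropped.
    """
    targets = list(dict.fromkeys(targets))
    target_set = set(targets)
    in_table = [t for t in targets if t in covariates.index]
    unmatched = [t for t in targets if t not in covariates.index]
    if pool is None:
        pool_ids = [g for g in covariates.index if g not in target_set]
    else:
        pool_ids = [g for g in dict.fromkeys(pool)
                    if g in covariates.index and g not in target_set]
    need = n_controls * len(in_table)
    if len(pool_ids) < need:
        raise ValueError(
            f"control pool too small: {len(pool_ids)} available, "
            f"{need} needed ({need - len(pool_ids)} short)"
        )

    both = covariates.loc[in_table + pool_ids]
    mu = both.mean(axis=0)
    sd = both.std(axis=0, ddof=0).replace(0.0, 1.0)  # constant column: no signal
    z = (both - mu) / sd
    weights = np.where(
        [c.startswith("dinuc_") for c in both.columns], 1.0 / np.sqrt(16.0), 1.0
    )
    zt = z.loc[in_table].to_numpy() * weights
    zp = z.loc[pool_ids].to_numpy() * weights
    dist = cdist(zt, zp, metric="euclidean")

    order = np.random.default_rng(rng_seed).permutation(len(in_table))
    available = np.ones(len(pool_ids), dtype=bool)
    rows: list[tuple[str, str, float]] = []
    for i in order:
        for _ in range(n_controls):
            masked = np.where(available, dist[i], np.inf)
            j = int(np.argmin(masked))
            available[j] = False
            rows.append((in_table[i], pool_ids[j], float(dist[i, j])))
    pairs = pd.DataFrame(rows, columns=["target", "control", "distance"])
    pairs = pairs.sort_values(["target", "control"], kind="mergesort").reset_index(drop=True)
    return ControlMatchSet(pairs, unmatched)


def balance_report(match_set: ControlMatchSet, covariates: CovariateTable) -> pd.Series:
    """Standardized mean difference per covariate between targets and controls.

    SMD = (mean_target - mean_control) / pooled SD with the pooled SD the
    root mean of the two group variances; a covariate constant in both groups
    gets SMD 0.
    """
    if len(match_set.pairs) < 2:
        raise ValueError("balance report needs at least 2 matched pairs")
    t = covariates.loc[match_set.target_genes]
    c = covariates.loc[match_set.control_genes]
    diff = t.mean(axis=0) - c.mean(axis=0)
    pooled = np.sqrt((t.var(axis=0, ddof=1) + c.var(axis=0, ddof=1)) / 2.0)
    smd = diff / pooled
    smd[(pooled == 0) & (diff == 0)] = 0.0
    smd.name = "smd"
    return smd
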