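"""Candidate calling across two knockout datasets, overlap and enrichment.

A candidate is a gene that (i) is a predicted seed-family target, (ii) shows
at least a ``fold``-times upregulation on knockout in dataset 1, (iii) the
same in dataset 2, and (iv) is expressed (above the wild-type intensity floor
in both datasets).  Overlap between the two datasets' upregulated sets is
summarised with a two-sided Fisher exact test, and the candidate list can be
tested for over-representation in user-supplied gene sets with a
hypergeometric upper-tail test plus Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection

__all__ = ["OverlapResult", "call_candidates", "overlap_stats", "set_enrichment"]


def call_candidates(
    annotations: pd.DataFrame,
    stats_1: pd.DataFrame,
    stats_2: pd.DataFrame,
    fold: float = 1.2,
) -> pd.DataFrame:
    """Flag candidates over the shared gene universe of all three inputs.

    Returns a frame indexed by gene_id (sorted) with the per-dataset LFCs,
    the four flags and ``is_candidate`` (their conjunction), site counts and
    conservation score carried through from the annotations.
    """
    if not fold > 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    universe = annotations.index.intersection(stats_1.index).intersection(stats_2.index)
    if universe.empty:
        raise ValueError("no gene shared between annotations and both datasets")
    universe = universe.sort_values()
    threshold = -math.log2(fold)
    out = pd.DataFrame(index=universe)
    out.index.name = "gene_id"
    out["is_predicted_target"] = annotations.loc[universe, "is_target"].to_numpy()
    out["lfc_1"] = stats_1.loc[universe, "lfc_wt_ko"].to_numpy()
    out["lfc_2"] = stats_2.loc[universe, "lfc_wt_ko"].to_numpy()
    out["up_in_dataset1"] = out["lfc_1"] <= threshold
    out["up_in_dataset2"] = out["lfc_2"] <= threshold
    out["expressed"] = (
        stats_1.loc[universe, "expressed"].to_numpy()
        & stats_2.loc[universe, "expressed"].to_numpy()
    )
    out["is_candidate"] = (
        out["is_predicted_target"]
        & out["up_in_dataset1"]
        & out["up_in_dataset2"]
        & out["expressed"]
    )
    for col in annotations.columns:
        if col.startswith("n_") or col == "conservation_score":
            out[col] = annotations.loc[universe, col].to_numpy()
    return out


@dataclass
class OverlapResult:
    """2x2 overlap of two gene sets within a universe, with Fisher exact p.

    The shared fractions are reported relative to each set (the overlap of a
    with b as a fraction of a, and vice versa).  The odds ratio is the sample
    odds ratio, with a Haldane half-count added to every cell when any cell
    is zero.
    """

    n_both: int
    n_only_a: int
    n_only_b: int
    n_neither: int
    shared_fraction_of_a: float
    shared_fraction_of_b: float
    odds_ratio: float
    fisher_p: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.n_both, self.n_only_a], [self.n_only_b, self.n_neither]]


def overlap_stats(set_a: Set[str], set_b: Set[str], universe: Iterable[str]) -> OverlapResult:
    """Overlap of two sets within ``universe`` plus a two-sided Fisher test.

    The two-sided p-value sums hypergeometric probabilities of all tables (at
    the observed margins) no more probable than the observed one.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a) & uni
    b = set(set_b) & uni
    if set(set_a) - uni or set(set_b) - uni:
        raise ValueError("sets must be subsets of the universe")
    n_both = len(a & b)
    n_only_a = len(a - b)
    n_only_b = len(b - a)
    n_neither = len(uni) - n_both - n_only_a - n_only_b
    table = np.array([[n_both, n_only_a], [n_only_b, n_neither]])
    _, p = sps.fisher_exact(table, alternative="two-sided")
    cells = table.astype(float)
    if (cells == 0).any():
        cells = cells + 0.5  # Haldane correction
    odds = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    return OverlapResult(
        n_both=n_both,
        n_only_a=n_only_a,
        n_only_b=n_only_b,
        n_neither=n_neither,
        shared_fraction_of_a=n_both / len(a) if a else float("nan"),
        shared_fraction_of_b=n_both / len(b) if b else float("nan"),
        odds_ratio=float(odds),
        fisher_p=float(p),
    )


def set_enrichment(
    candidates: Set[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``candidates`` in each gene set.

    Each set is intersected with the universe before testing; sets with no
    overlap with the universe are skipped with a warning.  The upper-tail
    p-value is P(X >= k) for k candidate members out of K set members in a
    universe of N with n candidates; q-values are Benjamini-Hochberg across
    the tested sets.  Rows come back sorted by p then set name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    cand = set(candidates) & uni
    if set(candidates) - uni:
        raise ValueError("candidates must be a subset of the universe")
    n_universe = len(uni)
    n_cand = len(cand)
    rows = []
    for name in sorted(gene_sets.sets):
        members = gene_sets.sets[name] & uni
        if not members:
            warnings.warn(f"gene set {name!r} has no overlap with the universe; "
                          "skipped", stacklevel=2)
            continue
        k = len(members & cand)
        big_k = len(members)
        p = float(sps.hypergeom.sf(k - 1, n_universe, big_k, n_cand))
        rows.append(
            {
                "set_name": name,
                "k_overlap": k,
                "n_candidates": n_cand,
                "K_set_in_universe": big_k,
                "N_universe": n_universe,
                "p_hypergeom": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_bh"] = sps.false_discovery_control(df["p_hypergeom"], method="bh")
    return df.sort_values(["p_hypergeom", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
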