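"""Spot condensation, expressed-gene floor, and per-gene log2 fold changes.

Sign convention used everywhere downstream: ``lfc_wt_ko`` is the mean log2
expression in wild type minus the mean log2 expression in knockout, so a
target derepressed on miRNA loss has a *negative* LFC.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["condense_spots", "compute_gene_stats", "upregulated_in_ko"]


def condense_spots(raw: ExpressionMatrix, spot_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Condense spot-level rows to gene-level rows by geometric means.

    Every spot id must map to exactly one gene; an unmapped spot is a hard
    error.  Equivalent to averaging log intensities per gene, so downstream
    mean-log statistics are unaffected by spot multiplicity.
    """
    unmapped = [s for s in raw.values.index if s not in spot_to_gene]
    if unmapped:
        raise KeyError(f"spots not mapped to any gene: {unmapped[:5]}")
    genes = pd.Index([spot_to_gene[s] for s in raw.values.index], name="gene_id")
    log2 = np.log2(raw.values)
    condensed = np.exp2(log2.groupby(genes, sort=True).mean())
    return ExpressionMatrix(condensed, dict(raw.condition_of))


def compute_gene_stats(
    expr: ExpressionMatrix,
    wt_label: str = "WT",
    ko_label: str = "KO",
    floor: float = 16.0,
) -> pd.DataFrame:
    """Per-gene condition means of log2 intensity, LFC, and expressed flag.

    ``expressed`` compares the arithmetic mean of the *linear* WT intensities
    against ``floor`` (the floor is stated on the linear scale, on the
    wild-type arrays).  Returns a frame indexed by gene_id with columns
    mean_log2_wt, mean_log2_ko, lfc_wt_ko, mean_linear_wt, expressed.
    """
    wt = expr.samples(wt_label)
    ko = expr.samples(ko_label)
    log2 = np.log2(expr.values)
    mean_wt = log2[wt].mean(axis=1)
    mean_ko = log2[ko].mean(axis=1)
    linear_wt = expr.values[wt].mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_log2_wt": mean_wt,
            "mean_log2_ko": mean_ko,
            "lfc_wt_ko": mean_wt - mean_ko,
            "mean_linear_wt": linear_wt,
            "expressed": linear_wt >= floor,
        }
    )
    out.index.name = "gene_id"
    return out


def upregulated_in_ko(stats: pd.DataFrame, fold: float) -> set[str]:
    """Expressed genes at least ``fold``-times up in KO.

    With the WT-minus-KO sign convention an x-fold upregulation on knockout
    means ``lfc_wt_ko <= -log2(fold)``.
    """
    if not fold > 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    mask = stats["expressed"] & (stats["lfc_wt_ko"] <= -math.log2(fold))
    return set(stats.index[mask])
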