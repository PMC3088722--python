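"""Synthetic UTR and two-condition expression data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a universe of 3'UTRs drawn from an order-1 Markov background, a
subset of target genes with canonical seed sites spliced in, and replicated
two-condition expression where targets are derepressed in the knockout by a
planted log2 effect.  Two knockout datasets can be simulated whose target
sets share a configurable fraction, mirroring a global-miRNA-loss experiment
and a cluster-specific deletion.

Ground truth is exact by construction: every planted gene's UTR scans to
exactly the planted site list, and genes outside the planted union contain no
site for the planted seed family (both enforced by rejection sampling), so
recovery tests can compare called candidates against truth sets directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MiRNARecord, UTRRecord
from .sites import SITE_TYPES, SeedSite, compile_patterns, scan_utr

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_transition_matrix",
    "simulate_utrs",
    "simulate_expression",
    "simulate_study",
    "write_study",
]

#: mmu-miR-295-3p (miRBase); seed AAGUGC, position 8 = U
DEFAULT_MIRNA_NAME = "miR-295-3p"
DEFAULT_MIRNA_SEQUENCE = "AAAGUGCUACUACUUUUGAGUCU"

_BASES = np.array(list("ACGT"))


def default_transition_matrix() -> np.ndarray:
    """Order-1 background with mild AT richness and CpG depletion."""
    base = np.array([0.29, 0.21, 0.21, 0.29])
    t = np.tile(base, (4, 1))
    t[1, 2] *= 0.25  # C->G transitions suppressed (CpG depletion)
    return t / t.sum(axis=1, keepdims=True)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    Lengths are log-normal (natural-log parameters), the expression baseline
    and replicate noise are on the log2 scale, and ``delta`` is the planted
    knockout-minus-wild-type derepression of a target in log2 units
    (``delta_conserved`` for the designated conserved subset).
    """

    n_genes: int = 10_000
    n_targets: int = 300
    utr_length_law: tuple[float, float] = (6.9, 0.7)  # ln-scale: median ~1 kb
    background_markov: np.ndarray = field(default_factory=default_transition_matrix)
    sites_per_target_law: dict[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.10, 4: 0.05}
    )
    site_type_law: dict[str, float] = field(
        default_factory=lambda: {
            "6mer": 0.40, "7mer-A1": 0.25, "7mer-m8": 0.25, "8mer": 0.10
        }
    )
    baseline_law: tuple[float, float] = (7.0, 2.0)  # log2 mean intensity
    replicate_sd: float = 0.25  # log2 per-replicate noise
    delta: float = 0.3
    delta_conserved: float = 0.6
    conserved_fraction: float = 0.10
    n_reps_wt: int = 3
    n_reps_ko: int = 3
    shared_fraction: float = 0.7
    mirna_name: str = DEFAULT_MIRNA_NAME
    mirna_sequence: str = DEFAULT_MIRNA_SEQUENCE
    min_utr_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_targets <= self.n_genes:
            raise ValueError("need 0 <= n_targets <= n_genes")
        if self.delta < 0 or self.delta_conserved < 0:
            raise ValueError("planted effects must be >= 0")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.n_reps_wt < 2 or self.n_reps_ko < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0 < self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must be in (0, 1]")
        t = np.asarray(self.background_markov, dtype=float)
        if t.shape != (4, 4) or (t < 0).any():
            raise ValueError("background_markov must be a non-negative 4x4 matrix")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("background_markov rows must sum to 1 within 1e-9")
        for law, domain in ((self.sites_per_target_law, {1, 2, 3, 4}),
                            (self.site_type_law, set(SITE_TYPES))):
            if not set(law) <= domain:
                raise ValueError(f"law keys {set(law)} outside {domain}")
            if not math.isclose(sum(law.values()), 1.0, abs_tol=1e-9):
                raise ValueError("law probabilities must sum to 1")
        if len(self.mirna_sequence) < 8:
            raise ValueError("planted miRNA must be >= 8 nt")

    @property
    def mirna(self) -> MiRNARecord:
        return MiRNARecord(self.mirna_name,
                           self.mirna_sequence.upper().replace("T", "U"))

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(1, self.n_genes + 1)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background_markov"] = np.asarray(self.background_markov).tolist()
        return d


@dataclass
class SimulatedStudy:
    """Everything a full two-dataset analysis consumes, plus the ground truth."""

    utrs: list[UTRRecord]
    mirna: MiRNARecord
    truth_targets: dict[str, set[str]]  # dataset name -> planted target genes
    truth_sites: list[SeedSite]
    conserved: set[str]
    expression_1: ExpressionMatrix
    expression_2: ExpressionMatrix
    conservation: pd.Series

    @property
    def planted_union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.truth_targets.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# sequence generation


def _stationary(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _markov_batch(rng: np.random.Generator, lengths: Sequence[int],
                  transition: np.ndarray) -> list[str]:
    """Draw one sequence per requested length from the order-1 chain.

    Vectorised across sequences: one RNG draw per position over all
    sequences, so cost scales with max(lengths), not sum of per-base Python
    steps.
    """
    lengths = np.asarray(lengths, dtype=int)
    n = lengths.size
    if n == 0:
        return []
    lmax = int(lengths.max())
    cum = np.cumsum(transition, axis=1)
    pi_cum = np.cumsum(_stationary(transition))
    states = np.empty((n, lmax), dtype=np.int64)
    states[:, 0] = np.searchsorted(pi_cum, rng.random(n), side="right").clip(0, 3)
    for t in range(1, lmax):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    chars = _BASES[states]
    return ["".join(chars[i, : lengths[i]]) for i in range(n)]


def _place_sites(rng: np.random.Generator, length: int,
                 site_lengths: Sequence[int]) -> list[int]:
    """Uniform non-overlapping start positions for sites of given lengths.

    Stars-and-bars construction: draw the gaps, then lay the sites (in a
    shuffled order so no site type is biased toward the 5' end).
    """
    order = rng.permutation(len(site_lengths))
    lens = [site_lengths[i] for i in order]
    free = length - sum(lens)
    if free < 0:
        raise ValueError("UTR too short for requested sites")
    cuts = np.sort(rng.integers(0, free + 1, size=len(lens)))
    starts_in_order = [int(cuts[i] + sum(lens[:i])) for i in range(len(lens))]
    # undo the shuffle: starts[j] is where the j-th requested site went
    starts = [0] * len(site_lengths)
    for rank, j in enumerate(order):
        starts[j] = starts_in_order[rank]
    return starts


def _draw_discrete(rng: np.random.Generator, law: Mapping, size: int) -> list:
    keys = list(law.keys())
    probs = np.array([law[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def simulate_utrs(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    target_genes: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
    max_attempts: int = 100,
) -> tuple[list[UTRRecord], list[SeedSite]]:
    """Generate the UTR universe with sites planted in the target genes.

    Every target UTR is rejection-sampled until scanning reproduces exactly
    the planted site list (no accidental extra sites, no type upgrades), and
    every non-target UTR until it is free of sites for the planted family.
    Raises after ``max_attempts`` failed redraws for any gene.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gene_ids = list(gene_ids) if gene_ids is not None else config.gene_ids()
    if target_genes is None:
        target_genes = sorted(
            rng.choice(gene_ids, size=config.n_targets, replace=False)
        ) if config.n_targets else []
    target_set = set(target_genes)
    if not target_set <= set(gene_ids):
        raise ValueError("target_genes must be a subset of the gene universe")

    mirna = config.mirna
    patterns = compile_patterns(mirna.seed, mirna.position8)
    by_type = {p.site_type: p for p in patterns}
    family = mirna.family_key
    meanlog, sdlog = config.utr_length_law

    def draw_length(minimum: int) -> int:
        for _ in range(max_attempts):
            length = int(round(rng.lognormal(meanlog, sdlog)))
            if length >= max(minimum, config.min_utr_length):
                return length
        raise RuntimeError("could not draw a UTR length hosting the requested sites")

    # planted site plan per target gene
    plans: dict[str, list[str]] = {}
    n_sites_draw = _draw_discrete(rng, config.sites_per_target_law, len(target_set))
    ordered_targets = [g for g in gene_ids if g in target_set]
    for gene, k in zip(ordered_targets, n_sites_draw):
        plans[gene] = _draw_discrete(rng, config.site_type_law, int(k))

    utr_of: dict[str, UTRRecord] = {}
    truth: dict[str, list[SeedSite]] = {}

    # targets: splice sites, verify scan == plan
    for gene in ordered_targets:
        types = plans[gene]
        site_lens = [len(by_type[t].match_string) for t in types]
        ok = False
        for _ in range(max_attempts):
            length = draw_length(sum(site_lens) + 2 * len(site_lens))
            seq = _markov_batch(rng, [length], config.background_markov)[0]
            starts = _place_sites(rng, length, site_lens)
            chars = list(seq)
            for start, ty in zip(starts, types):
                match = by_type[ty].match_string
                chars[start : start + len(match)] = match
            candidate = UTRRecord(gene, "".join(chars))
            expected = sorted(
                SeedSite(gene, s, s + len(by_type[t].match_string), t, family)
                for s, t in zip(starts, types)
            )
            found = scan_utr(candidate, patterns, family)
            if found == expected:
                utr_of[gene] = candidate
                truth[gene] = expected
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"failed to plant sites in {gene!r} after {max_attempts} attempts"
            )

    # non-targets: batched rejection until family-site-free
    nontargets = [g for g in gene_ids if g not in target_set]
    pending = nontargets
    for _ in range(max_attempts):
        if not pending:
            break
        lengths = [draw_length(0) for _ in pending]
        seqs = _markov_batch(rng, lengths, config.background_markov)
        still: list[str] = []
        for gene, seq in zip(pending, seqs):
            rec = UTRRecord(gene, seq)
            if scan_utr(rec, patterns, family):
                still.append(gene)
            else:
                utr_of[gene] = rec
        pending = still
    if pending:
        raise RuntimeError(
            f"failed to draw site-free UTRs for {len(pending)} genes "
            f"after {max_attempts} rounds"
        )

    utrs = [utr_of[g] for g in gene_ids]
    truth_sites = [s for g in ordered_targets for s in truth[g]]
    return utrs, truth_sites


def simulate_expression(
    config: SimulationConfig,
    targets: Iterable[str],
    rng: np.random.Generator | None = None,
    gene_ids: Sequence[str] | None = None,
    conserved: Iterable[str] = (),
    sample_prefix: str = "",
) -> ExpressionMatrix:
    """Replicated two-condition intensities with the planted derepression.

    Per gene g with log2 baseline b_g ~ Normal(baseline_law): WT replicate
    intensity 2**(b_g + eps) and KO replicate 2**(b_g + delta_g + eps) with
    eps ~ Normal(0, replicate_sd); delta_g is ``delta`` for targets
    (``delta_conserved`` for targets in ``conserved``), else 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gene_ids = list(gene_ids) if gene_ids is not None else config.gene_ids()
    target_set = set(targets)
    if not target_set <= set(gene_ids):
        raise ValueError("targets must be a subset of the gene universe")
    conserved_set = set(conserved) & target_set

    n = len(gene_ids)
    mu, sd = config.baseline_law
    baseline = rng.normal(mu, sd, size=n)
    delta = np.array(
        [
            config.delta_conserved if g in conserved_set
            else config.delta if g in target_set
            else 0.0
            for g in gene_ids
        ]
    )
    n_wt, n_ko = config.n_reps_wt, config.n_reps_ko
    noise = rng.normal(0.0, config.replicate_sd, size=(n, n_wt + n_ko)) \
        if config.replicate_sd > 0 else np.zeros((n, n_wt + n_ko))
    log2 = np.empty((n, n_wt + n_ko))
    log2[:, :n_wt] = baseline[:, None] + noise[:, :n_wt]
    log2[:, n_wt:] = (baseline + delta)[:, None] + noise[:, n_wt:]
    values = np.exp2(log2)
    wt_samples = [f"{sample_prefix}WT_{i+1}" for i in range(n_wt)]
    ko_samples = [f"{sample_prefix}KO_{i+1}" for i in range(n_ko)]
    samples = wt_samples + ko_samples
    design = {**{s: "WT" for s in wt_samples}, **{s: "KO" for s in ko_samples}}
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=samples)
    return ExpressionMatrix(df, design)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full two-dataset study: UTRs, truth targets, expression, conservation.

    The two datasets' target sets share ``round(shared_fraction * n_targets)``
    genes; sites are planted in the union.  The conserved subset is drawn
    from the shared targets (both datasets show the stronger effect) and is
    ranked highest in the conservation scores.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_ids()

    n_shared = int(round(config.shared_fraction * config.n_targets))
    n_only = config.n_targets - n_shared
    union_size = n_shared + 2 * n_only
    if union_size > config.n_genes:
        raise ValueError("n_genes too small for the requested target sets")
    planted = list(rng.choice(gene_ids, size=union_size, replace=False))
    shared = planted[:n_shared]
    t1 = set(shared) | set(planted[n_shared : n_shared + n_only])
    t2 = set(shared) | set(planted[n_shared + n_only :])

    n_cons = min(math.ceil(config.conserved_fraction * config.n_targets),
                 len(shared)) if config.n_targets else 0
    conserved = set(shared[:n_cons])

    utrs, truth_sites = simulate_utrs(config, rng, target_genes=sorted(planted),
                                      gene_ids=gene_ids)
    expr1 = simulate_expression(config, t1, rng, gene_ids, conserved, "d1_")
    expr2 = simulate_expression(config, t2, rng, gene_ids, conserved, "d2_")

    scores = pd.Series(
        rng.uniform(0.0, 10.0, size=len(planted)),
        index=pd.Index(sorted(planted), name="gene_id"),
        name="score",
    )
    scores.loc[sorted(conserved)] = rng.uniform(10.0, 20.0, size=len(conserved))

    return SimulatedStudy(
        utrs=utrs,
        mirna=config.mirna,
        truth_targets={"dataset_1": t1, "dataset_2": t2},
        truth_sites=truth_sites,
        conserved=conserved,
        expression_1=expr1,
        expression_2=expr2,
        conservation=scores,
    )


def write_study(study: SimulatedStudy, config: SimulationConfig, outdir) -> dict:
    """Write a simulated study as the plain-text inputs the pipeline reads.

    Emits utrs.fasta, mirna.fasta, expr_1.tsv / expr_2.tsv with design YAMLs,
    conservation.tsv, truth.tsv and the simulation config; TSV headers record
    tool version, config hash and seed.
    """
    from pathlib import Path

    import yaml

    from . import __version__
    from .io import write_tsv, write_utr_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = __import__("hashlib").sha256(
        __import__("json").dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]
    meta = {"tool": f"mirshift {__version__}", "config_hash": cfg_hash,
            "seed": config.seed}
    paths = {}

    paths["utrs"] = outdir / "utrs.fasta"
    write_utr_fasta(study.utrs, paths["utrs"])
    paths["mirna"] = outdir / "mirna.fasta"
    with open(paths["mirna"], "w") as fh:
        fh.write(f">{study.mirna.name}\n{study.mirna.sequence}\n")

    for key, expr in (("expr_1", study.expression_1), ("expr_2", study.expression_2)):
        paths[key] = outdir / f"{key}.tsv"
        write_tsv(expr.values, paths[key], meta)
        design_path = outdir / f"design_{key[-1]}.yaml"
        with open(design_path, "w") as fh:
            yaml.safe_dump(expr.condition_of, fh, sort_keys=True)
        paths[f"design_{key[-1]}"] = design_path

    paths["conservation"] = outdir / "conservation.tsv"
    write_tsv(study.conservation.to_frame(), paths["conservation"], meta)

    truth_rows = []
    for ds_name, genes in sorted(study.truth_targets.items()):
        for g in sorted(genes):
            truth_rows.append({"dataset": ds_name, "gene_id": g,
                               "conserved": g in study.conserved})
    paths["truth"] = outdir / "truth.tsv"
    write_tsv(pd.DataFrame(truth_rows), paths["truth"], meta, index=False)

    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
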