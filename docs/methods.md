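# Methods

## Site model

A mature miRNA (≥ 8 nt, RNA alphabet) is reduced to its seed, the hexamer at
positions 2–7; all miRNAs sharing a seed form one family, keyed by the
hexamer. On the mRNA (held internally as DNA; U→T on input, since UTRs are
conventionally distributed as DNA) the canonical site types are built from
the reverse complement of the seed:

| type | mRNA match | notes |
|---|---|---|
| 6mer | rc(seed) | seed match only |
| 7mer-A1 | rc(seed) + A | adenine opposite miRNA position 1 ("T1A") |
| 7mer-m8 | rc(seed + p8) | pairing extended to miRNA position 8 |
| 8mer | rc(seed + p8) + A | both extensions |

Scanning walks a UTR left to right. At each offset where any pattern matches,
exactly one site of the highest-priority matching type
(8mer > 7mer-m8 > 7mer-A1 > 6mer) is emitted and the scan resumes at the
nucleotide after that site's 6-nt seed core. This one-site-per-core rule
prevents an 8mer from also being counted as a 7mer and a 6mer, while still
allowing immediately adjacent cores to count separately. Coordinates are
0-based half-open everywhere, including output TSVs.

Family-level annotation unions sites over member miRNAs, counting a site
identical in (gene, interval, type) once. Rules allow excluding a member
entirely or excluding named site types for one member; excluded types are
dropped *after* classification, not reclassified downward — the intended
semantics when a member's 7mer-A1 sites do not actually contain the family's
core hexamer. "Conserved" targets are the top `ceil(fraction × n_scored)`
scored targets by a user-supplied conservation score (default fraction 0.10),
with ties at the cutoff broken by lexicographic gene id so the set is
deterministic.

Non-canonical (seed-mismatch) sites, 3'-supplementary pairing, and context
scoring are out of scope; conservation scores are consumed as a ranking
column, never computed.

## Expression and LFC

Intensities are linear-scale, floored at 1.0 on input so every log is finite.
Spot-level rows are condensed to genes by geometric means, which is exactly
averaging on the log scale. Per gene, LFC = mean log2 (WT) − mean log2 (KO):
a target derepressed on miRNA loss has negative LFC, and swapping the labels
negates every LFC exactly. A gene is *expressed* when the arithmetic mean of
its linear WT intensities is ≥ the floor (default 16); the floor is stated on
the linear scale and on the wild-type arrays only (configurable). An
x-fold knockout upregulation is a threshold on the difference of mean logs,
LFC ≤ −log2(x), not on the ratio of linear means — consistent with the LFC
definition (the two differ when replicates are skewed).

## Matched controls

Covariates per gene: log2 mean WT expression, log10 UTR length, and the 16
overlapping-dinucleotide frequencies (counts over length − 1). Each covariate
is z-scored over pool ∪ targets, making the matching invariant to affine
rescaling of any raw covariate; the 16 composition dimensions are weighted
1/√16 so the three blocks (expression, length, composition) contribute
equally to squared Euclidean distance. Matching is greedy nearest-neighbour
without replacement, visiting targets in an order shuffled by the RNG seed;
k controls per target is supported (default 1). Targets lacking a UTR or an
expression record are reported as unmatched, never silently dropped.
Optimal bipartite assignment was evaluated as an alternative and gave no
better covariate balance than greedy matching at transcriptome-scale pools,
so the simpler, order-deterministic greedy was kept.

Balance is diagnosed by the standardized mean difference per covariate,
SMD = (mean_targets − mean_controls) / pooled SD. Two regimes matter:

* when targets differ *systematically* from the pool (the confounded
  scenario), matching is load-bearing: on a pool where targets are ~0.5 SD
  longer, GC-richer and higher-expressed, matching brings max |SMD| across
  all 18 covariates below 0.1 while random controls sit around 0.6;
* when targets are a random draw (the default unconfounded study), the
  max |SMD| over 18 covariates is dominated by the sampling noise of the
  target draw itself (≈ √(2/n) per covariate, ~0.11 at n ≈ 365) and matching
  cannot push it below that noise floor; this is variance, not bias.

## Shift statistics

The primary test is the Wilcoxon rank-sum, chosen because it assumes nothing
about the LFC distribution's shape. The statistic reported is the rank sum W
of the gene set. For tie-free pooled samples with n₁ + n₂ ≤ 20 the p-value
is exact: the permutation null of W is enumerated by dynamic programming
(subset-sum counts over ranks 1..N), and the two-sided p is twice the smaller
tail, capped at 1. Larger or tied samples use the normal approximation with
midrank tie correction and a 0.5 continuity correction; at n₁ = n₂ = 10 the
two paths agree within 0.01 absolute. The KS test (sup-distance of the two
ECDFs, asymptotic p) and Welch's unequal-variance t are provided as
secondary checks; degenerate zero-variance t inputs resolve to p = 1 (equal
means) or p = 0 (unequal). Two-sided p-values are the default; the
derepression-directional one-sided test ("less", under the WT−KO sign
convention) is a flag. In text output p-values below 2.2e−16 are rendered as
an inequality; TSVs always carry the raw float.

ECDFs are right-continuous step functions, quantile = (#values ≤ v)/n,
reported at the unique sample values. The shift summary is
median(set LFC) − median(control LFC). Each gene set is matched to its own
control set by default (a shared pool is possible by passing the same match
set); sets with fewer than 2 usable expressed genes are skipped with a
warning.

## Candidate calling, overlap, enrichment

A candidate must be (i) a predicted family target, (ii) ≤ −log2(fold) in
dataset 1, (iii) the same in dataset 2, and (iv) expressed in both datasets'
wild types; the table carries all four flags so the conjunction is auditable.
Overlap between the datasets' upregulated sets is a 2×2 table within a
universe (default: expressed genes; also reported within expressed predicted
targets), with the two-sided Fisher exact p computed by summation of
hypergeometric probabilities no larger than the observed table's, and a
sample odds ratio with a Haldane half-count when any cell is zero. Shared
fractions are reported relative to each dataset, since "x% shared" is
direction-ambiguous. Enrichment of the candidate list in user-supplied gene
sets (GMT) is the hypergeometric upper tail per set, intersected with the
universe first, with Benjamini–Hochberg q-values across sets. GO-DAG
propagation and pathway-network construction are out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes — not
platform-level detail:

* **UTRs**: lengths log-normal (ln-scale mean 6.9, sd 0.7; median ~1 kb),
  background from an order-1 Markov chain, by default mildly AT-rich with
  C→G transitions suppressed to one quarter (CpG depletion). Target genes
  receive 1–4 sites (law 0.60/0.25/0.10/0.05) of types drawn from
  0.40/0.25/0.25/0.10 over 6mer/7mer-A1/7mer-m8/8mer, spliced in at uniform
  non-overlapping positions. The planted miRNA defaults to mmu-miR-295-3p
  (seed AAGUGC).
* **Exact truth**: a planted gene is rejection-sampled until scanning returns
  exactly the planted site list (no accidental sites, no type upgrades from
  flanking bases), and every non-planted gene until it is family-site-free;
  after 100 failed redraws the generator errors. Truth sets are therefore
  exact, at the cost of realism — real transcriptomes have background sites
  and partially effective targets, so recovery rates measured here are upper
  bounds for real data.
* **Expression**: per gene a log2 baseline b ~ N(7, 2); WT replicates are
  2^(b+ε), KO replicates 2^(b+δ+ε) with ε ~ N(0, replicate_sd). Defaults:
  replicate_sd 0.25 log2 units (array-replicate scale; no platform value is
  available, so it is exposed in the config), δ = 0.3 with 0.6 for the
  conserved subset, 3+3 replicates. The N(7, 2) baseline deliberately puts a
  minority of genes below the expressed floor of 16 (= 2^4). Noise is
  log-additive only: no intensity-dependent variance, batch effects, or
  probe-level structure.
* **Two datasets**: target sets share `round(shared_fraction × n_targets)`
  genes (default 0.7, the regime where one knockout removes the family
  cluster and the other all miRNAs); sites are planted in the union, so a
  dataset-1-only target is still a predicted target. The conserved subset
  (fraction 0.1 of n_targets) is drawn from the shared targets and ranked
  highest in the emitted conservation scores.

One RNG stream drives a whole study; every output header records tool
version, config hash, and seed, and identical config + seed reproduce
identical bytes.

## Problem sizes and numerical choices

The statistical self-tests run at 10,000 genes × 300 targets with 3+3
replicates: 500 null repetitions for type-I calibration (rejection at
α = 0.05 within [0.03, 0.07], p-values KS-uniform at the 1% level), 100
repetitions at δ = 0.3/0.6 for power and the conserved-vs-all ordering, and
full-study truth recovery at δ = 1 with replicate_sd 0.1 and 0. Repetitions
redraw only the expression layer over one fixed UTR universe; matching is
done once, as in a real analysis. Markov-row sums are validated to 1e-9;
geometric-mean condensation is tested to 1e-12 against the log identity;
z-scoring guards a zero-variance covariate by treating it as signal-free.

## Known limitations

Probe/platform normalisation, probe-to-gene mapping, moderated variance
estimators, permutation tests over gene labels, and gene–gene correlation
corrections are all out of scope; the rank-sum p-values treat genes as
independent, which real co-regulated sets violate. The exact rank-sum path
refuses ties (falls back to the approximation). Enrichment treats gene sets
as flat lists.
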