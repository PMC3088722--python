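# mirshift

Seed-site target prediction and CDF-shift derepression analysis for miRNA
knockout experiments, with a synthetic-data generator that makes the whole
pipeline testable end to end.

## The problem

When a miRNA (or all miRNAs, via Dicer loss) is removed from a cell, its
direct targets are *derepressed*: their mRNA levels rise. Given 3'UTR
sequences and replicated expression arrays from wild-type and knockout cells,
the analysis asks:

1. **Which genes carry canonical seed sites?** A miRNA's *seed* is the
   hexamer at positions 2–7 of the mature sequence; its reverse complement on
   an mRNA defines a site. Sites are classified into the standard hierarchy
   `8mer > 7mer-m8 > 7mer-A1 > 6mer` (position-8 pairing and/or an adenine
   opposite position 1 strengthen the match).
2. **Are predicted targets derepressed as a class?** Per gene, the log2 fold
   change LFC = mean log2 expression (WT) − mean log2 expression (KO), so
   derepression is a *negative* LFC. The empirical CDF of target LFCs is
   compared with that of control genes matched on expression level, 3'UTR
   length, and dinucleotide composition, using the Wilcoxon rank-sum test
   (KS and Welch t as secondary checks).
3. **Which individual genes are candidates?** Predicted targets that are
   expressed (WT intensity ≥ 16) and at least 1.2-fold upregulated in *both*
   of two independent knockout datasets, with the two datasets' overlap
   summarised by Fisher's exact test and the candidate list tested for
   gene-set over-representation (hypergeometric + Benjamini–Hochberg).

Because every stage is deterministic given a seed, and the generator plants
sites and effects with exact ground truth, the pipeline's statistical
behaviour (type-I error, power, matching balance, recovery) is itself tested.

## Worked example

Simulate a two-dataset study (2,000 genes, 150 targets per dataset, planted
derepression of 0.5 log2 units, 1.0 for the conserved subset) and run the
full analysis:

```sh
mirshift simulate --out sim --seed 42 --n-genes 2000 --n-targets 150 \
    --delta 0.5 --delta-conserved 1.0
cat > config.yaml <<EOF
utr_fasta: sim/utrs.fasta
mirna_file: sim/mirna.fasta
expr_1: sim/expr_1.tsv
design_1: sim/design_1.yaml
expr_2: sim/expr_2.tsv
design_2: sim/design_2.yaml
conservation: sim/conservation.tsv
outdir: results
seed: 42
EOF
mirshift run-all --config config.yaml
cat results/report.txt
```

which prints (abridged):

```
genes scanned: 2000
predicted targets: 195

CDF-shift tests (set vs matched controls):
  dataset_1  targets            ranksum  n=184    p=3.7e-32 median_shift=-0.451
  dataset_1  conserved_targets  ranksum  n=17     p=7.05e-07 median_shift=-0.768
  dataset_2  targets            ranksum  n=185    p=4.36e-29 median_shift=-0.439
  dataset_2  conserved_targets  ranksum  n=19     p=1.45e-06 median_shift=-0.893

two-dataset overlap of upregulated genes:
  universe=expressed                    both=97   shared_of_d1=35.3% shared_of_d2=34.5% fisher_p=3.46e-18
  universe=expressed_predicted_targets  both=80   shared_of_d1=68.4% shared_of_d2=65.0% fisher_p=0.485

candidates (target + up in both + expressed): 80
```

Reading this: predicted targets shift left (negative median LFC shift —
derepression) relative to matched controls with overwhelming rank-sum
significance; the conserved subset shifts further, as expected if it is
enriched for genuine targets; the two knockout datasets agree far more
within predicted targets (~68% shared) than transcriptome-wide (~35%); and
80 genes pass the full candidate filter.

The same stages are available individually (`mirshift scan`, `lfc`, `match`,
`cdfshift`, `candidates`, `enrich`, `report`) and as library functions
(`mirshift.scan_utr`, `compute_gene_stats`, `match_controls`,
`cdf_shift_analysis`, `call_candidates`, ...).

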