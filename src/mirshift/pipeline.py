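"""Orchestration of the full analysis: scan -> LFC -> match -> shift -> call.

Every stage writes a TSV whose '#' header records the tool version, the
config hash and the RNG seed, so a run is reproducible byte for byte from its
own outputs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .candidates import call_candidates, overlap_stats, set_enrichment
from .config import RunConfig
from .io import (
    read_conservation_tsv,
    read_expression_tsv,
    read_gmt,
    read_mirna_table,
    read_utr_fasta,
    write_tsv,
)
from .lfc import compute_gene_stats, upregulated_in_ko
from .matching import balance_report, build_covariates, match_controls
from .shift import cdf_shift_analysis, shift_results_frame
from .sites import FamilyRule, build_target_annotations, scan_collection, select_conserved

__all__ = ["run_all", "load_rules", "load_design"]

log = logging.getLogger("mirshift")


def load_design(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        design = yaml.safe_load(fh)
    if not isinstance(design, Mapping) or not design:
        raise ValueError(f"{path}: design must be a non-empty sample->condition map")
    return {str(k): str(v) for k, v in design.items()}


def load_rules(path: str | Path) -> list[FamilyRule]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    rules = []
    for entry in raw:
        rules.append(
            FamilyRule(
                family_key=entry["family_key"],
                mode=entry.get("mode", "include"),
                excluded_types=frozenset(entry.get("excluded_types", [])),
            )
        )
    return rules


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in dependency order; returns the output paths.

    Stages whose optional inputs are absent (second dataset, conservation,
    gene sets) are skipped.  Identical config and seed reproduce identical
    output bytes.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"mirshift {__version__}", "config_hash": config.config_hash,
            "seed": config.seed}
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = outdir / f"{name}.tsv"
        write_tsv(df, path, meta, index=index)
        outputs[name] = path

    t0 = _stage("load inputs")
    utrs = read_utr_fasta(config.utr_fasta)
    mirnas = read_mirna_table(config.mirna_file)
    rules = load_rules(config.rules) if config.rules else []
    expr1 = read_expression_tsv(config.expr_1, load_design(config.design_1))
    expr2 = (
        read_expression_tsv(config.expr_2, load_design(config.design_2))
        if config.expr_2
        else None
    )
    conservation = (
        read_conservation_tsv(config.conservation) if config.conservation else None
    )
    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
    log.info("loaded %d UTRs, %d miRNAs (%.1fs)", len(utrs), len(mirnas),
             time.perf_counter() - t0)

    _stage("scan")
    sites = scan_collection(utrs, mirnas, rules)
    emit("sites", sites, index=False)
    annotations = build_target_annotations(utrs, mirnas, rules, conservation)
    emit("annotations", annotations)
    targets = set(annotations.index[annotations["is_target"]])

    _stage("lfc")
    stats1 = compute_gene_stats(expr1, config.wt_label, config.ko_label, config.floor)
    emit("gene_stats_1", stats1)
    stats2 = None
    if expr2 is not None:
        stats2 = compute_gene_stats(expr2, config.wt_label, config.ko_label,
                                    config.floor)
        emit("gene_stats_2", stats2)

    _stage("match")
    set_defs: dict[str, set[str]] = {"targets": targets}
    if conservation is not None:
        set_defs["conserved_targets"] = select_conserved(
            annotations, config.conserved_fraction
        )
    covariates = build_covariates(utrs, stats1)
    expressed1 = set(stats1.index[stats1["expressed"]])
    pool = sorted((expressed1 & set(covariates.index)) - targets)
    match_sets = {
        name: match_controls(
            sorted(genes & expressed1), covariates, rng_seed=config.seed,
            pool=pool, n_controls=config.controls_per_target,
        )
        for name, genes in set_defs.items()
    }
    all_pairs = pd.concat(
        [ms.pairs.assign(set_name=name) for name, ms in match_sets.items()],
        ignore_index=True,
    )
    emit("matches", all_pairs, index=False)
    balance = pd.concat(
        {name: balance_report(ms, covariates) for name, ms in match_sets.items()},
        axis=1,
    )
    emit("balance", balance)

    _stage("cdfshift")
    all_results = []
    curves_rows = []
    datasets = [("dataset_1", stats1)] + ([("dataset_2", stats2)] if stats2 is not None else [])
    for ds_name, stats in datasets:
        results = cdf_shift_analysis(stats, set_defs, match_sets,
                                     alternative=config.alternative)
        frame = shift_results_frame(results)
        frame.insert(0, "dataset", ds_name)
        all_results.append(frame)
        for res in results:
            if res.test != "ranksum":
                continue
            for group, curve in (("set", res.ecdf_set), ("control", res.ecdf_control)):
                values, quantiles = curve
                curves_rows.append(
                    pd.DataFrame(
                        {"dataset": ds_name, "set_name": res.set_name,
                         "group": group, "lfc": values, "quantile": quantiles}
                    )
                )
    emit("shift_results", pd.concat(all_results, ignore_index=True), index=False)
    emit("ecdf_curves", pd.concat(curves_rows, ignore_index=True), index=False)

    if stats2 is not None:
        _stage("candidates")
        cand_table = call_candidates(annotations, stats1, stats2, config.fold)
        emit("candidates", cand_table)
        expressed_universe = set(cand_table.index[cand_table["expressed"]])
        up1 = upregulated_in_ko(stats1, config.fold) & expressed_universe
        up2 = upregulated_in_ko(stats2, config.fold) & expressed_universe
        venn_rows = []
        for universe_name, universe in (
            ("expressed", expressed_universe),
            ("expressed_predicted_targets", expressed_universe & targets),
        ):
            ov = overlap_stats(up1 & universe, up2 & universe, universe)
            venn_rows.append(
                {"universe": universe_name, "n_universe": len(universe),
                 "n_both": ov.n_both, "n_only_dataset1": ov.n_only_a,
                 "n_only_dataset2": ov.n_only_b, "n_neither": ov.n_neither,
                 "shared_fraction_of_dataset1": ov.shared_fraction_of_a,
                 "shared_fraction_of_dataset2": ov.shared_fraction_of_b,
                 "odds_ratio": ov.odds_ratio, "fisher_p": ov.fisher_p}
            )
        emit("venn", pd.DataFrame(venn_rows), index=False)

        if gene_sets is not None:
            _stage("enrich")
            enrich = set_enrichment(
                set(cand_table.index[cand_table["is_candidate"]]),
                gene_sets, expressed_universe,
            )
            emit("enrichment", enrich, index=False)

    _stage("report")
    report_path = outdir / "report.txt"
    report_path.write_text(render_report(outputs, meta))
    outputs["report"] = report_path

    config.to_yaml(outdir / "config.yaml")
    outputs["config"] = outdir / "config.yaml"
    return outputs


def render_report(outputs: Mapping[str, Path], meta: Mapping[str, object]) -> str:
    """Plain-text run summary assembled from the stage outputs."""
    lines = [
        "mirshift run summary",
        "====================",
        *(f"{k}: {v}" for k, v in meta.items()),
        "",
    ]
    if "annotations" in outputs:
        ann = pd.read_csv(outputs["annotations"], sep="\t", comment="#", index_col=0)
        lines.append(f"genes scanned: {len(ann)}")
        lines.append(f"predicted targets: {int(ann['is_target'].sum())}")
        lines.append("")
    if "shift_results" in outputs:
        shift = pd.read_csv(outputs["shift_results"], sep="\t", comment="#")
        lines.append("CDF-shift tests (set vs matched controls):")
        for _, row in shift.iterrows():
            lines.append(
                f"  {row['dataset']:>9s}  {row['set_name']:<18s} {row['test']:<8s}"
                f" n={row['n_set']:<6d} p={row['p_value']:.3g}"
                f" median_shift={row['median_shift']:+.3f}"
            )
        lines.append("")
    if "venn" in outputs:
        venn = pd.read_csv(outputs["venn"], sep="\t", comment="#")
        lines.append("two-dataset overlap of upregulated genes:")
        for _, row in venn.iterrows():
            lines.append(
                f"  universe={row['universe']:<28s} both={row['n_both']:<6d}"
                f" shared_of_d1={row['shared_fraction_of_dataset1']:.1%}"
                f" shared_of_d2={row['shared_fraction_of_dataset2']:.1%}"
                f" fisher_p={row['fisher_p']:.3g}"
            )
        lines.append("")
    if "candidates" in outputs:
        cand = pd.read_csv(outputs["candidates"], sep="\t", comment="#", index_col=0)
        lines.append(f"candidates (target + up in both + expressed): "
                     f"{int(cand['is_candidate'].sum())}")
        lines.append("")
    if "enrichment" in outputs:
        enr = pd.read_csv(outputs["enrichment"], sep="\t", comment="#")
        lines.append("top enriched gene sets:")
        for _, row in enr.head(5).iterrows():
            lines.append(
                f"  {row['set_name']:<30s} k={row['k_overlap']:<5d}"
                f" p={row['p_hypergeom']:.3g} q={row['q_bh']:.3g}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
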