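"""End-to-end orchestration: simulate or load a study, classify duplicates,
quantify body methylation and expression, score copy dynamics, estimate
dN/dS, and assemble a report of the headline comparisons.

The report mirrors the shape of a duplicate-methylation study: pair/gene
counts per duplication category, the fraction of pairs losing body CG
methylation (BCGM) in the mutant and the fraction changing expression,
between-copy divergence distributions and their WT-vs-mutant tests,
higher/lower copy-group shift tests, the 10-group convergent/divergent
taxonomy, and dS / dN/dS stratification by expression affect.  All
between-copy statistics are reported separately for the CG-only and
all-context methylation classes (plus their union).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import methylation as meth
from . import expression as expr
from . import dynamics as dyn
from . import evolution as evo
from .catalog import (
    GeneCatalog, classify_duplicates, detect_collinear_blocks, filter_candidates,
)
from .simulate import SimulationConfig, generate_study
from .stats import compare_distributions, compare_groups_anova, contingency_test, correlate
from scipy import stats as _scipy_stats

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

METH_CLASSES = ("CG_only", "all_context", "BCGM_pooled")


@dataclass
class PipelineConfig:
    """Inputs (either a simulation config or file paths) plus thresholds."""

    simulation: SimulationConfig | None = None
    inputs: dict | None = None  # keys: gff, blast, cx_wt, cx_mut, expression, cds

    min_reads: int = 4
    fpkm_threshold: float = 0.1
    alpha: float = 0.05
    site_error_rate: float = 0.005
    site_alpha: float = 0.01
    min_sites: int = 5
    bm_mode: str = "not_lower"
    pseudocount: float = 0.01
    max_ds: float = 3.0
    top_k: int = 5
    max_evalue: float = 1e-10
    proximal_max_gap: int = 10
    min_block_anchors: int = 5
    max_rank_gap: int = 25
    run_evolution: bool = True
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("provide exactly one of simulation config or input paths")
        for name in ("min_reads", "fpkm_threshold", "alpha", "max_ds", "top_k",
                     "max_evalue", "proximal_max_gap", "min_block_anchors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class ReportBundle:
    """Structured result of a full pipeline run."""

    catalog_summary: dict = field(default_factory=dict)
    duplicates: dict = field(default_factory=dict)
    recovery: dict | None = None
    methylation: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    evolution: dict | None = None
    stage_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return _plain({
            "catalog_summary": self.catalog_summary,
            "duplicates": self.duplicates,
            "recovery": self.recovery,
            "methylation": self.methylation,
            "expression": self.expression,
            "dynamics": self.dynamics,
            "evolution": self.evolution,
            "stage_log": self.stage_log,
        })

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _plain(obj):
    """Recursively convert numpy scalars/arrays so json can serialize."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    return obj


def _percent(k: int, n: int) -> dict:
    return {"n": int(k), "total": int(n),
            "percent": (100.0 * k / n) if n else None}


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        catalog, truth, hits, cx_wt, cx_mut, expression, cds = generate_study(
            cfg.simulation, with_cds=cfg.run_evolution
        )
        return catalog, hits, cx_wt, cx_mut, expression, cds, truth
    paths = cfg.inputs
    required = {"gff", "blast", "cx_wt", "cx_mut", "expression"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"input paths missing: {sorted(missing)}")
    catalog = dio.read_gff3(paths["gff"])
    hits = dio.read_blast_tab(paths["blast"])
    cx_wt = dio.read_cx_report(paths["cx_wt"])
    cx_mut = dio.read_cx_report(paths["cx_mut"])
    expression = dio.read_expression_table(paths["expression"])
    cds = dio.read_cds_fasta(paths["cds"]) if paths.get("cds") else None
    return catalog, hits, cx_wt, cx_mut, expression, cds, None


def _pair_class_index(partition: pd.DataFrame, klass: str) -> pd.Index:
    if klass == "BCGM_pooled":
        return partition.index[partition["meth_class"].isin(["CG_only", "all_context"])]
    return partition.index[partition["meth_class"] == klass]


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run every stage in dependency order; deterministic given the seed."""
    cfg.validate()
    report = ReportBundle()
    log = report.stage_log

    # ---- inputs -----------------------------------------------------------
    catalog, hits, cx_wt, cx_mut, expression, cds, truth = _load_inputs(cfg)
    report.catalog_summary = {
        "n_genes": len(catalog),
        "n_te_genes": int(catalog.genes["is_te"].sum()),
        "n_chromosomes": int(catalog.genes["chrom"].nunique()) if len(catalog) else 0,
    }
    log.append({"stage": "inputs", "genes": len(catalog), "hits": len(hits),
                "cx_sites_wt": len(cx_wt), "cx_sites_mut": len(cx_mut)})

    # ---- duplicate classification ----------------------------------------
    candidates = filter_candidates(hits, catalog, top_k=cfg.top_k,
                                   max_evalue=cfg.max_evalue)
    blocks = detect_collinear_blocks(candidates, catalog,
                                     min_block_anchors=cfg.min_block_anchors,
                                     max_rank_gap=cfg.max_rank_gap)
    pairs = classify_duplicates(candidates, blocks, catalog,
                                proximal_max_gap=cfg.proximal_max_gap)
    log.append({"stage": "classify", "hits_in": len(hits),
                "candidates": len(candidates), "blocks": len(blocks),
                "pairs": len(pairs)})

    if truth is not None:
        key = {(a, b): p for a, b, p in
               zip(truth.pairs["gene_a"], truth.pairs["gene_b"], truth.pairs["pair_id"])}
        pairs["pair_id"] = [
            key.get((a, b), f"{a}--{b}") for a, b in zip(pairs["gene_a"], pairs["gene_b"])
        ]
        truth_cat = {(a, b): c for a, b, c in
                     zip(truth.pairs["gene_a"], truth.pairs["gene_b"],
                         truth.pairs["category"])}
        matched = [truth_cat.get((a, b)) for a, b in zip(pairs["gene_a"], pairs["gene_b"])]
        planted_found = sum(
            1 for m, c in zip(matched, pairs["category"]) if m is not None and m == c
        )
        per_cat = {}
        for cat in ("WGD", "tandem", "proximal", "transposed"):
            n_planted = int((truth.pairs["category"] == cat).sum())
            n_correct = sum(1 for m, c in zip(matched, pairs["category"])
                            if m == cat and c == cat)
            per_cat[cat] = _percent(n_correct, n_planted)
        report.recovery = {
            "planted_pairs": len(truth.pairs),
            "recovered_correct_category": _percent(planted_found, len(truth.pairs)),
            "per_category": per_cat,
        }
    else:
        pairs["pair_id"] = [f"{a}--{b}" for a, b in zip(pairs["gene_a"], pairs["gene_b"])]

    cat_counts = pairs["category"].value_counts().to_dict()
    report.duplicates = {
        "pairs_per_category": {c: int(cat_counts.get(c, 0))
                               for c in ("WGD", "tandem", "proximal", "transposed")},
        "distinct_genes": int(pd.unique(pairs[["gene_a", "gene_b"]].to_numpy().ravel()).size),
        "n_blocks": len(blocks),
    }

    # ---- body methylation -------------------------------------------------
    ann_wt = meth.annotate_sites(cx_wt, catalog)
    ann_mut = meth.annotate_sites(cx_mut, catalog)
    prof_wt = meth.compute_body_levels(ann_wt, catalog, min_reads=cfg.min_reads)
    prof_mut = meth.compute_body_levels(ann_mut, catalog, min_reads=cfg.min_reads)
    sites_wt = meth.call_methylated_sites(ann_wt, error_rate=cfg.site_error_rate,
                                          alpha=cfg.site_alpha, min_reads=cfg.min_reads)
    sites_mut = meth.call_methylated_sites(ann_mut, error_rate=cfg.site_error_rate,
                                           alpha=cfg.site_alpha, min_reads=cfg.min_reads)
    bg_wt = meth.compute_background(sites_wt, catalog)
    bg_mut = meth.compute_background(sites_mut, catalog)
    status_wt = meth.classify_body_methylation(sites_wt, bg_wt, alpha=cfg.alpha,
                                               min_sites=cfg.min_sites, mode=cfg.bm_mode)
    partition = meth.partition_pairs(pairs, status_wt)
    gene_dm = meth.test_differential_methylation(prof_wt, prof_mut, context="CG",
                                                 alpha=cfg.alpha)
    partition["bcgm_reduced"] = meth.pair_bcgm_reduction(partition, gene_dm)

    div_wt = meth.bcgm_divergence(partition, prof_wt)
    div_mut = meth.bcgm_divergence(partition, prof_mut)

    # mean gene-body CG loss among WT-body-methylated genes
    cg_wt_lv = prof_wt.xs("CG", level="context")["body_level"]
    cg_mut_lv = prof_mut.xs("CG", level="context")["body_level"]
    bm_genes = status_wt.xs("CG", level="context")
    bm_genes = bm_genes.index[bm_genes["body_methylated"]]
    common = cg_wt_lv.index.intersection(cg_mut_lv.index).intersection(bm_genes)
    lv_w = cg_wt_lv.loc[common]
    lv_m = cg_mut_lv.loc[common]
    body_cg_loss = float(1.0 - lv_m.sum() / lv_w.sum()) if lv_w.sum() > 0 else None

    meth_divergence = {}
    for klass in METH_CLASSES:
        idx = _pair_class_index(partition, klass)
        sub = partition.loc[idx]
        per_cat = {}
        groups = list(sub.groupby("category")) + [("ALL", sub)]
        for cat, grp in groups:
            w = div_wt.loc[grp.index].dropna()
            m = div_mut.loc[grp.index].dropna()
            ks = compare_distributions(w, m) if len(w) >= 3 and len(m) >= 3 else None
            per_cat[cat] = {
                "n": len(grp),
                "mean_wt": float(w.mean()) if len(w) else None,
                "mean_mut": float(m.mean()) if len(m) else None,
                "ks": None if ks is None else
                      {"statistic": ks.statistic, "pvalue": ks.pvalue,
                       "reduced": bool(m.mean() < w.mean())},
            }
        meth_divergence[klass] = per_cat

    # WT-divergence ANOVA across categories (CG-only class)
    cg_idx = _pair_class_index(partition, "CG_only")
    anova_entry = None
    sub = partition.loc[cg_idx]
    vals = div_wt.loc[cg_idx]
    ok = vals.notna()
    if ok.sum() >= 8 and sub.loc[ok, "category"].nunique() >= 2:
        try:
            an = compare_groups_anova(vals[ok], sub.loc[ok, "category"])
            anova_entry = {"f": an.f_statistic, "pvalue": an.pvalue, "letters": an.letters}
        except ValueError:
            anova_entry = None

    class_counts = partition["meth_class"].value_counts().to_dict()
    report.methylation = {
        "background_rates_wt": bg_wt.rates,
        "background_rates_mut": bg_mut.rates,
        "body_cg_loss_fraction": body_cg_loss,
        "pairs_per_class": {k: int(class_counts.get(k, 0))
                            for k in ("CG_only", "all_context", "unmethylated", "excluded")},
        "divergence_tests": meth_divergence,
        "wt_divergence_anova_cg_only": anova_entry,
    }
    log.append({"stage": "methylation",
                "profiled_genes_wt": int(prof_wt.index.get_level_values(0).nunique()),
                "cg_only_pairs": int(class_counts.get("CG_only", 0)),
                "all_context_pairs": int(class_counts.get("all_context", 0))})

    # ---- expression -------------------------------------------------------
    summary = expr.summarize_expression(expression)
    expressed = expr.call_expressed(summary, threshold=cfg.fpkm_threshold)
    partition["retained"] = expr.retained_pairs(partition, expressed)

    # analysis set: methylated pairs, expressed, with BCGM loss in >=1 copy
    analysis = {}
    for klass in METH_CLASSES:
        idx = _pair_class_index(partition, klass)
        sub = partition.loc[idx]
        expressed_pairs = sub[sub["retained"]]
        reduced = expressed_pairs[expressed_pairs["bcgm_reduced"]]
        analysis[klass] = reduced
    genes_needed = pd.unique(
        pd.concat([analysis["BCGM_pooled"]["gene_a"], analysis["BCGM_pooled"]["gene_b"]])
    )
    gene_de = expr.wt_vs_mut_de(genes_needed, summary, alpha=cfg.alpha)

    expr_section = {}
    for klass in ("CG_only", "all_context"):
        idx = _pair_class_index(partition, klass)
        sub = partition.loc[idx]
        expressed_pairs = sub[sub["retained"]]
        reduced = analysis[klass]
        affected = expr.flag_affected_pairs(reduced, gene_de, alpha=cfg.alpha)
        per_cat = {}
        for cat, grp in reduced.groupby("category"):
            n_expr_cat = int((expressed_pairs["category"] == cat).sum())
            per_cat[cat] = {
                "expressed_pairs": n_expr_cat,
                "bcgm_reduced": _percent(len(grp), n_expr_cat),
                "expression_changed": _percent(int(affected.loc[grp.index].sum()),
                                               len(grp)),
            }
        # between-copy expression divergence, WT vs mutant
        dv_w = expr.expression_divergence(reduced, summary, "wt", cfg.pseudocount)
        dv_m = expr.expression_divergence(reduced, summary, "mut", cfg.pseudocount)
        div_tests = {}
        for cat, grp in list(reduced.groupby("category")) + [("ALL", reduced)]:
            w, m = dv_w.loc[grp.index].dropna(), dv_m.loc[grp.index].dropna()
            ks = compare_distributions(w, m) if len(w) >= 3 and len(m) >= 3 else None
            div_tests[cat] = None if ks is None else {
                "statistic": ks.statistic, "pvalue": ks.pvalue,
                "mean_wt": float(w.mean()), "mean_mut": float(m.mean()),
                "reduced": bool(m.mean() < w.mean()),
            }
        # between-copy correlation per genotype (log2 scale)
        corr = {}
        for genotype in ("wt", "mut"):
            s = summary.xs(genotype, level="genotype")["mean_fpkm"]
            fa = np.log2(s.reindex(reduced["gene_a"]).to_numpy() + cfg.pseudocount)
            fb = np.log2(s.reindex(reduced["gene_b"]).to_numpy() + cfg.pseudocount)
            if len(fa) >= 4:
                c = correlate(fa, fb)
                corr[genotype] = {"r": c.r, "pvalue": c.pvalue,
                                  "ci": [c.ci_low, c.ci_high], "n": c.n}
        # expressed-gene counts per genotype among pair genes
        pair_genes = pd.unique(pd.concat([sub["gene_a"], sub["gene_b"]]))
        exp_tab = expressed.reindex(pair_genes).fillna(False)
        table = [
            [int(exp_tab["wt"].sum()), int((~exp_tab["wt"]).sum())],
            [int(exp_tab["mut"].sum()), int((~exp_tab["mut"]).sum())],
        ]
        _odds, fisher_p = contingency_test(table)
        # between-copy DE duplicates per genotype
        de_counts = {}
        for genotype in ("wt", "mut"):
            cc = expr.copy_vs_copy_de(reduced, summary, genotype, alpha=cfg.alpha)
            de_counts[genotype] = int((cc["q"] < cfg.alpha).sum())
        n_w, n_m = de_counts["wt"], de_counts["mut"]
        de_balance_p = (float(_scipy_stats.binomtest(n_w, n_w + n_m, 0.5).pvalue)
                        if (n_w + n_m) else None)
        expr_section[klass] = {
            "pairs": len(sub), "expressed_pairs": len(expressed_pairs),
            "analysis_pairs": len(reduced),
            "per_category": per_cat,
            "divergence_tests": div_tests,
            "between_copy_correlation": corr,
            "expressed_genes_table": {"table": table, "fisher_p": fisher_p},
            "de_duplicates": {"wt": n_w, "mut": n_m, "binomial_p": de_balance_p},
        }
    report.expression = expr_section
    log.append({"stage": "expression",
                "genes_tested_wt_vs_mut": int(len(gene_de)),
                "analysis_pairs_cg_only": len(analysis["CG_only"])})

    # ---- copy dynamics ----------------------------------------------------
    dyn_section = {}
    for klass in METH_CLASSES:
        reduced = analysis[klass]
        if reduced.empty:
            dyn_section[klass] = None
            continue
        roles = dyn.assign_roles(reduced, summary, pseudocount=cfg.pseudocount)
        categorized = dyn.categorize_pairs(roles, gene_de)
        shift = {
            role: dyn.group_shift_test(categorized, role, gene_de, alpha=cfg.alpha)
            for role in ("higher", "lower")
        }
        dyn_section[klass] = {
            "n_pairs": len(categorized),
            "copy_group_shift": shift,
            "taxonomy": dyn.convergence_summary(categorized),
        }
    report.dynamics = dyn_section
    log.append({"stage": "dynamics",
                "pairs_scored": sum(v["n_pairs"] for v in dyn_section.values() if v)})

    # ---- sequence evolution ----------------------------------------------
    if cfg.run_evolution and cds:
        dnds = evo.pair_dnds(cds, partition, max_ds=cfg.max_ds)
        if dnds.empty:
            dnds = pd.DataFrame(columns=["dS", "dN", "dn_ds", "valid"])
        valid = dnds[dnds["valid"].astype(bool)]
        tab = partition.set_index("pair_id").join(valid, how="inner")
        an = None
        if tab["category"].nunique() >= 2 and len(tab) >= 8:
            res = compare_groups_anova(tab["dS"], tab["category"])
            an = {"f": res.f_statistic, "pvalue": res.pvalue, "letters": res.letters}
        pooled = analysis["BCGM_pooled"]
        affected_pooled = expr.flag_affected_pairs(pooled, gene_de, alpha=cfg.alpha)
        strat = evo.stratify_by_affect(dnds, pooled, affected_pooled)
        report.evolution = {
            "pairs_estimated": len(dnds),
            "pairs_valid": len(valid),
            "excluded_ds_gt_max": int((~dnds["valid"].astype(bool)).sum()),
            "ds_by_category": {
                cat: {"n": len(g), "median_ds": float(g["dS"].median())}
                for cat, g in tab.groupby("category")
            },
            "ds_anova": an,
            "affect_stratification": strat,
        }
        log.append({"stage": "evolution", "pairs": len(dnds), "valid": len(valid)})

    # ---- outputs ----------------------------------------------------------
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        partition.drop(columns=["slots"], errors="ignore").to_csv(
            out / "pairs.tsv", sep="\t", index=False)
        report.to_json(out / "report.json")
        with open(out / "stages.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(_plain(entry)) + "\n")
    return report
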