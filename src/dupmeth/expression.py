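"""Expression thresholds, exact count tests, and between-copy divergence.

Differential expression (both copy-vs-copy within a genotype and
WT-vs-mutant per copy) uses the exact conditional binomial test on pooled
replicate counts: given the total t = a + b, a ~ Bin(t, lib_a/(lib_a+lib_b))
under the null of equal relative expression.  Two-sided p-values follow the
double one-sided tail convention, capped at 1; q-values are BH-adjusted
across the tested family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, binom_two_sided

__all__ = [
    "summarize_expression",
    "call_expressed",
    "retained_pairs",
    "exact_count_test",
    "copy_vs_copy_de",
    "wt_vs_mut_de",
    "expression_divergence",
    "flag_affected_pairs",
]


def summarize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Pool replicates: per (gene, genotype) mean FPKM, summed counts and
    summed library sizes."""
    grp = expr.groupby(["gene_id", "genotype"])
    return grp.agg(
        mean_fpkm=("fpkm", "mean"),
        total_count=("count", "sum"),
        total_library=("library_size", "sum"),
        n_replicates=("replicate", "size"),
    )


def call_expressed(summary: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Gene x genotype expressed flags (mean FPKM strictly above threshold)."""
    flags = (summary["mean_fpkm"] > threshold).unstack("genotype")
    return flags


def retained_pairs(pairs: pd.DataFrame, expressed: pd.DataFrame) -> pd.Series:
    """Pair retained iff at least one copy is expressed in at least one
    genotype.  Genes absent from the table count as not expressed."""
    any_expr = expressed.any(axis=1)
    ea = any_expr.reindex(pairs["gene_a"]).fillna(False).to_numpy()
    eb = any_expr.reindex(pairs["gene_b"]).fillna(False).to_numpy()
    return pd.Series(ea | eb, index=pairs.index, name="retained")


def exact_count_test(counts_a, counts_b, lib_a, lib_b):
    """Exact conditional binomial test for two pooled counts.

    Returns (p, log2_fold_change) where the fold change is of library-
    normalised rates b over a.  Vectorized over array inputs.  Zero totals
    give p = NaN (no test).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    la = np.asarray(lib_a, dtype=float)
    lb = np.asarray(lib_b, dtype=float)
    t = a + b
    pi = la / (la + lb)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = binom_two_sided(a, t, p=pi)
        p = np.where(t > 0, p, np.nan)
        lfc = np.log2((b / lb) / (a / la))
    return p, lfc


def _de_frame(index, counts_a, counts_b, lib_a, lib_b, alpha: float) -> pd.DataFrame:
    p, lfc = exact_count_test(counts_a, counts_b, lib_a, lib_b)
    tested = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    q[tested] = bh_adjust(p[tested])
    sig = q < alpha
    direction = np.where(
        ~tested | ~sig, "none", np.where(np.asarray(lfc) > 0, "up", "down")
    )
    return pd.DataFrame({
        "p": p, "q": q, "log2_fold_change": lfc, "direction": direction,
    }, index=index)


def copy_vs_copy_de(
    pairs: pd.DataFrame,
    summary: pd.DataFrame,
    genotype: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-copy differential expression within one genotype.

    ``direction`` is ``up`` when copy b (gene_b) exceeds copy a after
    library normalisation.  Indexed like ``pairs``.
    """
    s = summary.xs(genotype, level="genotype")
    ca = s["total_count"].reindex(pairs["gene_a"]).to_numpy()
    cb = s["total_count"].reindex(pairs["gene_b"]).to_numpy()
    la = s["total_library"].reindex(pairs["gene_a"]).to_numpy()
    lb = s["total_library"].reindex(pairs["gene_b"]).to_numpy()
    return _de_frame(pairs.index, ca, cb, la, lb, alpha)


def wt_vs_mut_de(
    gene_ids,
    summary: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene WT-vs-mutant differential expression (exact count test on
    pooled counts; stand-in for an isoform-model DE caller).

    ``direction`` is ``up`` when the mutant is higher.
    """
    wt = summary.xs("wt", level="genotype")
    mut = summary.xs("mut", level="genotype")
    gene_ids = pd.Index(gene_ids)
    cw = wt["total_count"].reindex(gene_ids).to_numpy()
    cm = mut["total_count"].reindex(gene_ids).to_numpy()
    lw = wt["total_library"].reindex(gene_ids).to_numpy()
    lm = mut["total_library"].reindex(gene_ids).to_numpy()
    return _de_frame(gene_ids, cw, cm, lw, lm, alpha)


def expression_divergence(
    pairs: pd.DataFrame,
    summary: pd.DataFrame,
    genotype: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Absolute log2 between-copy FPKM ratio (pseudocount-guarded)."""
    s = summary.xs(genotype, level="genotype")["mean_fpkm"]
    fa = s.reindex(pairs["gene_a"]).to_numpy()
    fb = s.reindex(pairs["gene_b"]).to_numpy()
    div = np.abs(np.log2((fa + pseudocount) / (fb + pseudocount)))
    return pd.Series(div, index=pairs.index, name="expression_divergence")


def flag_affected_pairs(
    pairs: pd.DataFrame,
    gene_de: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Pair is expression-affected iff at least one copy changed
    significantly between WT and mutant (q < alpha)."""
    sig = set(gene_de.index[gene_de["q"] < alpha])
    return pd.Series(
        [a in sig or b in sig for a, b in zip(pairs["gene_a"], pairs["gene_b"])],
        index=pairs.index, name="affected",
    )
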