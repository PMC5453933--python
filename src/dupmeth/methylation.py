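"""Gene-body methylation levels, body-methylation calling, and
WT-vs-mutant differential methylation.

The body methylation level of a gene in a context is the pooled-read
("weighted") level: total methylated reads over total reads across all
covered cytosines inside the annotated gene span (both strands).  A gene is
called *body-methylated* in a context by a binomial test of its methylated-
site count against the genome background rate (the pooled proportion of
methylated sites over all non-TE gene bodies).  Following the convention
that a gene is body-methylated unless its level is *significantly lower*
than background, the default test is lower-tailed and a gene is flagged
when its BH-adjusted q-value is >= alpha; an upper-tail enrichment mode is
available behind ``mode="enriched"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .catalog import GeneCatalog
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundRates",
    "annotate_sites",
    "compute_body_levels",
    "call_methylated_sites",
    "compute_background",
    "classify_body_methylation",
    "partition_pairs",
    "test_differential_methylation",
    "pair_bcgm_reduction",
    "bcgm_divergence",
]

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class BackgroundRates:
    """Genome-background methylated-site proportions per context."""

    rates: dict            # context -> proportion in [0, 1] (or nan if undefined)
    covered_sites: dict    # context -> number of covered sites pooled

    def rate(self, context: str) -> float:
        return self.rates.get(context, float("nan"))


def annotate_sites(calls: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """Assign each cytosine to the gene body containing it.

    Sites outside any gene are dropped.  A site landing in several
    overlapping genes is counted once per gene.
    """
    if calls.empty or len(catalog) == 0:
        return calls.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    g = catalog.genes
    genes_gr = pr.PyRanges(pd.DataFrame({
        "Chromosome": g["chrom"].to_numpy(),
        "Start": g["start"].to_numpy() - 1,   # to 0-based half-open
        "End": g["end"].to_numpy(),
        "gene_id": g.index.to_numpy(),
    }))
    sites = calls.reset_index(drop=True)
    sites_gr = pr.PyRanges(pd.DataFrame({
        "Chromosome": sites["chrom"].to_numpy(),
        "Start": sites["pos"].to_numpy() - 1,
        "End": sites["pos"].to_numpy(),
        "site_idx": sites.index.to_numpy(),
    }))
    joined = sites_gr.join(genes_gr).df
    if joined.empty:
        return calls.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    out = sites.loc[joined["site_idx"].to_numpy()].copy()
    out["gene_id"] = joined["gene_id"].to_numpy()
    return out.reset_index(drop=True)


def compute_body_levels(
    calls: pd.DataFrame,
    catalog: GeneCatalog,
    min_reads: int = 4,
) -> pd.DataFrame:
    """Aggregate per-gene, per-context body methylation.

    Sites with fewer than ``min_reads`` total reads are excluded.  Returns a
    DataFrame indexed by (gene_id, context) with ``n_covered_sites,
    total_meth_reads, total_reads, body_level``.  Genes with no covered
    sites in a context are simply absent (undefined level, distinct from 0).
    """
    annotated = calls if "gene_id" in calls.columns else annotate_sites(calls, catalog)
    if annotated.empty:
        return pd.DataFrame(
            columns=["n_covered_sites", "total_meth_reads", "total_reads", "body_level"],
            index=pd.MultiIndex.from_arrays([[], []], names=["gene_id", "context"]),
        )
    total = annotated["count_methylated"] + annotated["count_unmethylated"]
    kept = annotated[total >= min_reads]
    grp = kept.groupby(["gene_id", "context"])
    out = grp.agg(
        n_covered_sites=("count_methylated", "size"),
        total_meth_reads=("count_methylated", "sum"),
        total_unmeth_reads=("count_unmethylated", "sum"),
    )
    out["total_reads"] = out["total_meth_reads"] + out["total_unmeth_reads"]
    out["body_level"] = out["total_meth_reads"] / out["total_reads"]
    return out.drop(columns=["total_unmeth_reads"])


def call_methylated_sites(
    calls: pd.DataFrame,
    error_rate: float = 0.005,
    alpha: float = 0.01,
    min_reads: int = 4,
) -> pd.DataFrame:
    """Flag individual cytosines as methylated.

    A covered site is methylated when the one-sided binomial tail
    P(X >= count_methylated | n = total reads, p = error_rate) is below
    ``alpha``; ``error_rate`` stands for bisulfite non-conversion plus
    sequencing error.  Sites below the coverage filter are dropped.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie strictly between 0 and 1")
    total = calls["count_methylated"] + calls["count_unmethylated"]
    kept = calls[total >= min_reads].copy()
    n = (kept["count_methylated"] + kept["count_unmethylated"]).to_numpy()
    k = kept["count_methylated"].to_numpy()
    pvals = stats.binom.sf(k - 1, n, error_rate)
    kept["site_methylated"] = pvals < alpha
    return kept


def compute_background(site_calls: pd.DataFrame, catalog: GeneCatalog) -> BackgroundRates:
    """Pooled methylated-site proportion per context over non-TE gene bodies.

    ``site_calls`` must carry ``gene_id`` and ``site_methylated`` (from
    :func:`annotate_sites` + :func:`call_methylated_sites`).
    """
    non_te = set(catalog.non_te_ids())
    sub = site_calls[site_calls["gene_id"].isin(non_te)]
    rates, covered = {}, {}
    for c in CONTEXTS:
        s = sub[sub["context"] == c]
        covered[c] = int(len(s))
        if len(s) == 0:
            rates[c] = float("nan")
            logger.warning("no covered %s sites in non-TE gene bodies; "
                           "background undefined", c)
        else:
            rates[c] = float(s["site_methylated"].mean())
    return BackgroundRates(rates=rates, covered_sites=covered)


def classify_body_methylation(
    site_calls: pd.DataFrame,
    rates: BackgroundRates,
    alpha: float = 0.05,
    min_sites: int = 5,
    mode: str = "not_lower",
) -> pd.DataFrame:
    """Per-gene, per-context body-methylation status.

    For each gene with at least ``min_sites`` covered sites in a context,
    the number of methylated sites k among n covered sites is tested against
    the background rate.  ``mode="not_lower"`` (default): lower-tail
    p = P(Bin(n, p_ctx) <= k); after BH adjustment across genes the gene is
    body-methylated iff q >= alpha (its level is *not* significantly lower
    than background).  ``mode="enriched"``: upper-tail test, body-methylated
    iff q < alpha.

    Returns a DataFrame indexed by (gene_id, context) with columns
    ``n_sites, n_methylated, p, q, body_methylated``.
    """
    if mode not in ("not_lower", "enriched"):
        raise ValueError(f"unknown mode {mode!r}")
    grp = site_calls.groupby(["gene_id", "context"])
    tab = grp.agg(n_sites=("site_methylated", "size"),
                  n_methylated=("site_methylated", "sum"))
    tab = tab[tab["n_sites"] >= min_sites].copy()
    frames = []
    for c in CONTEXTS:
        p_bg = rates.rate(c)
        sub = tab[tab.index.get_level_values("context") == c].copy()
        if sub.empty:
            continue
        if np.isnan(p_bg):
            logger.warning("background rate for %s undefined; statuses skipped", c)
            continue
        n = sub["n_sites"].to_numpy()
        k = sub["n_methylated"].to_numpy()
        if mode == "not_lower":
            p = stats.binom.cdf(k, n, p_bg)
            sub["p"] = p
            sub["q"] = bh_adjust(p)
            sub["body_methylated"] = sub["q"] >= alpha
        else:
            p = stats.binom.sf(k - 1, n, p_bg)
            sub["p"] = p
            sub["q"] = bh_adjust(p)
            sub["body_methylated"] = sub["q"] < alpha
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["n_sites", "n_methylated", "p", "q", "body_methylated"],
            index=pd.MultiIndex.from_arrays([[], []], names=["gene_id", "context"]),
        )
    return pd.concat(frames).sort_index()


def partition_pairs(pairs: pd.DataFrame, statuses: pd.DataFrame) -> pd.DataFrame:
    """Partition duplicate pairs by body-methylation context class.

    Classes: ``CG_only`` (at least one copy body-CG-methylated, neither copy
    body-CHG- nor body-CHH-methylated), ``all_context`` (at least one copy
    body-CG-methylated plus non-CG body methylation in either copy), and
    ``unmethylated`` (no body-CG-methylated copy).  Pairs with a copy whose
    status is undefined in any context are excluded (class ``excluded``).
    """
    flags = statuses["body_methylated"].unstack("context")
    out = []
    for r in pairs.itertuples():
        klass = "excluded"
        if r.gene_a in flags.index and r.gene_b in flags.index:
            fa, fb = flags.loc[r.gene_a], flags.loc[r.gene_b]
            if not (fa.isna().any() or fb.isna().any()) and \
                    set(flags.columns) >= set(CONTEXTS):
                bcgm = bool(fa["CG"] or fb["CG"])
                non_cg = bool(fa["CHG"] or fb["CHG"] or fa["CHH"] or fb["CHH"])
                if not bcgm:
                    klass = "unmethylated"
                elif non_cg:
                    klass = "all_context"
                else:
                    klass = "CG_only"
        if klass == "excluded":
            logger.debug("pair %s excluded: missing body-methylation status",
                         getattr(r, "pair_id", f"{r.gene_a}/{r.gene_b}"))
        out.append(klass)
    res = pairs.copy()
    res["meth_class"] = out
    return res


def test_differential_methylation(
    profiles_wt: pd.DataFrame,
    profiles_mut: pd.DataFrame,
    context: str = "CG",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Fisher's exact test of pooled body counts, WT vs mutant.

    The 2x2 table is [methylated reads, unmethylated reads] x [WT, mutant]
    pooled over the gene's covered body sites.  Returns a DataFrame indexed
    by gene_id with ``p, q, level_wt, level_mut, direction`` where direction
    is ``loss``/``gain`` when q < alpha and ``none`` otherwise.
    """
    wt = profiles_wt.xs(context, level="context")
    mut = profiles_mut.xs(context, level="context")
    common = wt.index.intersection(mut.index)
    wt, mut = wt.loc[common], mut.loc[common]
    usable = (wt["total_reads"] > 0) & (mut["total_reads"] > 0)
    wt, mut = wt[usable], mut[usable]
    pvals = np.empty(len(wt))
    for i, gid in enumerate(wt.index):
        table = [
            [int(wt.at[gid, "total_meth_reads"]),
             int(wt.at[gid, "total_reads"] - wt.at[gid, "total_meth_reads"])],
            [int(mut.at[gid, "total_meth_reads"]),
             int(mut.at[gid, "total_reads"] - mut.at[gid, "total_meth_reads"])],
        ]
        pvals[i] = stats.fisher_exact(table)[1]
    out = pd.DataFrame({
        "p": pvals,
        "q": bh_adjust(pvals),
        "level_wt": wt["body_level"].to_numpy(),
        "level_mut": mut["body_level"].to_numpy(),
    }, index=wt.index)
    sig = out["q"] < alpha
    out["direction"] = np.where(
        ~sig, "none", np.where(out["level_mut"] < out["level_wt"], "loss", "gain")
    )
    return out


def pair_bcgm_reduction(pairs: pd.DataFrame, gene_dm: pd.DataFrame) -> pd.Series:
    """Pair-level flag: significantly reduced body CG methylation in the
    mutant in at least one copy."""
    loss = gene_dm.index[gene_dm["direction"] == "loss"]
    loss = set(loss)
    return pd.Series(
        [a in loss or b in loss for a, b in zip(pairs["gene_a"], pairs["gene_b"])],
        index=pairs.index, name="bcgm_reduced",
    )


def bcgm_divergence(
    pairs: pd.DataFrame,
    profiles: pd.DataFrame,
    context: str = "CG",
) -> pd.Series:
    """Absolute between-copy difference in body methylation level.

    Pairs with an undefined level in either copy get NaN (excluded from
    downstream comparisons).
    """
    levels = profiles.xs(context, level="context")["body_level"]
    la = levels.reindex(pairs["gene_a"]).to_numpy()
    lb = levels.reindex(pairs["gene_b"]).to_numpy()
    return pd.Series(np.abs(la - lb), index=pairs.index, name="bcgm_divergence")
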