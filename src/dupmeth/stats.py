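"""Cross-cutting statistical kernels used throughout the pipeline.

Thin, well-specified wrappers over scipy/statsmodels: two-sample
Kolmogorov-Smirnov, one-way ANOVA with Tukey HSD and a compact letter
display, Pearson correlation with a Fisher-z confidence interval,
contingency tests, BH (FDR) adjustment, and the double-tail exact binomial
convention used by the count tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "binom_two_sided",
    "compare_distributions",
    "compare_groups_anova",
    "correlate",
    "contingency_test",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def binom_two_sided(k, n, p: float = 0.5):
    """Two-sided exact binomial p-value by the double one-sided tail
    convention: p = min(1, 2 * min(P(X <= k), P(X >= k))).

    Accepts scalars or arrays; returns the same shape.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_x: int
    n_y: int


def compare_distributions(x, y, method: str = "KS") -> KSResult:
    """Two-sample distribution comparison (Kolmogorov-Smirnov).

    Uses scipy's size-dependent exact/asymptotic p-value rule.  Samples
    smaller than 3 are refused with a warning (None returned).
    """
    if method != "KS":
        raise ValueError(f"unsupported method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        logger.warning("K-S test skipped: sample sizes %d, %d < 3", len(x), len(y))
        return None
    res = stats.ks_2samp(x, y)
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    n_x=len(x), n_y=len(y))


@dataclass
class AnovaResult:
    f_statistic: float
    pvalue: float
    letters: dict  # group -> compact-letter-display string
    tukey: object | None


def _compact_letters(groups, not_different: set) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Letters are the maximal cliques of the non-significance
    graph, lettered in order of the smallest group mean they contain."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(not_different)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: min(groups.index(m) for m in c))
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for member in clique:
            letters[member] += ch
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def compare_groups_anova(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD with a compact letter display.

    ``values``/``groups`` are parallel sequences.  Groups sharing a letter
    are not significantly different at ``alpha`` by Tukey HSD.  With
    degenerate (zero) variance everywhere, all groups share one letter.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    samples = [values[groups == g] for g in names]
    if len(names) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    order = np.argsort([s.mean() for s in samples])
    names_by_mean = [names[i] for i in order]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        logger.warning("degenerate variance: all observations identical")
        return AnovaResult(np.nan, 1.0, {g: "a" for g in names}, None)
    f, p = stats.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    not_diff = set()
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, reject = row[0], row[1], row[-1]
        if not reject:
            not_diff.add((g1, g2))
    letters = _compact_letters(names_by_mean, not_diff)
    return AnovaResult(float(f), float(p), letters, tukey)


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    ci_low: float
    ci_high: float
    n: int


def correlate(x, y, ci: float = 0.95) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("correlation needs at least 4 finite paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, len(x))
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(len(x) - 3)
    zcrit = stats.norm.ppf(0.5 + ci / 2.0)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(float(r), float(p), float(lo), float(hi), len(x))


def contingency_test(table):
    """Exact or asymptotic independence test for a contingency table.

    2x2 tables get Fisher's exact test; larger tables fall back to the
    chi-square test of independence (documented approximation).  Returns
    (statistic, pvalue).
    """
    t = np.asarray(table)
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if t.shape == (2, 2):
        odds, p = stats.fisher_exact(t)
        return float(odds), float(p)
    chi2, p, _dof, _exp = stats.chi2_contingency(t)
    return float(chi2), float(p)
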