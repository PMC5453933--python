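"""Higher/lower copy-group dynamics and the 10-group change taxonomy.

For every duplicate pair the copy with the larger wild-type expression is
the *higher* copy and the other the *lower* copy; roles are frozen from WT
even if the ranking inverts in the mutant.  Each copy's WT-to-mutant change
is a direction (up/down/none, from the per-gene differential-expression
q-value) and a magnitude (|log2 fold change|).  Pairs in which at least one
copy changed are scored into ten mutually exclusive codes which partition
into five *convergent* patterns (the change reduces the between-copy
expression difference) and five *divergent* ones (it augments it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CODES",
    "CONVERGENT",
    "DIVERGENT",
    "CONJUGATE_PAIRS",
    "assign_roles",
    "categorize",
    "categorize_pairs",
    "group_shift_test",
    "convergence_summary",
]

#: the ten change codes, in canonical order (groups i..x)
CODES = (
    "NH/UL", "NH/DL", "DH/NL", "UH/NL", "UH<UL",
    "UH>UL", "DH>DL", "DH<DL", "DH/UL", "UH/DL",
)
CONVERGENT = frozenset({"NH/UL", "DH/NL", "UH<UL", "DH>DL", "DH/UL"})
DIVERGENT = frozenset({"NH/DL", "UH/NL", "UH>UL", "DH<DL", "UH/DL"})
#: convergent/divergent code pairs tested against each other
CONJUGATE_PAIRS = (
    ("NH/UL", "NH/DL"), ("DH/NL", "UH/NL"), ("UH<UL", "UH>UL"),
    ("DH>DL", "DH<DL"), ("DH/UL", "UH/DL"),
)
ONE_COPY_CODES = frozenset({"NH/UL", "NH/DL", "DH/NL", "UH/NL"})


def assign_roles(
    pairs: pd.DataFrame,
    summary: pd.DataFrame,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Designate the higher- and lower-expressed copy of each pair in WT.

    Exact FPKM ties are broken by lexicographic gene id (the smaller id
    becomes the higher copy) and flagged.  Returns ``pairs`` plus columns
    ``higher, lower, role_tie``.
    """
    wt = summary.xs("wt", level="genotype")["mean_fpkm"]
    fa = wt.reindex(pairs["gene_a"]).to_numpy() + pseudocount
    fb = wt.reindex(pairs["gene_b"]).to_numpy() + pseudocount
    out = pairs.copy()
    tie = fa == fb
    a_higher = (fa > fb) | tie  # gene_a is lexicographically smaller by convention
    out["higher"] = np.where(a_higher, pairs["gene_a"], pairs["gene_b"])
    out["lower"] = np.where(a_higher, pairs["gene_b"], pairs["gene_a"])
    out["role_tie"] = tie
    return out


def categorize(dir_h: str, dir_l: str, mag_h: float, mag_l: float):
    """Map one pair's per-copy change (direction, magnitude) to its code.

    Returns (code, tie_flag) or (None, False) when neither copy changed.
    Same-direction pairs with exactly equal magnitudes are assigned to the
    convergent member of the code pair and tie-flagged.
    """
    if dir_h == "none" and dir_l == "none":
        return None, False
    if dir_h == "none":
        return ("NH/UL" if dir_l == "up" else "NH/DL"), False
    if dir_l == "none":
        return ("DH/NL" if dir_h == "down" else "UH/NL"), False
    if dir_h == "up" and dir_l == "up":
        if mag_h == mag_l:
            return "UH<UL", True
        return ("UH<UL" if mag_h < mag_l else "UH>UL"), False
    if dir_h == "down" and dir_l == "down":
        if mag_h == mag_l:
            return "DH>DL", True
        return ("DH>DL" if mag_h > mag_l else "DH<DL"), False
    if dir_h == "down" and dir_l == "up":
        return "DH/UL", False
    return "UH/DL", False


def categorize_pairs(roles: pd.DataFrame, gene_de: pd.DataFrame) -> pd.DataFrame:
    """Score every pair's WT-to-mutant change pattern.

    ``gene_de`` is the per-gene WT-vs-mutant differential-expression table
    (columns ``direction, log2_fold_change``).  Returns ``roles`` plus
    ``dir_higher, dir_lower, mag_higher, mag_lower, code, klass,
    magnitude_tie``; pairs with no changed copy get code None / klass
    ``unchanged``.
    """
    missing = (set(roles["higher"]) | set(roles["lower"])) - set(gene_de.index)
    if missing:
        raise ValueError(
            f"pairs reference genes without DE results: {sorted(missing)[:10]}"
        )
    dir_h = gene_de["direction"].reindex(roles["higher"]).to_numpy()
    dir_l = gene_de["direction"].reindex(roles["lower"]).to_numpy()
    mag_h = np.abs(gene_de["log2_fold_change"].reindex(roles["higher"]).to_numpy())
    mag_l = np.abs(gene_de["log2_fold_change"].reindex(roles["lower"]).to_numpy())
    codes, ties = [], []
    for dh, dl, mh, ml in zip(dir_h, dir_l, mag_h, mag_l):
        code, tie = categorize(dh, dl, mh, ml)
        codes.append(code)
        ties.append(tie)
    out = roles.copy()
    out["dir_higher"] = dir_h
    out["dir_lower"] = dir_l
    out["mag_higher"] = mag_h
    out["mag_lower"] = mag_l
    out["code"] = codes
    out["magnitude_tie"] = ties
    out["klass"] = [
        "unchanged" if c is None else ("convergent" if c in CONVERGENT else "divergent")
        for c in codes
    ]
    return out


def group_shift_test(categorized: pd.DataFrame, role: str, gene_de: pd.DataFrame,
                     alpha: float = 0.05) -> dict:
    """Up vs down counts in one copy-group, with an exact binomial test
    against equal probability.

    ``role`` is ``"higher"`` or ``"lower"``.  Only copies with a directional
    change count.  Returns {'n_up', 'n_down', 'pvalue'} (pvalue None when
    no copy changed).
    """
    if role not in ("higher", "lower"):
        raise ValueError("role must be 'higher' or 'lower'")
    dirs = gene_de["direction"].reindex(categorized[role])
    n_up = int((dirs == "up").sum())
    n_down = int((dirs == "down").sum())
    n = n_up + n_down
    p = float(stats.binomtest(n_up, n, 0.5).pvalue) if n > 0 else None
    return {"n_up": n_up, "n_down": n_down, "pvalue": p}


def convergence_summary(categorized: pd.DataFrame) -> dict:
    """Counts per code plus the group-level exact binomial tests.

    Tests: each convergent code against its divergent conjugate, the
    one-copy-changed total (codes i-iv) against the both-copies-changed
    total (codes v-x), and convergent against divergent overall.
    """
    changed = categorized[categorized["code"].notna()]
    counts = {c: int((changed["code"] == c).sum()) for c in CODES}

    def btest(k, n):
        return float(stats.binomtest(k, n, 0.5).pvalue) if n > 0 else None

    conjugate_tests = {}
    for conv, div in CONJUGATE_PAIRS:
        n = counts[conv] + counts[div]
        conjugate_tests[f"{conv} vs {div}"] = {
            "convergent": counts[conv], "divergent": counts[div],
            "pvalue": btest(counts[conv], n),
        }
    n_conv = sum(counts[c] for c in CODES if c in CONVERGENT)
    n_div = sum(counts[c] for c in CODES if c in DIVERGENT)
    n_one = sum(counts[c] for c in CODES if c in ONE_COPY_CODES)
    n_both = sum(counts[c] for c in CODES if c not in ONE_COPY_CODES)
    return {
        "counts": counts,
        "conjugate_tests": conjugate_tests,
        "n_convergent": n_conv,
        "n_divergent": n_div,
        "convergent_vs_divergent_p": btest(n_conv, n_conv + n_div),
        "n_one_copy_changed": n_one,
        "n_both_copies_changed": n_both,
        "one_vs_both_p": btest(n_one, n_one + n_both),
    }
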