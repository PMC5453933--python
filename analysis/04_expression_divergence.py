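#!/usr/bin/env python
"""Expression: thresholds, differential expression, between-copy divergence.

Restricts to methylated (CG-only or all-context) pairs that are expressed
(FPKM > 0.1 in at least one genotype) and lost body CG methylation in at
least one copy; runs the exact conditional count test WT-vs-mutant per copy
and copy-vs-copy per genotype; compares between-copy expression divergence
(|log2 ratio|) of WT and mutant; reports the between-copy Pearson
correlation per genotype.  Writes tables under results/expression/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dupmeth import expression as expr
from dupmeth import io as dio
from dupmeth.stats import compare_distributions, contingency_test, correlate

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "expression"


def main() -> None:
    table = dio.read_expression_table(BASE / "simdata" / "expression.tsv")
    part = pd.read_csv(BASE / "methylation" / "pair_methylation.tsv", sep="\t")
    summary = expr.summarize_expression(table)

    expressed = expr.call_expressed(summary)
    part["retained"] = expr.retained_pairs(part, expressed)
    analysis = part[
        part["meth_class"].isin(["CG_only", "all_context"])
        & part["retained"] & part["bcgm_reduced"]
    ].copy()
    print(f"analysis set: {len(analysis)} expressed, BCGM-reduced methylated pairs")

    genes = pd.unique(pd.concat([analysis["gene_a"], analysis["gene_b"]]))
    gene_de = expr.wt_vs_mut_de(genes, summary)
    analysis["affected"] = expr.flag_affected_pairs(analysis, gene_de)
    for cat, sub in analysis.groupby("category"):
        print(f"  {cat}: {sub['affected'].mean() * 100:.1f}% expression-affected")

    analysis["divergence_wt"] = expr.expression_divergence(analysis, summary, "wt")
    analysis["divergence_mut"] = expr.expression_divergence(analysis, summary, "mut")
    ks = compare_distributions(analysis["divergence_wt"], analysis["divergence_mut"])
    print(f"between-copy |log2 FC|: WT {analysis['divergence_wt'].mean():.2f} vs "
          f"mutant {analysis['divergence_mut'].mean():.2f} (K-S p = {ks.pvalue:.2g})")

    for gt in ("wt", "mut"):
        s = summary.xs(gt, level="genotype")["mean_fpkm"]
        fa = np.log2(s.reindex(analysis["gene_a"]).to_numpy() + 0.01)
        fb = np.log2(s.reindex(analysis["gene_b"]).to_numpy() + 0.01)
        c = correlate(fa, fb)
        print(f"between-copy correlation ({gt}): R = {c.r:.2f} "
              f"[{c.ci_low:.2f}, {c.ci_high:.2f}]")

    pair_genes = pd.unique(pd.concat([part["gene_a"], part["gene_b"]]))
    flags = expressed.reindex(pair_genes).fillna(False)
    tab = [[int(flags["wt"].sum()), int((~flags["wt"]).sum())],
           [int(flags["mut"].sum()), int((~flags["mut"]).sum())]]
    _, p = contingency_test(tab)
    print(f"expressed pair-genes WT {tab[0][0]} vs mutant {tab[1][0]} "
          f"(Fisher p = {p:.2g})")

    OUT.mkdir(parents=True, exist_ok=True)
    gene_de.to_csv(OUT / "wt_vs_mut_de.tsv", sep="\t")
    for gt in ("wt", "mut"):
        expr.copy_vs_copy_de(analysis, summary, gt).join(
            analysis[["pair_id"]]).to_csv(OUT / f"copy_de_{gt}.tsv", sep="\t", index=False)
    analysis.to_csv(OUT / "pair_expression.tsv", sep="\t", index=False)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
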