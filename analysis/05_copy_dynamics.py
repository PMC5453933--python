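#!/usr/bin/env python
"""Copy-group dynamics: who goes up, who goes down, and the 10-group
convergent/divergent taxonomy.

Assigns higher/lower roles from WT expression, scores each pair's
WT-to-mutant change pattern, and runs the group-level exact binomial tests.
Writes results/dynamics/pair_categories.tsv and a taxonomy summary table.
"""

from pathlib import Path

import pandas as pd

from dupmeth import dynamics as dyn
from dupmeth import expression as expr
from dupmeth import io as dio

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "dynamics"


def main() -> None:
    table = dio.read_expression_table(BASE / "simdata" / "expression.tsv")
    analysis = pd.read_csv(BASE / "expression" / "pair_expression.tsv", sep="\t")
    gene_de = pd.read_csv(BASE / "expression" / "wt_vs_mut_de.tsv", sep="\t",
                          index_col=0)
    summary = expr.summarize_expression(table)

    roles = dyn.assign_roles(analysis, summary)
    categorized = dyn.categorize_pairs(roles, gene_de)

    for role in ("higher", "lower"):
        res = dyn.group_shift_test(categorized, role, gene_de)
        print(f"{role}-expression copy-group: {res['n_up']} up / "
              f"{res['n_down']} down (binomial p = {res['pvalue']:.3g})")

    summary_tax = dyn.convergence_summary(categorized)
    print("counts per code:", summary_tax["counts"])
    print(f"convergent {summary_tax['n_convergent']} vs divergent "
          f"{summary_tax['n_divergent']} "
          f"(p = {summary_tax['convergent_vs_divergent_p']:.3g})")
    print(f"one-copy-only {summary_tax['n_one_copy_changed']} vs both-copy "
          f"{summary_tax['n_both_copies_changed']} "
          f"(p = {summary_tax['one_vs_both_p']:.3g})")

    OUT.mkdir(parents=True, exist_ok=True)
    categorized.to_csv(OUT / "pair_categories.tsv", sep="\t", index=False)
    rows = [{"code": c, "class": "convergent" if c in dyn.CONVERGENT else "divergent",
             "n_pairs": summary_tax["counts"][c]} for c in dyn.CODES]
    pd.DataFrame(rows).to_csv(OUT / "taxonomy_summary.tsv", sep="\t", index=False)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
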