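#!/usr/bin/env python
"""Duplicate age (dS) and selective constraint (dN/dS) by NG86.

Aligns each pair's coding sequences (protein-guided), estimates dS and dN
(Nei-Gojobori with Jukes-Cantor correction, dS > 3 excluded), compares dS
distributions across duplication categories (ANOVA + Tukey letters), and
tests whether expression-affected and -unaffected pairs differ in dS or
dN/dS (K-S per category).  Writes results/evolution/dnds.tsv.
"""

from pathlib import Path

import pandas as pd

from dupmeth import evolution as evo
from dupmeth import io as dio
from dupmeth.stats import compare_groups_anova

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "evolution"


def main() -> None:
    cds = dio.read_cds_fasta(BASE / "simdata" / "cds_pairs.fasta")
    analysis = pd.read_csv(BASE / "expression" / "pair_expression.tsv", sep="\t")

    dnds = evo.pair_dnds(cds, analysis)
    valid = dnds[dnds["valid"].astype(bool)]
    print(f"{len(valid)}/{len(dnds)} pairs with usable estimates (dS <= 3)")

    tab = analysis.set_index("pair_id").join(valid, how="inner")
    res = compare_groups_anova(tab["dS"], tab["category"])
    print(f"dS across categories: F = {res.f_statistic:.1f}, "
          f"p = {res.pvalue:.2g}, letters = {res.letters}")
    print(tab.groupby("category")["dS"].median().round(3).to_string())

    strat = evo.stratify_by_affect(dnds, analysis, analysis["affected"])
    for cat, entry in strat.items():
        ds_p = entry["ds_ks"]["pvalue"] if entry["ds_ks"] else None
        dn_p = entry["dnds_ks"]["pvalue"] if entry["dnds_ks"] else None
        print(f"  {cat}: affected {entry['n_affected']} vs unaffected "
              f"{entry['n_unaffected']}; dS K-S p = {ds_p}, dN/dS K-S p = {dn_p}")

    OUT.mkdir(parents=True, exist_ok=True)
    dnds.to_csv(OUT / "dnds.tsv", sep="\t")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
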