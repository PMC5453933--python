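#!/usr/bin/env python
"""Generate the reference synthetic study and write its data files.

Produces, under results/simdata/: the gene annotation (GFF3), the all-vs-all
homology table (BLAST outfmt 6), per-cytosine methylation reports for WT and
the CG-methyltransferase mutant, replicate-level expression tables, paired
coding sequences, and the ground truth (JSON).  Downstream scripts (02-06)
consume these files exactly as they would consume real data.
"""

from pathlib import Path

from dupmeth import SimulationConfig
from dupmeth import io as dio
from dupmeth.simulate import generate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    catalog, truth, hits, cx_wt, cx_mut, expr, cds = generate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    dio.write_gff3(catalog, OUT / "annotation.gff3")
    dio.write_blast_tab(hits, OUT / "homology.blast.tsv")
    dio.write_cx_report(cx_wt, OUT / "cx_wt.tsv")
    dio.write_cx_report(cx_mut, OUT / "cx_mut.tsv")
    dio.write_expression_table(expr, OUT / "expression.tsv")
    dio.write_cds_fasta(cds, OUT / "cds_pairs.fasta")
    dio.write_json(truth.to_dict(), OUT / "truth.json")

    n_cat = truth.pairs["category"].value_counts().to_dict()
    print(f"genome: {catalog.genes['chrom'].nunique()} chromosomes, "
          f"{len(catalog)} genes ({int(catalog.genes['is_te'].sum())} TE)")
    print(f"planted pairs: {n_cat}")
    print(f"methylome sites per genotype: {len(cx_wt)}")
    print(f"mutant CG retention: {cfg.cg_retention_mutant} "
          f"(i.e., {100 * (1 - cfg.cg_retention_mutant):.0f}% body CG loss)")
    print(f"wrote study to {OUT}")


if __name__ == "__main__":
    main()
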