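# dupmeth

Gene-body CG methylation (BCGM) and the expression divergence of duplicate
genes, studied through a wild-type / CG-methyltransferase-null contrast.

Rice retains thousands of duplicate gene pairs from whole-genome
duplication (WGD) and from single-gene mechanisms (tandem, proximal,
transposed duplication). The two copies of a pair typically differ in body
CG methylation and in expression, and the open question is whether the
methylation difference *causes* the expression difference. A null mutant of
the major CG methyltransferase — which erases ~91% of gene-body CG
methylation while leaving CHG and CHH contexts untouched — turns this into
a testable perturbation: if BCGM divergence drives expression divergence,
wiping it out should make the copies converge.

`dupmeth` implements that entire analysis as a tested, reusable library
plus a synthetic-data generator with known ground truth, so every stage can
be validated without the original sequencing data:

* **`dupmeth.simulate`** — generates a self-consistent study: annotation
  (GFF3), all-vs-all homology (BLAST outfmt 6), per-cytosine methylation
  reports for both genotypes (Bismark-CX-style), replicate-level expression
  tables, and paired coding sequences with planted substitution counts.
* **`dupmeth.catalog`** — candidate duplicates from homology (top-5 hits,
  E-value < 1e-10), collinear-block detection by gap-bounded monotone
  chaining of rank anchors, and classification into WGD / tandem /
  proximal / transposed.
* **`dupmeth.methylation`** — pooled body methylation levels (sites with
  ≥ 4 reads), binomial body-methylation calls against the genome
  background rate p<sub>cg</sub>, CG-only vs all-context pair classes,
  Fisher-exact WT-vs-mutant tests, between-copy divergence
  |level<sub>A</sub> − level<sub>B</sub>|.
* **`dupmeth.expression`** — FPKM > 0.1 expressed filter, the exact
  conditional count test (a ~ Bin(a+b, lib_a/(lib_a+lib_b))) with BH
  q-values, between-copy divergence |log2(FPKM_A/FPKM_B)|.
* **`dupmeth.dynamics`** — higher/lower expression copy-groups fixed in
  WT, the 10-group change taxonomy (NH/UL … UH/DL) split into convergent
  and divergent classes, and the group-level exact binomial tests.
* **`dupmeth.evolution`** — protein-guided codon alignment and
  Nei–Gojobori (1986) dS/dN with Jukes–Cantor correction and the dS > 3
  exclusion.
* **`dupmeth.pipeline` / `dupmeth.stats`** — end-to-end orchestration and
  the shared statistical kernels (K-S, ANOVA + Tukey letters, Pearson with
  Fisher-z CI, Fisher exact, BH).

## Worked example

The numbered scripts under `analysis/` run the study stepwise over files
(`01` writes the synthetic data; each later step reads the previous ones):

```bash
python analysis/01_simulate.py
python analysis/02_classify_duplicates.py
python analysis/03_body_methylation.py
python analysis/04_expression_divergence.py
python analysis/05_copy_dynamics.py
python analysis/06_sequence_evolution.py
```

Representative output (seed 1, 2,000 planted pairs):

```
planted-category recovery: 2000/2000 (100.0%)
mean gene-body CG level: WT 0.522 -> mutant 0.047
  WGD: between-copy BCGM divergence WT 0.411 vs mutant 0.039 (K-S p = 4.1e-135)
between-copy |log2 FC|: WT 1.69 vs mutant 1.24 (K-S p = 2.4e-14)
between-copy correlation (wt): R = 0.17 [0.13, 0.22]
between-copy correlation (mut): R = 0.40 [0.36, 0.44]
expressed pair-genes WT 3916 vs mutant 3965 (Fisher p = 7e-06)
higher-expression copy-group: 104 up / 766 down (binomial p = 2.39e-125)
lower-expression copy-group: 667 up / 59 down (binomial p = 2.48e-131)
convergent 1167 vs divergent 93 (p = 6.29e-237)
one-copy-only 924 vs both-copy 336 (p = 8.7e-64)
```

Reading: classification recovers every planted duplicate category; the
mutant loses ~91% of gene-body CG methylation and the between-copy BCGM
divergence collapses (0.40 → 0.04); between-copy expression differences
shrink and the copies' expression becomes more correlated; the copy that
was higher-expressed in WT is overwhelmingly down-regulated while the lower
copy is up-regulated; and convergent change patterns dominate divergent
ones — the causal signature the perturbation is designed to expose.

The same pipeline runs over real files (`dupmeth run --config
study.yaml`), with a YAML config pointing at a GFF3, a BLAST table, two
cytosine reports, an expression table and a CDS FASTA; `dupmeth --help`
lists the per-stage subcommands.

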