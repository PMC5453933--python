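# Methods

This note documents the models, defaults and numerical choices behind
`dupmeth`: what the synthetic study emulates, how each statistic is
defined, and where the design was genuinely open.

## The perturbation design

The analysis contrasts a wild type (WT) with an isogenic mutant null for
the major CG methyltransferase. The mutant's defining property is a
near-complete loss of gene-body CG methylation (BCGM) — the generator's
`cg_retention_mutant = 0.09` encodes a 91% loss — with CHG and CHH
methylation unchanged. Because copies of a duplicate pair differ in BCGM
in WT, erasing BCGM removes that difference; if BCGM causally conditions
expression, between-copy expression differences should shrink in the
mutant, with the higher-expressed copy moving down and the lower-expressed
copy moving up.

## Synthetic study generator (`dupmeth.simulate`)

All randomness derives from one master seed; each stage (annotation,
duplicate planting, methylation levels, methylomes, expression, coding
sequences) draws from a named substream (`SeedSequence(seed,
spawn_key=(crc32(name),))`), so adding or re-running a stage never
perturbs the others and identical configs give byte-identical outputs.

**Genome.** 12 chromosomes × 400 genes (gene lengths 1.5–3 kb, gaps
0.2–2 kb, non-overlapping, both strands); 2% of genes are flagged
TE-related and excluded from all duplicate analyses.

**Planted duplicates.** 2,000 pairs split 480 WGD / 880 transposed / 340
proximal / 300 tandem — the pair proportions observed among rice
duplicates, scaled down. WGD pairs are planted as collinear blocks of ~6
consecutive rank anchors across two chromosomes (random orientation);
tandem pairs are rank-adjacent; proximal pairs have rank gaps 2–10;
transposed pairs are cross-chromosome singletons. Each gene belongs to at
most one pair. After planting, block detection is run on the planted
anchors and any tandem/proximal/transposed pair that accidentally chained
into a block is re-placed, so noiseless recovery of every category is
achievable by construction. The homology table contains each planted pair
(both directions, E-value 1e-180–1e-20) plus 2,000 decoy hits between
non-duplicate genes with E-values above the 1e-10 candidate threshold
(`hard_decoys` lowers them below it to stress the classifier).

**Methylomes.** Cytosine sites are placed only inside gene bodies (the
analysis consumes body levels only): per gene 60 CG, 30 CHG and 60 CHH
sites at distinct positions, random strand. 70% of genes are
body-CG-methylated with true levels Beta(8, 3) (mean ≈ 0.73); the rest sit
at 0.005–0.04. 20% of genes additionally carry elevated non-CG methylation
(CHG 0.30, CHH 0.10); basal non-CG levels (0.005 / 0.003) are set near
the site-call error rate, as in real gene bodies, so the
background-binomial classifier can separate the classes. Mutant CG levels
are WT × retention; CHG/CHH are identical across genotypes. Coverage is
Poisson(20) per site (zero-coverage sites are emitted as 0/0) and
methylated counts are Binomial(coverage, level).

**Expression.** Pair copies share a between-pair log2 component (sd 1.0)
plus a within-pair component (sd 1.15), giving a baseline between-copy
correlation ≈ 0.43 on the log2 scale before selection effects. Each copy
responds to BCGM loss with probability 0.5 (`expression_response_prob`);
responding copies shift by `coupling × (CG level lost)` log2 units
(coupling 0.8), negative for the WT-higher copy and positive for the
WT-lower copy, plus N(0, 0.1) noise. The response probability makes
one-copy-only changes the majority outcome, as observed in the real
contrast. 5% of body-methylated lower copies are silenced in WT (0.02
FPKM) and, if they respond, reactivate to their pre-silencing level in the
mutant — this produces the excess of expressed genes in the mutant.
Counts are gamma-Poisson (negative binomial) with dispersion 0.002 per
replicate (2 replicates, library 20 M); FPKM is computed from counts, gene
length and library size. The dispersion default represents
technical-replicate noise: the downstream exact conditional test assumes
Poisson sampling and becomes anticonservative once dispersion × mean is
large (see Limitations).

**Coding sequences.** Each pair gets a 150-codon ancestor of random sense
codons; substitutions are applied sequentially at random positions
(synonymous or nonsynonymous against the current codon, never creating a
stop), with counts chosen to hit a category-specific target dS range (WGD
0.5–0.85, tandem 0.23–0.63, proximal 0.22–0.64, transposed 0.4–1.0) and a
dN/dS ratio of 0.05–0.6 by inverting the Jukes–Cantor correction at the
expected site fractions. Because repeated hits can strike the same site,
realized NG86 estimates run somewhat below the nominal targets; the rank
correlation between planted counts and estimates exceeds 0.9, and the
category ordering (WGD/transposed older than tandem/proximal) is
preserved.

## Duplicate classification (`dupmeth.catalog`)

Candidates: per query, the top 5 subjects by ascending E-value (ties by
descending bitscore, then id), kept only when E-value < 1e-10 (strict);
self-hits and TE genes removed; pairs symmetrized. Collinear blocks:
within each chromosome pair, anchors (rank, rank) are chained by the
longest strictly-monotone chain (both orientations) whose consecutive
anchors differ by ≤ 25 ranks in both coordinates; chains ≥ 5 anchors are
blocks, extracted greedily (longest first, ties to the "same" orientation
and the smaller first rank), each anchor in at most one block. This is a
count-scored simplification of the full synteny-scoring machinery of
MCScanX-style tools — deterministic and oracle-testable, and sufficient
for the categorical outcome the analysis consumes. Same-chromosome anchors
within 25 ranks of the self-comparison diagonal are masked before
chaining, the standard diagonal mask of self-synteny searches; without it,
dense tandem/proximal arrays chain along the diagonal into spurious
blocks. Classification precedence: block anchor → WGD; same chromosome
with rank gap 1 → tandem; gap 2–10 → proximal; otherwise transposed.
(How the original pipeline resolved overlapping assignments is not
stated anywhere we could find; this precedence is our documented choice,
and transposed is defined residually rather than by ancestral-locus
dating.)

## Body methylation (`dupmeth.methylation`)

The gene body is the full annotated span (start..end, strands pooled); a
`cds` body definition is a plausible alternative and is left as future
work. Sites with fewer than 4 total reads are excluded everywhere. The
body level is the pooled-read (weighted) level — total methylated reads
over total reads — not the mean of per-site levels; this matches the
Fisher-test pooling and is robust to uneven coverage. Genes with zero
covered sites in a context have an *undefined* level, distinct from 0.

Site-level methylation calls (needed to define the background proportion)
use a one-sided binomial test against an error rate of 0.005 (bisulfite
non-conversion plus sequencing error) at α = 0.01. The background
p_context is the pooled proportion of methylated covered sites over all
non-TE gene bodies, per context and genotype.

Gene-level body-methylation status tests the methylated-site count k of n
covered sites (n ≥ 5; fewer sites give an undefined status) against
p_context. Two readings of the rule are implemented because they yield
different gene sets: the default flags a gene as body-methylated when its
level is **not significantly lower** than background (lower-tail
p = P(Bin(n, p) ≤ k), BH across genes, flagged iff q ≥ α) — a permissive
rule under which most genes near background are body-methylated; the
`enriched` mode flags only genes significantly **above** background
(upper-tail, q < α). Pair classes use WT statuses: CG-only (≥ 1 copy
body-CG-methylated, neither copy CHG- nor CHH-body-methylated),
all-context (≥ 1 CG copy plus non-CG methylation), unmethylated
(excluded).

WT-vs-mutant differential methylation is Fisher's exact test on the 2×2
pooled-read table per gene, BH-adjusted; a pair is BCGM-reduced when at
least one copy has q < 0.05 with a lower mutant level. Between-copy
divergence is |level_A − level_B| (symmetric, 0 iff equal, ≤ 1).

## Expression (`dupmeth.expression`)

A gene is expressed when its mean FPKM exceeds 0.1 (strict); a pair enters
the analysis when at least one copy is expressed in at least one genotype
and the pair lost BCGM in at least one copy. Differential expression —
both copy-vs-copy within a genotype and WT-vs-mutant per copy — uses the
exact conditional binomial test on replicate-pooled counts: given
t = a + b, a ~ Bin(t, lib_a/(lib_a + lib_b)) under the null. The
WT-vs-mutant use replaces an isoform-model DE caller with the same exact
test, a deliberate methodological substitution that keeps the framework
self-consistent. Two-sided p-values are the doubled smaller one-sided
tail, capped at 1 (stated because exact-test two-sidedness has competing
conventions); q-values are BH within each tested family. Between-copy
divergence is |log2((FPKM_a + 0.01)/(FPKM_b + 0.01))|; the 0.01
pseudocount keeps silent-copy activations finite without dominating
ranks. A pair is expression-affected when at least one copy has
WT-vs-mutant q < 0.05.

## Copy dynamics (`dupmeth.dynamics`)

Roles (higher/lower) are fixed from WT mean FPKM (pseudocount-adjusted;
exact ties break to the lexicographically smaller id and are flagged) and
are not reassigned even if the ranking inverts in the mutant. Per copy,
the WT-to-mutant change is a direction (up/down when DE q < 0.05, else
none — a significance rule, not a fold-change window) and a magnitude
(|log2 fold change|). Pairs with at least one changed copy map to exactly
one of 10 codes; the same-direction cells split by strict magnitude
comparison, and exact magnitude ties are assigned to the convergent member
of the code pair and flagged (the choice is arbitrary; ties are
essentially impossible with continuous data). Convergent codes (NH/UL,
DH/NL, UH<UL, DH>DL, DH/UL) reduce the between-copy difference; divergent
codes (NH/DL, UH/NL, UH>UL, DH<DL, UH/DL) augment it. Group tests are
two-sided exact binomial: up-vs-down within each copy-group, each
convergent code against its divergent conjugate, one-copy-changed (codes
i–iv) against both-copies-changed (v–x), and convergent against divergent
overall.

## Sequence evolution (`dupmeth.evolution`)

Protein sequences are aligned globally (BLOSUM62, gap open 10 / extend
0.5) with Biopython's pairwise aligner, taking the first co-optimal
alignment (deterministic); the alignment is back-translated onto the CDS.
dS/dN is Nei–Gojobori (1986): per codon position, the fraction of the
three single-nucleotide changes that are synonymous counts toward S
(changes creating stops count as nonsynonymous, so S + N = 3 × codon
count exactly); observed differences are averaged over all minimal
substitution pathways, excluding pathways through stop codons (all
pathways are used if every one is blocked); proportions are
Jukes–Cantor-corrected, d = −3/4 ln(1 − 4p/3). Estimates are invalid when
p ≥ 3/4 or dS > 3 (the conventional saturation filter). Columns with gaps
or ambiguous bases are dropped and counted. NG86 was chosen over
heavier-weight ML estimators because it is fully specifiable and
oracle-testable, and the downstream use (distribution comparisons between
groups) is robust to the estimator choice. Only the universal genetic code
is supported.

## Statistics (`dupmeth.stats`)

Two-sample comparisons use Kolmogorov–Smirnov with scipy's
exact/asymptotic p-value rule; samples under 3 are skipped with a
warning. Category comparisons use one-way ANOVA plus Tukey HSD with a
compact letter display (letters are maximal cliques of the
non-significance graph, lettered by smallest contained group mean; groups
sharing a letter are not significantly different). Correlations are
Pearson with a Fisher-z 95% CI. Contingency tables use Fisher's exact
test for 2×2 and fall back to chi-square for larger tables. All
multiple-testing correction is Benjamini–Hochberg.

## Problem sizes

The reference condition is 2,000 pairs on a 4,800-gene genome with
720,000 cytosines per genotype; a full pipeline run takes ~45 s on one
CPU. The test suite exercises a 4-chromosome, 320-gene study (38 pairs)
for unit-level checks, the full reference condition for the
signature-recovery check, and 20 null runs (retention = 1, coupling = 0)
at 150 pairs each for specificity.

## What passing tests do and do not show

The generator produces exactly the structure the pipeline assumes:
non-overlapping genes, body-only cytosines, binomial site counts around a
single per-gene level, negative-binomial counts around a log-normal mean,
and duplicate pairs whose two copies are independent draws apart from the
planted coupling. Real data violate several of these (overlapping and
nested genes, spatially autocorrelated methylation within bodies,
coverage biases, mapping artifacts, TE misannotation, families with more
than two copies). Passing recovery and calibration tests therefore shows
the *pipeline logic* is correct and well-calibrated under its stated
model, not that the biological conclusions transfer to any particular
real dataset.

## Known limitations

- The exact conditional count test is exact under Poisson sampling;
  under strong overdispersion (dispersion × mean ≳ 0.5) it is
  anticonservative, and its nominal calibration holds only in the
  near-Poisson regime the generator's default dispersion represents.
  With biological replicates a dispersion-aware test would be the right
  replacement.
- The "not significantly lower than background" body-methylation rule is
  power-limited: with few covered sites it cannot reject, so
  low-coverage genes default to body-methylated. The enrichment mode is
  the conservative alternative.
- Block chaining is count-scored (no E-value weighting or HSP merging)
  and the self-diagonal mask prevents legitimate very-close
  intra-chromosomal blocks from being detected.
- Transposed duplicates are a residual category, not dated transposition
  events.
- Read-level simulation (FASTQ, mapping, bisulfite conversion) is out of
  scope; non-conversion is modeled only as the site-call error rate.
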