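"""Synthetic study generator: a self-consistent wild-type / CG-methylation-
mutant experiment with known ground truth.

The generator emulates the structure of a rice methyltransferase-null
experiment: a gene annotation with planted duplicate pairs of four origins
(WGD collinear blocks, tandem, proximal, transposed), per-cytosine
methylation reports for two genotypes in which the mutant retains only a
small fraction (default 9%) of gene-body CG methylation while CHG and CHH
are untouched, expression tables in which the loss of body CG methylation
(BCGM) shifts the two copies of a pair in opposite directions (higher-
expressed copy down, lower-expressed copy up), and coding-sequence pairs
carrying known synonymous/nonsynonymous substitution counts.

Randomness: one master seed; every stage draws from a named substream so
that adding or re-running a stage never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, detect_collinear_blocks

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "plant_duplicates",
    "simulate_methylomes",
    "simulate_expression",
    "generate_cds_pairs",
    "generate_study",
]

CONTEXTS = ("CG", "CHG", "CHH")
_TRINUCLEOTIDE = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
#: codon -> amino acid (``*`` = stop), standard genetic code
GENETIC_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def _default_category_counts() -> dict:
    # roughly the proportions seen among rice duplicate pairs
    return {"WGD": 480, "transposed": 880, "proximal": 340, "tandem": 300}


def _default_sites_per_gene() -> dict:
    return {"CG": 60, "CHG": 30, "CHH": 60}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    The defaults define the reference condition: 2,000 duplicate pairs on a
    12-chromosome genome, 91% loss of gene-body CG methylation in the mutant
    (``cg_retention_mutant = 0.09``), untouched CHG/CHH, and a positive
    coupling between methylation lost and expression shift that moves the
    higher-expressed copy of a pair down and the lower-expressed copy up.
    """

    n_chromosomes: int = 12
    genes_per_chromosome: int = 400
    category_counts: dict = field(default_factory=_default_category_counts)
    wgd_block_size: int = 6
    proximal_max_gap: int = 10
    min_block_anchors: int = 5
    frac_te: float = 0.02

    # methylome
    cg_retention_mutant: float = 0.09  # mutant keeps 9% of WT body CG methylation
    mean_coverage: float = 20.0
    sites_per_gene: dict = field(default_factory=_default_sites_per_gene)
    frac_bm_genes: float = 0.7        # genes with substantial body CG methylation
    bm_beta: tuple = (8.0, 3.0)       # CG level of body-methylated genes
    unmeth_cg_range: tuple = (0.005, 0.04)
    frac_all_context_genes: float = 0.2  # genes with elevated CHG/CHH as well
    # basal non-CG methylation in gene bodies is near zero; elevated levels
    # mark the all-context (TE-like) fraction
    chg_levels: tuple = (0.30, 0.005)  # (elevated, basal)
    chh_levels: tuple = (0.10, 0.003)

    # expression
    bcgm_expression_coupling: float = 0.8  # log2 units per unit CG level lost
    expression_response_prob: float = 0.5  # chance a copy responds to BCGM loss
    expression_noise_sd: float = 0.10      # per-copy log2 noise on the shift
    expr_log2_mean: float = 3.0
    # pair copies share a between-pair component; the within-pair component
    # sets the baseline between-copy correlation (~ 1.0^2 / (1.0^2 + 1.15^2))
    expr_log2_sd_between: float = 1.0
    expr_log2_sd_within: float = 1.15
    frac_silent_lower: float = 0.05        # lower copies silenced in WT
    silent_fpkm: float = 0.02
    # near-Poisson (technical-replicate) noise: the downstream exact
    # conditional count test assumes Poisson sampling and becomes
    # anticonservative when alpha*mu grows beyond ~0.5
    nb_dispersion: float = 0.002
    n_replicates: int = 2
    library_size: int = 20_000_000

    # homology decoys
    n_decoy_hits: int = 2000
    hard_decoys: bool = False  # decoy e-values below the candidate threshold

    # coding sequences
    cds_codons: int = 150
    ds_ranges: dict = field(default_factory=lambda: {
        # target dS range per category (WGD oldest, transposed broadest)
        "WGD": (0.5, 0.85), "tandem": (0.23, 0.63),
        "proximal": (0.22, 0.64), "transposed": (0.4, 1.0),
    })
    dnds_range: tuple = (0.05, 0.6)

    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 0 or self.genes_per_chromosome < 0:
            raise ValueError("chromosome and gene counts must be non-negative")
        if not 0.0 <= self.cg_retention_mutant <= 1.0:
            raise ValueError("cg_retention_mutant must lie in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if any(v < 0 for v in self.category_counts.values()):
            raise ValueError("category counts must be non-negative")
        n_genes = self.n_chromosomes * self.genes_per_chromosome
        n_avail = int(n_genes * (1.0 - self.frac_te))
        if 2 * sum(self.category_counts.values()) > n_avail:
            raise ValueError(
                f"category_counts need {2 * sum(self.category_counts.values())} "
                f"genes but only ~{n_avail} non-TE genes are available"
            )
        wgd = self.category_counts.get("WGD", 0)
        if 0 < wgd < self.min_block_anchors:
            raise ValueError(
                "WGD pair count is below min_block_anchors; blocks would be undetectable"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (stable across runs)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """Planted truth: pairs with categories plus per-gene generative values."""

    pairs: pd.DataFrame  # pair_id, gene_a, gene_b, category, block_id
    gene_meth: pd.DataFrame | None = None  # per gene: true levels per context/genotype
    gene_expr: pd.DataFrame | None = None  # per gene: true mean FPKM per genotype, role
    cds_truth: pd.DataFrame | None = None  # per pair: realized syn/nonsyn counts

    def to_dict(self) -> dict:
        out = {"pairs": self.pairs.to_dict(orient="list")}
        for name in ("gene_meth", "gene_expr", "cds_truth"):
            df = getattr(self, name)
            if df is not None:
                out[name] = df.reset_index().to_dict(orient="list")
        return out


# ------------------------------------------------------------- annotation

def generate_annotation(config: SimulationConfig) -> GeneCatalog:
    """Generate non-overlapping, strand-assigned genes with ordinal ranks."""
    config.validate()
    rng = config.rng("annotation")
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"Chr{c:02d}"
        n = config.genes_per_chromosome
        if n == 0:
            continue
        lengths = rng.integers(1500, 3001, size=n)
        gaps = rng.integers(200, 2001, size=n)
        starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
        strands = rng.choice(["+", "-"], size=n)
        te = rng.random(n) < config.frac_te
        for r in range(n):
            rows.append({
                "gene_id": f"Os{c:02d}g{(r + 1) * 10:05d}",
                "chrom": chrom,
                "start": int(starts[r]),
                "end": int(starts[r] + lengths[r] - 1),
                "strand": strands[r],
                "rank": r + 1,
                "is_te": bool(te[r]),
            })
    if not rows:
        df = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "is_te"]
        ).set_index("gene_id")
        df["rank"] = pd.Series(dtype=int)
        return GeneCatalog(df)
    return GeneCatalog(pd.DataFrame(rows).set_index("gene_id"))


# ---------------------------------------------------------- duplicate planting

def _find_run(avail: np.ndarray, length: int, rng) -> int | None:
    """Random start of a run of ``length`` consecutive available slots."""
    ok = np.ones(len(avail) - length + 1, dtype=bool) if len(avail) >= length else np.array([], bool)
    for off in range(length):
        ok &= avail[off: off + len(ok)]
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return None
    return int(rng.choice(idx))


class _Planter:
    def __init__(self, catalog: GeneCatalog, config: SimulationConfig, rng):
        self.catalog = catalog
        self.config = config
        self.rng = rng
        g = catalog.genes
        self.chroms = sorted(g["chrom"].unique())
        # per chromosome: gene ids ordered by rank, availability mask (non-TE only)
        self.by_chrom = {
            c: g.index[g["chrom"] == c][np.argsort(g.loc[g["chrom"] == c, "rank"])]
            for c in self.chroms
        }
        self.avail = {
            c: (~g.loc[self.by_chrom[c], "is_te"]).to_numpy().copy() for c in self.chroms
        }

    def take(self, chrom: str, idx0: int, length: int = 1):
        self.avail[chrom][idx0: idx0 + length] = False

    def release_pair(self, chrom_a, ia, chrom_b, ib):
        self.avail[chrom_a][ia] = True
        self.avail[chrom_b][ib] = True

    def plant_wgd_block(self, size: int):
        for _ in range(200):
            ca, cb = self.rng.choice(self.chroms, size=2, replace=False)
            sa = _find_run(self.avail[ca], size, self.rng)
            sb = _find_run(self.avail[cb], size, self.rng)
            if sa is None or sb is None:
                continue
            inverted = bool(self.rng.random() < 0.5)
            self.take(ca, sa, size)
            self.take(cb, sb, size)
            pairs = []
            for i in range(size):
                j = size - 1 - i if inverted else i
                pairs.append((self.by_chrom[ca][sa + i], self.by_chrom[cb][sb + j]))
            return pairs
        raise RuntimeError("could not place a WGD block; genome too crowded")

    def plant_gapped(self, gap: int):
        """Same-chromosome pair with the given rank gap (1 = tandem)."""
        for _ in range(500):
            c = self.rng.choice(self.chroms)
            av = self.avail[c]
            ok = np.flatnonzero(av[:-gap] & av[gap:]) if len(av) > gap else np.array([], int)
            if len(ok) == 0:
                continue
            i = int(self.rng.choice(ok))
            if gap == 1:
                self.take(c, i, 2)
            else:
                self.take(c, i)
                self.take(c, i + gap)
            return (self.by_chrom[c][i], self.by_chrom[c][i + gap]), (c, i, c, i + gap)
        raise RuntimeError(f"could not place a same-chromosome pair with gap {gap}")

    def plant_transposed(self):
        for _ in range(500):
            ca, cb = self.rng.choice(self.chroms, size=2, replace=False)
            ia = np.flatnonzero(self.avail[ca])
            ib = np.flatnonzero(self.avail[cb])
            if len(ia) == 0 or len(ib) == 0:
                continue
            i, j = int(self.rng.choice(ia)), int(self.rng.choice(ib))
            self.take(ca, i)
            self.take(cb, j)
            return (self.by_chrom[ca][i], self.by_chrom[cb][j]), (ca, i, cb, j)
        raise RuntimeError("could not place a transposed pair")


def _ordered(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def plant_duplicates(catalog: GeneCatalog, config: SimulationConfig):
    """Plant duplicate pairs of the four origins and emit a homology table.

    Genes are used by at most one pair.  After planting, block detection is
    run on the planted anchors and any tandem/proximal/transposed pair that
    accidentally joined (or formed) a collinear chain is re-placed, so that
    on noiseless input the classifier can recover every category exactly.
    """
    config.validate()
    if config.n_chromosomes < 2 and (
        config.category_counts.get("WGD", 0) or config.category_counts.get("transposed", 0)
    ):
        raise ValueError("WGD and transposed pairs require at least 2 chromosomes")
    rng = config.rng("duplicates")
    planter = _Planter(catalog, config, rng)

    records = []  # pair_id, gene_a, gene_b, category, block_id, slots
    block_id = 0

    n_wgd = config.category_counts.get("WGD", 0)
    while n_wgd > 0:
        size = config.wgd_block_size if n_wgd >= 2 * config.wgd_block_size else n_wgd
        if size < config.min_block_anchors:
            size = n_wgd  # fold remainder into a final larger chunk upstream
        pairs = planter.plant_wgd_block(size)
        block_id += 1
        for ga, gb in pairs:
            ga, gb = _ordered(ga, gb)
            records.append({"gene_a": ga, "gene_b": gb, "category": "WGD",
                            "block_id": f"B{block_id:03d}", "slots": None})
        n_wgd -= size

    for _ in range(config.category_counts.get("tandem", 0)):
        (ga, gb), slots = planter.plant_gapped(1)
        ga, gb = _ordered(ga, gb)
        records.append({"gene_a": ga, "gene_b": gb, "category": "tandem",
                        "block_id": None, "slots": slots})
    for _ in range(config.category_counts.get("proximal", 0)):
        gap = int(rng.integers(2, config.proximal_max_gap + 1))
        (ga, gb), slots = planter.plant_gapped(gap)
        ga, gb = _ordered(ga, gb)
        records.append({"gene_a": ga, "gene_b": gb, "category": "proximal",
                        "block_id": None, "slots": slots})
    for _ in range(config.category_counts.get("transposed", 0)):
        (ga, gb), slots = planter.plant_transposed()
        ga, gb = _ordered(ga, gb)
        records.append({"gene_a": ga, "gene_b": gb, "category": "transposed",
                        "block_id": None, "slots": slots})

    pairs_df = pd.DataFrame(
        records, columns=["gene_a", "gene_b", "category", "block_id", "slots"]
    )

    # re-place non-WGD pairs that chain into collinear blocks by accident
    for _ in range(50):
        if pairs_df.empty:
            break
        blocks = detect_collinear_blocks(
            pairs_df[["gene_a", "gene_b"]], catalog,
            min_block_anchors=config.min_block_anchors,
        )
        anchor_set = set()
        for b in blocks:
            anchor_set |= b.anchor_pairs()
        planted_wgd = {
            frozenset((r.gene_a, r.gene_b))
            for r in pairs_df[pairs_df["category"] == "WGD"].itertuples()
        }
        in_block = np.array([
            frozenset((a, b)) in anchor_set
            for a, b in zip(pairs_df["gene_a"], pairs_df["gene_b"])
        ])
        offending = pairs_df.index[(pairs_df["category"] != "WGD").to_numpy() & in_block]
        missing = planted_wgd - anchor_set
        if len(offending) == 0 and not missing:
            break
        if missing:
            raise RuntimeError(
                "planted WGD anchors were not recoverable as blocks; "
                "check min_block_anchors / wgd_block_size"
            )
        for idx in offending:
            row = pairs_df.loc[idx]
            ca, ia, cb, ib = row["slots"]
            planter.release_pair(ca, ia, cb, ib)
            if row["category"] == "transposed":
                (ga, gb), slots = planter.plant_transposed()
            else:
                gap = 1 if row["category"] == "tandem" else int(
                    rng.integers(2, config.proximal_max_gap + 1)
                )
                (ga, gb), slots = planter.plant_gapped(gap)
            ga, gb = _ordered(ga, gb)
            pairs_df.loc[idx, ["gene_a", "gene_b"]] = [ga, gb]
            pairs_df.at[idx, "slots"] = slots
    else:
        raise RuntimeError("could not avoid spurious collinear chains after 50 retries")

    pairs_df = pairs_df.drop(columns=["slots"])
    pairs_df.insert(0, "pair_id", [f"P{i:05d}" for i in range(len(pairs_df))])

    truth = GroundTruth(pairs=pairs_df.reset_index(drop=True))
    hits = _emit_homology(truth, catalog, config, rng)
    return truth, hits


def _emit_homology(truth: GroundTruth, catalog: GeneCatalog,
                   config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []

    def hit(q, s, evalue):
        length = int(rng.integers(150, 500))
        mism = int(rng.integers(0, 40))
        rows.append({
            "qseqid": q, "sseqid": s,
            "pident": round(float(rng.uniform(80, 99.5)), 2),
            "length": length, "mismatch": mism, "gapopen": int(rng.integers(0, 3)),
            "qstart": 1, "qend": length, "sstart": 1, "send": length,
            "evalue": float(evalue), "bitscore": round(float(rng.uniform(200, 1000)), 1),
        })

    for r in truth.pairs.itertuples():
        ev = 10.0 ** rng.uniform(-180, -20)
        hit(r.gene_a, r.gene_b, ev)
        hit(r.gene_b, r.gene_a, ev)

    paired = set(truth.pairs["gene_a"]) | set(truth.pairs["gene_b"])
    ids = [g for g in catalog.non_te_ids() if g not in paired]
    planted = {frozenset((a, b)) for a, b in zip(truth.pairs["gene_a"], truth.pairs["gene_b"])}
    lo, hi = (-30.0, -15.0) if config.hard_decoys else (-8.0, 0.0)
    n_decoys = min(config.n_decoy_hits, len(ids) * (len(ids) - 1) // 2 if len(ids) > 1 else 0)
    made = 0
    while made < n_decoys:
        q, s = rng.choice(ids, size=2, replace=False)
        if frozenset((q, s)) in planted:
            continue
        hit(q, s, 10.0 ** rng.uniform(lo, hi))
        made += 1
    df = pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ])
    return df


# ------------------------------------------------------------- methylomes

def _assign_true_levels(truth: GroundTruth, catalog: GeneCatalog,
                        config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng("methylation-levels")
    genes = catalog.gene_ids
    n = len(genes)
    bm = rng.random(n) < config.frac_bm_genes
    a, b = config.bm_beta
    cg_wt = np.where(
        bm, rng.beta(a, b, size=n),
        rng.uniform(*config.unmeth_cg_range, size=n),
    )
    allctx = rng.random(n) < config.frac_all_context_genes
    chg = np.where(allctx, config.chg_levels[0], config.chg_levels[1])
    chh = np.where(allctx, config.chh_levels[0], config.chh_levels[1])
    meth = pd.DataFrame({
        "cg_wt": cg_wt,
        "cg_mut": cg_wt * config.cg_retention_mutant,
        "chg_wt": chg, "chg_mut": chg,
        "chh_wt": chh, "chh_mut": chh,
        "body_methylated": bm, "all_context": allctx,
    }, index=genes)
    truth.gene_meth = meth
    return meth


def simulate_methylomes(truth: GroundTruth, catalog: GeneCatalog,
                        config: SimulationConfig):
    """Simulate per-cytosine reports for WT and mutant.

    Cytosine positions are placed inside gene bodies only; coverage is
    Poisson and methylated read counts binomial around the gene's true
    context level.  Mutant CG levels are WT levels times
    ``cg_retention_mutant``; CHG and CHH are identical across genotypes.
    Zero-coverage sites are emitted with 0/0 counts.
    """
    config.validate()
    if truth.gene_meth is None:
        _assign_true_levels(truth, catalog, config)
    meth = truth.gene_meth
    rng = config.rng("methylomes")

    g = catalog.genes
    site_rows = {"chrom": [], "pos": [], "strand": [], "context": [], "gene_id": []}
    for gene_id, row in g.iterrows():
        length = int(row["end"] - row["start"] + 1)
        total = sum(config.sites_per_gene.values())
        n_take = min(total, length)
        offsets = rng.choice(length, size=n_take, replace=False)
        offsets.sort()
        ctx = []
        for c in CONTEXTS:
            ctx += [c] * config.sites_per_gene[c]
        ctx = np.array(ctx[:n_take])
        rng.shuffle(ctx)
        site_rows["chrom"] += [row["chrom"]] * n_take
        site_rows["pos"] += list(int(row["start"]) + offsets)
        site_rows["strand"] += list(rng.choice(["+", "-"], size=n_take))
        site_rows["context"] += list(ctx)
        site_rows["gene_id"] += [gene_id] * n_take

    sites = pd.DataFrame(site_rows)
    out = {}
    for genotype in ("wt", "mut"):
        level = np.zeros(len(sites))
        for c in CONTEXTS:
            m = (sites["context"] == c).to_numpy()
            level[m] = meth.loc[sites.loc[m, "gene_id"], f"{c.lower()}_{genotype}"].to_numpy()
        cov = rng.poisson(config.mean_coverage, size=len(sites))
        methylated = rng.binomial(cov, level)
        df = sites.copy()
        df["count_methylated"] = methylated
        df["count_unmethylated"] = cov - methylated
        df["trinucleotide"] = df["context"].map(_TRINUCLEOTIDE)
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        out[genotype] = df[[
            "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
            "context", "trinucleotide",
        ]]
    return out["wt"], out["mut"]


# ------------------------------------------------------------- expression

def simulate_expression(truth: GroundTruth, catalog: GeneCatalog,
                        config: SimulationConfig) -> pd.DataFrame:
    """Simulate replicate-level counts and FPKM for both genotypes.

    Each pair copy responds to the loss of body CG methylation with
    probability ``expression_response_prob`` (expression change in one copy
    only is the common outcome).  For a responding copy the mutant log2 mean
    equals the WT log2 mean plus ``bcgm_expression_coupling`` times the true
    body CG level lost, with a negative sign for the copy that is
    higher-expressed in WT and a positive sign for the lower-expressed copy
    (plus per-copy Gaussian noise).  Counts are negative-binomial
    (gamma-Poisson); FPKM is computed from counts, gene length and library
    size.
    """
    config.validate()
    if truth.gene_meth is None:
        _assign_true_levels(truth, catalog, config)
    rng = config.rng("expression")
    g = catalog.genes
    genes = g.index

    sd_total = float(np.hypot(config.expr_log2_sd_between, config.expr_log2_sd_within))
    log2_wt = pd.Series(
        rng.normal(config.expr_log2_mean, sd_total, size=len(genes)),
        index=genes,
    )
    meth = truth.gene_meth
    sign = pd.Series(0.0, index=genes)  # -1 higher copy, +1 lower copy, 0 unpaired
    role = pd.Series("none", index=genes, dtype=object)
    # methylation-silenced lower copies: near-zero in WT, reactivating to
    # this pre-silencing level if they respond to the loss of methylation;
    # only body-methylated copies can be silenced this way
    unsilenced = pd.Series(np.nan, index=genes)
    for r in truth.pairs.itertuples():
        base = rng.normal(config.expr_log2_mean, config.expr_log2_sd_between)
        log2_wt[r.gene_a] = base + rng.normal(0, config.expr_log2_sd_within)
        log2_wt[r.gene_b] = base + rng.normal(0, config.expr_log2_sd_within)
        hi, lo = (r.gene_a, r.gene_b) if log2_wt[r.gene_a] >= log2_wt[r.gene_b] \
            else (r.gene_b, r.gene_a)
        if rng.random() < config.frac_silent_lower and meth.at[lo, "body_methylated"]:
            unsilenced[lo] = log2_wt[lo]
            log2_wt[lo] = np.log2(config.silent_fpkm)
        sign[hi], sign[lo] = -1.0, 1.0
        role[hi], role[lo] = "higher", "lower"

    lost = (meth["cg_wt"] - meth["cg_mut"]).reindex(genes).fillna(0.0)
    responds = (rng.random(len(genes)) < config.expression_response_prob) & (sign != 0)
    shift = np.where(
        responds,
        sign * config.bcgm_expression_coupling * lost
        + rng.normal(0, config.expression_noise_sd, len(genes)),
        0.0,
    )
    log2_mut = log2_wt + shift
    reactivates = responds & unsilenced.notna().to_numpy()
    log2_mut[reactivates] = unsilenced[reactivates]

    truth.gene_expr = pd.DataFrame({
        "wt_mean_fpkm": 2.0 ** log2_wt,
        "mut_mean_fpkm": 2.0 ** log2_mut,
        "role": role,
        "responds": responds,
    }, index=genes)

    lengths = g["end"] - g["start"] + 1
    scale = (lengths / 1e3) * (config.library_size / 1e6)  # FPKM -> expected count
    rows = []
    for genotype, mean_fpkm in (("wt", 2.0 ** log2_wt), ("mut", 2.0 ** log2_mut)):
        mu = (mean_fpkm * scale).to_numpy()
        for rep in range(1, config.n_replicates + 1):
            lam = rng.gamma(1.0 / config.nb_dispersion, mu * config.nb_dispersion)
            counts = rng.poisson(lam)
            rows.append(pd.DataFrame({
                "gene_id": genes,
                "genotype": genotype,
                "replicate": rep,
                "count": counts,
                "fpkm": counts / scale.to_numpy(),
                "library_size": config.library_size,
                "gene_length": lengths.to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------------- coding sequences

@lru_cache(maxsize=None)
def _synonymous_alternatives(codon: str) -> tuple:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                out.append(alt)
    return tuple(out)


@lru_cache(maxsize=None)
def _nonsynonymous_alternatives(codon: str) -> tuple:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[alt] not in (aa, "*"):
                out.append(alt)
    return tuple(out)


def mutate_codons(ancestor: list, n_syn: int, n_non: int, rng) -> tuple:
    """Apply ``n_syn`` synonymous and ``n_non`` nonsynonymous single-
    nucleotide substitutions to a codon list, in random interleaved order.

    Codons may be hit more than once; each substitution is classified
    against the *current* codon, never creates a stop, and the realized
    step counts are exactly (n_syn, n_non).  Raises when the sequence
    cannot absorb the requested substitutions (saturation).
    """
    derived = list(ancestor)
    L = len(derived)
    if n_syn + n_non > 2 * 3 * L:
        raise ValueError(
            f"requested {n_syn + n_non} substitutions exceed available sites "
            f"for {L} codons"
        )
    todo = ["syn"] * n_syn + ["non"] * n_non
    rng.shuffle(todo)
    for kind in todo:
        alt_of = _synonymous_alternatives if kind == "syn" else _nonsynonymous_alternatives
        for _attempt in range(20 * L):
            i = int(rng.integers(L))
            alts = alt_of(derived[i])
            if alts:
                derived[i] = str(rng.choice(alts))
                break
        else:
            raise ValueError(
                f"could not place a {kind}onymous substitution; sequence saturated"
            )
    return derived


def generate_cds_pairs(truth: GroundTruth, config: SimulationConfig) -> dict:
    """Generate a coding sequence pair per duplicate with planted
    synonymous/nonsynonymous substitution counts.

    Per-pair substitution counts are chosen to hit a category-specific
    target dS range (WGD oldest) and a target dN/dS ratio, by inverting the
    Jukes-Cantor correction at the expected site counts (~1/4 of sites
    synonymous for random codons).  Realized counts are recorded in the
    truth table.  Returns {pair_id: {gene: seq}}.
    """
    config.validate()
    rng = config.rng("cds")
    L = config.cds_codons
    cds: dict = {}
    recs = []
    for r in truth.pairs.itertuples():
        ancestor = list(rng.choice(SENSE_CODONS, size=L))
        lo, hi = config.ds_ranges.get(r.category, (0.2, 0.8))
        target_ds = rng.uniform(lo, hi)
        ratio = rng.uniform(*config.dnds_range)
        p_s = 0.75 * (1.0 - np.exp(-4.0 * target_ds / 3.0))
        p_n = 0.75 * (1.0 - np.exp(-4.0 * target_ds * ratio / 3.0))
        n_syn = int(round(p_s * 0.25 * 3 * L))
        n_non = int(round(p_n * 0.75 * 3 * L))
        derived = mutate_codons(ancestor, n_syn, n_non, rng)
        cds[r.pair_id] = {r.gene_a: "".join(ancestor), r.gene_b: "".join(derived)}
        recs.append({"pair_id": r.pair_id, "syn_subs": n_syn, "nonsyn_subs": n_non,
                     "target_ds": target_ds, "target_dnds": ratio})
    truth.cds_truth = pd.DataFrame(
        recs, columns=["pair_id", "syn_subs", "nonsyn_subs", "target_ds", "target_dnds"]
    )
    return cds


# ------------------------------------------------------------- orchestration

def generate_study(config: SimulationConfig, with_cds: bool = True):
    """Run every generator stage; returns (catalog, truth, hits, cx_wt,
    cx_mut, expression, cds)."""
    catalog = generate_annotation(config)
    truth, hits = plant_duplicates(catalog, config)
    cx_wt, cx_mut = simulate_methylomes(truth, catalog, config)
    expr = simulate_expression(truth, catalog, config)
    cds = generate_cds_pairs(truth, config) if with_cds else None
    return catalog, truth, hits, cx_wt, cx_mut, expr, cds
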