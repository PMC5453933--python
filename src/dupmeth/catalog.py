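"""Duplicate-pair identification and origin classification.

Candidate paralog pairs come from an all-vs-all protein homology search
(BLAST outfmt-6 table).  Pairs are classified into four duplication-origin
categories using gene order ("rank", the ordinal position of a gene on its
chromosome) and collinear-block detection:

* **WGD** -- the pair is an anchor of a collinear block (a chain of at least
  ``min_block_anchors`` homologous gene pairs whose ranks are jointly
  monotone on the two chromosomes, with bounded rank gaps);
* **tandem** -- same chromosome, adjacent ranks;
* **proximal** -- same chromosome, rank gap between 2 and ``proximal_max_gap``;
* **transposed** -- everything else (dispersed duplicates).

Block detection is a deterministic, count-scored, gap-bounded longest
monotone chain over anchors, applied greedily (best block first, each anchor
used at most once).  This captures the categorical outcome a synteny tool
such as MCScanX produces without its HSP-merging and e-value scoring layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "GeneCatalog",
    "CollinearBlock",
    "filter_candidates",
    "detect_collinear_blocks",
    "classify_duplicates",
]

CATEGORIES = ("WGD", "tandem", "proximal", "transposed")

#: column names of the BLAST tabular (outfmt 6) dialect consumed here
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class GeneCatalog:
    """Gene coordinates, strand, chromosome rank and TE status.

    Wraps a DataFrame indexed by ``gene_id`` with columns
    ``chrom, start, end, strand, rank, is_te``.  Coordinates are 1-based
    inclusive; ``rank`` is the ordinal position (1..N) of the gene on its
    chromosome ordered by start coordinate.
    """

    def __init__(self, genes: pd.DataFrame):
        required = {"chrom", "start", "end", "strand", "rank", "is_te"}
        missing = required - set(genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if genes.index.has_duplicates:
            dups = genes.index[genes.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if len(genes) and (genes["start"] > genes["end"]).any():
            bad = genes.index[genes["start"] > genes["end"]].tolist()
            raise ValueError(f"start > end for genes: {bad[:5]}")
        # ranks must be a permutation of 1..N per chromosome
        for chrom, sub in genes.groupby("chrom", sort=False):
            if sorted(sub["rank"]) != list(range(1, len(sub) + 1)):
                raise ValueError(f"ranks on {chrom} are not a permutation of 1..N")
        self.genes = genes.copy()

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def non_te_ids(self) -> pd.Index:
        return self.genes.index[~self.genes["is_te"]]

    def rank(self, gene_id: str) -> int:
        return int(self.genes.at[gene_id, "rank"])

    def chrom(self, gene_id: str) -> str:
        return self.genes.at[gene_id, "chrom"]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, assign_ranks: bool = False) -> "GeneCatalog":
        """Build a catalog, optionally (re)computing ranks from start order."""
        df = df.copy()
        if assign_ranks:
            df["rank"] = (
                df.groupby("chrom")["start"].rank(method="first").astype(int)
            )
        return cls(df)


@dataclass
class CollinearBlock:
    """A chain of rank-collinear anchor pairs between two chromosomes."""

    chrom_a: str
    chrom_b: str
    orientation: str  # "same" or "inverted"
    anchors: list = field(default_factory=list)  # [(gene_a, gene_b), ...] ordered by rank_a

    @property
    def score(self) -> int:
        return len(self.anchors)

    def anchor_pairs(self) -> set:
        return {frozenset(a) for a in self.anchors}


def _pair_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def filter_candidates(
    hits: pd.DataFrame,
    catalog: GeneCatalog,
    top_k: int = 5,
    max_evalue: float = 1e-10,
) -> pd.DataFrame:
    """Reduce raw homology hits to candidate duplicate pairs.

    A subject is kept for a query if it ranks among the query's ``top_k``
    subjects by ascending e-value (ties: descending bitscore, then id) and
    its best e-value is strictly below ``max_evalue``.  Self-hits and hits
    touching TE genes are dropped; the surviving (query, subject) relation is
    symmetrized into unordered pairs.

    Returns a DataFrame with columns ``gene_a, gene_b, evalue`` (best e-value
    seen for the pair), sorted by gene ids.
    """
    if not {"qseqid", "sseqid", "evalue", "bitscore"} <= set(hits.columns):
        raise ValueError("hits table lacks outfmt-6 columns qseqid/sseqid/evalue/bitscore")

    ids = set(catalog.gene_ids)
    unknown = (set(hits["qseqid"]) | set(hits["sseqid"])) - ids
    if unknown:
        raise ValueError(f"homology hits reference unknown gene ids: {sorted(unknown)[:10]}")

    h = hits.loc[hits["qseqid"] != hits["sseqid"], ["qseqid", "sseqid", "evalue", "bitscore"]].copy()
    te = set(catalog.gene_ids[catalog.genes["is_te"]])
    if te:
        h = h[~h["qseqid"].isin(te) & ~h["sseqid"].isin(te)]
    if h.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "evalue"])

    # best HSP per (query, subject): min evalue, then max bitscore
    h = (
        h.sort_values(["qseqid", "sseqid", "evalue", "bitscore"],
                      ascending=[True, True, True, False])
        .drop_duplicates(["qseqid", "sseqid"], keep="first")
    )
    # top_k subjects per query by (evalue asc, bitscore desc, sseqid asc)
    h = h.sort_values(["qseqid", "evalue", "bitscore", "sseqid"],
                      ascending=[True, True, False, True])
    h = h.groupby("qseqid", sort=False).head(top_k)
    h = h[h["evalue"] < max_evalue]
    if h.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "evalue"])

    keys = [_pair_key(q, s) for q, s in zip(h["qseqid"], h["sseqid"])]
    out = pd.DataFrame(keys, columns=["gene_a", "gene_b"])
    out["evalue"] = h["evalue"].to_numpy()
    out = (
        out.sort_values(["gene_a", "gene_b", "evalue"])
        .drop_duplicates(["gene_a", "gene_b"], keep="first")
        .reset_index(drop=True)
    )
    return out


def _anchor_table(candidates: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    g = catalog.genes
    a = candidates[["gene_a", "gene_b"]].copy()
    a["chrom_a"] = g.loc[a["gene_a"], "chrom"].to_numpy()
    a["chrom_b"] = g.loc[a["gene_b"], "chrom"].to_numpy()
    a["rank_a"] = g.loc[a["gene_a"], "rank"].to_numpy()
    a["rank_b"] = g.loc[a["gene_b"], "rank"].to_numpy()
    # canonical orientation: chrom_a <= chrom_b; on the same chromosome
    # rank_a < rank_b
    flip = (a["chrom_a"] > a["chrom_b"]) | (
        (a["chrom_a"] == a["chrom_b"]) & (a["rank_a"] > a["rank_b"])
    )
    for ca, cb in (("gene_a", "gene_b"), ("chrom_a", "chrom_b"), ("rank_a", "rank_b")):
        tmp = a.loc[flip, ca].copy()
        a.loc[flip, ca] = a.loc[flip, cb]
        a.loc[flip, cb] = tmp
    return a


def _best_chain(r1: np.ndarray, r2: np.ndarray, max_gap: int, direction: int):
    """Longest gap-bounded chain with r1 strictly increasing and r2 strictly
    monotone in ``direction`` (+1 increasing / -1 decreasing).

    Anchors are pre-sorted by (r1, r2).  Returns (length, indices) where the
    chain is the longest one; ties are broken toward the chain whose anchors
    appear earliest in the sorted order (deterministic).
    """
    n = len(r1)
    best_len = np.ones(n, dtype=int)
    parent = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            if not (0 < r1[i] - r1[j] <= max_gap):
                continue
            d2 = (r2[i] - r2[j]) * direction
            if not (0 < d2 <= max_gap):
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                parent[i] = j
    end = int(np.argmax(best_len))  # first index on ties
    chain = []
    k = end
    while k != -1:
        chain.append(k)
        k = parent[k]
    chain.reverse()
    return len(chain), chain


def detect_collinear_blocks(
    candidates: pd.DataFrame,
    catalog: GeneCatalog,
    min_block_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list:
    """Greedy extraction of collinear blocks from candidate anchors.

    For every chromosome pair, the highest-scoring (longest) gap-bounded
    monotone chain is extracted, its anchors removed, and the search
    repeated until no chain reaches ``min_block_anchors``.  Both
    orientations are searched; on equal length the "same"-orientation chain
    wins, then the chain starting at the smaller rank.

    Same-chromosome anchors within ``max_rank_gap`` ranks of the self-
    comparison diagonal are excluded from chaining (the standard diagonal
    mask in self-synteny searches): dense tandem/proximal arrays would
    otherwise chain along the diagonal into spurious blocks.
    """
    if candidates.empty:
        return []
    anchors = _anchor_table(candidates, catalog)
    near_diag = (anchors["chrom_a"] == anchors["chrom_b"]) & (
        (anchors["rank_b"] - anchors["rank_a"]).abs() <= max_rank_gap
    )
    anchors = anchors[~near_diag]
    if anchors.empty:
        return []
    blocks: list[CollinearBlock] = []
    for (ca, cb), sub in anchors.groupby(["chrom_a", "chrom_b"], sort=True):
        sub = sub.sort_values(["rank_a", "rank_b"]).reset_index(drop=True)
        alive = sub
        while len(alive) >= min_block_anchors:
            r1 = alive["rank_a"].to_numpy()
            r2 = alive["rank_b"].to_numpy()
            len_f, chain_f = _best_chain(r1, r2, max_rank_gap, +1)
            len_r, chain_r = _best_chain(r1, r2, max_rank_gap, -1)
            if len_f >= len_r:
                length, chain, orient = len_f, chain_f, "same"
            else:
                length, chain, orient = len_r, chain_r, "inverted"
            if length < min_block_anchors:
                break
            rows = alive.iloc[chain]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca, chrom_b=cb, orientation=orient,
                    anchors=list(zip(rows["gene_a"], rows["gene_b"])),
                )
            )
            alive = alive.drop(alive.index[chain]).reset_index(drop=True)
    # stable report order: by score desc, then chromosomes, then first anchor
    blocks.sort(key=lambda b: (-b.score, b.chrom_a, b.chrom_b,
                               b.anchors[0][0] if b.anchors else ""))
    return blocks


def classify_duplicates(
    candidates: pd.DataFrame,
    blocks: list,
    catalog: GeneCatalog,
    proximal_max_gap: int = 10,
) -> pd.DataFrame:
    """Assign each candidate pair exactly one duplication-origin category.

    Precedence: block anchor -> WGD; same chromosome with rank gap 1 ->
    tandem; rank gap 2..proximal_max_gap -> proximal; otherwise transposed.
    """
    cols = ["gene_a", "gene_b", "category"]
    if candidates.empty:
        return pd.DataFrame(columns=cols)
    missing = (set(candidates["gene_a"]) | set(candidates["gene_b"])) - set(catalog.gene_ids)
    if missing:
        raise ValueError(f"pairs reference genes absent from catalog: {sorted(missing)[:10]}")

    anchor_pairs = set()
    for b in blocks:
        anchor_pairs |= b.anchor_pairs()

    g = catalog.genes
    out = candidates[["gene_a", "gene_b"]].copy()
    chrom_a = g.loc[out["gene_a"], "chrom"].to_numpy()
    chrom_b = g.loc[out["gene_b"], "chrom"].to_numpy()
    gap = np.abs(
        g.loc[out["gene_a"], "rank"].to_numpy() - g.loc[out["gene_b"], "rank"].to_numpy()
    )
    same = chrom_a == chrom_b
    is_anchor = np.array(
        [frozenset((a, b)) in anchor_pairs for a, b in zip(out["gene_a"], out["gene_b"])]
    )
    cat = np.where(
        is_anchor, "WGD",
        np.where(same & (gap == 1), "tandem",
                 np.where(same & (gap >= 2) & (gap <= proximal_max_gap),
                          "proximal", "transposed")),
    )
    out["category"] = cat
    return out.reset_index(drop=True)
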