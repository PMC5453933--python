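"""Codon-aware pairwise alignment and Nei-Gojobori (1986) dN/dS.

Protein sequences are globally aligned (Needleman-Wunsch with affine gaps,
BLOSUM62, open 10 / extend 0.5) and the alignment is back-translated onto
the coding sequences to give a codon alignment.  dS and dN then follow the
NG86 recipe: per codon, each position contributes the fraction of its three
possible single-nucleotide changes that are synonymous to the synonymous
site count S (changes creating stop codons count as nonsynonymous, so
S + N = 3 x codon count); observed differences between a codon pair are
averaged over all minimal substitution pathways, excluding pathways that
pass through a stop codon; proportions are Jukes-Cantor corrected,
d = -3/4 ln(1 - 4p/3).  Pairs with p >= 3/4 or dS above ``max_ds`` are
flagged invalid (the conventional dS > 3 saturation filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .simulate import GENETIC_CODE
from .stats import compare_distributions

__all__ = [
    "DnDsResult",
    "align_pair",
    "translate_cds",
    "backtranslate",
    "compute_ng86",
    "pair_dnds",
    "stratify_by_affect",
]

_BASES = "TCAG"


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def translate_cds(cds: str) -> str:
    """Translate a CDS (length multiple of 3, no internal stops)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    protein = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = GENETIC_CODE.get(codon, "X")
        if aa == "*":
            if i == len(cds) - 3:
                break  # trailing stop is tolerated and trimmed
            raise ValueError(f"internal stop codon at nucleotide {i + 1}")
        protein.append(aa)
    return "".join(protein)


def align_pair(protein_a: str, protein_b: str):
    """Optimal global protein alignment; returns (aligned_a, aligned_b).

    Deterministic: of the co-optimal alignments the first in the aligner's
    enumeration order is taken.
    """
    if not protein_a or not protein_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _ALIGNER.align(protein_a, protein_b)[0]
    return str(alignment[0]), str(alignment[1])


def backtranslate(protein_aln: tuple, cds_a: str, cds_b: str):
    """Expand a protein alignment to a codon alignment.

    Returns two equal-length lists of codon strings with ``---`` gaps.
    """
    out = []
    for name, aln, cds in (("a", protein_aln[0], cds_a), ("b", protein_aln[1], cds_b)):
        cds = cds.upper()
        n_res = sum(1 for ch in aln if ch != "-")
        if len(cds) == 3 * (n_res + 1) and GENETIC_CODE.get(cds[-3:]) == "*":
            cds = cds[:-3]  # drop trailing stop
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"sequence {name}: CDS length {len(cds)} does not match "
                f"{n_res} aligned residues"
            )
        translated = translate_cds(cds)
        stripped = aln.replace("-", "")
        if translated != stripped:
            raise ValueError(
                f"sequence {name}: CDS translation does not match the aligned protein"
            )
        codons, i = [], 0
        for ch in aln:
            if ch == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * i: 3 * i + 3])
                i += 1
        out.append(codons)
    return out[0], out[1]


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that preserve the amino acid; stop-creating changes count as
    nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    codons.  Pathways through stop codons are excluded; if every pathway is
    blocked, all pathways are used."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [p for p in paths if not p[2]]
    use = open_paths if open_paths else paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float):
    """JC69 multiple-hit correction; None when undefined (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """NG86 estimates for one codon-aligned pair."""

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    dS: float | None
    dN: float | None
    dn_ds_ratio: float | None
    n_codons: int
    n_dropped: int
    valid: bool

    def to_dict(self) -> dict:
        return {
            "S_sites": self.S_sites, "N_sites": self.N_sites,
            "Sd": self.Sd, "Nd": self.Nd, "dS": self.dS, "dN": self.dN,
            "dn_ds": self.dn_ds_ratio, "n_codons": self.n_codons,
            "n_dropped": self.n_dropped, "valid": self.valid,
        }


def compute_ng86(codons_a, codons_b, max_ds: float = 3.0) -> DnDsResult:
    """NG86 dS/dN over a codon alignment (two parallel codon lists).

    Columns with a gap or an ambiguous base on either side are dropped (and
    counted).  ``valid`` is False when the Jukes-Cantor correction is
    undefined for either proportion or when dS exceeds ``max_ds``.
    """
    if len(codons_a) != len(codons_b):
        raise ValueError("codon alignments differ in length")
    S = N = Sd = Nd = 0.0
    n_used = n_dropped = 0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb or any(x not in _BASES for x in ca + cb):
            n_dropped += 1
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise ValueError("no ungapped codon columns to compare")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    valid = dS is not None and dN is not None and dS <= max_ds
    ratio = None
    if dS is not None and dN is not None and dS > 0:
        ratio = dN / dS
    return DnDsResult(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, dS=dS, dN=dN,
                      dn_ds_ratio=ratio, n_codons=n_used, n_dropped=n_dropped,
                      valid=valid)


def pair_dnds(cds: dict, pairs: pd.DataFrame, max_ds: float = 3.0) -> pd.DataFrame:
    """Align and estimate dS/dN for every pair with coding sequences.

    ``cds`` maps pair_id -> {gene_id: sequence}.  Sequences are matched to
    ``pairs`` rows by their two gene ids (pair ids may differ between the
    two tables).  Returns a DataFrame indexed by the pair ids of ``pairs``.
    """
    by_genes = {frozenset(seqs): seqs for seqs in cds.values()}
    rows = {}
    for r in pairs.itertuples():
        pid = getattr(r, "pair_id", None) or f"{r.gene_a}--{r.gene_b}"
        seqs = cds.get(pid) or by_genes.get(frozenset((r.gene_a, r.gene_b)))
        if seqs is None or set(seqs) != {r.gene_a, r.gene_b}:
            continue
        sa, sb = seqs[r.gene_a], seqs[r.gene_b]
        aln = align_pair(translate_cds(sa), translate_cds(sb))
        ca, cb = backtranslate(aln, sa, sb)
        rows[pid] = compute_ng86(ca, cb, max_ds=max_ds).to_dict()
    return pd.DataFrame.from_dict(rows, orient="index")


def stratify_by_affect(
    dnds: pd.DataFrame,
    pairs: pd.DataFrame,
    affected: pd.Series,
    min_group: int = 3,
) -> dict:
    """K-S comparison of dS and dN/dS between expression-affected and
    -unaffected pairs, per duplication category.

    Only pairs with a valid estimate enter.  Groups smaller than
    ``min_group`` are skipped.
    """
    tab = pairs.set_index("pair_id").join(dnds, how="inner")
    tab["affected"] = affected.set_axis(pairs["pair_id"]).reindex(tab.index)
    tab = tab[tab["valid"].astype(bool)]
    out = {}
    for cat, sub in tab.groupby("category"):
        aff = sub[sub["affected"] == True]   # noqa: E712
        una = sub[sub["affected"] == False]  # noqa: E712
        entry = {"n_affected": len(aff), "n_unaffected": len(una)}
        for col, label in (("dS", "ds"), ("dn_ds", "dnds")):
            a = aff[col].dropna()
            u = una[col].dropna()
            if len(a) < min_group or len(u) < min_group:
                entry[f"{label}_ks"] = None
                continue
            ks = compare_distributions(a, u)
            entry[f"{label}_ks"] = {"statistic": ks.statistic, "pvalue": ks.pvalue}
        out[cat] = entry
    return out
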