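"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: GFF3 gene annotation, BLAST outfmt-6 homology tables, 7-column
per-cytosine methylation reports (Bismark CX dialect), long-format
expression tables, and paired-CDS FASTA.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import OUTFMT6_COLUMNS, GeneCatalog

CX_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]

EXPRESSION_COLUMNS = [
    "gene_id", "genotype", "replicate", "count", "fpkm",
    "library_size", "gene_length",
]


# ---------------------------------------------------------------- GFF3

def write_gff3(catalog: GeneCatalog, path) -> None:
    """Write the catalog as a GFF3 file of ``gene`` features."""
    lines = ["##gff-version 3"]
    g = catalog.genes.sort_values(["chrom", "start"])
    for gene_id, row in g.iterrows():
        attrs = f"ID={gene_id}"
        if row["is_te"]:
            attrs += ";Note=transposable_element_gene"
        lines.append(
            "\t".join([
                str(row["chrom"]), "dupmeth", "gene",
                str(int(row["start"])), str(int(row["end"])),
                ".", row["strand"], ".", attrs,
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> GeneCatalog:
    """Read ``gene`` features from a GFF3 file into a catalog.

    Ranks are assigned by start-coordinate order per chromosome.  A gene is
    flagged TE when its attributes mention ``transposable_element``.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
        if ftype != "gene":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        gid = attr.get("ID")
        if gid is None:
            raise ValueError(f"{path}:{ln}: gene feature without ID attribute")
        rows.append({
            "gene_id": gid, "chrom": chrom, "start": int(start), "end": int(end),
            "strand": strand,
            "is_te": "transposable_element" in attrs,
        })
    if not rows:
        df = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "is_te"]
        ).set_index("gene_id")
        df["rank"] = pd.Series(dtype=int)
        return GeneCatalog(df)
    df = pd.DataFrame(rows).set_index("gene_id")
    return GeneCatalog.from_frame(df, assign_ranks=True)


# ---------------------------------------------------------- BLAST outfmt 6

def write_blast_tab(hits: pd.DataFrame, path) -> None:
    hits[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_blast_tab(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)


# ---------------------------------------------------------- cytosine report

def write_cx_report(calls: pd.DataFrame, path) -> None:
    calls[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_cx_report(path) -> pd.DataFrame:
    """Read a 7-column per-cytosine report; validates counts and context."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=CX_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
    )
    bad = df.index[
        df["context"].isna() | ~df["context"].isin(["CG", "CHG", "CHH"])
    ]
    if len(bad):
        raise ValueError(
            f"{path}: line {bad[0] + 1}: invalid context "
            f"{df.loc[bad[0], 'context']!r}"
        )
    if (df[["count_methylated", "count_unmethylated"]] < 0).any().any():
        bad = df.index[(df[["count_methylated", "count_unmethylated"]] < 0).any(axis=1)]
        raise ValueError(f"{path}: line {bad[0] + 1}: negative read count")
    return df


# ---------------------------------------------------------- expression table

def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: expression table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------- FASTA

def write_cds_fasta(cds: dict, path) -> None:
    """Write paired coding sequences.

    ``cds`` maps pair_id -> {gene_id: sequence} (two genes per pair).  The
    pair id is carried in the record description as ``pair=<id>``.
    """
    records = []
    for pair_id in sorted(cds):
        for gene_id in sorted(cds[pair_id]):
            records.append(
                SeqRecord(Seq(cds[pair_id][gene_id]), id=gene_id,
                          description=f"pair={pair_id}")
            )
    SeqIO.write(records, str(path), "fasta")


def read_cds_fasta(path) -> dict:
    """Read paired coding sequences written by :func:`write_cds_fasta`."""
    cds: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pair_id = None
        for token in rec.description.split():
            if token.startswith("pair="):
                pair_id = token[5:]
        if pair_id is None:
            raise ValueError(f"{path}: record {rec.id} lacks a pair=<id> tag")
        cds.setdefault(pair_id, {})[rec.id] = str(rec.seq)
    for pair_id, genes in cds.items():
        if len(genes) != 2:
            raise ValueError(f"{path}: pair {pair_id} has {len(genes)} records (need 2)")
    return cds


# ---------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
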