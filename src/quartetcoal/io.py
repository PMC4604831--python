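"""Readers and writers for the plain-text formats the pipeline exchanges.

Newick trees (dendropy), FASTA alignments (Biopython), VCF-like variant
TSVs, species-map TSVs, BED interval files and fastsimcoal-style joint-SFS
text.  File coordinates are 1-based (variant tables) or 0-based half-open
(BED); in-memory intervals are always 0-based half-open.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .trees import GeneTree

__all__ = [
    "read_newick", "write_newick", "read_fasta", "write_fasta",
    "read_variants", "write_variants", "read_species_map",
    "write_species_map", "read_bed", "write_bed", "read_sfs2d",
    "write_sfs2d",
]


def read_newick(path, species_map: dict | None = None) -> GeneTree:
    text = pathlib.Path(path).read_text()
    return GeneTree.from_newick(text, species_map=species_map)


def write_newick(path, gt: GeneTree):
    pathlib.Path(path).write_text(gt.to_newick() + "\n")


def read_fasta(path) -> dict:
    """FASTA file as ``{label: sequence}`` (order preserved)."""
    from Bio import SeqIO
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path, sequences: dict, width: int = 80):
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(seq), id=label, description="")
               for label, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


VARIANT_META = ["chrom", "pos", "anc", "der"]


def read_variants(path) -> pd.DataFrame:
    """Variant TSV: chrom, pos (1-based), anc, der, then one 0/1/. column
    per haplotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_META if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    df["pos"] = df["pos"].astype(int)
    return df


def write_variants(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False)


def read_species_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["haplotype", "species"], dtype=str)
    return dict(zip(df["haplotype"], df["species"]))


def write_species_map(path, species_map: dict):
    with open(path, "w") as fh:
        for hap, sp in species_map.items():
            fh.write(f"{hap}\t{sp}\n")


def read_bed(path):
    """BED intervals as ``[(chrom, start, end), ...]`` (0-based half-open,
    as in the file)."""
    out = []
    for lineno, line in enumerate(pathlib.Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed BED line")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(path, intervals):
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_sfs2d(path, sfs):
    """fastsimcoal-style joint-SFS text: a header line with the pair and
    sample sizes, then the (n1+1) x (n2+1) count matrix."""
    with open(path, "w") as fh:
        fh.write(f"# pair={sfs.pair[0]},{sfs.pair[1]} n1={sfs.n1} "
                 f"n2={sfs.n2} total_sites={sfs.total_sites}\n")
        fh.write("\t" + "\t".join(f"d{sfs.pair[1]}_{j}"
                                  for j in range(sfs.n2 + 1)) + "\n")
        for i in range(sfs.n1 + 1):
            row = "\t".join(f"{v:.6g}" for v in sfs.matrix[i])
            fh.write(f"d{sfs.pair[0]}_{i}\t{row}\n")


def read_sfs2d(path):
    from .sfsfit import Sfs2D
    lines = pathlib.Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}:1: missing joint-SFS header")
    meta = dict(kv.split("=") for kv in lines[0][1:].split())
    pair = tuple(meta["pair"].split(","))
    n1, n2 = int(meta["n1"]), int(meta["n2"])
    matrix = []
    for line in lines[2:2 + n1 + 1]:
        matrix.append([float(v) for v in line.split("\t")[1:]])
    return Sfs2D(pair=pair, n1=n1, n2=n2, matrix=np.array(matrix),
                 total_sites=float(meta["total_sites"]))
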