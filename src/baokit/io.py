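"""Readers and writers for the plain-text formats used across the toolkit.

FASTA goes through Biopython; VCF reading goes through cyvcf2 (see
:mod:`baokit.ploidy_inference` / :mod:`baokit.population_structure`).
GFF3 is handled here as a 9-column table with parsed attribute dicts, in the
TE-annotation dialect produced by homology+structural annotators (EDTA-style
``Method=`` and ``Identity=`` attributes).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


# ---------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {name: sequence-string} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


# ----------------------------------------------------------------------- GFF3

def parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for field in text.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        if "=" in field:
            key, value = field.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def format_gff_attributes(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame (1-based inclusive coordinates).

    The ``attributes`` column holds parsed dicts; ``score`` is float with NaN
    for '.'.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(parts)}")
            chrom, source, ftype, start, end, score, strand, phase, attrs = parts
            rows.append(
                {
                    "chrom": chrom,
                    "source": source,
                    "type": ftype,
                    "start": int(start),
                    "end": int(end),
                    "score": np.nan if score == "." else float(score),
                    "strand": strand,
                    "phase": phase,
                    "attributes": parse_gff_attributes(attrs),
                }
            )
    return pd.DataFrame(rows, columns=GFF_COLUMNS)


def write_gff3(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            score = "." if row.score is None or (isinstance(row.score, float) and np.isnan(row.score)) else f"{row.score:g}"
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        row.source,
                        row.type,
                        str(int(row.start)),
                        str(int(row.end)),
                        score,
                        row.strand,
                        row.phase,
                        format_gff_attributes(row.attributes),
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------- .histo text

def write_histo(depths, counts, path, k: int | None = None) -> Path:
    """Write a two-column k-mer depth histogram; optional ``#k=`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        if k is not None:
            fh.write(f"#k={int(k)}\n")
        for d, c in zip(depths, counts):
            fh.write(f"{int(d)} {int(c)}\n")
    return path


# ------------------------------------------------------------------- VCF text

def write_allele_depth_vcf(table: pd.DataFrame, path, sample: str = "sample1") -> Path:
    """Write per-site allele depths as a minimal single-sample VCF v4.2.

    Expects columns chrom, pos, ref_depth, alt_depth, qual. REF/ALT bases are
    placeholders (A/G); the information carried is the AD field.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(table["chrom"]):
            sub = table[table["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for row in table.itertuples(index=False):
            ref_d, alt_d = int(row.ref_depth), int(row.alt_depth)
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\tA\tG\t{float(row.qual):.1f}\tPASS\t.\t"
                f"GT:AD:DP\t0/1:{ref_d},{alt_d}:{ref_d + alt_d}\n"
            )
    return path


def write_genotype_vcf(dosages: np.ndarray, samples, ploidy: np.ndarray,
                       chroms, positions, path) -> Path:
    """Write a dosage matrix (samples x loci) as VCF v4.2 genotypes.

    Tetraploid samples get 4-allele GT calls (e.g. ``0/0/1/1``); missing
    dosage (negative) becomes ``./.``.
    """
    path = Path(path)
    dosages = np.asarray(dosages)
    ploidy = np.asarray(ploidy)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(pd.Series(chroms)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(dosages.shape[1]):
            calls = []
            for i in range(dosages.shape[0]):
                d, p = int(dosages[i, j]), int(ploidy[i])
                if d < 0:
                    calls.append("/".join(["."] * p))
                else:
                    calls.append("/".join(["1"] * d + ["0"] * (p - d)))
            fh.write(f"{chroms[j]}\t{int(positions[j])}\t.\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
    return path


# ---------------------------------------------------------------- anchors TSV

ANCHOR_COLUMNS = ["geneA", "geneB", "score", "chromA", "posA", "chromB", "posB"]


def read_anchors(path) -> pd.DataFrame:
    """Read an anchor-pair TSV (geneA geneB score chromA posA chromB posB).

    ``posA``/``posB`` are ordinal gene positions along their chromosome.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=ANCHOR_COLUMNS)
    df["posA"] = df["posA"].astype(int)
    df["posB"] = df["posB"].astype(int)
    return df


def write_anchors(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.loc[:, ANCHOR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    return path


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
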