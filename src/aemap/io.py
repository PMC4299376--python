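"""Readers and writers for the pipeline's on-disk formats.

Coordinates: VCF and GTF are written and read 1-based per their standards;
the in-memory model keeps 1-based SNP positions alongside 0-based half-open
masks (documented at each call site).  VCF parsing goes through pysam,
motif files through Biopython's MEME-minimal and TRANSFAC parsers, tables
through pandas TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import motifs as bio_motifs

from .motif_analysis import MotifMatrix
from .synthgen import PhasedGenotypeSet

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gtf",
    "read_gtf",
    "write_meme",
    "read_meme",
    "read_transfac",
    "write_fasta",
    "read_fasta",
    "write_table",
    "read_table",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=aemap-synthgen
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">
"""


def write_vcf(genotypes: PhasedGenotypeSet, path: str | os.PathLike) -> None:
    """Write phased genotypes as a plain-text VCF (alleles A=REF, B=ALT)."""
    snps = genotypes.snps
    hap = genotypes.haplotypes
    n = genotypes.n_samples
    samples = [f"S{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in snps["chrom"].unique():
            length = int(snps.loc[snps["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for k, row in snps.iterrows():
            gts = "\t".join(f"{hap[i, 0, k]}|{hap[i, 1, k]}" for i in range(n))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> PhasedGenotypeSet:
    """Read a phased VCF back into a PhasedGenotypeSet (unphased -> missing)."""
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    hap_cols = []
    meta = []
    for rec in vf.fetch() if vf.index is not None else vf:
        col = np.full((len(samples), 2), -1, dtype=np.int8)
        for i, s in enumerate(samples):
            sample = rec.samples[s]
            alleles = sample["GT"]
            if sample.phased and alleles is not None and None not in alleles:
                col[i, 0], col[i, 1] = alleles
        hap_cols.append(col)
        meta.append({"snp_id": rec.id, "chrom": rec.chrom, "pos": rec.pos})
    vf.close()
    hap = np.stack(hap_cols, axis=2) if hap_cols else np.zeros((len(samples), 2, 0), np.int8)
    snps = pd.DataFrame(meta)
    chroms = {c: i for i, c in enumerate(pd.unique(snps["chrom"]))}
    snps["locus"] = snps["chrom"].map(chroms)
    freq = np.where(hap >= 0, hap, np.nan).mean(axis=(0, 1))
    snps["maf_target"] = np.nan
    snps["maf_realized"] = np.minimum(freq, 1 - freq)
    return PhasedGenotypeSet(haplotypes=hap, snps=snps)


def write_gtf(transcripts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write transcript models as GTF (one transcript feature per row)."""
    with open(path, "w") as fh:
        for _, t in transcripts.iterrows():
            attrs = f'gene_id "{t["gene_id"]}"; transcript_id "{t["transcript_id"]}";'
            fh.write(
                f"{t['chrom']}\taemap\ttranscript\t{t['start']}\t{t['end']}\t.\t{t['strand']}\t.\t{attrs}\n"
            )


def read_gtf(path: str | os.PathLike) -> pd.DataFrame:
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    df = df[df["feature"] == "transcript"].copy()
    df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]+)"')
    df["transcript_id"] = df["attrs"].str.extract(r'transcript_id "([^"]+)"')
    return df[["gene_id", "transcript_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)


def write_meme(matrices: dict[str, np.ndarray] | list[MotifMatrix], path: str | os.PathLike) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    if isinstance(matrices, dict):
        items = [(mid, np.asarray(p)) for mid, p in matrices.items()]
    else:
        items = [(m.motif_id, m.probs) for m in matrices]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for mid, probs in items:
            fh.write(f"MOTIF {mid}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {probs.shape[0]} nsites= 20 E= 0\n")
            for row in probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | os.PathLike, source: str = "TRANSFAC-like") -> list[MotifMatrix]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
        out = []
        for m in parsed:
            probs = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
            probs = probs / probs.sum(axis=1, keepdims=True)
            out.append(MotifMatrix(motif_id=m.name, probs=probs, source=source))
    return out


def read_transfac(path: str | os.PathLike, source: str = "TRANSFAC-like") -> list[MotifMatrix]:
    """Read TRANSFAC-style count matrices, applying the standard pseudocount."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "transfac")
        out = []
        for m in parsed:
            counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)])
            out.append(MotifMatrix.from_counts(m.name, counts, source=source))
    return out


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
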