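"""Core allelic-expression statistics: from intensity ratios to per-sample,
per-transcript phased delta het ratios.

The delta het ratio is the deviation of the normalized cDNA allelic ratio
from its gDNA reference at a heterozygous SNP.  gDNA, carrying exactly one
copy of each allele, is the technical 50:50 reference: per SNP we apply an
affine correction that centres the mean gDNA heterozygote ratio at 0.5 and
apply the identical correction to the cDNA ratios of that SNP.  Per-SNP
deltas are then oriented by phase (positive = haplotype 1 over-expressed)
and averaged across a transcript's informative SNPs (minimum three) to give
an AE profile usable for association mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSummary",
    "normalize_ratios",
    "delta_het",
    "phase_align",
    "aggregate_transcript",
    "select_isoforms",
    "compute_ae_profiles",
    "MIN_SNPS_PER_TRANSCRIPT",
]

MIN_SNPS_PER_TRANSCRIPT = 3
FPKM_THRESHOLD = 0.01


@dataclass
class ExpressionSummary:
    """Expressed-transcript filter from RNA-seq medians."""

    table: pd.DataFrame  # transcript_id, gene_id, median_fpkm, expressed

    @classmethod
    def from_fpkm(cls, fpkm: pd.DataFrame, threshold: float = FPKM_THRESHOLD) -> "ExpressionSummary":
        t = fpkm.copy()
        t["expressed"] = t["median_fpkm"] > threshold
        return cls(table=t)

    def is_expressed(self, transcript_id: str) -> bool:
        rows = self.table[self.table["transcript_id"] == transcript_id]
        return bool(rows["expressed"].iloc[0]) if not rows.empty else False


def normalize_ratios(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP affine centring of allelic ratios on the gDNA heterozygotes.

    For each SNP the mean gDNA heterozygote ratio defines the technical
    offset from 0.5; that offset is subtracted from every ratio (gDNA and
    cDNA) of the SNP.  SNPs with no gDNA heterozygote cannot be calibrated
    and are excluded with a reason code.

    Parameters
    ----------
    records : DataFrame with columns sample, snp_id, assay ("gDNA"/"cDNA"),
        ratio (A-allele fraction, NaN where missing), genotype.

    Returns
    -------
    (normalized records, exclusions) where exclusions has columns
    snp_id, reason.
    """
    rec = records.copy()
    het_gdna = rec[(rec["assay"] == "gDNA") & (rec["genotype"] == "AB") & rec["ratio"].notna()]
    offsets = het_gdna.groupby("snp_id")["ratio"].mean() - 0.5

    all_snps = rec["snp_id"].unique()
    missing = sorted(set(all_snps) - set(offsets.index))
    exclusions = pd.DataFrame({"snp_id": missing, "reason": "no_gdna_het"})

    rec = rec[rec["snp_id"].isin(offsets.index)].copy()
    rec["ratio"] = rec["ratio"] - rec["snp_id"].map(offsets)
    return rec, exclusions


def delta_het(cdna_ratio, gdna_ratio):
    """Signed allelic-expression deviation at a heterozygous SNP.

    Both ratios are A-allele fractions for the same sample and SNP after
    normalization; the sign carries the A-allele orientation (positive =
    A allele over-represented in cDNA).
    """
    return np.asarray(cdna_ratio) - np.asarray(gdna_ratio)


def phase_align(delta, a_on_hap1):
    """Orient per-SNP deltas to the phased reference chromosome.

    A positive result means haplotype 1 is over-expressed regardless of
    which allele letter it carries: the A-oriented delta is kept when the A
    allele sits on haplotype 1 and negated when it sits on haplotype 2.
    """
    delta = np.asarray(delta, dtype=float)
    sign = np.where(np.asarray(a_on_hap1, dtype=bool), 1.0, -1.0)
    return delta * sign


def aggregate_transcript(
    snp_deltas: pd.DataFrame,
    mask: list[tuple[int, int]] | None = None,
    min_snps: int = MIN_SNPS_PER_TRANSCRIPT,
) -> dict | None:
    """Average phase-oriented SNP deltas into one transcript-level profile.

    ``snp_deltas`` needs columns snp_id, pos, delta (already haplotype-
    oriented).  ``mask`` is a list of low-confidence intervals
    (0-based half-open) — e.g. regions covered by more than one gene —
    whose SNPs are excluded; a transcript whose mask removed any SNP is
    flagged partial-length.  Returns None when fewer than ``min_snps``
    informative SNPs remain.
    """
    d = snp_deltas.dropna(subset=["delta"])
    masked_out = 0
    if mask:
        keep = np.ones(len(d), dtype=bool)
        pos0 = d["pos"].to_numpy() - 1  # input positions are 1-based
        for start, end in mask:
            keep &= ~((pos0 >= start) & (pos0 < end))
        masked_out = int((~keep).sum())
        d = d[keep]
    if len(d) < min_snps:
        return None
    return {
        "delta_het": float(d["delta"].mean()),
        "n_snps": int(len(d)),
        "completeness": "partial-length" if masked_out > 0 else "full-length",
    }


def select_isoforms(fpkm: pd.DataFrame, threshold: float = FPKM_THRESHOLD) -> pd.DataFrame:
    """Keep the single most expressed isoform per gene (FPKM above threshold).

    Ties at equal FPKM go to the longest transcript when a ``length`` column
    is present, then to the lexicographically smallest transcript id, so the
    selection is deterministic.
    """
    t = fpkm[fpkm["median_fpkm"] >= threshold].copy()
    if "length" not in t.columns:
        t["length"] = 0
    t = t.sort_values(
        by=["gene_id", "median_fpkm", "length", "transcript_id"],
        ascending=[True, False, False, True],
    )
    return t.groupby("gene_id", as_index=False).head(1).drop(columns="length")


def compute_ae_profiles(
    genotypes,
    sim_data=None,
    *,
    intensities: pd.DataFrame | None = None,
    transcript_snps: pd.DataFrame | None = None,
    fpkm: pd.DataFrame | None = None,
    masks: dict[str, list[tuple[int, int]]] | None = None,
    min_snps: int = MIN_SNPS_PER_TRANSCRIPT,
) -> pd.DataFrame:
    """Full AE profiling pipeline on an intensity-ratio experiment.

    Normalizes ratios against gDNA heterozygotes, forms per-SNP deltas,
    orients them by phase from the phased genotypes, and aggregates per
    transcript.  Only transcripts passing the expressed filter (and, per
    gene, only the top isoform) are profiled.

    Returns a DataFrame with columns sample, transcript_id, delta_het,
    n_snps, completeness.
    """
    if sim_data is not None:
        intensities = sim_data.intensities
        transcript_snps = sim_data.transcript_snps
        fpkm = sim_data.fpkm
    if intensities is None or transcript_snps is None:
        raise ValueError("intensities and transcript_snps are required")

    norm, _ = normalize_ratios(intensities)
    wide = norm.pivot_table(
        index=["sample", "snp_id"], columns="assay", values="ratio", aggfunc="first"
    ).reset_index()
    if "cDNA" not in wide.columns or "gDNA" not in wide.columns:
        raise ValueError("intensity table must contain both gDNA and cDNA assays")
    wide["delta_a"] = delta_het(wide["cDNA"], wide["gDNA"])

    if fpkm is not None:
        kept = select_isoforms(fpkm)
        transcript_snps = transcript_snps[
            transcript_snps["transcript_id"].isin(kept["transcript_id"])
        ]

    snp_meta = genotypes.snps.set_index("snp_id")
    sample_ids = np.array([f"S{i}" for i in range(genotypes.n_samples)])
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    wide = wide.merge(transcript_snps, on="snp_id", how="inner")
    wide["pos"] = wide["snp_id"].map(snp_meta["pos"])

    # phase orientation per (sample, snp)
    hap = genotypes.haplotypes
    si = wide["snp_id"].map(pd.Series(np.arange(genotypes.n_snps), index=genotypes.snps["snp_id"]))
    srow = wide["sample"].map(sample_pos)
    valid = si.notna() & srow.notna()
    wide = wide[valid]
    si = si[valid].astype(int).to_numpy()
    srow = srow[valid].astype(int).to_numpy()
    a1 = hap[srow, 0, si]
    a2 = hap[srow, 1, si]
    het = a1 != a2
    a_on_hap1 = a1 == 0
    wide = wide.assign(het=het, a_on_hap1=a_on_hap1)
    wide = wide[wide["het"]]  # unphased/hom rows carry no AE information
    wide["delta"] = phase_align(wide["delta_a"].to_numpy(), wide["a_on_hap1"].to_numpy())

    rows = []
    for (sample, tx), grp in wide.groupby(["sample", "transcript_id"], sort=False):
        prof = aggregate_transcript(
            grp[["snp_id", "pos", "delta"]],
            mask=(masks or {}).get(tx),
            min_snps=min_snps,
        )
        if prof is None:
            continue
        rows.append({"sample": sample, "transcript_id": tx, **prof})
    return pd.DataFrame(rows, columns=["sample", "transcript_id", "delta_het", "n_snps", "completeness"])
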