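"""TF-perturbation readout: transcripts whose allelic imbalance collapses
when the factor is inhibited.

An allelically TF-driven transcript should show imbalance when the factor is
active and attenuated imbalance when it is inhibited, in every individual
heterozygous for the transcript's top cis-rSNP; homozygous individuals are
the built-in negative control.  The caller requires the TF-active /
TF-inhibited imbalance ratio to exceed a fold threshold (default 1.2,
strict) in at least two qualifying individuals, each measured at three or
more independent heterozygous SNPs in both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerturbationCall",
    "call_perturbed",
    "homozygote_control",
    "perturbed_signal_test",
    "class_enrichment",
    "CONDITION_ACTIVE",
    "CONDITION_INHIBITED",
]

CONDITION_ACTIVE = "TF-active"
CONDITION_INHIBITED = "TF-inhibited"
CONDITIONS = (CONDITION_ACTIVE, CONDITION_INHIBITED, "vehicle", "untreated")
FOLD_THRESHOLD = 1.2
MIN_INDIVIDUALS = 2
MIN_HET_SNPS = 3


@dataclass
class PerturbationCall:
    transcript_id: object
    folds: dict[str, float] = field(default_factory=dict)
    n_individuals_passing: int = 0
    excluded: list[str] = field(default_factory=list)
    verdict: bool = False


def _transcript_imbalance(grp: pd.DataFrame, per_snp: bool) -> tuple[float, int]:
    vals = grp["imbalance"].to_numpy(dtype=float)
    n = grp["snp_id"].nunique()
    return (float(np.median(vals)) if per_snp else float(vals.mean())), int(n)


def call_perturbed(
    records: pd.DataFrame,
    genotypes: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    min_individuals: int = MIN_INDIVIDUALS,
    min_snps: int = MIN_HET_SNPS,
    per_snp: bool = False,
) -> PerturbationCall:
    """Perturbation verdict for one transcript.

    ``records`` holds per-SNP imbalance magnitudes (columns individual,
    condition, snp_id, imbalance) for the transcript; ``genotypes`` maps
    individual to its top-cis-rSNP genotype (column top_snp_genotype,
    het = "AB").  Only heterozygous individuals qualify; each needs at
    least ``min_snps`` distinct heterozygous SNPs measured in both the
    TF-active and TF-inhibited condition.  An individual passes when its
    TF-active imbalance exceeds the TF-inhibited one by strictly more than
    ``fold_threshold``-fold; the verdict is true with ``min_individuals``
    or more passes.  ``per_snp`` switches the transcript summary from the
    mean to the median of per-SNP imbalances.
    """
    tx = records["transcript_id"].iloc[0] if len(records) else None
    het_ind = set(genotypes.loc[genotypes["top_snp_genotype"] == "AB", "individual"])
    call = PerturbationCall(transcript_id=tx)
    for ind, grp in records.groupby("individual", sort=True):
        if ind not in het_ind:
            call.excluded.append(f"{ind}:homozygous_top_snp")
            continue
        active = grp[grp["condition"] == CONDITION_ACTIVE]
        inhibited = grp[grp["condition"] == CONDITION_INHIBITED]
        imb_a, n_a = _transcript_imbalance(active, per_snp) if len(active) else (np.nan, 0)
        imb_i, n_i = _transcript_imbalance(inhibited, per_snp) if len(inhibited) else (np.nan, 0)
        if min(n_a, n_i) < min_snps:
            call.excluded.append(f"{ind}:fewer_than_{min_snps}_het_snps")
            continue
        fold = imb_a / imb_i if imb_i > 0 else np.inf
        call.folds[ind] = float(fold)
        if imb_a > imb_i and fold > fold_threshold:
            call.n_individuals_passing += 1
    call.verdict = call.n_individuals_passing >= min_individuals
    return call


def call_perturbed_all(
    records: pd.DataFrame,
    genotypes: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`call_perturbed` across transcripts; one row per transcript."""
    rows = []
    for tx, grp in records.groupby("transcript_id", sort=True):
        g = genotypes[genotypes["transcript_id"] == tx] if "transcript_id" in genotypes else genotypes
        call = call_perturbed(grp, g, **kwargs)
        rows.append(
            {
                "transcript_id": tx,
                "verdict": call.verdict,
                "n_individuals_passing": call.n_individuals_passing,
                "folds": call.folds,
            }
        )
    return pd.DataFrame(rows)


def homozygote_control(records: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Condition differences for individuals homozygous at the top cis-rSNP.

    A calibration report, not a call: homozygotes carry no phased imbalance,
    so their TF-active minus TF-inhibited difference should sit within the
    noise band.  Heterozygous individuals are rejected by precondition.
    """
    hom_mask = genotypes["top_snp_genotype"] != "AB"
    if "transcript_id" in genotypes.columns:
        hom = set(zip(genotypes.loc[hom_mask, "transcript_id"], genotypes.loc[hom_mask, "individual"]))
        is_hom = lambda tx, ind: (tx, ind) in hom  # noqa: E731
    else:
        hom_ind = set(genotypes.loc[hom_mask, "individual"])
        is_hom = lambda tx, ind: ind in hom_ind  # noqa: E731
    rows = []
    for (tx, ind), grp in records.groupby(["transcript_id", "individual"], sort=True):
        if not is_hom(tx, ind):
            continue
        active = grp.loc[grp["condition"] == CONDITION_ACTIVE, "imbalance"]
        inhibited = grp.loc[grp["condition"] == CONDITION_INHIBITED, "imbalance"]
        if active.empty or inhibited.empty:
            continue
        rows.append(
            {
                "transcript_id": tx,
                "individual": ind,
                "delta": float(active.mean() - inhibited.mean()),
                "active_mean": float(active.mean()),
                "inhibited_mean": float(inhibited.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "individual", "delta", "active_mean", "inhibited_mean"])


def perturbed_signal_test(
    perturbed_at_snp: int,
    perturbed_flank: int,
    unperturbed_at_snp: int,
    unperturbed_flank: int,
) -> dict:
    """Chi-squared comparison of TF ChIP signal at perturbed vs unperturbed
    cis-rSNPs.

    Counts are summed reads at the SNP positions versus flanking background
    for the two transcript sets; the 2x2 chi-squared (continuity-corrected)
    tests whether the at-SNP signal rate differs.  fold is the ratio of
    at-SNP count rates.  A continuity guard (+0.5) protects zero cells in
    the fold computation.
    """
    table = np.array(
        [[perturbed_at_snp, perturbed_flank], [unperturbed_at_snp, unperturbed_flank]],
        dtype=float,
    )
    if table.sum() == 0:
        raise ValueError("no counts supplied")
    rate_p = (perturbed_at_snp + 0.5) / (perturbed_at_snp + perturbed_flank + 1.0)
    rate_u = (unperturbed_at_snp + 0.5) / (unperturbed_at_snp + unperturbed_flank + 1.0)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = np.nan
        chi2 = np.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return {"fold": float(rate_p / rate_u), "chi2": float(chi2), "p_value": float(p)}


def class_enrichment(
    perturbed: pd.DataFrame,
    biotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-biotype enrichment of perturbed transcripts vs the mapped background.

    ``perturbed`` has transcript_id + verdict (bool); ``biotypes`` maps
    transcript_id to biotype.  Each biotype present in the background gets a
    2x2 chi-squared of biotype membership vs perturbation status; biotypes
    absent from the perturbed set are still reported (fold 0) while biotypes
    absent entirely are skipped with a note column.
    """
    tbl = perturbed.merge(biotypes, on="transcript_id", how="left")
    tbl["biotype"] = tbl["biotype"].fillna("unknown")
    n_total = len(tbl)
    n_pert = int(tbl["verdict"].sum())
    rows = []
    for bt in sorted(tbl["biotype"].unique()):
        in_bt = tbl["biotype"] == bt
        a = int((in_bt & tbl["verdict"]).sum())
        b = n_pert - a
        c = int(in_bt.sum()) - a
        d = n_total - a - b - c
        expected = in_bt.mean() * n_pert
        fold = a / expected if expected > 0 else np.nan
        table = np.array([[a, b], [c, d]])
        note = ""
        if in_bt.sum() == 0:
            note = "biotype absent"
            p = np.nan
        elif n_pert == 0 or n_pert == n_total:
            note = "degenerate perturbation split"
            p = np.nan
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append(
            {
                "biotype": bt,
                "observed": a,
                "expected": float(expected),
                "fold": float(fold) if np.isfinite(fold) else np.nan,
                "p_value": float(p) if np.isfinite(p) else np.nan,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
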