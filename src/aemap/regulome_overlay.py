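"""Chromatin and GWAS overlays for mapped cis-rSNPs.

Links AE-mapped regulatory variants to orthogonal evidence: ChIP read depth
stratified by genotype (oriented to the over-expressed allele of the mapped
association), allelic ChIP read counts at heterozygous sites, haplotype LD
(r^2) with GWAS-catalog variants, and trait-category enrichment of the
resulting locus-disease table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDResult",
    "depth_genotype_test",
    "allelic_chip_test",
    "ld_r2",
    "gwas_intersect",
    "trait_enrichment",
]

HIGH_LD_R2 = 0.9
GWAS_P_MAX = 5e-8
EXACT_TEST_MAX_TOTAL = 25


@dataclass
class LDResult:
    snp_pair: tuple[str, str]
    r2: float
    n_haplotypes: int
    defined: bool = True


def depth_genotype_test(depths: pd.DataFrame) -> dict:
    """Compare ChIP depth between the two homozygote classes.

    ``depths`` needs columns n_over_alleles (0/1/2 copies of the
    over-expressed allele, oriented from the mapped association) and depth
    (library-size-normalized read depth, normalization assumed upstream).
    Returns the hom-over / hom-under mean-depth fold with a Welch t-test P.
    For activator-like sites the fold exceeds 1; repressor sites invert.
    """
    over = depths.loc[depths["n_over_alleles"] == 2, "depth"].to_numpy(dtype=float)
    under = depths.loc[depths["n_over_alleles"] == 0, "depth"].to_numpy(dtype=float)
    if len(over) < 2 or len(under) < 2:
        raise ValueError("need at least two samples in each homozygote class")
    t, p = stats.ttest_ind(over, under, equal_var=False)
    return {
        "fold": float(over.mean() / under.mean()),
        "t": float(t),
        "p_value": float(p),
        "n_over_hom": len(over),
        "n_under_hom": len(under),
    }


def allelic_chip_test(
    over_count: int,
    under_count: int,
    min_total: int = 10,
    exact_below: int = EXACT_TEST_MAX_TOTAL,
) -> dict:
    """Allelic imbalance of ChIP reads at a heterozygous site vs 50:50.

    Counts are oriented to the mapped association (reads carrying the
    over-expressed haplotype vs the other).  A chi-squared goodness-of-fit
    test is used, switching to the exact binomial when the total is below
    ``exact_below``.  Totals below ``min_total`` are rejected.
    """
    over_count, under_count = int(over_count), int(under_count)
    total = over_count + under_count
    if total < min_total:
        raise ValueError(f"total count {total} below minimum {min_total}")
    if total < exact_below:
        p = float(stats.binomtest(over_count, total, 0.5).pvalue)
        method = "exact-binomial"
        chi2 = np.nan
    else:
        exp = total / 2.0
        chi2 = float((over_count - exp) ** 2 / exp + (under_count - exp) ** 2 / exp)
        p = float(stats.chi2.sf(chi2, df=1))
        method = "chi-squared"
    return {
        "bias": over_count / under_count if under_count else np.inf,
        "chi2": chi2,
        "p_value": p,
        "method": method,
        "total": total,
    }


def ld_r2(hap_a, hap_b, snp_pair: tuple[str, str] = ("a", "b")) -> LDResult:
    """Haplotype-based LD r^2 between two biallelic sites.

    ``hap_a``/``hap_b`` are equal-length 0/1 allele vectors over the same
    phased haplotypes.  r^2 = D^2 / (pA qA pB qB) with D the haplotype
    frequency deviation pAB - pA pB.  Monomorphic input leaves r^2
    undefined (NaN, flagged).
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors must align")
    n = len(a)
    pa = a.mean()
    pb = b.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return LDResult(snp_pair, np.nan, n, defined=False)
    pab = np.mean((a == 1) & (b == 1))
    d = pab - pa * pb
    return LDResult(snp_pair, float(d * d / denom), n, defined=True)


def gwas_intersect(
    rsnps: pd.DataFrame,
    catalog: pd.DataFrame,
    haplotypes: dict[str, np.ndarray],
    r2_min: float = HIGH_LD_R2,
    p_gwas_max: float = GWAS_P_MAX,
) -> pd.DataFrame:
    """Locus-disease table from LD between cis-rSNPs and GWAS hits.

    ``rsnps`` carries the retained cis-rSNPs per locus (columns locus,
    snp_id); ``catalog`` is a GWAS-catalog-like table (snp_id, trait,
    p_value); ``haplotypes`` maps snp_id to its phased 0/1 allele vector.
    A locus qualifies when at least one of its retained SNPs is in high LD
    (r^2 >= r2_min) with a catalog SNP at genome-wide significance; one row
    is emitted per (locus, trait) since the same regulatory variant can be
    associated with several diseases.
    """
    cat = catalog[catalog["p_value"] < p_gwas_max]
    rows = []
    for locus, grp in rsnps.groupby("locus", sort=False):
        traits: dict[str, dict] = {}
        for sid in grp["snp_id"]:
            ha = haplotypes.get(sid)
            if ha is None:
                continue
            for _, hit in cat.iterrows():
                hb = haplotypes.get(hit["snp_id"])
                if hb is None:
                    continue
                res = ld_r2(ha, hb, (sid, hit["snp_id"]))
                if res.defined and res.r2 >= r2_min:
                    prev = traits.get(hit["trait"])
                    if prev is None or res.r2 > prev["r2"]:
                        traits[hit["trait"]] = {
                            "locus": locus,
                            "trait": hit["trait"],
                            "rsnp": sid,
                            "gwas_snp": hit["snp_id"],
                            "r2": res.r2,
                            "gwas_p": hit["p_value"],
                        }
        rows.extend(traits.values())
    return pd.DataFrame(rows, columns=["locus", "trait", "rsnp", "gwas_snp", "r2", "gwas_p"])


def trait_enrichment(
    locus_disease: pd.DataFrame,
    category_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(category, population) enrichment of GWAS-linked cis-rSNPs.

    ``locus_disease`` needs columns trait and population (the cell
    population whose specific cis-rSNPs produced the LD link);
    ``category_map`` maps trait to category.  For every category x
    population cell a 2x2 chi-squared test (with continuity correction)
    of category membership against population identity is computed;
    fold = observed / expected proportion.
    """
    tbl = locus_disease.merge(category_map, on="trait", how="left")
    tbl["category"] = tbl["category"].fillna("other")
    rows = []
    total = len(tbl)
    for cat in sorted(tbl["category"].unique()):
        in_cat = tbl["category"] == cat
        for pop in sorted(tbl["population"].unique()):
            in_pop = tbl["population"] == pop
            a = int((in_cat & in_pop).sum())
            b = int((in_cat & ~in_pop).sum())
            c = int((~in_cat & in_pop).sum())
            d = total - a - b - c
            n_pop = a + c
            expected = in_cat.mean() * n_pop
            fold = a / expected if expected > 0 else np.nan
            table = np.array([[a, b], [c, d]])
            if table.sum() == 0 or (a + b) == 0 or n_pop == 0:
                p = np.nan
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=True)
            rows.append(
                {
                    "category": cat,
                    "population": pop,
                    "observed": a,
                    "expected": float(expected),
                    "fold": float(fold) if np.isfinite(fold) else np.nan,
                    "p_value": float(p) if np.isfinite(p) else np.nan,
                }
            )
    return pd.DataFrame(rows)
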