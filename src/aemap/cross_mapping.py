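"""Cross-population sharing of AE associations.

Three complementary views of sharing between two cell populations:

* a strict per-locus verdict — a locus shares regulatory activity when at
  least one of its primary top associations falls in the secondary
  population's first percentile of tested SNPs, passes a fixed secondary
  P cutoff (default 1.1e-4) and agrees in effect direction;
* the Storey pi1 statistic — the estimated proportion of true associations
  among lead SNP-transcript pairs re-tested in the other population;
* Fisher's combined probability over populations for shared loci, which
  sharpens fine-mapping by breaking up LD blocks.

The strict verdict is deliberately asymmetric: primary associations are held
to their own discovery threshold while the secondary population is only
asked for corroboration, so swapping the roles can change the verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SharingVerdict",
    "SharingEstimate",
    "MetaAssociation",
    "shared_association",
    "direction_concordance",
    "estimate_pi1",
    "fisher_combine",
    "meta_shrinkage_report",
]

SECONDARY_P_CUTOFF = 1.1e-4
PERCENTILE = 1.0


@dataclass
class SharingVerdict:
    locus: object
    population_pair: tuple[str, str]
    shared: bool
    supporting_snps: list[str] = field(default_factory=list)
    in_percentile: list[str] = field(default_factory=list)
    below_cutoff: list[str] = field(default_factory=list)
    direction_concordant: bool = False


@dataclass
class SharingEstimate:
    population_pair: tuple[str, str]
    pi0: float
    lambda_grid: np.ndarray
    method: str = "cubic-smoother"

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


@dataclass
class MetaAssociation:
    snp_id: object
    transcript_id: object
    p_values: list[float]
    statistic: float
    combined_p: float

    @property
    def df(self) -> int:
        return 2 * len(self.p_values)


def shared_association(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    locus: object = None,
    population_pair: tuple[str, str] = ("A", "B"),
    p_cutoff: float = SECONDARY_P_CUTOFF,
    percentile: float = PERCENTILE,
) -> SharingVerdict:
    """Strict sharing verdict for one locus between two populations.

    ``primary`` holds the locus's retained top associations in the discovery
    population (columns snp_id, p_value, slope); ``secondary`` holds all
    tested SNPs for the same locus in the other population (same columns).
    A supporting SNP must (i) rank within the secondary population's first
    ``percentile`` of SNPs by P for this locus (at least one SNP), (ii) have
    secondary P below ``p_cutoff`` and (iii) agree in slope sign; each
    condition is reported separately.
    """
    sec = secondary.dropna(subset=["p_value"]).copy()
    n_keep = max(1, int(np.floor(len(sec) * percentile / 100.0)))
    top_sec = set(sec.nsmallest(n_keep, "p_value")["snp_id"])
    sec_p = sec.set_index("snp_id")["p_value"]
    sec_slope = sec.set_index("snp_id")["slope"]

    in_pct, below, supporting = [], [], []
    concordant = False
    for _, row in primary.dropna(subset=["p_value"]).iterrows():
        sid = row["snp_id"]
        if sid not in sec_p.index:
            continue
        cond_pct = sid in top_sec
        cond_p = sec_p[sid] < p_cutoff
        s_sec = np.sign(sec_slope[sid])
        cond_dir = bool(np.sign(row["slope"]) == s_sec) and s_sec != 0
        if cond_pct:
            in_pct.append(sid)
        if cond_p:
            below.append(sid)
        if cond_pct and cond_p:
            if cond_dir:
                supporting.append(sid)
                concordant = True
    return SharingVerdict(
        locus=locus,
        population_pair=population_pair,
        shared=len(supporting) > 0,
        supporting_snps=supporting,
        in_percentile=in_pct,
        below_cutoff=below,
        direction_concordant=concordant,
    )


def direction_concordance(slopes_a, slopes_b) -> dict:
    """Fraction of shared associations with the same effect direction."""
    a = np.sign(np.asarray(slopes_a, dtype=float))
    b = np.sign(np.asarray(slopes_b, dtype=float))
    if len(a) != len(b):
        raise ValueError("paired slope vectors must have equal length")
    same = a == b
    n = len(same)
    frac = float(same.mean()) if n else np.nan
    if n:
        ci = stats.binomtest(int(same.sum()), n).proportion_ci(0.95)
        lo, hi = float(ci.low), float(ci.high)
    else:
        lo = hi = np.nan
    return {"fraction": frac, "n": n, "ci_low": lo, "ci_high": hi}


def estimate_pi1(
    pvalues,
    population_pair: tuple[str, str] = ("A", "B"),
    lambda_grid: np.ndarray | None = None,
) -> SharingEstimate:
    """Storey estimate of the shared-association proportion pi1 = 1 - pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a lambda
    grid (default 0, 0.05, ..., 0.90), smoothed with a cubic polynomial and
    read off at the largest lambda, then clipped to [0, 1].  With fewer than
    100 P-values the smoother is unstable, so the estimate falls back to the
    single point lambda = 0.5 with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    m = len(p)
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.95, 0.05)
    if m < 100:
        warnings.warn("fewer than 100 P-values: using fixed lambda = 0.5", stacklevel=2)
        pi0 = float(np.clip((p > 0.5).sum() / (m * 0.5), 0.0, 1.0)) if m else np.nan
        return SharingEstimate(population_pair, pi0, np.array([0.5]), method="fixed-lambda-0.5")
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid])
    coef = np.polyfit(lambda_grid, pi0_lambda, deg=3)
    pi0 = float(np.clip(np.polyval(coef, lambda_grid.max()), 0.0, 1.0))
    return SharingEstimate(population_pair, pi0, lambda_grid)


def fisher_combine(p_values, snp_id=None, transcript_id=None) -> MetaAssociation:
    """Fisher's combined probability: -2 sum(ln p) against chi2 with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(statistic, df=2 * len(p)))
    return MetaAssociation(
        snp_id=snp_id,
        transcript_id=transcript_id,
        p_values=list(p),
        statistic=statistic,
        combined_p=combined,
    )


def meta_shrinkage_report(
    before: pd.Series | np.ndarray,
    after: pd.Series | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Fold reduction in associated SNPs per locus after meta-analysis.

    ``before``/``after`` are per-locus retained-SNP counts for the same loci.
    Returns the ratio of means with a bootstrap percentile CI.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if len(b) != len(a):
        raise ValueError("before/after must be paired per locus")
    if a.mean() == 0:
        raise ValueError("after counts are all zero")
    ratio = float(b.mean() / a.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(b), size=(n_boot, len(b)))
    boots = b[idx].mean(axis=1) / np.maximum(a[idx].mean(axis=1), 1e-300)
    return {
        "fold_reduction": ratio,
        "ci_low": float(np.quantile(boots, 0.025)),
        "ci_high": float(np.quantile(boots, 0.975)),
        "n_loci": len(b),
    }
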