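"""Synthetic data generation for allelic-expression (AE) mapping.

Every generator here produces data with a known ground truth so that each
downstream stage of the pipeline (AE profiling, cis-rSNP regression, motif
classification, chromatin overlays, perturbation calling) has a recoverable
answer.  The genotype model is deliberately simple: independent loci, each a
single LD block in which adjacent SNPs are correlated through a first-order
copying process (copy the previous allele with probability ``rho``, otherwise
redraw at the SNP's own allele frequency).  This creates the ranked-SNP
ambiguity that makes top-k causal retention a non-trivial question without
requiring a coalescent simulator.

Conventions
-----------
* Alleles are coded 0 = A and 1 = B; allelic ratios are A-allele fractions
  in [0, 1].
* Haplotype index 0 is "haplotype 1" (the phased reference chromosome).
* Each generator draws from its own RNG stream derived from the master seed,
  so adding a generator never shifts another generator's draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PhasedGenotypeSet",
    "GroundTruth",
    "AESimData",
    "MotifLandscape",
    "simulate_haplotypes",
    "make_ground_truth",
    "simulate_ae_intensities",
    "simulate_motif_landscape",
    "simulate_chip_depths",
    "simulate_perturbation",
]

# stream ids: one per generator, all derived from the master seed
_STREAM_HAPLOTYPES = 0
_STREAM_TRUTH = 1
_STREAM_INTENSITIES = 2
_STREAM_MOTIFS = 3
_STREAM_CHIP = 4
_STREAM_PERTURB = 5

NUCLEOTIDES = np.array(["A", "C", "G", "T"])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic AE experiment.

    Defaults describe the standard fixture: 100 samples, 200 candidate loci
    of 30 SNPs each with strong block LD (rho = 0.9), an additive allelic
    effect of 0.15 delta-het-ratio units per phased allele copy and
    per-measurement Gaussian noise of SD 0.05.
    """

    n_samples: int = 100
    n_loci: int = 200
    block_len: int = 60_000
    snps_per_block: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.9
    effect_size: float = 0.15
    noise_sd: float = 0.05
    gdna_noise_sd: float = 0.01
    snp_offset_sd: float = 0.02
    snps_per_transcript: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_loci": self.n_loci,
            "block_len": self.block_len,
            "snps_per_block": self.snps_per_block,
            "snps_per_transcript": self.snps_per_transcript,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.noise_sd < 0 or self.gdna_noise_sd < 0 or self.snp_offset_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.snps_per_transcript > self.snps_per_block:
            raise ValueError("snps_per_transcript cannot exceed snps_per_block")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class PhasedGenotypeSet:
    """Phased biallelic genotypes: per sample, two haplotypes of 0/1 alleles.

    ``haplotypes`` has shape (n_samples, 2, n_snps); haplotype index 0 is the
    phased reference chromosome. ``snps`` carries snp_id, chrom, pos (1-based),
    locus, maf_target and maf_realized.
    """

    haplotypes: np.ndarray
    snps: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def dosage(self) -> np.ndarray:
        """B-allele count per sample x SNP (0, 1 or 2)."""
        return self.haplotypes.sum(axis=1)

    def snp_index(self, snp_id: str) -> int:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return int(idx[0])

    def locus_snp_indices(self, locus: int) -> np.ndarray:
        return np.flatnonzero(self.snps["locus"].to_numpy() == locus)


@dataclass
class GroundTruth:
    """Planted truth: one causal cis-rSNP per locus with an additive effect.

    ``causal`` columns: locus, snp_id, snp_index, effect (magnitude in
    delta-het-ratio units), up_allele (0 = A, 1 = B: the allele whose
    haplotype is over-expressed).
    """

    causal: pd.DataFrame

    def causal_for(self, locus: int) -> pd.Series:
        rows = self.causal[self.causal["locus"] == locus]
        if rows.empty:
            raise KeyError(f"locus {locus} has no causal record")
        return rows.iloc[0]


def simulate_haplotypes(config: SimConfig) -> PhasedGenotypeSet:
    """Draw phased haplotypes with per-block first-order copying LD.

    Within a block, SNP j copies SNP j-1's allele on the same haplotype with
    probability ``rho`` and otherwise redraws a Bernoulli at its own target
    MAF; blocks are independent.  Any SNP whose realized minor allele
    frequency falls below the configured minimum is redrawn (the chain then
    continues from the accepted column), failing loudly if the configuration
    makes the bound unattainable.
    """
    lo, hi = config.maf_range
    n_hap = 2 * config.n_samples
    if np.ceil(lo * n_hap) > n_hap // 2:
        raise ValueError(
            f"minimum MAF {lo} cannot be realized with {config.n_samples} samples"
        )
    rng = _rng(config.seed, _STREAM_HAPLOTYPES)
    n_snps = config.n_loci * config.snps_per_block
    mafs = rng.uniform(lo, hi, size=n_snps)

    hap_flat = np.empty((n_hap, n_snps), dtype=np.int8)
    max_retries = 1000
    for b in range(config.n_loci):
        prev = None
        for j in range(config.snps_per_block):
            k = b * config.snps_per_block + j
            for attempt in range(max_retries + 1):
                fresh = (rng.random(n_hap) < mafs[k]).astype(np.int8)
                if prev is None or config.rho == 0.0:
                    col = fresh
                else:
                    copy = rng.random(n_hap) < config.rho
                    col = np.where(copy, prev, fresh).astype(np.int8)
                freq = col.mean()
                if min(freq, 1.0 - freq) >= lo:
                    break
            else:
                raise RuntimeError(
                    f"could not realize MAF >= {lo} at SNP {k} after {max_retries} redraws"
                )
            hap_flat[:, k] = col
            prev = col

    freq = hap_flat.mean(axis=0)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{b}_{j}" for b in range(config.n_loci) for j in range(config.snps_per_block)],
            "chrom": [f"L{b}" for b in range(config.n_loci) for _ in range(config.snps_per_block)],
            "pos": _block_positions(config, rng),
            "locus": np.repeat(np.arange(config.n_loci), config.snps_per_block),
            "maf_target": mafs,
            "maf_realized": np.minimum(freq, 1.0 - freq),
        }
    )
    haplotypes = hap_flat.reshape(config.n_samples, 2, n_snps)
    return PhasedGenotypeSet(haplotypes=haplotypes, snps=snps)


def _block_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """1-based sorted positions within each block; one block per chromosome."""
    out = np.empty(config.n_loci * config.snps_per_block, dtype=np.int64)
    for b in range(config.n_loci):
        pos = np.sort(
            rng.choice(config.block_len, size=config.snps_per_block, replace=False)
        )
        out[b * config.snps_per_block : (b + 1) * config.snps_per_block] = pos + 1
    return out


def make_ground_truth(genotypes: PhasedGenotypeSet, config: SimConfig) -> GroundTruth:
    """Pick one causal SNP per locus and an over-expressed ("up") allele."""
    rng = _rng(config.seed, _STREAM_TRUTH)
    records = []
    for b in range(config.n_loci):
        idx = genotypes.locus_snp_indices(b)
        causal = int(rng.choice(idx))
        records.append(
            {
                "locus": b,
                "snp_id": genotypes.snps.loc[causal, "snp_id"],
                "snp_index": causal,
                "effect": float(config.effect_size),
                "up_allele": int(rng.integers(2)),
            }
        )
    return GroundTruth(causal=pd.DataFrame(records))


@dataclass
class AESimData:
    """Synthetic intensity-ratio experiment.

    ``intensities`` mirrors the array export: one row per
    (sample, snp, assay) with the A-allele ratio and the genotype call;
    homozygous transcribed SNPs carry a missing ratio (NaN) rather than
    being silently dropped.  ``transcripts`` is the transcript model table,
    ``fpkm`` the RNA-seq expression summary used for the expressed filter.
    """

    intensities: pd.DataFrame
    transcripts: pd.DataFrame
    transcript_snps: pd.DataFrame
    fpkm: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def simulate_ae_intensities(
    genotypes: PhasedGenotypeSet, truth: GroundTruth, config: SimConfig
) -> AESimData:
    """Emit gDNA and cDNA allelic ratio tables with a planted cis effect.

    gDNA ratios at heterozygous transcribed SNPs sit at 0.5 plus a per-SNP
    technical offset (shared with cDNA, removed later by normalization) plus
    small noise.  cDNA ratios are additionally shifted by ``effect_size``
    toward the haplotype carrying the causal "up" allele, with the sign set
    by phase; samples homozygous at the causal SNP get no shift.
    """
    rng = _rng(config.seed, _STREAM_INTENSITIES)
    n = config.n_samples
    geno_names = np.array(["AA", "AB", "BB"])

    tx_rows, snp_rows, fpkm_rows, warn = [], [], [], []
    records: list[pd.DataFrame] = []
    for b in range(config.n_loci):
        block_idx = genotypes.locus_snp_indices(b)
        transcribed = np.sort(rng.choice(block_idx, size=config.snps_per_transcript, replace=False))
        causal = truth.causal_for(b)
        ci = int(causal["snp_index"])
        up = int(causal["up_allele"])
        eff = float(causal["effect"])

        hap = genotypes.haplotypes  # (n, 2, n_snps)
        causal_het = hap[:, 0, ci] != hap[:, 1, ci]
        # over-expressed haplotype index for causal hets: the one carrying `up`
        over_hap = np.where(hap[:, 0, ci] == up, 0, 1)

        offsets = rng.normal(0.0, config.snp_offset_sd, size=len(transcribed))
        any_het = False
        for t, si in enumerate(transcribed):
            a1 = hap[:, 0, si]
            a2 = hap[:, 1, si]
            het = a1 != a2
            any_het |= bool(het.any())
            dosage = a1 + a2
            # orientation: +1 if the A allele of this SNP rides the
            # over-expressed haplotype, -1 otherwise, 0 for causal homozygotes
            a_on_hap1 = a1 == 0
            s = np.zeros(n)
            sel = het & causal_het
            a_hap = np.where(a_on_hap1, 0, 1)  # haplotype carrying A at this SNP
            s[sel] = np.where(a_hap[sel] == over_hap[sel], 1.0, -1.0)

            gdna = 0.5 + offsets[t] + rng.normal(0.0, config.gdna_noise_sd, size=n)
            cdna = 0.5 + offsets[t] + s * eff + rng.normal(0.0, config.noise_sd, size=n)
            gdna = np.clip(gdna, 0.0, 1.0)
            cdna = np.clip(cdna, 0.0, 1.0)
            gdna[~het] = np.nan
            cdna[~het] = np.nan

            snp_id = genotypes.snps.loc[si, "snp_id"]
            base = pd.DataFrame(
                {
                    "sample": [f"S{i}" for i in range(n)],
                    "snp_id": snp_id,
                    "genotype": geno_names[dosage],
                }
            )
            g = base.copy()
            g["assay"] = "gDNA"
            g["ratio"] = gdna
            c = base.copy()
            c["assay"] = "cDNA"
            c["ratio"] = cdna
            records.append(g)
            records.append(c)
            snp_rows.append({"transcript_id": f"T{b}", "snp_id": snp_id, "snp_index": int(si)})

        if not any_het:
            warn.append(f"transcript T{b}: no heterozygous transcribed SNP in any sample")

        pos = genotypes.snps.loc[transcribed, "pos"]
        tx_rows.append(
            {
                "gene_id": f"G{b}",
                "transcript_id": f"T{b}",
                "chrom": genotypes.snps.loc[transcribed[0], "chrom"],
                "start": int(pos.min()) - 100,
                "end": int(pos.max()) + 100,
                "strand": "+",
            }
        )
        fpkm_rows.append(
            {"transcript_id": f"T{b}", "gene_id": f"G{b}", "median_fpkm": float(rng.uniform(1.0, 50.0))}
        )

    intensities = pd.concat(records, ignore_index=True)[
        ["sample", "snp_id", "assay", "ratio", "genotype"]
    ]
    for msg in warn:
        warnings.warn(msg, stacklevel=2)
    return AESimData(
        intensities=intensities,
        transcripts=pd.DataFrame(tx_rows),
        transcript_snps=pd.DataFrame(snp_rows),
        fpkm=pd.DataFrame(fpkm_rows),
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# motif landscape
# ---------------------------------------------------------------------------

@dataclass
class MotifLandscape:
    """Planted motif instances straddling variants, with true activity labels.

    ``motifs`` maps motif id -> (width x 4) probability matrix (column order
    A, C, G, T).  ``sites`` has one row per variant site: the two 31-nt
    allelic windows (variant at offset 15), which allele scores higher under
    the planted matrix, and which allele the mapped association says is
    over-expressed.  ``labels`` carries the true activity class per motif.
    """

    motifs: dict[str, np.ndarray]
    sites: pd.DataFrame
    labels: pd.DataFrame
    window_flank: int = 15


def _sample_pwm(rng: np.random.Generator, width: int, sharpness: float = 0.85) -> np.ndarray:
    pwm = np.full((width, 4), (1.0 - sharpness) / 3.0)
    dom = rng.integers(0, 4, size=width)
    pwm[np.arange(width), dom] = sharpness
    return pwm


def simulate_motif_landscape(
    n_motifs: int = 12,
    sites_per_motif: int = 40,
    width: int = 8,
    p_act: float = 0.9,
    labels: list[str] | None = None,
    seed: int = 0,
    window_flank: int = 15,
    sources: list[str] | None = None,
) -> MotifLandscape:
    """Plant motif instances over SNVs with a configurable allelic bias.

    For an activator-labeled motif the higher-scoring allele lands on the
    over-expressed haplotype with probability ``p_act``; repressors are
    mirrored (probability ``1 - p_act``); neutral motifs sit at 0.5.
    """
    if width > 2 * window_flank + 1:
        raise ValueError(
            f"motif width {width} exceeds the scan window of {2 * window_flank + 1} nt"
        )
    rng = _rng(seed, _STREAM_MOTIFS)
    if labels is None:
        cycle = ["activator", "repressor", "neutral"]
        labels = [cycle[i % 3] for i in range(n_motifs)]
    if len(labels) != n_motifs:
        raise ValueError("labels must have one entry per motif")
    bad = set(labels) - {"activator", "repressor", "neutral"}
    if bad:
        raise ValueError(f"unknown activity labels: {sorted(bad)}")
    if sources is None:
        src_cycle = ["TRANSFAC", "de-novo", "footprint-known"]
        sources = [src_cycle[i % 3] for i in range(n_motifs)]

    wlen = 2 * window_flank + 1
    motifs: dict[str, np.ndarray] = {}
    site_rows = []
    label_rows = []
    for m in range(n_motifs):
        motif_id = f"M{m}"
        pwm = _sample_pwm(rng, width)
        motifs[motif_id] = pwm
        consensus = pwm.argmax(axis=1)
        weakest = pwm.argmin(axis=1)
        label = labels[m]
        p_strong_over = {"activator": p_act, "repressor": 1.0 - p_act, "neutral": 0.5}[label]
        label_rows.append({"motif_id": motif_id, "true_label": label, "source": sources[m]})

        for s in range(sites_per_motif):
            flanks = rng.integers(0, 4, size=wlen)
            window = flanks.copy()
            # place the motif so that it covers the central variant position
            start = int(rng.integers(window_flank - width + 1, window_flank + 1))
            window[start : start + width] = consensus
            var_in_motif = window_flank - start
            strong = window.copy()
            weak = window.copy()
            weak[window_flank] = weakest[var_in_motif]
            if strong[window_flank] == weak[window_flank]:
                # degenerate column: force a different base on the weak allele
                weak[window_flank] = (strong[window_flank] + 1) % 4

            strong_is_ref = bool(rng.random() < 0.5)
            ref, alt = (strong, weak) if strong_is_ref else (weak, strong)
            strong_over = bool(rng.random() < p_strong_over)
            over_allele = ("ref" if strong_is_ref else "alt") if strong_over else (
                "alt" if strong_is_ref else "ref"
            )
            site_rows.append(
                {
                    "motif_id": motif_id,
                    "site_id": f"{motif_id}_s{s}",
                    "ref_window": "".join(NUCLEOTIDES[ref]),
                    "alt_window": "".join(NUCLEOTIDES[alt]),
                    "higher_allele": "ref" if strong_is_ref else "alt",
                    "over_allele": over_allele,
                    "motif_start": start,
                    "cell_type": f"C{rng.integers(3)}",
                }
            )
    return MotifLandscape(
        motifs=motifs,
        sites=pd.DataFrame(site_rows),
        labels=pd.DataFrame(label_rows),
        window_flank=window_flank,
    )


# ---------------------------------------------------------------------------
# ChIP depths and perturbation
# ---------------------------------------------------------------------------

def simulate_chip_depths(
    genotypes: PhasedGenotypeSet,
    truth: GroundTruth,
    site_labels: dict[int, str] | None = None,
    base_depth: float = 100.0,
    depth_effect: float = 0.2,
    depth_noise_sd: float = 5.0,
    allelic_total: int = 80,
    allelic_bias: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized ChIP depth per sample at causal SNPs + allelic het counts.

    Depth is linear in the number of over-expressed-allele copies for
    activator-labeled sites and inverted for repressor sites; allelic read
    counts at heterozygous sites are binomial with the matching bias
    (toward the over-expressed haplotype for activators, away for
    repressors).
    """
    rng = _rng(seed, _STREAM_CHIP)
    if site_labels is None:
        site_labels = {
            int(r["locus"]): ("activator" if i % 2 == 0 else "repressor")
            for i, (_, r) in enumerate(truth.causal.iterrows())
        }
    depth_rows, count_rows = [], []
    n = genotypes.n_samples
    for _, rec in truth.causal.iterrows():
        locus = int(rec["locus"])
        label = site_labels.get(locus, "activator")
        direction = 1.0 if label == "activator" else -1.0
        ci = int(rec["snp_index"])
        up = int(rec["up_allele"])
        hap = genotypes.haplotypes
        n_up = (hap[:, 0, ci] == up).astype(int) + (hap[:, 1, ci] == up).astype(int)
        depth = base_depth * (1.0 + direction * depth_effect * (n_up - 1)) + rng.normal(
            0.0, depth_noise_sd, size=n
        )
        for i in range(n):
            depth_rows.append(
                {
                    "snp_id": rec["snp_id"],
                    "locus": locus,
                    "label": label,
                    "sample": f"S{i}",
                    "n_over_alleles": int(n_up[i]),
                    "depth": float(max(depth[i], 0.0)),
                }
            )
        het = hap[:, 0, ci] != hap[:, 1, ci]
        p_over = 0.5 + direction * allelic_bias
        for i in np.flatnonzero(het):
            over = int(rng.binomial(allelic_total, p_over))
            count_rows.append(
                {
                    "snp_id": rec["snp_id"],
                    "locus": locus,
                    "label": label,
                    "sample": f"S{i}",
                    "over_count": over,
                    "under_count": allelic_total - over,
                }
            )
    return pd.DataFrame(depth_rows), pd.DataFrame(count_rows)


CONDITIONS = ("TF-active", "TF-inhibited", "vehicle", "untreated")


def simulate_perturbation(
    n_transcripts: int = 50,
    n_individuals: int = 6,
    n_het_snps: int = 4,
    frac_perturbed: float = 0.5,
    imbalance: float = 0.2,
    fold: float = 1.6,
    noise_sd: float = 0.02,
    het_prob: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-condition AE tables for a TF perturbation experiment.

    Truly TF-driven transcripts carry allelic imbalance ``imbalance`` in the
    TF-active condition that drops by ``fold`` under TF inhibition in every
    individual heterozygous for the top cis-rSNP; non-driven transcripts keep
    the same imbalance in both conditions.  Homozygous individuals show no
    imbalance beyond noise in any condition.

    Returns (condition AE table, per-individual top-SNP genotype table,
    ground-truth table).
    """
    rng = _rng(seed, _STREAM_PERTURB)
    ae_rows, geno_rows, truth_rows = [], [], []
    for t in range(n_transcripts):
        tx = f"P{t}"
        perturbed = bool(rng.random() < frac_perturbed)
        truth_rows.append({"transcript_id": tx, "perturbed": perturbed})
        # guarantee at least two informative hets so planted calls are possible
        het_flags = rng.random(n_individuals) < het_prob
        while het_flags.sum() < 2:
            het_flags = rng.random(n_individuals) < het_prob
        for i in range(n_individuals):
            ind = f"I{i}"
            het = bool(het_flags[i])
            geno_rows.append(
                {"individual": ind, "transcript_id": tx, "top_snp_genotype": "AB" if het else "AA"}
            )
            for cond in CONDITIONS:
                if not het:
                    level = 0.0
                elif cond == "TF-inhibited" and perturbed:
                    level = imbalance / fold
                else:
                    level = imbalance
                for s in range(n_het_snps):
                    dev = abs(rng.normal(level, noise_sd))
                    ae_rows.append(
                        {
                            "individual": ind,
                            "transcript_id": tx,
                            "condition": cond,
                            "snp_id": f"{tx}_snp{s}",
                            "imbalance": float(dev),
                        }
                    )
    return pd.DataFrame(ae_rows), pd.DataFrame(geno_rows), pd.DataFrame(truth_rows)
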