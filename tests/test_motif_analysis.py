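"""PWM scoring, exact score P-values, variant scanning, activity calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aemap import motif_analysis as ma
from aemap import synthgen


def _matrix(probs, motif_id="m", source="TRANSFAC-like"):
    return ma.MotifMatrix(motif_id=motif_id, probs=np.asarray(probs), source=source)


SHARP = _matrix(
    [
        [0.85, 0.05, 0.05, 0.05],
        [0.05, 0.85, 0.05, 0.05],
        [0.05, 0.05, 0.85, 0.05],
        [0.05, 0.05, 0.05, 0.85],
    ]
)


class TestLogOdds:
    def test_consensus_is_maximal(self):
        best = ma.pwm_logodds("ACGT", SHARP)
        for seq in ("".join(s) for s in itertools.product("ACGT", repeat=4)):
            assert ma.pwm_logodds(seq, SHARP) <= best + 1e-12

    def test_uniform_matrix_scores_zero(self):
        uni = _matrix(np.full((5, 4), 0.25))
        assert ma.pwm_logodds("ACGTA", uni) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # score(ACGA) = 3*log2(0.85/0.25) + log2(0.05/0.25)
        expected = 3 * np.log2(0.85 / 0.25) + np.log2(0.05 / 0.25)
        assert ma.pwm_logodds("ACGA", SHARP) == pytest.approx(expected)

    def test_ambiguous_base_contributes_background(self):
        with_n = ma.pwm_logodds("ACNT", SHARP)
        expected = 3 * np.log2(0.85 / 0.25)
        assert with_n == pytest.approx(expected)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            ma.pwm_logodds("ACGT", SHARP, background=np.array([0.3, 0.3, 0.3, 0.3]))


class TestScorePvalue:
    @pytest.mark.parametrize("width,seed", [(4, 0), (5, 1), (6, 2), (8, 3)])
    def test_matches_exhaustive_enumeration(self, width, seed):
        """DP tail probabilities equal brute-force enumeration over all 4^w
        sequences, applying the scorer's declared 1e-3 per-position score
        discretization to both paths."""
        rng = np.random.default_rng(seed)
        mat = _matrix(rng.dirichlet([1.0] * 4, size=width))
        binned = np.rint(mat.logodds() / ma.SCORE_BIN) * ma.SCORE_BIN
        all_scores = np.array(
            [binned[np.arange(width), idx].sum() for idx in itertools.product(range(4), repeat=width)]
        )
        for q in np.quantile(all_scores, [0.05, 0.5, 0.9, 0.999], method="nearest"):
            brute = (all_scores >= q - 1e-9).mean()
            assert ma.score_pvalue(mat, q) == pytest.approx(brute, abs=1e-9)

    def test_minimal_score_gives_one(self):
        lods = SHARP.logodds()
        assert ma.score_pvalue(SHARP, lods.min(axis=1).sum()) == pytest.approx(1.0)

    def test_above_maximum_gives_exact_zero(self):
        lods = SHARP.logodds()
        assert ma.score_pvalue(SHARP, lods.max(axis=1).sum() + 1.0) == 0.0

    def test_monotone_in_score(self):
        scores = np.linspace(-10, 10, 25)
        ps = [ma.score_pvalue(SHARP, s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestScanVariant:
    def test_variant_outside_motif_yields_no_pairs(self):
        # identical windows: no allelic score change anywhere
        win = "ACGTACGTACGTACGTACGTACGTACGTACG"
        assert ma.scan_variant(win, win, [SHARP]) == []

    def test_footprint_mask_excludes_variant(self):
        land = synthgen.simulate_motif_landscape(n_motifs=1, sites_per_motif=1, seed=1)
        site = land.sites.iloc[0]
        mats = [_matrix(land.motifs[site["motif_id"]], motif_id=site["motif_id"])]
        assert ma.scan_variant(site["ref_window"], site["alt_window"], mats, on_footprint=False) == []

    def test_planted_snp_recovers_matrix_arithmetic(self):
        land = synthgen.simulate_motif_landscape(n_motifs=2, sites_per_motif=6, seed=2)
        for _, site in land.sites.iterrows():
            mat = _matrix(land.motifs[site["motif_id"]], motif_id=site["motif_id"])
            pairs = ma.scan_variant(site["ref_window"], site["alt_window"], [mat])
            assert len(pairs) == 1
            ref_hit, alt_hit = pairs[0]
            start = site["motif_start"]
            expected_delta = ma.pwm_logodds(
                site["ref_window"][start : start + mat.width], mat
            ) - ma.pwm_logodds(site["alt_window"][start : start + mat.width], mat)
            assert ref_hit.score - alt_hit.score == pytest.approx(expected_delta)

    def test_palindromic_motif_tie_goes_to_plus_strand(self):
        pal = _matrix(
            [
                [0.97, 0.01, 0.01, 0.01],
                [0.01, 0.97, 0.01, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.01, 0.01, 0.97],
            ]
        )  # consensus ACGT is its own reverse complement
        ref = "TTTTTTTTTTTTTACGTTTTTTTTTTTTTTT"
        alt = "TTTTTTTTTTTTTACTTTTTTTTTTTTTTTT"
        pairs = ma.scan_variant(ref, alt, [pal], threshold=1.0)
        assert pairs
        assert pairs[0][0].strand == "+"

    def test_revcomp_window_with_strand_swap_is_invariant(self):
        land = synthgen.simulate_motif_landscape(n_motifs=1, sites_per_motif=4, seed=3)
        for _, site in land.sites.iterrows():
            mat = _matrix(land.motifs[site["motif_id"]], motif_id=site["motif_id"])
            fwd = ma.scan_variant(site["ref_window"], site["alt_window"], [mat])
            rev = ma.scan_variant(
                ma.revcomp(site["ref_window"]), ma.revcomp(site["alt_window"]), [mat]
            )
            assert len(fwd) == len(rev) == 1
            assert fwd[0][0].score == pytest.approx(rev[0][0].score)
            assert fwd[0][0].strand != rev[0][0].strand


class TestDisruptionCounts:
    def test_balanced_counts_not_flagged(self):
        hits = pd.DataFrame(
            {"motif_id": ["m1"] * 30 + ["m2"] * 30, "cell_type": ["LCL", "FB", "MNC"] * 20}
        )
        counts, tests = ma.disruption_counts(hits)
        assert not tests["selective"].any()
        assert counts.loc["m1"].sum() == 30

    def test_strong_excess_in_one_cell_type_flagged(self):
        # large balanced background keeps per-cell-type totals near-uniform,
        # so only the skewed motif deviates from its expectation
        rows = [("bg", ct) for ct in ["LCL", "FB", "MNC"] * 200]
        rows += [("hot", "LCL")] * 20 + [("hot", "FB")] * 2 + [("hot", "MNC")] * 2
        hits = pd.DataFrame(rows, columns=["motif_id", "cell_type"])
        _, tests = ma.disruption_counts(hits)
        assert tests.set_index("motif_id").loc["hot", "selective"]
        assert not tests.set_index("motif_id").loc["bg", "selective"]

    def test_single_cell_type_refused(self):
        hits = pd.DataFrame({"motif_id": ["m"] * 5, "cell_type": ["LCL"] * 5})
        with pytest.raises(ValueError):
            ma.disruption_counts(hits)


class TestClassifyActivity:
    def _pairs(self, n_over, n_under, motif_id="m"):
        return pd.DataFrame(
            {"motif_id": motif_id, "higher_on_over": [True] * n_over + [False] * n_under}
        )

    def test_balanced_split_is_ns(self):
        call = ma.classify_activity(self._pairs(10, 10)).iloc[0]
        assert call["p_value"] == pytest.approx(1.0)
        assert call["verdict"] == "ns"
        assert call["bias"] == pytest.approx(1.0)

    def test_exact_binomial_18_of_20(self):
        call = ma.classify_activity(self._pairs(18, 2)).iloc[0]
        expected = 2 * sum(
            stats.binom.pmf(k, 20, 0.5) for k in range(18, 21)
        )
        assert call["p_value"] == pytest.approx(expected, rel=1e-9)
        assert call["p_value"] == pytest.approx(4.025e-4, rel=1e-3)
        assert call["verdict"] == "activator"

    def test_bonferroni_mode_uses_corrected_alpha(self):
        call = ma.classify_activity(self._pairs(18, 2), bonferroni=True).iloc[0]
        assert call["verdict"] == "ns"  # 4e-4 > 0.05/1380
        extreme = ma.classify_activity(self._pairs(30, 0), bonferroni=True).iloc[0]
        assert extreme["verdict"] == "activator"
        assert extreme["zero_under"]
        assert np.isinf(extreme["bias"])

    def test_null_type_one_error_calibrated(self):
        """Under an unbiased landscape the false-call rate stays near alpha
        (the exact test is conservative on discrete counts)."""
        rng = np.random.default_rng(6)
        alpha = 0.01
        calls = ma.classify_activity(
            pd.DataFrame(
                {
                    "motif_id": np.repeat(np.arange(400), 40),
                    "higher_on_over": rng.random(16000) < 0.5,
                }
            ),
            alpha=alpha,
        )
        assert (calls["verdict"] != "ns").mean() <= 2 * alpha

    def test_repressor_landscape_called_repressor(self):
        """With only 10% of 40 sites scoring higher on the over-expressed
        haplotype (the mirrored-activator planting at p_act=0.9), the verdict
        is repressor in >=95% of seeded replicates of the full
        scan-and-classify path."""
        hits = 0
        reps = 20
        for seed in range(reps):
            land = synthgen.simulate_motif_landscape(
                n_motifs=1, sites_per_motif=40, p_act=0.9, labels=["repressor"], seed=100 + seed
            )
            pairs = _pairs_from_landscape(land)
            call = ma.classify_activity(pairs).iloc[0]
            hits += call["verdict"] == "repressor"
        assert hits / reps >= 0.95


def _pairs_from_landscape(land):
    rows = []
    for motif_id, probs in land.motifs.items():
        mat = ma.MotifMatrix(motif_id=motif_id, probs=probs)
        for _, site in land.sites[land.sites["motif_id"] == motif_id].iterrows():
            for ref_hit, alt_hit in ma.scan_variant(site["ref_window"], site["alt_window"], [mat]):
                higher = "ref" if ref_hit.score > alt_hit.score else "alt"
                rows.append(
                    {
                        "motif_id": motif_id,
                        "cell_type": site["cell_type"],
                        "higher_on_over": higher == site["over_allele"],
                    }
                )
    return pd.DataFrame(rows)


class TestEndToEndRecovery:
    def test_planted_labels_recovered(self):
        land = synthgen.simulate_motif_landscape(
            n_motifs=12, sites_per_motif=40, p_act=0.9, seed=7
        )
        pairs = _pairs_from_landscape(land)
        calls = ma.classify_activity(pairs)
        merged = calls.merge(land.labels, on="motif_id")
        merged["called"] = merged["verdict"].replace({"ns": "neutral"})
        accuracy = (merged["called"] == merged["true_label"]).mean()
        assert accuracy >= 0.90


class TestActivityBySource:
    def test_proportions_and_empty_class_guard(self):
        calls = pd.DataFrame(
            {
                "motif_id": ["a", "b", "c", "d"],
                "verdict": ["activator", "activator", "repressor", "ns"],
            }
        )
        sources = pd.DataFrame(
            {
                "motif_id": ["a", "b", "c", "d"],
                "source": ["TRANSFAC", "TRANSFAC", "de-novo", "footprint-known"],
            }
        )
        out = ma.activity_by_source(calls, sources).set_index("source")
        assert out.loc["TRANSFAC", "prop_activator"] == 1.0
        assert out.loc["de-novo", "prop_repressor"] == 1.0
        assert "footprint-known" not in out.index  # only an ns motif: absent, not 0/0

    def test_planted_mixture_recovered_within_ci(self):
        rng = np.random.default_rng(8)
        n = 60
        verdicts = np.where(rng.random(n) < 0.7, "activator", "repressor")
        calls = pd.DataFrame({"motif_id": [f"m{i}" for i in range(n)], "verdict": verdicts})
        sources = pd.DataFrame({"motif_id": calls["motif_id"], "source": "TRANSFAC"})
        out = ma.activity_by_source(calls, sources).iloc[0]
        assert out["ci_low"] <= 0.7 <= out["ci_high"]


class TestMatrixValidation:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _matrix(np.full((4, 4), 0.3))

    def test_minimum_width(self):
        with pytest.raises(ValueError):
            _matrix(np.full((3, 4), 0.25))

    def test_from_counts_applies_pseudocount(self):
        counts = np.zeros((4, 4))
        counts[:, 0] = 10
        mat = ma.MotifMatrix.from_counts("c", counts)
        assert mat.probs[0, 1] > 0  # no zero cells after pseudocounting
        assert np.allclose(mat.probs.sum(axis=1), 1.0)
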