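"""Genomic bins, gene assignment, calls and reference comparison."""

import numpy as np
import pandas as pd
import pytest

import spotgin as sg
from spotgin.cnv import (CALL_GAIN, CALL_LOSS, CALL_NEUTRAL, CnvProfile,
                         probe_density_diagnostic)


class TestBuildBins:
    def test_ceil_division_and_last_width(self):
        bins = sg.build_bins({"chr1": 3_500_000})
        assert len(bins) == 4
        assert bins.iloc[-1]["width"] == 500_000

    def test_width_equal_size_single_bin(self):
        bins = sg.build_bins({"chr1": 1_000_000})
        assert len(bins) == 1

    def test_total_width_equals_genome_size(self, rng):
        sizes = {f"chr{i}": int(rng.integers(1, 2 * 10**7)) for i in range(5)}
        bins = sg.build_bins(sizes)
        assert bins["width"].sum() == sum(sizes.values())
        assert (bins.index == np.arange(len(bins))).all()

    def test_nonpositive_width_errors(self):
        with pytest.raises(ValueError):
            sg.build_bins({"chr1": 100}, width=0)

    def test_arm_labels_by_midpoint(self):
        bins = sg.build_bins({"chr1": 4_000_000}, arms={"chr1": 2_000_000})
        assert list(bins["arm"]) == ["p", "p", "q", "q"]


class TestAssignGenes:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]
                            ).set_index("gene_id")

    def test_midpoint_on_bin_boundary(self):
        bins = sg.build_bins({"chr1": 2_000_000})
        genes = self._genes([("G1", "chr1", 999_000, 1_001_000)])
        # midpoint 1,000,000 falls in the first bin (1..1,000,000)
        assert sg.assign_genes(genes, bins).loc["G1"] == 0

    def test_gene_inside_second_bin(self):
        bins = sg.build_bins({"chr1": 2_000_000})
        genes = self._genes([("G1", "chr1", 1_200_000, 1_300_000)])
        assert sg.assign_genes(genes, bins).loc["G1"] == 1

    def test_matches_linear_scan_oracle(self, rng):
        bins = sg.build_bins({"chr1": 10_000_000, "chr2": 5_000_000})
        rows = []
        for i in range(100):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            size = 10_000_000 if chrom == "chr1" else 5_000_000
            start = int(rng.integers(1, size - 1000))
            rows.append((f"G{i}", chrom, start, start + 999))
        genes = self._genes(rows)
        assigned = sg.assign_genes(genes, bins)
        for gid, row in genes.iterrows():
            mid = (row["start"] + row["end"]) // 2
            hits = [j for j, b in bins.iterrows()
                    if b["chrom"] == row["chrom"]
                    and b["start"] <= mid <= b["end"]]
            assert assigned.loc[gid] == hits[0]

    def test_unknown_chromosome_skipped(self):
        bins = sg.build_bins({"chr1": 1_000_000})
        genes = self._genes([("G1", "chrX", 10, 20)])
        assert len(sg.assign_genes(genes, bins)) == 0


class TestCalls:
    def _profile(self, scores):
        scores = np.atleast_2d(np.asarray(scores, float))
        bins = sg.build_bins({"chr1": scores.shape[1] * 10**6},
                             arms={"chr1": scores.shape[1] * 10**6 // 2})
        frame = pd.DataFrame(scores,
                             index=[f"B{i}" for i in range(len(scores))],
                             columns=bins.index)
        return CnvProfile(scores=frame, bins=bins, reference_spots=[])

    def test_all_zero_scores_all_neutral(self):
        calls = sg.call_alterations(self._profile(np.zeros((2, 4))))
        assert (calls.to_numpy() == CALL_NEUTRAL).all()

    def test_boundary_score_is_neutral(self):
        prof = self._profile([[0.15, 0.1500001, -0.15, -0.2]])
        calls = sg.call_alterations(prof, tau_loss=0.15, tau_gain=0.15)
        assert list(calls.iloc[0]) == [CALL_NEUTRAL, CALL_GAIN,
                                       CALL_NEUTRAL, CALL_LOSS]

    def test_arm_level_uses_arm_mean(self):
        prof = self._profile([[0.4, 0.4, 0.0, 0.0]])
        arm_calls = sg.call_alterations(prof, level="arm")
        assert arm_calls.loc["B0", "chr1p"] == CALL_GAIN
        assert arm_calls.loc["B0", "chr1q"] == CALL_NEUTRAL

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            sg.call_alterations(self._profile(np.zeros((1, 2))), tau_gain=0.0)


class TestCompareToReference:
    def test_identical_calls_full_consensus(self):
        calls = pd.Series({"chr1p": 1, "chr1q": 0, "chr2p": -1})
        res = sg.compare_to_reference(calls, calls.copy())
        assert res["consensus"] == 1.0
        assert res["divergent_gain"] == 0.0

    def test_fully_opposite_calls(self):
        calls = pd.Series({"chr1p": 1.0, "chr1q": -1.0})
        ref = pd.Series({"chr1p": -1, "chr1q": 1})
        res = sg.compare_to_reference(calls, ref)
        assert res["consensus"] == 0.0
        assert res["divergent_gain"] == 0.5 and res["divergent_loss"] == 0.5

    def test_injected_error_rate_recovered(self, rng):
        arms = [f"chr{c}{a}" for c in range(1, 11) for a in "pq"]
        ref = pd.Series(rng.choice([-1, 0, 1], size=len(arms)), index=arms)
        frames = []
        flips = 0
        for _ in range(50):
            row = ref.copy()
            flip = rng.random(len(arms)) < 0.1
            row[flip] = (row[flip] + 2) % 3 - 1  # move to a different call
            flips += int(flip.sum())
            frames.append(row)
        calls = pd.DataFrame(frames).reset_index(drop=True)
        res = sg.compare_to_reference(calls, ref)
        observed = 1.0 - res["consensus"]
        expected = flips / (50 * len(arms))
        assert observed == pytest.approx(expected, abs=1e-12)
        # binomial window around the planted 10% rate
        assert 0.06 < observed < 0.14

    def test_arm_missing_from_reference_excluded(self):
        calls = pd.Series({"chr1p": 1.0, "chrXq": 1.0})
        ref = pd.Series({"chr1p": 1})
        res = sg.compare_to_reference(calls, ref)
        assert res["n_comparisons"] == 1


class TestProbeDensity:
    def _setup(self, n_bins=30, seed=0):
        rng = np.random.default_rng(seed)
        bins = sg.build_bins({"chr1": n_bins * 10**6})
        rows = []
        for i in range(n_bins * 4):
            start = i * 250_000 + 1
            rows.append((f"G{i}", "chr1", start, start + 999,
                         int(rng.integers(2, 60))))
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                            "end", "n_probes"]
                             ).set_index("gene_id")
        gene_bins = sg.assign_genes(genes, bins)
        return bins, genes, gene_bins

    def test_mismatch_proportional_to_density_high_r(self):
        bins, genes, gene_bins = self._setup()
        probes = np.zeros(len(bins))
        np.add.at(probes, gene_bins.to_numpy(),
                  genes["n_probes"].to_numpy(float))
        mism = pd.Series(probes, index=bins.index)  # exactly proportional
        res = probe_density_diagnostic(genes, gene_bins, bins, mism)
        assert res["r"] > 0.9

    def test_constant_mismatch_reports_missing(self):
        bins, genes, gene_bins = self._setup()
        mism = pd.Series(3.0, index=bins.index)
        res = probe_density_diagnostic(genes, gene_bins, bins, mism)
        assert np.isnan(res["r"])

    def test_too_few_bins_errors(self):
        bins, genes, gene_bins = self._setup()
        mism = pd.Series({0: 1.0, 1: 2.0})
        tiny = bins.iloc[:2]
        with pytest.raises(ValueError, match="fewer than 3"):
            probe_density_diagnostic(genes, gene_bins.iloc[:2], tiny, mism)


class TestRocGainLoss:
    def test_perfectly_ordered_scores(self):
        scores = np.array([-1.0, -0.9, 0.0, 0.1, 1.0, 1.2])
        labels = np.array([-1, -1, 0, 0, 1, 1])
        assert sg.roc_gain_loss(scores, labels) == 1.0

    def test_shuffled_labels_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.choice([-1, 0, 1], size=1000)
        assert sg.roc_gain_loss(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_two_class_equals_all_pairs_oracle(self, rng):
        scores = rng.normal(size=60)
        labels = rng.choice([0, 1], size=60)
        auc = sg.roc_gain_loss(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = np.mean((pos[:, None] > neg[None, :])
                        + 0.5 * (pos[:, None] == neg[None, :]))
        assert auc == pytest.approx(pairs, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            sg.roc_gain_loss(np.array([1.0, 2.0]), np.array([0, 0]))


class TestScoreBinsProperties:
    """Light scoring checks on a small cohort; the full planted-event
    recovery runs in the acceptance suite."""

    @pytest.fixture(scope="class")
    def scored(self):
        # 1,000 genes keeps the planted-program fraction realistic (~20%);
        # tiny panels let zone/label programs dominate per-arm averages
        cohort = sg.generate_cohort(n_samples=1, grid=(16, 16), n_genes=1000,
                                    n_classes=2, seed=11,
                                    subclass_mode="marginal",
                                    events={"SYN00": [("chr3", "p", "gain")]})
        ds = cohort.datasets[0]
        nm = sg.normalize_dataset(ds)
        bins = sg.build_bins(cohort.chrom_sizes, arms=cohort.arms)
        gene_bins = sg.assign_genes(cohort.genes, bins)
        ref = list(ds.histology.index[
            ds.histology.isin(("white matter", "cortex"))])
        profile = sg.score_bins(nm, gene_bins, ref, bins=bins)
        return cohort, ds, profile, ref

    def test_reference_spots_self_center(self, scored):
        _, _, profile, ref = scored
        ref_mean = profile.scores.loc[ref].mean(axis=0)
        assert np.nanmean(np.abs(ref_mean.to_numpy())) < 0.05

    def test_planted_arm_exceeds_neutral_arms(self, scored):
        cohort, ds, profile, ref = scored
        arm = profile.arm_scores()
        tumor = [b for b in arm.index if b not in set(ref)]
        mean = arm.loc[tumor].mean(axis=0)
        neutral = [a for a in mean.index if a != "chr3p"]
        assert mean["chr3p"] > max(mean[a] for a in neutral)

    def test_scale_invariance_of_scores(self, scored):
        cohort, ds, profile, ref = scored
        doubled = ds.counts.toarray().copy()
        doubled[:, 0] *= 2
        nm2 = sg.normalize_log(doubled, ds.gene_ids, ds.barcodes)
        bins = sg.build_bins(cohort.chrom_sizes, arms=cohort.arms)
        gene_bins = sg.assign_genes(cohort.genes, bins)
        profile2 = sg.score_bins(nm2, gene_bins, ref, bins=bins)
        a = profile.scores.to_numpy(float)
        b = profile2.scores.to_numpy(float)
        assert np.allclose(np.nan_to_num(a), np.nan_to_num(b), atol=1e-9)
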