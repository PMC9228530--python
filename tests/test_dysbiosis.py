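import numpy as np
import pytest
from skbio import DistanceMatrix

from dysbiome.diversity import beta_matrix
from dysbiome.dysbiosis import (
    cloud_test,
    doc_analysis,
    dysbiosis_report,
    median_distance_test,
)
from dysbiome.simulate import (
    CohortSpec,
    plant_dysbiotic_samples,
    simulate_cohort,
    simulate_universal_dynamics,
)


def euclid_dm(pts, prefix="s"):
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"{prefix}{i}" for i in range(len(pts))])


class TestMedianDistance:
    def test_overlapping_ids_rejected(self):
        dm = euclid_dm(np.random.default_rng(0).normal(size=(6, 2)))
        with pytest.raises(ValueError, match="overlap"):
            median_distance_test(dm, ["s0", "s1", "s2"], ["s2", "s3"])

    def test_in_distribution_sample_not_flagged(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(21, 3))
        pts[20] = pts[0]  # test sample duplicates a reference profile
        dm = euclid_dm(pts)
        res = median_distance_test(dm, [f"s{i}" for i in range(20)], ["s20"])
        assert not res.flags["s20"]

    def test_loo_self_consistency_flags_ten_percent(self):
        # by construction the cutoff is the 90% quantile of the same
        # functional, so ~3/30 reference samples exceed it
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(31, 4))
        dm = euclid_dm(pts)
        ref = [f"s{i}" for i in range(30)]
        res = median_distance_test(dm, ref, ["s30"])
        frac = (res.reference_medians > res.cutoff).mean()
        assert 2 / 30 <= frac <= 4 / 30

    def test_planted_outlier_flagged_end_to_end(self):
        t, _, _ = simulate_cohort(
            CohortSpec(n_group1=1, n_group2=30, n_taxa=100, seed=3)
        )
        t = plant_dysbiotic_samples(t, ["S000"], strength=20, seed=4)
        dm = beta_matrix(t, "bray_curtis")
        ref = [s for s in t.sample_ids if s != "S000"]
        res = median_distance_test(dm, ref, ["S000"])
        assert bool(res.flags["S000"])

    def test_pooled_cutoff_mode(self):
        rng = np.random.default_rng(5)
        dm = euclid_dm(rng.normal(size=(12, 2)))
        ref = [f"s{i}" for i in range(10)]
        a = median_distance_test(dm, ref, ["s10", "s11"], cutoff_mode="pooled")
        b = median_distance_test(dm, ref, ["s10", "s11"], cutoff_mode="loo_median")
        assert a.statistics.equals(b.statistics)  # statistic unchanged, cutoff differs


class TestDOC:
    def test_identical_samples_have_full_overlap_zero_dissimilarity(self):
        t = simulate_universal_dynamics(
            n_samples=12, n_taxa=30, presence_gradient=(1.0, 1.0),
            noise_sd=0.0, seed=0,
        )
        res = doc_analysis(t, n_boot=0)
        assert np.allclose(res.pairs["overlap"], 1.0)
        assert np.allclose(res.pairs["dissimilarity"], 0.0)

    def test_universal_dynamics_negative_high_overlap_correlation(self):
        t = simulate_universal_dynamics(n_samples=50, n_taxa=100, seed=1)
        res = doc_analysis(t, n_boot=0)
        assert res.spearman < 0
        assert res.slope < 0

    def test_independent_compositions_flat(self):
        t = simulate_universal_dynamics(n_samples=50, n_taxa=100, seed=2, universal=False)
        res = doc_analysis(t, n_boot=0)
        assert abs(res.spearman) < 0.3

    def test_bootstrap_band_present(self):
        t = simulate_universal_dynamics(n_samples=15, n_taxa=40, seed=3)
        res = doc_analysis(t, n_boot=10, seed=4)
        assert len(res.bootstrap) <= 10 and {"slope", "spearman"} <= set(res.bootstrap)

    def test_too_few_samples(self):
        t = simulate_universal_dynamics(n_samples=5, n_taxa=20, seed=5)
        with pytest.raises(ValueError, match="at least 10"):
            doc_analysis(t)


class TestCloud:
    def test_worked_ratio_example(self):
        # mean kNN diameter 0.6 vs reference average 0.2 -> r = 3
        n = 20
        arr = np.full((n + 1, n + 1), 0.2)
        np.fill_diagonal(arr, 0.0)
        arr[n, :n] = arr[:n, n] = 0.6
        ids = [f"R{i}" for i in range(n)] + ["X"]
        dm = DistanceMatrix(arr, ids)
        res = cloud_test(dm, ids[:n], "X", ref_fraction=1.0, k=3, n_draws=1, seed=0)
        assert res.r == pytest.approx(3.0)

    def test_degenerate_equal_distances_give_r_of_one(self):
        n = 15
        arr = np.full((n + 1, n + 1), 0.4)
        np.fill_diagonal(arr, 0.0)
        ids = [f"R{i}" for i in range(n)] + ["X"]
        dm = DistanceMatrix(arr, ids)
        res = cloud_test(dm, ids[:n], "X", ref_fraction=0.5, k=3, n_draws=20, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_in_distribution_sample(self):
        rng = np.random.default_rng(2)
        dm = euclid_dm(rng.normal(size=(31, 5)))
        ref = [f"s{i}" for i in range(30)]
        res = cloud_test(dm, ref, "s30", ref_fraction=0.3, n_draws=50, seed=3)
        assert 0.8 <= res.r <= 1.25
        assert res.p_value > 0.05

    def test_reference_loo_scores_average_near_one(self):
        rng = np.random.default_rng(4)
        dm = euclid_dm(rng.normal(size=(31, 5)))
        ref = [f"s{i}" for i in range(30)]
        res = cloud_test(dm, ref, "s30", ref_fraction=0.3, n_draws=50, seed=5)
        assert abs(res.reference_r.mean() - 1.0) < 0.15

    def test_subset_smaller_than_k_rejected(self):
        rng = np.random.default_rng(6)
        dm = euclid_dm(rng.normal(size=(11, 2)))
        with pytest.raises(ValueError, match="< k"):
            cloud_test(dm, [f"s{i}" for i in range(10)], "s10", ref_fraction=0.05, k=3)


class TestReport:
    def test_clean_cohort_mostly_unflagged(self):
        t, md, _ = simulate_cohort(
            CohortSpec(n_group1=15, n_group2=20, n_taxa=80, seed=7)
        )
        rep = dysbiosis_report(t, md, "HC", n_draws=20, seed=8)
        d = rep.to_dict()
        md_flags = [v["flag"] for v in d["median_distance"]["samples"].values()]
        assert sum(md_flags) <= 2
        assert d["doc"]["HC"]["spearman"] is not None

    def test_planted_outlier_flagged_by_median_and_cloud(self):
        t, md, _ = simulate_cohort(
            CohortSpec(n_group1=5, n_group2=30, n_taxa=80, seed=9)
        )
        t = plant_dysbiotic_samples(t, ["S000"], strength=25, seed=10)
        rep = dysbiosis_report(t, md, "HC", n_draws=30, seed=11)
        assert bool(rep.median_distance.flags["S000"])
        cres = rep.cloud[("S000", 0.30)]
        assert cres.r > 1 and cres.p_value < 0.05

    def test_empty_test_set_reference_only_doc(self):
        t, md, _ = simulate_cohort(
            CohortSpec(n_group1=0, n_group2=15, n_taxa=50, seed=12)
        )
        rep = dysbiosis_report(t, md, "HC", n_draws=10, seed=13)
        assert rep.doc["test"] is None
        assert rep.doc["HC"] is not None
        assert len(rep.median_distance.statistics) == 0
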