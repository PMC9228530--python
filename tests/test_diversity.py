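import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from dysbiome.diversity import (
    alpha_diversity,
    beta_matrix,
    kruskal_wallis_alpha,
    pcoa,
    permanova,
    permanova_family,
)
from dysbiome.simulate import simulate_tree
from conftest import make_table, make_metadata, two_group_metadata


# ---------------------------------------------------------------------------
# Brute-force per-branch UniFrac oracle (independent of scikit-bio)
# ---------------------------------------------------------------------------

def unifrac_oracle(tree: TreeNode, taxa, x: np.ndarray, y: np.ndarray, weighted: bool):
    """Enumerate every branch; presence / subtree-mass difference per branch."""
    idx = {t: i for i, t in enumerate(taxa)}
    px, py = x / x.sum(), y / y.sum()
    unique = shared_or = 0.0
    wsum = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        positions = [idx[t] for t in tips if t in idx]
        in_x = any(x[p] > 0 for p in positions)
        in_y = any(y[p] > 0 for p in positions)
        if weighted:
            wsum += length * abs(px[positions].sum() - py[positions].sum())
        else:
            if in_x or in_y:
                shared_or += length
                if in_x != in_y:
                    unique += length
    return wsum if weighted else (unique / shared_or if shared_or else 0.0)


def random_case(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    tree = simulate_tree(n, seed=seed)
    taxa = sorted(t.name for t in tree.tips())
    x = rng.integers(0, 20, size=n)
    y = rng.integers(0, 20, size=n)
    if x.sum() == 0:
        x[rng.integers(n)] = 1
    if y.sum() == 0:
        y[rng.integers(n)] = 1
    return tree, taxa, x, y


class TestAlphaClosedForms:
    def test_uniform_four_taxa(self):
        t = make_table([[10], [10], [10], [10]])
        assert alpha_diversity(t, "shannon")["S000"] == pytest.approx(2.0)
        assert alpha_diversity(t, "pielou")["S000"] == pytest.approx(1.0)

    def test_single_taxon(self):
        t = make_table([[7], [0]])
        assert alpha_diversity(t, "shannon")["S000"] == 0.0
        assert alpha_diversity(t, "observed_features")["S000"] == 1

    def test_faith_pd_spanning_case(self, star_tree):
        t = make_table([[1], [1], [1], [1]])
        total = sum(n.length or 0 for n in star_tree.traverse(include_self=False))
        assert alpha_diversity(t, "faith_pd", tree=star_tree)["S000"] == pytest.approx(total)

    def test_faith_pd_missing_taxon_errors(self, star_tree):
        t = make_table(np.ones((5, 1), dtype=int))
        with pytest.raises(ValueError, match="missing from tree"):
            alpha_diversity(t, "faith_pd", tree=star_tree)


class TestBetaClosedForms:
    def test_identical_samples_zero_for_all_metrics(self, star_tree):
        t = make_table([[4, 4], [3, 3], [2, 2], [1, 1]])
        for metric in ("jaccard", "bray_curtis"):
            assert beta_matrix(t, metric)["S000", "S001"] == 0.0
        for metric in ("unweighted_unifrac", "weighted_unifrac"):
            assert beta_matrix(t, metric, tree=star_tree)["S000", "S001"] == 0.0

    def test_disjoint_samples(self, star_tree):
        t = make_table([[4, 0], [3, 0], [0, 2], [0, 1]])
        assert beta_matrix(t, "jaccard")["S000", "S001"] == 1.0
        assert beta_matrix(t, "bray_curtis")["S000", "S001"] == 1.0
        assert beta_matrix(t, "unweighted_unifrac", tree=star_tree)["S000", "S001"] == 1.0

    def test_weighted_unifrac_two_leaf_star_closed_form(self):
        tree = TreeNode.read(["(T0000:1,T0001:1):0;"])
        t = make_table([[9, 3], [1, 7]])
        pa, pb = np.array([0.9, 0.1]), np.array([0.3, 0.7])
        expected = np.abs(pa - pb).sum()  # unit branches
        got = beta_matrix(t, "weighted_unifrac", tree=tree)["S000", "S001"]
        assert got == pytest.approx(expected)

    def test_zero_total_sample_errors(self):
        t = make_table([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="zero total"):
            beta_matrix(t, "bray_curtis")

    @pytest.mark.parametrize("weighted", [False, True])
    def test_unifrac_matches_branch_enumeration(self, weighted):
        metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
        for seed in range(30):
            tree, taxa, x, y = random_case(seed)
            t = make_table(np.column_stack([x, y]), taxa=taxa)
            got = beta_matrix(t, metric, tree=tree)["S000", "S001"]
            want = unifrac_oracle(tree, taxa, x.astype(float), y.astype(float), weighted)
            assert got == pytest.approx(want, abs=1e-9), f"seed={seed}"


class TestGroupTests:
    def test_kruskal_disjoint_ranges(self):
        vals = pd.Series(
            np.r_[np.arange(10), np.arange(100, 110)],
            index=[f"S{i:03d}" for i in range(20)],
        )
        md = two_group_metadata(10, 10)
        res = kruskal_wallis_alpha({"shannon": vals}, md)[0]
        assert res.p_value < 0.001

    def test_bh_family_correction(self):
        rng = np.random.default_rng(0)
        ids = [f"S{i:03d}" for i in range(20)]
        md = two_group_metadata(10, 10)
        alphas = {
            m: pd.Series(rng.normal(size=20), index=ids)
            for m in ("shannon", "pielou", "observed_features", "faith_pd")
        }
        results = kruskal_wallis_alpha(alphas, md)
        assert len(results) == 4
        for r in results:
            assert 0 <= r.q_value <= 1

    def test_permanova_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(1)
        pts = np.r_[rng.normal(0, 0.01, (8, 2)), rng.normal(10, 0.01, (8, 2))]
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"S{i:03d}" for i in range(16)]
        dm = DistanceMatrix(d, ids=ids)
        md = two_group_metadata(8, 8)
        res = permanova(dm, md, permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_permanova_no_structure(self):
        n = 12
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(d, ids=[f"S{i:03d}" for i in range(n)])
        md = two_group_metadata(6, 6)
        res = permanova(dm, md, permutations=499, seed=0)
        # all F values tie up to float noise; far from any rejection level
        assert res.p_value > 0.5
        assert res.statistic == pytest.approx(1.0)

    def test_permanova_reproducible_and_order_stable(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(14, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"S{i:03d}" for i in range(14)]
        dm = DistanceMatrix(d, ids=ids)
        md = two_group_metadata(7, 7)
        a = permanova(dm, md, permutations=199, seed=3)
        b = permanova(dm, md, permutations=199, seed=3)
        assert a.p_value == b.p_value
        # reordering samples leaves the observed statistic unchanged
        perm = list(reversed(ids))
        dm2 = DistanceMatrix(d[np.ix_(range(13, -1, -1), range(13, -1, -1))], ids=perm)
        c = permanova(dm2, md, permutations=199, seed=3)
        assert c.statistic == pytest.approx(a.statistic)

    def test_permanova_small_group_errors(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(d, ids=["S000", "S001", "S002"])
        md = make_metadata({"S000": "CD", "S001": "HC", "S002": "HC"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            permanova(dm, md)

    def test_permanova_family_q_values(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"S{i:03d}" for i in range(12)]
        dms = {m: DistanceMatrix(d, ids=ids) for m in ("jaccard", "bray_curtis")}
        md = two_group_metadata(6, 6)
        results = permanova_family(dms, md, permutations=99, seed=0)
        assert all(r.q_value is not None for r in results)


class TestPCoA:
    def test_euclidean_recovery(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
        res = pcoa(dm)
        coords = res.samples.to_numpy()[:, :2]
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(d, ids=["a", "b", "c"])
        res = pcoa(dm)
        eig = res.eigvals.to_numpy()
        pos = np.sort(eig[eig > 1e-12])
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_proportions_valid(self):
        rng = np.random.default_rng(6)
        t = make_table(rng.integers(0, 50, size=(20, 8)))
        dm = beta_matrix(t, "bray_curtis")
        res = pcoa(dm)
        props = res.proportion_explained.to_numpy()
        assert props.sum() <= 1 + 1e-9
        assert (np.diff(res.eigvals.to_numpy()) <= 1e-12).all()
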