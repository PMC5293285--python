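"""Group averaging, ordination, clustering, classification metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import cohen_kappa_score

from radnorm import (
    DistanceMatrix,
    average_nrads,
    classify_nrads,
    cmds,
    generate_labeled_nrad_set,
    hierarchical_cluster,
    kappa,
    middle_band_shapes,
)
from test_distance import make_nrad


class TestAverageNrads:
    def test_single_member_is_itself(self):
        n = make_nrad([0.6, 0.4], "a")
        avg = average_nrads([n], group="g")
        np.testing.assert_array_equal(avg.mean.abundances, n.abundances)
        np.testing.assert_array_equal(avg.mean.ci_low, avg.mean.abundances)
        assert avg.n_members == 1

    def test_identical_members_zero_width_ci(self):
        n = make_nrad([0.6, 0.4])
        avg = average_nrads([n, n], n_boot=200, seed=0)
        np.testing.assert_allclose(avg.mean.abundances, [0.6, 0.4])
        np.testing.assert_allclose(avg.mean.ci_low, [0.6, 0.4])
        np.testing.assert_allclose(avg.mean.ci_high, [0.6, 0.4])

    def test_arithmetic_mean(self):
        avg = average_nrads([make_nrad([0.6, 0.4]), make_nrad([0.8, 0.2])], seed=1)
        np.testing.assert_allclose(avg.mean.abundances, [0.7, 0.3])

    def test_average_is_valid_nrad(self, rng):
        """NRADs are closed under averaging: result sums to 1 and is sorted."""
        members = [make_nrad(np.sort(rng.dirichlet(np.ones(8)))[::-1]) for _ in range(5)]
        avg = average_nrads(members, n_boot=300, seed=2)
        a = avg.mean.abundances
        assert a.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(a) <= 1e-15)
        assert np.all(avg.mean.ci_low <= a) and np.all(avg.mean.ci_high >= a)

    def test_mixed_r_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            average_nrads([make_nrad([0.6, 0.4]), make_nrad([0.5, 0.3, 0.2])])


class TestCmds:
    def test_collinear_points_recovered_exactly(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = cmds(DistanceMatrix(("a", "b", "c"), D), k=1)
        coords = res.coordinates.to_numpy().ravel()
        got = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(got, D, atol=1e-10)
        assert res.explained_fraction == pytest.approx(1.0)

    def test_planar_round_trip(self, rng):
        """Euclidean distances of recovered coordinates equal the input."""
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        res = cmds(DistanceMatrix(tuple(f"p{i}" for i in range(12)), D), k=2)
        got = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(got, D, atol=1e-8)
        assert res.explained_fraction == pytest.approx(1.0)

    def test_identical_points_zero_coordinates(self):
        D = np.zeros((4, 4))
        res = cmds(DistanceMatrix(tuple("abcd"), D), k=2)
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0.0)

    def test_k_reduction_warning(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])  # 1-D geometry
        with pytest.warns(UserWarning, match="reducing k"):
            cmds(DistanceMatrix(("a", "b", "c"), D), k=2)

    def test_agrees_with_skbio_pcoa(self, rng):
        """Cross-check against the scikit-bio principal-coordinates oracle."""
        skbio_dm = pytest.importorskip("skbio.stats.distance").DistanceMatrix
        from skbio.stats.ordination import pcoa

        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        labels = tuple(f"s{i}" for i in range(10))
        res = cmds(DistanceMatrix(labels, D), k=3)
        ref = pcoa(skbio_dm(D, ids=list(labels)), number_of_dimensions=3)
        ours = np.abs(res.coordinates.to_numpy())
        theirs = np.abs(ref.samples.to_numpy()[:, :3])
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestHierarchicalCluster:
    def test_two_samples_merge_at_their_distance(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        res = hierarchical_cluster(dm)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.4)
        assert res.to_newick() == "(a:0.4,b:0.4):0;"

    def test_forced_topology(self):
        D = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = hierarchical_cluster(DistanceMatrix(("A", "B", "C"), D))
        Z = res.linkage_matrix
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(1.0)

    def test_manual_complete_linkage_trace(self):
        # distances: d(a,b)=0.2, d(a,c)=0.9, d(a,d)=1.0, d(b,c)=0.8, d(b,d)=0.95, d(c,d)=0.3
        # complete linkage: {a,b}@0.2, {c,d}@0.3, then max(0.9,1.0,0.8,0.95)=1.0
        D = squareform([0.2, 0.9, 1.0, 0.8, 0.95, 0.3])
        res = hierarchical_cluster(DistanceMatrix(tuple("abcd"), D))
        heights = res.linkage_matrix[:, 2]
        np.testing.assert_allclose(heights, [0.2, 0.3, 1.0])

    def test_newick_parseable_by_skbio(self):
        skbio = pytest.importorskip("skbio")
        import io

        D = squareform([0.2, 0.9, 1.0, 0.8, 0.95, 0.3])
        res = hierarchical_cluster(DistanceMatrix(tuple("abcd"), D))
        tree = skbio.TreeNode.read(io.StringIO(res.to_newick()))
        assert {t.name for t in tree.tips()} == set("abcd")
        # leaf depth equals the root merge height in an ultrametric tree
        assert tree.find("a").accumulate_to_ancestor(tree) == pytest.approx(1.0)


class TestKappa:
    def test_hand_worked_table(self):
        assert kappa(7, 10, (6, 4), (5, 5)) == pytest.approx(0.4)

    def test_perfect_and_chance_models(self):
        assert kappa(10, 10, (5, 5), (5, 5)) == pytest.approx(1.0)
        # ACC equal to expected accuracy gives 0
        assert kappa(5, 10, (5, 5), (5, 5)) == pytest.approx(0.0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kappa(10, 10, (10, 0), (10, 0))

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError, match="sum to N"):
            kappa(5, 10, (6, 5), (5, 5))

    def test_agrees_with_cohen_kappa_oracle(self):
        """Matches sklearn's Cohen's kappa on 1000 random confusion tables."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 1000:
            n00, n01, n10, n11 = rng.integers(0, 30, 4)
            N = n00 + n01 + n10 + n11
            if N == 0:
                continue
            y_true = [0] * (n00 + n01) + [1] * (n10 + n11)
            y_pred = [0] * n00 + [1] * n01 + [0] * n10 + [1] * n11
            n_pred = (n00 + n10, n01 + n11)
            n_true = (n00 + n01, n10 + n11)
            expected_acc = (n_pred[0] * n_true[0] + n_pred[1] * n_true[1]) / N**2
            if expected_acc >= 1.0:
                continue
            ours = kappa(n00 + n11, N, n_pred, n_true)
            ref = cohen_kappa_score(y_true, y_pred)
            assert ours == pytest.approx(ref, abs=1e-12)
            checked += 1


@pytest.fixture(scope="module")
def band_set():
    shapes = middle_band_shapes(richness=200, band=(30, 100), decay=0.05)
    nrads, labels = generate_labeled_nrad_set(
        24, shapes, R=150, rng=0, depth=150_000, n_reps=2
    )
    return shapes, nrads, labels


class TestClassifyNrads:

    def test_separable_families_high_kappa(self, band_set):
        _, nrads, labels = band_set
        report = classify_nrads(nrads, labels, seed=0, n_trees=200)
        assert report.kappa > 0.8
        assert report.acc > 0.9

    def test_importance_concentrated_in_band(self, band_set):
        _, nrads, labels = band_set
        report = classify_nrads(nrads, labels, seed=0, n_trees=200)
        imp = report.importance
        assert imp[30:100].mean() > 5 * max(np.r_[imp[:30], imp[100:]].mean(), 1e-9)

    def test_shuffled_labels_kappa_near_zero(self, band_set):
        _, nrads, labels = band_set
        rng = np.random.default_rng(5)
        report = classify_nrads(nrads, rng.permutation(labels), seed=0, n_trees=100)
        assert abs(report.kappa) < 0.35

    def test_single_class_rejected(self, band_set):
        _, nrads, labels = band_set
        with pytest.raises(ValueError, match="two classes"):
            classify_nrads(nrads, ["A"] * len(nrads), seed=0)
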