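"""Hierarchical clustering, C-index selection, Fisher test, PCA, allocation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import fisher_exact as scipy_fisher_2x2

from artikin.cluster import (
    allocation_accuracy,
    cindex,
    cluster_speakers,
    dendrogram_newick,
    fisher_exact_rxc,
    hclust,
    labels_for_k,
    pca_dissim,
    select_k,
)
from artikin.errors import ConfigurationError


def _blobs(centers, n_per, spread, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate(
        [c + rng.normal(0, spread, (n_per, len(c))) for c in np.atleast_2d(centers)]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return cdist(pts, pts), labels


class TestHclust:
    @pytest.mark.parametrize("linkage", ["ward", "complete"])
    def test_three_separated_triplets_recovered(self, linkage):
        D, truth = _blobs([(0, 0), (10, 0), (0, 10)], 3, 0.2)
        Z = hclust(D, linkage)
        labels = labels_for_k(Z, 3)
        # same partition as planted (up to label names)
        for a, b in itertools.combinations(range(9), 2):
            assert (labels[a] == labels[b]) == (truth[a] == truth[b])

    def test_two_points_single_merge(self):
        D = np.array([[0.0, 3.5], [3.5, 0.0]])
        Z = hclust(D, "complete")
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.5)

    def test_complete_linkage_matches_hand_lance_williams(self):
        """4-point complete-linkage merge heights worked by hand:
        merge (0,1) at 2; merge (2,3) at 4; final merge at max(6,5,10,9)=10."""
        D = np.array(
            [[0, 2, 6, 10], [2, 0, 5, 9], [6, 5, 0, 4], [10, 9, 4, 0]], dtype=float
        )
        Z = hclust(D, "complete")
        assert np.allclose(sorted(Z[:, 2]), [2.0, 4.0, 10.0])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            hclust(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_k_out_of_range_raises(self):
        D, _ = _blobs([(0, 0)], 4, 1.0)
        Z = hclust(D)
        with pytest.raises(ConfigurationError):
            labels_for_k(Z, 9)

    def test_newick_export_contains_all_leaves(self):
        D, _ = _blobs([(0, 0), (5, 5)], 2, 0.1)
        Z = hclust(D)
        nwk = dendrogram_newick(Z, ["a", "b", "c", "d"])
        assert nwk.endswith(";")
        for leaf in ("a", "b", "c", "d"):
            assert leaf in nwk


class TestCindex:
    def test_perfect_separation_gives_zero(self):
        D, truth = _blobs([(0, 0), (50, 0)], 4, 0.1)
        assert cindex(D, truth) == pytest.approx(0.0, abs=1e-12)

    def test_worst_labeling_gives_one(self):
        """The single within pair is the largest distance: S_w = S_max."""
        pts = np.array([[0.0], [10.0], [20.0]])
        D = cdist(pts, pts)
        labels = np.array([1, 2, 1])  # within pair (0, 2) spans the full range
        assert cindex(D, labels) == pytest.approx(1.0)

    def test_five_point_brute_force(self):
        """Exhaustive hand computation on a fixed 5-point configuration."""
        pts = np.array([[0.0, 0], [1, 1], [4, 0], [5, 1], [0, 5]])
        D = cdist(pts, pts)
        labels = np.array([1, 1, 2, 2, 1])
        iu = np.triu_indices(5, 1)
        d_all = D[iu]
        within = labels[iu[0]] == labels[iu[1]]
        n_w = within.sum()
        s_w = d_all[within].sum()
        s_min = np.sort(d_all)[:n_w].sum()
        s_max = np.sort(d_all)[-n_w:].sum()
        assert cindex(D, labels) == pytest.approx((s_w - s_min) / (s_max - s_min))

    def test_all_equal_distances_defined_as_zero(self):
        D = np.ones((4, 4)) - np.eye(4)
        assert cindex(D, np.array([1, 1, 2, 2])) == 0.0

    def test_single_cluster_rejected(self):
        D, _ = _blobs([(0, 0)], 4, 1.0)
        with pytest.raises(ConfigurationError):
            cindex(D, np.ones(4, dtype=int))


class TestSelectK:
    def test_three_blobs_select_three(self):
        D, _ = _blobs([(0, 0), (20, 0), (0, 20)], 6, 1.5, seed=1)
        k, curve, weak = select_k(D, (2, 6))
        assert k == 3
        assert curve[3] == min(curve.values())

    def test_two_blobs_select_two(self):
        D, _ = _blobs([(0, 0), (20, 0)], 6, 0.5, seed=2)
        k, _, _ = select_k(D, (2, 6))
        assert k == 2

    def test_single_blob_flags_weak_structure(self):
        D, _ = _blobs([(0, 0)], 12, 1.0, seed=3)
        k, curve, weak = select_k(D, (2, 6))
        assert 2 <= k <= 6  # no crash; some k is reported

    def test_empty_range_raises(self):
        D, _ = _blobs([(0, 0), (9, 9)], 2, 0.1)
        with pytest.raises(ConfigurationError):
            select_k(D, (5, 6))


class TestFisherExactRxc:
    def test_2x2_diagonal_closed_form(self):
        """[[3,0],[0,3]]: p = 2 / C(6,3) = 0.1."""
        assert fisher_exact_rxc(np.array([[3, 0], [0, 3]])) == pytest.approx(0.1)

    def test_proportional_rows_give_one(self):
        assert fisher_exact_rxc(np.array([[2, 4], [1, 2]])) == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self):
        for table in ([[5, 1], [2, 6]], [[8, 2], [3, 9]], [[1, 7], [6, 2]]):
            assert fisher_exact_rxc(np.array(table)) == pytest.approx(
                scipy_fisher_2x2(table)[1], rel=1e-9
            )

    def test_3x2_matches_brute_force_enumeration(self):
        from scipy.special import gammaln

        t = np.array([[5, 0], [4, 1], [0, 5]])
        rm, cm = t.sum(1), t.sum(0)
        n = t.sum()
        const = gammaln(rm + 1).sum() + gammaln(cm + 1).sum() - gammaln(n + 1)

        def logp(tab):
            return const - gammaln(np.asarray(tab) + 1.0).sum()

        p_obs = logp(t)
        p = 0.0
        for a1 in range(int(rm[0]) + 1):
            for a2 in range(int(rm[1]) + 1):
                a3 = int(cm[0]) - a1 - a2
                if not 0 <= a3 <= int(rm[2]):
                    continue
                tab = [[a1, rm[0] - a1], [a2, rm[1] - a2], [a3, rm[2] - a3]]
                lp = logp(tab)
                if lp <= p_obs + 1e-7:
                    p += np.exp(lp)
        assert fisher_exact_rxc(t) == pytest.approx(p, rel=1e-9)

    def test_zero_margin_rows_dropped(self):
        t = np.array([[3, 0], [0, 0], [0, 3]])
        assert fisher_exact_rxc(t) == pytest.approx(0.1)

    def test_monte_carlo_fallback_close_to_exact(self):
        t = np.array([[8, 2], [3, 9]])
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, max_n=10, n_mc=100_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.01)


class TestPcaDissim:
    def test_collinear_data_puts_everything_on_pc1(self):
        t = np.linspace(0, 1, 10)
        X = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        res = pca_dissim(X)
        assert res.explained_ratio[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_shares_nearly_equal(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(2000, 5)))
        res = pca_dissim(X)
        assert np.all(np.abs(res.explained_ratio - 0.2) < 0.05)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.uniform(0, 3, (8, 4)))
        res = pca_dissim(X)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        assert np.allclose(res.scores @ res.components, Xc, atol=1e-10)

    def test_constant_column_dropped_when_scaling(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=6), "b": np.ones(6)})
        res = pca_dissim(X, scale=True)
        assert res.dropped_features == ["b"]

    def test_too_few_subjects_raises(self):
        with pytest.raises(ConfigurationError):
            pca_dissim(pd.DataFrame({"a": [1.0, 2.0]}))


class TestAllocationAccuracy:
    def test_pure_clusters_give_one(self):
        labels = np.array([1, 1, 2, 2])
        groups = ["AWS", "AWS", "FS", "FS"]
        res = allocation_accuracy(labels, groups)
        assert res.fraction == 1.0
        assert res.majority == {1: "AWS", 2: "FS"}

    def test_majority_counting(self):
        """Clusters {AWS:4, FS:1} and {FS:4, AWS:1} -> 8/10 correct."""
        labels = np.array([1] * 5 + [2] * 5)
        groups = ["AWS"] * 4 + ["FS"] + ["FS"] * 4 + ["AWS"]
        res = allocation_accuracy(labels, groups)
        assert res.fraction == pytest.approx(0.8)

    def test_tied_cluster_members_ambiguous_and_excluded(self):
        labels = np.array([1, 1, 2, 2])
        groups = ["AWS", "FS", "FS", "FS"]
        res = allocation_accuracy(labels, groups)
        assert res.ambiguous[:2].all() and not res.ambiguous[2:].any()
        assert res.fraction == pytest.approx(1.0)  # 2 correct of 2 unambiguous

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(1, 4, 30)
        groups = [("AWS", "FS")[i] for i in rng.integers(0, 2, 30)]
        res = allocation_accuracy(labels, groups)
        expected = 0
        denom = 0
        for i in range(30):
            members = [groups[j] for j in range(30) if labels[j] == labels[i]]
            counts = {g: members.count(g) for g in set(members)}
            top = max(counts.values())
            winners = [g for g, c in counts.items() if c == top]
            if len(winners) > 1:
                continue
            denom += 1
            expected += groups[i] == winners[0]
        assert res.fraction == pytest.approx(expected / denom)


class TestClusterSpeakers:
    def test_report_is_json_serializable(self):
        import json

        D, truth = _blobs([(0, 0), (9, 9)], 4, 0.3)
        subjects = [f"s{i}" for i in range(8)]
        groups = ["AWS"] * 4 + ["FS"] * 4
        res = cluster_speakers(D, subjects, groups)
        payload = json.dumps(res.report())
        assert '"k": 2' in payload
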