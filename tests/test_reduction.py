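"""Clustering of correlated features and per-gene representative selection."""

import numpy as np
import pandas as pd
import pytest

from radiomut.reduction import (
    ClusterRepresentativeSelector,
    complete_linkage_clusters,
    correlation_distance_matrix,
    select_cluster_representatives,
    spearman_rho,
)

from .oracles import brute_force_complete_linkage_partitions, midrank_pearson


class TestSpearmanRho:
    def test_perfect_monotone_and_antitone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_binary_labels_match_midrank_pearson_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert spearman_rho(x, y) == pytest.approx(midrank_pearson(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_tied_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        y = rng.integers(0, 2, size=30).astype(float)
        if np.all(y == y[0]) or np.all(x == x[0]):
            pytest.skip("degenerate draw")
        assert spearman_rho(x, y) == pytest.approx(midrank_pearson(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestDistanceMatrix:
    def test_definition_and_monotone_invariance(self, rng):
        table = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        dist = correlation_distance_matrix(table)
        assert np.allclose(np.diag(dist), 0.0)
        assert np.allclose(dist, dist.T)
        assert dist.min() >= 0.0 and dist.max() <= 1.0
        rho_ab = spearman_rho(table["a"], table["b"])
        assert dist[0, 1] == pytest.approx(1.0 - rho_ab**2, abs=1e-12)
        # a feature and its exponential are at distance 0
        table["e"] = np.exp(table["a"])
        dist2 = correlation_distance_matrix(table)
        assert dist2[0, 4] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_column_named_in_error(self):
        table = pd.DataFrame({"x": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            correlation_distance_matrix(table)


class TestCompleteLinkage:
    def test_extreme_cuts(self, rng):
        table = pd.DataFrame(rng.standard_normal((30, 5)))
        dist = correlation_distance_matrix(table)
        singles = complete_linkage_clusters(dist, 5)
        assert sorted(singles.assignment.values()) == [1, 2, 3, 4, 5]
        lump = complete_linkage_clusters(dist, 1)
        assert set(lump.assignment.values()) == {1}
        with pytest.raises(ValueError):
            complete_linkage_clusters(dist, 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_planted_blocks_recovered_and_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        u, v = rng.standard_normal(n), rng.standard_normal(n)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = u + 0.3 * rng.standard_normal(n)
        for i in range(3):
            cols[f"b{i}"] = v + 0.3 * rng.standard_normal(n)
        table = pd.DataFrame(cols)
        dist = correlation_distance_matrix(table)
        partition = complete_linkage_clusters(dist, 2, list(table.columns))
        groups = {}
        for f, c in partition.assignment.items():
            groups.setdefault(c, set()).add(f)
        expected = [{"a0", "a1", "a2"}, {"b0", "b1", "b2"}]
        assert sorted(groups.values(), key=min) == expected
        # every optimal merge sequence of the enumeration oracle agrees
        oracle_partitions = brute_force_complete_linkage_partitions(dist, 2)
        names = list(table.columns)
        oracle_sets = [
            sorted(({names[i] for i in fs} for fs in part), key=min)
            for part in oracle_partitions
        ]
        assert sorted(groups.values(), key=min) in oracle_sets


class TestRepresentatives:
    def test_argmax_matches_brute_force(self, rng):
        n = 80
        y = (rng.random(n) < 0.5).astype(float)
        table = pd.DataFrame(
            {
                "a0": y + 0.5 * rng.standard_normal(n),
                "a1": y + 2.0 * rng.standard_normal(n),
                "b0": rng.standard_normal(n),
                "b1": y * 0.5 + rng.standard_normal(n),
            }
        )
        dist = correlation_distance_matrix(table)
        partition = complete_linkage_clusters(dist, 2, list(table.columns))
        reduced = select_cluster_representatives(table, y, partition)
        assert len(reduced.features) == 2
        for cluster, feature, score in zip(
            range(1, 3), reduced.features, reduced.scores
        ):
            members = partition.members(cluster)
            best = max(
                sorted(members),
                key=lambda f: spearman_rho(table[f], y) ** 2,
            )
            assert feature == best
            assert score == pytest.approx(spearman_rho(table[best], y) ** 2)

    def test_single_member_cluster_and_constant_labels(self, rng):
        table = pd.DataFrame({"x": rng.standard_normal(30), "y": rng.standard_normal(30)})
        dist = correlation_distance_matrix(table)
        partition = complete_linkage_clusters(dist, 2, ["x", "y"])
        labels = np.r_[np.zeros(15), np.ones(15)]
        reduced = select_cluster_representatives(table, labels, partition)
        assert sorted(reduced.features) == ["x", "y"]
        with pytest.raises(ValueError):
            select_cluster_representatives(table, np.ones(30), partition)

    def test_reduction_invariant_to_monotone_column_transform(self, fixture_cohort):
        features, labels = fixture_cohort
        y = labels["TP53"].to_numpy()
        dist = correlation_distance_matrix(features)
        partition = complete_linkage_clusters(dist, 7, list(features.columns))
        reduced = select_cluster_representatives(features, y, partition)
        warped = features.copy()
        warped["GLCM_f07"] = np.exp(warped["GLCM_f07"] / warped["GLCM_f07"].std())
        dist_w = correlation_distance_matrix(warped)
        partition_w = complete_linkage_clusters(dist_w, 7, list(warped.columns))
        assert partition_w.assignment == partition.assignment
        reduced_w = select_cluster_representatives(warped, y, partition_w)
        assert reduced_w.features == reduced.features


class TestSelectorEstimator:
    def test_fit_transform_and_partition_reuse(self, fixture_cohort):
        features, labels = fixture_cohort
        sel = ClusterRepresentativeSelector(k=7).fit(features, labels["KRAS"])
        out = sel.transform(features)
        assert out.shape == (47, 7)
        assert list(out.columns) == sel.selected_features_
        # a second gene reusing the same partition shares the identical cut
        sel2 = ClusterRepresentativeSelector(k=7, partition=sel.partition_).fit(
            features, labels["TP53"]
        )
        assert sel2.partition_ is sel.partition_
        assert len(sel2.selected_features_) == 7

    def test_requires_labels(self, fixture_cohort):
        features, _ = fixture_cohort
        with pytest.raises(ValueError):
            ClusterRepresentativeSelector(k=7).fit(features)
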