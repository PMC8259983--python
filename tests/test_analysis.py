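"""Composition statistics: PCA, outliers, clustering, rank-sum tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from me_allocate.analysis import (
    characterize_clusters,
    cluster_conditions,
    conditional_essentiality,
    find_outliers,
    max_normalize,
    pca_compositions,
    wilcoxon_rank_sum,
)
from me_allocate.synthetic import ClusterSpec, generate_composition_table


def permutation_rank_sum_p(x, y):
    """Exact permutation null of the rank-sum statistic (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    observed = ranks[: n1].sum()
    values = [ranks[list(idx)].sum()
              for idx in combinations(range(len(pooled)), n1)]
    mean = np.mean(values)
    return float(np.mean([abs(v - mean) >= abs(observed - mean) - 1e-12
                          for v in values]))


class TestPCA:
    def test_planted_two_group_separation(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, size=8)
        rows = []
        for i in range(10):
            row = base * (1 + rng.normal(0, 0.01, size=8))
            if i < 5:
                row[:3] *= 3.0  # group shift in three components
            rows.append(row)
        table = pd.DataFrame(rows, index=[f"c{i}" for i in range(10)])
        res = pca_compositions(table)
        signs = np.sign(res.scores["PC1"].to_numpy())
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]

    def test_aerobicity_sign_convention(self, demand_table, scan_metadata):
        res = pca_compositions(demand_table,
                               growth=scan_metadata["growth_rate"],
                               aerobic=scan_metadata["aerobic"])
        aer = scan_metadata["aerobic"].reindex(demand_table.index)
        assert res.scores.loc[aer, "PC1"].mean() < 0
        # aerobically-favored cofactors load negative, the NAD analog positive
        assert res.loadings.loc["q8", "PC1"] < 0
        assert res.loadings.loc["heme", "PC1"] < 0
        assert res.loadings.loc["nad", "PC1"] > 0

    def test_reports_growth_correlation(self, demand_table, scan_metadata):
        res = pca_compositions(demand_table,
                               growth=scan_metadata["growth_rate"],
                               aerobic=scan_metadata["aerobic"])
        assert res.pc2_growth_spearman is not None
        assert -1 <= res.pc2_growth_spearman <= 1
        assert res.pc2_growth_pearson is not None

    def test_constant_matrix_is_degenerate(self):
        table = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="constant"):
            pca_compositions(table)


class TestOutliers:
    def test_identical_conditions_no_outliers(self):
        table = pd.DataFrame(np.ones((8, 3)), columns=list("abc"))
        assert find_outliers(table).empty

    def test_planted_outlier_found_exactly_zero_noise(self):
        # zero background noise: the lone outlier sits at the maximal
        # attainable sample z, (n-1)/sqrt(n); nothing else is called
        spec = ClusterSpec(k=1, log2_effect=0.0, noise_sd=0.0,
                           n_outliers=1, outlier_z=5.0)
        table, _, planted = generate_composition_table(40, 6, spec, seed=3)
        found = find_outliers(table, z_thresh=3.0)
        assert list(zip(found["condition"], found["component"])) == planted
        assert found["z"].iloc[0] >= 5.0

    def test_planted_z_value_with_background_noise(self):
        spec = ClusterSpec(k=1, log2_effect=0.0, noise_sd=0.05,
                           n_outliers=1, outlier_z=5.0)
        table, _, planted = generate_composition_table(40, 6, spec, seed=3)
        found = find_outliers(table, z_thresh=3.0)
        hit = found.set_index(["condition", "component"])
        assert hit.loc[planted[0], "z"] == pytest.approx(5.0, abs=1e-6)

    def test_log2fc_zero_at_mean(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0])
        table = pd.DataFrame({"a": vals})
        found = find_outliers(table, z_thresh=0.0)  # report everything
        at_mean = found[np.isclose(found["condition"].map(
            lambda i: vals[i]), vals.mean())]
        if len(at_mean):
            assert np.allclose(at_mean["log2fc"], 0.0)
        # direct identity: log2(value/mean) is 0 when value == mean
        assert np.log2(vals.mean() / vals.mean()) == 0.0


class TestClustering:
    def test_perfect_recovery_on_separated_blobs(self):
        spec = ClusterSpec(k=2, log2_effect=2.0, noise_sd=0.05)
        table, labels, _ = generate_composition_table(20, 6, spec, seed=1)
        res = cluster_conditions(table, k=2)
        ari = adjusted_rand_score(labels.values,
                                  res.labels.reindex(labels.index).values)
        assert ari == 1.0

    def test_max_normalization_maps_max_to_one(self, demand_table):
        norm = max_normalize(demand_table)
        assert np.allclose(norm.max(axis=0), 1.0)

    def test_k_one_single_label(self, demand_table):
        res = cluster_conditions(demand_table, k=1)
        assert res.k == 1
        assert set(res.labels) == {1}

    def test_outliers_excluded_before_clustering(self, demand_table):
        outliers = pd.DataFrame({"condition": [demand_table.index[0]],
                                 "component": [demand_table.columns[0]],
                                 "z": [5.0], "log2fc": [1.0]})
        res = cluster_conditions(demand_table, outliers, k=2)
        assert demand_table.index[0] in res.excluded_outliers
        assert demand_table.index[0] not in res.labels.index

    def test_k_exceeding_conditions_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_conditions(table, k=10)

    def test_invariant_to_order_and_component_scale(self):
        spec = ClusterSpec(k=3, log2_effect=1.5, noise_sd=0.05)
        table, _, _ = generate_composition_table(24, 8, spec, seed=9)
        res1 = cluster_conditions(table, k=3)
        shuffled = table.sample(frac=1.0, random_state=4)
        scaled = shuffled * (10.0 ** np.arange(shuffled.shape[1]))
        res2 = cluster_conditions(scaled, k=3)
        joined = pd.concat([res1.labels.rename("a"),
                            res2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_gap_statistic_recovers_planted_k(self):
        hits = 0
        for seed in range(10):
            spec = ClusterSpec(k=3, log2_effect=1.0, noise_sd=0.1)
            table, _, _ = generate_composition_table(36, 10, spec, seed=seed)
            res = cluster_conditions(table, k=None, k_range=range(1, 7),
                                     B=50, seed=seed)
            hits += (res.k == 3)
        assert hits >= 9


class TestCharacterizeClusters:
    def shifted_table(self, seed=5):
        spec = ClusterSpec(k=2, shifts=[[0, 1], [2, 3]], log2_effect=1.0,
                           noise_sd=0.05)
        return generate_composition_table(24, 8, spec, seed=seed)

    def test_retains_exactly_shifted_components(self):
        table, labels, _ = self.shifted_table()
        res = characterize_clusters(table, labels)
        for cluster in (0, 1):
            comps = set(res[res["cluster"] == cluster]["component"])
            assert comps == {"comp_00", "comp_01", "comp_02", "comp_03"}
        own = res[(res["cluster"] == 0) & (res["component"] == "comp_00")]
        assert own["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.2)

    def test_constant_component_never_retained(self):
        table, labels, _ = self.shifted_table()
        table["flat"] = 3.14
        res = characterize_clusters(table, labels)
        assert "flat" not in set(res["component"])

    def test_label_swap_negates_log2fc(self):
        table, labels, _ = self.shifted_table()
        res = characterize_clusters(table, labels)
        swapped = characterize_clusters(table, 1 - labels)
        a = res.set_index(["cluster", "component"])["log2fc"]
        b = swapped.set_index(["cluster", "component"])["log2fc"]
        for (cluster, comp), value in a.items():
            assert b[(1 - cluster, comp)] == pytest.approx(value, rel=1e-9)

    def test_no_shift_retains_nothing(self):
        spec = ClusterSpec(k=2, shifts=[[], []], log2_effect=0.0,
                           noise_sd=0.05)
        table, labels, _ = generate_composition_table(24, 8, spec, seed=11)
        assert characterize_clusters(table, labels).empty

    def test_singleton_cluster_skipped(self):
        table, labels, _ = self.shifted_table()
        labels = labels.copy()
        labels.iloc[:] = 0
        labels.iloc[0] = 99
        res = characterize_clusters(table, labels)
        assert 99 not in set(res.get("cluster", []))


class TestWilcoxon:
    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (6, 8), (8, 8)])
    def test_agrees_with_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + rng.uniform(-1, 1)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                permutation_rank_sum_p(x, y), abs=1e-10)


class TestConditionalEssentiality:
    def test_respiratory_cofactors_anaerobically_dispensable(
            self, demand_table, scan_metadata):
        ess = conditional_essentiality(demand_table,
                                       cofactors=["q8", "heme", "nad"])
        aer = scan_metadata["aerobic"].reindex(demand_table.index)
        assert not ess.loc[~aer, "q8"].any()
        assert not ess.loc[~aer, "heme"].any()
        assert ess.loc[aer, "q8"].all()
        # the NAD analog is required wherever growth occurs
        assert ess["nad"].all()

    def test_all_zero_column_all_false(self):
        table = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.0]})
        ess = conditional_essentiality(table)
        assert not ess["a"].any()
        assert ess["b"].tolist() == [True, False]
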