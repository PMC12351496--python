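import numpy as np
import pandas as pd
import pytest

from organoid_quant.core_io import CountMatrix, CtTable, ValidationError
from organoid_quant.expression_stats import (
    cluster_profiles,
    normalize_counts,
    qc_controls,
    relative_expression,
    select_de,
)
from organoid_quant.synthetic import gen_count_matrix, gen_ct_table


def _cm(counts, hk, groups=None, index=None):
    df = pd.DataFrame(counts)
    if index is not None:
        df.index = index
    return CountMatrix(df, groups or {}, hk)


def average_linkage_oracle(matrix):
    """O(n³) agglomerative average linkage on Pearson distance, from scratch."""
    n = matrix.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 1.0 - np.corrcoef(matrix[i], matrix[j])[0, 1]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = (np.inf, None, None)
        for a_i, a in enumerate(keys):
            for b in keys[a_i + 1 :]:
                dist = np.mean([d[p, q] for p in clusters[a] for q in clusters[b]])
                if dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights)


class TestNormalize:
    def test_hand_computed_scale_factors(self):
        cm = _cm({"s1": [100.0, 7.0], "s2": [400.0, 9.0]}, ["HK"], index=["HK", "G1"])
        normed, rep = normalize_counts(cm, min_avg_count=50)
        assert rep.scale_factor_per_sample["s1"] == pytest.approx(2.0)
        assert rep.scale_factor_per_sample["s2"] == pytest.approx(0.5)

    def test_equal_geomeans_give_identity(self):
        cm = _cm({"s1": [500.0, 3.0], "s2": [500.0, 8.0]}, ["HK"], index=["HK", "G1"])
        normed, rep = normalize_counts(cm)
        np.testing.assert_allclose(list(rep.scale_factor_per_sample.values()), 1.0)
        np.testing.assert_allclose(normed.counts.values, cm.counts.values)

    def test_low_abundance_housekeeping_excluded(self):
        cm = _cm(
            {"s1": [500.0, 300.0, 3.0], "s2": [600.0, 290.0, 8.0]},
            ["HK1", "HK2"],
            index=["HK1", "HK2", "G1"],
        )
        _, rep = normalize_counts(cm, min_avg_count=450)
        assert rep.retained_housekeeping == ["HK1"]

    def test_no_housekeeping_passing_filter_is_an_error(self):
        cm = _cm({"s1": [100.0], "s2": [90.0]}, ["HK1"], index=["HK1"])
        with pytest.raises(ValidationError, match="average-count"):
            normalize_counts(cm, min_avg_count=450)

    def test_post_normalization_geomeans_equal_and_idempotent(self):
        cm, _ = gen_count_matrix(n_genes=50, n_hk=5, n_per_group=3, seed=9)
        normed, _ = normalize_counts(cm)
        hk = normed.counts.loc[normed.housekeeping_ids].to_numpy()
        gm = np.exp(np.log(hk).mean(axis=0))
        assert np.ptp(gm) / gm.mean() < 1e-9
        again, rep2 = normalize_counts(normed)
        np.testing.assert_allclose(again.counts.values, normed.counts.values, rtol=1e-12)


class TestSelectDE:
    def _pair(self, a, b):
        ga = _cm({f"a{i}": col for i, col in enumerate(a)}, [])
        gb = _cm({f"b{i}": col for i, col in enumerate(b)}, [])
        return ga, gb

    def test_fold_change_gate_blocks_significant_small_changes(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(100, 200, 50)
        a = [base * rng.normal(1, 0.01, 50) for _ in range(3)]
        b_small = [base * 1.2 * rng.normal(1, 0.01, 50) for _ in range(3)]  # FC 1.2
        b_big = [base * 1.8 * rng.normal(1, 0.01, 50) for _ in range(3)]  # FC 1.8
        ga = _cm({f"a{i}": a[i] for i in range(3)}, [])
        t_small = select_de(ga, _cm({f"b{i}": b_small[i] for i in range(3)}, []))
        t_big = select_de(ga, _cm({f"b{i}": b_big[i] for i in range(3)}, []))
        assert (t_small.p_value <= 0.05).mean() > 0.9  # significant...
        assert (t_small.call == "ns").all()  # ...but inside the FC gate
        assert (t_big.call == "up").mean() > 0.9

    def test_identical_groups_are_ns_with_fc_one(self):
        col = list(np.linspace(10, 500, 20))
        ga = _cm({"a1": col, "a2": col}, [])
        gb = _cm({"b1": col, "b2": col}, [])
        t = select_de(ga, gb)
        np.testing.assert_allclose(t.fold_change, 1.0)
        assert (t.call == "ns").all()
        np.testing.assert_allclose(t.p_value, 1.0)  # zero variance, equal means

    def test_up_down_reciprocity(self):
        cm, _ = gen_count_matrix(
            n_genes=200, n_hk=5, n_per_group=4, de_fraction=0.2, fold_change=3.0, seed=3
        )
        normed, _ = normalize_counts(cm)
        a, b = normed.subset_group("CTRL"), normed.subset_group("MUT")
        ab = select_de(a, b)
        ba = select_de(b, a)
        assert set(ab.index[ab.call == "up"]) == set(ba.index[ba.call == "down"])
        np.testing.assert_allclose(ab.fold_change * ba.fold_change, 1.0, rtol=1e-9)

    def test_single_sample_group_rejected(self):
        ga = _cm({"a1": [1.0, 2.0]}, [])
        gb = _cm({"b1": [1.0, 2.0], "b2": [2.0, 3.0]}, [])
        with pytest.raises(ValidationError):
            select_de(ga, gb)

    def test_fdr_column_is_monotone_transform_of_p(self):
        cm, _ = gen_count_matrix(n_genes=100, n_hk=5, n_per_group=3, seed=5)
        normed, _ = normalize_counts(cm)
        t = select_de(normed.subset_group("CTRL"), normed.subset_group("MUT"), add_fdr=True)
        order = np.argsort(t.p_value.values)
        assert (np.diff(t.p_adj_bh.values[order]) >= -1e-12).all()


class TestCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        m = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4, 1, 0, 2.0]])
        res = cluster_profiles(m)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_pair_distance_two(self):
        m = np.array([[1.0, 2, 3], [3.0, 2, 1]])
        res = cluster_profiles(m)
        assert res.linkage_matrix[0, 2] == pytest.approx(2.0)

    def test_merge_heights_match_bruteforce_oracle(self, rng):
        for n in (4, 6, 8):
            m = rng.normal(size=(n, 6))
            res = cluster_profiles(m)
            np.testing.assert_allclose(
                np.sort(res.linkage_matrix[:, 2]),
                np.sort(average_linkage_oracle(m)),
                rtol=1e-9,
            )

    def test_zero_variance_profile_rejected(self):
        with pytest.raises(ValidationError):
            cluster_profiles(np.array([[1.0, 1, 1], [0.0, 1, 2]]))


class TestRelativeExpression:
    def test_delta_ct_closed_form(self):
        ct = CtTable(pd.DataFrame(
            {"sample_label": ["s", "s"], "gene_id": ["ATP5O", "X"], "ct_value": [20.0, 25.0]}
        ))
        rel = relative_expression(ct)
        assert rel[rel.gene_id == "X"].rel_expr.iloc[0] == pytest.approx(2**-5)

    def test_equal_cts_give_unit_ratio(self):
        ct = CtTable(pd.DataFrame(
            {
                "sample_label": ["s"] * 3,
                "gene_id": ["ATP5O", "4R", "3R"],
                "ct_value": [20.0, 24.0, 24.0],
            }
        ))
        rel = relative_expression(ct, ratios=[("4R", "3R")])
        assert rel[rel.gene_id == "4R/3R"].rel_expr.iloc[0] == pytest.approx(1.0)

    def test_ct_shift_doubles_everything(self):
        rows = pd.DataFrame(
            {
                "sample_label": ["s"] * 2,
                "gene_id": ["ATP5O", "X"],
                "ct_value": [20.0, 23.0],
            }
        )
        base = relative_expression(CtTable(rows))
        shifted = rows.copy()
        shifted.loc[shifted.gene_id == "X", "ct_value"] -= 1.0
        up = relative_expression(CtTable(shifted))
        assert (
            up[up.gene_id == "X"].rel_expr.iloc[0]
            == pytest.approx(2 * base[base.gene_id == "X"].rel_expr.iloc[0])
        )

    def test_missing_reference_gene_rejected(self):
        ct = CtTable(pd.DataFrame(
            {"sample_label": ["s"], "gene_id": ["X"], "ct_value": [25.0]}
        ))
        with pytest.raises(ValidationError):
            relative_expression(ct)

    def test_generator_truth_recovered_without_noise(self):
        ct, truth = gen_ct_table({"4R": 0.5, "3R": 0.25}, ct_noise_sd=0.0, n_samples=2, seed=1)
        rel = relative_expression(ct, ratios=[("4R", "3R")])
        for g, v in truth.items():
            got = rel[rel.gene_id == g].rel_expr
            np.testing.assert_allclose(got, v, rtol=1e-12)
        np.testing.assert_allclose(rel[rel.gene_id == "4R/3R"].rel_expr, 2.0, rtol=1e-12)


def test_qc_controls_reports_linearity_and_background():
    rep = qc_controls(
        positive_counts=np.array([100.0, 400, 1600, 6400]),
        positive_inputs=np.array([1.0, 4, 16, 64]),
        negative_counts=np.array([3.0, 5, 4, 6]),
    )
    assert rep["positive_control_r2"] == pytest.approx(1.0, abs=1e-9)
    assert rep["negative_control_background"] > 4.5
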