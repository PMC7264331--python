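"""Cohort statistics: standardization, correlation, reduction, PCA."""

import numpy as np
import pandas as pd
import pytest

from hrvnet.stats import (DEFAULT_DROP_LIST, RedundancyReducer, correlation_report,
                          find_redundant_pairs, fit_pca, impute_missing,
                          joint_histogram, marker_columns, pearson_matrix,
                          reduce_markers, resolve_drop_list, standardize)


def frame(x, labels=None):
    df = pd.DataFrame(np.asarray(x, float),
                      columns=[f"m{i + 1:02d}" for i in range(np.shape(x)[1])])
    df.insert(0, "label", labels if labels is not None else "H")
    return df


class TestStandardize:
    def test_population_convention(self):
        df, center, scale = standardize(frame([[1], [2], [3]]))
        assert center.iloc[0] == 2
        assert scale.iloc[0] == pytest.approx(np.sqrt(2 / 3))  # 1/M convention
        assert df["m01"].mean() == pytest.approx(0, abs=1e-12)
        assert df["m01"].std(ddof=0) == pytest.approx(1)

    def test_idempotent(self):
        df1, _, _ = standardize(frame([[1, 5], [2, 9], [4, 6]]))
        df2, _, _ = standardize(df1)
        assert np.allclose(df1[["m01", "m02"]], df2[["m01", "m02"]])

    def test_constant_column_centered_only(self):
        df, _, scale = standardize(frame([[1, 7], [2, 7], [3, 7]]))
        assert scale.iloc[1] == 1.0
        assert np.allclose(df["m02"], 0)


class TestPearson:
    def test_brute_force_oracle(self, rng):
        x = rng.normal(size=(10, 5))
        got = pearson_matrix(frame(x)).to_numpy()
        m = x.shape[0]
        mu = x.mean(axis=0)
        cov = (x - mu).T @ (x - mu) / m
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        assert np.allclose(got, expected, atol=1e-10)

    def test_hand_example(self):
        got = pearson_matrix(frame([[0, 0], [1, 2], [2, 4]]))
        assert got.iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelated(self):
        got = pearson_matrix(frame([[0, 0], [1, -1], [2, -2]]))
        assert got.iloc[0, 1] == pytest.approx(-1.0)


class TestRedundancy:
    def test_forced_pairs_on_marker_cohort(self, markers100):
        imputed, _ = impute_missing(markers100)
        pairs = find_redundant_pairs(pearson_matrix(imputed))
        found = {(i, j) for i, j, _ in pairs}
        assert (5, 38) in found
        assert (18, 22) in found
        assert (31, 35) in found

    def test_threshold_above_one_empty(self, markers100):
        imputed, _ = impute_missing(markers100)
        assert find_redundant_pairs(pearson_matrix(imputed), threshold=1.01) == []

    def test_paper_default_drop_list(self):
        drop = resolve_drop_list([], mode="paper_default")
        assert drop == (22, 27, 29, 31, 33, 34, 35, 38)

    def test_greedy_tie_breaks_high_index(self):
        assert resolve_drop_list([(1, 2, 0.999)], mode="greedy") == (2,)

    def test_greedy_covers_published_pair_set(self):
        # the documented redundant couples of the 49-marker battery
        pairs = [(5, 38, 1.0), (14, 27, 0.998), (16, 29, 1.0), (18, 22, -1.0),
                 (18, 31, 0.992), (18, 35, -0.992), (20, 33, 0.999),
                 (21, 34, 0.998), (22, 31, -0.992), (22, 35, 0.992),
                 (31, 35, -1.0)]
        drop = resolve_drop_list(pairs, mode="greedy")
        assert len(drop) <= 8
        remaining = [(i, j) for i, j, _ in pairs if i not in drop and j not in drop]
        assert remaining == []


class TestReduce:
    def test_default_drop_yields_41(self, markers100):
        reduced = reduce_markers(markers100)
        assert len(marker_columns(reduced)) == 41
        assert "m22" not in reduced.columns and "m38" not in reduced.columns
        # surviving columns keep their original numbering
        assert "m39" in reduced.columns

    def test_empty_drop_identity(self, markers100):
        assert reduce_markers(markers100, ()).equals(markers100)

    def test_unknown_index_errors(self, markers100):
        with pytest.raises(KeyError):
            reduce_markers(markers100, (99,))

    def test_reducer_estimator(self, rng):
        x = rng.normal(size=(20, 49))
        red = RedundancyReducer().fit(x)
        assert red.transform(x).shape == (20, 41)
        assert list(red.drop_list_) == list(DEFAULT_DROP_LIST)


class TestJointHistogram:
    def test_sums_to_one(self, markers100):
        h, _, _ = joint_histogram(markers100, "H", 40, 45)
        assert h.sum() == pytest.approx(1.0)

    def test_single_patient_single_bin(self, markers100):
        one = markers100[markers100.label == "AF"].iloc[:1]
        pooled = pd.concat([one, markers100[markers100.label == "H"]])
        h, _, _ = joint_histogram(pooled, "AF", 40, 45)
        assert np.count_nonzero(h) == 1

    def test_empty_class_errors(self, markers100):
        with pytest.raises(ValueError):
            joint_histogram(markers100, "nosuch", 40, 45)


class TestPCA:
    def test_line_data_one_component(self):
        t = np.linspace(-1, 1, 50)
        x = np.c_[t, 2 * t]
        x = (x - x.mean(0)) / x.std(0)
        model = fit_pca(x)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_rotation_and_fractions(self, rng):
        x = rng.normal(size=(40, 6))
        x = (x - x.mean(0)) / x.std(0)
        model = fit_pca(x)
        r = model.rotation
        assert np.allclose(r.T @ r, np.eye(6), atol=1e-8)
        evf = model.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() == pytest.approx(1.0)

    def test_round_trip(self, rng):
        x = rng.normal(size=(30, 5))
        x = (x - x.mean(0)) / x.std(0)
        model = fit_pca(x)
        back = model.back_rotate(model.scores(x))
        assert np.allclose(back, x, atol=1e-8)
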