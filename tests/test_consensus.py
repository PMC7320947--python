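"""Consensus pooling, unanimity voting and the Model/Results interface."""

import numpy as np
import pandas as pd
import pytest

from consvote import (ConsensusModel, ProbabilityMatrix, agreement_mask,
                      consensus1, consensus2, optimize_threshold, pool, roc)


def matrix_from(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"m{j}" for j in range(values.shape[1])]
    ids = [f"c{i}" for i in range(values.shape[0])]
    return ProbabilityMatrix(ids, names, values, np.asarray(labels))


class TestPool:
    def test_row_arithmetic(self):
        m = matrix_from([[0.2, 0.6, 0.7]], [1])
        assert pool(m, "min")[0] == pytest.approx(0.2)
        assert pool(m, "ave")[0] == pytest.approx(0.5)
        assert pool(m, "max")[0] == pytest.approx(0.7)

    def test_identical_models_collapse(self, rng):
        col = rng.random(15)
        m = matrix_from(np.tile(col[:, None], 3), rng.integers(0, 2, 15))
        for mode in ("min", "ave", "max"):
            assert pool(m, mode) == pytest.approx(col)

    def test_ave_matches_brute_force_means(self, rng):
        values = rng.random((20, 4))
        m = matrix_from(values, rng.integers(0, 2, 20))
        expected = np.array([sum(row) / 4 for row in values])
        assert pool(m, "ave") == pytest.approx(expected, abs=1e-12)

    def test_rowwise_ordering_min_ave_max(self, small_prob_matrix):
        m = small_prob_matrix
        assert np.all(pool(m, "min") <= pool(m, "ave") + 1e-15)
        assert np.all(pool(m, "ave") <= pool(m, "max") + 1e-15)

    def test_unknown_mode(self, small_prob_matrix):
        with pytest.raises(ValueError, match="mode"):
            pool(small_prob_matrix, "median")


class TestAgreementMask:
    def test_two_model_example(self):
        classes = np.array([[1, 1], [0, 1], [1, 1]])
        assert agreement_mask(classes).tolist() == [True, False, True]

    def test_identical_models_all_true(self, rng):
        col = rng.integers(0, 2, 30)
        assert agreement_mask(np.tile(col[:, None], 4)).all()

    def test_matches_brute_force_uniformity(self, rng):
        classes = rng.integers(0, 2, size=(50, 5))
        expected = [len(set(row)) == 1 for row in classes.tolist()]
        assert agreement_mask(classes).tolist() == expected


class TestConsensus1:
    def test_single_model_identity(self, rng):
        col = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        m = matrix_from(col[:, None], labels)
        res = consensus1(m)["ave"]
        assert res.pooled == pytest.approx(col)
        assert res.auc == pytest.approx(roc(labels, col).auc)
        assert res.excluded_ratio == 0.0

    def test_perfect_plus_antiperfect_instance(self):
        # pair-counting enumeration by hand: ave pools to AUC 4/9 while the
        # min and max pools are label-symmetric (AUC exactly 1/2)
        labels = np.array([1, 1, 1, 0, 0, 0])
        good = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])   # AUC 1
        bad = np.array([0.1, 0.3, 0.2, 0.8, 0.9, 0.7])    # AUC 0
        m = matrix_from(np.column_stack([good, bad]), labels)
        res = consensus1(m)
        assert roc(labels, good).auc == 1.0
        assert roc(labels, bad).auc == 0.0
        assert res["ave"].auc == pytest.approx(4 / 9)
        assert res["min"].auc == pytest.approx(0.5) != res["ave"].auc
        assert res["max"].auc == pytest.approx(0.5) != res["ave"].auc

    def test_exclusion_is_always_zero(self, small_prob_matrix):
        for res in consensus1(small_prob_matrix).values():
            assert res.excluded_ratio == 0.0 and res.keep_mask.all()


class TestConsensus2:
    def test_unanimous_models_reduce_to_consensus1(self, rng):
        col = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        m = matrix_from(np.tile(col[:, None], 3), labels)
        c1 = consensus1(m)
        c2 = consensus2(m, thresholds=[0.5, 0.5, 0.5])
        for mode in ("min", "ave", "max"):
            assert c2[mode].keep_mask.all()
            assert c2[mode].pooled == pytest.approx(c1[mode].pooled)
            assert c2[mode].auc == pytest.approx(c1[mode].auc)
            assert c2[mode].threshold.threshold == pytest.approx(
                c1[mode].threshold.threshold)
            assert c2[mode].excluded_ratio == 0.0

    def test_one_disagreement_excludes_quarter(self):
        labels = [1, 0, 1, 0]
        values = np.array([[0.9, 0.9], [0.1, 0.1], [0.8, 0.7],
                           [0.2, 0.9]])  # last row splits at t=0.5
        m = matrix_from(values, labels)
        res = consensus2(m, thresholds=[0.5, 0.5])["ave"]
        assert res.excluded_ratio == pytest.approx(0.25)
        assert res.keep_mask.tolist() == [True, True, True, False]

    def test_boundary_disagreement_raises_kept_auc(self):
        # 200 compounds, 6 models; models disagree on the hardest 30%
        gen = np.random.default_rng(42)
        n, m = 200, 6
        labels = np.repeat([1, 0], n // 2)
        signal = np.where(labels == 1, 0.75, 0.25)
        hardest = np.zeros(n, dtype=bool)
        hardest[::3] = True  # planted ~33% hard rows near the boundary
        probs = np.empty((n, m))
        for j in range(m):
            noise = gen.normal(0, 0.05, n)
            pj = np.clip(signal + noise, 0.01, 0.99)
            flip = hardest & (gen.random(n) < 0.5)
            pj = np.where(flip, 1 - pj, pj)  # disagreement on hard rows
            probs[:, j] = pj
        matrix = matrix_from(probs, labels)
        c1_auc = consensus1(matrix)["ave"].auc
        res2 = consensus2(matrix, thresholds=[0.5] * m)["ave"]
        assert 0.0 < res2.excluded_ratio < 0.6
        assert res2.auc >= c1_auc

    def test_keep_set_is_subset_and_metrics_ignore_excluded(
            self, small_prob_matrix):
        thresholds = [0.5, 0.5, 0.5]
        res = consensus2(small_prob_matrix, thresholds)["ave"]
        kept_labels = small_prob_matrix.labels[res.keep_mask]
        assert len(res.pooled) == res.keep_mask.sum() <= 20
        assert res.active_ratio_kept == pytest.approx(kept_labels.mean())

    def test_column_permutation_changes_nothing(self, small_prob_matrix):
        m = small_prob_matrix
        perm = [2, 0, 1]
        permuted = ProbabilityMatrix(
            m.ids, [m.model_names[j] for j in perm], m.values[:, perm],
            m.labels)
        t = {"m0": 0.4, "m1": 0.55, "m2": 0.6}
        a = consensus2(m, t)
        b = consensus2(permuted, t)
        for mode in ("min", "ave", "max"):
            assert a[mode].pooled == pytest.approx(b[mode].pooled)
            assert a[mode].auc == b[mode].auc
            assert np.array_equal(a[mode].keep_mask, b[mode].keep_mask)

    def test_no_unanimous_rows_is_explicit(self):
        m = matrix_from([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.3, 0.8]],
                        [1, 0, 1, 0])
        with pytest.raises(ValueError, match="unanimous"):
            consensus2(m, thresholds=[0.5, 0.5])

    def test_single_class_kept_rows_is_explicit(self):
        m = matrix_from([[0.9, 0.9], [0.8, 0.8], [0.2, 0.9], [0.3, 0.8]],
                        [1, 1, 0, 0])
        with pytest.raises(ValueError, match="single-class"):
            consensus2(m, thresholds=[0.5, 0.5])


class TestConsensusModelResults:
    def test_fit_summary_and_predictions(self, small_prob_matrix):
        results = ConsensusModel(small_prob_matrix, scheme=2).fit()
        text = results.summary()
        assert "Consensus 2" in text and "AUC" in text
        preds = results.predict("ave")
        assert set(preds.columns) == {"compound_id", "kept", "pooled_prob",
                                      "predicted_class"}
        # excluded compounds surface as explicit no-calls
        assert (preds.loc[~preds["kept"], "predicted_class"] == -1).all()
        assert preds["kept"].sum() == len(
            results["ave"].pooled)

    def test_frozen_thresholds_differ_from_refit(self, small_prob_matrix):
        frozen = {"m0": 0.9, "m1": 0.9, "m2": 0.9}
        res_frozen = ConsensusModel(small_prob_matrix, scheme=2,
                                    thresholds=frozen).fit()
        res_refit = ConsensusModel(small_prob_matrix, scheme=2).fit()
        assert not np.array_equal(res_frozen["ave"].keep_mask,
                                  res_refit["ave"].keep_mask)

    def test_from_dataframe(self, small_prob_matrix):
        df = pd.DataFrame(small_prob_matrix.values,
                          columns=small_prob_matrix.model_names)
        df["label"] = small_prob_matrix.labels
        df["compound_id"] = small_prob_matrix.ids
        model = ConsensusModel.from_dataframe(df, scheme=1)
        assert model.matrix.n_models == 3
        res = model.fit(modes=("ave",))
        assert res["ave"].auc == consensus1(small_prob_matrix)["ave"].auc

    def test_scheme2_requires_two_models(self, rng):
        col = rng.random(10)
        labels = rng.integers(0, 2, 10)
        labels[:2] = [0, 1]
        m = matrix_from(col[:, None], labels)
        with pytest.raises(ValueError, match="at least 2"):
            ConsensusModel(m, scheme=2)

    def test_metrics_threshold_consistency(self, small_prob_matrix):
        # AUC reported by metrics equals the mode's own curve AUC
        results = ConsensusModel(small_prob_matrix, scheme=1).fit()
        for mode in results.modes:
            assert results.metrics(mode).auc == results[mode].auc


class TestProbabilityMatrixValidation:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            matrix_from([[1.2, 0.5]], [1])

    def test_rejects_missing_cells(self):
        with pytest.raises(ValueError):
            matrix_from([[np.nan, 0.5]], [1])

    def test_csv_roundtrip(self, tmp_path, small_prob_matrix):
        p = tmp_path / "probs.csv"
        small_prob_matrix.to_csv(p)
        back = ProbabilityMatrix.from_csv(p)
        assert back.model_names == small_prob_matrix.model_names
        assert back.values == pytest.approx(small_prob_matrix.values)
        assert np.array_equal(back.labels, small_prob_matrix.labels)
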