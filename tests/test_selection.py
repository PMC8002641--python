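import numpy as np
import pytest
from scipy import stats
from sklearn.feature_selection import chi2 as sklearn_chi2

from spenhancer.seq_io import ValidationError
from spenhancer.seqpose import EncodedMatrix
from spenhancer.selection import (
    apply_mask,
    chi2_position,
    load_mask,
    onehot_expand,
    remove_top_k,
    removal_sweep,
    save_mask,
    score_all_positions,
)


def matrix_from(ids, labels=None, k=2, mode="forward"):
    ids = np.asarray(ids)
    m = EncodedMatrix.__new__(EncodedMatrix)
    m.ids = ids
    m.k = k
    m.track_mode = mode
    m.n = ids.shape[1] + k - 1
    m.labels = None if labels is None else np.asarray(labels)
    return m


class TestOnehotExpand:
    def test_two_category_column(self):
        w = onehot_expand([1, 1, 2, 2], [1, 1, 0, 0])
        assert w.X.shape == (4, 2)
        assert w.vFeatureSum.tolist() == [2.0, 2.0]
        assert w.vProbP == 0.5
        assert w.vProbP + w.vProbN == 1.0

    def test_single_category_column(self):
        w = onehot_expand([7, 7, 7], [1, 0, 1])
        assert w.categories.tolist() == [7]
        assert w.vFeatureSum.tolist() == [3.0]

    def test_category_count_equals_distinct_ids(self, rng):
        col = rng.integers(0, 9, size=50)
        labels = rng.integers(0, 2, size=50)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        w = onehot_expand(col, labels)
        assert len(w.categories) == len(set(col.tolist()))
        # observed cells sum to N; expected columns sum to the column totals
        assert w.vObserved.sum() == 50
        np.testing.assert_allclose(w.vExpected.sum(axis=0), w.vFeatureSum)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            onehot_expand([1, 2, 1], [1, 1, 1])


class TestChi2Position:
    def test_worked_example(self):
        w = onehot_expand([1, 1, 2, 2], [1, 1, 0, 0])
        statistics, pvalues, position_p = chi2_position(w)
        np.testing.assert_array_equal(w.vObserved, [[0, 2], [2, 0]])
        np.testing.assert_array_equal(w.vExpected, [[1, 1], [1, 1]])
        np.testing.assert_allclose(statistics, [2.0, 2.0])
        # independent survival-function oracle at df=1
        expected_p = 2 * stats.chi2.sf(2.0, 1)
        assert position_p == pytest.approx(expected_p, abs=1e-9)
        assert position_p == pytest.approx(0.31460, abs=5e-6)

    def test_uninformative_column_scores_one(self):
        w = onehot_expand([1, 1, 1, 1], [1, 1, 0, 0])
        statistics, pvalues, position_p = chi2_position(w)
        assert statistics.tolist() == [0.0]
        assert pvalues.tolist() == [1.0]
        assert position_p == 1.0

    def test_matches_contingency_oracle_on_random_instances(self, rng):
        """Per-category statistics equal a 2xC contingency computation."""
        for _ in range(200):
            n = int(rng.integers(4, 31))
            col = rng.integers(0, rng.integers(2, 8), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            w = onehot_expand(col, labels)
            statistics, pvalues, _ = chi2_position(w)
            ref_stat, ref_p = sklearn_chi2(w.X, labels)
            np.testing.assert_allclose(statistics, ref_stat, atol=1e-9)
            np.testing.assert_allclose(pvalues, ref_p, atol=1e-9)

    def test_invariant_to_row_order_and_id_relabeling(self, rng):
        col = rng.integers(1, 5, size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        _, _, p_ref = chi2_position(onehot_expand(col, labels))
        perm = rng.permutation(40)
        _, _, p_rows = chi2_position(onehot_expand(col[perm], labels[perm]))
        relabel = {1: 9, 2: 3, 3: 17, 4: 5}
        col2 = np.array([relabel[c] for c in col])
        _, _, p_ids = chi2_position(onehot_expand(col2, labels))
        assert p_rows == pytest.approx(p_ref, abs=1e-12)
        assert p_ids == pytest.approx(p_ref, abs=1e-12)


class TestScoreAllPositions:
    def test_one_pvalue_per_column(self, rng):
        ids = rng.integers(1, 5, size=(30, 12))
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        table = score_all_positions(matrix_from(ids, labels))
        assert table.position_pvalues.shape == (12,)

    def test_constant_columns_all_score_one(self):
        ids = np.full((10, 6), 3)
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        table = score_all_positions(matrix_from(ids, labels))
        assert (table.position_pvalues == 1.0).all()

    def test_planted_columns_rank_most_informative(self, rng):
        """5 label-correlated columns among 50 get the smallest p-values."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            labels = np.r_[np.ones(25, int), np.zeros(25, int)]
            ids = r.integers(1, 9, size=(50, 50))
            planted = [3, 11, 22, 37, 48]
            for c in planted:
                ids[labels == 1, c] = 1
                ids[labels == 0, c] = 2
            table = score_all_positions(matrix_from(ids, labels))
            bottom5 = set(table.ranking[-5:].tolist())
            hits += bottom5 == set(planted)
        assert hits / n_rep >= 0.95


class TestRemoveAndApply:
    def make_table(self, pvals):
        m = matrix_from(
            np.tile(np.arange(1, len(pvals) + 1), (6, 1)),
            [1, 1, 1, 0, 0, 0],
        )
        table = score_all_positions(m)
        table.position_pvalues = np.asarray(pvals, float)
        table.ranking = np.argsort(-table.position_pvalues, kind="stable")
        return table

    def test_k_zero_removes_nothing(self):
        table = self.make_table([0.5, 0.2, 0.9])
        assert remove_top_k(table, 0).sum() == 0

    def test_398_columns_k45_keeps_353(self, rng):
        ids = rng.integers(1, 17, size=(20, 398))
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        m = matrix_from(ids, labels, mode="duplex")
        table = score_all_positions(m)
        mask = remove_top_k(table, 45)
        assert mask.sum() == 45
        kept = apply_mask(m, mask)
        assert kept.ids.shape == (20, 353)

    def test_tie_rule_removes_lower_index_first(self):
        table = self.make_table([0.7, 0.7, 0.7, 0.7])
        mask = remove_top_k(table, 3)
        assert np.flatnonzero(mask).tolist() == [0, 1, 2]

    def test_removed_sets_nest_as_k_grows(self):
        table = self.make_table([0.4, 0.9, 0.1, 0.6, 0.6])
        sets = []
        for K in range(5):
            sets.append(set(np.flatnonzero(remove_top_k(table, K)).tolist()))
        for a, b in zip(sets, sets[1:]):
            assert a <= b

    def test_k_out_of_range_errors(self):
        table = self.make_table([0.5, 0.5])
        with pytest.raises(ValidationError):
            remove_top_k(table, 2)

    def test_apply_mask_identical_on_train_and_test(self, rng):
        labels = np.r_[np.ones(8, int), np.zeros(8, int)]
        train = matrix_from(rng.integers(1, 5, size=(16, 10)), labels)
        test = matrix_from(rng.integers(1, 5, size=(7, 10)))
        table = score_all_positions(train)
        mask = remove_top_k(table, 4)
        kept_cols = np.flatnonzero(~mask)
        t1 = apply_mask(train, mask)
        t2 = apply_mask(test, mask)
        assert (t1.ids == train.ids[:, kept_cols]).all()
        assert (t2.ids == test.ids[:, kept_cols]).all()

    def test_all_false_mask_is_identity(self, rng):
        m = matrix_from(rng.integers(1, 5, size=(4, 6)))
        out = apply_mask(m, np.zeros(6, bool))
        assert (out.ids == m.ids).all()

    def test_length_mismatch_errors(self, rng):
        m = matrix_from(rng.integers(1, 5, size=(4, 6)))
        with pytest.raises(ValidationError, match="mask length"):
            apply_mask(m, np.zeros(5, bool))


class TestSweepAndSerialization:
    def test_coarse_and_fine_row_counts(self, rng):
        ids = rng.integers(1, 5, size=(20, 60))
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        m = matrix_from(ids, labels)
        rows = removal_sweep(
            m, evaluator=lambda mask: {"Acc": 0.5}, coarse_step=5,
            coarse_max=45, fine_steps=5,
        )
        ks = [r["K"] for r in rows]
        assert ks == [0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 46, 47, 48, 49, 50]

    def test_removing_null_positions_helps_a_downstream_classifier(self):
        """Dropping the uninformative positions should not hurt accuracy."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import OneHotEncoder

        wins = 0
        n_rep = 20
        n_null = 35
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            labels = np.r_[np.ones(20, int), np.zeros(20, int)]
            ids = r.integers(1, 17, size=(40, 40))
            for c in range(5):  # planted signal in the first 5 columns
                flip = r.random(20) < 0.7
                ids[np.flatnonzero(labels == 1)[flip], c] = 1
            m = matrix_from(ids, labels)
            train_idx = np.r_[0:10, 20:30]
            test_idx = np.setdiff1d(np.arange(40), train_idx)

            def evaluate(mask):
                kept = np.flatnonzero(~mask)
                enc = OneHotEncoder(handle_unknown="ignore")
                Xtr = enc.fit_transform(ids[np.ix_(train_idx, kept)])
                Xte = enc.transform(ids[np.ix_(test_idx, kept)])
                clf = LogisticRegression(max_iter=200).fit(Xtr, labels[train_idx])
                return {"Acc": clf.score(Xte, labels[test_idx])}

            rows = removal_sweep(
                matrix_from(ids[train_idx], labels[train_idx]),
                evaluator=evaluate, coarse_step=n_null, coarse_max=n_null,
                fine_steps=0,
            )
            assert [r_["K"] for r_ in rows] == [0, n_null]
            wins += rows[1]["Acc"] >= rows[0]["Acc"]
        assert wins > n_rep / 2

    def test_mask_json_round_trip(self, tmp_path):
        mask = np.zeros(10, bool)
        mask[[2, 5]] = True
        save_mask(mask, tmp_path / "m.json", k=2, track_mode="forward")
        assert (load_mask(tmp_path / "m.json") == mask).all()
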