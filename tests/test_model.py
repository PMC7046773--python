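import numpy as np
import pytest
from sklearn.base import clone

import pnet
from pnet import model
from pnet.dataio import NEG, POS, UNLABELED, DataError
from pnet.model import (PNetClassifier, _select_tau_array, rank_auroc,
                        select_decision_threshold, select_tau)
from conftest import label_vector


def _two_block_kernel(n_per=3, within=0.9, between=0.1):
    n = 2 * n_per
    K = np.full((n, n), between)
    K[:n_per, :n_per] = within
    K[n_per:, n_per:] = within
    np.fill_diagonal(K, 1.0)
    ids = [f"P{i}" for i in range(n)]
    y = np.array([POS] * n_per + [NEG] * n_per)
    return pnet.KernelGraph(ids, K, 2.0, 1), label_vector(ids, y)


class TestSelectTau:
    def test_two_block_kernel_argmax_matches_enumeration(self):
        Kg, labels = _two_block_kernel()
        cfg = pnet.PNetConfig(m_prime=1, tau_grid_size=20)
        tau, crit = select_tau(Kg, labels, cfg)
        # independent enumeration of the same candidate grid
        from pnet.model import _filter_array, _tau_grid
        from pnet.scoring import score_array
        best = None
        for t in _tau_grid(Kg.K, 20):
            s = score_array(_filter_array(Kg.K, t), labels.status == POS,
                            labels.status == NEG, "Dnorm", loo=True)
            a = rank_auroc(labels.status == POS, s)
            if best is None or a > best[1]:
                best = (float(t), a)
        assert (tau, crit) == best
        assert crit == 1.0
        # the unfiltered kernel already ranks the blocks perfectly, so the
        # ties-to-smallest rule keeps every edge
        assert tau == 0.0

    def test_all_zero_offdiagonal_returns_zero_with_warning(self):
        ids = ["P0", "P1", "P2", "P3"]
        Kg = pnet.KernelGraph(ids, np.eye(4), 2.0, 1)
        labels = label_vector(ids, [POS, POS, NEG, NEG])
        cfg = pnet.PNetConfig(m_prime=1)
        with pytest.warns(UserWarning, match="tau=0"):
            tau, crit = select_tau(Kg, labels, cfg)
        assert tau == 0.0

    def test_null_labels_fixed_tau_auroc_centered_for_av(self):
        # for the count-normalized AV score the fixed-tau LOO AUROC is
        # centered under label shuffling; the maximized criterion can only
        # sit above it (grid-search selection bias). The differential
        # scores are structurally below 0.5 at the null because hold-out
        # removes one evidence term from the node's own class.
        from pnet.scoring import score_array
        cfg = pnet.PNetConfig(m_prime=1, score_name="AV")
        fixed, maxed = [], []
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = 20
            K = r.random((n, n)); K = (K + K.T) / 2; np.fill_diagonal(K, 1.0)
            y = np.array([POS] * 10 + [NEG] * 10)
            r.shuffle(y)
            s = score_array(K, y == POS, y == NEG, "AV", loo=True)
            fixed.append(rank_auroc(y == POS, s))
            maxed.append(_select_tau_array(K, y, cfg)[1])
        assert abs(np.mean(fixed) - 0.5) < 0.05
        assert np.mean(maxed) >= np.mean(fixed)

    def test_requires_both_classes(self):
        ids = ["P0", "P1"]
        Kg = pnet.KernelGraph(ids, np.eye(2), 2.0, 1)
        with pytest.raises(DataError):
            select_tau(Kg, label_vector(ids, [POS, POS]),
                       pnet.PNetConfig(m_prime=1))


class TestDecisionThreshold:
    def _table(self, ids, scores):
        return pnet.ScoreTable(list(ids), np.asarray(scores, dtype=float),
                               np.arange(1, len(ids) + 1), "Dnorm")

    def test_separable_scores_first_maximizing_midpoint(self):
        ids = ["P1", "P2", "P3", "P4"]
        labels = label_vector(ids, [POS, POS, NEG, NEG])
        thr = select_decision_threshold(self._table(ids, [0.9, 0.8, 0.1, 0.2]), labels)
        assert thr == pytest.approx(0.5)

    def test_all_equal_scores_follow_majority(self):
        ids = [f"P{i}" for i in range(5)]
        labels = label_vector(ids, [POS, POS, NEG, NEG, NEG])  # NEG majority
        thr = select_decision_threshold(self._table(ids, [0.3] * 5), labels)
        assert thr > 0.3  # classify everyone negative
        labels2 = label_vector(ids, [POS, POS, POS, NEG, NEG])  # POS majority
        thr2 = select_decision_threshold(self._table(ids, [0.3] * 5), labels2)
        assert thr2 < 0.3

    def test_single_pair_perfect_separation(self):
        ids = ["P1", "P2"]
        labels = label_vector(ids, [POS, NEG])
        thr = select_decision_threshold(self._table(ids, [0.8, 0.2]), labels)
        assert 0.2 < thr < 0.8

    def test_unlabeled_scores_ignored(self):
        ids = ["P1", "P2", "P3"]
        labels = label_vector(ids, [POS, NEG, UNLABELED])
        thr = select_decision_threshold(self._table(ids, [0.9, 0.1, -5.0]), labels)
        assert 0.1 < thr < 0.9


class TestEstimator:
    def _xy(self, seed=0, **kw):
        spec = pnet.SyntheticSpec(n_patients=40, m_features=120, n_differential=10,
                                  effect_size=2.5, unlabeled_fraction=0.1,
                                  seed=seed, **kw)
        M, labels, _ = pnet.generate_cohort(spec)
        return M.values.T, labels.status.copy()

    def test_m_prime_is_required(self):
        X, y = self._xy()
        with pytest.raises(DataError, match="m_prime"):
            PNetClassifier().fit(X, y)

    def test_fitted_attributes_and_transduction(self):
        X, y = self._xy()
        est = PNetClassifier(m_prime=30).fit(X, y)
        assert est.selected_features_.shape == (30,)
        assert est.kernel_.shape == (40, 40)
        assert est.scores_.shape == (40,)
        assert set(np.unique(est.transduction_)) <= {0, 1}
        assert np.array_equal(est.predict(X), est.transduction_)
        assert np.array_equal(est.predict(X) == 1,
                              est.decision_function(X) > 0)

    def test_predict_rejects_other_cohort(self):
        X, y = self._xy()
        est = PNetClassifier(m_prime=30).fit(X, y)
        with pytest.raises(DataError, match="transductive"):
            est.predict(X + 1.0)

    def test_sklearn_clone_compatible(self):
        est = PNetClassifier(m_prime=10, p=2, score="NN")
        params = clone(est).get_params()
        assert params["p"] == 2 and params["score"] == "NN"

    def test_held_out_labels_never_read(self):
        X, y = self._xy()
        held = np.flatnonzero(y != UNLABELED)[:8]
        y_masked = y.copy()
        y_masked[held] = UNLABELED
        est1 = PNetClassifier(m_prime=30).fit(X, y_masked)
        est2 = PNetClassifier(m_prime=30).fit(X, y_masked)
        assert np.array_equal(est1.scores_, est2.scores_)
        assert est1.tau_ == est2.tau_
        assert est1.decision_threshold_ == est2.decision_threshold_


class TestPipeline:
    def test_strong_signal_training_loo_auroc(self):
        # clearly separated synthetic cohorts: the internal LOO criterion
        # should be essentially perfect
        crits = []
        for seed in range(5):
            spec = pnet.SyntheticSpec(n_patients=100, m_features=500,
                                      n_differential=20, effect_size=2.0,
                                      unlabeled_fraction=0.0, seed=seed)
            M, labels, _ = pnet.generate_cohort(spec)
            fitted = pnet.fit(M, labels, pnet.PNetConfig(m_prime=100))
            crits.append(fitted.tau_criterion)
        assert np.mean(crits) >= 0.95

    def test_fit_is_deterministic(self, small_cohort):
        M, labels, _ = small_cohort
        cfg = pnet.PNetConfig(m_prime=30)
        f1 = pnet.fit(M, labels, cfg)
        f2 = pnet.fit(M, labels, cfg)
        assert f1.selected_features == f2.selected_features
        assert f1.tau == f2.tau
        assert f1.decision_threshold == f2.decision_threshold
        t1 = pnet.predict(f1, M, labels)
        t2 = pnet.predict(f2, M, labels)
        assert np.array_equal(t1.score, t2.score)

    def test_fit_ignores_non_training_labels(self, small_cohort):
        M, labels, _ = small_cohort
        cfg = pnet.PNetConfig(m_prime=30)
        labeled = [p for p, s in zip(labels.patient_ids, labels.status)
                   if s != UNLABELED]
        training = labeled[: len(labeled) - 6]
        held = labeled[len(labeled) - 6:]
        f1 = pnet.fit(M, labels, cfg, training_ids=training)
        # scramble held-out labels
        st = labels.status.copy()
        idx = {p: i for i, p in enumerate(labels.patient_ids)}
        for p in held:
            st[idx[p]] = POS if st[idx[p]] == NEG else NEG
        f2 = pnet.fit(M, pnet.LabelVector(labels.patient_ids, st), cfg,
                      training_ids=training)
        assert f1.selected_features == f2.selected_features
        assert f1.tau == f2.tau
        assert f1.decision_threshold == f2.decision_threshold
        s1 = pnet.predict(f1, M, labels).score
        s2 = pnet.predict(f2, M, pnet.LabelVector(labels.patient_ids, st)).score
        assert np.array_equal(s1, s2)

    def test_held_out_patient_with_positive_neighbors_predicted_positive(self):
        # two tight expression clusters; the held-out patient sits in the
        # positive one
        rng = np.random.default_rng(0)
        base_pos = rng.standard_normal(30)
        base_neg = rng.standard_normal(30)
        cols = []
        for _ in range(4):
            cols.append(base_pos + 0.05 * rng.standard_normal(30))
        for _ in range(4):
            cols.append(base_neg + 0.05 * rng.standard_normal(30))
        cols.append(base_pos + 0.05 * rng.standard_normal(30))  # held out
        values = np.array(cols).T
        ids = [f"P{i}" for i in range(9)]
        M = pnet.ExpressionMatrix([f"g{i}" for i in range(30)], ids, values)
        labels = label_vector(ids, [POS] * 4 + [NEG] * 4 + [UNLABELED])
        fitted = pnet.fit(M, labels, pnet.PNetConfig(m_prime=30))
        table = pnet.predict(fitted, M, labels)
        assert bool(table.predicted_class[8])

    def test_threshold_above_max_score_predicts_all_negative(self, small_cohort):
        M, labels, _ = small_cohort
        fitted = pnet.fit(M, labels, pnet.PNetConfig(m_prime=30))
        fitted.decision_threshold = 1e9
        fitted._estimator = None  # force recomputation path
        table = pnet.predict(fitted, M, labels)
        assert not table.predicted_class.any()

    def test_json_round_trip_reproduces_predictions(self, tmp_path, small_cohort):
        M, labels, _ = small_cohort
        fitted = pnet.fit(M, labels, pnet.PNetConfig(m_prime=30))
        direct = pnet.predict(fitted, M, labels)
        path = tmp_path / "model.json"
        fitted.to_json(path)
        loaded = pnet.FittedPNet.from_json(path)
        recomputed = pnet.predict(loaded, M, labels)
        assert np.allclose(direct.score, recomputed.score, atol=1e-12)
        assert np.array_equal(direct.predicted_class, recomputed.predicted_class)

    def test_predict_patient_set_mismatch(self, small_cohort):
        M, labels, _ = small_cohort
        fitted = pnet.fit(M, labels, pnet.PNetConfig(m_prime=30))
        M2 = pnet.ExpressionMatrix(M.feature_ids,
                                   [f"X{i}" for i in range(M.n_patients)],
                                   M.values)
        with pytest.raises(DataError):
            pnet.predict(fitted, M2, pnet.LabelVector(M2.patient_ids,
                                                      labels.status))


def test_config_validation():
    with pytest.raises(DataError):
        pnet.PNetConfig(m_prime=0)
    with pytest.raises(DataError):
        pnet.PNetConfig(m_prime=10, a=1.0)
    with pytest.raises(DataError):
        pnet.PNetConfig(m_prime=10, score_name="nope")
    cfg = pnet.PNetConfig(m_prime=10)
    assert pnet.PNetConfig.from_dict(cfg.to_dict()) == cfg
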