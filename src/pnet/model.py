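"""The end-to-end transductive estimator.

Pipeline (fit): rank features by t-test on training labels, keep the top m',
build the patient similarity graph over *all* patients from the selected
features, apply the p-step random-walk kernel, choose the edge-filter
threshold tau by maximizing a leave-one-out criterion on the training
subgraph, then choose the score cut-point that maximizes LOO training
accuracy. Prediction scores every patient on the filtered kernel with the
training labels as the only evidence; unlabeled and held-out patients shape
the graph but never contribute label information.

The symbol tau names the edge filter only; the score cut-point is the
``decision_threshold`` — the two are never conflated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import features as _features
from . import network as _network
from . import scoring as _scoring
from .dataio import NEG, POS, UNLABELED, DataError, ExpressionMatrix, LabelVector
from .scoring import ScoreTable

logger = logging.getLogger(__name__)

TAU_METRICS = ("auroc", "accuracy")


@dataclass
class PNetConfig:
    """Bundle of all pipeline parameters (the CLI/config-file surface).

    ``m_prime`` has no library-level default: the number of retained features
    is cohort-dependent and must be stated.
    """

    m_prime: int
    similarity_measure: str = "pearson-filtered"
    a: float = 2.0
    p: int = 1
    score_name: str = "Dnorm"
    k: int = 3
    tau_metric: str = "auroc"
    tau_grid_size: int = 50
    negatives: str = "labeled-only"
    seed: int = 0
    equal_var: bool = False

    def __post_init__(self):
        if self.m_prime < 1:
            raise DataError("m_prime must be a positive integer")
        if self.similarity_measure not in _network.SIMILARITY_MEASURES:
            raise DataError(f"unknown similarity measure {self.similarity_measure!r}")
        if self.a < 2:
            raise DataError("a must be >= 2")
        if self.p < 1:
            raise DataError("p must be >= 1")
        if self.score_name not in _scoring.SCORE_NAMES:
            raise DataError(f"unknown score function {self.score_name!r}")
        if self.k < 1:
            raise DataError("k must be >= 1")
        if self.tau_metric not in TAU_METRICS:
            raise DataError(f"unknown tau metric {self.tau_metric!r}")
        if self.tau_grid_size < 1:
            raise DataError("tau_grid_size must be >= 1")
        if self.negatives not in _scoring.NEGATIVES_MODES:
            raise DataError(f"unknown negatives mode {self.negatives!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PNetConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# threshold searches

def _tau_grid(K: np.ndarray, grid_size: int) -> np.ndarray:
    """Candidate filter thresholds: 0 plus empirical quantiles of the
    strictly positive off-diagonal kernel entries."""
    off = K[~np.eye(K.shape[0], dtype=bool)]
    vals = off[off > 0]
    if vals.size == 0:
        return np.array([0.0])
    qs = np.quantile(vals, np.linspace(0.0, 1.0, grid_size))
    return np.unique(np.concatenate(([0.0], qs)))


def _filter_array(K: np.ndarray, tau: float) -> np.ndarray:
    Kf = K.copy()
    diag = Kf.diagonal().copy()
    Kf[Kf < tau] = 0.0
    np.fill_diagonal(Kf, diag)
    return Kf


def _best_accuracy_cut(scores: np.ndarray, y: np.ndarray):
    """Exhaustive cut-point search maximizing accuracy of ``score > t``.

    Candidates are midpoints between consecutive distinct sorted scores plus
    one point below the minimum and one above the maximum; ties resolve to
    the smallest threshold.
    """
    uniq = np.unique(scores)
    cands = np.concatenate((
        [uniq[0] - 1.0],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 1.0],
    ))
    is_pos = y == POS
    best_t, best_acc = cands[0], -1.0
    for t in cands:
        acc = float(np.mean((scores > t) == is_pos))
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    return best_t, best_acc


def rank_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC as the midrank Mann-Whitney statistic.

    Equals the trapezoidal ROC area with average-rank tie handling; used in
    the inner LOO loops where it is much cheaper than the curve construction.
    """
    y_true = np.asarray(y_true).astype(bool)
    r = stats.rankdata(scores)
    n1 = int(y_true.sum())
    n0 = y_true.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("both classes required for AUROC")
    return float((r[y_true].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _tau_criterion(scores: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "auroc":
        return rank_auroc(y == POS, scores)
    return _best_accuracy_cut(scores, y)[1]


def _select_tau_array(K: np.ndarray, y: np.ndarray, config: PNetConfig):
    """Grid-search tau by the LOO criterion on a training kernel.

    ``y`` holds POS/NEG/UNLABELED codes for the kernel's patients; the
    criterion is evaluated on the labeled ones. Ties go to the smallest tau
    (retain more edges); if the LOO scores are constant at every tau the
    search is degenerate and tau = 0 is returned with a warning.
    """
    lab = y != UNLABELED
    y_lab = y[lab]
    if (y_lab == POS).sum() == 0 or (y_lab == NEG).sum() == 0:
        raise DataError("tau selection needs both classes among training labels")
    pos = y == POS
    neg = (y == NEG) if config.negatives == "labeled-only" else ~pos
    grid = _tau_grid(K, config.tau_grid_size)
    best_tau, best_crit = float(grid[0]), -np.inf
    any_signal = False
    for tau in grid:
        Kf = _filter_array(K, float(tau))
        s = _scoring.score_array(Kf, pos, neg, config.score_name, k=config.k, loo=True)
        s_lab = s[lab]
        if np.ptp(s_lab) > 0:
            any_signal = True
        crit = _tau_criterion(s_lab, y_lab, config.tau_metric)
        if crit > best_crit:
            best_tau, best_crit = float(tau), crit
    if not any_signal:
        warnings.warn("LOO scores constant at every candidate tau; returning tau=0")
        Kf = _filter_array(K, 0.0)
        s = _scoring.score_array(Kf, pos, neg, config.score_name, k=config.k, loo=True)
        return 0.0, _tau_criterion(s[lab], y_lab, config.tau_metric)
    return best_tau, best_crit


def select_tau(Kg: _network.KernelGraph, labels: LabelVector, config: PNetConfig):
    """Edge-filter threshold maximizing the LOO criterion on this (training)
    kernel graph. Returns ``(tau, criterion_value)``."""
    if list(Kg.patient_ids) != list(labels.patient_ids):
        raise DataError("kernel and label patient sets differ")
    return _select_tau_array(Kg.K, labels.status, config)


def select_decision_threshold(loo: ScoreTable, labels: LabelVector) -> float:
    """Score cut-point maximizing LOO training accuracy (rule: score >
    threshold => positive); ties resolve to the smallest candidate."""
    if list(loo.patient_ids) != list(labels.patient_ids):
        raise DataError("score table and label patient sets differ")
    lab = labels.status != UNLABELED
    y = labels.status[lab]
    if (y == POS).sum() == 0 or (y == NEG).sum() == 0:
        raise DataError("decision threshold needs both classes")
    t, _ = _best_accuracy_cut(loo.score[lab], y)
    return t


# ---------------------------------------------------------------------------
# the estimator

class PNetClassifier(ClassifierMixin, BaseEstimator):
    """Transductive patient classifier over a kernel-transformed similarity
    network.

    Follows the scikit-learn semi-supervised convention: ``fit(X, y)`` takes
    the whole cohort with ``X`` of shape (n_patients, n_features) and ``y``
    in {1: positive, 0: negative, -1: unlabeled}. Held-out patients are
    simply passed with ``y = -1``; they shape the similarity graph but no
    fitted quantity depends on their labels. Being transductive, the fitted
    model is bound to the cohort it was fitted on: ``predict`` only accepts
    the same ``X``.

    Parameters
    ----------
    m_prime : int
        Number of top-ranked features retained by the t-test filter.
    similarity : str
        Patient similarity measure ("pearson-filtered", "spearman-filtered",
        "inverse-euclidean", "inverse-manhattan").
    a : float
        Diagonal shift of the random-walk kernel; must be >= 2 so the 1-step
        kernel stays positive semidefinite.
    p : int
        Number of random-walk steps (kernel matrix power).
    score : str
        Neighborhood score function ("AV", "NN", "kNN", "TOT", "Diff",
        "Dnorm").
    k : int
        Neighborhood size for the kNN score.
    tau_metric : str
        LOO criterion maximized by the edge-filter search ("auroc" or
        "accuracy").
    tau_grid_size : int
        Number of quantile-spaced candidate thresholds.
    negatives : str
        Negative-evidence set for TOT/Diff/Dnorm: labeled negatives only
        ("labeled-only") or every non-positive patient ("all-non-positive").

    Attributes
    ----------
    selected_features_ : ndarray of int
        Indices of the retained features, in ranking order.
    tau_ : float
        Selected edge-filter threshold.
    tau_criterion_ : float
        LOO criterion value achieved at ``tau_``.
    decision_threshold_ : float
        Score cut-point of the classification rule (score > threshold).
    kernel_ : ndarray
        Filtered p-step kernel over all patients.
    scores_ : ndarray
        Transductive score of every patient.
    transduction_ : ndarray of int
        Predicted class (0/1) of every patient.
    """

    def __init__(
        self,
        m_prime: int | None = None,
        similarity: str = "pearson-filtered",
        a: float = 2.0,
        p: int = 1,
        score: str = "Dnorm",
        k: int = 3,
        tau_metric: str = "auroc",
        tau_grid_size: int = 50,
        negatives: str = "labeled-only",
        equal_var: bool = False,
    ):
        self.m_prime = m_prime
        self.similarity = similarity
        self.a = a
        self.p = p
        self.score = score
        self.k = k
        self.tau_metric = tau_metric
        self.tau_grid_size = tau_grid_size
        self.negatives = negatives
        self.equal_var = equal_var

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise DataError("X must be 2-dimensional (patients x features)")
        if y.shape != (X.shape[0],):
            raise DataError("y length does not match the number of patients")
        if not set(np.unique(y)) <= {POS, NEG, UNLABELED}:
            raise DataError("y entries must be in {1: positive, 0: negative, -1: unlabeled}")
        if self.m_prime is None:
            raise DataError(
                "m_prime is required: set the number of features to retain "
                "(there is no library-level default)"
            )
        config = PNetConfig(
            m_prime=self.m_prime, similarity_measure=self.similarity,
            a=self.a, p=self.p, score_name=self.score, k=self.k,
            tau_metric=self.tau_metric, tau_grid_size=self.tau_grid_size,
            negatives=self.negatives, equal_var=self.equal_var,
        )
        if config.m_prime > X.shape[1]:
            raise DataError(
                f"m_prime={config.m_prime} exceeds the {X.shape[1]} available features"
            )

        # feature ranking on training labels only
        t, pv = _features.ttest_statistics(X.T[:, y != UNLABELED], y[y != UNLABELED],
                                           equal_var=self.equal_var)
        ids = np.array([f"{i:09d}" for i in range(X.shape[1])], dtype=object)
        order = _features._ranking_order(ids, t, pv)
        sel = order[: config.m_prime]

        # transductive graph over all patients
        W = _network.similarity_from_profiles(X[:, sel].T, self.similarity)
        K1p = _network.one_step_kernel(W, self.a)
        K = np.linalg.matrix_power(K1p, int(self.p))
        K = (K + K.T) / 2.0

        tr = y != UNLABELED
        tr_idx = np.flatnonzero(tr)
        tau, crit = _select_tau_array(K[np.ix_(tr_idx, tr_idx)], y[tr_idx], config)
        Kf = _filter_array(K, tau)

        pos_tr = y[tr_idx] == POS
        neg_tr = (y[tr_idx] == NEG) if self.negatives == "labeled-only" else ~pos_tr
        s_tr = _scoring.score_array(Kf[np.ix_(tr_idx, tr_idx)], pos_tr, neg_tr,
                                    self.score, k=self.k, loo=True)
        thr, _ = _best_accuracy_cut(s_tr, y[tr_idx])

        pos = y == POS
        neg = (y == NEG) if self.negatives == "labeled-only" else ~pos
        scores = _scoring.score_array(Kf, pos, neg, self.score, k=self.k, loo=False)

        self.classes_ = np.array([NEG, POS])
        self.n_features_in_ = X.shape[1]
        self.selected_features_ = sel
        self.feature_statistic_ = t
        self.feature_p_value_ = pv
        self.tau_ = float(tau)
        self.tau_criterion_ = float(crit)
        self.decision_threshold_ = float(thr)
        self.kernel_ = Kf
        self.unfiltered_kernel_ = K
        self.scores_ = scores
        self.transduction_ = (scores > thr).astype(int)
        self.label_input_ = y.copy()
        self._X_fit = X.copy()
        return self

    def _check_same_cohort(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.shape != self._X_fit.shape or not np.array_equal(X, self._X_fit):
            raise DataError(
                "transductive model: predict only accepts the cohort it was fitted on"
            )

    def decision_function(self, X):
        self._check_same_cohort(X)
        return self.scores_ - self.decision_threshold_

    def predict(self, X):
        self._check_same_cohort(X)
        return self.transduction_.copy()

    def score_samples(self, X):
        """Raw transductive patient scores (before thresholding)."""
        self._check_same_cohort(X)
        return self.scores_.copy()


# ---------------------------------------------------------------------------
# functional layer over domain types

@dataclass
class FittedPNet:
    """Serializable record of a fitted model (cohort-bound)."""

    config: PNetConfig
    selected_features: list[str]
    tau: float
    decision_threshold: float
    training_patient_ids: list[str]
    tau_criterion: float = 0.0
    _estimator: PNetClassifier | None = field(default=None, repr=False, compare=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "config": self.config.to_dict(),
                "selected_features": self.selected_features,
                "tau": self.tau,
                "decision_threshold": self.decision_threshold,
                "training_patient_ids": self.training_patient_ids,
                "tau_criterion": self.tau_criterion,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedPNet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(PNetConfig.from_dict(d["config"]), d["selected_features"],
                   d["tau"], d["decision_threshold"], d["training_patient_ids"],
                   d.get("tau_criterion", 0.0))


def _masked_y(labels: LabelVector, training_ids) -> np.ndarray:
    """Status vector with every non-training patient forced to UNLABELED."""
    training = set(training_ids)
    unknown = training - set(labels.patient_ids)
    if unknown:
        raise DataError(f"training IDs absent from the cohort: {sorted(unknown)}")
    y = np.full(len(labels.patient_ids), UNLABELED, dtype=int)
    for i, pid in enumerate(labels.patient_ids):
        if pid in training:
            y[i] = labels.status[i]
    return y


def fit(M: ExpressionMatrix, labels: LabelVector, config: PNetConfig,
        training_ids=None) -> FittedPNet:
    """Fit the transductive pipeline; only ``training_ids``' labels are used
    (default: all labeled patients)."""
    labels = labels if list(labels.patient_ids) == list(M.patient_ids) \
        else labels.aligned_to(M.patient_ids)
    if training_ids is None:
        training_ids = [p for p, s in zip(labels.patient_ids, labels.status)
                        if s != UNLABELED]
    y = _masked_y(labels, training_ids)
    est = PNetClassifier(
        m_prime=config.m_prime, similarity=config.similarity_measure,
        a=config.a, p=config.p, score=config.score_name, k=config.k,
        tau_metric=config.tau_metric, tau_grid_size=config.tau_grid_size,
        negatives=config.negatives, equal_var=config.equal_var,
    ).fit(M.values.T, y)
    return FittedPNet(
        config=config,
        selected_features=[M.feature_ids[i] for i in est.selected_features_],
        tau=est.tau_,
        decision_threshold=est.decision_threshold_,
        training_patient_ids=[p for p in M.patient_ids if p in set(training_ids)],
        tau_criterion=est.tau_criterion_,
        _estimator=est,
    )


def predict(model: FittedPNet, M: ExpressionMatrix, labels: LabelVector) -> ScoreTable:
    """Score and classify every patient of the fitted cohort.

    Training labels are the only evidence; the stored tau and decision
    threshold are applied. Recomputes the graph deterministically when the
    fitted estimator is not attached (e.g. after JSON round-trip).
    """
    labels = labels if list(labels.patient_ids) == list(M.patient_ids) \
        else labels.aligned_to(M.patient_ids)
    missing = set(model.training_patient_ids) - set(M.patient_ids)
    if missing:
        raise DataError(f"patient set mismatch: missing {sorted(missing)}")
    est = model._estimator
    if est is not None and est._X_fit.shape == (M.n_patients, est.n_features_in_) \
            and np.array_equal(est._X_fit, M.values.T):
        scores = est.scores_
    else:
        idx = {f: i for i, f in enumerate(M.feature_ids)}
        try:
            rows = [idx[f] for f in model.selected_features]
        except KeyError as e:
            raise DataError(f"selected feature {e} absent from the matrix") from None
        W = _network.similarity_from_profiles(M.values[rows], model.config.similarity_measure)
        K1 = _network.one_step_kernel(W, model.config.a)
        K = np.linalg.matrix_power(K1, int(model.config.p))
        K = (K + K.T) / 2.0
        Kf = _filter_array(K, model.tau)
        y = _masked_y(labels, model.training_patient_ids)
        pos = y == POS
        neg = (y == NEG) if model.config.negatives == "labeled-only" else ~pos
        scores = _scoring.score_array(Kf, pos, neg, model.config.score_name,
                                      k=model.config.k, loo=False)
    predicted = scores > model.decision_threshold
    table = ScoreTable(list(M.patient_ids), np.asarray(scores, dtype=float),
                       _scoring._ranks(M.patient_ids, scores),
                       model.config.score_name,
                       model.config.k if model.config.score_name == "kNN" else None,
                       predicted.astype(bool))
    return table
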