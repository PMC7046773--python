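"""Univariate feature selection: rank features by class association (t-test)
and restrict the expression matrix to the top m' of them.

Only labeled patients ever enter the test, so selection on a training split
never reads held-out labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataio import NEG, POS, DataError, ExpressionMatrix, LabelVector

logger = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    """Features ordered by ascending p-value (ties: larger |t|, then ID)."""

    feature_ids: list[str]
    statistic: np.ndarray
    p_value: np.ndarray

    def to_text(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"feature_id{delimiter}statistic{delimiter}p_value\n")
            for f, t, p in zip(self.feature_ids, self.statistic, self.p_value):
                fh.write(f"{f}{delimiter}{t:.17g}{delimiter}{p:.17g}\n")


def ttest_statistics(X: np.ndarray, y: np.ndarray, equal_var: bool = False):
    """Per-row two-sample t statistic and p-value (rows = features).

    ``y`` holds 1 for positive and 0 for negative columns. Degenerate rows
    (zero variance in both classes) get t = 0, p = 1 when the class means
    agree, and |t| = inf, p = 0 when they differ (perfect separation).
    """
    pos = X[:, y == 1]
    neg = X[:, y == 0]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise DataError("t-test needs at least 2 patients per class")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision-loss warning; they are repaired below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(pos, neg, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        diff = pos.mean(axis=1) - neg.mean(axis=1)
        same = bad & (diff == 0)
        sep = bad & (diff != 0)
        t[same], p[same] = 0.0, 1.0
        t[sep], p[sep] = np.sign(diff[sep]) * np.inf, 0.0
        if same.any():
            logger.info("%d zero-variance features pushed to the bottom", int(same.sum()))
    return t, p


def _ranking_order(feature_ids, t, p):
    # ascending p, then descending |t|, then lexicographic feature ID
    ids = np.asarray(feature_ids, dtype=object)
    return np.lexsort((ids, -np.abs(t), p))


def rank_features_ttest(
    M: ExpressionMatrix, labels: LabelVector, equal_var: bool = False
) -> FeatureRanking:
    """Rank all features by two-sample t-test on labeled patients only.

    Welch's unequal-variance test by default; ``equal_var=True`` selects the
    pooled-variance variant.
    """
    if list(M.patient_ids) != list(labels.patient_ids):
        labels = labels.aligned_to(M.patient_ids)
    y = labels.status
    if (y == POS).sum() < 2 or (y == NEG).sum() < 2:
        raise DataError("feature ranking needs >=2 positive and >=2 negative patients")
    lab = y != -1
    t, p = ttest_statistics(M.values[:, lab], y[lab], equal_var=equal_var)
    order = _ranking_order(M.feature_ids, t, p)
    return FeatureRanking(
        [M.feature_ids[i] for i in order], t[order], p[order]
    )


def select_top(M: ExpressionMatrix, ranking: FeatureRanking, m_prime: int) -> ExpressionMatrix:
    """Restrict the matrix to the first ``m_prime`` ranked features, rows in
    ranking order."""
    if m_prime < 1:
        raise DataError("m_prime must be positive")
    if m_prime > M.n_features:
        raise DataError(f"m_prime={m_prime} exceeds the {M.n_features} available features")
    idx = {f: i for i, f in enumerate(M.feature_ids)}
    chosen = ranking.feature_ids[:m_prime]
    rows = [idx[f] for f in chosen]
    return ExpressionMatrix(list(chosen), list(M.patient_ids), M.values[rows])


class TTestFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer keeping the ``m_prime`` most class-associated
    features by two-sample t-test.

    Works on the sklearn orientation (samples = patients on rows). Entries of
    ``y`` equal to -1 are treated as unlabeled and ignored by the test.
    """

    def __init__(self, m_prime: int = 100, equal_var: bool = False):
        self.m_prime = m_prime
        self.equal_var = equal_var

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        if self.m_prime > X.shape[1]:
            raise DataError(
                f"m_prime={self.m_prime} exceeds the {X.shape[1]} available features"
            )
        lab = y != -1
        t, p = ttest_statistics(X[lab].T, y[lab], equal_var=self.equal_var)
        self.statistic_ = t
        self.p_value_ = p
        ids = np.array([f"{i:09d}" for i in range(X.shape[1])], dtype=object)
        order = _ranking_order(ids, t, p)
        self.ranking_ = order
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[: self.m_prime]] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_
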