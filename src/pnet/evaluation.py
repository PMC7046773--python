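"""Evaluation harnesses: metrics, repeated stratified k-fold CV, Monte-Carlo
CV at fixed training sizes, and the label-permutation significance test.

All protocols are transductive: held-out and unlabeled patients stay in the
graph, but every fitted quantity of a split is a function of that split's
training labels only, and metrics are computed on held-out labeled patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import model as _model
from . import scoring as _scoring
from .dataio import NEG, POS, UNLABELED, DataError, ExpressionMatrix, LabelVector
from .model import PNetConfig
from .network import KernelGraph
from .scoring import ScoreTable

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auroc", "auprc", "accuracy", "f1")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic stream of sub-seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def compute_metrics(scores: ScoreTable, labels: LabelVector) -> dict:
    """AUROC / AUPRC from the scores, accuracy / F1 from the predicted class,
    over labeled patients only."""
    if list(scores.patient_ids) != list(labels.patient_ids):
        raise DataError("score table and label patient sets differ")
    lab = labels.status != UNLABELED
    y = (labels.status[lab] == POS).astype(int)
    if y.min() == y.max():
        raise DataError("both classes required to compute ranking metrics")
    s = scores.score[lab]
    out = {
        "auroc": float(roc_auc_score(y, s)),
        "auprc": float(average_precision_score(y, s)),
    }
    if scores.predicted_class is not None:
        pred = scores.predicted_class[lab].astype(int)
        out["accuracy"] = float(accuracy_score(y, pred))
        out["f1"] = float(f1_score(y, pred, zero_division=0))
    else:
        out["accuracy"] = float("nan")
        out["f1"] = float("nan")
    return out


@dataclass
class CVResult:
    """Per-split metrics plus aggregates for one cross-validation protocol."""

    protocol: str
    per_split: dict
    n_splits: int
    seed: int
    training_size: int | None = None

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_split[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.per_split[metric], ddof=1))

    def sem(self, metric: str) -> float | None:
        if self.n_splits < 2:
            return None
        return self.sd(metric) / np.sqrt(self.n_splits)

    def summary(self) -> dict:
        out = {"protocol": self.protocol, "n_splits": self.n_splits, "seed": self.seed}
        if self.training_size is not None:
            out["training_size"] = self.training_size
        for m in METRIC_NAMES:
            out[f"{m}_mean"] = self.mean(m)
            out[f"{m}_sd"] = self.sd(m) if self.n_splits > 1 else None
            out[f"{m}_sem"] = self.sem(m)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"summary": self.summary(),
                       "per_split": {k: list(map(float, v))
                                     for k, v in self.per_split.items()}}, fh, indent=1)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("split," + ",".join(METRIC_NAMES) + "\n")
            for i in range(self.n_splits):
                fh.write(str(i) + "," +
                         ",".join(f"{self.per_split[m][i]:.17g}" for m in METRIC_NAMES)
                         + "\n")


def _split_metrics(M, labels, config, training_ids, test_ids) -> dict:
    fitted = _model.fit(M, labels, config, training_ids)
    table = _model.predict(fitted, M, labels)
    idx = {p: i for i, p in enumerate(table.patient_ids)}
    test_idx = [idx[p] for p in test_ids]
    sub = ScoreTable([table.patient_ids[i] for i in test_idx],
                     table.score[test_idx],
                     _scoring._ranks([table.patient_ids[i] for i in test_idx],
                                     table.score[test_idx]),
                     table.score_name, table.k,
                     table.predicted_class[test_idx])
    sub_labels = LabelVector([labels.patient_ids[i] for i in test_idx],
                             labels.status[test_idx])
    return compute_metrics(sub, sub_labels)


def repeated_kfold(M: ExpressionMatrix, labels: LabelVector, config: PNetConfig,
                   n_folds: int = 10, n_repeats: int = 15,
                   seed: int = 0) -> CVResult:
    """Repeated stratified k-fold over labeled patients.

    Per split, the held-out fold's labels are withheld during fitting (the
    patients stay in the graph) and metrics are computed on them afterwards.
    """
    labels = labels if list(labels.patient_ids) == list(M.patient_ids) \
        else labels.aligned_to(M.patient_ids)
    lab_idx = np.flatnonzero(labels.status != UNLABELED)
    y_lab = (labels.status[lab_idx] == POS).astype(int)
    if min((y_lab == 1).sum(), (y_lab == 0).sum()) < n_folds:
        raise DataError("each class needs at least n_folds labeled patients "
                        "for stratified folds with both classes held out")
    seeds = _child_seeds(seed, n_repeats)
    per = {m: [] for m in METRIC_NAMES}
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(seeds[rep]))
        for tr, te in skf.split(lab_idx, y_lab):
            training_ids = [labels.patient_ids[i] for i in lab_idx[tr]]
            test_ids = [labels.patient_ids[i] for i in lab_idx[te]]
            res = _split_metrics(M, labels, config, training_ids, test_ids)
            for m in METRIC_NAMES:
                per[m].append(res[m])
    return CVResult("repeated-kfold", per, n_folds * n_repeats, seed)


def mccv(M: ExpressionMatrix, labels: LabelVector, config: PNetConfig,
         training_sizes, n_splits: int = 1000, seed: int = 0) -> dict:
    """Monte-Carlo CV: many random stratified splits at each fixed training
    size; returns ``{training_size: CVResult}`` (mean accuracy and its
    standard error via the summaries)."""
    labels = labels if list(labels.patient_ids) == list(M.patient_ids) \
        else labels.aligned_to(M.patient_ids)
    lab_idx = np.flatnonzero(labels.status != UNLABELED)
    y_lab = (labels.status[lab_idx] == POS).astype(int)
    n_labeled = lab_idx.size
    results = {}
    for size in training_sizes:
        if not 2 <= size < n_labeled:
            raise DataError(f"training size {size} not in [2, {n_labeled})")
        seeds = _child_seeds(seed + size, n_splits)
        per = {m: [] for m in METRIC_NAMES}
        for s in range(n_splits):
            tr, te = train_test_split(np.arange(n_labeled), train_size=size,
                                      stratify=y_lab, random_state=int(seeds[s]))
            if y_lab[tr].min() == y_lab[tr].max() or y_lab[te].min() == y_lab[te].max():
                raise DataError(f"training size {size} cannot hold both classes")
            training_ids = [labels.patient_ids[i] for i in lab_idx[tr]]
            test_ids = [labels.patient_ids[i] for i in lab_idx[te]]
            res = _split_metrics(M, labels, config, training_ids, test_ids)
            for m in METRIC_NAMES:
                per[m].append(res[m])
        results[int(size)] = CVResult("mccv", per, n_splits, seed,
                                      training_size=int(size))
    return results


@dataclass
class PermutationResult:
    """Label-shuffling significance of the patient ranking."""

    observed_auc: float
    n_permutations: int
    n_greater: int
    p_value: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _loo_auc(K_lab: np.ndarray, y_lab: np.ndarray, config: PNetConfig):
    """Select tau on this labeled kernel, then LOO AUROC at the selected tau."""
    tau, _ = _model._select_tau_array(K_lab, y_lab, config)
    Kf = _model._filter_array(K_lab, tau)
    pos = y_lab == POS
    neg = (y_lab == NEG) if config.negatives == "labeled-only" else ~pos
    s = _scoring.score_array(Kf, pos, neg, config.score_name, k=config.k, loo=True)
    return _model.rank_auroc(y_lab == POS, s)


def permutation_test(M: ExpressionMatrix, labels: LabelVector, config: PNetConfig,
                     n_permutations: int = 10000, seed: int = 0,
                     full_refit: bool = False,
                     plus_one_correction: bool = False) -> PermutationResult:
    """Compare the LOO ranking AUC under the true labels with its
    distribution under label shuffling.

    The p-value is the frequency with which a shuffled-label AUC exceeds the
    observed one. By default each permutation re-runs tau selection and
    scoring on the kernel built once from the true-label feature selection;
    ``full_refit=True`` also re-runs feature selection and the kernel per
    permutation. ``plus_one_correction`` applies the
    (n_greater + 1) / (n_permutations + 1) small-sample estimate.
    """
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    labels = labels if list(labels.patient_ids) == list(M.patient_ids) \
        else labels.aligned_to(M.patient_ids)
    lab_idx = np.flatnonzero(labels.status != UNLABELED)
    y_lab = labels.status[lab_idx]
    if (y_lab == POS).sum() < 2 or (y_lab == NEG).sum() < 2:
        raise DataError("permutation test needs both classes (>=2 each)")
    rng = np.random.default_rng(seed)

    def kernel_for(y_full: np.ndarray) -> np.ndarray:
        t, pv = _features_stats(M.values[:, lab_idx], y_full[lab_idx], config)
        order = _features_order(M.feature_ids, t, pv)
        sel = order[: min(config.m_prime, M.n_features)]
        from .network import one_step_kernel, similarity_from_profiles
        W = similarity_from_profiles(M.values[sel], config.similarity_measure)
        K1 = one_step_kernel(W, config.a)
        K = np.linalg.matrix_power(K1, int(config.p))
        return ((K + K.T) / 2.0)[np.ix_(lab_idx, lab_idx)]

    K_lab = kernel_for(labels.status)
    observed = _loo_auc(K_lab, y_lab, config)

    n_greater = 0
    for _ in range(n_permutations):
        y_perm = y_lab[rng.permutation(y_lab.size)]
        if full_refit:
            y_full = labels.status.copy()
            y_full[lab_idx] = y_perm
            K_perm = kernel_for(y_full)
        else:
            K_perm = K_lab
        auc = _loo_auc(K_perm, y_perm, config)
        if auc > observed:
            n_greater += 1
    if plus_one_correction:
        p = (n_greater + 1) / (n_permutations + 1)
    else:
        p = n_greater / n_permutations
    return PermutationResult(observed, n_permutations, n_greater, float(p), seed)


def _features_stats(X_lab, y_lab, config):
    from .features import ttest_statistics
    return ttest_statistics(X_lab, y_lab, equal_var=config.equal_var)


def _features_order(feature_ids, t, p):
    from .features import _ranking_order
    return _ranking_order(feature_ids, t, p)
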