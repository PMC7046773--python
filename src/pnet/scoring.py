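"""Neighborhood score functions over the kernel graph, and the efficient
leave-one-out.

Six scores assign each patient a value from the kernel weights toward the
positive set V_C (and, for the differential family, the negative set):

    AV     mean kernel weight toward V_C
    NN     largest kernel weight toward V_C
    kNN    mean of the k largest kernel weights toward V_C
    TOT    positive weight fraction  sum_pos / (sum_pos + sum_neg)
    Diff   sum_pos - sum_neg
    Dnorm  (sum_pos - sum_neg) / (sum_pos + sum_neg)

The leave-one-out of every patient in one pass rests on the observation that
zeroing k_ii removes patient i's own label evidence from its score: a single
sweep over the diagonal-zeroed kernel reproduces the n separate hold-out runs
exactly. For the two count-normalized scores (AV, kNN) the per-row positive
count / candidate set is likewise reduced for rows inside V_C, so the single
pass is arithmetically identical to the naive hold-out, not just close.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import NEG, POS, DataError, LabelVector
from .network import KernelGraph

logger = logging.getLogger(__name__)

SCORE_NAMES = ("AV", "NN", "kNN", "TOT", "Diff", "Dnorm")
NEGATIVES_MODES = ("labeled-only", "all-non-positive")


@dataclass
class ScoreTable:
    """Per-patient score and rank (1 = highest score; ties broken by ID)."""

    patient_ids: list[str]
    score: np.ndarray
    rank: np.ndarray
    score_name: str
    k: int | None = None
    predicted_class: np.ndarray | None = None

    def to_text(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            cols = ["patient_id", "score", "rank"]
            if self.predicted_class is not None:
                cols.append("predicted_class")
            fh.write(delimiter.join(cols) + "\n")
            for i, p in enumerate(self.patient_ids):
                row = [p, f"{self.score[i]:.17g}", str(int(self.rank[i]))]
                if self.predicted_class is not None:
                    row.append("positive" if self.predicted_class[i] else "negative")
                fh.write(delimiter.join(row) + "\n")


def score_array(
    K: np.ndarray,
    pos_mask: np.ndarray,
    neg_mask: np.ndarray,
    score_name: str,
    k: int = 3,
    loo: bool = False,
) -> np.ndarray:
    """Score every row of ``K`` against the positive/negative column masks.

    With ``loo=True`` each patient is scored as if held out: it is excluded
    from its own evidence sets (equivalently, its diagonal entry is zeroed
    and, for the count-normalized scores, the per-row positive count is
    reduced), which reproduces the naive per-patient hold-out exactly.

    Evidence sums run over patients in index order via 1-D reductions, so the
    result is bit-reproducible against a per-definition evaluation.
    """
    if score_name not in SCORE_NAMES:
        raise DataError(f"unknown score function {score_name!r}")
    pos_mask = np.asarray(pos_mask, dtype=bool)
    neg_mask = np.asarray(neg_mask, dtype=bool)
    if not pos_mask.any():
        raise DataError("no positive patients: scores undefined")
    if score_name == "kNN" and k < 1:
        raise DataError("k must be >= 1")
    n = K.shape[0]
    pos_idx = np.flatnonzero(pos_mask)
    neg_idx = np.flatnonzero(neg_mask)
    # ascontiguousarray: column gathers come back F-ordered, and a strided
    # axis-1 reduction would not sum in index order
    Kpos = np.ascontiguousarray(K[:, pos_idx])

    def _drop(row: np.ndarray, j: int) -> np.ndarray:
        return np.concatenate((row[:j], row[j + 1:]))

    if score_name == "kNN":
        out = np.zeros(n)
        for i in range(n):
            cand = pos_idx[pos_idx != i] if loo else pos_idx
            if cand.size == 0:
                continue
            kk = min(k, cand.size)
            # descending sort; ties at the k-th value carry equal weights,
            # so any resolution yields the same mean
            top = np.sort(K[i, cand])[::-1][:kk]
            out[i] = top.sum() / kk
        return out

    if score_name == "NN":
        # max(..., 0) realizes the empty-neighborhood convention: a patient
        # with no positively weighted edge into V_C scores 0
        out = np.maximum(Kpos.max(axis=1), 0.0)
        if loo:
            for j, i in enumerate(pos_idx):
                sub = _drop(Kpos[i], j)
                out[i] = max(0.0, float(sub.max())) if sub.size else 0.0
        return out

    # evidence sums, vectorized over rows; LOO rows that belong to an
    # evidence set get their sum recomputed without the self term (same
    # elements in the same index order as a per-definition evaluation)
    sp = Kpos.sum(axis=1)
    if loo:
        for j, i in enumerate(pos_idx):
            sub = _drop(Kpos[i], j)
            sp[i] = sub.sum() if sub.size else 0.0

    if score_name == "AV":
        counts = np.full(n, float(pos_idx.size))
        if loo:
            counts[pos_idx] -= 1.0
        out = np.zeros(n)
        nz = counts > 0
        out[nz] = sp[nz] / counts[nz]
        return out

    Kneg = np.ascontiguousarray(K[:, neg_idx])
    sn = Kneg.sum(axis=1) if neg_idx.size else np.zeros(n)
    if loo and neg_idx.size:
        for j, i in enumerate(neg_idx):
            sub = _drop(Kneg[i], j)
            sn[i] = sub.sum() if sub.size else 0.0

    if score_name == "Diff":
        return sp - sn
    den = sp + sn
    out = np.zeros(n)
    nz = den != 0  # 0/0 -> 0 convention for isolated nodes
    if score_name == "TOT":
        out[nz] = sp[nz] / den[nz]
    else:
        out[nz] = (sp[nz] - sn[nz]) / den[nz]
    return out


def evidence_masks(labels: LabelVector, negatives: str = "labeled-only"):
    """Positive/negative evidence masks; unlabeled patients count as negative
    evidence only under the literal set-complement reading."""
    if negatives not in NEGATIVES_MODES:
        raise DataError(f"unknown negatives mode {negatives!r}")
    pos = labels.status == POS
    if negatives == "labeled-only":
        neg = labels.status == NEG
    else:
        neg = ~pos
    return pos, neg


def _ranks(patient_ids: Sequence[str], score: np.ndarray) -> np.ndarray:
    ids = np.asarray(patient_ids, dtype=object)
    order = np.lexsort((ids, -score))
    rank = np.empty(len(ids), dtype=int)
    rank[order] = np.arange(1, len(ids) + 1)
    return rank


def score_patients(
    Kg: KernelGraph,
    labels: LabelVector,
    score_name: str = "Dnorm",
    k: int = 3,
    negatives: str = "labeled-only",
) -> ScoreTable:
    """Score and rank every patient from its labeled kernel neighborhood."""
    if list(Kg.patient_ids) != list(labels.patient_ids):
        raise DataError("kernel and label patient sets differ")
    pos, neg = evidence_masks(labels, negatives)
    s = score_array(Kg.K, pos, neg, score_name, k=k, loo=False)
    return ScoreTable(list(Kg.patient_ids), s, _ranks(Kg.patient_ids, s),
                      score_name, k if score_name == "kNN" else None)


def loo_scores(
    Kg: KernelGraph,
    labels: LabelVector,
    score_name: str = "Dnorm",
    k: int = 3,
    negatives: str = "labeled-only",
) -> ScoreTable:
    """Leave-one-out scores of all patients in a single pass.

    Equals, patient by patient, the score obtained by withdrawing that
    patient's label and rescoring it on the remaining labeled graph.
    """
    if list(Kg.patient_ids) != list(labels.patient_ids):
        raise DataError("kernel and label patient sets differ")
    pos, neg = evidence_masks(labels, negatives)
    s = score_array(Kg.K, pos, neg, score_name, k=k, loo=True)
    return ScoreTable(list(Kg.patient_ids), s, _ranks(Kg.patient_ids, s),
                      score_name, k if score_name == "kNN" else None)


def rank_from_scores(scores: ScoreTable) -> ScoreTable:
    """Reassign ranks from the scores (1 = highest; ties by patient ID)."""
    return ScoreTable(
        list(scores.patient_ids),
        scores.score.copy(),
        _ranks(scores.patient_ids, scores.score),
        scores.score_name,
        scores.k,
        None if scores.predicted_class is None else scores.predicted_class.copy(),
    )
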