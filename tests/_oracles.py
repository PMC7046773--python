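"""Independent reference implementations used as test oracles.

Everything here evaluates the defining formulas directly (per patient, plain
sums in patient-index order, exhaustive pair counting) and never calls the
package's vectorized paths.
"""

import numpy as np


def definition_score(K, i, pos, neg, name, k):
    """Score of patient ``i`` straight from the defining formula.

    ``pos``/``neg`` are the evidence index sets; sums run in index order.
    """
    pos = sorted(pos)
    neg = sorted(neg)
    kij = K[i]
    sp = float(kij[pos].sum()) if pos else 0.0
    sn = float(kij[neg].sum()) if neg else 0.0
    if name == "AV":
        return sp / len(pos) if pos else 0.0
    if name == "NN":
        return max(0.0, float(kij[pos].max())) if pos else 0.0
    if name == "kNN":
        if not pos:
            return 0.0
        top = np.sort(kij[pos])[::-1][: min(k, len(pos))]
        return float(top.sum() / len(top))
    if name == "TOT":
        return sp / (sp + sn) if sp + sn != 0 else 0.0
    if name == "Diff":
        return sp - sn
    if name == "Dnorm":
        return (sp - sn) / (sp + sn) if sp + sn != 0 else 0.0
    raise ValueError(name)


def naive_loo_scores(K, status, name, k, negatives="labeled-only"):
    """Hold each patient out in turn and rescore it from scratch.

    Removing patient i's label withdraws it from both evidence sets of its
    own score (a held-out patient is never evidence for itself).
    """
    n = K.shape[0]
    pos_all = set(np.flatnonzero(status == 1))
    if negatives == "labeled-only":
        neg_all = set(np.flatnonzero(status == 0))
    else:
        neg_all = set(np.flatnonzero(status != 1))
    return np.array([
        definition_score(K, i, pos_all - {i}, neg_all - {i}, name, k)
        for i in range(n)
    ])


def plain_scores(K, status, name, k, negatives="labeled-only"):
    """Per-definition scores of all patients (no hold-out)."""
    n = K.shape[0]
    pos_all = set(np.flatnonzero(status == 1))
    if negatives == "labeled-only":
        neg_all = set(np.flatnonzero(status == 0))
    else:
        neg_all = set(np.flatnonzero(status != 1))
    return np.array([
        definition_score(K, i, pos_all, neg_all, name, k) for i in range(n)
    ])


def pairwise_auroc(y, scores):
    """Exhaustive concordant-pair AUROC with half credit for ties."""
    y = np.asarray(y).astype(bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_instance(rng, n_max=30, ensure_pos=True, ensure_neg=False):
    """A random symmetric nonnegative kernel plus a random label vector."""
    n = int(rng.integers(4, n_max + 1))
    K = rng.random((n, n))
    K = (K + K.T) / 2.0
    status = rng.choice([1, 0, -1], size=n, p=[0.4, 0.4, 0.2])
    if ensure_pos and (status == 1).sum() == 0:
        status[0] = 1
    if ensure_neg and (status == 0).sum() == 0:
        status[-1] = 0
    return K, status
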