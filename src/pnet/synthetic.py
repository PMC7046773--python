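"""Synthetic patient cohorts with planted two-class structure.

Emulates the shape of prognosis microarray cohorts: far more features than
patients, a small set of class-associated features shifted between the two
outcome groups, and a fraction of unlabeled patients that join the graph
without label evidence. Values mimic log-scale intensities (Gaussian noise by
default; a heavy-tailed variant behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import NEG, POS, UNLABELED, DataError, ExpressionMatrix, LabelVector


@dataclass
class SyntheticSpec:
    """Cohort recipe; a cohort is a pure function of ``(spec, seed)``.

    Defaults plant a clearly separable signal: 120 patients, 1000 features of
    which 20 are shifted by 2 standard deviations in the positive class, 20%
    of patients unlabeled, balanced classes.
    """

    n_patients: int = 120
    m_features: int = 1000
    n_differential: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    unlabeled_fraction: float = 0.2
    positive_fraction: float = 0.5
    block_correlation: float = 0.0
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise DataError("need at least 4 patients")
        if self.n_differential > self.m_features:
            raise DataError("n_differential exceeds m_features")
        if not 0 <= self.unlabeled_fraction < 1:
            raise DataError("unlabeled_fraction must be in [0, 1)")
        if not 0 < self.positive_fraction < 1:
            raise DataError("positive_fraction must be in (0, 1)")
        if not 0 <= self.block_correlation < 1:
            raise DataError("block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def generate_cohort(spec: SyntheticSpec):
    """Draw one cohort.

    Returns ``(ExpressionMatrix, LabelVector, truth)`` where ``truth`` flags
    the planted differential features. Non-differential features are
    class-independent noise; differential features get a mean shift of
    ``effect_size * noise_sd`` in the positive class, optionally with
    equicorrelated residuals at ``block_correlation`` (shared per-patient
    factor). Unlabeled masking is class-balanced so the labeled subsample
    keeps the positive fraction.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_patients, spec.m_features
    n_pos = int(round(spec.positive_fraction * n))
    n_pos = min(max(n_pos, 2), n - 2)
    true_status = np.full(n, NEG, dtype=int)
    true_status[rng.permutation(n)[:n_pos]] = POS

    if spec.heavy_tails:
        # Student-t(3) rescaled to unit variance, then to noise_sd
        raw = rng.standard_t(3, size=(m, n)) / np.sqrt(3.0)
    else:
        raw = rng.standard_normal((m, n))
    values = raw * spec.noise_sd

    truth = np.zeros(m, dtype=bool)
    diff_idx = np.sort(rng.choice(m, size=spec.n_differential, replace=False))
    truth[diff_idx] = True
    rho = spec.block_correlation
    if rho > 0 and spec.n_differential > 0:
        shared = rng.standard_normal(n) * spec.noise_sd
        values[diff_idx] = (np.sqrt(rho) * shared[None, :]
                            + np.sqrt(1 - rho) * values[diff_idx])
    values[np.ix_(diff_idx, true_status == POS)] += spec.effect_size * spec.noise_sd

    status = true_status.copy()
    if spec.unlabeled_fraction > 0:
        for cls in (POS, NEG):
            idx = np.flatnonzero(true_status == cls)
            n_mask = int(round(spec.unlabeled_fraction * idx.size))
            n_mask = min(n_mask, idx.size - 2)  # keep >=2 labeled per class
            if n_mask > 0:
                status[rng.choice(idx, size=n_mask, replace=False)] = UNLABELED

    width = len(str(n))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]
    fwidth = len(str(m))
    fids = [f"G{i + 1:0{fwidth}d}" for i in range(m)]
    return (ExpressionMatrix(fids, pids, values),
            LabelVector(pids, status),
            truth)
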