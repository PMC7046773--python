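"""Patient similarity graph construction, the p-step random-walk kernel, and
edge filtering.

The similarity matrix W (one node per patient, edge weights >= 0, empty
diagonal) is transformed into the kernel

    K1 = (a - 1) I + D^{-1/2} W D^{-1/2},      d_ii = sum_j w_ij,

and the p-step kernel is the p-th matrix power of K1. With a >= 2 the 1-step
kernel equals a*I minus the normalized Laplacian plus (a-2)I shifts, hence is
positive semidefinite; raising it to any integer power preserves that. Weak
edges of the resulting dense kernel are removed by thresholding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .dataio import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

SIMILARITY_MEASURES = (
    "pearson-filtered",
    "spearman-filtered",
    "inverse-euclidean",
    "inverse-manhattan",
)


@dataclass
class SimilarityGraph:
    """Symmetric nonnegative n x n patient similarity matrix with zero diagonal."""

    patient_ids: list[str]
    W: np.ndarray
    measure: str

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.patient_ids)
        if self.W.shape != (n, n):
            raise DataError("similarity matrix shape does not match patient IDs")


@dataclass
class KernelGraph:
    """Symmetric n x n kernel matrix with its parameters.

    ``tau`` records the edge-filter threshold if one has been applied.
    """

    patient_ids: list[str]
    K: np.ndarray
    a: float
    p: int
    tau: float | None = None

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.patient_ids)
        if self.K.shape != (n, n):
            raise DataError("kernel matrix shape does not match patient IDs")

    def subgraph(self, indices) -> "KernelGraph":
        indices = np.asarray(indices)
        return KernelGraph(
            [self.patient_ids[i] for i in indices],
            self.K[np.ix_(indices, indices)],
            self.a, self.p, self.tau,
        )


def similarity_from_profiles(values: np.ndarray, measure: str = "pearson-filtered",
                             patient_ids=None) -> np.ndarray:
    """n x n similarity from an m-features x n-patients array (columns compared)."""
    if measure not in SIMILARITY_MEASURES:
        raise DataError(f"unknown similarity measure {measure!r}")
    n = values.shape[1]
    ids = patient_ids if patient_ids is not None else [str(i) for i in range(n)]
    if measure in ("pearson-filtered", "spearman-filtered"):
        sd = values.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise DataError(
                "zero-variance patient profiles under a correlation measure: "
                + ", ".join(str(ids[i]) for i in flat)
            )
        if measure == "pearson-filtered":
            W = np.corrcoef(values, rowvar=False)
        else:
            W = stats.spearmanr(values).statistic
            if np.ndim(W) == 0:  # scipy collapses n=2 to a scalar
                W = np.array([[1.0, float(W)], [float(W), 1.0]])
        W = np.maximum(W, 0.0)
    else:
        metric = "euclidean" if measure == "inverse-euclidean" else "cityblock"
        W = 1.0 / (1.0 + squareform(pdist(values.T, metric=metric)))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def build_similarity(M: ExpressionMatrix, measure: str = "pearson-filtered") -> SimilarityGraph:
    """Build the patient similarity graph from expression profiles.

    Correlation measures clip negative values to zero (filtered correlation);
    distance measures map a distance d to 1/(1+d). The diagonal is forced to
    zero: W is a graph adjacency, not a Gram matrix.
    """
    W = similarity_from_profiles(M.values, measure, M.patient_ids)
    return SimilarityGraph(list(M.patient_ids), W, measure)


def one_step_kernel(W: np.ndarray, a: float) -> np.ndarray:
    """(a-1) I + D^{-1/2} W D^{-1/2}; isolated nodes get D^{-1/2} entry 0."""
    d = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    K = dinv[:, None] * W * dinv[None, :]
    K[np.diag_indices_from(K)] += a - 1.0
    return K


def random_walk_kernel(Wg: SimilarityGraph, a: float = 2.0, p: int = 1) -> KernelGraph:
    """The p-step random-walk kernel of the similarity graph.

    Requires ``a >= 2`` (positive semidefiniteness of the 1-step kernel) and
    an integer ``p >= 1``. An all-zero W is allowed (warning): the kernel
    degenerates to ``(a-1)^p I``.
    """
    if a < 2:
        raise DataError(f"a={a} < 2 breaks positive semidefiniteness")
    if p < 1 or int(p) != p:
        raise DataError("p must be a positive integer")
    if not np.allclose(Wg.W, Wg.W.T):
        raise DataError("similarity matrix is not symmetric")
    if (Wg.W < 0).any():
        raise DataError("similarity matrix has negative entries")
    if not Wg.W.any():
        logger.warning("empty similarity graph: kernel is diagonal")
    K1 = one_step_kernel(Wg.W, a)
    K = np.linalg.matrix_power(K1, int(p))
    K = (K + K.T) / 2.0
    return KernelGraph(list(Wg.patient_ids), K, float(a), int(p))


def filter_kernel(Kg: KernelGraph, tau: float) -> KernelGraph:
    """Zero every off-diagonal entry strictly below ``tau``; diagonal untouched."""
    if tau < 0:
        raise DataError("tau must be >= 0")
    K = Kg.K.copy()
    diag = K.diagonal().copy()
    K[K < tau] = 0.0
    np.fill_diagonal(K, diag)
    return KernelGraph(list(Kg.patient_ids), K, Kg.a, Kg.p, float(tau))


# ---------------------------------------------------------------------------
# text round-trip for square matrices

def write_kernel(Kg: KernelGraph, path: str | Path) -> None:
    """Square delimited matrix with patient-ID header row/column; parameters
    (a, p, tau) in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(Kg.K, index=Kg.patient_ids, columns=Kg.patient_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"a": Kg.a, "p": Kg.p, "tau": Kg.tau}, fh)


def read_kernel(path: str | Path) -> KernelGraph:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    params = {"a": 2.0, "p": 1, "tau": None}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            params.update(json.load(fh))
    return KernelGraph(list(df.index.astype(str)), df.to_numpy(),
                       params["a"], params["p"], params["tau"])
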