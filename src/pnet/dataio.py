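"""Reading and writing expression matrices, label files, configs and patient graphs.

Expression data travel as delimited text with features on rows and patients on
columns (one header row of patient IDs, one leading column of feature IDs);
labels as two-column delimited text. Graphs are exported losslessly as GraphML
or as Cytoscape.js JSON for interactive inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: per-patient status codes
POS = 1
NEG = 0
UNLABELED = -1

_STATUS_NAMES = {POS: "positive", NEG: "negative", UNLABELED: "unlabeled"}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise DataError(f"duplicate {what} IDs: {', '.join(sorted(dups))}")


@dataclass
class ExpressionMatrix:
    """An m-feature x n-patient real matrix with row and column identifiers.

    Columns are patients' biomolecular profiles; rows are features (genes,
    probes). Missing values are never allowed in a constructed instance.
    """

    feature_ids: list[str]
    patient_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        m, n = len(self.feature_ids), len(self.patient_ids)
        if self.values.shape != (m, n):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{m} features x {n} patients"
            )
        if m < 1 or n < 2:
            raise DataError("need at least 1 feature and 2 patients")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.patient_ids, "patient")
        if np.isnan(self.values).any():
            raise DataError("expression matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.patient_ids)


@dataclass
class LabelVector:
    """Per-patient phenotype status in {POS, NEG, UNLABELED}.

    POS patients form the phenotype subgroup of interest (poor prognosis,
    responders, ...); UNLABELED patients enter the graph as transductive
    nodes but never contribute label evidence.
    """

    patient_ids: list[str]
    status: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.patient_ids),):
            raise DataError("status vector length does not match patient IDs")
        bad = set(np.unique(self.status)) - {POS, NEG, UNLABELED}
        if bad:
            raise DataError(f"invalid status codes: {sorted(bad)}")
        _check_unique(self.patient_ids, "patient")

    @property
    def n_pos(self) -> int:
        return int((self.status == POS).sum())

    @property
    def n_neg(self) -> int:
        return int((self.status == NEG).sum())

    @property
    def n_unlabeled(self) -> int:
        return int((self.status == UNLABELED).sum())

    def aligned_to(self, patient_ids: Sequence[str]) -> "LabelVector":
        """Reorder/extend to ``patient_ids``; patients missing here become UNLABELED."""
        idx = {p: i for i, p in enumerate(self.patient_ids)}
        extra = set(self.patient_ids) - set(patient_ids)
        if extra:
            raise DataError(
                f"label file contains patients absent from the expression matrix: "
                f"{', '.join(sorted(extra))}"
            )
        status = np.full(len(patient_ids), UNLABELED, dtype=int)
        n_missing = 0
        for j, p in enumerate(patient_ids):
            if p in idx:
                status[j] = self.status[idx[p]]
            else:
                n_missing += 1
        if n_missing:
            logger.info("%d patients without a label entry treated as unlabeled", n_missing)
        return LabelVector(list(patient_ids), status)


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if delimiter is None:
        # auto-detect between tab and comma from the header line
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    # pandas silently renames duplicate header columns, so check them here
    _check_unique([t.strip() for t in header.rstrip("\n").split(delimiter)[1:]],
                  "column")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    _check_unique(list(df.index), "row")
    return df


def read_expression(
    path: str | Path,
    orientation: str = "features-as-rows",
    delimiter: str | None = None,
    drop_missing_rows: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression matrix, normalizing to features x patients.

    Parameters
    ----------
    orientation
        ``"features-as-rows"`` (default) or ``"patients-as-rows"``.
    delimiter
        Explicit delimiter; tab/comma auto-detected when ``None``.
    drop_missing_rows
        When True, feature rows containing missing values are dropped (with a
        logged count) instead of raising.
    """
    if orientation not in ("features-as-rows", "patients-as-rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path, delimiter)
    if orientation == "patients-as-rows":
        df = df.T
    try:
        values = df.astype(float)
    except ValueError:
        # locate the first offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                if cell is not None and not _is_number(cell):
                    raise DataError(
                        f"non-numeric cell {cell!r} at feature {df.index[i]!r}, "
                        f"patient {df.columns[j]!r}"
                    ) from None
        raise
    vals = values.to_numpy()
    if np.isnan(vals).any():
        if drop_missing_rows:
            keep = ~np.isnan(vals).any(axis=1)
            logger.warning("dropping %d feature rows with missing values", int((~keep).sum()))
            values = values.loc[keep]
            vals = values.to_numpy()
        else:
            i, j = np.argwhere(np.isnan(vals))[0]
            raise DataError(
                f"missing value at feature {values.index[i]!r}, patient {values.columns[j]!r}"
            )
    return ExpressionMatrix(list(values.index), list(values.columns), vals)


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_expression(M: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write features x patients delimited text at 17 significant digits."""
    M.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


def read_labels(
    path: str | Path,
    positive_token: str,
    negative_token: str,
    delimiter: str | None = None,
) -> LabelVector:
    """Load a two-column (patient ID, label token) file.

    Tokens other than the two configured map to UNLABELED.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise DataError(f"no labels in {path}")
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.empty:
        raise DataError(f"no labels in {path}")
    ids = [str(x).strip() for x in df.iloc[:, 0]]
    _check_unique(ids, "patient")
    tokens = [str(x).strip() for x in df.iloc[:, 1]]
    status = np.full(len(ids), UNLABELED, dtype=int)
    for i, t in enumerate(tokens):
        if t == positive_token:
            status[i] = POS
        elif t == negative_token:
            status[i] = NEG
    lv = LabelVector(ids, status)
    logger.info(
        "labels loaded: %d positive, %d negative, %d unlabeled",
        lv.n_pos, lv.n_neg, lv.n_unlabeled,
    )
    if lv.n_pos == 0 and lv.n_neg == 0:
        logger.warning("no token matched %r or %r: all patients unlabeled",
                       positive_token, negative_token)
    return lv


def write_labels(labels: LabelVector, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for p, s in zip(labels.patient_ids, labels.status):
            fh.write(f"{p}{delimiter}{_STATUS_NAMES[int(s)]}\n")


def read_label_names(path: str | Path, delimiter: str | None = None) -> LabelVector:
    """Read labels written by :func:`write_labels` (tokens positive/negative)."""
    return read_labels(path, "positive", "negative", delimiter=delimiter)


# ---------------------------------------------------------------------------
# graph export

def build_patient_graph(K_graph, labels: LabelVector, scores=None) -> nx.Graph:
    """Assemble a networkx graph: one node per patient, one edge per strictly
    positive off-diagonal kernel entry; self-loops omitted.

    Node attributes encode ground truth (``true_status``, ``shape``: squares
    mark positives) and, when scores are given, ``score``, ``predicted_class``
    and a prediction ``color`` readable by a Cytoscape style.
    """
    if list(K_graph.patient_ids) != list(labels.patient_ids):
        raise DataError("kernel and label patient sets differ")
    if scores is not None and list(scores.patient_ids) != list(K_graph.patient_ids):
        raise DataError("score table patient set differs from kernel")
    g = nx.Graph()
    for i, p in enumerate(K_graph.patient_ids):
        st = int(labels.status[i])
        attrs = {
            "true_status": _STATUS_NAMES[st],
            "shape": "square" if st == POS else "ellipse",
        }
        if scores is not None:
            attrs["score"] = float(scores.score[i])
            if scores.predicted_class is not None:
                pred = bool(scores.predicted_class[i])
                attrs["predicted_class"] = "positive" if pred else "negative"
                attrs["color"] = "#d62728" if pred else "#1f77b4"
        g.add_node(p, **attrs)
    K = K_graph.K
    n = K.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if K[i, j] > 0:
                g.add_edge(K_graph.patient_ids[i], K_graph.patient_ids[j],
                           weight=float(K[i, j]))
    return g


def export_graph(K_graph, labels: LabelVector, scores, path: str | Path,
                 format: str = "graphml") -> None:
    """Write the patient graph as GraphML (lossless) or Cytoscape.js JSON."""
    g = build_patient_graph(K_graph, labels, scores)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "cytoscape-json":
        data = nx.cytoscape_data(g)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    else:
        raise DataError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# config files

def read_config(path: str | Path) -> dict:
    """Read a YAML (or flat ``key: value``) config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise DataError(f"config file {path} must contain a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
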