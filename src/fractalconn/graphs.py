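"""Construction of binarized functional connectivity graphs.

The pipeline here mirrors the standard high-threshold approach to
resting-state functional connectivity: per-subject ROI time-series are
pairwise Pearson-correlated, the diagonal of self-correlations is zeroed so
the matrix can serve as a simple-graph adjacency, and only the strongest
5% of correlations (by default) are kept as unweighted edges, with negative
survivors discarded.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd
import scipy.io
import scipy.sparse

from fractalconn.exceptions import (
    AllRoisDeadError,
    DeadRoiError,
    EmptyInputError,
    NonNumericCellError,
    RaggedRowsError,
)


@dataclass
class RoiTimeSeriesSet:
    """One subject's ROI x time table.

    ``samples`` has one row per time point and one column per ROI, in the
    order of ``roi_labels``. ROIs removed upstream (dead signal) are listed
    in ``removed_rois`` and are no longer columns of ``samples``.
    """

    subject_id: str
    condition: str
    samples: np.ndarray
    roi_labels: list[str]
    removed_rois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (time x ROI)")
        if self.samples.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels but "
                f"{self.samples.shape[1]} columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")
        if set(self.removed_rois) & set(self.roi_labels):
            raise ValueError("removed_rois overlaps roi_labels")

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[0]

    @property
    def n_rois(self) -> int:
        return self.samples.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with zeroed diagonal."""

    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match roi_labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(self.values).max(initial=0.0) > 1.0 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")


def load_timeseries(
    path: str | Path,
    *,
    sep: str | None = None,
    subject_id: str | None = None,
    condition: str = "",
) -> RoiTimeSeriesSet:
    """Read a ROI x time table (rows = time points, header row = ROI labels).

    The delimiter is inferred from the extension (``.csv`` -> comma,
    otherwise tab) unless ``sep`` is given. Raises :class:`EmptyInputError`,
    :class:`RaggedRowsError` or :class:`NonNumericCellError` on malformed
    input, naming the offending row/column where possible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise EmptyInputError(f"{path} has a header but no data rows")
    header = [c.strip() for c in rows[0]]
    width = len(header)
    data = np.empty((len(rows) - 1, width), dtype=float)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise RaggedRowsError(
                f"{path}: row {i + 1} has {len(row)} fields, expected {width}"
            )
        for j, cell in enumerate(row):
            try:
                data[i - 1, j] = float(cell)
            except ValueError:
                raise NonNumericCellError(
                    f"{path}: non-numeric cell at row {i + 1}, "
                    f"column {header[j]!r}: {cell!r}"
                ) from None
    return RoiTimeSeriesSet(
        subject_id=subject_id if subject_id is not None else path.stem,
        condition=condition,
        samples=data,
        roi_labels=header,
    )


def drop_dead_rois(ts: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    """Remove zero-variance ROI columns (dead or constant signal).

    Pearson correlation is undefined for constant series, so any column
    with zero variance — not only all-zero columns — is dropped. Survivor
    column order is preserved and the removed labels are recorded.
    """
    var = ts.samples.var(axis=0)
    alive = var > 0.0
    if not alive.any():
        raise AllRoisDeadError(
            f"subject {ts.subject_id}: all {ts.n_rois} ROIs have zero variance"
        )
    if alive.all():
        return ts
    dead = [lab for lab, a in zip(ts.roi_labels, alive) if not a]
    return RoiTimeSeriesSet(
        subject_id=ts.subject_id,
        condition=ts.condition,
        samples=ts.samples[:, alive],
        roi_labels=[lab for lab, a in zip(ts.roi_labels, alive) if a],
        removed_rois=ts.removed_rois + dead,
    )


def correlation_matrix(ts: RoiTimeSeriesSet) -> CorrelationMatrix:
    """Pairwise Pearson correlation of all ROI pairs, diagonal zeroed.

    The unit diagonal would correspond to a self-loop on every node if the
    matrix were used directly as an adjacency matrix, so it is set to zero.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    if np.any(ts.samples.var(axis=0) == 0.0):
        raise DeadRoiError(
            "zero-variance ROI column present; run drop_dead_rois first"
        )
    with np.errstate(invalid="raise"):
        m = np.corrcoef(ts.samples, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 0.0)
    return CorrelationMatrix(values=m, roi_labels=list(ts.roi_labels))


def threshold_binarize(
    M: CorrelationMatrix, percentile: float = 95.0
) -> nx.Graph:
    """Binarize a correlation matrix at a rank percentile, dropping negatives.

    The E = R(R-1)/2 upper-triangle entries are ranked and exactly
    ``floor((1 - percentile/100) * E)`` largest are retained as candidate
    edges (ties broken by stable (i, j) index order); any retained entry
    that is negative is then discarded. The result is a simple undirected
    graph on the ROI labels, with thresholding provenance attached.
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    labels = M.roi_labels
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    vals = M.values[iu, ju]
    n_keep = math.floor((1.0 - percentile / 100.0) * vals.size)
    # lexsort: primary key last — descending value, then ascending (i, j)
    order = np.lexsort((ju, iu, -vals))
    kept = order[:n_keep]
    kept = kept[vals[kept] >= 0.0]
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[i], labels[j]) for i, j in zip(iu[kept], ju[kept]))
    if g.number_of_edges() == 0:
        warnings.warn("no edges survived thresholding", stacklevel=2)
    g.graph["provenance"] = {
        "threshold_percentile": percentile,
        "n_candidate_pairs": int(vals.size),
        "n_rank_retained": int(n_keep),
        "n_negative_discarded": int(n_keep - kept.size),
    }
    return g


# ---------------------------------------------------------------------------
# graph I/O: MatrixMarket pattern files and edge-list TSV, with a label map


def write_graph(g: nx.Graph, path: str | Path) -> None:
    """Write a graph as MatrixMarket pattern-symmetric (.mtx) or edge-list
    TSV, with node labels in a ``<stem>.labels.csv`` sidecar (0-based index,
    label)."""
    path = Path(path)
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    if path.suffix == ".mtx":
        rows, cols = [], []
        for u, v in g.edges:
            i, j = index[u], index[v]
            # store lower triangle for symmetric MatrixMarket
            if i < j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
        mat = scipy.sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(nodes), len(nodes))
        )
        scipy.io.mmwrite(path, mat, field="pattern", symmetry="symmetric")
    else:
        with open(path, "w") as fh:
            for u, v in g.edges:
                fh.write(f"{index[u]}\t{index[v]}\n")
    with open(path.with_suffix(".labels.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "label"])
        for i, v in enumerate(nodes):
            w.writerow([i, v])


def read_graph(path: str | Path) -> nx.Graph:
    """Read a graph written by :func:`write_graph` (labels restored from the
    sidecar when present; bare integer labels otherwise)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path).tocoo()
        n = mat.shape[0]
        edges = [(int(i), int(j)) for i, j in zip(mat.row, mat.col) if i != j]
    else:
        edges = []
        n = 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                i, j = (int(x) for x in line.split("\t"))
                edges.append((i, j))
                n = max(n, i + 1, j + 1)
    labels_path = path.with_suffix(".labels.csv")
    if labels_path.exists():
        df = pd.read_csv(labels_path)
        labels = df.sort_values("index")["label"].astype(str).tolist()
        n = max(n, len(labels))
    else:
        labels = [str(i) for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, j in edges:
        if i != j:
            g.add_edge(labels[i], labels[j])
    return g
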