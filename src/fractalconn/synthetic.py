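"""Synthetic inputs with known structure for validating every stage.

Three generators are provided:

* ``generate_uv_flower`` — deterministic (u,v)-flower graphs, whose
  box-counting dimension is known in closed form (ln(u+v)/ln u for u > 1),
  used as an analytic oracle for the network-dimension estimator.
* ``generate_fbm`` — exact fractional Brownian motion by circulant
  embedding of the fractional Gaussian noise covariance, used as an
  analytic oracle for the Higuchi estimator (D = 2 - H).
* ``generate_cohort`` — multi-subject, multi-group ROI time-series drawn
  from hierarchical-modular correlation matrices with a per-group effect
  scalar, standing in for resting-state cohorts so the full pipeline can be
  exercised end to end. The cohort is an artifact of this package: its
  parameters are validation choices, not estimates of any clinical cohort.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

from fractalconn.graphs import RoiTimeSeriesSet

__all__ = [
    "FractalGraphSpec",
    "CohortSpec",
    "flower_counts",
    "generate_uv_flower",
    "generate_fbm",
    "hierarchical_correlation",
    "generate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# (u,v)-flower graphs


@dataclass(frozen=True)
class FractalGraphSpec:
    """Parameters of a (u,v)-flower: generation 0 is a single edge, and each
    generation replaces every edge by two parallel paths of u and v edges."""

    u: int
    v: int
    generations: int

    def __post_init__(self) -> None:
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if self.v < self.u:
            raise ValueError("v must be >= u")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @property
    def expected_dimension(self) -> float:
        """ln(u+v)/ln(u); undefined (nan) for u = 1."""
        if self.u == 1:
            return float("nan")
        return math.log(self.u + self.v) / math.log(self.u)


def flower_counts(u: int, v: int, generations: int) -> tuple[int, int]:
    """Closed-form (node, edge) counts: E_g = (u+v)^g and
    N_g = N_{g-1} + E_{g-1} (u+v-2) with N_0 = 2."""
    w = u + v
    nodes, edges = 2, 1
    for _ in range(generations):
        nodes = nodes + edges * (w - 2)
        edges = edges * w
    return nodes, edges


def generate_uv_flower(
    spec: FractalGraphSpec, *, max_nodes: int = 100_000
) -> nx.Graph:
    """Build the (u,v)-flower deterministically (stable integer labels).

    Each generation replaces every edge (a, b) by a path of u edges and a
    path of v edges between a and b; new interior nodes take consecutive
    integer labels, so repeated runs yield identical graphs.
    """
    n_final, _ = flower_counts(spec.u, spec.v, spec.generations)
    if n_final > max_nodes:
        raise ValueError(
            f"flower would have {n_final} nodes, exceeding cap {max_nodes}"
        )
    g = nx.Graph()
    g.add_nodes_from([0, 1])
    g.add_edge(0, 1)
    next_label = 2
    for _ in range(spec.generations):
        new = nx.Graph()
        new.add_nodes_from(g.nodes)
        for a, b in sorted(g.edges):
            for length in (spec.u, spec.v):
                prev = a
                for _step in range(length - 1):
                    new.add_edge(prev, next_label)
                    prev = next_label
                    next_label += 1
                if length == 1 and new.has_edge(a, b):
                    # u = 1: the second path would duplicate the edge
                    continue
                new.add_edge(prev, b)
        g = new
    return g


# ---------------------------------------------------------------------------
# fractional Brownian motion


def _fgn_autocov(k: np.ndarray, hurst: float) -> np.ndarray:
    return 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )


def generate_fbm(n: int, hurst: float, seed: int) -> np.ndarray:
    """Exact fractional Brownian motion path of length ``n``.

    Fractional Gaussian noise is synthesized by circulant embedding
    (Davies-Harte): the covariance sequence is embedded in a circulant
    matrix whose eigenvalues are obtained by FFT, giving an exact sample
    when the embedding is positive semi-definite (it is for all H in (0,1)
    at these sizes; if a tiny negative eigenvalue appears it is clipped
    with a warning). The path is the cumulative sum of the increments, so
    Var[x_t] = t^(2H).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    m = 2 * n
    k = np.arange(n + 1)
    row = np.concatenate([_fgn_autocov(k, hurst), _fgn_autocov(k[-2:0:-1], hurst)])
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8:
        warnings.warn(
            "circulant embedding not PSD; clipping negative eigenvalues "
            "(approximate synthesis)",
            stacklevel=2,
        )
    eig = np.clip(eig, 0.0, None)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(eig / (2 * m)) * z)
    fgn = w[:n].real * math.sqrt(2.0)
    return np.cumsum(fgn)


# ---------------------------------------------------------------------------
# hierarchical-modular cohorts


@dataclass
class CohortSpec:
    """Synthetic cohort layout and effect sizes.

    ROIs sit at the leaves of a ``module_branching``-ary tree with
    ``module_levels`` levels. The correlation between two ROIs is
    ``within_module_corr ** (1 + depth * group_effect)``, where depth is the
    number of tree levels to their lowest common module. The group effect
    thus scales how sharply correlation decays with modular depth — how
    *differentiated* the modular hierarchy is. At effect 1 the signals are
    strongly differentiated across modules; as the effect shrinks the
    correlation profile flattens toward undifferentiated global synchrony,
    whose thresholded graphs are hub-dominated and structurally degraded
    (monotonically lower box-counting dimension). AR(1) smoothing emulates
    the temporal autocorrelation of slow haemodynamic signals.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"awake": 15, "mid": 10, "low": 8}
    )
    n_rois: int = 256
    n_timepoints: int = 150
    module_branching: int = 2
    module_levels: int = 8
    within_module_corr: float = 0.5
    group_effect: dict[str, float] = field(
        default_factory=lambda: {"awake": 1.0, "mid": 0.6, "low": 0.3}
    )
    ar1_coeff: float = 0.3
    seed: int = 0
    dead_rois_per_subject: int = 0
    psd_repair_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if set(self.n_per_group) != set(self.group_effect):
            raise ValueError(
                "n_per_group and group_effect must share group labels"
            )
        for g, e in self.group_effect.items():
            if not 0.0 < e <= 1.0:
                raise ValueError(f"group_effect[{g!r}] must be in (0, 1]")
        if not 0.0 < self.within_module_corr < 1.0:
            raise ValueError("within_module_corr must be in (0, 1)")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must be in [0, 1)")


def _module_depth(n_rois: int, branching: int, levels: int) -> np.ndarray:
    """Depth of the lowest common module for each ROI pair: 0 for leaf
    siblings, up to levels-1 for pairs joined only at the root."""
    idx = np.arange(n_rois)
    depth = np.full((n_rois, n_rois), levels - 1, dtype=float)
    for lev in range(levels, 0, -1):
        block = branching**lev
        same = (idx[:, None] // block) == (idx[None, :] // block)
        depth[same] = lev - 1
    return depth


def hierarchical_correlation(
    n_rois: int,
    branching: int,
    levels: int,
    within_module_corr: float,
    group_effect: float,
    *,
    repair_tolerance: float = 0.1,
) -> np.ndarray:
    """Hierarchical-modular correlation matrix, repaired to nearest PSD.

    Entry (i, j) is ``within_module_corr ** (1 + depth_ij * group_effect)``
    with unit diagonal; negative eigenvalues from the construction are
    clipped and the matrix renormalized to unit diagonal. Raises if the
    repair perturbs any entry by more than ``repair_tolerance``.
    """
    depth = _module_depth(n_rois, branching, levels)
    corr = within_module_corr ** (1.0 + depth * group_effect)
    np.fill_diagonal(corr, 1.0)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-10:
        repaired = (eigvec * np.clip(eigval, 1e-10, None)) @ eigvec.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        if np.abs(repaired - corr).max() > repair_tolerance:
            raise ValueError("nearest-PSD repair exceeded tolerance")
        corr = repaired
    return corr


def _sample_subject(
    corr: np.ndarray, n_timepoints: int, ar1: float, rng: np.random.Generator
) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(corr)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((n_timepoints, corr.shape[0]))
    x = z @ root.T
    if ar1 > 0.0:
        # stationary AR(1) filter per column; preserves cross-correlations
        y = np.empty_like(x)
        y[0] = x[0]
        scale = math.sqrt(1.0 - ar1 * ar1)
        for t in range(1, n_timepoints):
            y[t] = ar1 * y[t - 1] + scale * x[t]
        x = y
    return x


def generate_cohort(spec: CohortSpec) -> list[RoiTimeSeriesSet]:
    """Draw one multi-group cohort of ROI time-series.

    Each subject's rows are multivariate-normal samples from their group's
    hierarchical-modular correlation matrix, optionally AR(1)-smoothed in
    time. Per-subject RNG substreams are derived from the cohort seed by
    counter, so output is bit-identical under a fixed seed regardless of
    generation order. ``dead_rois_per_subject`` zeroes that many randomly
    chosen ROI columns per subject to exercise dead-ROI removal.
    """
    subjects: list[RoiTimeSeriesSet] = []
    labels = [f"roi{j:04d}" for j in range(spec.n_rois)]
    corr_by_group = {
        g: hierarchical_correlation(
            spec.n_rois,
            spec.module_branching,
            spec.module_levels,
            spec.within_module_corr,
            e,
            repair_tolerance=spec.psd_repair_tolerance,
        )
        for g, e in spec.group_effect.items()
    }
    for gi, (group, n_sub) in enumerate(sorted(spec.n_per_group.items())):
        for si in range(n_sub):
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(gi, si))
            )
            x = _sample_subject(
                corr_by_group[group], spec.n_timepoints, spec.ar1_coeff, rng
            )
            if spec.dead_rois_per_subject > 0:
                dead = rng.choice(
                    spec.n_rois, size=spec.dead_rois_per_subject, replace=False
                )
                x[:, dead] = 0.0
            subjects.append(
                RoiTimeSeriesSet(
                    subject_id=f"{group}_{si:02d}",
                    condition=group,
                    samples=x,
                    roi_labels=list(labels),
                )
            )
    return subjects


def write_cohort(
    subjects: list[RoiTimeSeriesSet], outdir: str | Path, *, seed: int | None = None
) -> Path:
    """Write one TSV per subject plus a manifest CSV; returns the manifest
    path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "condition", "path", "seed"])
        for ts in subjects:
            path = outdir / f"{ts.subject_id}.tsv"
            with open(path, "w") as tfh:
                tfh.write("\t".join(ts.roi_labels) + "\n")
                for row in ts.samples:
                    tfh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
            w.writerow([ts.subject_id, ts.condition, path.name, seed])
    return manifest
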