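"""Null-model graphs for contextualizing network fractal dimensions.

Two reference families: k-nearest-neighbour ring lattices (k = 2D for an
embedding dimension D) as a maximally ordered null, and uniform G(n, m)
random graphs edge-matched to the empirical connectivity graphs as a
maximally disordered null. The batch runner applies the same box-covering
estimator to each replicate with independent seed substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from fractalconn.netfd import network_fractal_dimension

__all__ = [
    "NullBatchResult",
    "ring_lattice",
    "grid_lattice",
    "random_gnm",
    "null_fd_distribution",
]


@dataclass
class NullBatchResult:
    """Fractal dimensions of one batch of null graphs."""

    kind: str
    parameters: dict
    dimensions: list[float]
    summary: tuple[float, float, float]  # median, q25, q75


def ring_lattice(n: int, embedding_dim: int) -> nx.Graph:
    """Circulant ring: node i joined to i +- 1..embedding_dim (mod n),
    i.e. each node to its k = 2*embedding_dim nearest neighbours."""
    if embedding_dim < 1:
        raise ValueError("embedding_dim must be >= 1")
    if 2 * embedding_dim >= n:
        raise ValueError("k = 2*embedding_dim must be < n")
    return nx.circulant_graph(n, list(range(1, embedding_dim + 1)))


def grid_lattice(rows: int, cols: int) -> nx.Graph:
    """Rectangular grid alternative (4-neighbour), since 'D-dimensional
    lattice' is also read as a grid; integer node labels."""
    return nx.convert_node_labels_to_integers(
        nx.grid_2d_graph(rows, cols), ordering="sorted"
    )


def random_gnm(n: int, m: int, seed: int) -> nx.Graph:
    """Uniform simple graph with exactly m edges (seed-reproducible)."""
    if not 0 <= m <= n * (n - 1) // 2:
        raise ValueError("m out of range")
    return nx.gnm_random_graph(n, m, seed=int(seed))


def null_fd_distribution(
    kind: str,
    n: int,
    parameter: int,
    replicates: int = 50,
    *,
    l_min: int = 1,
    l_max: int = 10,
    restarts: int = 10,
    seed: int = 0,
) -> NullBatchResult:
    """Fractal dimensions of a batch of null graphs.

    ``kind`` is ``"lattice"`` (parameter = embedding dimension; a single
    deterministic graph) or ``"random"`` (parameter = edge count m,
    matched to the empirical graphs; ``replicates`` independent draws).
    """
    if kind == "lattice":
        graphs = [ring_lattice(n, parameter)]
    elif kind == "random":
        rng_seeds = np.random.SeedSequence(seed).generate_state(replicates)
        graphs = [random_gnm(n, parameter, int(s) % 2**31) for s in rng_seeds]
    else:
        raise ValueError(f"unknown null kind {kind!r}")
    dims = [
        network_fractal_dimension(
            g,
            l_min=l_min,
            l_max=l_max,
            restarts=restarts,
            seed=seed + 1000 + i,
        ).dimension
        for i, g in enumerate(graphs)
    ]
    med, q25, q75 = np.percentile(dims, [50, 25, 75])
    return NullBatchResult(
        kind=kind,
        parameters={
            "n": n,
            ("embedding_dim" if kind == "lattice" else "m"): parameter,
            "replicates": len(graphs),
            "seed": seed,
        },
        dimensions=[float(d) for d in dims],
        summary=(float(med), float(q25), float(q75)),
    )
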