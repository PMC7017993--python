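"""2-D box-counting fractal dimension of adjacency-matrix images.

A graph's adjacency matrix is rendered one pixel per entry (1 where an edge
exists) and scanned with square grids of increasing box side. For each grid
origin and consecutive pair of box sizes the instantaneous scaling slope
``-Δln N(ε) / Δln ε`` is computed; the minimum and maximum slopes over all
origins and size pairs bound the dimension, and their mean is reported as
the fractal dimension of the edge distribution. Images are stored
losslessly (PNG/PGM): lossy compression would corrupt a binary box count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import scipy.stats
from PIL import Image

__all__ = [
    "BoxCountScan",
    "adjacency_to_image",
    "save_image",
    "load_image",
    "image_to_graph",
    "boxcount_2d",
    "matrix_fractal_dimension",
]

#: grid anchor corners used by default
DEFAULT_ORIGINS = ("tl", "tr", "bl", "br")


@dataclass
class BoxCountScan:
    """Occupied-box counts per grid origin and box size, with the derived
    lower/upper/mean dimension estimates and per-origin OLS slopes."""

    grid_origins: list[str]
    sizes: list[int]
    counts: dict  # origin -> {size: occupied box count}
    d_lower: float
    d_upper: float
    d_mean: float
    ols_slopes: dict = field(default_factory=dict)  # origin -> OLS dimension


def adjacency_to_image(g: nx.Graph) -> np.ndarray:
    """Render a graph as a square binary pixel array, one pixel per
    adjacency-matrix entry (row i top-to-bottom in node order)."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot render an empty graph")
    a = nx.to_numpy_array(g, nodelist=list(g.nodes), dtype=float)
    return (a > 0).astype(np.uint8)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a binary image losslessly (PNG or PGM by extension)."""
    Image.fromarray((np.asarray(img) > 0).astype(np.uint8) * 255).save(Path(path))


def load_image(path: str | Path) -> np.ndarray:
    """Read a binary image written by :func:`save_image`."""
    return (np.asarray(Image.open(Path(path)).convert("L")) > 127).astype(np.uint8)


def image_to_graph(img: np.ndarray) -> nx.Graph:
    """Inverse of :func:`adjacency_to_image` (integer node labels)."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("adjacency image must be square")
    g = nx.Graph()
    g.add_nodes_from(range(img.shape[0]))
    ii, jj = np.nonzero(np.triu(img, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def _default_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 up to floor(min(W, H) / 4)."""
    top = min(shape) // 4
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        sizes = [2, max(3, top)] if top >= 2 else [2, 3]
    return sizes


def _origin_offsets(origin: str, shape: tuple[int, int], size: int) -> tuple[int, int]:
    """Grid offset (row, col) anchoring the grid at the named corner."""
    oy = (-shape[0]) % size
    ox = (-shape[1]) % size
    dy = oy if origin[0] == "b" else 0
    dx = ox if origin[1] == "r" else 0
    return dy, dx


def boxcount_2d(
    img: np.ndarray,
    sizes: list[int] | None = None,
    grid_origins: tuple[str, ...] = DEFAULT_ORIGINS,
) -> BoxCountScan:
    """Count occupied grid boxes at each size for each grid origin.

    A box is occupied when it contains at least one foreground pixel;
    partial boxes at the image edge count. Raises on an empty foreground
    (the dimension is undefined) or on non-ascending sizes.
    """
    img = np.asarray(img)
    ys, xs = np.nonzero(img)
    if ys.size == 0:
        raise ValueError("empty foreground: box-counting dimension undefined")
    if sizes is None:
        sizes = _default_sizes(img.shape)
    sizes = list(sizes)
    if any(s < 2 for s in sizes) or any(
        b <= a for a, b in zip(sizes, sizes[1:])
    ):
        raise ValueError("sizes must be >= 2 and strictly ascending")
    counts: dict[str, dict[int, int]] = {}
    for origin in grid_origins:
        per = {}
        for s in sizes:
            dy, dx = _origin_offsets(origin, img.shape, s)
            by = (ys + dy) // s
            bx = (xs + dx) // s
            per[s] = int(np.unique(by * (img.shape[1] // s + 2) + bx).size)
        counts[origin] = per
    scan = BoxCountScan(
        grid_origins=list(grid_origins),
        sizes=sizes,
        counts=counts,
        d_lower=float("nan"),
        d_upper=float("nan"),
        d_mean=float("nan"),
    )
    _attach_dimensions(scan)
    return scan


def _attach_dimensions(scan: BoxCountScan) -> None:
    slopes = []
    for origin in scan.grid_origins:
        per = scan.counts[origin]
        ln_n = np.log([per[s] for s in scan.sizes])
        ln_e = np.log(scan.sizes)
        slopes.extend(
            -(ln_n[i + 1] - ln_n[i]) / (ln_e[i + 1] - ln_e[i])
            for i in range(len(scan.sizes) - 1)
        )
        if np.allclose(ln_n, ln_n[0]):
            scan.ols_slopes[origin] = 0.0
        else:
            scan.ols_slopes[origin] = float(
                -scipy.stats.linregress(ln_e, ln_n).slope
            )
    scan.d_lower = float(min(slopes))
    scan.d_upper = float(max(slopes))
    scan.d_mean = (scan.d_lower + scan.d_upper) / 2.0


def matrix_fractal_dimension(
    img: np.ndarray,
    sizes: list[int] | None = None,
    grid_origins: tuple[str, ...] = DEFAULT_ORIGINS,
) -> float:
    """Mean of the lower/upper instantaneous-slope bounds on the 2-D
    box-counting dimension (see :func:`boxcount_2d`)."""
    if sizes is not None and len(sizes) < 2:
        raise ValueError("need at least 2 box sizes")
    return boxcount_2d(img, sizes=sizes, grid_origins=grid_origins).d_mean
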