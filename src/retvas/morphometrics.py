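"""Per-image vascular morphometrics.

Four metrics summarize each segmented fundus image:

1. **Vessel density** — percentage of FOV pixels classified as vessel.
2. **Edge-length distribution** — lengths of the skeleton-graph edges.
3. **Node counts** — external nodes (EN, terminals, degree 1) and internal
   nodes (IN, bifurcations degree 3 plus crossings degree 4), and the number
   of edges.
4. **Box-counting fractal dimension** — the skeleton is covered by regular
   grids of mesh size ``s``; ``N(s)`` counts occupied boxes, and
   ``FD = lim_{s->0} log N(s) / log(1/s)`` is approximated by the
   least-squares slope of log N(s) versus log(1/s).  For planar skeletons FD
   lies between 1 (a line) and 2 (a filled region).

FD is computed on the skeleton, not the filled mask; junction nodes of
degree above 4 — rare thinning artefacts — are counted as crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import VesselGraph

__all__ = [
    "MetricSet",
    "FractalEstimate",
    "vessel_density",
    "edge_length_distribution",
    "count_nodes",
    "fractal_dimension",
]

DEFAULT_N_BOX_SIZES = 7
MIN_BOX_SIZE = 2.0  # px; the box ladder stops here


@dataclass
class FractalEstimate:
    fd: float
    box_sizes: np.ndarray
    counts: np.ndarray
    fit_r2: float


@dataclass
class MetricSet:
    """The four morphometric summaries of one segmented image."""

    density_pct: float
    edge_lengths: np.ndarray
    n_external: int
    n_internal: int
    n_edges: int
    fd: FractalEstimate | None = field(default=None, repr=False)

    @property
    def fd_value(self) -> float:
        return float("nan") if self.fd is None else self.fd.fd


def vessel_density(mask: np.ndarray, fov: np.ndarray) -> float:
    """Vessel area as a percentage of the FOV area."""
    mask = np.asarray(mask, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if mask.shape != fov.shape:
        raise ValueError("mask and fov must be congruent")
    n_fov = fov.sum()
    if n_fov == 0:
        raise ValueError("empty FOV")
    return float(100.0 * (mask & fov).sum() / n_fov)


def edge_length_distribution(
    graph: VesselGraph, bin_edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized histogram of edge lengths; returns (hist, bin_edges, lengths).

    Bins default to the Freedman-Diaconis rule on the lengths at hand.  With
    no edges, empty arrays are returned (flagged by their zero size).
    """
    lengths = graph.edge_lengths()
    if lengths.size == 0:
        return np.array([]), np.array([]), lengths
    if bin_edges is None:
        bin_edges = np.histogram_bin_edges(lengths, bins="fd")
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
    hist, bin_edges = np.histogram(lengths, bins=bin_edges)
    hist = hist / hist.sum() if hist.sum() else hist.astype(float)
    return hist, bin_edges, lengths


def count_nodes(graph: VesselGraph) -> tuple[int, int, int]:
    """Return (EN, IN, n_edges): terminals, bifurcations+crossings, edges."""
    en = sum(n.kind == "terminal" for n in graph.nodes)
    inn = sum(n.kind in ("bifurcation", "crossing") for n in graph.nodes)
    return en, inn, graph.n_edges


def fractal_dimension(skel: np.ndarray, n_sizes: int = DEFAULT_N_BOX_SIZES) -> FractalEstimate:
    """Box-counting fractal dimension of a binary skeleton raster.

    The grid is anchored at the skeleton's bounding-box origin, with mesh
    sizes ``s = side / 2**k`` for ``k = 1..n_sizes`` (``side`` the longer
    bounding-box side), truncated below 2 px.  Mesh sizes small enough that
    ``N(s)`` saturates at the number of skeleton pixels carry no scaling
    information and are excluded from the fit.  The estimate is the
    least-squares slope of log N(s) against log(1/s).
    """
    if n_sizes < 4:
        raise ValueError("need at least 4 box sizes")
    skel = np.asarray(skel, dtype=bool)
    rr, cc = np.nonzero(skel)
    if rr.size == 0:
        raise ValueError("empty skeleton")
    rr = rr - rr.min()
    cc = cc - cc.min()
    side = float(max(rr.max(), cc.max()) + 1)

    sizes, counts = [], []
    for k in range(1, n_sizes + 1):
        s = side / 2.0**k
        if s < MIN_BOX_SIZE:
            break
        boxes = np.unique(np.stack([(rr // s).astype(np.int64), (cc // s).astype(np.int64)]), axis=1)
        sizes.append(s)
        counts.append(boxes.shape[1])
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)

    keep = counts < rr.size  # drop saturated meshes (one pixel per box)
    if keep.sum() >= 2:
        fs, fc = sizes[keep], counts[keep]
    else:
        fs, fc = sizes, counts
    x = np.log(1.0 / fs)
    y = np.log(fc)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FractalEstimate(fd=float(slope), box_sizes=sizes, counts=counts, fit_r2=r2)
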