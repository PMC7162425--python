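"""Fixed-radius neighbour graphs and local density estimates.

Every clusterer in this package consumes a per-detection scalar density.
Three estimators are provided:

* radius-count: the number of other detections within ``r`` nm (the degree
  in the fixed-radius graph);
* Voronoi: the reciprocal area (2D) or volume (3D) of the detection's
  tessellation tile;
* a local Ripley-style L score, the radius-count renormalized so that its
  expectation under complete spatial randomness is ``r``.

Distances exactly equal to ``r`` are inside the neighbourhood ("within"
reads as inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Voronoi, cKDTree
from scipy.spatial import QhullError

from .core_data import DetectionTable
from .errors import DegenerateGeometryError, ParameterError


@dataclass
class RadiusGraph:
    """Undirected fixed-radius graph: edge (i, j) iff dist(i, j) <= r.

    Vertices are row positions into the detection table; ``edges`` is an
    (m, 2) array with i < j, lexicographically sorted.
    """

    n: int
    edges: np.ndarray
    radius: float

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency_lists(self) -> list[np.ndarray]:
        nbrs: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.asarray(a, dtype=int) for a in nbrs]


@dataclass
class DensityEstimate:
    """Per-detection density values with a tag for the estimator used."""

    values: np.ndarray
    method: str
    params: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ParameterError("density values must be finite and >= 0")


def build_radius_graph(t: DetectionTable, r: float) -> RadiusGraph:
    """Exact fixed-radius neighbour graph (k-d tree backed, boundary inclusive)."""
    if r <= 0:
        raise ParameterError("radius must be > 0")
    pairs = cKDTree(t.coords).query_pairs(r, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    else:
        pairs = np.empty((0, 2), dtype=int)
    return RadiusGraph(n=t.n, edges=pairs, radius=float(r))


def radius_count_density(t: DetectionTable, r: float, graph: RadiusGraph | None = None) -> DensityEstimate:
    """f_i = number of other detections within r of detection i."""
    g = graph if graph is not None and graph.radius == r else build_radius_graph(t, r)
    return DensityEstimate(g.degrees().astype(float), "radius-count", {"r": float(r)})


def _polytope_measure(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def voronoi_density(
    t: DetectionTable, clip_box: tuple[float, ...] | None = None
) -> tuple[DensityEstimate, np.ndarray]:
    """Voronoi tessellation density: f_i = 1 / tile area (2D) or volume (3D).

    Unbounded tiles get density 0 so field-edge detections read as sparse.
    Alternatively ``clip_box`` (axis lengths, origin at 0) clips every tile to
    the observation window first (2D only).  Also returns the tile adjacency
    (detections sharing a Voronoi ridge) as an (m, 2) array for cluster growth.
    """
    pts = t.coords
    if t.n < t.dim + 1:
        raise DegenerateGeometryError("need at least dim+1 points for a tessellation")
    try:
        vor = Voronoi(pts)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate point configuration: {e}") from e

    f = np.zeros(t.n)
    if clip_box is not None:
        if t.dim != 2:
            raise ParameterError("clip_box is only supported in 2D")
        # mirror the points across all four window edges so every original
        # cell is bounded, then intersect with the window
        from shapely.geometry import Polygon, box

        w, h = float(clip_box[0]), float(clip_box[1])
        window = box(0.0, 0.0, w, h)
        mirrored = [pts]
        for axis, bound in ((0, 0.0), (0, w), (1, 0.0), (1, h)):
            m = pts.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            mirrored.append(m)
        vor_c = Voronoi(np.concatenate(mirrored))
        for i in range(t.n):
            verts = vor_c.regions[vor_c.point_region[i]]
            if -1 in verts or len(verts) < 3:
                continue
            poly = Polygon(vor_c.vertices[verts]).intersection(window)
            if poly.area > 0:
                f[i] = 1.0 / poly.area
    else:
        for i, reg in enumerate(vor.point_region):
            verts = vor.regions[reg]
            if -1 in verts or len(verts) < t.dim + 1:
                continue  # unbounded tile -> density 0
            measure = _polytope_measure(vor.vertices[verts])
            if measure > 0:
                f[i] = 1.0 / measure

    adj = np.sort(vor.ridge_points, axis=1)
    adj = adj[np.lexsort((adj[:, 1], adj[:, 0]))]
    return DensityEstimate(f, "voronoi", {"clip_box": clip_box}), adj


def voronoi_tile_measures(t: DetectionTable) -> tuple[np.ndarray, np.ndarray]:
    """Tile areas/volumes (np.inf for unbounded tiles) plus tile adjacency."""
    dens, adj = voronoi_density(t)
    areas = np.full(t.n, np.inf)
    nz = dens.values > 0
    areas[nz] = 1.0 / dens.values[nz]
    return areas, adj


def ripley_local_score(
    t: DetectionTable, r: float, window_area: float | None = None
) -> DensityEstimate:
    """Per-detection Ripley-style L score.

    ``L_i = sqrt(A * k_i / (pi * (n - 1)))`` in 2D, where ``k_i`` is the
    neighbour count within ``r`` and ``A`` the observation-window area; under
    CSR its expectation is approximately ``r``.  In 3D the analogue
    ``(3 A k_i / (4 pi (n-1)))^(1/3)`` with A the window volume is used.
    If ``window_area`` is omitted the bounding-box measure of the data is used.
    """
    if r <= 0:
        raise ParameterError("radius must be > 0")
    if window_area is None:
        span = t.coords.max(axis=0) - t.coords.min(axis=0)
        window_area = float(np.prod(span))
    if window_area <= 0:
        raise ParameterError("observation window area must be > 0")
    k = radius_count_density(t, r).values
    denom = max(t.n - 1, 1)
    if t.dim == 2:
        L = np.sqrt(window_area * k / (np.pi * denom))
    else:
        L = (3.0 * window_area * k / (4.0 * np.pi * denom)) ** (1.0 / 3.0)
    return DensityEstimate(L, "ripley", {"r": float(r), "window_area": window_area})
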