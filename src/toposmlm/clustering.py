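"""Persistence-based clustering (ToMATo) and baseline clusterers.

ToMATo (Topological Mode Analysis Tool) clusters a point cloud by mode
seeking on a local density estimate ``f`` over a fixed-radius graph.  Each
detection follows a pseudo-gradient to its highest-density neighbour;
detections with no higher neighbour are density modes and found candidate
clusters.  Sweeping the density from high to low, the level at which a
candidate first touches a candidate of higher birth density is its death
density ``f_d``; its birth density ``f_b`` is the density of its mode.  A
candidate with prominence (persistence) ``P = f_b - f_d`` below a threshold
``tau`` is merged into the neighbour it touches; the rest survive as
clusters.  Surviving candidates whose birth density is zero (isolated
detections with no neighbours within the search radius) are designated
noise.

The three comparison baselines (DBSCAN, a local Ripley-L threshold, and
Voronoi tile-area thresholding) share the same :class:`ClusterResult`
contract: per-detection integer labels with 0 = noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import DBSCAN

from .core_data import DetectionTable
from .errors import ParameterError
from .neighbor_density import (
    DensityEstimate,
    RadiusGraph,
    build_radius_graph,
    radius_count_density,
    ripley_local_score,
    voronoi_tile_measures,
)


@dataclass
class CandidateCluster:
    """A density mode: birth density, death density (−inf for the highest
    peak of a connected component) and the member detections at death."""

    mode: int                 # detection id of the mode
    f_b: float
    f_d: float
    members: np.ndarray       # detection ids in the candidate when it died/survived

    @property
    def persistence(self) -> float:
        return self.f_b - self.f_d


@dataclass
class ClusterResult:
    """Per-detection labels (0 = noise, 1..K clusters) plus the parameters used.

    For ToMATo the full candidate diagram (all birth/death pairs from a
    merge-everything sweep) is attached.
    """

    labels: np.ndarray
    params: dict
    diagram: list[CandidateCluster] | None = None

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


# ---------------------------------------------------------------------------
# ToMATo
# ---------------------------------------------------------------------------

def _tomato_sweep(f, ids, neighbors, order, rank, tau, record_diagram):
    """Union-find sweep in decreasing density order.

    ``tau=inf`` merges every finite-persistence candidate (elder rule) and
    yields the complete diagram; a finite ``tau`` yields the clustering.
    Returns (root array, diagram, birth array indexed by root).
    """
    n = len(f)
    parent = np.arange(n)
    birth = np.full(n, -np.inf)       # birth density of the candidate rooted here
    mode_of = np.arange(n)
    members: list[list[int]] | None = [[] for _ in range(n)] if record_diagram else None
    diagram: list[CandidateCluster] = []

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in order:
        ups = [j for j in neighbors[i] if rank[j] < rank[i]]
        higher = [j for j in ups if f[j] > f[i]]
        if not higher:
            birth[i] = f[i]           # i is a mode, new candidate
            if members is not None:
                members[i] = [i]
        else:
            g = min(higher, key=lambda j: (-f[j], ids[j]))
            rg = find(g)
            parent[i] = rg
            if members is not None:
                members[rg].append(i)
        for j in sorted(ups, key=lambda j: (-f[j], ids[j])):
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            # elder rule: candidate with lower birth (ties: higher id) is younger
            if (birth[ri], -ids[mode_of[ri]]) < (birth[rj], -ids[mode_of[rj]]):
                young, old = ri, rj
            else:
                young, old = rj, ri
            if birth[young] - f[i] < tau:
                if record_diagram:
                    diagram.append(
                        CandidateCluster(
                            mode=int(ids[mode_of[young]]),
                            f_b=float(birth[young]),
                            f_d=float(f[i]),
                            members=ids[np.asarray(members[young], dtype=int)],
                        )
                    )
                    members[old].extend(members[young])
                    members[young] = []
                parent[young] = old

    roots = np.array([find(i) for i in range(n)])
    if record_diagram:
        for r in np.unique(roots):
            diagram.append(
                CandidateCluster(
                    mode=int(ids[mode_of[r]]),
                    f_b=float(birth[r]),
                    f_d=-np.inf,
                    members=ids[roots == r],
                )
            )
    return roots, diagram, birth


def tomato_cluster(
    t: DetectionTable,
    r: float,
    tau: float,
    density: DensityEstimate | None = None,
    graph: RadiusGraph | None = None,
    density_filter_quantile: float | None = None,
) -> ClusterResult:
    """ToMATo persistence-based clustering.

    Parameters
    ----------
    r
        Search radius (nm) for both the density estimate and the linking graph.
    tau
        Persistence threshold (same units as the density, i.e. detections for
        the default radius-count estimate).
    density, graph
        Optional precomputed inputs (must match ``r``); any density estimate
        can be substituted for the default radius count.
    density_filter_quantile
        If set, detections with density below this quantile are dropped to
        noise before mode seeking (useful when the signal-to-noise ratio
        varies across the field).
    """
    if r <= 0:
        raise ParameterError("radius must be > 0")
    if not tau >= 0:
        raise ParameterError("tau must be >= 0")
    g = graph if graph is not None and graph.radius == r else build_radius_graph(t, r)
    dens = density if density is not None else radius_count_density(t, r, graph=g)
    f_all = dens.values
    ids_all = t.ids

    keep = np.arange(t.n)
    if density_filter_quantile is not None:
        cut = np.quantile(f_all, density_filter_quantile)
        keep = np.nonzero(f_all >= cut)[0]

    labels = np.zeros(t.n, dtype=int)
    if len(keep) == 0:
        return ClusterResult(labels, {"r": r, "tau": tau}, [])

    pos_of = -np.ones(t.n, dtype=int)
    pos_of[keep] = np.arange(len(keep))
    f = f_all[keep]
    ids = ids_all[keep]
    nbrs_all = g.adjacency_lists()
    neighbors = [
        np.asarray([pos_of[j] for j in nbrs_all[i] if pos_of[j] >= 0], dtype=int)
        for i in keep
    ]
    order = np.lexsort((ids, -f))
    rank = np.empty(len(keep), dtype=int)
    rank[order] = np.arange(len(keep))

    _, diagram, _ = _tomato_sweep(f, ids, neighbors, order, rank, np.inf, True)
    roots, _, birth = _tomato_sweep(f, ids, neighbors, order, rank, float(tau), False)

    cluster_roots = [r_ for r_ in np.unique(roots) if birth[r_] > 0]
    cluster_roots.sort(key=lambda r_: (-birth[r_], ids[r_]))
    for lab, r_ in enumerate(cluster_roots, start=1):
        labels[keep[roots == r_]] = lab
    return ClusterResult(labels, {"r": float(r), "tau": float(tau)}, diagram)


def tomato_diagram(cr: ClusterResult) -> tuple[np.ndarray, np.ndarray, float]:
    """Births and deaths of every candidate cluster plus a suggested bin width.

    Deaths of the highest peak per connected component are −inf.  Densities
    from the radius-count estimate are integers, so a unit bin is the natural
    histogram resolution when the diagram is too dense to scatter-plot.
    """
    if cr.diagram is None:
        raise ParameterError("this cluster result carries no ToMATo diagram")
    births = np.array([c.f_b for c in cr.diagram])
    deaths = np.array([c.f_d for c in cr.diagram])
    return births, deaths, 1.0


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def dbscan_cluster(t: DetectionTable, eps: float, min_pts: int) -> ClusterResult:
    """Standard DBSCAN; the neighbour count includes the point itself.

    Noise is 0; clusters are renumbered 1..K in order of the smallest member
    row.
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(t.coords)
    return ClusterResult(_canonical_labels(raw + 1), {"eps": eps, "min_pts": min_pts})


def _components_to_labels(n: int, keep: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Connected components of the subgraph induced by ``keep`` (boolean mask)."""
    labels = np.zeros(n, dtype=int)
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        return labels
    pos = -np.ones(n, dtype=int)
    pos[idx] = np.arange(len(idx))
    if len(edges):
        m = keep[edges[:, 0]] & keep[edges[:, 1]]
        e = edges[m]
    else:
        e = np.empty((0, 2), dtype=int)
    graph = coo_matrix(
        (np.ones(len(e)), (pos[e[:, 0]], pos[e[:, 1]])), shape=(len(idx), len(idx))
    )
    _, comp = connected_components(graph, directed=False)
    labels[idx] = comp + 1
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..K by first appearance in row order; 0 stays 0."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab <= 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def ripley_cluster(
    t: DetectionTable,
    r: float,
    score_threshold: float,
    window_area: float | None = None,
    score: DensityEstimate | None = None,
) -> ClusterResult:
    """Keep detections with local Ripley L >= threshold; clusters are the
    connected components of the radius graph restricted to kept detections."""
    if r <= 0:
        raise ParameterError("radius must be > 0")
    s = score if score is not None else ripley_local_score(t, r, window_area)
    g = build_radius_graph(t, r)
    keep = s.values >= score_threshold
    labels = _components_to_labels(t.n, keep, g.edges)
    return ClusterResult(labels, {"r": r, "score_threshold": score_threshold})


def voronoi_cluster(
    t: DetectionTable,
    max_tile_area: float,
    tiles: tuple[np.ndarray, np.ndarray] | None = None,
) -> ClusterResult:
    """Keep detections whose Voronoi tile area (volume in 3D) is <= the
    threshold; clusters are the connected components under tile adjacency."""
    areas, adj = tiles if tiles is not None else voronoi_tile_measures(t)
    keep = areas <= max_tile_area
    labels = _components_to_labels(t.n, keep, adj)
    return ClusterResult(labels, {"max_tile_area": max_tile_area})


def parameter_grid(algorithm: str, grid: dict[str, list]) -> list[dict]:
    """Deterministic Cartesian product of parameter ranges for benchmarking."""
    for name, values in grid.items():
        values = list(values)
        if not values:
            raise ParameterError(f"empty parameter range for {name!r}")
        grid[name] = values
    keys = list(grid)
    return [
        {"algorithm": algorithm, **dict(zip(keys, combo))}
        for combo in itertools.product(*(grid[k] for k in keys))
    ]
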