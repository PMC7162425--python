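"""Rips filtrations, persistence diagrams and the sub-sampled consensus.

The Rips complex at scale ``s`` contains a simplex whenever all of its
vertices are pairwise within ``s`` (the scale is the pairwise-distance
threshold, i.e. the ball *diameter*).  Sweeping ``s`` from 0 to
``max_scale`` gives a filtration; the births and deaths of connected
components (H0), loops/holes (H1) and, in 3D, enclosed voids (H2) across
the filtration form the persistence diagram.

Persistence pairs are computed over GF(2): H0 with a union-find over the
distance-sorted edges, H1/H2 by boundary-matrix column reduction using the
clearing ("twist") optimisation — columns of one dimension are reduced
before the dimension below, and pivot rows found there are skipped since
their own columns must reduce to zero.  Columns are stored as Python
integers used as bit-sets, so the XOR of two columns is a single bigint
operation.

Counting the features per dimension >= 1 whose persistence clears a
threshold yields the *topological configuration* of a cluster (number of
holes, and voids in 3D).  Because SMLM data carries false detections and
blinking artifacts, the configuration of a cluster is also estimated by a
weighted bootstrap: detections are resampled with replacement, more
precisely localized detections being more likely to be drawn, and the modal
configuration over resamples is reported together with the percentage of
resamples that agree with it (the agreement, alpha).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .clustering import ClusterResult
from .core_data import DetectionTable
from .errors import DataError, ParameterError


# ---------------------------------------------------------------------------
# diagrams and configurations
# ---------------------------------------------------------------------------

@dataclass
class PersistenceDiagram:
    """Features of a Rips filtration: (dimension, birth scale, death scale).

    ``death`` is ``inf`` for essential features that survive to
    ``max_scale``.
    """

    features: np.ndarray          # structured: dim (int), birth, death (float)
    max_scale: float
    max_dim: int                  # maximum simplex dimension included

    def by_dim(self, dim: int) -> np.ndarray:
        return self.features[self.features["dim"] == dim]

    def persistences(self, dim: int) -> np.ndarray:
        f = self.by_dim(dim)
        return f["death"] - f["birth"]


@dataclass(frozen=True, order=True)
class TopoConfiguration:
    """Counts of persistent features per homology dimension >= 1.

    ``counts[0]`` is the number of holes (H1); ``counts[1]``, when present,
    the number of enclosed voids (H2).  Ordering sorts simpler
    configurations (fewer total features) first, which is how consensus ties
    are broken.
    """

    counts: tuple[int, ...] = field(compare=False)
    sort_index: tuple = field(default=(), compare=True)

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ParameterError("feature counts must be non-negative")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        object.__setattr__(self, "sort_index", (sum(self.counts), self.counts))

    @property
    def holes(self) -> int:
        return self.counts[0] if self.counts else 0

    @property
    def voids(self) -> int:
        return self.counts[1] if len(self.counts) > 1 else 0

    def __str__(self) -> str:
        names = ["holes", "voids"]
        return "(" + ", ".join(f"{c} {names[i]}" for i, c in enumerate(self.counts)) + ")"


@dataclass
class ConsensusResult:
    """Modal topological configuration over weighted resamples of a cluster."""

    consensus: TopoConfiguration
    alpha: float                  # % of resamples returning the consensus
    n_resamples: int
    configurations: Counter

    def __post_init__(self):
        if not 0.0 < self.alpha <= 100.0:
            raise ParameterError("alpha must be in (0, 100]")


# ---------------------------------------------------------------------------
# Rips persistence
# ---------------------------------------------------------------------------

def _sorted_edges(dm: np.ndarray, max_scale: float):
    """Edges (i<j, d<=max_scale) sorted by (length, i, j); returns index
    arrays and lengths."""
    n = dm.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = dm[iu, ju]
    m = d <= max_scale
    iu, ju, d = iu[m], ju[m], d[m]
    order = np.lexsort((ju, iu, d))
    return iu[order], ju[order], d[order]


def _h0_pairs(n: int, ei, ej, ed):
    """Kruskal sweep: returns per-edge 'merged' flag and H0 bars (0, d)."""
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    merged = np.zeros(len(ei), dtype=bool)
    deaths = []
    for k in range(len(ei)):
        ra, rb = find(ei[k]), find(ej[k])
        if ra != rb:
            parent[ra] = rb
            merged[k] = True
            deaths.append(ed[k])
    n_components = n - int(merged.sum())
    return merged, deaths, n_components


def _triangles(adj: np.ndarray, dm: np.ndarray, ei, ej):
    """Enumerate triangles of the thresholded graph, sorted by filtration value.

    Returns (tri_filt, tri_edges, tri_verts, tri_index): filtration value per
    triangle, its three boundary edges as indices into the sorted edge
    arrays, its sorted vertex triple, and the triple -> index map.  The
    triangle index order refines the filtration order, so triangles can be
    used directly as reduction rows.
    """
    edge_index = {(int(ei[k]), int(ej[k])): k for k in range(len(ei))}
    tri_filt, tri_edges, tri_verts = [], [], []
    for k in range(len(ei)):
        i, j = int(ei[k]), int(ej[k])
        common = np.nonzero(adj[i] & adj[j])[0]
        for c in common[common > j]:
            c = int(c)
            tri_filt.append(max(dm[i, j], dm[i, c], dm[j, c]))
            tri_edges.append((k, edge_index[(i, c)], edge_index[(j, c)]))
            tri_verts.append((i, j, c))
    tri_filt = np.asarray(tri_filt)
    order = np.lexsort((np.arange(len(tri_filt)), tri_filt))
    tri_filt = tri_filt[order]
    tri_edges = [tri_edges[o] for o in order]
    tri_verts = [tri_verts[o] for o in order]
    tri_index = {v: idx for idx, v in enumerate(tri_verts)}
    return tri_filt, tri_edges, tri_verts, tri_index


def _reduce(columns_rows: list[tuple[int, ...]], col_filts: np.ndarray,
            skip: set[int] | None = None):
    """GF(2) column reduction.

    ``columns_rows[c]`` lists the row indices of column ``c``; columns are
    processed in order of (filtration value, index).  Returns
    (pairs, zero_columns) where pairs maps pivot row -> (row filt, col filt)
    and zero_columns is the set of columns that reduced to zero.
    """
    order = np.lexsort((np.arange(len(col_filts)), col_filts))
    pivot: dict[int, int] = {}          # pivot row -> column bitset
    pairs: dict[int, float] = {}        # pivot row -> column filtration value
    zero_cols: set[int] = set()
    for c in order:
        c = int(c)
        if skip is not None and c in skip:
            continue
        col = 0
        for r_ in columns_rows[c]:
            col ^= 1 << r_
        while col:
            low = col.bit_length() - 1
            other = pivot.get(low)
            if other is None:
                pivot[low] = col
                pairs[low] = float(col_filts[c])
                break
            col ^= other
        else:
            zero_cols.add(c)
    return pairs, zero_cols


def rips_persistence(
    points: np.ndarray, max_scale: float | None = None, max_dim: int = 2
) -> PersistenceDiagram:
    """Persistent homology of the Rips filtration of a point cloud.

    Parameters
    ----------
    points
        (n, d) coordinates.
    max_scale
        Filtration truncation (pairwise-distance threshold); defaults to the
        point-cloud diameter so no finite feature is lost to truncation.
    max_dim
        Maximum simplex dimension: 2 computes H0/H1, 3 additionally H2.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise ParameterError("at least one point is required")
    if max_dim not in (1, 2, 3):
        raise ParameterError("max_dim must be 1, 2 or 3 (simplices up to tetrahedra)")
    n = len(points)
    if n == 1:
        feats = np.array([(0, 0.0, np.inf)], dtype=_FEATURE_DTYPE)
        return PersistenceDiagram(feats, float(max_scale or 0.0), max_dim)

    dm = squareform(pdist(points))
    if max_scale is None:
        max_scale = float(dm.max())
    elif max_scale <= 0:
        raise ParameterError("max_scale must be > 0")

    ei, ej, ed = _sorted_edges(dm, max_scale)
    merged, h0_deaths, n_components = _h0_pairs(n, ei, ej, ed)

    feats: list[tuple[int, float, float]] = []
    for d in h0_deaths:
        if d > 0:
            feats.append((0, 0.0, float(d)))
    feats.extend((0, 0.0, np.inf) for _ in range(n_components))

    if max_dim >= 2:
        adj = dm <= max_scale
        np.fill_diagonal(adj, False)
        tri_filt, tri_edges, tri_verts, tri_index = _triangles(adj, dm, ei, ej)

        skip_triangles: set[int] = set()
        if max_dim >= 3 and len(tri_filt):
            tet_filt, tet_rows = _tetrahedra(adj, dm, tri_filt, tri_verts, tri_index)
            h2_pairs, _ = _reduce(tet_rows, tet_filt)
            for tri_row, death in h2_pairs.items():
                birth = float(tri_filt[tri_row])
                if death > birth:
                    feats.append((2, birth, death))
            skip_triangles = set(h2_pairs.keys())

        h1_pairs, zero_tris = _reduce(tri_edges, tri_filt, skip=skip_triangles)
        for edge_row, death in h1_pairs.items():
            birth = float(ed[edge_row])
            if death > birth:
                feats.append((1, birth, death))
        # essential H1: cycle edges never killed by a triangle
        for k in np.nonzero(~merged)[0]:
            if int(k) not in h1_pairs:
                feats.append((1, float(ed[k]), np.inf))
        if max_dim >= 3:
            # essential H2: creator triangles never killed by a tetrahedron
            for c in zero_tris:
                feats.append((2, float(tri_filt[c]), np.inf))

    arr = np.array(feats, dtype=_FEATURE_DTYPE) if feats else np.empty(0, dtype=_FEATURE_DTYPE)
    return PersistenceDiagram(arr, float(max_scale), max_dim)


_FEATURE_DTYPE = [("dim", int), ("birth", float), ("death", float)]


def _tetrahedra(adj, dm, tri_filt, tri_verts, tri_index):
    """Enumerate tetrahedra; boundary rows are (filtration-ordered) triangle
    indices."""
    tet_filt, tet_rows = [], []
    for t_idx, (i, j, k) in enumerate(tri_verts):
        common = np.nonzero(adj[i] & adj[j] & adj[k])[0]
        for l_ in common[common > k]:
            l_ = int(l_)
            f = max(tri_filt[t_idx], dm[i, l_], dm[j, l_], dm[k, l_])
            tet_filt.append(f)
            tet_rows.append(
                (t_idx, tri_index[(i, j, l_)],
                 tri_index[(i, k, l_)], tri_index[(j, k, l_)])
            )
    return np.asarray(tet_filt), tet_rows


def threshold_diagram(pd_: PersistenceDiagram, pers_threshold: float) -> TopoConfiguration:
    """Count features per dimension >= 1 with persistence >= the threshold.

    Essential features (infinite death) always count as persistent.
    """
    if pers_threshold < 0:
        raise ParameterError("persistence threshold must be >= 0")
    top_dim = max(pd_.max_dim - 1, 1)
    counts = []
    for dim in range(1, top_dim + 1):
        pers = pd_.persistences(dim)
        counts.append(int(np.sum(pers >= pers_threshold)))
    return TopoConfiguration(tuple(counts))


# ---------------------------------------------------------------------------
# uncertainty-weighted sub-sampling consensus
# ---------------------------------------------------------------------------

def sampling_weights(
    uncertainties: np.ndarray, mu: float = 2.3, normalize: bool = True
) -> np.ndarray:
    """Resampling weights ``exp(-mu * w)`` from localization uncertainties.

    ``w`` is the min–max normalized uncertainty within the cluster (all-equal
    clusters get w = 0 everywhere).  With the default ``mu = -ln 0.1 = 2.3``
    the most precise detection is ten times more likely to be drawn than the
    least precise one.  ``normalize=True`` rescales the weights to sum to 1.
    """
    u = np.asarray(uncertainties, dtype=float)
    if len(u) == 0:
        raise ParameterError("at least one detection is required")
    if np.any(u < 0):
        raise DataError("localization uncertainties must be >= 0")
    if mu < 0:
        raise ParameterError("mu must be >= 0")
    span = u.max() - u.min()
    w = (u - u.min()) / span if span > 0 else np.zeros_like(u)
    raw = np.exp(-mu * w)
    return raw / raw.sum() if normalize else raw


def subsample_consensus(
    points: np.ndarray,
    uncertainties: np.ndarray | None,
    pers_threshold: float,
    mu: float = 2.3,
    n_resamples: int = 100,
    rng: np.random.Generator | None = None,
    max_dim: int = 2,
    max_scale: float | None = None,
) -> ConsensusResult:
    """Bootstrap the topological configuration of one cluster.

    Each resample draws n detections with replacement (n = cluster size)
    using the uncertainty weights (uniform if uncertainties are absent),
    collapses duplicates, and computes the thresholded configuration of the
    resample's Rips filtration.  The modal configuration is the consensus;
    ties are broken toward the simpler configuration.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n == 0:
        raise ParameterError("cluster must be non-empty")
    if n_resamples < 1:
        raise ParameterError("n_resamples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    p = sampling_weights(uncertainties, mu) if uncertainties is not None else None
    if max_scale is None:
        max_scale = float(pdist(points).max()) if n > 1 else 1.0

    configs = Counter()
    for _ in range(n_resamples):
        idx = np.unique(rng.choice(n, size=n, replace=True, p=p))
        diag = rips_persistence(points[idx], max_scale=max_scale, max_dim=max_dim)
        configs[threshold_diagram(diag, pers_threshold)] += 1

    top = max(configs.values())
    consensus = min(c for c, k in configs.items() if k == top)
    return ConsensusResult(
        consensus=consensus,
        alpha=100.0 * top / n_resamples,
        n_resamples=n_resamples,
        configurations=configs,
    )


# ---------------------------------------------------------------------------
# per-cluster driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologySettings:
    """Knobs for the per-cluster topology pipeline (defaults per the study
    conditions: 15 nm persistence threshold, mu = -ln 0.1, 100 resamples)."""

    pers_threshold: float = 15.0
    mu: float = 2.3
    n_resamples: int = 100
    min_cluster_size: int = 4
    max_scale: float | None = None    # None: per-cluster diameter
    max_dim: int | None = None        # None: 2 in 2D, 3 in 3D


@dataclass
class ClusterTopology:
    label: int
    n_detections: int
    full_diagram: PersistenceDiagram
    full_config: TopoConfiguration
    consensus: ConsensusResult
    n_components_full: int            # H0 diagnostics (a segmented cluster should be 1)


def per_cluster_topology(
    t: DetectionTable,
    cr: ClusterResult,
    settings: TopologySettings = TopologySettings(),
    rng: np.random.Generator | None = None,
) -> tuple[dict[int, ClusterTopology], dict[int, str]]:
    """Run the full-diagram and consensus topology for every non-noise cluster.

    Returns (results keyed by cluster label, skipped labels with reasons).
    Clusters smaller than ``min_cluster_size`` are skipped.
    """
    rng = rng if rng is not None else np.random.default_rng()
    max_dim = settings.max_dim if settings.max_dim is not None else (2 if t.dim == 2 else 3)
    results: dict[int, ClusterTopology] = {}
    skipped: dict[int, str] = {}
    unc = t.uncertainty
    for label in sorted(np.unique(cr.labels[cr.labels > 0])):
        rows = np.nonzero(cr.labels == label)[0]
        if len(rows) < settings.min_cluster_size:
            skipped[int(label)] = f"cluster size {len(rows)} < {settings.min_cluster_size}"
            continue
        pts = t.coords[rows]
        diag = rips_persistence(pts, max_scale=settings.max_scale, max_dim=max_dim)
        full_config = threshold_diagram(diag, settings.pers_threshold)
        cons = subsample_consensus(
            pts,
            unc[rows] if unc is not None else None,
            settings.pers_threshold,
            mu=settings.mu,
            n_resamples=settings.n_resamples,
            rng=rng,
            max_dim=max_dim,
            max_scale=settings.max_scale,
        )
        h0 = diag.by_dim(0)
        results[int(label)] = ClusterTopology(
            label=int(label),
            n_detections=len(rows),
            full_diagram=diag,
            full_config=full_config,
            consensus=cons,
            n_components_full=int(np.sum(np.isinf(h0["death"]))),
        )
    return results, skipped


def diagram_histogram(
    pd_: PersistenceDiagram, dim: int = 1, bin_size: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint (birth, death) histogram with square bins for dense diagrams.

    Returns (counts, birth_edges, death_edges); infinite deaths are excluded.
    """
    f = pd_.by_dim(dim)
    finite = f[np.isfinite(f["death"])]
    if len(finite) == 0:
        edges = np.array([0.0, bin_size])
        return np.zeros((1, 1)), edges, edges
    top = max(finite["birth"].max(), finite["death"].max())
    edges = np.arange(0.0, top + 2 * bin_size, bin_size)
    counts, be, de = np.histogram2d(finite["birth"], finite["death"], bins=(edges, edges))
    return counts, be, de
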