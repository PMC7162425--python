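"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the production code paths: full dense boundary-matrix
reduction over GF(2) for persistence, O(n^2) scans for neighbourhoods,
reachability BFS for DBSCAN, exhaustive bijection search for assignment
scoring, and an explicit level-scan for persistence-based clustering.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# persistence by full boundary-matrix reduction
# ---------------------------------------------------------------------------

def brute_persistence(points: np.ndarray, max_scale: float, max_dim: int = 2):
    """All persistence bars of the Rips filtration, by explicit simplex
    enumeration and dense GF(2) reduction.  Returns a list of
    (dim, birth, death) with death = inf for essential classes.  Only
    feasible for small point sets."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dm = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))

    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for v in range(n):
        simplices.append((0.0, 0, (v,)))
    for p in range(1, max_dim + 1):
        for verts in itertools.combinations(range(n), p + 1):
            filt = max(dm[a][b] for a, b in itertools.combinations(verts, 2))
            if filt <= max_scale:
                simplices.append((filt, p, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: k for k, s in enumerate(simplices)}

    pivot: dict[int, int] = {}
    pairs: dict[int, int] = {}          # creator index -> destroyer index
    creators: set[int] = set()
    for k, (filt, p, verts) in enumerate(simplices):
        col = 0
        if p > 0:
            for face in itertools.combinations(verts, p):
                col ^= 1 << index[face]
        while col:
            low = col.bit_length() - 1
            if low not in pivot:
                pivot[low] = col
                pairs[low] = k
                break
            col ^= pivot[low]
        else:
            creators.add(k)

    bars = []
    for creator in creators:
        filt_b, dim_b, _ = simplices[creator]
        if creator in pairs:
            filt_d = simplices[pairs[creator]][0]
            if filt_d > filt_b:
                bars.append((dim_b, filt_b, filt_d))
        elif dim_b < max_dim:
            # creators of top dimension cannot be assessed for death
            bars.append((dim_b, filt_b, np.inf))
    return bars


# ---------------------------------------------------------------------------
# geometry scans
# ---------------------------------------------------------------------------

def brute_radius_edges(points: np.ndarray, r: float) -> set[tuple[int, int]]:
    n = len(points)
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.linalg.norm(points[i] - points[j]) <= r
    }


def brute_neighbor_counts(points: np.ndarray, r: float) -> np.ndarray:
    n = len(points)
    counts = np.zeros(n, dtype=int)
    for i, j in brute_radius_edges(points, r):
        counts[i] += 1
        counts[j] += 1
    return counts


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN by explicit reachability expansion (self counted as neighbour)."""
    n = len(points)
    nbrs = [
        [j for j in range(n) if np.linalg.norm(points[i] - points[j]) <= eps]
        for i in range(n)
    ]
    core = [len(nbrs[i]) >= min_pts for i in range(n)]
    labels = np.zeros(n, dtype=int)
    next_label = 0
    for i in range(n):
        if labels[i] != 0 or not core[i]:
            continue
        next_label += 1
        queue = [i]
        labels[i] = next_label
        while queue:
            q = queue.pop()
            if not core[q]:
                continue
            for j in nbrs[q]:
                if labels[j] == 0:
                    labels[j] = next_label
                    queue.append(j)
    return labels


# ---------------------------------------------------------------------------
# assignment scoring
# ---------------------------------------------------------------------------

def exhaustive_percent_correct(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Best achievable percent-correct over all one-to-one cluster matchings."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    t_set = sorted(set(true_labels[true_labels > 0]))
    p_set = sorted(set(pred_labels[pred_labels > 0]))
    base = int(np.sum((true_labels == 0) & (pred_labels == 0)))
    overlap = {
        (tl, pl): int(np.sum((true_labels == tl) & (pred_labels == pl)))
        for tl in t_set
        for pl in p_set
    }
    best = 0
    k = min(len(t_set), len(p_set))
    for t_sub in itertools.permutations(t_set, k):
        for p_sub in itertools.combinations(p_set, k):
            score = sum(overlap[(tl, pl)] for tl, pl in zip(t_sub, p_sub))
            best = max(best, score)
    n = len(true_labels)
    return 100.0 * (base + best) / n if n else float("nan")


# ---------------------------------------------------------------------------
# persistence-based clustering by explicit level scan
# ---------------------------------------------------------------------------

def level_scan_tomato(points: np.ndarray, ids: np.ndarray, r: float, tau: float) -> np.ndarray:
    """Persistence-based clustering via explicit component bookkeeping.

    Components are kept as explicit sets and merge events are enumerated by
    scanning detections in decreasing-density order; tie rules match the
    production contract (attach to the max-density neighbour, ties toward the
    lower id; elder rule by birth then lower mode id).
    """
    n = len(points)
    counts = brute_neighbor_counts(points, r)
    edges = brute_radius_edges(points, r)
    nbrs = [[] for _ in range(n)]
    for i, j in edges:
        nbrs[i].append(j)
        nbrs[j].append(i)

    order = sorted(range(n), key=lambda i: (-counts[i], ids[i]))
    rank = {v: k for k, v in enumerate(order)}
    comp_of: dict[int, int] = {}
    comps: dict[int, set[int]] = {}
    birth: dict[int, float] = {}
    mode: dict[int, int] = {}
    next_comp = 0

    for i in order:
        ups = [j for j in nbrs[i] if rank[j] < rank[i]]
        higher = [j for j in ups if counts[j] > counts[i]]
        if not higher:
            comp_of[i] = next_comp
            comps[next_comp] = {i}
            birth[next_comp] = float(counts[i])
            mode[next_comp] = i
            next_comp += 1
        else:
            g = min(higher, key=lambda j: (-counts[j], ids[j]))
            c = comp_of[g]
            comp_of[i] = c
            comps[c].add(i)
        for j in sorted(ups, key=lambda j: (-counts[j], ids[j])):
            ci, cj = comp_of[i], comp_of[j]
            if ci == cj:
                continue
            young, old = sorted(
                (ci, cj), key=lambda c: (birth[c], -ids[mode[c]])
            )
            if birth[young] - counts[i] < tau:
                for v in comps[young]:
                    comp_of[v] = old
                comps[old] |= comps.pop(young)

    labels = np.zeros(n, dtype=int)
    surviving = sorted(comps, key=lambda c: (-birth[c], ids[mode[c]]))
    lab = 0
    for c in surviving:
        if birth[c] <= 0:
            continue
        lab += 1
        for v in comps[c]:
            labels[v] = lab
    return labels
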