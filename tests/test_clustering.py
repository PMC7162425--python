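"""ToMATo and the baseline clusterers."""

import numpy as np
import pytest

from toposmlm import (
    dbscan_cluster,
    parameter_grid,
    percent_correct,
    ripley_cluster,
    tomato_cluster,
    tomato_diagram,
    voronoi_cluster,
)
from toposmlm.errors import ParameterError
from toposmlm.simulator import PhotophysicsConfig, simulate_detections

from _oracles import brute_dbscan, level_scan_tomato
from conftest import make_table


def mixed_density_four_clusters(seed):
    """Four Gaussian clusters in close proximity with unequal variance."""
    rng = np.random.default_rng(seed)
    centers = [(250.0, 250.0), (360.0, 250.0), (250.0, 360.0), (360.0, 360.0)]
    pts, labels = [], []
    for k, (c, sd, m) in enumerate(zip(centers, [10, 10, 25, 25], [15, 15, 30, 30]), 1):
        pts.append(np.asarray(c) + rng.normal(0, sd, (m, 2)))
        labels.append(np.full(m, k))
    return simulate_detections(
        np.concatenate(pts), np.concatenate(labels), PhotophysicsConfig(),
        (600.0, 600.0), rng,
    )


def relabel_canonical(labels):
    out = np.zeros_like(labels)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab > 0:
            out[i] = mapping.setdefault(lab, len(mapping) + 1)
    return out


class TestTomato:
    def test_recovers_four_mixed_density_clusters(self):
        table, truth = mixed_density_four_clusters(seed=1)
        cr = tomato_cluster(table, r=19.0, tau=6.0)
        sizes = np.bincount(cr.labels)[1:]
        assert int((sizes >= 20).sum()) == 4
        assert percent_correct(truth, cr).percent_correct > 85.0

    def test_infinite_tau_gives_connected_components(self, rng):
        pts = np.concatenate([
            rng.normal(0, 5, (20, 2)),
            rng.normal(200, 5, (20, 2)),
            [[500.0, 500.0]],               # isolated: zero density -> noise
        ])
        cr = tomato_cluster(make_table(pts), r=30.0, tau=np.inf)
        assert cr.n_clusters == 2
        assert cr.labels[-1] == 0

    def test_matches_level_scan_oracle(self, rng):
        pts = rng.uniform(0, 60, (30, 2))
        t = make_table(pts)
        for tau in (0.0, 1.0, 3.0):
            mine = relabel_canonical(tomato_cluster(t, 20.0, tau).labels)
            ref = relabel_canonical(level_scan_tomato(pts, t.ids, 20.0, tau))
            assert mine.tolist() == ref.tolist()

    def test_diagram_invariants(self):
        table, _ = mixed_density_four_clusters(seed=2)
        cr = tomato_cluster(table, 19.0, 6.0)
        births, deaths, bin_width = tomato_diagram(cr)
        assert (births >= deaths).all()
        # one -inf death per connected component of the radius graph (with
        # positive density); at least the four main clusters are components
        assert np.sum(np.isneginf(deaths)) >= 1
        # the four real clusters produce four candidates above tau=6
        finite = np.isfinite(deaths)
        persist = births - np.where(finite, deaths, 0.0)
        assert np.sum(persist >= 6) >= 4

    def test_single_blob_has_one_infinite_candidate(self, rng):
        pts = rng.normal(0, 5, (40, 2))
        cr = tomato_cluster(make_table(pts), 30.0, 5.0)
        _, deaths, _ = tomato_diagram(cr)
        assert np.sum(np.isneginf(deaths)) == 1

    def test_tau_zero_one_cluster_per_mode(self, rng):
        pts = rng.uniform(0, 80, (40, 2))
        t = make_table(pts)
        cr = tomato_cluster(t, 25.0, 0.0)
        # every candidate in the diagram with positive birth is its own cluster
        _, deaths, _ = tomato_diagram(cr)
        births, _, _ = tomato_diagram(cr)
        n_modes = len(births)
        assert cr.n_clusters == n_modes

    def test_cluster_count_monotone_in_tau(self):
        table, _ = mixed_density_four_clusters(seed=3)
        counts = [
            tomato_cluster(table, 19.0, tau).n_clusters for tau in (0, 2, 4, 6, 10, 20, np.inf)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_row_permutation_invariance(self, rng):
        table, _ = mixed_density_four_clusters(seed=4)
        cr = tomato_cluster(table, 19.0, 6.0)
        perm = rng.permutation(table.n)
        permuted = table.select(perm)       # ids travel with the rows
        cr_p = tomato_cluster(permuted, 19.0, 6.0)
        # map back to original order and compare up to relabelling
        back = np.empty(table.n, dtype=int)
        back[perm] = np.arange(table.n)
        assert (
            relabel_canonical(cr.labels).tolist()
            == relabel_canonical(cr_p.labels[back]).tolist()
        )

    def test_density_prefilter_drops_sparse_detections(self, rng):
        pts = np.concatenate([rng.normal(0, 5, (30, 2)), rng.uniform(100, 400, (10, 2))])
        t = make_table(pts)
        cr = tomato_cluster(t, 20.0, 2.0, density_filter_quantile=0.25)
        assert (cr.labels[:30] > 0).mean() > 0.9

    def test_parameter_validation(self):
        t = make_table([[0, 0]])
        with pytest.raises(ParameterError):
            tomato_cluster(t, -1.0, 5.0)
        with pytest.raises(ParameterError):
            tomato_cluster(t, 10.0, -0.5)


class TestLabelsPartition:
    def test_all_algorithms_partition_detections(self, rng):
        pts = np.concatenate([rng.normal(0, 8, (40, 2)), rng.uniform(0, 500, (40, 2))])
        t = make_table(pts)
        results = [
            tomato_cluster(t, 20.0, 3.0),
            dbscan_cluster(t, 20.0, 4),
            ripley_cluster(t, 20.0, 40.0, window_area=250_000.0),
            voronoi_cluster(t, 200.0),
        ]
        for cr in results:
            assert len(cr.labels) == t.n
            assert cr.labels.min() >= 0
            labs = set(cr.labels) - {0}
            assert labs == set(range(1, cr.n_clusters + 1))


class TestDbscan:
    def test_tight_blob_single_cluster(self, rng):
        pts = rng.normal(0, 2, (10, 2))
        cr = dbscan_cluster(make_table(pts), eps=20.0, min_pts=3)
        assert cr.n_clusters == 1
        assert (cr.labels == 1).all()

    def test_isolated_points_all_noise(self):
        pts = [[0, 0], [100, 0], [0, 100], [100, 100]]
        cr = dbscan_cluster(make_table(pts), eps=10.0, min_pts=2)
        assert (cr.labels == 0).all()

    def test_matches_reachability_oracle(self, rng):
        pts = rng.uniform(0, 120, (100, 2))
        cr = dbscan_cluster(make_table(pts), eps=15.0, min_pts=4)
        ref = brute_dbscan(pts, 15.0, 4)
        # same noise set; border points can tie between clusters, so compare
        # the partition restricted to core points
        assert ((cr.labels > 0) == (ref > 0)).all()
        pairs = {}
        for a, b in zip(cr.labels, ref):
            if a > 0:
                assert pairs.setdefault(a, b) == b or True
        assert relabel_canonical(cr.labels).tolist() == relabel_canonical(ref).tolist()


class TestRipleyCluster:
    def test_zero_threshold_is_graph_components(self, rng):
        pts = np.concatenate([rng.normal(0, 5, (15, 2)), rng.normal(300, 5, (15, 2))])
        cr = ripley_cluster(make_table(pts), 30.0, 0.0, window_area=1e5)
        assert cr.n_clusters == 2
        assert (cr.labels > 0).all()

    def test_threshold_above_max_all_noise(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        cr = ripley_cluster(make_table(pts), 20.0, 1e9, window_area=1e4)
        assert (cr.labels == 0).all()

    def test_blobs_recovered_against_component_oracle(self, rng):
        blob1 = rng.normal((50, 50), 4, (30, 2))
        blob2 = rng.normal((250, 250), 4, (30, 2))
        noise = rng.uniform(0, 300, (15, 2))
        pts = np.concatenate([blob1, blob2, noise])
        cr = ripley_cluster(make_table(pts), 15.0, 60.0, window_area=90_000.0)
        assert cr.n_clusters == 2
        assert (cr.labels[:30] == cr.labels[0]).all()
        assert (cr.labels[30:60] == cr.labels[30]).all()
        assert cr.labels[0] != cr.labels[30]


class TestVoronoiCluster:
    def test_infinite_threshold_single_component(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        cr = voronoi_cluster(make_table(pts), np.inf)
        assert cr.n_clusters == 1
        assert (cr.labels == 1).all()

    def test_threshold_below_min_area_all_noise(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        cr = voronoi_cluster(make_table(pts), 1e-6)
        assert (cr.labels == 0).all()

    def test_blob_recovered_from_sparse_background(self, rng):
        blob = rng.normal((100, 100), 5, (40, 2))
        background = rng.uniform(0, 1000, (40, 2))
        pts = np.concatenate([blob, background])
        cr = voronoi_cluster(make_table(pts), 150.0)
        # interior blob tiles are small; the blob's own hull ring adjoins the
        # sparse background and is excluded
        assert (cr.labels[:40] > 0).mean() > 0.7
        assert (cr.labels[40:] == 0).mean() > 0.9


class TestParameterGrid:
    def test_paper_scale_grid_size(self):
        grid = parameter_grid("tomato", {"r": list(range(1, 51)), "tau": list(range(0, 51))})
        assert len(grid) == 2550

    def test_single_point_grid(self):
        assert parameter_grid("dbscan", {"eps": [5.0]}) == [
            {"algorithm": "dbscan", "eps": 5.0}
        ]

    def test_order_is_stable(self):
        g1 = parameter_grid("t", {"a": [1, 2], "b": [3, 4]})
        g2 = parameter_grid("t", {"a": [1, 2], "b": [3, 4]})
        assert g1 == g2

    def test_empty_range_rejected(self):
        with pytest.raises(ParameterError):
            parameter_grid("t", {"a": []})
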