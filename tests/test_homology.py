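"""Rips persistence, thresholded configurations and the sub-sampled consensus."""

import numpy as np
import pytest

from toposmlm import (
    TopoConfiguration,
    TopologySettings,
    per_cluster_topology,
    rips_persistence,
    sampling_weights,
    subsample_consensus,
    threshold_diagram,
    tomato_cluster,
)
from toposmlm.clustering import ClusterResult
from toposmlm.errors import DataError, ParameterError
from toposmlm.homology import diagram_histogram
from toposmlm.pipeline import hexagon_points, two_circles_points

from _oracles import brute_persistence
from conftest import make_table


def canon(bars):
    return sorted(
        (int(d), round(float(b), 9), round(float(dd), 9) if np.isfinite(dd) else np.inf)
        for d, b, dd in bars
    )


class TestRipsPersistence:
    def test_two_points_merge_at_their_distance(self):
        diag = rips_persistence(np.array([[0.0, 0.0], [7.0, 0.0]]), max_scale=20.0)
        h0 = diag.by_dim(0)
        assert canon([(0, b, d) for _, b, d in h0[["dim", "birth", "death"]]]) == [
            (0, 0.0, 7.0),
            (0, 0.0, np.inf),
        ]
        assert len(diag.by_dim(1)) == 0

    def test_hexagon_hole_birth_and_death(self):
        diag = rips_persistence(hexagon_points(10.0), max_dim=2)
        h1 = diag.by_dim(1)
        assert len(h1) == 1
        assert h1["birth"][0] == pytest.approx(10.0)
        assert h1["death"][0] == pytest.approx(10.0 * np.sqrt(3))

    def test_two_circles_have_two_significant_holes(self):
        diag = rips_persistence(two_circles_points(), max_scale=60.0, max_dim=2)
        cfg = threshold_diagram(diag, 15.0)
        assert cfg.holes == 2

    @pytest.mark.parametrize("dim,max_dim", [(2, 2), (3, 3)])
    def test_matches_boundary_matrix_oracle(self, dim, max_dim, rng):
        for _ in range(8):
            n = int(rng.integers(4, 13))
            pts = rng.uniform(0, 50, (n, dim))
            max_scale = float(rng.uniform(20, 80))
            prod = rips_persistence(pts, max_scale=max_scale, max_dim=max_dim)
            mine = canon([(f["dim"], f["birth"], f["death"]) for f in prod.features])
            ref = canon(brute_persistence(pts, max_scale, max_dim))
            assert mine == ref

    def test_scale_equivariance(self, rng):
        pts = rng.uniform(0, 40, (10, 2))
        d1 = rips_persistence(pts, max_scale=100.0)
        d2 = rips_persistence(pts * 3.0, max_scale=300.0)
        b1 = canon([(f["dim"], f["birth"], f["death"]) for f in d1.features])
        b2 = canon([(f["dim"], 3 * f["birth"], 3 * f["death"]) for f in d2.features])
        # compare scaled: multiply d1 by 3 instead to avoid rounding asymmetry
        b1x = canon([(d, 3 * b, 3 * dd if np.isfinite(dd) else np.inf) for d, b, dd in b1])
        b2x = canon(
            [(f["dim"], f["birth"], f["death"]) for f in d2.features]
        )
        assert len(b1x) == len(b2x)
        for (da, ba, dda), (db, bb, ddb) in zip(b1x, b2x):
            assert da == db
            assert ba == pytest.approx(bb, abs=1e-6)
            if np.isfinite(dda) or np.isfinite(ddb):
                assert dda == pytest.approx(ddb, abs=1e-6)

    def test_death_at_least_birth_everywhere(self, rng):
        pts = rng.uniform(0, 60, (25, 2))
        diag = rips_persistence(pts, max_dim=2)
        finite = np.isfinite(diag.features["death"])
        assert (diag.features["death"][finite] >= diag.features["birth"][finite]).all()

    def test_sphere_has_a_void_in_3d(self, rng):
        # vertices of an icosahedron-ish sampling: random points on a sphere
        v = rng.normal(size=(40, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        diag = rips_persistence(60.0 * v, max_dim=3)
        cfg = threshold_diagram(diag, 25.0)
        assert cfg.voids >= 1

    def test_rejects_unsupported_dimension(self):
        with pytest.raises(ParameterError):
            rips_persistence(np.zeros((3, 2)), max_dim=4)


class TestThresholdDiagram:
    def test_empty_diagram_counts_zero(self):
        diag = rips_persistence(np.array([[0.0, 0.0]]), max_scale=10.0)
        assert threshold_diagram(diag, 5.0).counts == (0,)

    def test_hexagon_hole_below_threshold_not_counted(self):
        diag = rips_persistence(hexagon_points(10.0), max_dim=2)
        assert threshold_diagram(diag, 15.0).holes == 0   # persistence ~7.32
        assert threshold_diagram(diag, 5.0).holes == 1

    def test_essential_features_always_persist(self):
        # truncating the filtration below the death scale leaves the hole open
        diag = rips_persistence(hexagon_points(10.0), max_scale=12.0, max_dim=2)
        assert threshold_diagram(diag, 1e9).holes == 1


class TestSamplingWeights:
    def test_exponential_form(self):
        raw = sampling_weights(np.array([0.0, 0.5, 1.0]), mu=2.3, normalize=False)
        assert raw[0] == pytest.approx(1.0)
        assert raw[1] == pytest.approx(np.exp(-1.15))
        assert raw[2] == pytest.approx(0.1, abs=1e-3)   # mu = 2.3 rounds -ln 0.1

    def test_ten_to_one_ratio_at_default_mu(self):
        raw = sampling_weights(np.array([12.0, 40.0]), mu=-np.log(0.1), normalize=False)
        assert raw[0] / raw[1] == pytest.approx(10.0)

    def test_equal_uncertainties_uniform(self):
        p = sampling_weights(np.array([7.0, 7.0, 7.0]))
        assert np.allclose(p, 1 / 3)

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(DataError):
            sampling_weights(np.array([-1.0, 2.0]))


class TestConsensus:
    def test_single_resample_is_its_own_consensus(self, rng):
        pts = rng.uniform(0, 30, (12, 2))
        res = subsample_consensus(pts, None, 5.0, n_resamples=1, rng=rng)
        assert res.alpha == 100.0
        assert sum(res.configurations.values()) == 1

    def test_dense_ring_hole_stable_under_resampling(self):
        a = 2 * np.pi * np.arange(80) / 80
        jitter = np.random.default_rng(0).normal(0, 1.0, (80, 2))
        pts = np.stack([60 * np.cos(a), 60 * np.sin(a)], axis=1) + jitter
        res = subsample_consensus(
            pts, None, 15.0, n_resamples=50, rng=np.random.default_rng(1)
        )
        assert res.consensus == TopoConfiguration((1,))
        assert res.alpha > 90.0

    def test_reproducible_with_fixed_seed(self, rng):
        pts = rng.uniform(0, 50, (20, 2))
        unc = rng.uniform(5, 30, 20)
        r1 = subsample_consensus(pts, unc, 10.0, n_resamples=20, rng=np.random.default_rng(5))
        r2 = subsample_consensus(pts, unc, 10.0, n_resamples=20, rng=np.random.default_rng(5))
        assert r1.consensus == r2.consensus
        assert r1.alpha == r2.alpha
        assert r1.configurations == r2.configurations

    def test_tie_breaks_toward_simpler_configuration(self):
        assert TopoConfiguration((0,)) < TopoConfiguration((1,))
        assert TopoConfiguration((1,)) < TopoConfiguration((2,))
        assert TopoConfiguration((1, 0)) < TopoConfiguration((0, 2))


class TestPerClusterTopology:
    def _ring_table(self, seed=3):
        rng = np.random.default_rng(seed)
        a = 2 * np.pi * np.arange(70) / 70
        ring = np.stack([60 * np.cos(a) + 300, 60 * np.sin(a) + 300], axis=1)
        ring = ring + rng.normal(0, 2, ring.shape)
        blob = rng.normal((800.0, 800.0), 15.0, (50, 2))
        tiny = np.array([[50.0, 50.0], [52.0, 50.0]])
        pts = np.concatenate([ring, blob, tiny])
        labels = np.concatenate([np.full(70, 1), np.full(50, 2), np.full(2, 3)])
        t = make_table(pts, uncertainty=rng.uniform(5, 20, len(pts)))
        return t, ClusterResult(labels, {})

    def test_ring_and_blob_configurations(self, rng):
        t, cr = self._ring_table()
        settings = TopologySettings(pers_threshold=15.0, n_resamples=30)
        results, skipped = per_cluster_topology(t, cr, settings, rng=rng)
        assert results[1].consensus.consensus == TopoConfiguration((1,))
        assert results[2].consensus.consensus == TopoConfiguration((0,))
        assert 3 in skipped and "size" in skipped[3]

    def test_noise_label_never_analyzed(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        cr = ClusterResult(np.zeros(30, dtype=int), {})
        results, skipped = per_cluster_topology(make_table(pts), cr, rng=rng)
        assert results == {} and skipped == {}

    def test_h0_diagnostic_counts_one_component(self, rng):
        t, cr = self._ring_table()
        settings = TopologySettings(pers_threshold=15.0, n_resamples=5)
        results, _ = per_cluster_topology(t, cr, settings, rng=rng)
        assert results[2].n_components_full == 1


class TestDiagramHistogram:
    def test_bins_are_unit_squares(self):
        diag = rips_persistence(two_circles_points(), max_scale=60.0, max_dim=2)
        counts, be, de = diagram_histogram(diag, dim=1, bin_size=1.0)
        assert np.allclose(np.diff(be), 1.0)
        h1 = diag.by_dim(1)
        finite = np.isfinite(h1["death"])
        assert counts.sum() == finite.sum()
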