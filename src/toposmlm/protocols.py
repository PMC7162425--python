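"""Standard study protocols: the synthetic experiments the package reproduces.

Each function wires the simulator, the clustering stage and the topology
stage together under fixed, documented conditions so that the same
experiment can be run from the CLI, the test-suite or a script:

* ``ring_recovery`` — ring clusters (radius 60 nm) under the default
  photophysics; ToMATo segmentation; sub-sampled persistent homology at a
  15 nm persistence threshold; radial profile of the clusters that pass the
  single-hole, agreement>90% filter.
* ``csr_robustness`` — the identical pipeline on a completely spatially
  random field; counts clusters that (spuriously) pass the same filter.
* ``two_circles_demo`` — the evenly-spaced two-circles illustration;
  counts H1 features above the persistence threshold.
* ``simulator_calibration`` — empirical noise fraction, blink detection
  rate and fluorophores per molecule on a large simulated population.
* ``separation_benchmark`` — Gaussian cluster pairs at a given centre
  separation; ToMATo vs DBSCAN, local-Ripley and Voronoi clustering over
  fixed parameter grids; maximal mean percent-correct per algorithm.

Problem sizes are kept at desk scale (a few clusters, a few reps); see the
methods notes for the rationale behind each default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis_stats import (
    AlgorithmSpec,
    DbscanSpec,
    RipleySpec,
    TomatoSpec,
    VoronoiSpec,
    benchmark,
    best_performance,
    filter_clusters_by_topology,
    radial_profile,
)
from .clustering import tomato_cluster
from .homology import (
    TopoConfiguration,
    TopologySettings,
    per_cluster_topology,
    rips_persistence,
    threshold_diagram,
)
from .pipeline import substream, two_circles_points
from .simulator import (
    PhotophysicsConfig,
    ScenarioConfig,
    generate_benchmark_suite,
    place_molecules,
    simulate_detections,
    simulate_scenario,
)

#: segmentation defaults for the topology protocols (search radius / persistence
#: threshold in detections).  For ring-shaped structures the density modes
#: along the circumference are sampling artifacts, so the persistence
#: threshold is set high enough that each connected structure is one cluster.
RING_TOMATO_R = 25.0
RING_TOMATO_TAU = 35.0
PERS_THRESHOLD_NM = 15.0


@dataclass
class RingRecoveryResult:
    peak_nm: float | None
    n_selected: int
    n_clusters_analyzed: int
    profile: object | None
    topology: dict


def _ring_scenario(n_rings: int) -> ScenarioConfig:
    return ScenarioConfig(
        kind="ring",
        field_size=(2000.0, 2000.0),
        n_clusters=n_rings,
        molecules_per_cluster=16,
        ring_radius=60.0,
        placement="grid",
    )


def _topology_settings() -> TopologySettings:
    # max_scale 90 nm: well above the death scale of a 60 nm ring's hole
    # (~sqrt(3) * inner-hole radius); features outliving it count as persistent
    return TopologySettings(pers_threshold=PERS_THRESHOLD_NM, max_scale=90.0)


def ring_recovery(seed: int, n_rings: int = 12, bin_width: float = 5.0) -> RingRecoveryResult:
    """Ring simulation -> ToMATo -> consensus topology -> radial profile peak."""
    table, _truth = simulate_scenario(
        _ring_scenario(n_rings), PhotophysicsConfig(), substream(seed, "simulate")
    )
    cr = tomato_cluster(table, RING_TOMATO_R, RING_TOMATO_TAU)
    topo, _ = per_cluster_topology(
        table, cr, _topology_settings(), rng=substream(seed, "resample")
    )
    selected = filter_clusters_by_topology(topo, TopoConfiguration((1,)), min_alpha=90.0)
    if not selected:
        return RingRecoveryResult(None, 0, len(topo), None, topo)
    pts = [table.coords[cr.labels == lab] for lab in selected]
    prof = radial_profile(pts, bin_width=bin_width)
    return RingRecoveryResult(prof.peak, len(selected), len(topo), prof, topo)


def csr_robustness(seed: int, n_molecules: int = 300) -> tuple[int, int]:
    """CSR field through the identical pipeline.

    Returns (number of clusters passing the >=1-hole, agreement>90% filter —
    expected 0 —, number of clusters analyzed).
    """
    sc = ScenarioConfig(kind="csr", field_size=(2000.0, 2000.0), n_molecules=n_molecules)
    table, _ = simulate_scenario(sc, PhotophysicsConfig(), substream(seed, "simulate"))
    cr = tomato_cluster(table, RING_TOMATO_R, RING_TOMATO_TAU)
    topo, _ = per_cluster_topology(
        table, cr, _topology_settings(), rng=substream(seed, "resample")
    )
    with_holes = [
        lab
        for lab, ct in topo.items()
        if ct.consensus.consensus.holes >= 1 and ct.consensus.alpha > 90.0
    ]
    return len(with_holes), len(topo)


def two_circles_demo(pers_threshold: float = 15.0) -> int:
    """H1 features above the persistence threshold for the two-circles cloud
    (filtration over scales up to 60 a.u.)."""
    diag = rips_persistence(two_circles_points(), max_scale=60.0, max_dim=2)
    return threshold_diagram(diag, pers_threshold).holes


def simulator_calibration(seed: int, n_molecules: int = 10_000) -> dict[str, float]:
    """Empirical photophysics rates on a large CSR population.

    Returns percentages for the noise fraction and blink detection rate, the
    mean fluorophore count per molecule, and 1-standard-error values for each.
    """
    side = float(np.ceil(np.sqrt(n_molecules)) * 200.0)  # keep density realistic
    sc = ScenarioConfig(kind="csr", field_size=(side, side), n_molecules=n_molecules)
    rng = substream(seed, "simulate")
    mols, labels = place_molecules(sc, rng)
    table, truth = simulate_detections(mols, labels, PhotophysicsConfig(), sc.field_size, rng)

    n_noise = int((truth.molecule_id == -1).sum())
    n_total = table.n
    noise_frac = n_noise / n_total
    blinks = truth.stats["total_blinks"]
    detected = truth.stats["detected_blinks"]
    det_rate = detected / blinks
    fluors = truth.stats["fluors_per_molecule"]
    mean_fluors = float(np.mean(fluors))
    return {
        "noise_pct": 100.0 * noise_frac,
        "noise_pct_se": 100.0 * np.sqrt(noise_frac * (1 - noise_frac) / n_total),
        "detection_rate_pct": 100.0 * det_rate,
        "detection_rate_pct_se": 100.0 * np.sqrt(det_rate * (1 - det_rate) / blinks),
        "mean_fluors": mean_fluors,
        "mean_fluors_se": float(np.std(fluors, ddof=1) / np.sqrt(len(fluors))),
        "n_detections": n_total,
        "n_blinks": blinks,
    }


# ---------------------------------------------------------------------------
# separation benchmark
# ---------------------------------------------------------------------------

#: benchmark scenario: 4 well-separated pairs of Gaussian clusters per field
PAIR_ANCHORS = ((500.0, 500.0), (1500.0, 500.0), (500.0, 1500.0), (1500.0, 1500.0))
PAIR_FIELD = (2000.0, 2000.0)
PAIR_CLUSTER_SD = 10.0
PAIR_MOLECULES = 15

#: parameter grids, fixed across separations (radii/eps in nm; tau/min_pts in
#: detections; Ripley thresholds in nm of L score; tile areas in nm^2)
GRID_TOMATO_R = (5.0, 10.0, 15.0, 20.0, 25.0)
GRID_TOMATO_TAU = (2.0, 5.0, 10.0, 15.0, 25.0)
GRID_DBSCAN_EPS = (5.0, 10.0, 15.0, 20.0, 25.0)
GRID_DBSCAN_MINPTS = (3, 5, 10, 15, 25)
GRID_RIPLEY_R = (5.0, 10.0, 15.0, 20.0, 25.0)
GRID_RIPLEY_L = (20.0, 40.0, 80.0, 160.0, 240.0)
GRID_VORONOI_AREA = (25.0, 50.0, 100.0, 200.0, 400.0)


def pair_scenario(separation: float) -> ScenarioConfig:
    """Gaussian cluster pairs at the requested centre separation (nm)."""
    centers = []
    for ax, ay in PAIR_ANCHORS:
        centers.append((ax - separation / 2.0, ay))
        centers.append((ax + separation / 2.0, ay))
    return ScenarioConfig(
        kind="gaussian",
        field_size=PAIR_FIELD,
        n_clusters=len(centers),
        molecules_per_cluster=PAIR_MOLECULES,
        cluster_sd=PAIR_CLUSTER_SD,
        centers=tuple(centers),
    )


def default_algorithm_specs() -> list[AlgorithmSpec]:
    area = float(PAIR_FIELD[0] * PAIR_FIELD[1])
    return [
        TomatoSpec(GRID_TOMATO_R, GRID_TOMATO_TAU),
        DbscanSpec(GRID_DBSCAN_EPS, GRID_DBSCAN_MINPTS),
        RipleySpec(GRID_RIPLEY_R, GRID_RIPLEY_L, window_area=area),
        VoronoiSpec(GRID_VORONOI_AREA),
    ]


def separation_benchmark(
    separation: float, reps: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark all four algorithms on the pair scenario.

    Returns (tidy per-run results, best mean performance per algorithm).
    """
    suite = generate_benchmark_suite(
        [pair_scenario(separation)], reps, PhotophysicsConfig(), seed
    )
    results = benchmark(suite, default_algorithm_specs())
    return results, best_performance(results)


def tomato_advantage(best: pd.DataFrame) -> float:
    """ToMATo's margin (percentage points) over the best competing algorithm."""
    by_alg = best.set_index("algorithm")["best_mean_percent_correct"]
    baselines = by_alg.drop("tomato")
    return float(by_alg["tomato"] - baselines.max())
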