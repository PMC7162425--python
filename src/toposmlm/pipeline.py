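"""End-to-end pipelines, configuration and fixture generation.

A :class:`PipelineConfig` describes every stage of the analysis: the input
(a detection table on disk, or a simulation scenario), the pre-processing
filters, the clustering algorithm, the per-cluster topology settings and
the downstream statistics.  ``run_pipeline`` executes the stages in order,
writing plain CSV outputs plus a JSON run manifest that records every
parameter and the master seed, so a run can be reproduced exactly.

Randomness is organised as named sub-streams derived from the master seed
(``simulate`` and ``resample``), so stages can be re-run independently with
identical draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering
from .analysis_stats import cluster_stats, filter_clusters_by_topology, radial_profile
from .clustering import ClusterResult, tomato_diagram
from .core_data import (
    DetectionTable,
    filter_by_intensity,
    link_consecutive_frames,
    read_detections,
    write_detections,
)
from .errors import ConfigurationError
from .homology import TopoConfiguration, TopologySettings, per_cluster_topology
from .simulator import PhotophysicsConfig, ScenarioConfig, simulate_scenario

log = logging.getLogger("toposmlm")

_STREAMS = {"simulate": 0, "resample": 1}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class PipelineConfig:
    """Full description of one analysis run (round-trips through YAML)."""

    seed: int = 0
    output_dir: str = "toposmlm_output"
    # input: either a file or a simulation scenario
    input_path: str | None = None
    scenario: dict | None = None          # ScenarioConfig fields
    photophysics: dict = field(default_factory=dict)  # PhotophysicsConfig overrides
    # pre-processing
    min_photons: float | None = None
    link_max_dist: float | None = None
    # clustering
    algorithm: str = "tomato"
    cluster_params: dict = field(default_factory=lambda: {"r": 20.0, "tau": 10.0})
    # topology
    run_topology: bool = True
    topology: dict = field(default_factory=dict)      # TopologySettings overrides
    # downstream
    radial_bin_width: float = 5.0
    radial_min_alpha: float = 90.0
    radial_want_holes: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """Paths of everything a run produced, plus the in-memory objects."""

    output_dir: Path
    table: DetectionTable
    cluster_result: ClusterResult
    topology: dict | None
    outputs: dict[str, Path]


_ALGORITHMS = {
    "tomato": clustering.tomato_cluster,
    "dbscan": clustering.dbscan_cluster,
    "ripley": clustering.ripley_cluster,
    "voronoi": clustering.voronoi_cluster,
}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages; outputs are flushed per stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name: str, **params):
        log.info("stage %s: %s", name, params)
        manifest["stages"].append({"stage": name, **params})
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    # ---- input ----
    if config.input_path is not None:
        table = read_detections(config.input_path)
        stage("read", path=str(config.input_path), n=table.n)
        truth = None
    elif config.scenario is not None:
        sc = ScenarioConfig(**config.scenario)
        pc = PhotophysicsConfig(**config.photophysics)
        table, truth = simulate_scenario(sc, pc, substream(config.seed, "simulate"))
        stage("simulate", scenario=config.scenario, n=table.n)
        truth.to_dataframe().to_csv(out / "ground_truth.csv", index=False)
        outputs["ground_truth"] = out / "ground_truth.csv"
    else:
        raise ConfigurationError("config needs input_path or scenario")

    # ---- pre-processing ----
    if config.min_photons is not None:
        table = filter_by_intensity(table, config.min_photons)
        stage("filter_by_intensity", min_photons=config.min_photons, n=table.n)
    if config.link_max_dist is not None:
        table = link_consecutive_frames(table, config.link_max_dist)
        stage("link_consecutive_frames", max_dist=config.link_max_dist, n=table.n)

    # ---- clustering ----
    try:
        cluster_fn = _ALGORITHMS[config.algorithm]
    except KeyError:
        raise ConfigurationError(f"unknown algorithm {config.algorithm!r}") from None
    cr = cluster_fn(table, **config.cluster_params)
    stage("cluster", algorithm=config.algorithm, params=config.cluster_params,
          n_clusters=cr.n_clusters)
    write_detections(table, out / "detections_labeled.csv", labels=cr.labels)
    outputs["detections_labeled"] = out / "detections_labeled.csv"
    if cr.diagram is not None:
        births, deaths, _ = tomato_diagram(cr)
        pd.DataFrame({"birth": births, "death": deaths}).to_csv(
            out / "tomato_diagram.csv", index=False
        )
        outputs["tomato_diagram"] = out / "tomato_diagram.csv"

    # ---- topology ----
    topo = None
    if config.run_topology:
        settings = TopologySettings(**config.topology)
        topo, skipped = per_cluster_topology(
            table, cr, settings, rng=substream(config.seed, "resample")
        )
        rows = [
            {
                "label": ct.label,
                "n_detections": ct.n_detections,
                "holes_full": ct.full_config.holes,
                "holes_consensus": ct.consensus.consensus.holes,
                "voids_consensus": ct.consensus.consensus.voids,
                "alpha": ct.consensus.alpha,
            }
            for ct in topo.values()
        ]
        pd.DataFrame(rows).to_csv(out / "topology.csv", index=False)
        outputs["topology"] = out / "topology.csv"
        stage("topology", settings=asdict(settings), n_analyzed=len(topo),
              n_skipped=len(skipped))

        # radial profile of clusters passing the topology filter
        want_dims = 1 if table.dim == 2 else 2
        want = TopoConfiguration(
            (config.radial_want_holes,) + ((0,) if want_dims == 2 else ())
        )
        selected = filter_clusters_by_topology(topo, want, config.radial_min_alpha)
        if selected:
            pts = [table.coords[cr.labels == lab] for lab in selected]
            prof = radial_profile(pts, bin_width=config.radial_bin_width)
            pd.DataFrame(
                {"bin_center": prof.bin_centers, "frequency": prof.frequency}
            ).to_csv(out / "radial_profile.csv", index=False)
            outputs["radial_profile"] = out / "radial_profile.csv"
            stage("radial", n_selected=len(selected), peak=prof.peak)
        else:
            stage("radial", n_selected=0)

    # ---- cluster statistics ----
    span = table.coords.max(axis=0) - table.coords.min(axis=0)
    field_area = float(np.prod(span)) if np.all(span > 0) else 1.0
    if cr.n_clusters:
        stats = cluster_stats(table, cr, field_area)
        stats.per_cluster.to_csv(out / "cluster_stats.csv", index=False)
        outputs["cluster_stats"] = out / "cluster_stats.csv"
        stage("stats", n_clusters=stats.n_clusters, mean_area=stats.mean_area)

    return PipelineResult(out, table, cr, topo, outputs)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def two_circles_points(
    n_small: int = 16, n_large: int = 24, r_small: float = 15.0, r_large: float = 25.0,
    separation: float = 80.0,
) -> np.ndarray:
    """The evenly-spaced two-circles illustration (arbitrary units)."""
    a = 2 * np.pi * np.arange(n_small) / n_small
    b = 2 * np.pi * np.arange(n_large) / n_large
    small = np.stack([r_small * np.cos(a), r_small * np.sin(a)], axis=1)
    large = np.stack([r_large * np.cos(b) + separation, r_large * np.sin(b)], axis=1)
    return np.concatenate([small, large])


def hexagon_points(circumradius: float = 10.0) -> np.ndarray:
    a = 2 * np.pi * np.arange(6) / 6
    return np.stack([circumradius * np.cos(a), circumradius * np.sin(a)], axis=1)


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write small deterministic test datasets (each well under 500 detections)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, table: DetectionTable, truth=None):
        p = out / f"{name}.csv"
        write_detections(table, p)
        paths[name] = p
        if truth is not None:
            tp = out / f"{name}_truth.csv"
            truth.to_dataframe().to_csv(tp, index=False)
            paths[f"{name}_truth"] = tp

    save("two_circles", DetectionTable.from_arrays(two_circles_points()))
    save("hexagon", DetectionTable.from_arrays(hexagon_points()))

    pc = PhotophysicsConfig()
    small_field = (1000.0, 1000.0)
    scenarios = {
        "mini_csr": ScenarioConfig("csr", small_field, n_molecules=60),
        "mini_gaussian": ScenarioConfig(
            "gaussian", small_field, n_clusters=3, molecules_per_cluster=10, cluster_sd=15.0
        ),
        "mini_ring": ScenarioConfig(
            "ring", small_field, n_clusters=2, molecules_per_cluster=12, ring_radius=60.0
        ),
    }
    for i, (name, sc) in enumerate(sorted(scenarios.items())):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100 + i,)))
        table, truth = simulate_scenario(sc, pc, rng)
        save(name, table, truth)
    return paths
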