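"""Synthetic dSTORM point-cloud generator with ground truth.

Molecules are placed in a 2D or 3D field according to a scenario (complete
spatial randomness, isotropic Gaussian clusters, or circular rings with
molecules evenly spaced on the circumference).  Photophysics then turns each
molecule into detections:

* each molecule carries ``Poisson(mean_fluors_per_molecule)`` fluorophores
  (labelling stochasticity; molecules may receive none and stay dark);
* each fluorophore blinks ``Geometric(p_dark)`` times (support 1, 2, ...;
  mean ``1/p_dark``), modelling the chance of photoswitching to the dark
  state after every emission burst;
* each blink is detected with probability ``detection_rate``;
* a detected blink becomes a detection at the molecule position plus
  isotropic normal error with SD drawn per event from
  ``LogNormal(uncertainty_meanlog, uncertainty_sdlog)`` (nm); the draw is
  also reported as the detection's localization uncertainty;
* finally uniformly distributed false detections are appended so that they
  make up ``noise_fraction`` of the table.

Every detection keeps its generating molecule and cluster in a parallel
:class:`GroundTruth` object so segmentation algorithms can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DetectionTable
from .errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class PhotophysicsConfig:
    """Blinking / detection model parameters (defaults: AlexaFluor647-like dSTORM)."""

    p_dark: float = 0.5
    mean_fluors_per_molecule: float = 5.0
    uncertainty_meanlog: float = 2.8
    uncertainty_sdlog: float = 0.28
    detection_rate: float = 0.70
    noise_fraction: float = 0.10
    frames: int = 10_000
    intensity_meanlog: float = math.log(1500.0)
    intensity_sdlog: float = 0.5

    def __post_init__(self):
        for name in ("p_dark", "detection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.p_dark == 0.0:
            raise ConfigurationError("p_dark must be > 0 (blink counts are geometric)")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ConfigurationError("noise_fraction must be in [0, 1)")
        if not (np.isfinite(self.uncertainty_meanlog) and np.isfinite(self.uncertainty_sdlog)):
            raise ConfigurationError("log-normal uncertainty parameters must be finite")


@dataclass(frozen=True)
class ScenarioConfig:
    """Molecule-placement scenario.

    ``kind`` is one of ``csr``, ``gaussian``, ``ring`` or ``gaussian-pair``
    (Gaussian clusters placed in pairs separated by ``pair_separation`` nm).
    ``field_size`` is the side length per axis in nm (2 or 3 entries).
    """

    kind: str
    field_size: tuple[float, ...] = (2000.0, 2000.0)
    n_molecules: int = 100            # csr
    n_clusters: int = 4               # gaussian / ring / gaussian-pair (pairs: must be even)
    molecules_per_cluster: int = 15
    cluster_sd: float = 10.0          # gaussian
    ring_radius: float = 60.0         # ring
    centers: tuple[tuple[float, ...], ...] | None = None
    placement: str = "random"         # random | grid | pair
    pair_separation: float | None = None
    ring_orientation: str = "xy"      # xy | random (3D only)
    margin: float | None = None       # keep-out border for random centres

    def __post_init__(self):
        if self.kind not in ("csr", "gaussian", "ring", "gaussian-pair"):
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")
        if len(self.field_size) not in (2, 3) or any(s <= 0 for s in self.field_size):
            raise ConfigurationError("field_size must be 2 or 3 positive lengths")
        if self.cluster_sd <= 0 or self.ring_radius <= 0:
            raise ConfigurationError("cluster_sd and ring_radius must be > 0")
        if self.kind == "gaussian-pair" and self.pair_separation is None:
            raise ConfigurationError("gaussian-pair requires pair_separation")

    @property
    def dim(self) -> int:
        return len(self.field_size)


@dataclass
class GroundTruth:
    """Per-detection provenance emitted by the simulator.

    ``true_label`` is 0 for false (noise) detections, otherwise the cluster
    label of the generating molecule.  ``molecule_id`` is −1 for noise.
    """

    true_label: np.ndarray
    molecule_id: np.ndarray
    molecule_positions: np.ndarray
    molecule_labels: np.ndarray
    stats: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": np.arange(len(self.true_label)),
             "true_label": self.true_label,
             "molecule_id": self.molecule_id}
        )


# ---------------------------------------------------------------------------
# molecule placement
# ---------------------------------------------------------------------------

def _random_centers(sc: ScenarioConfig, n: int, margin: float, rng: np.random.Generator) -> np.ndarray:
    lo = np.full(sc.dim, margin)
    hi = np.asarray(sc.field_size) - margin
    if np.any(hi <= lo):
        raise ConfigurationError("field too small for the requested margin")
    return rng.uniform(lo, hi, size=(n, sc.dim))


def _grid_centers(sc: ScenarioConfig, n: int) -> np.ndarray:
    per_axis = int(np.ceil(n ** (1.0 / sc.dim)))
    axes = [np.linspace(s / (per_axis + 1), s * per_axis / (per_axis + 1), per_axis)
            for s in sc.field_size]
    mesh = np.stack([m.ravel() for m in np.meshgrid(*axes, indexing="ij")], axis=1)
    return mesh[:n]


def _cluster_centers(sc: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    extent = sc.ring_radius if sc.kind == "ring" else 3.0 * sc.cluster_sd
    margin = sc.margin if sc.margin is not None else extent + 3.0 * sc.cluster_sd
    if sc.centers is not None:
        centers = np.asarray(sc.centers, dtype=float)
        if centers.shape[1] != sc.dim:
            raise ConfigurationError("centre dimensionality does not match field")
        if np.any(centers < 0) or np.any(centers > np.asarray(sc.field_size)):
            raise ConfigurationError("cluster centre outside field")
        return centers
    if sc.kind == "gaussian-pair" or sc.placement == "pair":
        if sc.n_clusters % 2:
            raise ConfigurationError("pair placement needs an even n_clusters")
        s = float(sc.pair_separation)
        anchors = _random_centers(sc, sc.n_clusters // 2, margin + s, rng)
        theta = rng.uniform(0, 2 * np.pi, len(anchors))
        u = np.zeros((len(anchors), sc.dim))
        u[:, 0], u[:, 1] = np.cos(theta), np.sin(theta)
        return np.concatenate([anchors - u * s / 2.0, anchors + u * s / 2.0], axis=0)
    if sc.placement == "grid":
        return _grid_centers(sc, sc.n_clusters)
    return _random_centers(sc, sc.n_clusters, margin, rng)


def place_molecules(sc: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place molecules for a scenario; returns positions (m, dim) and cluster labels.

    Labels are 0 for CSR (no cluster structure) and 1..K otherwise.
    """
    if sc.kind == "csr":
        pos = rng.uniform(0, sc.field_size, size=(sc.n_molecules, sc.dim))
        return pos, np.zeros(sc.n_molecules, dtype=int)

    centers = _cluster_centers(sc, rng)
    m = sc.molecules_per_cluster
    positions, labels = [], []
    for k, c in enumerate(centers, start=1):
        if sc.kind in ("gaussian", "gaussian-pair"):
            pts = c + rng.normal(0.0, sc.cluster_sd, size=(m, sc.dim))
        else:  # ring
            phase = rng.uniform(0, 2 * np.pi)
            angles = phase + 2 * np.pi * np.arange(m) / m
            circle = np.stack(
                [sc.ring_radius * np.cos(angles), sc.ring_radius * np.sin(angles)], axis=1
            )
            if sc.dim == 3:
                circle = np.concatenate([circle, np.zeros((m, 1))], axis=1)
                if sc.ring_orientation == "random":
                    circle = circle @ _random_rotation(rng).T
            pts = c + circle
        positions.append(pts)
        labels.append(np.full(m, k, dtype=int))
    return np.concatenate(positions), np.concatenate(labels)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# ---------------------------------------------------------------------------
# photophysics
# ---------------------------------------------------------------------------

def simulate_detections(
    molecules: np.ndarray,
    molecule_labels: np.ndarray,
    pc: PhotophysicsConfig,
    field_size: tuple[float, ...],
    rng: np.random.Generator,
    shuffle: bool = True,
) -> tuple[DetectionTable, GroundTruth]:
    """Run the blinking/detection model over placed molecules.

    Returns the detection table and the aligned ground truth.  Blink-level
    bookkeeping (fluorophore counts, total and detected blink counts) is kept
    in ``GroundTruth.stats`` for calibration checks.
    """
    molecules = np.asarray(molecules, dtype=float)
    if molecules.ndim != 2 or len(molecules) == 0:
        raise ParameterError("at least one molecule is required")
    n_mol, dim = molecules.shape

    fluors = rng.poisson(pc.mean_fluors_per_molecule, n_mol)
    fluor_mol = np.repeat(np.arange(n_mol), fluors)
    blinks = rng.geometric(pc.p_dark, size=len(fluor_mol)) if len(fluor_mol) else np.zeros(0, int)
    blink_mol = np.repeat(fluor_mol, blinks)
    detected = rng.random(len(blink_mol)) < pc.detection_rate
    det_mol = blink_mol[detected]

    sigma = rng.lognormal(pc.uncertainty_meanlog, pc.uncertainty_sdlog, len(det_mol))
    pos = molecules[det_mol] + rng.normal(0.0, 1.0, (len(det_mol), dim)) * sigma[:, None]
    labels = molecule_labels[det_mol]

    nf = pc.noise_fraction
    n_noise = int(round(nf / (1.0 - nf) * len(det_mol)))
    noise_pos = rng.uniform(0, field_size, size=(n_noise, dim))
    noise_sigma = rng.lognormal(pc.uncertainty_meanlog, pc.uncertainty_sdlog, n_noise)

    all_pos = np.concatenate([pos, noise_pos])
    all_sigma = np.concatenate([sigma, noise_sigma])
    all_labels = np.concatenate([labels, np.zeros(n_noise, dtype=int)])
    all_mol = np.concatenate([det_mol, np.full(n_noise, -1)])
    n_tot = len(all_pos)
    frames = rng.integers(0, pc.frames, n_tot)
    intensity = rng.lognormal(pc.intensity_meanlog, pc.intensity_sdlog, n_tot)

    if shuffle and n_tot:
        perm = rng.permutation(n_tot)
        all_pos, all_sigma = all_pos[perm], all_sigma[perm]
        all_labels, all_mol = all_labels[perm], all_mol[perm]
        frames, intensity = frames[perm], intensity[perm]

    table = DetectionTable.from_arrays(
        all_pos, frame=frames, intensity=intensity, uncertainty=all_sigma
    )
    truth = GroundTruth(
        true_label=all_labels,
        molecule_id=all_mol,
        molecule_positions=molecules,
        molecule_labels=np.asarray(molecule_labels),
        stats={
            "n_molecules": n_mol,
            "fluors_per_molecule": fluors,
            "total_blinks": int(blinks.sum()),
            "detected_blinks": int(detected.sum()),
            "n_noise": n_noise,
        },
    )
    return table, truth


def simulate_scenario(
    sc: ScenarioConfig, pc: PhotophysicsConfig, rng: np.random.Generator
) -> tuple[DetectionTable, GroundTruth]:
    """Convenience wrapper: place molecules then run the photophysics model."""
    mols, labels = place_molecules(sc, rng)
    return simulate_detections(mols, labels, pc, sc.field_size, rng)


# ---------------------------------------------------------------------------
# benchmark suites
# ---------------------------------------------------------------------------

@dataclass
class SimulatedField:
    scenario_index: int
    rep: int
    config: ScenarioConfig
    table: DetectionTable
    truth: GroundTruth


def generate_benchmark_suite(
    scenarios: list[ScenarioConfig],
    reps: int,
    pc: PhotophysicsConfig,
    seed: int,
) -> list[SimulatedField]:
    """Simulate ``reps`` independent fields per scenario, deterministically.

    The stream for (scenario i, rep j) is derived from the master seed alone,
    so any field can be regenerated in isolation.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    fields = []
    for i, sc in enumerate(scenarios):
        for j in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, j)))
            table, truth = simulate_scenario(sc, pc, rng)
            fields.append(SimulatedField(i, j, sc, table, truth))
    return fields


def suite_manifest(fields: list[SimulatedField]) -> pd.DataFrame:
    """Tidy summary of a simulated suite for batch evaluation."""
    return pd.DataFrame(
        [
            {
                "scenario_index": f.scenario_index,
                "kind": f.config.kind,
                "rep": f.rep,
                "n_detections": f.table.n,
                "n_molecules": len(f.truth.molecule_positions),
                "n_noise": int((f.truth.molecule_id == -1).sum()),
            }
            for f in fields
        ]
    )
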