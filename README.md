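# toposmlm

Topological data analysis for single-molecule localization microscopy
(SMLM/dSTORM) point clouds: persistence-based clustering (ToMATo),
per-cluster persistent homology with an uncertainty-weighted sub-sampling
consensus, baseline clusterers for benchmarking, and a realistic dSTORM
simulator with ground truth.

## The problem

An SMLM experiment yields a table of *detections* — one localized blinking
event per row, with nanometre coordinates, a frame index, a photon count
and a localization precision. Grouping detections into clusters gives
per-cluster statistics (area, density), but clustering alone cannot tell a
filled protein cluster from a ring-shaped complex of the same size.
`toposmlm` addresses both steps:

**Segmentation.** ToMATo clusters by mode seeking on a local density
estimate *f* (by default the number of neighbours within a search radius
*r*) over the fixed-radius graph. Each density mode is a candidate cluster
with birth density *f_b* (its peak) and death density *f_d* (the saddle at
which it meets a stronger candidate); candidates with persistence
*P = f_b − f_d < τ* are merged into the neighbour they meet. Because the
merge criterion is the *prominence* of a mode rather than a global density
threshold, ToMATo separates adjacent structures even when their densities
differ — the regime where DBSCAN, Voronoi-tile and Ripley-threshold
clustering struggle.

**Topology.** For every segmented cluster a Rips filtration is built: at
scale *s* a simplex is included when all its vertices are pairwise within
*s*. Tracking homology across scales gives a persistence diagram of
(birth, death) scales per feature; features with persistence above a
threshold (15 nm throughout) are counted into the *topological
configuration* — number of holes (H1), plus enclosed voids (H2) in 3D.
Because SMLM data carries false detections and blinking artifacts, the
configuration is additionally bootstrapped: detections are resampled with
replacement with probability ∝ e^(−μw) (w = min–max-normalized
localization uncertainty, μ = −ln 0.1 ≈ 2.3, so the most precise detection
is 10× more likely to be drawn than the least precise), and the modal
configuration over resamples is reported with its agreement α (% of
resamples that return it). Filtering on the consensus (e.g. one hole,
α > 90%) is robust against noise-induced misclassification.

The persistent-homology engine (union-find for H0, GF(2) boundary-matrix
column reduction with the clearing optimisation for H1/H2) is implemented
in the package and is cross-checked in the test-suite against an
independent dense reduction on small fixtures.

## Worked example

Simulate four rings of radius 60 nm (16 molecules each, default dSTORM
photophysics: Poisson(5) fluorophores/molecule, Geometric(0.5) blinks,
70% detection rate, log-normal localization SD, 10% false detections),
segment, and run the consensus topology:

```python
import numpy as np
from toposmlm import (tomato_cluster, per_cluster_topology, TopologySettings,
                      TopoConfiguration, filter_clusters_by_topology, radial_profile)
from toposmlm.simulator import ScenarioConfig, PhotophysicsConfig, simulate_scenario
from toposmlm.pipeline import substream

sc = ScenarioConfig(kind="ring", field_size=(2000., 2000.), n_clusters=4,
                    molecules_per_cluster=16, ring_radius=60., placement="grid")
table, truth = simulate_scenario(sc, PhotophysicsConfig(), substream(1, "simulate"))
cr = tomato_cluster(table, r=25., tau=35.)
topo, _ = per_cluster_topology(table, cr,
                               TopologySettings(pers_threshold=15., max_scale=90.),
                               rng=substream(1, "resample"))
for lab, ct in sorted(topo.items()):
    print(f"cluster {lab}: n={ct.n_detections} holes={ct.consensus.consensus.holes} "
          f"alpha={ct.consensus.alpha:.0f}%")
sel = filter_clusters_by_topology(topo, TopoConfiguration((1,)), 90.)
prof = radial_profile([table.coords[cr.labels == l] for l in sel], bin_width=5.)
print("selected:", sel, f"radial peak: {prof.peak:.1f} nm")
```

Output:

```
cluster 1: n=125 holes=1 alpha=96%
cluster 2: n=106 holes=1 alpha=99%
cluster 3: n=91 holes=1 alpha=100%
cluster 4: n=72 holes=1 alpha=90%
selected: [1, 2, 3] radial peak: 67.5 nm
```

All four ring clusters get a single-hole consensus; three clear the strict
α > 90% filter and their averaged radial detection histogram peaks near the
true 60 nm ring radius (with only three clusters the 5 nm-bin argmax is
noisy; the standard 12-ring protocol in `toposmlm.protocols.ring_recovery`
lands in the bin containing 60 nm).

The same pipeline is available from the shell:

```sh
toposmlm simulate --kind ring --n-clusters 4 --seed 1 --out det.csv
toposmlm cluster det.csv --algorithm tomato --radius 25 --tau 35 --out labeled.csv
toposmlm topology labeled.csv --pers-threshold 15 --seed 1 --out topology.csv
```

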