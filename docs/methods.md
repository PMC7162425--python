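# Methods notes

This note records the models, algorithmic conventions and design choices
behind `toposmlm`, in the spirit of a software methods appendix. Nothing
here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Detection tables and pre-processing

A detection table is a point cloud in nanometres (2D or 3D) with optional
frame index, photon count and localization precision per detection. Row
ids are stable: every tie-breaking rule downstream refers to ids, which
makes all clustering output invariant to row permutation (up to label
renaming).

Two standard filters are provided. The photon-count filter keeps
detections with intensity ≥ the threshold (inclusive — "minimum value"
reads as ≥; 1000 photons is the conventional choice for AF647 dSTORM).
Frame linking collapses repeated localizations of one blinking event:
chains of detections in strictly consecutive frames, each within 75 nm of
the previous link, merge into a single detection. The merged attributes
are not uniquely defined by convention, so we follow common SMLM software:
intensity-weighted mean position, summed intensity, first frame, minimum
uncertainty. Conflicts (two candidates within range) resolve greedily —
chains are serviced in head-id order and claim their nearest candidate,
ties toward the lower id. Linking is idempotent for realistic (sparse)
molecule fields but not for adversarial geometries where two distinct
chains end within 75 nm of each other.

## The dSTORM simulator

The generator separates *where molecules are* from *what fluorophores do*.

Placement scenarios: complete spatial randomness (uniform over the field);
isotropic Gaussian clusters of SD `cluster_sd` around centres (random with
a keep-out margin, on a grid, or in pairs separated by a given distance);
rings with molecules evenly spaced on the circumference at a random phase
(3D rings lie in the xy-plane unless random orientation is requested).

Photophysics, per molecule: a Poisson(5) fluorophore count (labelling
stochasticity; the mean of 5 fluorophores per molecule is the standard
secondary-antibody load, and a Poisson draw is the usual model for
"randomly distributed between molecules" — molecules with zero
fluorophores stay dark). Each fluorophore blinks Geometric(p=0.5) times on
support {1, 2, …} (each emission burst ends with probability p in
permanent darkness; mean 1/p = 2 blinks). Each blink survives detection
with probability 0.70. A surviving blink becomes a detection at the
molecule position plus isotropic normal error whose SD σ is drawn per
event from LogNormal(meanlog 2.8, sdlog 0.28) — parameters on the log
scale, giving a median precision of e^2.8 ≈ 16.4 nm, the AF647 regime;
natural-scale parameters would give sub-nanometre precision, which is not
physical. σ is also reported as the detection's uncertainty field.
Finally `round(f/(1−f)·n_true)` false detections (f = 0.10) are appended
uniformly over the field, so noise makes up 10% of the final table.

Every detection carries its generating molecule and cluster in a parallel
ground-truth object; blink-level counts are kept so the empirical noise
fraction, detection rate and fluorophore load can be verified against the
configured rates (they agree within 3 standard errors at 10⁴ molecules —
`scripts/acceptance.py` recomputes this).

Frames are drawn uniformly and intensities log-normally; they are carriers
for the pre-processing filters, not a kinetic model. The simulator does
not render camera images or PSFs, does not model drift, and draws each
blink's position independently (no within-fluorophore correlation), so
passing tests say nothing about image-fitting artifacts in real data.

## ToMATo

Density estimate: the number of other detections within the search radius
r (ties at exactly r are inside — "within" is inclusive). Any per-detection
density (Voronoi, local Ripley L) can be substituted.

Mode seeking: detections sorted by decreasing density (ties by id). Each
detection attaches to its neighbour of strictly higher density with
maximal density (ties toward the lower id); detections with no strictly
higher neighbour are modes. Integer densities make ties common, so the
deterministic rules matter.

Merging: a union-find sweep in the same order. When two candidates meet at
a detection of density f (the saddle), the elder rule applies: the
candidate with lower birth (ties: higher mode id) is the younger; if its
prominence `birth − f < τ` it merges into the elder. The full candidate
diagram is produced by a second sweep with τ = ∞, which merges everything
and records every candidate's (f_b, f_d); the highest peak of each
connected component never dies (f_d = −∞).

Noise: a surviving candidate whose birth density is 0 — an isolated
detection with no neighbours within r — is noise; every other surviving
candidate becomes a cluster. This matches the observable behaviour on CSR
fields: isolated false detections are noise, while multi-blink artifacts
(several detections from one molecule) legitimately form small clusters.
An optional density pre-filter (drop detections below a density quantile
before mode seeking) is available for data with strongly varying SNR.

Baselines: DBSCAN is delegated to scikit-learn (the neighbour count
includes the point itself, the common convention); local-Ripley clustering
keeps detections with L(r) = sqrt(A·k/(π(n−1))) ≥ a threshold (expectation
≈ r under CSR; the 3D analogue uses the window volume) and takes connected
components of the radius graph; Voronoi clustering keeps tiles with area ≤
a threshold and takes components under tile adjacency. Unbounded Voronoi
tiles get density 0 (area ∞), so field-edge detections read as sparse; a
mirror-and-clip alternative bounded by the observation window is available
in 2D.

## Rips persistence

The filtration scale is the pairwise-distance threshold (ball *diameter*):
a simplex enters when all its vertices are pairwise within the scale. The
computation is exact over continuous scale — simplex filtration values are
the maxima of their edge lengths — not a stepped approximation.

H0 comes from a Kruskal-style union-find over distance-sorted edges. H1
(and H2 when tetrahedra are included, i.e. for 3D data) comes from GF(2)
boundary-matrix column reduction with the clearing ("twist") optimisation:
the dimension above is reduced first and its pivot rows are skipped below,
since their own columns must reduce to zero. Columns are Python integers
used as bit-sets, so column addition is one XOR. Row indices refine the
filtration order, which is what makes the pivot (the highest set bit) the
latest facet. Features with death = birth are dropped; features alive at
`max_scale` are essential (death ∞) and always count as persistent when
thresholding — this matters because `max_scale` defaults to the cluster
diameter but can be capped for speed without losing long-lived features.

The engine is validated feature-for-feature against an independent dense
full-boundary-matrix reduction on ≤ 12-point fixtures in 2D and 3D, and
against closed forms (a regular hexagon with circumradius R has one H1
bar born at the side length R and dying at the triangle fill-in R√3).

## Sub-sampling consensus

Per cluster: n detections are resampled with replacement (sample size n)
with probability ∝ e^(−μw), where w is the cluster-internal min–max
normalization of the localization uncertainty (all-equal clusters resample
uniformly, as do clusters with no uncertainty column) and μ = −ln 0.1 ≈ 2.3
so the extreme-uncertainty detections differ 10× in sampling probability.
Duplicates are collapsed before the filtration (a Rips complex on repeated
points is degenerate), so the effective sample size is ≤ n — this is the
mechanism that suppresses features induced by single noisy detections.
The consensus is the modal thresholded configuration over 100 resamples
(count not prescribed by convention; 100 keeps α resolution at 1% and
desk-scale runtimes), α its frequency ×100; ties break toward the simpler
configuration (fewer total features, then lexicographically). In 3D the
configuration is the joint (holes, voids) tuple, so α measures agreement
on the whole tuple. H0 is excluded from configurations (a segmented
cluster is one component by construction) but reported as a diagnostic.
Clusters below 4 detections are skipped with a recorded reason (the
smallest 2D simplex structure needs dim+2 points to be non-trivial).

## Study protocols and problem sizes

`toposmlm.protocols` freezes the synthetic experiments:

* **Ring recovery** — 12 rings of radius 60 nm on a grid in a 2 µm field,
  16 molecules per ring (2πR/16 ≈ 24 nm spacing, a Nup-like stoichiometry
  that keeps the circumference connected at the 25 nm search radius),
  default photophysics. Segmentation r = 25 nm, τ = 35: for ring-shaped
  structures the density modes along the circumference are sampling
  artifacts, so τ is set high enough that each connected structure is one
  cluster. Topology at a 15 nm persistence threshold with `max_scale`
  90 nm (well above the ~45 nm death scale of a blurred 60 nm ring's
  hole). Clusters passing the (1 hole, α > 90%) filter enter a 5 nm-bin
  radial profile. The peak sits in the bin containing 60 nm; the ~17 nm
  median localization error biases the radial *distance* mode slightly
  above the ring radius (Rice-distribution shift ≈ σ²/2R ≈ 2.4 nm), which
  stays within one bin.
* **CSR robustness** — 300 molecules in the same field through the same
  pipeline; multi-blink artifacts do form clusters, but none should reach
  ≥ 1 hole with α > 90%.
* **Separation benchmark** — four pairs of Gaussian clusters (SD 10 nm,
  15 molecules each) at fixed anchors in a 2 µm field, centre separation
  varied; 5 replicate fields. After the ~17 nm localization blur the
  effective cluster footprint (~20 nm SD) is comparable to a 60 nm
  separation — the "adjacent structures" regime where prominence-based
  merging should show its advantage. Grids are fixed across separations:
  ToMATo r ∈ {5..25} × τ ∈ {2..25}, DBSCAN eps ∈ {5..25} ×
  min_pts ∈ {3..25}, Ripley r ∈ {5..25} × L ∈ {20..240}, Voronoi tile
  area ∈ {25..400} nm² (5 values per axis). The figure of merit is the
  max over parameter sets of the rep-averaged percent of correctly
  assigned detections, with a greedy one-to-one overlap matching between
  predicted and true clusters (the exhaustive optimal matching is used as
  a test oracle only; greedy agrees on realistic confusion structures).

Problem sizes (12 rings, 300 CSR molecules, 5 reps, 5×5 grids) are the
package's desk-scale defaults: they keep the full acceptance recomputation
around a minute while leaving each estimate comfortably inside its
tolerance; all are configurable.

## Known limitations

* The bit-set reduction is exact but O(n³) in cluster size via the
  triangle count; clusters beyond a few hundred detections should be
  sub-sampled or capped via `max_scale`.
* Voronoi densities in 3D use unclipped cells only (unbounded → 0).
* The noise rule makes isolated *pairs* of false detections legitimate
  two-point clusters; downstream minimum-size filters (and the consensus
  filter) are the intended guards.
* Benchmarks and calibrations are validated on the simulator's idealized
  noise model; real data adds drift, correlated blinking and non-uniform
  labelling that the simulator does not emulate.
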