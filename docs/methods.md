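# Methods

This note documents the models, numerical choices, and limitations behind
`dsfiber`. Notation: a fiber *F_i* is an ordered polyline of 3D points in
world mm; after resampling it has exactly *k* points *p^i_1 … p^i_k*.

## Fiber representation

Every streamline is resampled to *k* = 12 points equally spaced in arc
length along an interpolating B-spline (cubic; degree reduced for inputs
with fewer than 4 distinct points, down to linear for 2-point segments).
The arc-length parameterization is inverted numerically on 1024 dense
spline samples, which keeps consecutive-segment length ratios within a
fraction of a percent on smooth fibers and makes resampling idempotent to
about 1e−5 mm. Endpoints are pinned exactly. Twelve points is the standard
operating point for streamline clustering; the clustering results are not
sensitive to moderate changes in *k*.

Streamlines carry no orientation, so the flipped point order is treated as
the same fiber in every metric: `d_pp` minimizes over the flip of its
second argument, and the landmark distance minimizes over the
block-reversed encoding. Flipping the first argument instead is equivalent
(reversing both orders together leaves all corresponding pairs intact), so
a single flip suffices and both metrics are symmetric.

Fibers shorter than 3 mm (strictly; exactly 3 mm is kept) are discarded
before clustering — they are tracking debris, and very short fibers are
also the case where the landmark encoding is least faithful. An optional
hemisphere split partitions fibers against a single sagittal plane
`x = midplane_x` (strict side test on all points; crossing or touching
fibers are "inter-hemispheric"). The plane location is a parameter because
the right choice (atlas midline vs. image midline) depends on the data.

## Distances and affinities

Two streamline-space distances are implemented over resampled fibers:

* symmetrized mean-closest-point,
  `d_smp = ½(d_m(F_i,F_j) + d_m(F_j,F_i))` with
  `d_m = (1/k) Σ_a min_b ‖p_a − q_b‖` (computed over the sampled points
  only, not segment-wise);
* symmetrized point-to-point,
  `d_pp = min(d_p(F_i,F_j), d_p(F_i,flip(F_j)))` with
  `d_p = (1/k) Σ_a ‖p_a − q_a‖`.

`d_pp ≥ d_smp` always (closest-point minima lower-bound corresponding-point
distances). Affinities are `a_ij = exp(−d_ij/σ)`, zero diagonal (no
self-loops), over the complete graph on all fiber pairs — no sparsification
rule is applied. `σ` defaults to the maximum pairwise distance of the
dataset, which bounds all off-diagonal affinities into `[e^{−1}, 1]`
regardless of scale. If every distance is zero (degenerate input of
identical fibers) `σ` resolves to 1 so that all affinities are exactly 1.

A consequence of `σ = max` worth knowing: the normalization is scale-free,
so what the clustering sees is only the *shape* of the distance
distribution. A lone Gaussian bundle clustered in isolation is therefore
split into a dense core plus peripheral shells (the dominant set holds
roughly a third of the fibers) no matter how tight the bundle is; whole
bundles come out as single clusters exactly when the dataset contains
several bundles, because inter-bundle distances then set `σ` and
within-bundle affinities saturate near 1. That multi-bundle regime is the
intended use, and it is the regime the recovery tests exercise.

## Dominant sets and replicator dynamics

Clusters are dominant sets: supports of strict local maximizers of
`xᵀAx` on the simplex, found by discrete replicator dynamics
`x_i(t+1) = x_i(t)(Ax)_i / (xᵀAx)`. For symmetric non-negative `A` the
objective is non-decreasing and the simplex is invariant; the iterate is
renormalized to sum 1 each step to absorb floating-point drift. If
`xᵀAx = 0` at any iterate (no positive affinity under the current support)
a no-cohesive-structure error is raised and the caller treats the
remaining nodes as residual singletons.

Numerical choices, each load-bearing:

* **Start point.** The theoretical start is the simplex barycenter, but on
  any matrix with equal row sums (e.g. regular unweighted graphs) the
  barycenter is itself a fixed point, typically a saddle, and the dynamics
  would never leave it. The default start therefore mixes the barycenter
  with a small (1%) deterministic size-seeded random simplex point. The
  same matrix and config always produce the same output; an explicitly
  supplied `x0` (including the exact barycenter) is used as-is.
* **Stopping rule.** The dynamics stop when the Euclidean step norm drops
  below ε = 1e−7 *and* every component above the support threshold
  satisfies the equilibrium payoff condition `|(Ax)_i/(xᵀAx) − 1| ≤ 1e−5`.
  The second clause exists because a slowly extinguishing component can
  make per-step changes smaller than ε while still carrying weight above
  the support threshold; its payoff is visibly below average, so iteration
  continues until it either equilibrates or falls out of the support.
  A hard cap of 10 000 iterations (with a warning) prevents hangs.
* **Support threshold.** Converged components are never exactly zero, so
  the support is `{i : x_i > θ·max(x)}` with θ = 1e−5. θ must be < 1
  (the config validator enforces θ ∈ [0, 1)): at θ = 1 the strict
  inequality empties the support.
* **Spectral regularization.** On unweighted (0/1) affinity graphs the
  plain quadratic form has *spurious* non-strict maximizers whose supports
  are not cliques — on a 4-cycle, every x with `x₁+x₃ = x₂+x₄ = ½` is a
  fixed point attaining the global optimum — and the dynamics genuinely
  converge to them. The optional shift `regularization = α ∈ [0, 1)` makes
  the dynamics maximize `xᵀ(A + αI)x`, under which strict local maximizers
  correspond one-to-one with maximal cliques; α = ½ is the customary
  choice for clique recovery, and with it the first dominant set matched
  exhaustive maximal-clique enumeration on every random graph tried
  (2 200 graphs across 11 seeds). The default is α = 0 — the plain method,
  correct for the generic real-valued affinities of fiber data — and
  cohesiveness is always reported on the unshifted matrix.

Peeling extracts dominant sets repeatedly from the surviving submatrix
(rows/columns deleted; the affinity matrix and its σ are computed once
globally, never re-normalized after peeling). Extraction stops when fewer
than two nodes remain or no cohesive structure exists; leftovers are
emitted as explicitly flagged residual singletons so the clusters always
partition the index set.

## Cluster selection (stage 1)

Cluster quality is the cohesiveness `C = xᵀAx` recorded in extraction
order. Selection happens in two passes, in this order: (1) residual
singletons and the last `ceil(0.05·M)` clusters by extraction rank are
dropped (`ceil` guarantees at least one removal; late extractions are
low-cohesion leftovers); (2) a second-order polynomial is least-squares
fitted to the survivors' cohesiveness curve and subtracted, the residual
spread is estimated as a zero-mean Gaussian (σ̂ = RMS of residuals — the
mean is pinned at zero by the model), and clusters with residual below
`−z_{1−α}·σ̂` (α = 0.05, z = 1.6449; one-sided — only the negative tail is
anomalous) are rejected. With fewer than 3 survivors the quadratic fit is
underdetermined and residuals fall back to centered values. Each kept
cluster is represented by its medoid under the stage-1 metric (`d_pp`),
ties broken toward the lowest fiber index.

## Cross-subject matching (stage 2)

Medoids are encoded as the `k·n` vector of distances from each of the `k`
fiber points to each of the `n` landmarks (point-major order). Every entry
is a point-landmark distance, hence exactly invariant under a rigid
transform applied jointly to the fiber and the landmarks — this is what
makes the stage registration-free, and it is asserted numerically to
1e−9 mm. The full encoding (rather than the n-vector of per-landmark
minima) is used because its distances correlate best with the
streamline-space `d_pp` on synthetic subjects (Pearson ≈ 0.97–0.99, the
largest of the four streamline × landmark pairings), so landmark-space
clustering preserves streamline-space structure most faithfully.

The pooled block affinity uses `exp(−d_l/σ_{k,h})` with a *per-block*
normalization `σ_{k,h}` = maximum landmark distance within the
subject-pair block (the alternative single global σ is a config switch).
Same-subject entries are identically zero, which provably excludes two
bundles of one subject from any exact dominant set. Numerically, a
slowly-extinguishing component can survive the stopping rule just above
the support threshold; if such a straggler duplicates a subject already
represented with more weight in the same cluster, it is removed and
re-emitted as an incomplete singleton, keeping the output a partition.
Final selection keeps clusters spanning all subjects (`min_subjects`
relaxes this), regardless of cohesiveness.

## Synthetic cohorts

The generator builds one canonical subject — `n_bundles` gently curved
centerlines (quadratic Bezier arcs) packed by rejection sampling inside a
sphere (default radius 50 mm) with a minimum center separation of
`separation_factor × cross_section_sd` (default 20 × 0.5 mm = 10 mm) — and
surrounds each centerline with fibers offset by a constant per-fiber
Gaussian draw in the perpendicular plane (both components
N(0, cross_section_sd)), i.i.d. per-point jitter, and a 50% random point-
order flip. Defaults (10 bundles × 50 fibers for single-subject tests,
4 subjects × 8 bundles for cohort tests, spread 0.5 mm) put the data in
the well-separated regime: minimum inter-bundle `d_pp` exceeds 3× the
maximum intra-bundle `d_pp` by construction, which is where clustering
recovery is expected and asserted. Cohort subjects are rigid copies of the
canonical subject (random rotation up to 30°, translation up to 20 mm)
with landmarks co-transformed, so cross-subject ground truth is exact by
construction; per-point jitter is added per subject after the transform,
so zero jitter means exact rigid copies. Because the perpendicular offset
is a 2-D Gaussian draw, the offset magnitude is Rayleigh-distributed with
mean `spread·√(π/2)` — the oracle used by the generator's own test.

The master seed spawns one RNG stream for the canonical subject plus
landmarks and one per subject, so adding subjects never perturbs earlier
subjects' draws and equal seeds give bitwise-identical cohorts.

What the generator does *not* emulate: crossing and broken fibers, partial
volume effects, density gradients within bundles, fanning/branching
geometry, and anatomically realistic landmark placement (landmarks are
uniform in the sphere). Passing recovery tests therefore demonstrate the
machinery is correct in the separable regime, not that real tractograms of
arbitrary quality will segment cleanly.

## Evaluation

Recovered labelings are scored with the Hubert–Arabie adjusted Rand index
and entropy completeness `1 − H(K|C)/H(K)` (defined as 1 when `H(K) = 0`;
the log base cancels in the ratio). A pair-counting completeness variant
(fraction of truly co-bundled pairs that are co-clustered) ships alongside
as a cross-check; both satisfy the same verbal definition and agree at the
extremes. Index implementations are backed by scikit-learn and verified in
the tests against an independent brute-force pair-counting oracle.

`metric_correlation` reports the four Pearson correlations between
condensed pairwise distance sets under {d_smp, d_pp} × {min-landmark,
full-landmark}, plus 2-D histograms; zero-variance distance sets yield NaN
("undefined") rather than an arbitrary number.

## Interfaces

TRK/TCK streamline I/O goes through nibabel and always converts to world
mm (RAS) on load; nothing downstream sees voxel indices. Landmarks load
from NIfTI integer label volumes (unweighted centers of gravity of the
requested label ids, in the requested order — label volumes carry no
intensities to weight by), or from JSON/CSV coordinate tables re-ordered
to a canonical label list so all subjects align. Configuration is strict:
unknown keys are errors, never silently ignored, and every output manifest
embeds a content hash of the configuration for provenance. Problem sizes
in the test-suite and acceptance runs (hundreds of fibers per subject, 4
subjects) are chosen to exercise every code path at interactive runtimes;
the method itself is O(N²) in fibers per subject by construction.

## Known limitations

* O(N²) distance matrices bound the practical per-subject fiber count;
  the hemisphere split exists precisely to cut N, and no approximate
  nearest-neighbor acceleration is provided.
* Dominant sets over-segment diffuse structures (see the σ = max
  discussion): bundle cores separate from halos when a subject contains
  few bundles.
* Landmark selection is user configuration; the encoding's fidelity
  degrades for very short fibers and for landmark sets that do not
  surround the tracts.
* No out-of-sample assignment: new fibers or subjects require re-running
  the affected stage.
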