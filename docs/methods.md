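# Methods

## The model

A scalar map `y` on a triangulated surface (or tetrahedral volume) is
decomposed onto the eigenmodes of the Laplace–Beltrami operator,

    Δψ_η = −λ_η ψ_η ,         y = Σ_Λ Σ_μ β_Λμ ψ_Λμ + ε ,

discretized with linear (P1) finite elements: cotangent stiffness matrix
`A`, consistent mass matrix `B`, and the generalized eigenproblem
`A ψ = λ B ψ`. Modes are `B`-orthonormal with ascending eigenvalues
(units mm⁻²); coefficients are mass inner products `β = Ψᵀ B y` for fully
valid maps, or an ordinary least-squares fit on the valid vertices when a
missing-data mask (e.g. a medial wall) is present. Open meshes get the
natural (Neumann) boundary condition — no constraint rows — so a cut
boundary behaves as a reflecting edge rather than a hard zero.

On a sphere the modes are spherical harmonics: degree Λ contributes 2Λ+1
modes sharing one eigenvalue, so the spanned subspace is rotation
invariant. General geometry perturbs the eigenvalues but approximately
preserves the grouping, so modes are partitioned **by index** into groups
of sizes 1, 3, 5, … after the ascending sort. Each rotatable group is
normalized to its degenerate spherical representation by the elementwise
scaling κ = λ^(−1/2), multiplied by a Haar-uniform random orthogonal
matrix (drawn on the full orthogonal group, reflections included, since
mode signs are arbitrary), and mapped back with ζ = λ^(1/2). Reconstructing
with the *original* coefficients yields a surrogate map with the original
per-group power — hence the original spatial autocorrelation (SA) — but
randomized alignment. The constant mode (λ = 0) is never rotated; its
contribution, the map mean, is added back verbatim.

Surrogate assembly options:

- **residuals** — the truncation residual ε is either uniformly permuted
  over valid vertices (default) or zeroed;
- **amplitude adjustment** (default on) — a rank-order remap assigns the
  k-th smallest surrogate value the k-th smallest original value, undoing
  the Gaussianization of the randomized modal sum and restoring the exact
  value multiset;
- **mode count** — fixed, or chosen by the smoothness heuristic below.

Inference is fully nonparametric: a two-tailed surrogate p-value
`p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + S)` (never exactly zero), with
Westfall–Young max-statistic correction across families of target maps
that share one surrogate ensemble.

## Mode-count heuristic

The decomposition depth is the one free parameter. The heuristic estimates
the map's autocorrelation FWHM from the variogram proxy
ρ(h) = 1 − γ(h)/sill (sill = map variance; FWHM = 2·h½ at ρ = 0.5, by
linear interpolation between distance bins, on geodesic distances), and
keeps every whole eigengroup whose nominal wavelength 2π/√λ̄ is at least
that FWHM, always including at least one rotatable group.

A group's own autocorrelation FWHM is roughly *half* its wavelength (the
ACF of an isotropic degree-ℓ field is P_ℓ(cos θ), which falls to ½ at
about one half-lobe). Comparing the *full* wavelength against the map
FWHM therefore keeps groups down to half the map's summary scale — a
deliberate one-octave guard band. For single-scale fields the extra
octave is nearly empty; for multiscale (power-law) fields a substantial
variance fraction lies below the summary FWHM, and without the guard band
that structure would fall into the residual, be whitened by the
permutation, and narrow the null (inflating false positives). The guard
band keeps the retained basis responsible for the bulk of the SA while
still truncating hard for smooth maps: on the 642-vertex benchmark sphere
the selected counts run 625 → 75 → 32 modes for spectral slopes
α = 0 → 2 → 3.

Two practical notes. The map-FWHM estimate is floored by the resolution
of the sampled vertex-pair set: for white noise it reports the first
nonempty distance bin, which on a subsampled pair set can exceed the mesh
edge length, mildly over-smoothing the estimate (harmless for
calibration, since white residuals are exchangeable under permutation).
And when ρ(h) never reaches 0.5 within the lag window, the map is treated
as at least that smooth and only the coarsest groups are kept.

## Synthetic benchmark

Because the method's guarantees are geometry generic, the benchmark runs
on synthetic spheres rather than cortical surfaces: an icosphere of
radius 28 mm (subdivisions 4 → 2,562 vertices for the headline runs;
subdivisions 3 → 642 vertices in the test suite) centered in a 64³ grid
of 1-mm voxels, i.e. the domain nearly fills the volume the way a
hemisphere fills a scanner's field of view, while keeping the required
two-voxel sampling margin.

Gaussian random fields are synthesized spectrally: a white complex
spectrum is shaped by the amplitude filter |k|^(−α) (zero-frequency term
removed), inverse-transformed, standardized to mean 0 / variance 1, and
sampled at the mesh vertices by trilinear interpolation. α = 0 is iid
noise. The amplitude exponent is calibrated so the α = 0…3 sweep spans
the intended regimes on this domain: chance-correlation dispersion
between independent pairs grows steadily with α (variance ratio ≈ 17 at
α = 2 versus α = 0), autocorrelation FWHMs reach tens of mm, and only a
handful of whole eigengroups survive the truncation heuristic at α = 3.
A gentler filter leaves the maps effectively white up to α ≈ 2.5 on a
domain of this size, which would make the smoothness sweep vacuous.

Each field is sampled at a uniformly random 3-D rotation of the mesh
("pose"). This matters: the periodic FFT grid concentrates low-k power in
its six axis-aligned fundamental modes, so at high α two "independent"
fields share preferred orientations, and the true chance-correlation
distribution becomes wider than any exchangeability-based null can
reproduce — a ~11% false-positive rate at α = 3 that no amount of basis
depth repairs. Random poses restore the isotropy the model intends.
Independent pairs get independent poses; fixed-correlation pairs (mixed
at the volume stage, z = ρy + √(1−ρ²)w) share one pose so the built-in
correlation survives sampling; heterogeneous composites (front half from
a smooth field, rear half from a rough one, split at the median of one
coordinate) use one pose per composite map.

The experiment harnesses measure, per field pair: surrogates of the first
map (fresh ensemble per pair), correlations of each surrogate with the
second map, the two-tailed p, and the rejection proportion at level 0.05
with its exact (Clopper–Pearson) binomial confidence interval. An
SA-naive baseline (vertex permutation) is available for contrast and
shows the motivating failure: calibrated at α = 0, but over-rejecting
several-fold for smooth maps.

## What the generator does and does not emulate

The synthetic data reproduce: tunable isotropic SA with power-law
(multiscale) spectra, missing-data masks, spatially heterogeneous
smoothness, and volumetric (tetrahedral) domains. They do not reproduce:
cortical folding (and hence the systematic eigenvalue splitting and mode
localization of real hemispheres — only the mild icosahedral splitting of
the icosphere is present), anisotropic or long-tailed SA, scanner noise,
or interpolation artifacts of real volume-to-surface resamplers. Passing
benchmarks here shows the machinery is calibrated on smooth generic
geometry; it does not certify behavior on a specific cortical mesh.

## Numerical choices

- Eigen-solver: dense `scipy.linalg.eigh` for meshes up to 4,096 vertices
  (the benchmark sizes; ~4 s at 2,562 vertices), otherwise sparse
  shift-invert Lanczos with a small negative shift. Sign convention: each
  mode's largest-magnitude entry is positive. If the requested count cuts
  a numerically degenerate cluster (relative gap < 1e-8), the basis is
  extended to the cluster end so a rotation never sees a split subspace.
  Within a degenerate cluster the orthonormal frame is solver-arbitrary;
  every downstream quantity is invariant to it.
- Consistent (not lumped) P1 mass matrix throughout.
- Geodesic distances use the heat method (prefactorized; time step =
  squared mean edge length), clipped from below by the Euclidean chord —
  a true lower bound — so `geodesic ≥ euclidean` holds exactly. Accuracy
  on an icosphere is ~1–2% (antipodal distance within 2% of πr).
  Tetrahedral meshes use Euclidean distances only.
- Variogram: Matheron estimator, 25 equal-width bins by default, default
  max lag a quarter of the largest sampled pair distance; empty bins are
  reported as missing, never zero. Above 5,000 vertices distances default
  to a seeded 500-vertex subsample.
- Moran's I weights: inverse distance over the (sub)sampled pair set, or
  binary mesh adjacency. The inverse-distance default keeps long-range
  structure in the statistic, which is what eigengroup rotation preserves.
- Random rotations: QR-based Haar sampling on O(n) (n = 1 draws ±1).
- Determinism: every ensemble and experiment is a pure function of its
  seed; per-surrogate and per-pair seeds are spawned from one root
  `SeedSequence`, and provenance (options, child seeds, basis hash) is
  recorded alongside outputs.
- Amplitude adjustment ties are broken by stable vertex order, making the
  remap idempotent.

## Problem sizes

Benchmarks are sized for a single CPU: the headline replications use
2,562-vertex spheres, 200 pairs, 199 surrogates per pair (≈12 minutes
total for the four experiments, dominated by the α = 0 run where the
heuristic keeps ~2,500 modes). The test suite repeats the same
experiments at 642 vertices with 60–200 pairs and 99–199 surrogates.
Full-scale studies (10,242-vertex cortical meshes, 1,000 pairs × 1,000
surrogates) are a straightforward scale-up: the eigenbasis is computed
once per mesh and cached by content hash.

## Known limitations

- **Moran's I drift at small N.** The amplitude-adjustment rank remap
  perturbs every value at the empirical-quantile noise scale σ/√N; on a
  642-vertex sphere this alone shifts Moran's I by ≈ −3e-3 per surrogate,
  and the whitened truncation residual adds a further negative bias. With
  amplitude adjustment off and a complete basis the pipeline preserves I
  to ~4e-4 at that size. Both effects vanish with mesh resolution and
  decomposition depth; at desk scale a mean |ΔI| of a few 1e-3 under
  default settings is expected, not a defect of the rotation machinery.
- Heterogeneous smoothness is handled through a single global FWHM; a
  smoothness step of Δα = 0.7 sits at the edge of false-positive control
  (measured ≈ 8.5% at level 5% on the desk-scale sphere), and larger
  steps inflate further. Anisotropic operators would be the principled
  extension.
- The FWHM heuristic assumes the variogram reaches half its sill inside
  the lag window; constant maps are rejected, near-constant maps select
  only the coarsest groups.
- Index-based grouping assumes the sorted spectrum keeps the 1, 3, 5, …
  cluster structure; on strongly non-spherical geometry groups blend
  across wavelengths, which widens (never biases) the null.
- No spatiotemporal (4-D) surrogates, no partial/incremental rotations,
  and no anisotropic Laplace–Beltrami operators.
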