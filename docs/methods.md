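# Methods

`headpsf` compares three four-shell volume-conductor models of the human
head — a sensor-fitted multilayer sphere (SPH), a surface boundary-element
model (BEM) and a voxel finite-difference model (FDM) — by the spatial
resolution of their EEG lead fields, quantified through point spread
functions (PSFs) and their full width at half maximum (FWHM). This note
records the models, the synthetic geometry that stands in for segmented-MRI
anatomy, the numerical choices, and what the tests do and do not establish.

## Head model and study conditions

All three models share one physical description: four nested homogeneous
compartments — scalp, skull, cerebrospinal fluid (CSF) and brain — with
radius proportions 1 : 0.95 : 0.87 : 0.84 and conductivities 0.33, 0.0042,
1.79 and 0.33 S/m. The default scalp radius is 92 mm (adult scale; the
proportions, not the absolute size, are what the benchmark specifies — the
radius is configurable). The default analysis uses 62 scalp electrodes,
5000 cortical source points, 26 probe ("true") sources, three Cartesian
dipole orientations per source, BEM surfaces resampled to 1500 vertices
each, and a 2 mm FDM grid. These counts give nine lead-field matrices of
62 × 5000 (3 models × 3 orientations) and 78 PSF maps per model.

## Synthetic head geometry

The benchmark anatomy (an averaged-MRI head) is not reproducible from
printed material, so the geometry module generates a stand-in with the
same structure:

- **Surfaces.** Spheres are meshed by triangulating a golden-angle
  (Fibonacci) point set with its convex hull, which meets any vertex budget
  exactly (icosphere subdivision only allows 12, 42, 162, …, and the BEM
  contract needs 1500 ± 20 %). A "realistic-like" head applies one smooth
  low-order real-spherical-harmonic radial field (degree ≤ 4, seeded)
  coherently to all four surfaces, preserving thickness proportions; with
  zero amplitude the head is exactly the concentric-sphere model, which is
  what makes the analytic solver an oracle for the numerical ones.
  Per-surface amplitudes are allowed and nesting is then checked radially
  (the surfaces are star-shaped), raising on intersection.
- **Electrodes.** A golden-angle spiral on the upper 130° polar cap,
  projected radially onto the scalp mesh (exact ray–triangle intersection).
  The montage is even-coverage by construction; no published montage is
  claimed.
- **Source space.** Fibonacci directions at the brain surface's local
  radius (barycentric interpolation of vertex radii) shrunk by 8 % —
  sources sit strictly inside the brain compartment, as cortex does. An
  optional high-order "wrinkle" field mimics gyral/sulcal depth variation;
  it is off in the study configuration because the comparison statistics
  never reference cortical folding.
- **Probe sources.** Farthest-point sampling (deterministic, started from
  the vertex nearest the +z pole) gives the 26 probes uniform spatial
  coverage. The benchmark placed its probes manually on anatomy; positional
  equivalence is not claimed, only the same count and a comparably uniform
  sampling.
- **Voxel volume.** Voxels are labeled by the innermost surface containing
  their center (radial containment, exact for star-shaped surfaces). No
  partial-volume weighting: the labeling is the testable contract
  (brain-voxel volume within 5 % of the enclosed analytic volume), and the
  FDM consumes the labels directly.

## Forward solvers

**Analytic multilayer sphere.** The potential of a dipole in nested
concentric shells is the classical Legendre series; the per-degree transfer
coefficient T_n is obtained by solving the small interface system
(potential and radial-current continuity at the three interfaces, insulated
outer boundary) with per-layer normalized basis functions (r/b_j)^n and
(a_j/r)^(n+1). The naive r^±n parameterization loses ~2n·log10(1/ρ) digits
to column imbalance and visibly corrupts high-contrast models by n ≈ 40;
the normalized form is exact to rounding (checked against a symbolic
two-layer closed form and the homogeneous (2n+1)/n limit). The series is
truncated at 200 terms — with the series variable b/R ≤ 0.8 at the maximum
usable eccentricity, the tail is below 10⁻¹⁹, so no acceleration is needed.
Potentials are average-referenced; the reference convention cancels in the
PSF (Pearson centering) but a fixed convention is required for solver
cross-validation.

**Sensor-fitted sphere.** For each electrode, a sphere is least-squares
fitted (algebraic fit) to the scalp vertices within 40 mm of the sensor,
the outer radius is reset to the sensor–center distance, and the inner
radii follow the shell proportions. On coarse meshes the patch is widened
until it holds at least 12 vertices; a near-planar patch falls back to the
global best-fit sphere and is flagged. Sources falling outside a fitted
brain shell (possible under deformation) are evaluated with eccentricity
clipped at 0.98 and counted.

**BEM.** Linear (vertex) collocation on the double-layer formulation with
analytically integrated per-triangle solid-angle weights; the weights were
verified to 10⁻¹⁴ against an independent implementation of the same
analytic element integrals. Diagonal (auto) elements are restored from the
on-surface solid-angle identity (each row of a same-surface block sums to
2π). The undetermined potential constant is removed by rank-one deflation
(1/N added to every entry). The isolated problem approach (IPA) treats the
poorly conducting skull: the sub-problem on the surfaces inside the
skull's inner boundary (CSF interface + brain surface, insulated at the
CSF interface) is solved first, and the full system is then driven by a
residual source proportional to σ_skull carrying the isolated solution on
the isolation surface. This keeps the discretization error of the large
interior potentials out of the skull-attenuated scalp potentials; on this
geometry it reduces the shape error (RDM) against the analytic oracle by
roughly a factor of five (e.g. 0.40 → 0.055 at eccentricity 0.8, 642
vertices/surface). IPA is on by default and engaged when
σ_skull/σ_CSF < 0.1. Electrodes read the scalp potential by barycentric
interpolation on their radial projection; lead fields reuse the
electrode-transfer rows across all sources.

**FDM.** Conservative-flux 7-point stencil: each voxel face carries the
harmonic mean of the adjacent conductivities times the spacing;
faces to air carry nothing (homogeneous Neumann). The operator is
symmetric and singular on constants; solves use Jacobi-preconditioned
conjugate gradients at relative residual 10⁻⁸ (cap 10⁴ iterations) and the
mean is removed. A dipole is two opposite monopoles on the nodes straddling
the position along the moment, with I·d equal to the moment magnitude. Lead
fields are assembled reciprocally — one solve per sensor (current between
the sensor node and the reference sensor's node), reading each dipole off
its two monopole nodes — which is an exact discrete identity by symmetry;
the residual tolerance is amplified by conditioning (measured ≈ 100–200×),
so reciprocal and direct assemblies agree to ~10⁻⁶ at the default
tolerance, tightening proportionally as the tolerance is reduced.

Solver accuracy at the study resolutions, against the analytic four-shell
oracle over 20 random dipoles of eccentricity ≤ 0.8: median RDM ≤ 0.10 for
both BEM (1500 vertices/surface) and FDM (2 mm), with errors decreasing
under refinement. The skull and thin CSF layer (2.76 mm between surfaces
meshed at ~7.6 mm edge length) are the accuracy bottleneck for the BEM;
the FDM is limited by layer quantization (the skull spans < 2 voxels at
4 mm, which is why 3 mm is the coarsest spacing the tests treat as
meaningful).

## PSF analysis

The PSF of a seed source is the Pearson correlation between its lead-field
column and every other column; zero-variance columns yield undefined (not
zero) values, which are excluded from statistics and fits with a count.
The three orientation maps of a seed combine pointwise as
RMS = sqrt((PSF_x² + PSF_y² + PSF_z²)/3). Maps are smoothed by a
Gaussian-weighted neighbourhood average in Euclidean 3-D distance (default
kernel FWHM 10 mm, 3σ cutoff; recorded in output metadata) — Euclidean
rather than geodesic distance because the synthetic cortex has no folded
anatomy to respect. The smoothed PSF-versus-distance profile is fitted by
least squares with a two-component Gaussian
a₁·exp(−d²/2s₁²) + a₂·exp(−d²/2s₂²) (falling back to a single Gaussian,
flagged, on non-convergence), and the FWHM is always read numerically from
the fitted curve's half-maximum crossing, so the choice of fitting family
only affects fit quality, never the FWHM definition. σ_equivalent =
FWHM / (2√(2 ln 2)) = FWHM / 2.35482.

## Comparison statistics

The packaged reference tables (mean PSF, minimum PSF, FWHM; 26 sources ×
3 models × 4 orientation columns, checksummed TSV) drive the replication:

- **Pairwise counts** of source × orientation conditions where one model's
  statistic exceeds another's. Comparisons operate on the tables' printed
  precision, and ties count toward the direction being tested — the only
  rule consistent with the published per-orientation counts, which contain
  exact ties (e.g. three x-orientation ties in the mean-PSF table make the
  published 13/26 reachable only tie-inclusive). One published count
  (minimum-PSF SPH > FDM, stated as 66/78 with x at "100 %") is not
  reproducible from the printed cells (they give 64, with one x-row going
  the other way by 0.01); it evidently reflects pre-rounding data and is
  excluded from the replication set.
- **Column means ± sample SD** over the 26 sources, compared at the print
  rounding (2 decimals for PSF, 1 for FWHM).
- **Paired t-tests** (two-tailed, 25 df) between models per orientation.
  p-values recomputed from rounded cells are asserted only as significance
  bounds (p < 10⁻³), never as equal to published values computed on
  pre-rounding data — though several reproduce closely anyway.
- **SNR.** With σ = FWHM/2.35482, the PSF distribution's SNR is the
  reciprocal coefficient of variation, mean PSF/σ. The headline summary is
  the relative change of the *mean* SNR over the 26 sources (for z-oriented
  sources, BEM vs SPH this gives +22.9 % from the printed cells, matching
  the published 22.7 % within cell rounding); the mean of per-source
  changes (+23.7 %) is also reported but does not reproduce the published
  figure, so the change-of-means is the summary of record.

## Verification configurations

The test suite exercises the solvers at reduced sizes chosen to keep the
default run practical on one CPU: unit tests use 342–642-vertex surfaces
and 3–8 mm grids; the acceptance tests run the BEM oracle at the full 1500
vertices/surface and the FDM oracle at 2 mm, and verify the pipeline's
dimensional contract (nine 62 × 5000 matrices, 78 PSF maps per model) at
default counts with 242-vertex BEM surfaces and a 6 mm grid, accuracy at
study resolution being covered by the oracle tests. The full-resolution
pipeline (1500-vertex BEM, 2 mm FDM) is run from
`analysis/03_leadfields_and_psf.py`.

## What passing tests do and do not show

The synthetic head preserves the *structure* the analysis assumes — four
nested closed surfaces with the stated proportions and conductivities, an
even electrode montage, a quasi-uniform interior source space — and in the
spherical limit it equals the analytic model exactly. It does not contain
cortical folding, skull-thickness variation, anisotropy or anatomical
landmarks, so solver accuracy measured here bounds only geometric/numerical
error, not anatomical-model error; and the PSF tables computed on the
synthetic head characterise the machinery, while the replication of the
published statistics runs on the published tables themselves. The paranasal
sinuses, a known confound near frontal sources, are (as in the benchmark)
not modeled as a separate compartment.

## Known limitations

- The BEM's accuracy near the thin CSF layer is resolution-limited at 1500
  vertices/surface; the published analysis reports anomalies for its own
  BEM z-oriented sources, which cannot be disentangled here.
- The FDM uses binary voxel labels; partial-volume conductivity averaging
  was measured to give only marginal improvement at 2 mm and is not used.
- Probe-source positions are a deterministic uniform sampling, not the
  benchmark's anatomical placements, so per-source rows of newly computed
  tables are not comparable one-to-one with the published rows; only the
  published tables themselves support exact replication.
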