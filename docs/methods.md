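# Methods

`vesselwall` quantifies arterial wall geometry from paired cross-sectional
MRI and tests longitudinal wall change in a lesion-vs-control design. This
note records the model, the numerical choices, the synthetic-data conditions
the package is validated under, and the known limits of both.

## Segmentation model

### Active contour

A wall boundary is represented as a closed polyline **x**(s) in physical
millimetres that minimises the classical snake energy

    E = ∮ [ α |x′(s)|² + β |x″(s)|² ] ds − E_ext(x)

with tension α and rigidity β. Discretised on n vertices with cyclic
differences, the internal force is a cyclic pentadiagonal matrix A, and one
semi-implicit time step solves

    (γ I − A) x_new = γ x_old + κ F_ext(x_old)

for the x and y coordinate vectors separately (γ is the viscosity / inverse
step size, κ the external-force weight). The semi-implicit scheme is
unconditionally stable in the internal force; the matrix is factorised once
per evolution (sparse LU) and reused.

Defaults: α = 0.1, β = 0.1, γ = 1, κ = 2, n = 100 vertices, displacement
tolerance 10⁻³ mm, arc-length resampling every 10 iterations, at most 400
iterations. All are dimensionless except the tolerance; all are exposed in
the run configuration.

Two non-obvious choices:

* **Normal-projected external force.** Only the component of F_ext along the
  local contour normal is applied. Tangential force components slide
  vertices along the curve without changing its shape, which bunches
  vertices at strong edges and prevents the displacement-based stopping rule
  from ever firing; equal-arc-length resampling maintains vertex spacing
  instead.
* **Convergence bookkeeping.** The per-iteration mean vertex displacement is
  recorded; on a static field it decreases monotonically over the tail of
  the evolution except for the single iteration after each resample (a
  re-parametrisation, not energy ascent). A contour whose final position
  feels no external force at all is flagged `no_external_force`: its
  equilibrium is set by internal forces only and does not mark a boundary.

### Gradient Vector Flow

The external force is the GVF field: the vector field (u, v) minimising

    ∬ μ (|∇u|² + |∇v|²) + |∇f|² |(u,v) − ∇f|² dx dy

where f = |∇(G_σ ∗ I)|², the squared gradient magnitude of the
Gaussian-smoothed image, max-normalised. The field is computed by explicit
iteration of the descent PDE from (u, v) = ∇f with replicate boundaries and
time step Δt = 1/(4μ + max|∇f|²). That step satisfies the diffusion
stability bound Δt ≤ 1/(4μ) and additionally keeps every entry of the
iteration operator in [0, 1], which makes the max-norm update residual
provably non-increasing — the residual trace is stored and asserted on.
Iteration stops when the max per-pixel update falls below 10⁻⁴ of the
initial gradient scale (≤ 2000 iterations).

**μ = 0.05 by default.** μ trades field smoothness against edge fidelity.
On a *curved* boundary the diffusion averages over the curve's neighbourhood
and the field's zero-crossing sits slightly inside the edge ridge, by an
amount that grows with μ: at the curvature of a 1.5 mm lumen sampled at
0.1 mm (radius ≈ 15 px), μ = 0.2 displaces the converged contour ≈ 0.13 px
inward on both boundaries, which is a 2% wall-area error on a 0.5 mm wall;
μ = 0.05 keeps the displacement below 0.05 px while the converged field
still spans the whole domain (it solves a Laplace problem away from edges),
so the capture-range benefit of GVF is unaffected. Pixel units are used
inside the PDE; anisotropic in-plane spacing is rejected rather than
silently mishandled.

### Dual-sequence protocol

The two boundaries come from different sequences, where each has its
strongest contrast:

1. **Inner (lumen) boundary on the bright-blood slice.** Flowing blood is
   bright against the dark wall and surroundings, so the dominant edge is
   the lumen interface. The snake starts from a coarse operator- or
   phantom-supplied seed on the first slice.
2. **Transfer.** The converged inner contour seeds the next slice's inner
   snake (warm start, cranial → caudal, no backward pass) and, inflated
   outward by `inflation_mm` (default 0.2 mm ≈ one expected wall thickness)
   along per-vertex rays from the centroid, the same slice's outer snake.
3. **Outer boundary on the proton-density-weighted slice.** Before the edge
   map is computed, the lumen is *in-painted*: pixels inside the inner
   contour buffered by 0.12 mm are replaced by the median intensity of a
   0.15 mm band just outside the buffer. The lumen–wall interface is
   already accounted for by step 1; removing it smoothly (no constant-to-
   image cliff, hence no artificial edge) prevents the outer snake from
   locking onto the wrong interface when the wall is much thicker than the
   inflation. The outer snake then evolves on the in-painted slice's GVF
   field.

Quality flags (`not_converged`, `clamped`, `self_intersection`,
`outer_inside_inner`, `no_external_force`) accumulate per slice; containment
of inner by outer is checked with a 10⁻³ mm touching tolerance, so a
collapsed (zero-thickness) wall is legal.

## Morphometry

Per slice, two endpoints are reported, because "wall thickness" admits two
operationalisations and downstream statistics may want either:

* `wall_area_mm2` = outer polygon area − inner polygon area (shoelace
  formula, orientation-normalised; self-intersecting polygons are rejected —
  callers must consult flags first).
* `mean_thickness_mm`: 360 rays cast from the area centroid of the inner
  contour; per ray, thickness = outer-crossing distance − inner-crossing
  distance, using the outermost crossing where a contour is crossed more
  than once. Rays are centroid-anchored rather than normal-based for
  robustness on non-convex contours. Rays missing either contour are
  excluded (> 10% exclusions raises a flag); negative per-ray values are
  clipped to zero and flagged.

On near-circular annuli the two endpoints satisfy the identity
mean_thickness ≈ wall_area / mean(perimeter) to within 5%, which the test
suite asserts.

## Synthetic phantom

No imaging data accompany the study design this package targets, so a
generator produces paired stacks with known truth; it is first-class,
tested code.

**Per-slice appearance.** An analytic ellipse annulus (default circular,
lumen radius 1.5 mm) is rasterised with 4× supersampled anti-aliasing as a
partial-volume surrogate, Gaussian-blurred (σ = 0.12 mm) and degraded with
additive Gaussian noise (σ = 3% of the sequence dynamic range), clipped at
zero. Bright-blood slices show lumen 1.0, wall 0.15, background 0.10, plus
an optional second bright disk standing in for the adjacent vena cava.
Proton-density slices show a dark lumen (0.15), an intermediate wall (0.65)
and piecewise-constant perivascular patches (levels 0.15/0.22/0.29 on a
2.4 mm tile grid) — so the dominant PDW edge is the outer wall interface,
with realistic distracting edges between tissue patches.

**Longitudinal design.** 6 animals × {lesion, proximal} × 6 axial slices
per 2 cm segment, examined at baseline and 4 weeks, with the first 3 animals
also examined at 10 weeks (180 slice pairs in all). True wall thickness per
slice is cell mean + animal effect + slice effect: lesion trajectory
0.3 → 0.7 → 0.55 mm (thickening then partial regression), proximal constant
0.3 mm, animal effects N(0, 0.05 mm) shared across all of an animal's
cells, slice effects N(0, 0.03 mm) i.i.d., floored at zero. A single seed
fans out to per-(animal, region, timepoint, slice) child seeds via
`SeedSequence` spawn keys, so enlarging the design never perturbs existing
draws. The noise/blur/variability values were calibrated once against the
closed-loop accuracy and power checks and then frozen; they are the
package's definition of "default conditions".

**What the phantom does not model.** Rician magnitude statistics (noise is
Gaussian), respiratory and flow motion artifacts, through-plane partial
volume from oblique vessels, intensity inhomogeneity, and any distinction
between intima and media. Passing the closed loop therefore demonstrates
the geometry pipeline's correctness under controlled degradation — not
clinical-grade robustness.

## Statistics

The study table (one row per animal × region × timepoint × slice) is
analysed with the linear mixed model

    response ~ region * timepoint + (1 | animal)

fitted by REML (slices are exchangeable replicates within a cell). Fixed
terms use sum-to-zero coding so each Wald F tests the marginal effect —
on balanced data the F statistics reduce to the classical two-way table,
which the suite checks against a sums-of-squares oracle. Denominator df is
containment-style: all tested terms vary within animal, so
ddf = n_obs − rank(X) − (n_animals − 1). Cell-mean contrasts
(lesion − proximal at one timepoint; lesion week 4 − week 10) use the same
covariance and df. Gradient-based REML can fail when the animal variance
collapses to the boundary; the fit falls back to derivative-free optimisers
automatically.

Calibration, measured on generated null studies (no lesion effect): the
region × time Wald F rejects at nominal α = 0.05 with empirical rate
≈ 0.07 — mildly liberal, as expected of Wald tests with REML-estimated
variance components and an unbalanced third timepoint, and inside the
[0.02, 0.10] band the acceptance suite enforces.

Pearson correlation between measured and reference wall area uses the
product-moment formula with the two-sided t approximation
t = r √((n−2)/(1−r²)); the implementation is checked against an
explicit-sums oracle and against `scipy.stats.pearsonr`.

## Problem sizes used in validation

The default validation runs are sized so the whole suite is comfortably
reproducible on a single CPU: one 192² noiseless annulus for the geometry
oracle; the full 180-slice-pair rendered study (192², default noise) for
parameter recovery; 100 regenerated studies for pattern power and 200 for
the null type-I rate (truth tables only — no rendering, since segmentation
accuracy is established separately by the rendered study); and a reduced
2-animal, 128² configuration for the byte-identical determinism check of
the end-to-end runner.

## Known limitations

* **Thin-wall bias.** When wall thickness approaches the total blur width
  (image blur + edge-map smoothing ≈ 0.16 mm), the overlapping inner and
  outer intensity transitions displace the outer gradient ridge outward;
  measured thickness is biased high by up to ≈ +0.09 mm at 0.2 mm walls,
  falling to ≈ +0.01 mm at 0.55 mm. This is partial-volume physics, not an
  implementation artifact, and it stays inside the 0.1 mm (1 px) per-slice
  accuracy contract for walls ≥ 0.2 mm.
* **Zero-thickness floor.** A degenerate annulus (outer = inner) cannot be
  measured as exactly zero: lumen in-painting plus the point-spread width
  impose an apparent-thickness floor of ≈ 0.26 mm (margin + PSF). The
  degenerate case is flagged-free and containment-legal, just floor-limited.
* **Operator seeding.** Only the first slice of a series needs a seed, but
  one seed per (animal, region, timepoint) series is required; there is no
  automatic lumen detection.
* **No registration.** The two sequences are assumed co-registered; no
  per-slice correction is attempted.
* **Statistics scope.** No post-hoc multiplicity correction is applied to
  the cell-mean contrasts; the mixed model assumes a common residual
  variance across cells.
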