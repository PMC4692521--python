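# Methods

This note documents the models, the numerical choices and the synthetic
data behind `neoribbon`, in the order the pipeline runs. It states what
the defaults are and why; every empirical claim here is one the test
suite or `scripts/acceptance.py` computes.

## EM segmentation with a partial-volume class

Intensities inside the brain mask follow a Gaussian mixture whose
per-voxel mixing weights are spatial prior maps (in practice propagated
from an atlas; in the phantoms, blurred one-hot maps of the true labels,
σ = 2 mm). The E-step responsibility of class k at voxel v is
prior_k(v)·N(x_v; μ_k, σ_k²) normalized over classes; the M-step
re-estimates μ_k, σ_k² from the responsibilities. Class identity
therefore comes from the priors, never from intensity order — neonatal
T2 (WM bright, CGM dark) and adult-like contrast are handled
identically.

* **Initialization.** Prior-weighted moments. When several classes have
  indistinguishable initial moments (uniform priors), their means are
  spread over intensity quantiles; a symmetric initialization is
  otherwise an exact EM fixed point.
* **Variance floor** 10⁻³ × the global intensity variance, preventing a
  class from collapsing onto single voxels.
* **Convergence**: relative log-likelihood change < 10⁻⁵, cap 100
  iterations. The log-likelihood trace is monotone up to 10⁻⁸ relative
  slack and tests assert it on every fit.

The PV voxels on the CGM–WM boundary have intermediate intensity; with
one class per tissue roughly half of them land in CGM, inflating the
ribbon (≈ +33% CGM volume on the contaminated phantom). The PV class
has spatial prior κ·min(dilate₁(p_CGM), dilate₁(p_WM)) — nonzero only
where 1-voxel-dilated CGM and WM priors overlap — with κ = 0.5 by
default; the prior stack is renormalized per voxel. Its Gaussian starts
at the midpoint mean and the larger parent variance. After convergence
the PV responsibility is added to WM and hard labels are the argmax
(ties to the lowest class id, for determinism). On the phantom this
brings the CGM volume error from ≈ +33% to ≈ −3%. κ→0 recovers the
no-PV segmentation continuously.

## Laplace-equation thickness

The potential φ solves the discrete Laplace equation over the CGM mask
with Dirichlet values 0 on the inner (WM-side) region and 1 on the outer
(CSF-side) region, 7-point stencil with anisotropic spacing. The
Dirichlet value is imposed on the tissue *interface* — a ghost node at
half spacing, weight 2/h² — rather than at the neighbouring voxel
centre; this halves the boundary bias and makes the effective boundary
agree with where the streamlines terminate. CGM components touching no
boundary are reported and excluded. Systems up to 4·10⁴ unknowns use a
direct sparse solve, larger ones conjugate gradients.

Thickness at a voxel is the arc length of the streamline through the
normalized gradient of φ, integrated both ways with RK2 midpoint steps
of half the minimum voxel spacing, terminated by interpolated crossing
of the target-tissue indicator at 0.5 (the interface), with a fractional
last step. Zero-gradient voxels and lines entering an `avoid` mask are
flagged invalid. On a 4 mm slab the median is exact to < 0.05 mm; on a
4 mm spherical shell it reads 4.02 mm at 1 mm spacing and 4.0005 mm at
0.5 mm — the error falls with resolution, which the tests assert.

## Sulci detection and enhancement

The inner cortical surface (CGM voxels 6-adjacent to WM) is propagated
through CGM ∪ CSF ∪ intra-cranial background by fast marching with
speed F = max(p_CSF, 0.05): the floor keeps fronts moving through
PV-obscured sulci where the CSF posterior is ≈ 0. The Eikonal update is
the standard second-order upwind stencil (the first-order scheme's
diagonal error exceeds a voxel diagonal at realistic distances); each
interface voxel is its own seed and accepted voxels inherit the origin
of their most upwind neighbour.

**Shock points.** A bank collision is a voxel pair (6-adjacent) whose
origin seeds lie ≥ d_min = 3 mm apart *and* whose front directions
oppose (negative dot product of the unit vectors from origin seed to
voxel). The direction test matters: discrete front propagation produces
benign origin discontinuities ("sutures") even on a convex blob, with
seed separations up to a few voxel diagonals, but those fronts flow the
same way; only genuine collisions oppose. The second shock type flags
CGM voxels 26-adjacent to CGM of the other hemisphere.

**Relabelling rule.** For each shock voxel still labelled CGM, D_WM is
its streamline length to the CGM–WM interface — the thickness it would
contribute if kept — and D_allowed is the median thickness of valid
neighbouring cortex within r_nbhd = 5 mm (samples whose own streamlines
avoid shock voxels) plus τ = half the minimum spacing. If no valid
sample exists within r_nbhd (deeply buried neighbourhoods), the nearest
16 valid samples stand in — the "neighbouring parts of the ribbon" are
simply farther away. The voxel becomes CSF iff D_WM > D_allowed. The
relabel → re-solve → re-measure cycle runs twice: cortical thickness is
only a couple of voxels, so the first pass captures nearly all change
and the second verifies stability. Non-shock voxels are never touched,
so the CGM count is non-increasing.

On the default buried-sulcus phantom (2 mm ribbon, fully buried sulci)
the uncorrected median thickness reads 5.8 mm; after enhancement it is
2.15 mm and the relabelled voxels overlap the true buried CSF with Dice
0.74.

## Surface reconstruction and curvature

The interior mask (WM + deep GM + ventricles — everything the CGM–WM
interface encloses) is blurred with an isotropic 1 mm Gaussian, the 0.5
isosurface extracted with marching cubes (padded so the mesh closes),
and the mesh smoothed with 20 umbrella-Laplacian iterations (relaxation
0.5). Both the blur and the smoothing bias the surface inward, several
percent of area for small structures, so the closed mesh is finally
rescaled about its centroid to enclose the same volume as the voxel
segmentation it represents. A Taubin λ|μ smoother is available as an
alternative; it preserves area without rescaling but leaves more
mid-frequency ripple.

Vertices whose nearest deep-GM/ventricle voxel (within 2 mm) is closer
than the nearest CGM voxel are flagged as the WM–deep GM boundary and
excluded from all area and curvature summaries; a triangle is dropped
when ≥ 2 of its vertices are flagged, so flagged + retained area equals
the total exactly.

**Curvature.** Principal curvatures come from a least-squares quadric
z = ax² + bxy + cy² + dx + ey over the neighbours within a support
radius D of each vertex, in its tangent frame, via the shape operator at
the origin (outward normals; convex surfaces have positive H).
Neighbours whose normals oppose the centre's are discarded — on thin
structures (the 2 mm ribbon, a plate) a Euclidean ball otherwise leaks
through to the opposite sheet. Two error sources trade off against D:
residual voxelization ripple drowns the quadric sag when D is small, and
the surface's quartic term inflates the fitted curvature by
≈ (κD)²-order when D is large. Balancing them gives
D = 0.56·(ē·R_est³)^¼, where ē is the median edge length and R_est the
reciprocal median curvedness of a small-support first pass; the
remaining truncation bias is divided out as k ← k/(1 + (kD)²/7), with
the coefficient calibrated on sphere phantoms across R = 10–50 mm. All
lengths are in units of ē, so the estimator is exactly invariant under
uniform scaling. Fixed supports (`rings=...`) remain available.

The T-normalized norms use the retained area A, the mesh-enclosed
volume V (divergence theorem, chosen over the segmentation voxel volume
for self-consistency of the mesh metrics; the volume-restoring rescale
makes the two agree to < 1% anyway), T = 3V/A, and barycentric vertex
area weights. Each norm
equals 1 exactly on a sphere under the adopted formulas, which fixes the
typographically ambiguous exponents: GC_T = (T/A)Σc dA,
MLN_T = T·[(1/A)ΣH²dA]^½, GLN_T = T·[(1/A)ΣG²dA]^¼ — the unique
dimensionless, sphere-calibrated reading. Measured on reconstructed
sphere phantoms R = 10–50 mm, all three norms, T/R, the area ratio and
the Gauss–Bonnet integral sit within ≈ 2% of their analytic values.

Vertex region labels are the id of the nearest CGM voxel centre (ties to
the lowest id); a triangle belongs to the majority region of its
vertices. Regional norms use the region's own area with the global T.
Relative volumes divide by the brain volume excluding CSF, ventricles
and backgrounds; relative surface areas divide by the total retained
area, so each sums to 100%.

## 4D atlas by kernel regression

P_{k,t} = Σ_s w(t_s,t)·M_{s,k} / Σ_s w(t_s,t) with the Gaussian kernel
w = (σ_w√2π)⁻¹·exp(−(t_s−t)²/2σ_w²), σ_w = 1 week, and w forced to 0
when the subject's rounded age is more than 3 weeks from t — matching
the range of template ages each segmentation is warped to (window = ∞
gives the pure kernel). Registration itself is out of scope: the builder
consumes pre-warped masks on a common grid from a manifest, and fuzzy
(interpolated) masks are averaged unchanged. The default grid is 28–44
weeks, weekly: 17 timepoints. When the input masks partition the grid,
the per-voxel probability sums stay 1 to 10⁻⁶, and the maximum
probability atlas takes the argmax (ties to the lowest id). Tests check
exact agreement with a brute-force weighted average at sampled voxels,
the single-subject identity, and that an age-growing phantom cohort
yields monotonically growing atlas structures.

## Growth models

The signed Gompertz f(t) = β₁ + β₂·exp(−exp(−β₃(t−β₄))) (initial value
β₁, total signed change β₂, rate β₃, peak-growth age β₄; β₂ < 0 models
decline) is fitted by Levenberg–Marquardt from a deterministic
multistart grid: β₄ at the quartiles of the age range, β₃ in
{±0.1, ±0.3, ±1}, (β₁, β₂) from the endpoint means in both
orientations, plus one near-linear start (tiny rate, matched slope) that
guarantees the fit never does worse than the least-squares line. No
parameter bounds. The linear comparator reports Pearson r and adjusted
R² = 1 − (1−R²)(n−1)/(n−2); constant-y data returns a flagged degenerate
fit (r = 0) so batch runs over many structures never abort. Models are
compared by SSE; a Gompertz fit is "substantial" at ≥ 5% SSE reduction.
Noiseless curves are recovered to 10⁻³ relative; with 5%-of-range noise
at n = 200 the median β₄ error is ≈ 0.06 weeks over 100 seeded cohorts.

## Phantoms: what they emulate, and what they do not

All generators are bit-reproducible from (parameters, seed) and carry
enough analytic truth to score each method without re-deriving geometry.
Default contrast (arbitrary units): CSF 200, WM 140, deep GM 110, CGM
90, background 20, Gaussian noise σ = 8 — the WM > CGM ordering of
neonatal T2.

* **Sphere / shell / slab** — analytic area, volume and thickness
  oracles for the surface and Laplace estimators.
* **Folded ribbon** — WM under the surface z = z₀ + A·cos(2πx/λ) with a
  constant-thickness CGM sheet (all voxels within Euclidean distance t₀
  of WM) and CSF above. Defaults t₀ = 2 mm, λ = 10 mm, A = 10 mm: deep,
  narrow sulci whose CSF channels stay thinner than the PV width over
  nearly their full depth, so that with `buried=True` (thin-CSF found by
  morphological opening with a ball of `pv_width` = 5 voxels, then given
  CGM labels and intensity) essentially the whole sulcal channel is
  fused — the pathology the enhancement targets. `pv_boundary=True`
  gives the WM-side interface layer mixture intensities
  α·I_WM + (1−α)·I_CGM, α ~ U(0.25, 0.75), for the EM PV class.
* **Hemisphere contact** — left/right CGM blocks meeting on a known
  plane, for the inter-hemispheric shock rule.
* **Atlas cohort** — concentric core/shell/CSF label maps with outer
  radius 2.0 + 0.45·age mm over ages uniform in [27, 45] weeks
  (identity warp), mirroring the scan-age span of a neonatal cohort.
* **Growth cohort** — seeded noisy samples from a known Gompertz curve.

What the phantoms do **not** emulate: bias fields, Rician noise, motion,
real gyral geometry (single-direction sinusoidal folds only), real
registration error in the atlas masks (identity warps), and anatomical
variability between subjects beyond a radius law. Passing tests
therefore demonstrate the correctness and calibration of the numerics on
controlled geometry — not clinical-grade performance on real MRI.

## Problem sizes

Unit tests run on 24³–64³ grids and spheres up to R = 50 mm at 1 mm
spacing; the acceptance script uses the same sizes plus a 50-subject 64³
atlas cohort and 100 Gompertz cohorts of n = 200. The full suite
completes in about four minutes on one CPU; the acceptance script in
about five.

## Known limitations

* Mesh topology is not corrected; the inner surface of a clean
  segmentation is relied on to be genus 0 (phantoms are).
* The volume-restoring rescale is a global uniform scaling; it restores
  the enclosed volume exactly but compensates curvature-dependent blur
  erosion only on average.
* The adaptive curvature support uses one global radius derived from the
  median curvedness; surfaces mixing very different curvature scales are
  estimated at a compromise support (per-vertex adaptation was tried and
  rejected: it self-selects on noise).
* Sulci enhancement only relabels; it does not re-run EM afterwards.
* Bank collisions closer than d_min (very shallow fused sulci) are
  undetectable by construction; the thickness rule could not relabel
  them anyway without violating the local-thickness constraint.
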