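# Methods

## Diffusion models

**Tensor fit.** The diffusion tensor is estimated voxel-wise by ordinary
least squares on the log-signal with the design
`[-b g_x^2, -b g_y^2, -b g_z^2, -2b g_x g_y, -2b g_x g_z, -2b g_y g_z, 1]`
acting on the six unique tensor components and log S0. Eigenvalues are
clamped at zero before scalar computation (noise can break positivity;
clamping keeps FA in [0, 1] and matches common tooling behaviour). Scalars
follow the standard formulas: MD = (λ1+λ2+λ3)/3, AD = λ1, RD = (λ2+λ3)/2,
FA = sqrt(3/2 · Σ(λi − λ̄)² / Σλi²), with FA of an all-zero tensor defined
as 0. Voxels with non-positive signal are flagged invalid rather than
aborting the fit. Shell extraction keeps one shell's diffusion-weighted
volumes (±50 s/mm² matching tolerance) plus all b=0 volumes.

**Watson-NODDI.** The normalized signal is

    S/S0 = (1 − f_iso)·[f_icvf·A_ic + (1 − f_icvf)·A_ec] + f_iso·exp(−b·d_iso)

with fixed diffusivities d_par = 1.7×10⁻³ mm²/s and d_iso = 3.0×10⁻³ mm²/s
(standard in-vivo defaults). A_ic averages the stick attenuation
exp(−b·d_par·(g·n)²) over a Watson(μ, κ) orientation distribution. The
average is computed by product quadrature in the μ-frame — 50-point
Gauss–Legendre in cos θ times 32 uniform azimuthal nodes; the Watson weight
is azimuth-free so the normalization constant uses the same nodes and
cancels quadrature bias. Against a 400×200 reference rule the worst error
over κ ∈ [0.1, 100] is below 10⁻⁹. Above κ = 10⁴ the distribution is
treated as a delta (coherent stick); quadrature would need resolution
~1/√κ there. A_ec is the Watson-averaged axisymmetric Gaussian compartment:
with the tortuosity constraint d_perp = d_par·(1 − f_icvf) and
τ₁ = ⟨(μ·n)²⟩, the averaged tensor has axial diffusivity
d_perp + (d_par − d_perp)·τ₁ and radial (d_par − d_perp)(1 − τ₁)/2 above
d_perp. The orientation dispersion index is ODI = (2/π)·arctan(1/κ).

**Fitting.** Per voxel: S0 is the mean of the b=0 volumes; the orientation
is seeded from the tensor principal eigenvector; a coarse deterministic
grid over (f_iso, f_icvf, ODI) (6×5×6 candidates, with the κ-dependent
pieces computed once per ODI) picks the start for bounded nonlinear least
squares over (f_iso, f_icvf, log κ, θ, φ). No random restarts — the fit is
a pure function of the data. Noise-free recovery over the acceptance grid
(f_iso ∈ [0, 0.4], f_icvf ∈ [0.3, 0.8], ODI ∈ [0.05, 0.6]) is exact to
~10⁻⁷ per parameter. The compartment reparameterization
FICV = (1 − f_iso)·f_icvf, FECV = (1 − f_iso)(1 − f_icvf), FISO = f_iso
closes to 1 by construction; the RGB composite maps red = FECV,
green = FICV, blue = FISO.

## Along-tract profiling

Streamlines are reoriented so that every first vertex is the end nearer a
common origin anchor (ties within 10⁻⁶ mm keep the original order, logged).
Each streamline is reparameterized by an interpolating cubic B-spline
(linear fallback below 4 vertices) and resampled to 100 points at equal
arc-length increments; arc length is inverted on a 1000-segment
piecewise-linear subdivision of the spline. Metric volumes are sampled at
each vertex through the inverse affine; the default interpolation is
trilinear (exact on linear fields), nearest-neighbour is selectable.
Samples outside the grid or over NaN background are undefined and excluded
from the point's statistics (zero-filling would bias fractions downward).
The cross-sectional mean and sample SD (n−1 denominator; SD of a
single-streamline tract defined as 0) over the per-point vertex set give
the profile; points 1, 2, 99, 100 are then discarded (endpoint
instability), retaining labels 3–98. The skeleton is the per-index mean of
the resampled vertex coordinates and is used for inspection and as a test
oracle, not for statistics — profiles are computed over per-vertex sets.

## Normative database

Per tract/side/metric and per trimmed point: across-subject mean, sample
SD, and the t-based 95% CI mean ± t(0.975, n−1)·SD/√n, so CI width / SD =
2·t(0.975, n−1)/√n (≈ 1.1076 at n = 15). Outlier screening runs two
independent tests per point: Tukey fences at Q1 − 1.5·IQR / Q3 + 1.5·IQR
with type-7 (linear-interpolation) quartiles, and a ROUT-style screen
adapted to a univariate location model — the robust center is the
Lorentzian M-estimate found by damped IRLS from the median (weights
1/(1 + (r/s)²), scale s re-estimated each sweep as the RSDR: the 68.27th
percentile of |residuals| times n/(n−1)); scaled residuals are referred to
a t distribution with n−1 df and tested step-down from the largest |t|,
flagging while the two-tailed p < Q·(n−i+1)/n. On clean Gaussian 15-value
sets at Q = 1% the flag rate is ≈ 1%. The coefficient of variation
100·SD/mean is summarized by median and quartiles over the 96 points
(zero-mean points excluded, logged). Inter-metric relations use Spearman
rank correlation with midranks and the large-sample p-value; constant
input reports r as missing.

## Asymmetry testing

Left and right cross-sectional means are compared per point with a
Wilcoxon matched-pairs signed-rank test: zero differences discarded,
midranks for tied magnitudes, exact two-sided p from the subset-sum null
distribution of W (equivalent to enumerating all 2ⁿ sign patterns) when
the effective n ≤ 25 and there are no ties, otherwise a normal
approximation with continuity and tie corrections. Bonferroni multiplies
by exactly 96 (the per-tract-metric family size); significance is strict
(adjusted p < 0.05). Points with fewer than 6 complete pairs are skipped —
the exact p cannot reach the corrected threshold at such n. A
D'Agostino–Pearson omnibus normality screen (n ≥ 8) is provided to
document why the nonparametric test is used; it never gates the Wilcoxon
test. Significant points are reported as contiguous ranges with the
direction of the median paired difference.

## Patient deviation and pattern taxonomy

A patient point is flagged when |patient − normative mean| ≥ 2 normative
SDs (boundary inclusive; the normative SD is the across-subject SD of
cross-sectional means). Zero-SD points are unflaggable and marked missing.
Maximal contiguous runs are reported as "points [a–b]" with no minimum run
length. Classification evaluates, in order:

* **D** — FISO-high present and no other metric flagged;
* **C** — FICV-low, FECV-high, FA-low and FISO-high all present, with the
  FA-low extent ≥ ρ times the FICV-low extent;
* **B** — FICV-low and FECV-high with any FA-high segment;
* **A** — FICV-low and FECV-high, no FA-high, and FA-low extent < ρ times
  the FICV-low extent;
* **none** otherwise.

"Remarkably shorter segment" is operationalized as the point-count ratio
ρ = 0.5 (configurable); D precedes C so the singleton patterns are not
absorbed, and the trace records the counts and the rule that fired. The
FA used for patient comparison defaults to the high-b (b = 3000 s/mm²)
shell; the shell-wise MD comparison flags each shell against its own
normative profile and summarizes state agreement and whether the low-b
curve dominates (restricted diffusion lowers apparent diffusivity at high
b, so healthy MD(b=711) > MD(b=3000) point-wise).

## Synthetic cohort

The generator defines the study conditions: 15 bilateral subjects, 7
nameable bundle shapes (AF, FAT, IFOF, UF, CING, CST, OR — synthetic
helical/arc centerlines that exercise curvature, reorientation and
resampling; not anatomical models), 20 streamlines per bundle with smooth
3-D jitter of 1 mm pointwise SD, and 2 mm isotropic grids (a typical dMRI
resolution; the acquisition geometry is otherwise unspecified upstream).
Along-arc templates are smooth functions of s ∈ [0, 1] with FISO ≈ 0.05
(free water nearly absent in healthy tracts), tissue intra-neurite
fraction ≈ 0.55, ODI in the coherent-to-moderate range and FA tied
inversely to ODI; diffusivity templates satisfy MD = (AD + 2RD)/3.
Compartment closure holds to 10⁻¹² everywhere, before and after
perturbation.

Between-subject variability is a smooth random field per subject, side and
metric — sd/√3 · (z₀ + √2 z₁ cos πs + √2 z₂ sin πs), which has pointwise
SD exactly `sd` — with default SD 0.017 for fraction-type metrics (inside
the healthy range of across-subject SDs for such metrics) and 3×10⁻⁵
mm²/s for diffusivities. Compartment offsets are the sum-zero projection
of three iid fields scaled by √(3/2), so each compartment keeps the
nominal pointwise SD and the sum-to-1 constraint holds without
renormalization shrinkage. Configured asymmetries (e.g. a left-only FICV
offset) are compensated in the complementary tissue compartment so the
named metric shifts by exactly the configured delta.

Lesion perturbations apply windowed deltas (cubic smoothstep taper, width
0.05 inside the interval edges) with pattern-specific signs; compartment
deltas are renormalized to closure. Pattern defaults: A (FICV −0.10,
FECV +0.10), B (adds ODI −0.10, FA +0.10), C (FICV −0.15, FECV +0.07,
FISO +0.08, FA −0.12; deltas sum to zero across compartments), D (FISO
+0.055). D's amplitude is deliberately smaller: renormalization spreads an
FISO rise across the tissue fractions by ≈ FICV·δ/(1+δ), and above ≈ 0.06
that induced shift would itself cross the 2-SD band, making an "isolated"
FISO upsurge unrealizable.

DWI simulation evaluates the Watson-NODDI forward model per voxel on the
two-shell scheme (60 directions at b = 3000 s/mm², 35 at b = 711 s/mm²,
11 b=0 volumes; Fibonacci-spiral gradient tables) and applies Rician noise
(magnitude-MRI convention, sigma = S0/SNR, seeded). Volume painting
assigns each traversed voxel the template value at the arc position of the
nearest dense streamline sample, pads a 2.5 mm rim by nearest-neighbour
propagation (so trilinear sampling near the bundle surface does not touch
NaN background), and fills the background with NaN.

What the generator does not emulate: tractography errors (crossing-fiber
ambiguity, spurious streamlines), acquisition artifacts (eddy currents,
susceptibility distortion, motion), partial-volume mixing of multiple
tracts, and anatomically realistic bundle shapes. Passing tests therefore
demonstrate correctness of the models and statistics under the stated
conditions, not robustness to those real-data effects.

## Problem sizes and determinism

The test suite runs the NODDI recovery grid at 5×5×5 parameter
combinations on a single orientation, statistical calibrations at 100–200
simulated cohorts (10,000 sets for the ROUT false-discovery check, 1,500
subjects for the null flag-rate calibration, whose per-subject counts are
heavy-tailed because smooth noise flags whole runs at once), and the
classifier confusion matrix at 20 seeded lesions per pattern with
deterministic patients flagged against the generator's true mean and SD —
the 100%-recovery property belongs to the decision rules, while behaviour
under healthy variability is covered by the flag-rate calibration. All
randomness flows through seeded `numpy` generators; every generator output
is a pure function of (configuration, seed).

## Known limitations

* The NODDI fit holds d_par and d_iso fixed (as standard); bias from
  misspecified diffusivities is not modelled.
* ROUT is defined for nonlinear regression; the univariate location
  adaptation documented above is this package's own.
* No age/sex covariate adjustment of the normative database.
* Bingham-type anisotropic dispersion and restricted-sphere (tumor-cell)
  compartments are out of scope.
* Single-shell NODDI fits are accepted with a warning but are poorly
  identified.
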