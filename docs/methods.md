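# Methods

## Signal model and estimators

The package models the diffusion-weighted signal with the two-term cumulant
expansion

    log S(b, n̂) = −b nᵢnⱼDᵢⱼ + (b²/6) D̄² nᵢnⱼnₖnₗWᵢⱼₖₗ,

valid for moderate diffusion weighting (second order in b).  `D` is the
symmetric positive-semidefinite diffusion tensor in μm²/ms; `W` is the
fully symmetric rank-4 kurtosis tensor (dimensionless, 15 unique
components); `D̄ = Tr(D)/3` is the mean diffusivity (MD).  b-values are in
ms/μm² throughout, so b = 1 means 1000 s/mm².

The mean of the kurtosis tensor (MKT, `W̄`) is the spherical average of the
apparent kurtosis `W(n̂) = nᵢnⱼnₖnₗWᵢⱼₖₗ`.  For fully symmetric `W` this
equals `(1/5)Tr(W)` with
`Tr(W) = W_xxxx + W_yyyy + W_zzzz + 2W_xxyy + 2W_xxzz + 2W_yyzz`, which is
also the Frobenius pairing `(1/5)⟨W, I⟩` with the fully symmetric isotropic
tensor `I_ijkl = (δᵢⱼδₖₗ + δᵢₖδⱼₗ + δᵢₗδⱼₖ)/3` (unit trace-form: `I(n̂) = 1`
for every unit vector).  `W` can equivalently be defined from fourth-order
displacement moments over the diffusion time; the package never computes
from displacements, only from signals, so that definition is documentation
only.

### The 1-9-9 scheme

One b = 0 volume plus nine directions at each of two shells b₁ < b₂.  The
default directions are the coordinate axes (weight 1/15 each) and the six
in-plane bisectors (1,±1,0)/√2, (1,0,±1)/√2, (0,1,±1)/√2 (weight 2/15
each).  What makes the scheme work is a pair of moment identities for the
weighted direction set:

    Σ w_d n̂n̂ᵀ = Id/3        (rank 2)
    Σ w_d n̂⊗n̂⊗n̂⊗n̂ = I/5     (rank 4)

so the weighted average of `n̂ᵀDn̂` is exactly `D̄` and of `W(n̂)` exactly
`W̄`, for arbitrary (also anisotropic) tensors: the bisector pairs cancel
every mixed-index cross term.  Scheme construction certifies these two
conditions to 1e−10, which means any globally rotated direction set is
accepted and anything invalid is rejected at configuration time — the
published direction tables are only specified up to such a rotation.

With the weighted log-sums `A_s = Σ w_d log(S(b_s, n̂_d)/S₀)` the model
collapses to `A_s = −b_s D̄ + (b_s²/6) D̄² W̄`, two equations solved in
closed form:

    D̄ = (b₁²A₂ − b₂²A₁)/(b₁b₂² − b₁²b₂)
    W̄ = 6b₁b₂(A₁b₂ − A₂b₁)(b₁ − b₂)/(A₁b₂² − A₂b₁²)².

For noiseless two-term signals the inversion is exact (MD to 1e−10, MKT to
1e−8 in the test suite); the protocol timings δ/Δ are carried as metadata
only, since the closed forms depend on b alone.

### Numerical policy

* Signals are clamped to `max(S, 1e−6·S₀)` before the log; any clamped
  voxel is flagged `NONPOSITIVE_SIGNAL`.
* `|A₁b₂² − A₂b₁²| < 1e−12` (zero decay, i.e. background) flags
  `DEGENERATE_DENOMINATOR` and reports NaN rather than ±inf.
* Estimates outside MD ∈ [0, 4] μm²/ms or MKT ∈ [−1, 5] are flagged, never
  clipped — the plausibility windows are generous around fixed-tissue
  values and configurable.
* A nonpositive S₀ yields an all-flagged NaN estimate, never an exception,
  so whole-volume fits cannot die on background voxels.

## The phantom

The generator emulates the study conditions, not rat anatomy: an
axis-aligned brain ellipsoid (semi-axes 6.8 × 7.4 × 6.8 mm, 1.433 cm³ — the
whole-brain scale of the fixed-tissue volumetry), split into hemispheres at
the mid-sagittal plane, on a 64 × 64 × 30 grid of 0.25 × 0.25 × 0.5 mm
voxels.  The lesion is two confocal ellipsoids in the right hemisphere: a
core (2.4 × 5.0 × 4.62 mm semi-axes, 0.2322 cm³, matching the reported MD
lesion group mean) and the same shape scaled by 1.31^(1/3) (0.3042 cm³,
the reported MKT lesion mean) — so the MKT lesion is 31% larger by design;
rasterized on the grid the voxel-count excess is 31.5%.

Tissue parameters (all configurable):

| region       | MD (μm²/ms) | MKT  |
|--------------|-------------|------|
| normal       | 0.50        | 0.8  |
| lesion core  | 0.35        | 1.3  |
| lesion ring  | 0.50        | 1.3  |

The MD drop is confined to the core while the MKT elevation spans core and
ring — the contrast pattern behind the MD/MKT lesion mismatch — with
magnitudes typical of fixed tissue at high field.  Voxels are isotropic by
default (`D = D̄·Id`, `W = W̄·I`); an axially symmetric mode with
configurable FA exists because the estimators must be exact for
anisotropic voxels too.

Noise is Rician: `S_noisy = √((S + ε₁)² + ε₂²)`, ε ~ N(0, σ), σ = S₀/SNR
referenced to the b = 0 tissue signal.  The default SNR of 50 is a
deliberate choice for long ex-vivo acquisitions (no reported value exists
to copy); a Gaussian mode supports estimator-theory tests.  Identical
(spec, seed) inputs give byte-identical outputs.

What the phantom does **not** emulate: realistic anatomy, partial-volume
mixing at boundaries, B₀/eddy artifacts, fixation gradients, or biological
between-subject variability beyond the optional lesion-size jitter used in
the cohort driver.  Passing tests show the estimator and volumetry chains
are correct under the stated noise model — not that segmentation of real
fixed-brain data would reach the same Dice.  One visible consequence: with
within-phantom variability this small, even a ~1% systematic offset
between measurement arms is statistically "significant" in a paired test
on 7 subjects, so the cohort driver's p-values demonstrate the machinery,
not a claim about real tissue.

## Segmentation

The study this pipeline reproduces outlined lesions manually; an artifact
must be objective, so segmentation is threshold-based against the
contralateral hemisphere: detection selects voxels below mean − k·SD of
the contralateral distribution (`md_low`) or above mean + k·SD
(`mkt_high`), k = 2 by default, keeps the largest 26-connected component,
and seals it morphologically (closing + hole filling) — per-voxel MKT
noise (SD ≈ 0.2 at SNR 50, against a 0.5 contrast) otherwise leaves
interior gaps no rater would draw.

The k·SD cut alone is volumetrically biased: it sits near the normal-tissue
tail, far from the lesion/normal midpoint, so boundary voxels are
misclassified asymmetrically.  The boundary is therefore refined with the
half-way (FWHM) rule standard in lesion and infarct volumetry: the lesion
level is the median map value inside the detected component, and the final
mask is re-thresholded at the midpoint of lesion and contralateral levels
on a lightly smoothed map (masked Gaussian, σ = 1 voxel).  The half-way
crossing of a smoothed two-level edge coincides with the true edge
independently of the blur width (curvature bias ~σ²/r, negligible here),
which is what makes the volumes nearly unbiased: at SNR 50 the recovered
MD and MKT lesion volumes sit within ~1–3% of truth, Dice ≥ 0.98, and the
recovered volume excess averages 29.1 ± 0.6% against the 31.5% voxelized
design.  The residual ~2-point deficit is the remaining noise-asymmetry of
the MKT boundary (the core's MKT noise is largest because the closed form
divides by D̄², and D̄ is lowest there).

Degenerate inputs behave predictably: a uniform map yields an empty mask
(the SD floor `1e−9·(|mean|+1)` prevents knife-edging on float jitter in
noiseless maps); an empty contralateral mask or unknown mode raises.
Hemisphere statistics use explicit masks; the default split is the
mid-sagittal plane.  Mask volume is exact integer arithmetic times the
voxel volume, reported in cm³.

## Stereology

`slice_sections` cuts a mask into contiguous coronal sections of nominal
thickness t (40 μm default) by nearest-neighbor resampling at each section
center; a partial terminal section is kept iff it spans ≥ t/2.
`systematic_sample` keeps every (1/SSF)-th section from a start offset;
across all offsets each section is used exactly once, which is the
algebraic content of Cavalieri unbiasedness: the mean of
`V = t·(1/SSF)·Σaᵢ` over the 1/SSF equally likely starts equals the
full-stack Riemann volume exactly, and matches the voxel volume of the
sectioned mask to well under 2%.

Per-section areas come from two estimators:

* **Point counting**: a d-spaced grid (default d = 0.1 mm) with uniform
  random offset; a point counts iff its containing pixel is foreground
  (half-open pixel convention — deterministic on rasters).  Unbiased over
  offsets; exact for axis-aligned rectangles with dividing grids.
* **2D nucleator**: `a = π·mean l(θ)²` over a systematic fan of 64 rays
  with one uniform random rotation, where l(θ) is the distance to the
  first boundary crossing, found by marching at 0.25-pixel steps on a
  bilinearly sampled mask with linear interpolation at the 0.5-level
  crossing.  Exact for sections star-shaped about the reference point
  (disk recovered to < 0.1%); if any ray re-enters the mask the result
  carries a `non_star_shaped` flag, since the estimate is then biased low.
  Grid spacing and ray count were not reported for the original software
  and are exposed in the API.

## Statistics

Shapiro–Wilk (3 ≤ n ≤ 5000, Royston's approximation via scipy; holds its
5% size at n = 7 to within Monte-Carlo tolerance), two-sided paired t
(df = n − 1; identical pairs give t = 0, p = 1; a constant nonzero shift
reports ±inf with p = 0), and one-way ANOVA delegate to vetted routines.
The single-measure two-way absolute-agreement ICC — the conservative
default when each cell holds one rating — is computed here from the
two-way mean squares,

    ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)),

with the F-based 95% CI; it is cross-checked against an independent
implementation in the tests.  Absolute agreement penalizes systematic
rater offsets, unlike consistency ICCs, which is the property the
volumetry comparison needs.  `build_report` consumes a tidy table
(subject, method, volume_cm3, optional rater/repeat), excludes subjects
missing any method listwise with a logged warning (mirroring cohorts where
one arm fails for some subjects), and emits group means ± SD, all pairwise
paired tests, the MKT-vs-MD mismatch percent, and ICC tables where repeats
exist.  Tests are two-sided at α = 0.05 with no multiplicity correction.

## Problem sizes

The default phantom (45,856 brain voxels, 19 volumes) fits in well under a
second per noise realization, so the repeated-measures drivers use 50
realizations and the test suite's Monte-Carlo checks use 10⁴ replicates
for test calibration, 10³ tensors for the exactness properties, and 3–5
seeds where a property is already tight per seed.  These sizes give
standard errors comfortably below the asserted tolerances.
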