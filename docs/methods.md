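# Methods

## Tissue model and simulation

Each voxel of tissue class *c* follows the indicator-dilution model

    C(t) = k · (CBF_c / 60) · (AIF ⊛ R_c)(t − delay_c)

with a mono-exponential residue function `R_c(t) = exp(−t / MTT_c)` (a box
residue of width MTT is available as the plug-flow alternative). The unit
constant *k* folds tissue density and hematocrit correction into a single
factor, default 1.0 so that map-recovery checks are exact; it is
configurable for realism. Under this model the central volume principle
`CBV = CBF · MTT / 60` holds identically, and the time-integral of the
tissue curve equals `k · CBV` times the AIF integral — a conservation law
the test suite checks by dense-grid quadrature to 1%.

The arterial input is a gamma-variate,
`AIF(t) = A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)`, normalised to peak at
amplitude *A* exactly at `t0 + αβ`; the venous curve is a delayed, scaled
copy. Defaults: `t0 = 4 s` (scan start precedes bolus arrival, giving a
pre-bolus baseline), `α = 3`, `β = 1.5 s`, `A = 300 HU`. Acquisition
defaults emulate a clinical DCI screening protocol: 4-s sampling, 60-s
duration, additive i.i.d. Gaussian noise of 2 HU. Tissue curves are
computed per class on a 0.1-s grid with trapezoid-corrected discrete
convolution, then sampled at the acquisition times; every stochastic step
takes an explicit seed and no global random state is used.

The phantom is a mirror-symmetric ellipsoidal brain (two hemispheres split
at the mid-sagittal grid plane; "left" is the lower-index half of the last
array axis — an array convention, not a radiological one) of homogeneous
normal tissue (CBF 50 mL/100 g/min, MTT 4 s) with one spherical lesion.
The default lesion (CBF 12 mL/100 g/min, MTT 8 s, arrival delay 7 s, hence
CBV 1.6 mL/100 g) was chosen so that every default segmentation rule is
violated strictly in ground truth — rCBF 0.24 < 0.30, rMTT 2.0 > 1.5,
CBV < 2 mL/100 g, Tmax ≈ 7 s > 6 s — while the convolution tail still fits
inside the 60-s acquisition (tail truncation of the lesion curve < 2%,
keeping area-based CBV estimation honest).

## Map estimation

All curves are baseline-subtracted (baseline window = frames before the
AIF reaches 10% of its peak) and linearly resampled to a common 1-s grid.
Per voxel:

* **CBV** = (∫C_tissue / ∫AIF′)/k, with AIF′ optionally area-rescaled to
  the venous curve (partial-volume correction, default off for synthetic
  data where k = 1 makes it redundant);
* **CBF** = 60 · max_t r̂(t) / k, where r̂ is the truncated-SVD
  deconvolution of the tissue curve against the AIF. The default mode is
  block-circulant (curves zero-padded to twice their length), whose SVD is
  the discrete Fourier transform; truncation zeroes singular values below
  0.2 of the largest. Block-circulant deconvolution is delay-insensitive:
  an arrival delay shifts the residue peak rather than attenuating it,
  which is exactly how **Tmax** (= argmax of r̂) is read off. A standard
  (lower-triangular Toeplitz, delay-sensitive) mode is available for
  comparison.
* **MTT** = 60 · CBV / CBF where CBF > 0, else 0 — so the central volume
  principle holds in the output by construction; voxels without measurable
  contrast (non-positive curve area) get all parameters 0 by convention and
  are excluded from reference means.
* **TTP** = argmax of the tissue curve, measured from scan start (Tmax is
  likewise reported from scan start; both live on the 1-s grid).
* **CTH** = standard deviation of the transit-time density
  `h(t) = −dR̂/dt` (clipped at 0, renormalised), with the residue
  normalised at its peak so the estimate is delay-robust. For an
  exponential residue CTH equals MTT (sd = mean); for a box residue it is
  0 up to grid resolution.

Relative maps divide each voxel by the mean of the parameter over the
brain-masked, perfused voxels of the *contralateral* hemisphere (rCBF,
rMTT).

### Known limitation: SVD CBF bias at 4-s sampling

Truncated-SVD deconvolution reconstructs the residue from the frequency
band where the AIF has spectral power. For a mono-exponential residue with
MTT comparable to the sampling interval, the residue peak needs
frequencies far beyond that band, so its reconstruction is biased low —
tens of percent at 4-s sampling — and the bias is MTT-dependent (short-MTT
normal tissue loses more than the long-MTT lesion). Lowering the
truncation does not help: below ~1% of the largest singular value, the
interpolation error of the 4-s-sampled tissue curve is amplified
catastrophically. Consequences, all measured by the acceptance machinery:
CBV recovers within ~2% (it needs no deconvolution), Tmax shifts match
designed delays to the grid step, but CBF is underestimated (~30–50%) and
MTT correspondingly overestimated, and the differential bias inflates
estimated rCBF enough that the full simulate→deconvolve→segment chain
reports 0 mL core for the default lesion (its hypoperfused Tmax volume is
recovered correctly). This mirrors the well-known underestimation
behaviour of SVD-based CTP software rather than a fixable defect of this
implementation; the segmentation rules themselves are therefore validated
on designed (ground-truth) maps via `maps_from_phantom`, and the
estimation chain's accuracy is reported as measured.

## Segmentation rules

All inequalities are strict, exactly as the vendors state them. The
pathological side is the hemisphere holding the larger Tmax-lesion volume
(ties: larger summed Tmax, then left; a zero lesion is flagged). For the
threshold and mirror methods, hypoperfused = {Tmax > 6 s} within the brain
mask, and core ⊆ hypoperfused by construction. The mirror method's
baseline is the median CBF inside the lesion mirrored across the midline;
if the mirror ROI leaves the brain mask entirely (midline lesions), the
contralateral-hemisphere median is used and the result flagged. The ISP
method partitions the rMTT > 150% lesion by the 2 mL/100 g CBV cutoff into
disjoint compartments; because the published rule direction inverts
standard core physiology, both dialects ship (`conventional`: core = low
CBV, the default; `as-printed`: the inequalities exactly as published,
with CBV = 2 ties going to the other compartment so the compartments always
partition the lesion). The midline is the mid-plane of the mask's bounding
box along the left–right axis (override available); voxels exactly on an
integer midline plane are assigned left.

Whether a vendor's "hypoperfused volume" excludes core voxels is not
standardised: the Cercare-style methods here report the full Tmax lesion
as hypoperfused (core is a subset), while ISP reports disjoint
compartments plus their union.

## Final-infarct standard

The follow-up plain CT is thresholded below a configurable hypodensity
cutoff (default 25 HU, typical subacute infarct attenuation — a stand-in,
passed explicitly wherever it matters) inside the brain mask; a supplied
prior-lesion mask is subtracted (emulating the exclusion of pre-existing
post-hemorrhagic or ischemic lesions), and 26-connected components below
0.5 mL are removed as the non-interactive stand-in for manual clean-up.

## Cohort generator and statistics

Cohort records are generated per examination: final-infarct positivity is
drawn once (it is shared by all algorithms), then each algorithm ×
compartment draws predicted positivity conditional on infarct status so
the designed four-category mixture is matched in distribution. Default
mixtures and mean volumes are calibrated to the published 123-examination
cohort (hypoperfused means 13.7/38.0/41.6 mL for threshold/mirror/ISP,
cores 2.7/6.4/9.8 mL — cohort means including zeros; the nonzero
log-normal component mean is mean/positive-fraction, with log-sd 1.0). The
final-infarct cohort mean defaults to 9.0 mL, a value at the core-volume
scale chosen because the source cohort prints no infarct mean. Treatment
flags (treated/untreated/excluded) follow the published 56/51/16 split.
The order-of-magnitude differences between algorithm means produce the
variance heterogeneity that motivates Welch-type statistics. The generator
emulates the *joint positivity structure and marginal volume scales* of a
real cohort; it does not model between-algorithm volume correlations
within an examination or core ⊆ hypoperfused ordering, so passing tests
validate the evaluation machinery, not clinical effect sizes.

Welch's ANOVA and Games–Howell are implemented from their closed forms on
scipy's F and studentized-range distributions; a group with zero variance
raises an error naming the group. At k = 2 with balanced, equal-variance
groups Welch's F equals the classical ANOVA F exactly; for k > 2 the
small-sample denominator `1 + 2(k−2)A/(k²−1)` keeps them apart at finite
n, a fact the tests pin down explicitly. Games–Howell p values come from
the studentized range at `q = t√2` with Welch–Satterthwaite pairwise df,
which reduces exactly to the two-sided Welch t-test at k = 2. pingouin's
independent implementations serve as cross-checks in the test suite.

Prediction positivity is strict (> 0 mL, epsilon configurable for noisy
segmentations); undefined metrics are never coerced to 0 or 1 but carried
as an explicit marker and printed `/`; percentages display at one decimal
while raw fractions are kept in machine output. Treatment strata drop
records flagged `excluded` (prior intra-arterial treatment); the overall
stratum keeps everything.

## Problem sizes and numerical choices

The acceptance machinery uses the 64³ default phantom (≈81k brain voxels,
deconvolution vectorised over voxels via rFFT), 100 random 12×20×20 map
phantoms for segmentation invariants, and n = 10⁴ cohorts for generator
calibration — sizes at which every check runs in seconds on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances. Studentized
-range p values are evaluated numerically (documented tolerance 1e-6).
Degenerate inputs are defined, not special-cased ad hoc: empty Tmax
lesions yield zero-volume results with a flag, zero-contrast voxels yield
zero maps, and zero denominators yield the undefined marker.
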