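# Methods

## Imaging model and conventions

Volumes are 3D scalar grids with voxel spacing `(dx, dy, dz)` in mm;
axial slices are stacked along the third array axis, and every
"per-slice" computation iterates that axis. Coordinates are
voxel-center based: voxel `(i, j, k)` sits at `origin + (i·dx, j·dy,
k·dz)`. CT and PET are assumed co-registered on a common grid (hybrid
PET/CT output); any shape/spacing/origin mismatch larger than 1e-6 mm
between companion volumes aborts the computation rather than producing
a number. Masks are booleans in memory and 0/1 integer NIfTI on disk.
The default slice thickness everywhere is 3 mm, the acquisition value
the classic Agatston formulation presumes; scoring logs a warning if
the input differs and applies no thickness rescaling.

## Spill-over exclusion

Vertebral Na[18F]F uptake is roughly an order of magnitude above
vascular uptake, and scanner point-spread makes it bleed into the
adjacent aorta. The exclusion takes the vertebral mask, applies a
morphological closing, dilates the result by 10 mm, and subtracts it
from the aortic mask.

Numerical choices:

* Dilation (and the erosion inside closing) is *metric*: a voxel is
  included iff its center lies within the stated Euclidean distance (in
  mm, using the anisotropic spacing) of a foreground voxel center,
  computed with an exact Euclidean distance transform. Voxel-count
  structuring elements would turn "10 mm" into 30 mm along a 3 mm
  axis.
* The distance threshold is inclusive (≤ 10 mm, with a 1e-9 guard for
  float square roots) — conservative for an exclusion.
* The closing radius is not specified by the protocol this follows;
  the default is 3 mm (one slice thickness), enough to bridge
  inter-vertebral gaps without inflating the column, and it is a
  configuration knob. Closing operates in 3D.
* Blood-pool sphere VOIs (1 mL → radius 6.2035 mm) are rasterized by
  the same voxel-center-inside-radius rule; their placement is an
  explicit caller input because it is a manual step in practice.

## Quantification

**Agatston.** Lesions are 2D per-slice objects: 8-connected components
(diagonals connect; 4-connectivity available) of in-mask voxels with
HU ≥ 130 (inclusive), kept when their area `pixels · dx · dy` is
*strictly* greater than 1 mm². Each lesion scores area × weight with
weight 1/2/3/4 for peak HU 130–199/200–299/300–399/≥400; the total is
the sum over lesions and slices. A calcification spanning several
slices contributes one lesion per slice. Lesion ordering (slice, then
first flat pixel index) is deterministic.

**cSUVmax.** The per-slice SUVmax is taken over mask voxels of each
axial slice that intersects the mask; slices without mask voxels are
omitted from the denominator (an empty slice has no maximum). The
blood-pool reference is the mean of the per-sphere SUVmean values
("mean of means" — three measurements averaged), with a pooled-voxel
alternative available; cSUVmax = average per-slice SUVmax − blood-pool
SUVmean, and negative values are returned as-is with a logged warning.

## Survival and agreement statistics

Implemented from first principles; `lifelines` serves only as an
independent cross-check in the tests.

* **Tertiles:** boundaries are the 33.33rd/66.67th
  linear-interpolation percentiles; values equal to a boundary go to
  the lower group. Degenerate (coincident) boundaries are an error.
* **Kaplan–Meier:** product-limit estimator; at tied times events
  precede censorings (censored subjects stay in the risk set at their
  censoring time).
* **Log-rank:** k-group chi-square from the grouped observed-minus-
  expected vector and its hypergeometric covariance, df = k − 1;
  pairwise two-group tests are reported without multiplicity
  adjustment (matching how such pairwise p-values are conventionally
  presented in this literature).
* **Cox regression:** partial likelihood with Efron tie handling
  (Breslow available; identical when no ties), maximized by Newton
  iteration with step-halving to gradient max-norm < 1e-8 (at most 100
  iterations). Covariates are internally standardized for
  conditioning and back-transformed. Standard errors come from the
  inverse observed information; the likelihood-ratio test compares
  against the null model; Wald z = coef/SE per covariate. A
  standardized coefficient exceeding 10 flags likely monotone
  likelihood (separation). The step-halving acceptance slack is
  relative to |log-likelihood| so float-level wiggle near the optimum
  cannot stall the iteration. The default analysis adjusts for age
  only and uses the continuous biomarker (tertile-group predictors are
  possible by passing indicator covariates).
* **Cohen's kappa:** κ = (p_o − p_e)/(1 − p_e) with chance agreement
  from marginal products; 95% CI = κ ± 1.96·SE with the large-sample
  SE √(p_o(1−p_o)/(n(1−p_e)²)).
* **Concordance:** percent identically classified, overall and per
  group, with per-group denominators defined by the *first* labelling
  (the cSUVmax groups in the standard analysis) — the convention is
  stated because the alternative denominator is equally defensible.

## Synthetic phantoms

A phantom is a tube ("aorta", soft-tissue lumen 40 HU, blood-pool
1.0 SUV) beside an axis-aligned cuboid column ("vertebrae", 700 HU,
10 SUV) in a −50 HU background, with rectangular uniform-HU lesions
(parameterized 60–1000 HU, so both sides of the 130 HU threshold and
all four weight bins occur) and single-voxel PET hotspots (1.5–5 SUV)
inside the aorta, on a 48 × 48 × 28 grid at (1, 1, 3) mm. Bone uptake
spills into a halo `3·exp(−d/2 mm)` truncated at 9 mm from the column.

The ground truth is closed form, not image-derived: total Agatston is
Σ area × weight over lesions with HU ≥ 130 and area > 1 mm², and
cSUVmax is the mean over aortic slices of max(blood pool, hotspots on
that slice) minus the blood pool. Three design rules make the truth
exact for the *corrected*-mask pipeline at zero noise:

1. the spill halo stops strictly below the 10 mm exclusion distance,
   so no surviving aortic voxel is contaminated;
2. lesions/hotspots must sit > 13 mm (10 mm dilation + 3 mm closing)
   from bone — the generator validates this and rejects specs where
   the exclusion could remove a lesion;
3. same-slice lesions must not touch under 8-connectivity, so
   components never merge.

Gaussian voxel noise (seeded) can be added for robustness experiments;
the reported truth always refers to the noise-free configuration. The
phantoms deliberately do not model PET physics (scatter, PSF blur,
reconstruction), anatomy beyond tube-and-column geometry, or HU
heterogeneity inside a lesion — so passing closure tests demonstrates
the correctness of the *computations*, not robustness to realistic
image degradation.

## Simulated cohorts

Per subject: (cSUVmax, Agatston) are correlated log-normals (log-scale
correlation 0.5) calibrated to the observed cohort scale — cSUVmax
median 0.64, log-sd 0.57 (reproducing tertile boundaries near
0.50/0.77); Agatston median 2893, log-sd 1.9 (tertiles near 1403/7153
and a heavy right tail). Age is normal 61 ± 17 truncated to 7–92
years. Event times are exponential with hazard `baseline ×
HR(tertile of cSUVmax)`; default hazard ratios (1, 1, 5) concentrate
risk in the high tertile. Censoring is administrative, uniform over
0.5–7.3 years (median ≈ 3.9 years and spread matching the reported
follow-up distribution). The default baseline hazard is solved
numerically (≈ 0.0065/yr) so the expected event count is 12 among
n = 216 — the observed clinical scale. All randomness is driven by a
single integer seed per call.

Two deliberate calibration choices:

* The **type-I calibration check** runs the null (hazard ratios
  1, 1, 1) at a baseline of 0.10/yr (~70 expected events) rather than
  the 12-event scale: the chi-square reference distribution of the
  log-rank test is only trustworthy with adequate events, and the
  check is about the test statistic, not the cohort scale. Measured
  rejection rate: ~4.8% over 400 cohorts.
* The **power at the observed scale** is itself a finding: with ~12
  expected events and a 5× high-tertile hazard, the high-vs-low
  pairwise log-rank is significant in only ~60% of simulated cohorts
  (~88% at 24 expected events; see
  `analysis/05_operating_characteristics.py`). A single small cohort
  showing the pattern strongly is therefore partly fortunate, which is
  the package's quantitative caveat on small-cohort feasibility
  claims of this design.

## Known limitations

* No DICOM, resampling or registration: inputs must share a grid.
* SUV values are taken as given; no dose/decay/weight arithmetic.
* The Agatston implementation targets 3 mm non-gated low-dose CT; no
  mass/volume scores, no coronary scoring.
* Kappa's simple asymptotic SE is anti-conservative for very sparse
  tables; for 3×3 tables at n ≈ 216 it is adequate.
* The cohort generator draws biomarkers from smooth log-normals and
  cannot produce the point mass at Agatston = 0 present in real
  populations with no calcification.
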