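# Methods

This note documents the models behind `tsrquant`, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
choices made where the design was genuinely open.

## TSR definition and cutoff

For a tumor region of interest (ROI), the pixel-path tumor–stroma ratio
is

    TSR = A_epithelium / A_stroma

with both areas counted in pixels inside the ROI.  Necrosis and other
non-tumor tissue are labeled 0 ("other") and enter neither numerator nor
denominator.  TSR > 1 denotes a *low stromal component*, TSR ≤ 1 a *high
stromal component*; the cutoff (default 1.0) is configurable everywhere
it is used.  TSR = f/(1−f) is strictly increasing in the epithelium
fraction f of tumor tissue, so the category switches exactly at f = 0.5.
A slide with epithelium but no stroma yields an infinite TSR rather than
an error: the category is still well defined by the cutoff.

The semi-quantitative path emulates pathologist scoring: per-field
epithelium fractions from medium-power fields are averaged, the mean is
rounded to the nearest decile, and the score is expressed as
epithelium/stroma out of 10 (6/4 → TSR 1.5).  The tie rule is round half
up on the epithelium mean (0.45 → 5/5); no convention is standard for
this, so a deterministic documented one was chosen.  Multi-slide pooling
differs by path on purpose: the pixel path sums areas across a patient's
slides (area weighting falls out of pixel counting), while the
semi-quantitative path averages field estimates unweighted, mirroring
how per-field scoring is averaged in practice.

## Tiling

The patch grid is anchored at the top-left corner of the ROI bounding
box and steps by the tile size (default 512 px) in both axes; windows
that touch no ROI pixel are dropped.  Two edge policies exist because
partial boundary windows have no canonical handling: `pad` (default)
keeps clipped boundary windows and pads extracted patches to full tile
size with a flagged, excluded-from-everything fill; `drop` discards
windows not fully inside the bounding box.  Padding is the default
because dropping boundary tissue would bias TSR in irregular ROIs.
Coordinates are 0-based, row-major, half-open.  Pixels are assigned to
the ROI by a center-point even-odd test (pixel (r, c) is inside iff
(r+0.5, c+0.5) is strictly inside the polygon) — the simplest
unambiguous rasterization.  Stitching places disjoint windows back on
the canvas, drops padded pixels, and forces everything outside the ROI
to background; extract-then-stitch is exactly lossless on ROI pixels.

## Segmentation

The reference segmenter is a deterministic stain-deconvolution rule:

1. optical density per channel, OD = −log10((I+1)/256), so white glass
   is 0;
2. linear unmixing against the standard H&E(+residual) stain matrix
   (unit-norm rows ≈ hematoxylin (0.65, 0.70, 0.29), eosin
   (0.07, 0.99, 0.11), residual (0.27, 0.57, 0.78)); negative
   concentrations are clipped to zero;
3. pixels with total OD < 0.15 (or outside the ROI) are background;
4. remaining tissue pixels are epithelium where the Gaussian-smoothed
   hematoxylin-minus-eosin concentration exceeds 0.20, stroma otherwise;
   a per-class morphological opening (disk radius 2 px) removes specks,
   with ties and opened-away pixels falling to stroma, the majority
   class in desmoplastic tumors.

The epithelium threshold sits midway between the smoothed dominance
scores of pure hematoxylin-dominant and pure eosin-dominant tissue
(≈ +0.75 and −0.35 under the default rendering), which recovers class
boundaries without systematic bias; with a threshold near zero the
smoothing otherwise inflates the epithelium fraction by ~1.5 percentage
points.  All parameters live in `StainModel` and are overridable.

Slide-level segmentation is strictly patchwise — each window is
predicted without neighboring-patch context, matching non-overlapping
window inference — and therefore differs from whole-canvas
classification only in a band around tile borders whose width is set by
the smoothing/morphology radius.  The backend interface
(`predict(patch)`, optional `fit`) admits trainable models; a shallow
decision-tree pixel classifier is included as a working example, and an
oracle backend (returns ground truth per window) isolates the tiling
path in tests.  A deep generative segmentation model can be registered
the same way; it is deliberately out of scope here, and the pipeline
contract is independent of the backend.

## Synthetic data

`generate_wholemount` renders tumor epithelium as a union of random
disks (log-normal radii around min(canvas)/24) inside the ROI tissue,
stroma as the remainder, and necrosis as pale label-0 holes carved
first.  The disk count is initialized by inverting the Poisson coverage
formula n = −A·ln(1−f)/(πr²), corrected multiplicatively for up to 50
rounds, and finished by flipping single-pixel-deep boundary layers until
the realized epithelium fraction matches the target exactly (well within
the ±1 percentage point contract).  Rendering colors are Beer–Lambert
transmissions of the stain vectors (epithelium hematoxylin-dominant at
concentration ≈ 0.9, stroma eosin-dominant ≈ 0.45) plus Gaussian noise
(SD 8 on the 0–255 scale).  Every generator draws from a single
per-call seeded NumPy generator, so identical specs are bit-identical.

What this emulates: separable stain statistics, exact and countable
ground truth, ROI-confined tissue, controllable class balance.  What it
does not: nuclei-scale texture, stain variability between labs, scanner
formats, tissue folds and artifacts.  Passing segmentation tests
therefore demonstrates that the pipeline recovers areas and categories
correctly from images whose color model matches its assumptions — not
that the reference rule would match pathologists on real slides.

`generate_cohort` draws independent Bernoulli/multinomial covariates,
event times from an exponential proportional-hazards model
(hazard = λ₀·exp(Σβx)), independent exponential censoring
(observed time = min(event, censoring), mirroring
censor-at-last-contact), and optionally a logistic low-stromal label.
The default study-like spec uses marginal prevalences typical of a
resected-PDAC cohort (necrosis 51%, G3 30%, perineural invasion 82%,
R1 34%, TNM I/II/III = 25/54/21%), log hazard ratios 2.584/4.384 (stage
II/III vs I), 1.876 (low vs high stroma), 2.124 (G3), 2.147 (PNI),
logistic odds ratios 3.530 (necrosis) and 2.281 (R1) with intercept
−0.6 (≈58% low-stromal prevalence), baseline hazard 0.02/month and
censoring 0.025/month.  Joint covariate correlations are left
independent: no distributional information beyond marginals is
available, and independence is the only defensible default.  Printed
study-level HRs/ORs/p-values cannot be reproduced without patient-level
data; the package instead verifies *parameter recovery*: cohorts
simulated at these truths return the generating coefficients (mean
log-HR bias ≤ 0.10 at n = 2000 over 20 seeds) and calibrated type-I
behavior under nulls.

## Agreement statistics

The confusion table takes the pathologists' evaluation as the reference
standard and high stromal component as the positive class.  Kappa is
computed from the weighted disagreement form κ = 1 − q_o/q_e (weights
0/1, linear, or quadratic on the category distance); on two categories
all weightings coincide bitwise with the unweighted
(p_o − p_e)/(1 − p_e).  The default CI is a bootstrap percentile
interval over 10,000 case resamples (seeded; degenerate resamples are
skipped and counted, with a warning above 10%), which naturally yields
the asymmetric, wider-below intervals seen at small n; Cohen's
large-sample SE √(p_o(1−p_o)/(n(1−p_e)²)) is offered as the asymptotic
alternative, and the two agree within 0.02 per endpoint on balanced
n = 500 tables.  Report rounding: percentages to one decimal, kappa to
three.  Note one arithmetic corner: the 2×2 table (17, 1, 3, 20) gives
F1 = 34/38 = 0.894737, i.e. 89.5% at one-decimal rounding and 89.4%
under truncation.

## Cohort statistics

Exclusion filtering removes any flagged patient and counts each once
under the first true flag in listing-priority order (metastasis/R2 →
neoadjuvant → prior malignancy → 90-day death → lost to follow-up).
Baseline comparisons use Pearson chi-squared without continuity
correction (configurable) for categorical variables and Wilcoxon
rank-sum (Kruskal–Wallis for >2 groups) otherwise.  Logistic modeling
screens candidates univariately at p < 0.05 and fits all survivors in
one multivariate model (the full-model reading; a stepwise logistic
variant was considered and rejected as under-specified).  Cox modeling
screens at p < 0.1, then forward-selects with entry at p < 0.05 by the
partial-likelihood-ratio test, ties broken by candidate order;
collinear candidates that cannot be fitted alongside selected terms are
skipped, so duplicated covariates enter exactly once.  Ties in event
times use Efron's method (the lower-bias default).  Kaplan–Meier curves
carry Greenwood variances; the log-rank test is the standard
observed-minus-expected chi-squared over pooled event times.
`stratified_tsr_analysis` emits, per TNM stage, the high/low-stromal KM
curves and the log-rank comparison, skipping single-category strata
with a warning.

## Problem sizes and numerical choices

Default test and acceptance workloads are desk-scale by design: 640×640
synthetic whole-mounts (the smallest canvas on which the default inset
ROI exceeds one 512² tile — smaller ROIs are rejected as degenerate),
20-slide fraction-recovery sweeps, cohorts of n = 500–4000, 20-seed
recovery loops, and 1000-replicate null calibrations.  Stochastic
checks fix every seed.  Known limitations: the stain-rule segmenter is
tuned to the synthetic color model and is not a claim about real H&E
variability; exponential event/censoring times satisfy proportional
hazards by construction and cannot probe misspecification; the
agreement CI method of the original report is unknown, so both bootstrap
and asymptotic intervals are reported side by side rather than guessing.
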