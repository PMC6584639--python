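# Methods

This note records the models behind each analysis, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Hydrodynamic sizing

Two linear calibrations against standard proteins are assumed:
log₁₀ R_s against V_e − V₀ for size-exclusion chromatography
(thyroglobulin 8.5 nm, apoferritin 6.1 nm, catalase 5.2 nm, BSA 3.48 nm)
and S against volume-from-gradient-top for glycerol gradients
(apoferritin 17.6 S, catalase 11.3 S, glucose oxidase 8 S, BSA 4.6 S).
Calibration is ordinary least squares (scipy `linregress`), returning
slope/intercept standard errors. The gradient abscissa is taken in ml from
the gradient top (0.2 ml fractions; SEC uses 0.5 ml fractions) — fraction
number would differ only by a constant factor absorbed into the slope.

Peak location fits a Gaussian to the ±3 fractions around the maximal
fraction, falling back to an intensity-weighted centroid when the fit
fails (degenerate covariance, centre escaping the window). The reported
location uncertainty is never below half the fraction spacing, the
resolution of fraction collection. A symmetric two-maximum tie returns the
midpoint. Monotone profiles raise an error rather than report a boundary
"peak".

Molecular weight is M = 4205·R_s·S (Da, R_s in nm, S in Svedberg) — the
Siegel–Monty combination, which assumes the two measurements probe the
same species and eliminates the partial specific volume; no buffer-density
or viscosity corrections are applied. The frictional ratio is
f/f_min = S_max/S with S_max = 0.00361·M^(2/3), evaluated by default at
the sequence-predicted mass of the assembled species (e.g. 308 kDa for a
GFP-tagged dimer) so that shape and mass inference stay decoupled.
Uncertainties propagate to first order; results outside R_s 1–20 nm or
S 1–30 are flagged rather than rejected.

## Bleach-step counting

Traces are segmented by binary change-point segmentation minimising the
within-segment sum of squares, accepting a split while the SSE reduction
exceeds a penalty of 2.2 σ² ln n, with σ estimated from the median
absolute first difference. The penalty is deliberately low enough to
resolve two steps separated by a single frame; the over-segmentation this
allows is cleaned up afterwards: segments of ≤2 frames whose flanking
levels agree to within the minimum step size are discarded as blinking or
noise spikes (a genuine short-lived intermediate level between two quick
steps has disagreeing flanks and survives), and remaining adjacent levels
closer than the minimum step are merged. Only downward level changes ≥ the
minimum step count as bleach steps, so upward excursions are never
counted. The count is invariant to common rescaling of trace and minimum
step.

Two failure modes are irreducible under this counting rule: two
fluorophores bleaching within the same frame interval appear as one
double-height step, and a fluorophore surviving past the end of the
acquisition contributes no step. With exponential dwells of mean 60 s
under a 0.5 s / 600 s acquisition these affect ~3.5% of four-step traces,
which bounds exact-count accuracy at high step numbers; pooled over 1–4
steps the detector is ~97% exact at SNR 5.

## Oligomer-state fit

The mixed binomial for a dimer/tetramer population with independently
active GFPs is fitted to the step histogram by multinomial maximum
likelihood. Fits default to the detection-conditioned model
P(k)/(1 − P(0)) on k = 1..4, because spots with no active GFP are not
scored; the unconditioned model is available by flag. The likelihood
surface has a shallow ridge (trading x against p), so a full 0.01-step
grid scan precedes Nelder–Mead refinement — cheap insurance against local
optima. Histograms concentrated in a single bin pin the fit to a parameter
boundary and are flagged non-identifiable rather than reported as interior
solutions. A chi-square statistic against fitted expected counts is
reported with dof = (occupied bins − 1 − 2).

At the experimental sample size (108 motors) the tetramer-fraction
estimate has an IQR of roughly ±0.02 around 0.12 and the active-GFP
fraction of roughly ±0.05 around 0.80.

## Kymograph tracing and motility statistics

Kymographs (rows = frames at 0.1 s, columns = 105 nm position bins) are
smoothed (σ = 1 px), binarised, and foreground structures are followed
frame by frame: each row contributes blob centroids (maximal runs of
foreground pixels, intensity-weighted), assigned greedily to ongoing
tracks by velocity-extrapolated distance within a 4 px gate. Two tracks
may share a blob while they cross — this is what separates crossing events
that form one connected structure. The default threshold is
median + 4·1.4826·MAD of the smoothed image: on kymographs the foreground
is far too sparse for Otsu's criterion to be reliable, though Otsu and
absolute thresholds remain available. Tracks must span ≥10 frames (1 s).
Each track yields a run from a Theil–Sen line fit, refitted once after
trimming residuals beyond max(2 px, 3× median) — the frames perturbed by a
crossing. Known limitation: two motors bleaching/landing at the same place
within a ~3-frame, 4-px window can be chained into one track.

Runs are classified running if speed is strictly above 25 nm/s. Landing
rate is events per µm of microtubule per minute, pooled over microtubules
(total events / total µm·min), which makes it exactly invariant to
splitting observation windows.

Run lengths observed in such assays are right-censored: a run ending at
the microtubule plus end (fitted endpoint within 3 px of the border in the
direction of travel) or persisting to the movie's final frames is a lower
bound, not a length. Summaries report both the naive mean of observed
extents and a corrected estimate: for exponential run lengths with
censoring independent of length, total observed run length divided by the
number of uncensored runs is the maximum-likelihood mean. Because the
tracer cannot see runs shorter than its minimum track duration T_min, the
detected sample is also left-truncated; by memorylessness, subtracting
each run's detection floor (speed·T_min) before the estimate removes that
bias exactly. On 15 µm microtubules with 8.6 µm mean runs the naive mean
is ~4.5 µm while the corrected estimate recovers 8.6 µm; the corrected
estimate has a sampling SD of ~12% per 30 microtubules, which is why the
replication scripts use 60–240 microtubules. Plus-end accumulation can be
simulated (`end_behavior="accumulate"`), but the default truncates and
records censoring, and censored runs stay in the summary (flag-carried),
since excluding them would length-bias the sample.

Vesicle tracks are stationary when their *total path length* is below
1.5 µm (an oscillating vesicle is not stationary even with zero net
displacement); otherwise direction follows the sign of net displacement.
Flux counts every signed crossing of a location line, so one vesicle
oscillating across it contributes multiple counts in both directions.

## Binding

The quadratic (ligand-depletion) isotherm is evaluated in the stable form
f_b = 2L/(A + √(A² − 4RL)), A = R + L + K_d, which passes continuously to
the hyperbola L/(L + K_d) at R = 0. The quadratic is the default because a
50 nM receptor is only marginally negligible against a ~1 µM K_d; the
hyperbolic model is selectable. Fitting is nonlinear least squares over
(ln K_d, f_free, f_bound), with K_d initialised at the mid-transition
concentration and the plateaux at the terminal signals; the log
parameterisation keeps K_d positive and makes the fit scale-free. Series
must span a decade of ligand; flat series raise a non-identifiability
error, and fits whose plateau separation is within noise are flagged. The
standard dilution scheme (37 µM stock, twofold series, 4:1 mixing → top
ligand 29.6 µM, receptor 50 nM) is built into the generator. Thermophoresis
normalisation specifics are abstracted into a generic signal column.

Decoration intensity is the mean along each microtubule line ROI minus a
paired local-background region; negative corrected values are kept but
flagged as noise.

## Cell images

Podosome counting thresholds the cortactin maximum-intensity Z-projection
(Otsu default; absolute override), labels connected components, rejects
objects below 16 px (2.58 µm², i.e. ~0.402 µm/px — the calibration implied
by that pair, used for all synthetic podosome images), and accepts a
component only if its mean actin intensity is ≥1.5× the median actin level
outside all objects — an automated stand-in for the visual actin-
coincidence check, with the factor configurable. Clusters can be split by
watershed on the distance transform seeded at local maxima ≥2 px apart.
Counts are monotone non-increasing in both the size filter and the
coincidence factor.

Tail enrichment is (mean_tail − mean_bg)/(mean_cyto − mean_bg) per channel
from manually drawn disjoint masks (≥25 px each), with the GFP:mCherry
ratio-of-ratios comparing a construct against the co-expressed internal
control. The ratio is exactly affine-invariant; a non-positive
cytoplasm-minus-background denominator raises instead of returning a
signed ratio.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed) using one
`numpy` Generator per call, and returns its ground truth alongside the
data. Defaults encode the study conditions: bleach acquisition 0.5 s ×
1200 frames with unit step 100 AU and noise 20 AU (SNR 5), mean
fluorophore dwell 60 s; wild-type motility 0.15 landings·µm⁻¹·min⁻¹ with
truncated-normal speeds 0.45 ± 0.12 µm/s, exponential 8.6 µm runs, 30%
static events dwelling ~20 s; kymographs at 105 nm/px, 0.1 s/frame,
Gaussian PSF σ = 1.3 px, signal 100 / noise 20; titrations per the mixing
scheme above; podosomes as non-overlapping discs (rejection placement)
with an actin-coincident subset. The landing rate and static fraction are
not printed quantities; they were fixed once at values typical for sparse
sub-nanomolar TIRF assays (~7 events per 15 µm microtubule in 3 min).

What the generators do **not** emulate — and hence what passing recovery
tests cannot certify about real data: camera physics (shot noise, EM
gain), 3D optics and defocus, fluorophore blinking during motility,
stage drift, non-exponential run-length mixtures, heterogeneous motor
populations, and real cell morphology (regions are geometric shapes).
Estimator behaviour under those effects must be judged separately.

## Orchestration and statistics

Pipelines are configuration-driven (YAML/JSON): stages run in order, each
seeded deterministically from the base seed and its position, and results
are collected into a JSON report with provenance (config SHA-256, seed,
package version) and no time- or path-dependent fields, so identical
(config, seed) reproduces byte-identical reports. Stage failures are
recorded and execution continues, yielding a partial bundle.

Group comparisons delegate to scipy/statsmodels (two-tailed equal-variance
t, Mann–Whitney U, Kolmogorov–Smirnov, one-way ANOVA with Tukey HSD;
Bonferroni = raw p × number of comparisons capped at 1, Holm–Šídák via
statsmodels). These are standard procedures, deliberately not re-derived;
the package's own contribution is the domain-specific estimators above.
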