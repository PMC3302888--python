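# Methods

This note records the models implemented in `pibquant`, their
assumptions, the defaults of the synthetic-data generator, and the design
choices made where the underlying study protocol left the design open.

## Kinetic models

**Forward model.** Tissue curves are simulated under the simplified
reference tissue model (SRTM): the reference region (cerebellum) follows
one-tissue kinetics C_R = K₁′·(C_p ⊗ e^{−k₂′t}) and the target region

C_T(t) = R₁·C_R(t) + (k₂ − R₁·k₂ₐ)·(C_R ⊗ e^{−k₂ₐt})(t),  k₂ₐ = k₂/(1+BP_ND).

`SRTMParams.consistent` enforces a common non-displaceable distribution
volume (k₂ = R₁·k₂′), the regime in which reference-tissue estimators are
exact.  Convolutions use an exponential-kernel recursion that is exact
for piecewise-linear inputs on the simulation grid (0.25 s default), and
frame values are frame averages because PET frames integrate counts.

**Arterial input.** The estimators never see plasma; an input curve is
needed only to shape realistic reference kinetics.  The default is a
gamma-variate bolus (shape 2, peak 0.5 min) plus a recirculation tail
(20% of peak) clearing mono-exponentially at 0.01 min⁻¹.  A single
clearing gamma-variate cannot provide both the early bolus peak and a
terminal plasma rate slower than tissue efflux; the slow tail is what
puts the late scan into transient equilibrium, where the
target/reference ratio rises toward DVR and the AUC-ratio estimate
approaches BP_ND from below.  With shape 0 and no tail the input reduces
to a pure mono-exponential, which the test oracles compare against the
closed-form tissue curve.

**Estimators.** MRTM is the exact multilinear rearrangement of
one-tissue kinetics, C_T = γ₁∫C_R + γ₂∫C_T + γ₃C_R, fitted by ordinary
least squares over frames with midpoint ≥ t*; BP_ND = −(γ₁/γ₂+1),
k₂′ = γ₁/γ₃.  MRTM2 fixes k₂′ and drops to two parameters.  Design
choices where the protocol is silent:

* t* defaults to 5 min (cortical and cerebellar curves separate from
  about 3 min post-injection); configurable.
* k₂′ is pooled over four cortical regions by the median (robust to one
  failed regional fit); mean available.
* Regression is unweighted OLS; frame-duration weighting was considered
  and not made default because the upstream software's convention is
  undocumented.
* Cumulative TAC integrals treat the curve as the step function that
  reproduces each frame integral (frame values are frame averages); the
  multilinear fits use trapezoid accumulation over frame midpoints with
  a zero anchor at t = 0.  Both are standard for frame-averaged data and
  agree with dense quadrature to well under 0.5% on the 52-frame
  schedule.
* A target exactly proportional to the reference makes the MRTM design
  rank-deficient; the proportionality constant still identifies
  DVR = c, so the fit returns BP_ND = c − 1 with k₂′ flagged
  unidentifiable instead of failing.  Genuine rank deficiency (e.g. an
  all-zero voxel) yields a flagged NaN result, never an exception, so
  parametric maps record failures per voxel.

The voxelwise MRTM2 map solves the per-voxel 2×2 normal equations in
vectorised form; on a noiseless two-region 32³ phantom the regional map
means agree with the VOI fits to machine precision.

**Noise.** TAC noise is Gaussian with variance proportional to
concentration/frame duration (the standard PET weighting assumption),
scaled by a single `NoiseSpec.scale` parameter in kBq·min¹ᐟ²/cc.

## Registration

Rigid transforms use intrinsic z-y-x Euler angles about the volume
centre, world coordinates in mm with the origin at the centre.  NMI is
computed from a 32-bin joint histogram over finite overlapping voxels;
the score is 1 for independent and 2 for identical discrete images.
Invariance to monotone intensity remaps is exact for affine remaps (the
equal-width bin partition is preserved) and approximate otherwise.
Optimisation is Nelder–Mead on a two-level pyramid (Gaussian smoothing +
2× decimation first), deterministic for a fixed initialisation;
non-convergence is flagged with the best transform so far.  The
protocol's final manual-correction step is replaced by binary-contour
overlay QC (red = one volume, green = the other, coinciding contours
yellow) at several thresholds on all three mid-planes.  Capture range is
what the study needs (a few voxels / ~10°, template pre-matched data);
the package makes no global-search claim beyond it.

## Saturation binding

The global model shares the nonspecific slope NS (optionally an additive
background) between total and blocked curves and fits all replicate
wells jointly by unweighted least squares, with K_d in log space for
positivity and B_max, NS bounded at zero.  Two-site fits start from a
log-spaced K_d grid (lowest RSS wins, ties to the smaller K_d₁); sites
are reported in ascending K_d, with flags for poorly separated sites
(K_d ratio < 5) and boundary-pinned components.  Model selection between
one and two sites uses the extra-sum-of-squares F-test at α = 0.05; the
semilog inflection count (sign changes of the model curve's second
derivative in log L) is reported as the qualitative diagnostic — one
inflection for a single site, three for well-separated sites.

Parameter standard errors use the heteroscedasticity-robust (sandwich)
covariance: well noise in this assay is multiplicative, and the
homoscedastic (JᵀJ)⁻¹s² form understates the uncertainty of parameters
driven by high-signal wells (coverage of the nominal 95% intervals then
falls several points short in simulation).  Confidence bands for the
fitted curve come from the delta method on that covariance.

Free-ligand depletion is ignored (free ≈ added); the free-tracer
calibration column is carried for bookkeeping.  Units are nM and
fmol/mg throughout, with the density convention 1 g brain ≡ 1 ml making
1 fmol/mg ≡ 1 nM, so BP = ΣB_max,i/K_d,i is dimensionless.

## Histology

Plaque recognition is deliberately simple and deterministic, since the
original analysis-script parameters are unpublished: Gaussian smoothing
(σ = 1 px), rolling-ball background subtraction (radius 50 px, executed
on a 4× decimated copy for speed and rescaled), a fixed global threshold
(1500 counts above background, calibrated once on the synthetic
reference images whose plaque amplitude is 3000 counts — half amplitude
recovers rendered boundaries after smoothing), 8-connected component
labelling, and clipping to the ROI.  The same parameters are applied to
every stain and region.  The Aβ40 small-object exclusion defaults to the
area of a 4-pixel object at the fixture pixel size (100 µm² at
5 µm/px).

Burden is the union area of retained objects over the ROI area (overlap
never double-counted).  Radii are equivalent-circle radii r = √(area/π).
The size-distribution KDE uses the Epanechnikov kernel with a
Silverman-type plug-in bandwidth h = 2.345·σ̂·n^{−1/5} (robust scale
min(SD, IQR/1.349)); the kernel is named by the protocol, the bandwidth
is this package's choice.  Distribution comparisons use the two-sample
Kolmogorov–Smirnov test (exact p for small samples).  The exact KS test
is conservative at small n because the statistic is discrete
(~3% rejection at nominal 5% with n = 40); calibration checks are
therefore run at n = 500 per sample, the scale of the study's pooled
plaque datasets, where the nominal level is realised.

## Synthetic plaque images

Disks with lognormal radii (median 18 µm, log-SD 0.45 at 5 µm/px) are
placed uniformly in the ROI until the rendered union-mask area fraction
is within 0.1 percentage points of the target burden; candidates that
would overshoot are redrawn (the working band is a quarter of the stated
tolerance so small targets are neither under- nor overshot).  Ground
truth is measured on the rendered union mask, matching the definition of
burden as an area fraction.  The Thioflavin-like channel carries every
plaque; the antibody channels share 80% of objects (co-localisation is
described qualitatively in the source material; the number is a
default), with the remainder split evenly.  Backgrounds are Gaussian
(mean 200, SD 8 counts) with plaque amplitude 3000 in 16-bit range.
What the generator does not emulate: non-circular plaque morphology,
intensity gradients within plaques, stain-dependent backgrounds varying
by neuroanatomy, and tiling artefacts — so passing tests demonstrate
correctness of the measurement chain, not robustness to those real-data
effects.

## Autoradiography and unmixing

Integrated density is the ROI pixel sum divided by the ROI pixel count
after background subtraction (scalar level or the mean of a user-drawn
empty region), clipped at zero.  Ratios are per-section and invariant to
global rescaling.

Dual-label exposures model a stable isotope (³H, half-life 12.32 y;
decay < 10⁻⁴ over ≤ 2 h exposures) and ¹¹C (half-life 20.364 min).
Expected counts in exposure bin b are a·Δt_b + c·∫_b e^{−λt}dt with a
the ³H rate and c the ¹¹C initial rate; the generator draws Poisson
counts.  Unmixing solves this two-column linear model per pixel under
nonnegativity — for two variables the active-set solution of the normal
equations is exact, and the whole image is solved vectorised.  The
vendor's proprietary separation algorithm is not reproduced; the
round-trip property on synthetic data is the verifiable claim.

## Biodistribution

%ID/g = 100·(tissue counts / full-dose-equivalent standard counts)/mass,
with both counts decay-corrected to injection time using the ¹¹C
constant.  The correction convention is immaterial for the
region-to-cerebellum ratios (simultaneous counting cancels it), which is
why the choice is safe to fix.  The region vocabulary is the study's
four brain parts; free-text tissues are accepted with a warning.

## Cohort generator and validation statistics

The cohort model draws each animal's modality vector from a multivariate
normal with group-specific means/SDs and a common cross-modality
correlation (default 0.7, configurable; the source reports pooled
scatter, not per-group coefficients, so the correlation is a parameter,
not an assertion).  Group summaries used as defaults: autoradiograph
neocortex-to-cerebellum ratios 0.93±0.02 / 1.25±0.07 / 1.90±0.26 /
2.54±0.27 and Thioflavin burdens 0.61±0.17 / 4.68±0.70 / 7.72±1.03 /
11.78±1.63 % for control-old / homozygous-young / hemizygous-old /
homozygous-old; telencephalon biodistribution ratios 0.67±0.12 /
1.87±0.58 / 4.23±0.46 with no biodistribution arm for the
hemizygous-old group (designed missingness, exercising pairwise
deletion).  Insoluble Aβ40/42 levels centre on the per-group assayed
tissue values with a 15% CV, and the PET BP_ND group parameters
(−0.05±0.03, 0.30±0.06, 0.55±0.10, 1.10±0.15) are plausible values
consistent with the published severity ordering and the individual
control values around −0.06; per-group PET summaries are not published,
so these are generator defaults, not reproductions.  Group sizes default
to n = 5 per group, the size of the major subgroups.

Welch t-tests (two-sided, unequal variances, Welch–Satterthwaite df) are
applied between severity-adjacent groups in the fixed order control-old
< homozygous-young < hemizygous-old < homozygous-old, uncorrected at
α = 5% by design (a Holm option exists, off by default).  Two samples
with zero variance and equal means return p = 1 by convention.  Note a
power fact about the printed autoradiography summaries: with n = 5 per
group, the typical p for hemizygous-old vs homozygous-young data at
those summaries is ≈ 0.004, and the probability of p < 0.01 across
replicates is only ≈ 0.79 — a single printed p-value near a threshold
does not imply near-certain replication past it.

Pearson matrices are pairwise-complete with per-cell n, requiring ≥ 3
complete pairs; constant columns yield a flagged NaN.  Group separation
checks that per-group [min, max] ranges are pairwise disjoint in
severity order and reports the margins; with normal marginals at the
printed summaries, full separation of the two old transgenic groups is
itself a borderline event (~50% of seeds), which the observed data
narrowly achieved.

## Problem sizes and determinism

The verification suites run at: 200 plates for saturation recovery, 100
seeded perturbations for registration, 10⁴ null draws (n = 500 per
sample) for KS calibration, 48² pixels × 5 bins for unmixing, 400
replicates for the Welch behaviour, and a 32³ phantom for the parametric
map — sizes chosen to make Monte-Carlo error small relative to the
tolerances they check.  Every stochastic component consumes a
`numpy.random.default_rng` seed; identical seeds give bit-identical
outputs end to end, which the pipeline driver verifies by byte-comparing
its own CSV bundle.

## Known limitations

* The SRTM forward model and the MRTM estimators share the one-tissue
  assumption; the suite demonstrates estimator correctness under the
  model, not robustness to two-tissue target kinetics or partial-volume
  effects.
* Registration is validated on smooth noiseless phantoms within a small
  capture range; real multi-modal mouse data would add intensity
  non-correspondence that NMI handles only partially.
* The histology pipeline's fixed threshold presumes the synthetic
  contrast regime; real micrographs need the threshold recalibrated
  (all parameters are exposed in `SegmentationParams`).
* ELISA protein levels enter the cohort table as given values; their
  wet-lab derivation is out of scope.
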