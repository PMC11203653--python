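# Methods

This note documents the models, numerical choices and design decisions
behind `calfmolli`, and what the synthetic phantom does and does not show
about real data.

## Signal model and T1 fitting

The inversion-recovery signal is `y(TI) = A − B·exp(−TI/T1)`; magnitude
reconstruction records `|y|`.  The fitter reports the T1 that appears in
this exponent as *the* T1, matching how MOLLI analysis tools print their
maps.  A Look–Locker correction `T1 = T1*·(B/A − 1)` is available via
`FitOptions(ll_correction=True)` and is reported *in addition*, never in
place of the apparent value: native muscle peaks near 1900 ms at 3 T are
high relative to literature muscle T1 (~1400 ms), consistent with
uncorrected apparent values, so both readings are exposed and the default
follows the printed model.

**Polarity restoration.**  For n samples in TI order there are exactly
n+1 physically admissible sign patterns (the signed curve crosses zero at
most once, at TI₀ = T1·ln(B/A)).  All candidates are enumerated —
exhaustive search is exact and costs nothing at n = 7.

**Optimization.**  For fixed T1 the model is linear in (A, B), so each
candidate is first scanned over a 48-point geometric T1 grid
(20–8000 ms) with exact linear subfits (variable projection; residuals
evaluated via orthonormal projections).  The best grid point seeds a
damped Gauss–Newton (Levenberg–Marquardt) polish with analytic Jacobian,
per-voxel damping, relative step tolerance 1e-11 and at most 100
iterations.  `fit_voxel` polishes every polarity candidate; `fit_map`
polishes the two best-ranked candidates per voxel (ranking comes from the
exact grid minimisation, and the winner after polishing is the grid
winner in practice — a unit test checks map/voxel agreement on noisy
data).  Both paths share one vectorised engine, so a masked map fit
equals the per-voxel fit restricted to the mask.

**Bounds and validity.**  T1 is constrained to [1, 10000] ms; fits at a
bound, non-converged fits and constant signals (B ≈ 0, T1 unidentifiable)
are flagged invalid and excluded from region metrics — never silently
zeroed.  An optional residual threshold flags additional voxels.

**Precision at the study conditions.**  With the seven inversion times
(90…2790 ms) and SNR 50 at A, the per-voxel T1 standard deviation is
≈ 150 ms at T1 = 1900 ms (the longest TI is only 1.5·T1, so A and T1 are
weakly separated), ≈ 60 ms at 1200 ms and ≈ 16 ms at 400 ms; the median
bias is near zero throughout.  This is a property of the acquisition, not
of the optimizer, and it shapes everything downstream of the
max-over-ROI "peak" statistic.

## Region metrics

Peak = exact maximum over valid in-mask voxels (the study's definition);
a percentile variant exists (`peak_percentile`-style robustness is
deliberately *not* the default).  Mean and min are arithmetic over the
same voxels; cross-sectional area is the valid-voxel count times the
pixel area.  The blood pool is the mean of per-artery maxima over
whichever of AT/PT/PE have valid voxels (missing arteries are skipped
with a warning).  Subject-level metrics are the bilateral average
whenever both sides exist — per-side rows are kept alongside.

## ECV

`ECV = (1 − Hct)·Δ(1/T1m)/Δ(1/T1b)` with peak muscle and averaged-peak
blood T1.  Hematocrit is a fraction; inputs above 1 are treated as
percent and divided by 100 (a value like "1 − 38.5" would be
meaningless).  Results outside [0, 1] are returned with a
`plausible=False` flag, not clamped.  A `use_mean` option computes the
cardiac-style mean-T1 ECV for sensitivity analyses.  Subjects missing any
of the five inputs are excluded from cohort ECV and counted.

Because ECV is a ratio of R1 *changes* normalised by the blood R1 change,
a shared multiplicative error in the four peak T1 estimates largely
cancels; ECV recovery is therefore much more forgiving than raw peak-T1
recovery (observed per-subject ECV error ≈ 2 pp sd at SNR 50 versus
≈ 150 ms on a single peak).

## Statistics

* Shapiro–Wilk gate at α = 0.05 per group; both normal → Student's
  t-test (equal variances), else two-sided Mann–Whitney–Wilcoxon (exact
  for n ≤ 8 without ties, tie-corrected normal approximation otherwise).
  Summaries follow the branch: mean ± sd vs median (IQR); the gate
  outcomes are reported because published tables rarely are explicit
  about them.
* Categorical 2×2: Fisher's exact when any **observed** cell < 5, else
  uncorrected Pearson chi-square; r×k always chi-square.  The observed-
  cell rule (rather than the textbook expected-cell rule) is what
  reproduces the reference group-characteristics table this layer is
  modelled on; the expected-cell rule is available by option.
* Univariate OLS: standardized β (= Pearson r in the univariate case),
  raw slope and SE, R², adjusted r² = 1 − (1−R²)(n−1)/(n−2) (which can be
  negative), two-sided slope p.  No multiple-testing correction — the
  emulated analysis plan applies none.
* ICC(2,k): two-way random-effects, absolute agreement, average
  measures, from the ANOVA mean squares
  `ICC(A,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n)`, with the McGraw–Wong
  F-based 95% CI (single-measures interval stepped up by
  Spearman–Brown).  Absolute agreement is the stricter reading of
  "two-way random effects, average ICC"; the consistency form is an
  option.  ICC > 0.7 is flagged excellent.  The implementation is checked
  against pingouin's ICC2k to 1e-10.

## The phantom

Geometry is defined in millimetres and rasterised onto any grid: a
104×96 mm elliptical leg with five muscle sectors whose areas land on the
reported compartment medians (AM ≈ 840, LM ≈ 500, DM ≈ 690, SM ≈ 1440,
GM ≈ 1310 mm²), tibia/fibula exclusions, three artery lumens placed in
the intermuscular gaps, and unlabeled soft tissue elsewhere.  Default
single-phantom grid is 128×128 at 1.48 mm (one leg of the acquisition
FOV); the cohort uses 64×64 at 3.0 mm per leg to keep a 100-subject
bilateral run around a minute.  At that scale each artery lumen is a
single voxel — realistic for 2–4 mm vessels at 3 mm pixels — which also
keeps the max-over-lumen blood peak an unbiased single-voxel estimate.

**Within-compartment T1 structure.**  Reported ROI statistics show peak
≈ 1750–1950 ms, mean ≈ 1200 ms and min ≈ 700–900 ms, i.e. real
compartment ROIs are broad distributions whose maximum lives in a small
hot region.  The phantom mirrors that: a textured baseline between
0.42·peak and 0.68·peak plus one sharp Gaussian hot spot (width 0.55
voxel, baseline suppressed around it) whose top voxel equals the
configured peak exactly.  Two consequences, verified by simulation:
(1) the measured peak is the hot voxel in ≈ 59/60 of noisy realisations,
so "peak" estimates a well-defined quantity with near-zero median bias;
(2) a *homogeneous* compartment would instead make the peak a pure
extreme-value statistic biased by +2–3 noise sd (hundreds of ms), which
is a statement about the metric, not about the fitter.  A
`heterogeneity="uniform"` mode renders flat compartments for exact
model-recovery tests.  Post-contrast fields are the native fields shifted
voxelwise in R1 by a compartment-wise constant derived from the
configured ECV, so stored ground truth is exactly ECV-consistent and
post < pre everywhere.

**Noise.**  Rician by default (magnitude of complex Gaussian), Gaussian
and none selectable; the cohort's SNR 50 is defined at the muscle A
(σ = A/50 = 20).  Inversion efficiency B/A defaults to 1.95.

**Cohort sampling.**  Group anchors are medians + IQRs (T1, ECV, blood
T1) or means + sds (hematocrit, covariates) taken from the emulated
study's group tables; post-contrast blood T1 (not reported there)
defaults to 400 ± 30 ms, placing muscle post-contrast T1 near 450–750 ms
and ECVs in the reported 10–35% band.  Ground truth is drawn by
*balanced quantiles*: each variable block uses the midpoint plotting
positions Φ⁻¹((i−½)/n) of its configured normal in a seeded random
order, so the sample median equals the configured median exactly and a
50-per-group cohort is a faithful representation rather than a
Monte-Carlo perturbation of the design.  Regional values within a block
(the five T1s; the five ECVs) share one latent severity rank —
claudicant compartments co-vary, as the reported tables suggest — while
blocks are permuted independently.  ABI and peak walking time couple
negatively (ρ = 0.35) to the T1/ECV severity, giving the regression layer
realistic inverse associations; claudication onset time exists only for
claudicants; lower-tail values are clamped to physiological ranges
(e.g. ECV ≥ 3%), which leaves medians untouched.  Leg size scales
per subject so control cross-sectional areas run ≈ 23% larger, matching
the reported area gap.

**What the phantom does not emulate:** partial-volume mixtures, motion,
B1 inhomogeneity, perfusion dynamics, contrast-dose differences between
agents, incomplete post-contrast equilibration, or anatomically faithful
compartment shapes.  Passing recovery tests therefore demonstrate the
*pipeline's* correctness under the stated noise model, not acquisition
robustness.

## Recovery behaviour at the study scale

With 50 subjects per group, bilateral legs, SNR 50 and 64×64 grids, the
pipeline recovers configured group medians with ≈ ±0.3 pp (median
standard error) for compartment ECV and ≈ ±10 ms for the five-compartment
averaged native peak T1; the latter is dominated by the irreducible
single-voxel uncertainty at T1 ≈ 1900 ms (150 ms / √10 per subject).  A
±15 ms recovery check on the averaged peak is therefore intrinsically
tight (≈ 1.2 median-SEs) even for this unbiased estimator — worth
remembering when choosing seeds or sample sizes for new experiments.

## Degenerate inputs and tie-breaks

Constant voxel signals are flagged unidentifiable rather than fitted;
empty masks and all-empty artery sets raise; overlapping region masks are
rejected at construction; duplicate inversion times are a format error
naming the duplicates; frames may arrive in any order and are sorted by
TI.  Equal-RSS polarity candidates resolve to the smaller flip count
(argmin order).  CSV outputs use a fixed header and `%.10g` floats so
reruns at a fixed seed are byte-identical.
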