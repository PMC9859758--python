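# Methods

This note documents the models, numerical choices and limitations of the
`tipbody` package: what each stage assumes, which parameters matter, what
the synthetic generators do and do not emulate, and where open design
choices were resolved.

## Trajectory model and the synthetic generator

The in vivo observable is a punctum–SPB distance series sampled at a fixed
frame interval (default dt = 3.5 s, 50 frames — a typical plus-end
tracking movie). The generator implements two-state dynamic instability as
a continuous-time Markov process: growth at speed `v_growth` switches to
shrinkage with catastrophe rate `f_cat`, and back with rescue rate `f_res`
(exponential waiting times). Defaults `v_growth = v_shrink = 0.02` μm/s
and `f_cat = f_res = 0.01`/s give phases of ~100 s mean duration and
length excursions of order 1 μm over a movie, which is the scale regime
the annotation is designed for. A microtubule shrinking to zero length
restarts a growth phase by default (`reflect_at_zero`), emulating punctum
re-assembly next to the pole; this is configurable off, in which case the
length waits at zero until a rescue fires.

Punctum intensity follows a phase-dependent linear drift (growing ends
accumulate signal, shrinking ends lose it) with additive Gaussian noise,
floored at zero. During shrinkage a punctum-loss event fires with hazard
`loss_hazard_shrink`; afterwards the intensity record is missing (NaN)
rather than zero, so loss-frequency counting is unambiguous and
annotation runs on the longest non-missing prefix.

Measurement noise on length and intensity is additive Gaussian. This is
an assumption — no distributional form is established for these
measurements — and real trajectories additionally contain projection
effects (the measured 2-D distance underestimates a 3-D length),
tracking glitches and heteroscedastic localisation error. Lengths here
are one-dimensional true lengths plus noise; the annotation operates on
the scalar series regardless of its origin, so passing tests demonstrate
correctness of the algorithms, not robustness to every artefact of real
microscopy data.

## Phase annotation

Four steps, run on the raw (unsmoothed) series except where stated:

1. **Smoothing** (changepoint detection only): Savitzky–Golay, polynomial
   order 1, window 5 frames. With a symmetric window an order-1 SG filter
   is exactly the centred moving average; the implementation satisfies
   this identity and the test suite asserts it. Near the edges the window
   shrinks symmetrically (fit on the available points) rather than
   reflecting data.
2. **Changepoints**: for each candidate count k = 0..5, exact dynamic
   programming finds the segmentation minimising the total RSS of
   per-segment least-squares lines, with every segment at least 5 frames.
   The count is chosen by BIC = n·ln(RSS/n) + m·(3k+2)·ln(n), counting two
   line parameters per segment plus each breakpoint location; the penalty
   multiplier m (default 1) is configurable. The DP is exact — the test
   suite checks it against exhaustive enumeration — so the only modelling
   freedom is the stopping rule, and BIC is the package's choice of a
   principled one.
3. **Extremum refinement**: each changepoint moves to the nearest local
   maximum/minimum of the raw series whose topographic prominence is at
   least 25% of the trajectory's full range (minima via sign inversion);
   ties go to the earlier frame, and a changepoint with no qualifying
   extremum is kept as a boundary itself.
4. **Classification**: segments between consecutive boundaries (boundary
   frames shared) are fitted by OLS on the raw data; slope sign plus a
   two-sided t-test at α = 0.05 assigns growth/shrinkage, otherwise
   indeterminate. Segments shorter than 3 points (the minimum for a slope
   t-test with one residual df) are indeterminate with missing statistics.
   A perfect fit (zero residuals) gets p = 0 for a nonzero slope and p = 1
   for a zero slope — the limits of the t statistic — with "nonzero"
   judged against the data scale to absorb floating-point slope residue.

Whether a boundary frame belongs to the preceding or following segment is
a convention; segments share boundary frames, and per-frame labels assign
shared frames to the earlier segment.

At the default noise level (0.05 μm, i.e. ~0.7 frame-to-frame growth
steps of 0.07 μm), median frame-level agreement with simulator ground
truth is ≥ 90% over 100 movies, dominated by single-frame boundary
placement differences.

## Rate models

Each annotated growth/shrinkage segment becomes a partial trajectory with
time restarted at the phase start, so the fitted intercept is the initial
length (or intensity) of the phase. Indeterminate segments are excluded.
Per-segment OLS uses the closed form with n − 2 df.

The joint model has per-strain fixed intercepts and slopes (cell-means
coding — each strain reports its own estimates, which is what a per-strain
figure needs), one correlated random intercept/slope pair per partial
trajectory with shared covariance Ψ, a single residual variance across
strains, and maximum-likelihood estimation (not REML). The implementation
is statsmodels' `MixedLM`; the package standardises t and y internally
before fitting because raw-scale variance components (slopes in μm/s over
times in seconds) differ by orders of magnitude and stall the optimiser —
all estimates, covariances, Ψ, σ² and the log-likelihood are transformed
back to the raw scale exactly. If the full Ψ is singular or the optimiser
fails, the fit is retried with diagonal Ψ and a warning is recorded on
the fit object.

Fixed-effect t-tests use residual df = n_obs − n_fixed, the convention of
the common mixed-model tools this analysis style comes from; no
Satterthwaite correction is applied. Strain contrasts are Wald tests on
the fixed-effect covariance block. Null-calibration of the contrast
p-values is verified by simulation (KS uniformity test in the suite).
The intensity models use the same random-effect structure as the length
models.

## Intensity statistics

The asymmetry index |I_bud − I_mother|/(I_bud + I_mother) and cumulative
intensity take background-subtracted intensities; background conventions
(slide vs cell background) are the input table's responsibility — the
package subtracts a provided background, it does not segment images.
Stoichiometry calibration divides a reference punctum intensity by its
known molecule count (sites × copies per site); the aggregation choice
(median for the reference, mean for the query, as is conventional for
skewed intensity distributions vs. symmetric ones) is the caller's, and
both are exposed. Punctum loss is consumed as a flag — in real data it is
a manual call; a loss time, when available (synthetic data), restricts
counting to the observation window.

Binomial CIs are Wilson score intervals (no continuity correction); the
two-proportion z-test uses the pooled standard error with the degenerate
all-success/all-failure case mapped to z = 0, p = 1; Welch's t-test uses
Welch–Satterthwaite df.

## Droplet analysis

The aspect-parameter fit A(t) = A0·e^(−t/τ) has no additive offset: A → 0
at full relaxation by definition. The final radius R is the mean of
(L + W)/4 over the last 10% of frames where A < 0.05; when relaxation is
incomplete the area-equivalent radius √(L·W)/2 over the last 10% of
frames is used instead. The τ-vs-R line is fitted through the origin
(physics forces τ(0) = 0), equivalent to the R²-weighted mean of τ/R; an
intercept-free fit of a single droplet reports its τ/R with an undefined
standard error.

The full two-fluid relaxation-time prefactor is implemented as
(2λ+3)(19λ+16)/(40(λ+1)), whose λ → ∞ limit is exactly the 19/20 of the
simplified form — the constant is configurable. The simplified form is
valid for λ ≫ 1 (condensed phase much more viscous than the dilute
phase). Internal units are μm, s, Pa·s and N/m; inverse capillary
velocities are reported in s/μm, the scale on which measured condensate
values (units of s/μm, magnitudes 2–124) live.

The fusion simulator conserves cross-sectional area (two equal parents of
radius r fuse into R = √2·r) and inverts A(t) exactly into (L, W) before
adding independent Gaussian axis noise; `axes_from_aspect` and
`aspect_parameter` are exact mutual inverses, which the round-trip tests
exploit. FRAP correction divides the background-subtracted target trace by
the average of pre-bleach-normalised reference traces and renormalises to
the target's pre-bleach mean, so shared acquisition bleaching/defocus
cancels and a full recovery plateaus at 1.

## Phase diagrams

A phase grid holds one separated/soluble call per (concentration, salt)
well. The binodal boundary at each concentration is the arithmetic
midpoint in salt between the contiguous separated block starting at the
lowest tested salt and the next tested salt; arithmetic (not geometric)
midpoints are a convention choice. Columns separated at all (none of the)
tested salts are censored above (below) the range. Separation reappearing
at higher salt can only arise from scoring noise — the physical direction
is separation at low ionic strength — so the lowest-salt block wins and a
warning is emitted. With noiseless calls the recovery error is bounded by
half the salt grid spacing by construction, and the tests assert that
bound.

## Problem sizes and numerics

Simulation-backed checks use: 100 movies of 50 frames for annotation
agreement; 100 fusion events (80 frames) for τ recovery and 20 for the
slope; 100 replicates of 2 strains × 40 partial trajectories × 10 frames
for mixed-model CI coverage and 200 smaller replicates for null
calibration; 1,000 replicates for Welch type-I error. These sizes give
Monte-Carlo standard errors comfortably inside the asserted margins while
keeping the whole suite fast. Changepoint DP cost uses cumulative sums
(O(1) per segment); BIC guards log(0) with a data-scaled RSS floor so an
exactly-linear series selects k = 0. The mixed-model optimiser runs
L-BFGS with BFGS/CG fallbacks, a deterministic OLS-based start, and the
standardisation described above; convergence failures surface on the fit
object rather than being silenced.

## Known limitations

- No image processing beyond binary-mask ellipse axes: no spot detection,
  tracking, segmentation or deconvolution.
- The annotation assumes piecewise-linear length dynamics; curved
  (accelerating) phases bias boundaries.
- The mixed model assumes Gaussian random effects and residuals and a
  shared residual variance across strains.
- Fusion/fission event *detection* is out of scope — events are inputs.
- The synthetic generators are the only data source the tests use;
  agreement thresholds quantify algorithm correctness under the stated
  noise model, not performance on any particular microscope's data.
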