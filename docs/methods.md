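# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `symspeed`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Stimuli (`symspeed.stimgen`)

Patterns are 32 full-contrast dots of 0.24° diameter in a 13.74° square
window (0.17 dots/deg²), shown for 400 ms at 85 Hz (34 frames).  A fraction
of the dots forms mirror pairs about the vertical axis: left-half positions
are sampled uniformly and reflected, so the mirror invariant
x_left = −x_right, y_left = y_right holds exactly (to float precision) in
every frame.  Pair drift directions are mirrored (θ_right = π − θ_left);
noise dots are balanced across halves, with the left-half noise directions
sampled uniformly and their mirrored multiset permuted over the right half,
so both halves share one direction distribution without dot-level symmetry.

Every drifting element travels 1.18° before it dies and is relocated.  The
travel time is quantized to whole frames, giving lifetimes of 30/15/10
frames (352.94/176.47/117.65 ms) and relocation temporal frequencies of
2.83/5.67/8.5 Hz at 3.33/6.67/10 deg/s.  Nominal speed is stored; the
frame-derived effective speed (e.g. 10.03 deg/s for the nominal 10) is also
exposed.  Pairs are relocated simultaneously to fresh mirrored positions
with a fresh mirrored direction; different pairs die asynchronously because
starting ages are uniform whole frames in [0, lifetime).

Decisions where the procedure was genuinely open:

- **Window exit.** Treated as death: the dot (with its pair partner) is
  relocated as if its lifetime had expired.  This keeps density and the
  symmetry level constant using machinery the design already requires.
- **Noise relocation half.** A noise dot is relocated within its birth
  half, preserving the equal-per-half noise balance through relocations;
  drifting across the axis between deaths is allowed.
- **Overlap.** Dots may overlap (pure uniform sampling); a
  `min_separation` flag enforces a minimum centre distance when wanted.
- **Axis straddling.** Left-half positions are sampled with
  x < −dot_radius so a mirrored pair can never degenerate into a single
  dot on the axis.
- **Coordinates.** Origin at the window centre, x rightward, y upward,
  mirror axis x = 0, angles in radians (0 = rightward, CCW positive).

Foils copy the target's per-half, per-speed dot counts and use the same
direction-multiset construction, with all dots randomly positioned — the
two intervals of a trial differ only in positional symmetry.

## Probability summation (`symspeed.ps_model`)

The forward model, its inverse and the segregated→non-segregated
prediction are described in the README.  Numerical choices:

- **Integration**: adaptive quadrature (`scipy.integrate.quad`,
  `epsabs=1e-10`) over t ∈ [−10, 10 + d′]; the neglected tails are below
  1e-12, comfortably inside the 1e-6 contract checked by the tests.
- **Inversion**: Brent's method on a bracket [0, SL_hi], SL_hi doubled
  geometrically until the forward model exceeds the requested PC.
  Requests at/below chance or at/above 1 raise informative errors.
- **Monitored channels**: Q equals the number of speeds present in the
  stimulus (2 throughout the two-speed experiment).  The model itself
  accepts any 1 ≤ n ≤ Q, M ≥ 2.
- **Verification**: an independent Monte-Carlo oracle simulates the same
  decision process trial by trial; quadrature and oracle agree within 3
  binomial SEs at 10⁶ trials across a (SL, Q, n) grid, and the Q = n = 1,
  M = 2 case matches Φ(d′/√2) to 1e-6.

g and τ are exposed but default to 1: fitting them is out of scope, and
only SL ratios matter at those defaults (the full-strength segregated
signal corresponds to 16 symmetric dots in one channel, half strength to
8).

## Observers (`symspeed.observer`)

Both observers are synthetic stand-ins for human participants.

- **ChannelObserver** draws the channel deviates explicitly and applies the
  max rule, so its long-run percent correct equals `pc_ps` by construction;
  it is the oracle for the segregated/non-segregated logic.  Its per-channel
  stimulus level is `gain ×` (symmetric dots at that speed / 32).  The
  default gain of 3.0 puts the 50%-symmetry segregated condition at
  d′ = 1.5 (PC ≈ 0.80), a realistic suprathreshold operating point; it was
  chosen once and is not tuned per experiment.
- **LogisticObserver** responds with probability
  guess + (1 − guess − λ)·σ((x − α)/β), guess = 0.5.  Defaults α = 40%
  symmetry, β = 8% place the 80% point at 43.2%, mid-range for the
  staircase; λ defaults to 0 for exact oracle checks (0.02 is suggested for
  realism in robustness exercises).

What the generators deliberately do **not** emulate: inter-observer
variability, learning/fatigue, lapses at the default settings, serial
dependencies between trials, and any spatial inhomogeneity of symmetry
processing.  Passing tests therefore certify the machinery and the model's
internal consistency, not human behaviour.

## Staircase (`symspeed.staircase`)

One-up three-down: a wrong response raises the symmetry level one step,
three consecutive correct responses lower it one step; the drift-free point
solves p³ = ½, i.e. PC = (1/2)^(1/3) ≈ 0.7937.  Levels are quantized to
whole mirror pairs of the 32-dot pattern (steps of 6.25%) because the
procedure controls a dot count; they clip to [0, 100].  Two 75-trial
tracks, starting at 100% and 0% symmetry, are interleaved — strict
alternation by default, randomized order behind a flag.  Ten runs per
condition reproduce the 750-trials-per-track accounting.  The fixed point
is verified by simulation: over 200 runs against a logistic observer, the
true PC at the mean of the final 20 levels per track lands within 0.03 of
0.7937.

## Fitting (`symspeed.psychofit`)

Trials are pooled over tracks and runs, binned per level, and fit by
maximum likelihood with PC(x) = 0.5 + (0.5 − λ)·σ((x − α)/β) (λ fixed at 0
by default; a free lapse ≤ 0.06 is available behind a flag).  The threshold
is solved from the fitted curve at PC = 0.80 — deliberately not the
staircase's 79.37% convergence point; the 0.63-point discrepancy between
procedure and analysis is part of the replicated design and is preserved,
not reconciled.  Optimization is Nelder-Mead on (α, log β) from three slope
starts (one warm start inside the bootstrap).  Degenerate data (one level,
all-correct, all-wrong) raise errors naming the deficiency.

Bootstrap SEs resample trials with replacement 1000 times and refit;
resampling is implemented as a multinomial draw over the binned
(level, outcome) cells, which is distributionally identical to resampling
individual trials and much faster.  Failed refits are excluded and counted.
Recovery calibration (computed by the acceptance suite): over 100
simulated 750-trial experiments, mean threshold bias is within 2% symmetry
and the ±1.96·SE interval covers the generating observer's true 80% point
95% ± 5% of the time.

Quadratic tuning curves are ordinary least squares on y = ax² + bx + c; two
curves are compared with the extra-sum-of-squares F test (one pooled vs two
separate quadratics), df = (3, N − 6), i.e. (3, 12) for two 9-point curves.
The logit transform for percent-correct analyses raises at 0/1 unless an
explicit continuity correction is passed.

## Experiments (`symspeed.pipeline`)

**Experiment 1** (thresholds).  Conditions: all 9 ordered pairs of the
three speeds, all 9 ordered pairs of the three matched lifetimes (flicker),
and a static baseline — the lifetime design mirrors the speed design
exactly.  Because no human observer model exists for thresholds, the
default config drives each condition with a LogisticObserver whose true 80%
point follows quadratic tuning curves: thresholds of
−5.321x² − 0.133x + 43.819 (% symmetry) against x = log₂(speed ratio),
−1.808x² + 0.906x + 47.455 against the reversed log lifetime-ratio axis,
and a 55% static baseline.  The log₂ abscissa is this package's choice of
plotting axis (symmetric about ratio 1, in doubling units; the reversal for
flicker aligns shorter relative lifetimes with faster relative speeds);
`fit_quadratic` itself is axis-agnostic.  The run is thus a recovery
exercise: 10 interleaved staircase runs per condition, pooled logistic
fits, bootstrap SEs, and the quadratic coefficients re-estimated from the
recovered thresholds.

**Experiment 2** (percent correct).  50% position symmetry throughout
(16 symmetric dots = 8 pairs; dots and pairs are distinct units — 50% of 32
dots is 8 pairs).  For each unordered speed pair, both segregated
sub-conditions and the non-segregated condition are simulated with the
ChannelObserver (500 trials per sub-condition by default), complementary
segregated conditions averaged, and the prediction applied.  Segregated
PCs at or below chance yield NaN predictions with the row retained.  A
user-supplied table of measured segregated PCs can be pushed through the
identical prediction path (`predict_from_table`, `symspeed ps-predict
--table`).

Problem sizes used by the acceptance script: 200 staircase runs for the
convergence check, 10⁶ Monte-Carlo trials per grid cell for the oracle
comparison, 100 replicates × 1000 bootstrap resamples for recovery
calibration, 2000 trials per sub-condition for Experiment 2, and 100 seeded
trials for the stimulus invariants.

## Known limitations

- The synthetic observers are internally consistent with the analysis
  model; agreement between prediction and simulation in Experiment 2 is a
  self-consistency check, not evidence about human vision.
- Rasterized frames are mirror-symmetric only up to pixel quantization.
- The quadratic ground-truth curves for Experiment 1 fix a plotting-axis
  convention (log₂ ratio) that the original threshold data do not pin down;
  coefficient recovery is exact only under that convention.
- Repeated-measures ANOVAs and post-hoc tests on observer samples are out
  of scope; the pipeline emits tidy trial and threshold tables for any
  external stats package.
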