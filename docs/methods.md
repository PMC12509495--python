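# Methods

`cholinepipe` analyzes dual-channel fiber-photometry recordings of
septo-hippocampal cholinergic activity from mice performing an object
location memory (ObLoM) task, together with pose tracking and a frame-level
ethogram. Because such recordings are rarely shareable, the package ships a
synthetic-session generator with the same statistical structure, so every
stage of the analysis can be validated against known ground truth. This note
documents the models, the parameters that matter, the numerical choices, and
the known limits of what the synthetic validation demonstrates.

## ΔF/F correction (photometry)

The calcium-dependent 465 nm signal `s` and the isosbestic 405 nm control `c`
share photobleaching and motion artifacts. The correction:

1. fit a quadratic in time (centered at the session midpoint, for
   conditioning) to `s − c` by least squares and add it back to `c`,
   producing the *adjusted control* — this lets the control track the slow
   bleaching difference between the channels;
2. scale the adjusted control onto the signal by minimizing
   `Σ (s − (c·α + β))²`; this objective is ordinary least squares, so α and β
   are computed in closed form rather than by iterative search;
3. `ΔF/F = (s − f)/f` with `f = c·α + β`.

The transform order is fixed and recorded in each series' `stage_tags`:
correction at the native rate (610 Hz) → Fourier resampling to the 30 Hz
video clock (rational-factor polyphase with a Kaiser-8 kernel and linear
edge padding; passband amplitude error < 1e-4) → 0.5 s centered moving
average → per-session z-score. The moving average shrinks its window at the
series edges instead of padding, because the session start — where the
recency analysis lives — must not be biased by padded values. A window
shorter than one sample period degrades to the identity with a logged
warning. Whether z-scoring should be per session or per phase is not
determined by the data model; per session is used, which also removes
between-session intercepts from the mixed model's response.

**An inherent property worth knowing:** step 1 subtracts the quadratic-in-
time projection of *everything* in `s − c`, including the true signal. The
recovered ΔF/F therefore equals the latent activity minus its own quadratic
trend. On synthetic sessions this is measurable: the corrected trace
correlates with the *detrended* latent activity at r ≈ 0.998 (the artifact
removal itself is essentially exact), but with the raw latent activity only
at r ≈ 0.94–0.98, because the session-start recency transient and slow
behavioral occupancy drifts have a non-trivial quadratic component. Any
pipeline using this correction mildly compresses slow signal components;
the recency decay constant estimated downstream is biased a few percent
short for the same reason.

## Behavior

Speed is the frame-to-frame Euclidean displacement of the neck marker times
the frame rate; frame 0 copies frame 1 so the series stays aligned with
ΔF/F at t = 0. Object exploration is split into stationary vs nonstationary
by the nose's distance to the object centers (10 cm radius; frames within
both radii go to the nearer center, exact ties break deterministically to
the stationary object and are logged; exploration outside both radii becomes
background).

DI = (t_nonstat − t_stat)/(t_nonstat + t_stat); undefined (an error, treated
as missing by callers) when no exploration occurred. The headline windows
are the first 3 min of the test session and the first 12 min of the sample
session; the sliding DI uses 3 min windows with a 30 s step (the step is a
package choice; only the window length is principled).

Bouts are maximal runs of a binary flag, half-open `[onset, offset)` on the
video clock with no sub-frame interpolation. Runs shorter than 2 s are
discarded; a surviving run is excluded when any same-behavior frame lies
within 4 s before its onset or after its offset (frames of discarded short
runs count). Bout extraction is oracle-tested against an exhaustive scan.

## Speed code and recency

Cholinergic activity is modeled as linear in `log2(max(speed, v0))` with a
speed floor v0 = 1 cm/s, so that zero and near-zero speeds map to 0 rather
than −∞; the floor is configurable and recorded. The timescale curve smooths
both series with the same centered boxcar (0.25–256 s in half-octave steps)
and reports Pearson r per window; windows longer than the session are
missing. Per-session curves at long windows rest on very few effective
samples, so the *experiment-level* best timescale is read off the
session-averaged curve.

The speed→ΔF/F regression is per session (matching the mixed model's
session-specific-baseline philosophy); its residual is the speed-adjusted
activity. Because 30 Hz residuals are strongly autocorrelated (intrinsic
dynamics ~2 s plus the 0.5 s smoothing kernel), the model-based standard
error is reported alongside an effective-sample-size-adjusted one (inflation
`sqrt(1 + 2·Σ ρ̂_k)` from the residual autocorrelation, summed to the first
nonpositive lag or 10 s). Recovery claims in the test suite use the adjusted
errors; naive errors are kept for table parity.

Session-start decays are fit as `A·exp(−t/τ) + offset` over the first 180 s
by nonlinear least squares with multi-starts over τ ∈ {5, 15, 30, 60, 120} s
and bounds 0.1 s ≤ τ ≤ 10·window; the offset term is included because
baseline activity otherwise biases τ (an offset-free mode exists for
sensitivity checks). Near-constant inputs are flagged degenerate instead of
returning an arbitrary τ. The default analysis mode fits the
across-session *average* trace for observed, speed-predicted, and residual
activity: single-session fits are dominated by per-session slope error and
intrinsic noise and scatter far more than the averaged fit.

## Event-triggered profiles and timing

Each bout contributes 5 s of pre-onset signal at 30 Hz, the within-bout
samples linearly interpolated onto a fixed 100-point relative-time grid
(exact for linear signals; the identity when the grid matches the bout
length), and 5 s post-offset. Rows are averaged to mean ± SEM; the
speed-predicted comparison profile is built from the same bouts sliced from
the session-level regression prediction. Bouts whose margins leave the
session are dropped and logged.

Rise/decay timing uses a threshold at `baseline + 0.98·(during − baseline)`
(baseline = mean of the 5 s before onset, or after offset; during = mean
over the bout). Crossings are located on the 30 Hz grid with linear
interpolation between straddling samples, searched 3 s before to 1 s after
the onset (mirrored at the offset), in the direction of the during-vs-
baseline change; the per-bout estimate is the median of all crossings in the
window, and bouts with no crossing are excluded and counted. The 98%
fraction makes the estimator deliberately near-plateau and therefore
noise-sensitive; timing experiments in the test suite use a low-noise
generator configuration for exactly this reason. Observed and predicted
estimates are compared per bout with a Wilcoxon signed-rank test; fewer than
5 valid pairs flags the result low-n.

## Cluster-based permutation test

Observed and speed-predicted matrices (events × aligned time) are compared
with a pointwise paired t test (zero-variance columns yield t = 0, which is
conservative and avoids infinite-mass clusters on degenerate synthetic
input). Contiguous runs above the two-sided critical t at α = 0.05 form
clusters scored by mass (sum of t) and length (seconds; warped core columns
are worth `mean bout duration / 100` each). The null shuffles condition
labels within events — equivalently, random sign flips of each event's
difference curve — recording the maximum |mass| and maximum length per
permutation; 500 permutations for the session-start comparison and 1000 for
bout comparisons. Monte-Carlo p uses the plus-one rule
`(1 + #{null ≥ obs})/(1 + n_perm)` (valid size, never zero); exhaustive
enumeration of all 2^n sign patterns replaces sampling for small n and then
reports exact proportions. A cluster is significant when either the mass or
the length criterion passes, and significant-cluster coverage is also
reported as a percentage of the tested span. Positive and negative clusters
compete against a single two-sided max-|mass| null.

Measured calibration (200 null bout sets, 20 events, α = 0.05): family-wise
error ≈ 0.035.

## Mixed model

One row per 30 Hz frame: z-scored ΔF/F on
`phase * (log2speed + exp_nonstat + exp_stat + rearing + grooming)`, with
phase treatment-coded (sample = 0). Locomotion is deliberately absent —
movement speed is its continuous representation and the two are collinear.
The backend is statsmodels MixedLM (REML). It supports one top-level
grouping factor, so the nested random structure is expressed as mouse-level
effects plus variance components for task repetition (ObLoM) and session;
the requested structure falls back on failure, full covariance → diagonal
slope components → intercepts only, and the level used is recorded. The
intercepts rung groups by session directly: with a per-session z-scored
response, mouse and repetition intercept components estimate to ~0 while
slowing the fit ~20-fold. Degrees of freedom are residual
(`n − p`); no small-sample correction.

Model-based standard errors at 30 Hz are badly anti-conservative under
autocorrelated residuals, so each coefficient also carries a robust SE from
a panel Newey–West (HAC) refit of the fixed design: OLS on the same
formula, session-grouped with a 10 s Bartlett bandwidth, thinned to 10 Hz
(above the residual correlation time the long-run variance is
rate-invariant, so thinning only shrinks the lag window threefold). The
spatial-novelty question is the Wald contrast
`(phase × exp_nonstat) − (phase × exp_stat)` with 1 numerator df, reported
with both covariances. Measured calibration at the generator's Table-scale
effect (0.3 z): false-positive rate 1/14 under a symmetric-novelty null,
detection 12/14 with the asymmetry present.

The sliding variant refits the model per 3 min window of within-session
time (60 s step — heavier fits than DI windows), skipping a phase's value
when it has under 1 s of exploration of either object in the window, and
dropping predictors that do not vary in the window. Each window yields per
phase the nonstationary-minus-stationary coefficient difference; the
meta-model is OLS of that difference on `phase × window index`.

## Synthetic sessions

The generator is seeded and deterministic end to end (independent
deterministic substreams for trajectory, ethogram, latent noise, and
rendering). Defaults are the study's conditions: 15 min sessions, 610 Hz
photometry, 30 fps video, 40 × 40 cm arena with two objects 10 cm from
corners (adjacent corners in sample; one object moved to a diagonal corner
in test).

*Behavior* is a semi-Markov chain over locomotion, grooming, rearing,
background, and object-visit states with exponential dwell times (means
4–8 s) and no self-transitions; object visits steer the animal to the
chosen object and exploration is labeled only while the nose is inside the
10 cm radius, co-occurring only with locomotion (fast approach) or
object-supported rearing. In the first 3 min of test sessions, visit
allocation is biased toward the moved object by `test_preference` (default
odds multiplier 3), which produces the positive early-test DI.

*Speed* relaxes with a ~1 s OU timescale toward a state-conditioned
log-normal target (locomotion median 12 cm/s, grooming 0.25, rearing 0.6,
background 1.2), multiplied by an exploratory drive `1 + exp(−t/45 s)` so
early-session speed is elevated with a *slower* decay than the neural
recency term — the dissociation the recency analysis must resolve.

*Latent activity* (z-units, 30 Hz) is the additive composition
`0.25·log2(max(speed, 1)) − 0.75·I_groom + 0.15·I_rear +
0.3·I_novel_bout + 2·exp(−t/28 s) + OU(τ = 2 s, sd 0.5)`, with the
component breakdown stored so it provably sums to the total. Effect sizes
follow the scale of the frame-level model's published coefficients for this
preparation (speed ≈ 0.24, grooming ≈ −0.75, rearing ≈ 0.14, object
novelty ≈ 0.3); the recency amplitude and its 28 s constant, and the 45 s
speed-drive constant, mirror the reported decays. Novelty transients attach
to both objects in sample sessions and only to the moved object in test
sessions (configurable). A `speed_lead` option shifts the speed drive of
the latent signal earlier in time, for validating the timing estimator.

*Rendering*: `F465 = B(t)·(1 + g·z) + M(t)`, `F405 = c0·B(t) + M(t)` at
610 Hz, with `B` a shared two-exponential bleach (τ ≈ 60 s and 1000 s,
5% + 15% amplitude on a 200 a.u. base), g = 0.05 per z-unit, c0 = 0.8, and
`M` Poisson-timed (0.05 Hz) biexponential transients of ±2 a.u. added
identically to both channels so the subtraction can remove them. Optional
per-channel white measurement noise defaults to zero — the OU term in the
latent composition is the noise model.

**What the generator does not emulate:** pose-estimation jitter and label
noise; indicator kinetics beyond the single OU smoothness scale (no
rise/decay asymmetry); hemodynamic or wavelength-dependent artifacts
(motion enters both channels identically, which is the best case for the
correction); slow arousal drift uncoupled from the modeled terms; and any
deviation from additivity of the latent components. Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes and validation design

Simulation-heavy checks run at reduced scale chosen once: 300 s sessions
for replicate-heavy recovery and power experiments, 450 s with enriched
object visits for the novelty-contrast calibration, 900 s (the study's
session length) wherever slow components matter (correction
identifiability, recency recovery — the quadratic detrend distorts a 28 s
exponential badly on short sessions). Recovery experiments switch off
generator terms that the estimator under test does not model (novelty and
recency for the speed-slope recovery; the speed drive's slow decay and
novelty for the recency recovery; behavioral-preference clustering for the
novelty contrast, where the detrend would otherwise couple early-test bout
clustering into a phase-asymmetric bias); each such choice is a statement
about what the experiment isolates, not a claim about real data. Because
the pipeline z-scores ΔF/F per session, recovered coefficients live on the
standardized scale; synthetic recovery experiments convert them back to
generator units with the ground-truth trace's standard deviation.

## Known limitations

- The quadratic detrend inside the stated correction removes the latent
  signal's own quadratic-in-time projection; per-session correlation with
  the full latent trace saturates around 0.94–0.98 even with noise off, and
  slow components (recency amplitude, occupancy drifts) are mildly
  compressed.
- The correlation-vs-smoothing-window curve peaks at the timescale where
  noise suppression crosses shared-signal loss; under this generator's
  latent composition that is the behavioral-episode timescale (~8–16 s),
  not the intrinsic-noise timescale.
- The full published random-effects structure (hundreds of random slopes
  across three nested factors) is not expressible in the backend; the
  fallback ladder plus robust SEs is the package's substitute, and the
  recorded `random_level` makes the substitution auditable.
- Timing estimates at a 98% threshold are near-plateau crossings and
  degrade quickly with noise; treat them as order-of-magnitude statements
  unless the signal-to-noise ratio is high.
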