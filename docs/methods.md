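# Methods

This note documents the models, defaults and numerical conventions
behind pallidoseek, and what its synthetic validation does and does not
establish about real recordings.

## Operant schedule engines

Sessions are simulated event-wise. The responder is a homogeneous
Poisson process per behavior (active pokes, inactive pokes, unrewarded
magazine checks); a `deterministic_pokes` flag switches active pokes to
a regular 1/rate grid for calibration runs with a "constant" or
"every-frame" responder.

- **RR value** — each active poke is reinforced independently with
  probability 1/value, so pokes-per-reward is Geometric(1/value) with
  mean = value. The schedule is specified in the literature only by its
  mean; the memoryless per-response Bernoulli is the canonical reading.
- **RI value** — a reward arms after a delay drawn from an Exponential
  with mean = value seconds, measured from the previous reward's
  *collection* (reinforced poke + 1 s collection latency); the first
  active poke at/after arming is reinforced. A uniform-on-[0, 2·value]
  arming alternative is selectable via `ScheduleSpec.ri_arming`. Again
  only the mean is prescribed; the exponential is the memoryless
  default. Note the realized inter-reinforcement interval therefore
  exceeds the nominal value by the ~1 s collection latency plus the
  sub-frame wait for the next poke — about 1% at RI120 with a
  saturating responder, well inside the Monte-Carlo tolerance of the
  calibration checks.
- **FR value** — every value-th poke reinforced (FR1 = continuous
  reinforcement).
- **Caps** — sessions stop at min(30 min, 60 reinforcements) by
  default. When the reward cap binds, the session ends with the final
  reward's collection and no further pokes are recorded during that
  collection (the hole is treated as inactive once the last
  reinforcement is earned).

Reinforced pokes trigger a reward delivery at the poke time and a
rewarded magazine entry after a fixed 1 s latency with an
exponentially distributed dwell (mean 2 s by default). Unrewarded
magazine checks that would overlap an ongoing visit are dropped, so
entries and exits strictly alternate.

Training curricula follow the published stage progressions (RI30 ×2,
RI60 ×2–3, RI120 ×4; RR2 ×1–2, RR5 ×2–3, RR10 ×2–3, RR20 ×2–3), with
the minimum day counts as defaults and per-stage counts configurable
within the printed ranges. Devaluation is modeled as a rate multiplier
on active pokes in a 10-min nonreinforced extinction session:
goal-directed agents use a factor < 1 (default 0.3), habitual agents 1.

`calibrate_schedule` runs the same reinforcement-engine internals on a
long vectorized poke stream without materializing per-event objects;
it exists because calibration runs (≥10³–10⁴ reinforcements) would
otherwise allocate millions of event records to compute two numbers.

## Trace generator

F_RAW(t) = f0 + Σ over events amplitude · K(t − t_event) + ε(t),
clipped at 10⁻³·f0 so fluorescence stays positive. K is a
double-exponential kernel (rise 0.2 s, decay 1.0 s, GCaMP6s-like)
normalized to peak 1, so an isolated transient's maximum is f0 +
amplitude at the closed-form lag (rise·decay/(decay−rise))·ln(decay/rise).
ε is i.i.d. Gaussian per frame (default SD 0.02 at f0 = 1). Default
amplitudes encode the condition effects the analyses must recover —
RI > RR around nose pokes and rewarded magazine entries, RR > RI at
rewarded magazine exits, no effect for unrewarded entries/exits — with
magnitudes (0.25–0.8 ΔF/F-scale) chosen as plausible population-GCaMP
transients; the literature constrains only the orderings. Per-decile
drift slopes add block·slope to the amplitude, where the block (0–9) is
the event's ordinal decile within its class, emulating within-session
response growth.

What the generator does **not** emulate: photobleaching and slow
rig drift (optional hooks exist but default off), motion artifacts,
hemodynamic contamination, indicator nonlinearity/saturation,
autocorrelated noise, and any biophysical spiking model. Passing tests
therefore certify the *analysis chain* (given transients with a known
structure, the pipeline recovers it), not robustness to every artifact
of real photometry.

## ΔF/F pipeline

Three causal stages: trailing mean over (t − 0.75 s, t] (current frame
included); baseline = min of the averaged trace over [t − 3 s, t)
(current frame excluded, matching "preceding"); ratio; then an
exponentially weighted trailing average over (t − 1 s, t] with weights
∝ exp(−Δt/0.2 s) normalized to sum 1 over the frames present. Window
membership is decided by strict time inequalities on the frame grid
(k/fps < width, etc.), so at 30 fps the windows hold 23, 90 and 30
frames. Frames without a complete baseline history are NaN (the first
3.73 s at defaults) and remain NaN after smoothing; the smoother
renormalizes over defined frames rather than extending the warm-up.
A centered variant of the stage-1 mean sits behind
`DffParams.centered_avg`; the orientation of that window is not
specified by the upstream acquisition software, and causal is the
default for consistency with the baseline.

Properties enforced by tests: exact agreement (1e−10) with a naive
per-frame reference; scale invariance (ΔF/F of c·F_RAW equals ΔF/F of
F_RAW to 1e−12); constant input ⇒ identically zero output; smoothing
is a convex combination of the unsmoothed trace over its window.

Ca²⁺ events are maximal runs of frames with smoothed ΔF/F ≥ 0.02 (the
2% criterion; whether the published threshold applied pre- or
post-smoothing is unstated — smoothed chosen since that is the trace
the rest of the analysis consumes). NaN frames break runs. Summaries
report events/min and mean duration (NaN when no events).

## Peri-event analysis

Windows are half-open [t − 2 s, t + 2 s), 120 frames at 30 fps, with
the event at the first post-window frame (index 60); the event's frame
is `round(t·fps)`. Events whose window leaves the defined trace are
dropped and counted. Deciles for the trial-progression analysis are
assigned by event *ordinal* within the class (10% increments of that
event count), partitioned as block k = floor(k·n/10)…floor((k+1)·n/10)−1;
the per-event "degree of change" metric defaults to post-window mean
minus pre-window mean (peak-minus-pre and post-AUC selectable), and the
block means are regressed on the block index 1…10 by OLS.

The pointwise group comparison is a per-frame Welch t test with
Benjamini–Hochberg correction across the 120 frames, reported as
maximal runs of significant frames. It is a screening approximation of
a repeated-measures posthoc readout, not a reimplementation of one;
zero-variance frames are treated as non-significant.

## Decoding protocol

Features default to two scalars per trial — mean ΔF/F over the pre- and
post-event halves of the input range (−2 s, 2 s); frame-wise vectors
are available for alternative input ranges. Per repeat (400 total):
undersample the majority class without replacement to the minority
count; stratified 4-fold CV; standardize features with training-fold
statistics only; fit a linear maximum-margin classifier with fixed
C = 1 (kernel and regularization are not constrained upstream; linear
with unit cost is the simplest faithful choice and both are exposed);
pool the held-out decision values into one ROC/AUC and one confusion
table at decision threshold 0. ROC curves are vertically averaged on a
101-point false-positive-rate grid. RI is the positive class. With
balanced evaluation sets, accuracy = (sensitivity + specificity)/2
exactly, which the tests assert.

`permute_labels=True` shuffles each repeat's labels independently,
yielding the empirical chance distribution: averaging over 400 fresh
permutations concentrates the null mean AUC to 0.5 ± ~0.005, whereas
the null AUC of any single fixed dataset scatters by ~0.58/√n_trials.
This distinction matters when judging "at chance" claims at desk-scale
trial counts.

## Behavioral statistics

The devaluation test is a two-sided Wilcoxon signed-rank on paired
valued/devalued counts. Zero differences are dropped (classic Wilcoxon
convention rather than Pratt). For n ≤ 25 informative pairs the p-value
is exact, computed from the full null distribution of the positive-rank
sum via convolution on a doubled-rank lattice (average ranks for tied
magnitudes give half-integers); above that, the tie-corrected normal
approximation without continuity correction. All-tied input returns
p = 1 with a flag. The devaluation index devalued/(valued+devalued)
summarizes each subject (0.5 = insensitive).

Group comparisons use the scipy Kruskal–Wallis omnibus plus Dunn's
pairwise z tests computed from pooled ranks with tie-corrected
variance; pairwise p-values are Bonferroni-adjusted over the tested
pairs (the adjustment used upstream is unnamed; Bonferroni is the
conservative default), either all unordered pairs or all pairs against
a reference group. Evaporation normalization subtracts the mean loss of
empty control cages and floors at zero with a clamp flag.

## Pipeline, sizes and reproducibility

`run_pipeline` chains simulation → ΔF/F → peri-event → decoding →
devaluation statistics and writes per-stage CSV/TSV outputs plus a
summary JSON. All randomness flows from one master seed through
`numpy.random.SeedSequence` substreams, so identical (config, seed)
runs are byte-identical end to end.

Default problem sizes are desk-scale by design: 2 sessions per
condition of 10 min (against the 30-min cap used for calibration
checks), 400 undersampling repeats, and calibration runs of 1.2×10³
(RI) and 10⁴ (RR) reinforcements; the test suite further trims session
counts and repeats. These sizes put Monte-Carlo error well inside each
check's tolerance while keeping runs in seconds to minutes.

Known limitations: single-channel model only (no isosbestic reference
regression); no repeated-measures ANOVA (the pointwise screen is not a
substitute for inference on real data); the SVM is not tuned (no kernel
or C search) since the protocol's purpose is information detection, not
performance maximization; the agent model has no learning dynamics —
curricula produce stationary behavior per session, so cross-session
acquisition curves are out of scope.
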