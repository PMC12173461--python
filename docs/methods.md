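# Methods

This note documents the models, conventions and numerical choices
behind `vrcfc`, what the synthetic generators do and do not emulate,
and the known limitations.

## Behavioral quantification

**Freezing.** A frame is freezing when `|velocity| ≤ ε`. The faithful
definition is ε = 0 cm/s; real rotary encoders quantize, so ε is a
config parameter with a recommended 0.05 cm/s for noisy logs. Velocity
is signed and backward movement is never freezing. Freezing *epochs*
are maximal runs of freezing frames strictly longer than
`min_duration` (default 1 s): at 30 Hz a 30-frame run (exactly 1.0 s)
is not an epoch, a 31-frame run is. The strict reading is the literal
one; the boundary is tested explicitly.

**Laps.** A lap is a completed 0→200 cm traversal; it ends on the
frame the track end is reached. The imposed 1.5 s end-of-lap teleport
pause is excluded from lap durations and from per-lap freezing
denominators — the pause is imposed by the task, not behavior. The
first lap is the first completed traversal after context onset; a
traversal still in progress at session end is reported separately,
never as a lap. Completion uses a 0.5 cm tolerance at the track end to
absorb logging quantization.

**Session metrics.** Per-lap freezing % is freezing frames in the lap
divided by total lap frames. `avg_freezing_pct` is the *unweighted
mean of per-lap percentages* (the conventional per-trial average).
Because freezing lengthens exactly the laps that contain it, this
average sits a few points below the frame-level freeze probability;
`total_freezing_pct` (all freezing frames in laps / all lap frames) is
the frame-weighted companion and is the quantity that converges to the
generator's stationary freeze probability. Both are reported. Sessions
with zero completed laps return NaN metrics with `defined = False`
rather than spurious zeros. Sessions of unequal duration are never
concatenated; all averages are within-session.

**Shock response.** For each shock with a full window (default 5 s) on
both sides, the mean absolute running speed pre vs post, skipping
teleport-pause frames. A session is "responsive" when post > pre for
at least 2/3 of evaluable shocks — a QC flag only, since the escape
response is a hardware sanity check, not an outcome measure.

## Behavior simulator

A two-state Markov chain (run/freeze) drives velocity: run frames draw
speed ~ Normal(15, 5) cm/s truncated at 0 (negated with probability
0.01 to model backward movement), freeze frames have velocity 0.
Position integrates velocity at 30 Hz over a 200 cm track with a 1.5 s
pause at the end of each lap. Tail shocks inject an additive sprint
decaying exponentially (amplitude 20 cm/s, τ = 2 s); shock amplitude in
mA is carried as metadata only. The chain was chosen as the minimal
generator with the right freezing-epoch structure whose expectations
are analytic: stationary freeze probability `p_rf / (p_rf + p_fr)` and
mean bout length `1 / (p_fr · frame_rate)`. The default mean freeze
bout is 2 s, so that bouts regularly exceed the 1 s epoch threshold.

`freeze_fraction_to_rates` converts a target freeze percentage into
transition probabilities. Cohorts assign each mouse a Gaussian
freezing set-point (baseline 16 %, mouse-level sd 5 shared across
contexts so it cancels in paired contrasts, session-level sd 4) and
add an `effect` (default +8 points, i.e. 16 % vs 24 %) to the
shock-paired context on recall days, decaying geometrically (×0.4 per
day) on later days. The three cohort designs differ as in the task:
design 1 uses the familiar training context as the neutral
comparison; designs 2–3 use two novel contexts with an extra
habituation day; design 3 packs the six 1 s shocks at ~22.5 s
intervals (vs 60 s) and keeps the tail-coat on during recall (a
metadata flag). Context presentation order alternates with mouse
parity (counterbalancing). Exposure sessions last 10 min,
recall sessions 5 min; conditioning sessions append six shocks after a
10 min exploration block.

Not emulated: within-session extinction time-courses (rates are
constant within a session, so the simulated *first lap* is not
systematically more fearful than later laps), licking microstructure,
acquisition dynamics during conditioning, and any physiological
signal. Passing recovery tests therefore validates the measurement
pipeline, not claims about real within-session dynamics.

## Spatial maps and place-field detection

The 2 m track is divided into 40 bins of 5 cm (bins half-open, the
last closed at 200 cm; all indices 0-based). Frames with speed
< 1 cm/s are excluded so tuning is estimated during active running,
never during freezing bouts. Per cell × lap × bin the map holds the
mean ΔF/F over included frames; (lap, bin) cells with no included
frames are unobserved (NaN) and excluded from all means.

**Transients.** The trace is smoothed with a centered 5-frame boxcar.
An event is a run of smoothed frames above baseline + 1σ that lasts at
least 0.5 s and contains at least one frame above baseline + 2σ
(onset/sustain hysteresis matching the indicator's fast-rise,
slow-decay asymmetry). Baseline is the per-cell median; σ comes from
the sub-baseline residuals mirrored about zero, since transients only
deflect upward. The reported onset is the first in-run frame where the
raw trace sits above the 2σ level for two consecutive frames. Under
the package's own generator this recovers ≥ 95 % of onsets within ±2
frames at SNR 4 while producing < 0.002 false events/s on pure noise.

**Field criteria.** Candidate fields are maximal contiguous bin runs
whose mean profile exceeds baseline + 0.10 ΔF/F, where baseline is the
20th percentile of the cell's 40-bin mean map (a low-percentile map
statistic is robust to field occupancy; the percentile is
configurable). ΔF/F is itself a percentage quantity, so "10 % above
baseline" is implemented as an absolute 0.10 ΔF/F offset: a purely
multiplicative rule (baseline × 1.1) degenerates when the baseline of
a mean-zero map approaches 0, accepting most of the track for any
active-but-untuned cell (measured as a ~27 % false-positive place-cell
rate among rate-matched untuned cells, vs ~0–2 % with the absolute
offset). The offset is a parameter (`min_dff`), so detection is
equivariant under joint rescaling of traces and threshold; criteria
2–4 are rank/ratio-based and scale-free.

A candidate becomes a place field iff, in order:

1. mean in-field ΔF/F > baseline + 0.10, and the candidate leaves some
   observed out-of-field track (a candidate spanning every observed
   bin has no defined contrast and is rejected);
2. reliability — the fraction of laps with ≥ 1 running-frame transient
   onset inside the field's bins — strictly exceeds 0.30;
3. the field's suprathreshold run starts after bin 0: a profile
   truncated at the teleport boundary has no rising flank on the
   track. This is a spatial operationalization of "the rising phase of
   the mean transient is on the track";
4. bootstrap p < 0.05 (below).

Rejections carry the first failed criterion. Multiple fields per cell
are treated independently; a cell is a place cell if it holds ≥ 1
accepted field, and the place-cell fraction is place cells / recorded
cells × 100.

**Bootstrap null.** The statistic is mean in-candidate minus mean
out-of-candidate ΔF/F on the laps × bins map. Each lap's bin vector is
independently circularly rotated by a uniform random offset —
preserving within-lap autocorrelation while destroying lap-consistent
tuning — and the add-one estimator `p = (1 + #{null ≥ observed}) /
(1 + n_shuffles)` (default 1000 shuffles) never returns 0. With a
fixed candidate window the p-values are uniform on untuned maps
(type-I error at 0.05 calibrated to [0.03, 0.07]); because candidates
are *selected* from the same map, end-to-end false positives are
controlled jointly by criteria 1–4 rather than by the bootstrap alone.
The null is deliberately swappable behind `bootstrap_field_test`.

**Field parameters.** COM is the activity-weighted mean of in-field
bin centers. Width is the extent around the in-field peak where the
profile stays above baseline + 25 % of (peak − baseline), crossings
linearly interpolated between bin centers, clipped to the track, never
reported below one bin (5 cm). The out/in ratio is mean out-of-field
over mean in-field activity (0 = perfectly specific).

## Calcium simulator and ground truth

Place cells have Gaussian spatial tuning (center uniform on the track,
σ = 10 cm by default). On each lap, with probability `reliability`
(default 0.8), one transient is triggered as the mouse crosses a
position drawn from the tuning curve; transients rise instantly to
`amplitude` (1.0 ΔF/F) and decay exponentially (τ = 0.5 s,
GCaMP6f-like), implemented as a first-order recursive filter over
impulse trains. Untuned cells emit the same number of transients per
session at uniformly random running frames, so the two classes match
in event rate and detection cannot separate them by activity alone.
Gaussian noise (sd 0.2, i.e. SNR 5) is added last.

Because the indicator kernel is causal, fluorescence mass trails the
triggering position by roughly run-speed × τ (~6–8 cm at these
defaults). The generator therefore records two truths per place cell:
the latent tuning center, and the COM/width of the *noise-free* binned
profile given the actual trajectory and kinetics (`com_noise_free`,
`width_noise_free`). Recovery is assessed against the noise-free
profile, which is the quantity a map-based pipeline can recover
without spike deconvolution (deconvolution is out of scope); the
latent center differs from it by the kinetic offset by construction,
in the simulation as in real indicators.

The paired-session generator copies session-1 tuning into session 2,
reassigns a `remap_fraction` subset of place cells to new uniform
centers (the task reports remapping but no displacement law, so
remapped centers are independent of old ones) and multiplies all
widths by `width_scale_session2` (< 1 models post-conditioning field
narrowing), returning the ground-truth cell-identity map.

## Stability and population comparisons

Split-half correlation: Pearson correlation (Spearman by option)
between the mean profiles of the first and second half of laps, the
extra lap of an odd count going to the first half; undefined below 4
laps. Across-session correlation: Pearson correlation of session-mean
profiles of matched cells, restricted — when a reference field table
is supplied — to cells with an accepted field in the reference
session. In both, bins unobserved in either profile are dropped
pairwise and pairs sharing < 10 bins are undefined. The across-day COM
pair takes the reference field's COM and the COM of the other
session's profile over the same bins, weighted above that session's
baseline. The within-session control population is the same
field-holding cells, mirroring the reference-session restriction.

Population comparisons (width, reliability, out/in, fraction) are
paired at the *mouse* level — per-mouse means, paired t-test across
mice — to avoid pseudoreplicating cells; pooled-cell two-sample KS
statistics are retained as descriptive distribution comparisons. With
a single mouse the comparison is descriptive only.

## Statistics

Paired contrasts use the two-sided paired t-test with a t-distribution
95 % CI of the mean difference; identical differences are flagged
degenerate. The paired effect size defaults to d_z =
mean(diff)/sd(diff) (d_av — dividing by the average condition sd — by
option). Bonferroni adjustment is `min(1, p·m)` with `m` at least the
number of tests. Distribution comparisons use the asymptotic
two-sample KS test.

Extinction is modelled per context and per metric (first-lap or
average freezing) as freezing ~ categorical(day, reference =
pre-conditioning Day 0) with a random intercept per mouse, estimated
by REML (statsmodels MixedLM) with normal-approximation (Wald)
p-values; the estimation flavor is stated because likelihood-ratio or
Satterthwaite p-values would differ slightly in small samples. A
near-zero random-intercept variance is flagged singular but estimates
are still returned.

## Numerical and design choices

- All randomness flows through numpy Generators seeded explicitly;
  simulators, bootstrap and pipeline are bit-reproducible from their
  seeds, and the pipeline manifest records seeds and a config hash.
- The sequential frame loop of the behavior simulator is compiled with
  numba; random draws are made beforehand in numpy so seeding is
  unaffected by the compiled code.
- Bins: 0-based, half-open except the last; positions in cm; `n_bins ×
  bin_width` must equal the track length and configs violating this
  are rejected before execution.
- Degenerate inputs: empty sessions produce empty lap tables (not
  errors); flat traces produce no transients; maps with no observed
  bins are skipped; candidates spanning all observed bins are rejected
  with a named reason.
- Scaled test conditions: the statistical guarantees are exercised at
  reduced but stated sizes chosen as this package's own test
  conditions — 1000 untuned cells at 399 shuffles for bootstrap
  calibration, 50 cells per tuning width for recovery, 200-cell
  populations for remapping, 50 replicate 8-mouse cohorts for
  narrowing power, 100 replicate 20-mouse tables for the extinction
  model, 200 replicate 27-mouse cohorts for behavioral power.

## Known limitations

- The per-lap-average freezing metric is downward-biased relative to
  the frame-level freeze probability whenever freezing and lap length
  are positively coupled; use `total_freezing_pct` when comparing to a
  generative freeze rate.
- Field COM inherits the indicator's kinetic offset; comparisons
  across sessions are unaffected (the offset is common), but absolute
  COM should not be read as the latent tuning center.
- The bootstrap controls lap-consistency significance for a given
  candidate; candidate selection is data-driven, so the end-to-end
  false-positive rate depends on all four criteria together (measured
  at ~0–2 % of untuned cells under the default generator).
- Cell matching across sessions is consumed as an input map and
  assumed correct; image-based alignment is out of scope.
- The extinction model assumes a common residual variance across days
  and mice; heavy-tailed or heteroscedastic freezing distributions are
  not modelled.
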