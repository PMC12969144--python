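# Methods

This note documents the models and procedures implemented in `respalign`, the
choices made where several designs were defensible, and what the synthetic
experiments do and do not establish about real recordings.

## Respiratory phase model

A breath cycle is the interval between two successive inspiration onsets
(troughs of the respiration trace), with peak inhalation in between. Phase is
piecewise linear within each cycle:

φ(t) = π·(t − t_on)/(t_peak − t_on) for the inhale segment, and
φ(t) = π + π·(t − t_peak)/(t_end − t_peak) for the exhale segment,

so φ = 0 at inspiration onset, π at peak inhalation, and → 2π at expiration
end. Phase is evaluated *directly* on the 20 Hz analysis grid from the
landmark times — never by filtering or interpolating wrapped phase values,
which would smear the 2π → 0 discontinuity. Samples outside complete cycles
or inside atypical cycles carry a validity flag instead of a value.

This two-segment construction is deliberately landmark-based. The Hilbert
analytic-signal phase of the band-limited trace is exposed
(`analytic_phase`) as a cross-check — it must co-rotate with the landmark
phase — but is not the primary definition, because the analytic phase of an
asymmetric breath waveform advances non-linearly within a cycle.

## Segmentation

Landmarks are detected on a zero-phase 4th-order Butterworth low-pass (2 Hz
cutoff) of the trace: troughs and peaks via prominence-gated peak picking
(prominence ≥ 0.1 of the 5th–95th percentile amplitude range, trough spacing
≥ 1.5 s). Near its extrema the raw trace is noise-dominated — the waveform is
locally flat, so an argmin on raw samples jitters by ~100 ms at realistic
noise levels. Troughs are therefore localized as the *intersection of the two
linear flanks* fitted on a lightly smoothed copy (8 Hz low-pass) just outside
the rounded tip (60–400 ms from the detected minimum). A breath trough is a
kink (exhale running into the next inhale), and flank intersection is robust
both to sample noise (regression averaging) and to the systematic shift that
heavier smoothing induces when the two adjacent cycles differ in duration.
Landmark-based segmentation, phase, and the atypicality screen are invariant
under affine amplitude transforms of the trace (gain > 0, any offset).

Cycles tile the segmented span; membership of a time point uses half-open
intervals [onset, end), so a stimulus landing exactly on a shared trough
belongs to the cycle starting there.

## Atypical cycles

Each cycle's waveform is taken from the z-scored trace, time-normalized to
100 points, and compared to the pointwise-mean (centroid) cycle by mean
squared distance. A cycle is atypical when its distance exceeds
mean + 3 SD of the distance distribution (single pass, no re-centroiding).
Two numerical guards: when the distance SD is zero nothing is flagged, and
distances below 1e−3 squared z-units never count as atypical — resampling
round-off on effectively identical cycles must not register as an outlier.
Note the screen is *shape*-based: a cycle that is merely long or short but
has the usual waveform is not atypical, because time normalization removes
duration.

## Trial handling

A trial is included iff its onset is covered by a typical cycle, a response
was registered (when the paradigm imposes a deadline), and the RT lies in
[0.2, 3.0] s. Each excluded trial carries exactly one reason, assigned in the
order coverage → atypicality → response → RT bounds. Phase epochs are sliced
from the continuous 20 Hz phase series around each onset — window (−8, +4) s,
241 samples — with nearest-sample alignment; out-of-recording and atypical
cells are masked rather than dropped, and per-time trial counts are adjusted
accordingly. The window is wide enough to contain any condition cluster the
analyses are expected to resolve, with margin on both sides.

## plvs and its inference

plvs(t) is the resultant length of the trial-averaged unit phase vector over
valid trials; time points with fewer than 10 contributing trials are reported
as missing (NaN), never as 0.

**Surrogate null.** Each iteration circularly shifts every trial's epoch
(phase and validity mask together) by an independent uniform integer lag
within the window, recomputes per-participant plvs, averages over
participants (complete-case over time), and takes the maximum over time. The
corrected threshold is the 99th percentile of these maxima, giving p < 0.01
family-wise over the 241 time points. Shifts wrap within the epoch rather
than re-epoching from the continuous record so the surrogate's data content
is identical to the observed data; this is configurable in principle but was
chosen as the default because it makes the null exactly exchangeable with
the observed statistic.

**Cluster test.** Per time point, a paired t statistic of the condition
difference across participants; cluster-forming rule: contiguous same-sign
runs with |t| above the two-sided α = 0.05 critical value, lasting at least
250 ms (5 samples at 20 Hz). The cluster statistic is the within-run sum of
t values (max-sum). The null distribution collects, per randomization of
independent participant-wise sign flips, the maximum |cluster sum|;
p = (1 + exceedances)/(1 + n_rand), so p is never exactly 0. For n ≤ 20
participants the full 2ⁿ enumeration is available and is what the test-suite
checks against a brute-force oracle. Cohen's D is reported at the time point
of largest |group-mean difference| within each cluster, as mean/SD of the
paired differences (n − 1 denominator). Time points where any participant
lacks plvs are dropped from the group statistics (complete-case over time)
and break cluster contiguity, which is conservative.

A calibration caveat documented by the test-suite: cluster tests calibrate
against a *smooth* null. On temporally white null traces essentially no
250 ms same-sign run forms, so the rejection rate collapses toward zero
(conservative, not anticonservative); the type-I checks therefore use
smoothed null traces, matching the smoothness of real plvs time courses.

**plvs slope.** max plvs over [+1, +2] s minus min plvs over [−2, −1] s. On
smooth traces the statistic is insensitive to moderate window shifts (the
suite checks < 15% change under a 0.5 s shift of both windows).

**Angular condition difference.** The estimate is the circular mean of the
per-participant wrapped angle differences. The randomization test flips each
participant's difference sign; because sign flips leave every cos(dᵢ)
invariant and negate sin(dᵢ), the test statistic reduces exactly to the mean
sine component. This is equivalent to comparing the mean angles whenever the
cosine sum is positive (always, in practice, for concentrated phase data) and
remains well defined where the raw angle statistic degenerates (antipodal
resultants). The 95% CI is a percentile bootstrap over participants of the
circular-mean difference, centred on the observed direction to avoid wrap
artifacts; a randomization-percentile CI is available as an alternative.

## Synthetic experiments

The generator emulates three paradigms:

| | pre-stimulus | ITI (uniform) | response epoch | conditions |
|---|---|---|---|---|
| experiment 1 | 1.0 s fixed | 3.5–4.0 s | 1.00 s | LONG then SHORT blocks |
| experiment 2 | 3.0 s cue | 1.7–2.8 s | 2.33 s | trial-wise high/low value (1:2.33), independent difficulty |
| experiment 3 | 3.0 s cue | 1.7–2.8 s | 2.17 s | value yoked to difficulty |

The response-epoch lengths are derived from the onset-to-onset intervals the
paradigms produce (≈5.75 s for experiment 1, ≈7.6/7.4 s for experiments
2–3) net of the pre-stimulus period and mean ITI. Value labels are assigned
by a seeded permutation with the 1:2.33 high:low ratio, so they are not
predictable from trial history.

**Respiration.** Cycles are half-cosine inhale + half-cosine exhale segments
(inhale fraction 0.45), with lognormal durations (default mean 3.55–4.23 s
per experiment, matching the printed group means; CV 0.12) and a smooth
per-cycle amplitude envelope that equals 1 at every trough (so cycle
boundaries stay continuous and peak-detectable), plus white measurement
noise (SD 0.01 of unit amplitude). Event coupling: for each scheduled onset
a target phase is drawn from von Mises(μ, κ_condition), with μ defaulting to
π (peak inhalation — the phase participants empirically prefer). The chain of
cycles between the previous position and the onset is laid so that the drawn
phase lands exactly on the onset time: k filler cycles plus the leading
fraction of the onset cycle share a common rescaling, with k chosen so the
rescaling stays near 1. Durations are bounded to [0.47, 1.9] × the mean and
the onset cycle may never extend past the next onset; when these bounds bind
(≈5% of onsets at κ ≈ 2) the realized phase deviates boundedly from the
draw. κ = 0 disables the adjustment entirely — respiration free-runs and the
phase at onset is uniform by construction.

Two deliberate consequences of this mechanism, verified empirically:

- the phase-at-onset distribution matches von Mises(μ, κ), so plvs at onset
  recovers the Bessel ratio I₁(κ)/I₀(κ) within Monte-Carlo error at
  κ ∈ {0, 1, 2, 4}, n = 400 trials;
- under strong coupling, cycle durations near onsets are mechanically
  modulated (onset-containing cycles average ≈0.3 s longer than the nominal
  mean at κ ∈ [1, 4], and the duration CV rises). This is not a bug: aligning
  a ~3.8 s rhythm to events ~5.75 s apart *requires* duration modulation.
  Duration-recovery checks therefore use the uncoupled generator, where
  onset-cycle durations are exact (up to the classical length-biased-sampling
  factor 1 + CV², ≈ +1.4%).

The mechanism is one of several physiologically plausible ones (alignment
could equally arise from anticipatory shortening, lengthening, or pausing);
nothing downstream depends on which is true, and no claim about physiology is
intended.

**Behavior.** RT = location + Lognormal(log scale, σ) per condition
(σ = 0.4); accuracy and misses are Bernoulli per condition. Experiment
defaults are set so the simulated group means land near the published
behavioral profile of each paradigm (e.g., ≈0.46 vs ≈0.62 s mean RT and
90.7% vs 96.8% accuracy for SHORT vs LONG).

**What passing tests do not show.** The generator's waveform is far cleaner
than real thermistor data: no baseline drift, no movement artifacts, no oral
breathing episodes, stationary noise, and atypical cycles only when
engineered. Preprocessing fidelity numbers (≥99% trough recovery within
±50 ms, circular RMS phase error ≈0.02 rad) are therefore upper bounds on
real-data performance; the statistical machinery (surrogate correction,
cluster permutation, circular tests) is distribution-free given valid epochs
and transfers as-is.

## Determinism and seeding

One master seed fans out via `numpy` `SeedSequence` keyed substreams to
schedule, respiration, behavior, and each statistical procedure, keyed by
(seed, participant, procedure) rather than execution order; identical
configurations reproduce results bit for bit, and participant-level
parallelism could not change them. Every output artifact embeds a hash of the
full configuration.

## Problem sizes used in the checks

The suite and the acceptance script run entirely on simulated data: traces
are synthesized at 100 Hz (the phase analysis operates at 20 Hz regardless,
and landmark accuracy at 100 Hz is ~10 ms, an order below the ±50 ms
criterion); the planted-effect analysis uses the full study scale of 27
participants × 600 trials with 400 surrogate iterations and 1000
randomizations; error-control rates use 500 replicate null datasets of 8
participants × 40 time points (cluster type I) and 4 × 8 participants × 100
trials × 241 time points (surrogate family-wise rate). These sizes give
binomial/Monte-Carlo standard errors comfortably inside the tolerance bands
they are checked against.

## Known limitations

- The cluster-forming threshold (per-sample paired t at two-sided α = 0.05)
  and the within-epoch wrap of surrogate shifts are defaults chosen here;
  both are exposed as parameters and conclusions should be checked for
  robustness across them.
- The atypicality screen cannot catch duration-only anomalies (see above).
- The angular-difference CI bootstraps participants; with < ~10 participants
  percentile bootstrap intervals on circular means are optimistic.
- `plvs` requires ≥ 10 valid trials per time point by default; sparse designs
  need that threshold lowered consciously.
- The generator plants condition effects only through κ (alignment
  concentration), not through preferred-phase shifts; analyses of μ
  differences are exercised only under the null.
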