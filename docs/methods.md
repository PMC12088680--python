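# Methods

This note documents the analysis procedure, the synthetic-data model
behind the test suite, the numerical conventions, and the places where
the design was genuinely open.

## Stimulus-aligned analysis

**Binning and PSTHs.** Spikes are counted in half-open 5-ms bins
`[a, a + 5)` spanning −500 to +500 ms around each stimulus onset
(200 bins); a spike exactly on an edge belongs to the bin starting
there, so the bins partition time.  Rates are counts divided by the
bin width; the per-trial matrix is kept so late-phase tests can pair
observations by trial.  A 1-ns epsilon guards the floor operation
against float round-off; spike times are stored on a microsecond grid,
so no physical spike can be moved by it.

**Baseline and z-scoring.** Baseline statistics (mean μ_b, s.d. σ_b,
ddof = 1) are computed over the 50 baseline bins (−250–0 ms) of the
*trial-averaged* PSTH.  The plausible alternative — pooling
single-trial baseline bins — is isolated behind `baseline_stats` and
would be a one-line change; the trial-averaged reading matches
z-scoring "the PSTH" rather than individual trials.  A numerically
flat baseline (σ_b < 1 nHz) is treated as degenerate and flagged.

**Responsiveness and the rate-quantum floor.** A unit is responsive
when its maximum z exceeds 2.5 (strictly) inside the response window,
(0, 100] ms by default.  At quiescent-state baselines (~1.2 Hz in S1,
~0.6 Hz in M1) the empirical σ_b is dominated by counting granularity:
with 25 trials, a *single* spike anywhere in a 20-bin search window
yields a bin rate of 8 Hz, which exceeds μ_b + 2.5 σ_b for most
low-rate units.  Under a pure-Poisson baseline that raw rule flags
~19 % of silent S1 units and ~78 % of silent M1 units — it is not a
usable detector at these rates.  The detection denominator is
therefore floored at the one-spike rate quantum 1/(n_trials · Δ)
(8 Hz at 25 trials), so a detection requires an elevation worth
2.5 spikes-per-bin-block; the measured null false-positive rate drops
to ~1 % (S1) and ~0.3 % (M1).  The floor extends the degenerate-
baseline rule (which already needs a rate floor when σ_b = 0) to the
near-degenerate regime, and is a config switch
(`detection_sd_floor_quantum`).

**Latency read-outs.** Conditional on a unit being responsive, onset
latency is the start time of the first bin whose *unfloored* z exceeds
2.5 — the classical rule; durations run from onset to the first bin
with z below 1, censored at the span end when never reached.
Latencies are reported as bin-start times (the conservative earliest
time consistent with naming a bin).  At sparse baselines the unfloored
first-crossing occasionally fires on a lone pre-onset spike; across a
population these early misfires roughly offset the power-limited late
crossings, and grand-mean onsets land within one bin of truth in the
recovery tests.

**Suppression and rebound.** Mean rate in 110–170 ms (suppression) and
the mean within ±20 ms of the 190–400 ms window maximum (rebound;
earliest bin on ties, clipped and flagged at the span edge) are each
paired per trial against that trial's baseline mean and tested with a
two-sided Wilcoxon signed rank (zero differences discarded).  The
pairing unit was an open choice; trials are the only within-unit
replication available.  Suppressed requires significance *and* a
window mean below baseline; rebounding, significance and a mean above
baseline.  Suppression depth is reported as percent of baseline
(undefined and flagged when the baseline mean is zero).

**Signed-rank implementation.** Exact null distribution for ≤ 25
tie-free differences; tie-corrected normal approximation with
continuity correction otherwise.  Validated against a full 2^n
enumeration oracle in the tests.

**Opto-tagging.** PV units are identified from 20-ms cortical light
pulses using 1-ms bins (the pulse spans only four standard bins):
latency ≤ 5 ms, rate above baseline for ≥ 75 % of the pulse,
≥ 1 evoked spike on ≥ 50 % of trials, and no comparable response to
laser-off sham events.  The three thresholds are declared defaults,
not inferred values, and are config keys.  Tagging achieves
precision = recall = 1.0 on the default synthetic block.

**Laminar profiles.** Normalized depth (0 = pia, 1 = white matter) is
binned at 5 % (20 bins); the per-unit amplitude "around the peak" is
the mean of the baseline-subtracted trace over the peak bin ± 2 bins
(25 ms; the exact window was unstated and is configurable).  Bins are
averaged within recording, then across recordings (mean ± s.e.m.);
empty bins are NaN, never zero.

**Aggregation and group tests.** Unit → recording means use
responsive-only denominators for phase fractions; recording → grand
averages are unweighted with n−1 s.d.  Paired comparisons auto-select
signed rank (n ≥ 6) vs paired t; Friedman (n ≥ 4) gates Dunn–Šidák
post hocs; Spearman ρ uses the t-approximation for p; BH-FDR is
applied within explicitly declared families (which comparisons form a
family is a caller decision).

**Protocol analyses.** Propagation speed = distance/latency (mm/ms =
m/s), reported both as mean-of-ratios (primary) and ratio-of-means;
non-positive latency differences are excluded and flagged.  The
paired-pulse second response is measured in the standard peak window
re-aligned to the second pulse with the baseline taken before the
*first* pulse, then normalized to the single-pulse response; lags
shorter than the peak window are rejected.  The silencing statistic is
the integral of the trial-averaged rate over 15–50 ms (rectangle rule,
half-open window), computed raw for the condition ratio — matching the
positive printed integrals — with a baseline-subtracted copy also
emitted; whether the reference integrals are per-unit means or sums is
indeterminate, and the ratio is scale-invariant either way.  The video
motion index differences each post-stimulus frame against the 100-ms
pre-stimulus per-pixel average, averages over a hand ROI and the
6–100 ms window (LED-on frames excluded), and tests trials against
zero.

## Synthetic sessions

The generator emulates what the analysis assumes about the recordings:
quiescent baselines, a responsive subset with area-specific triphasic
profiles, 25-trial blocks at 1 s spacing, and the special protocols.

**Rate model.** Baseline b; linear rise from onset to peak latency; a
5-ms plateau at b + A; exponential decay (τ = 7 ms S1, 9 ms M1, chosen
so the z-based duration read-out reproduces the ~27/~22 ms measured
durations); multiplicative suppression b·f in 110–170 ms; Gaussian
rebound (σ = 30 ms, compact ±4σ support) after the suppression window;
clipped at zero.  The plateau makes the configured amplitude
commensurate with the 5-ms-bin measurement scale, since the measured
amplitudes *are* bin averages.  Presets: S1 b = 1.2 Hz, onset 14.7 ms,
peak 21.4 ms, A = 83 Hz, f = 0.082, rebound 31.4 Hz at 289 ms; M1
b = 0.6 Hz, onset 24.3 ms, peak 31.2 ms, A = 25.8 Hz, f = 0.056,
rebound 20.2 Hz at 274.7 ms.  Fractions: responsive 36.7 %/25.6 %,
suppressed 22.3 %/8.4 % and rebounding 30.9 %/8.1 % of responsive.

**Heterogeneity.** Mean-preserving lognormal multipliers on amplitude
(σ = 0.5) and baseline (σ = 0.4) give realistically skewed
distributions; a common Gaussian latency shift (s.d. 2.5 ms, clipped
at ±5 ms) moves onset, peak and rebound together.  Depths are
Beta(2, 2); a Gaussian laminar gain (centre 0.5 for S1, 0.3 for M1)
modulates amplitude and is mean-normalized so population averages stay
at the presets.

**Sampling and seeding.** Exact inhomogeneous Poisson by thinning
against the profile ceiling; spike times rounded to 1 µs (making the
TSV bundle round trip lossless) and deduplicated.  One cohort seed
spawns per-recording child seeds by index, so extending a cohort
leaves earlier recordings bit-identical.  A seed is mandatory.

**Special blocks.** Opto-tag: 25 pulses then 25 laser-off shams at the
same cadence; PV units fire ~150 Hz sustained for the pulse at ~1 ms
latency, non-PV units are suppressed to 10 % of baseline for ~60 ms.
Silencing: interleaved hand / cortex / hand+cortex trials (27 each);
combined trials scale the hand-evoked profile by the configured
attenuation (default 0.7).  Paired pulse: single pulses interleaved
with pairs at 150/250/350 ms; per-lag amplitude scaling defaults to
(0.5, 1, 1).  Paired-pulse trials are spaced 1.5 s (the plain-block
1 s spacing would fold a trial's rebound into the next trial's
baseline once a 350-ms second pulse is present).

**What the generator does not model** — and hence what passing
recovery tests do and do not show: no trial-to-trial over-dispersion
or slow state fluctuations (real baselines are noisier than Poisson,
which would *raise* σ_b and change detection trade-offs), no spike
waveforms or sorting artifacts, no correlations between units, no LFP,
no biophysics.  Recovery results certify the pipeline's arithmetic and
its behavior under the stated statistical structure, not performance
on real recordings.

## Known limitations (measured, not hidden)

* **Max-statistic amplitude bias.** The peak amplitude is the maximum
  of ~20 noisy bins; at 25 trials the per-bin counting noise is ~31 %
  of an 83-Hz S1 response and ~55 % of a 25.8-Hz M1 response.  The S1
  grand mean consequently runs ~8 % high; the M1 grand mean runs
  ~50–70 % high because detection conditioning (units are found *by*
  their fluctuations at this SNR) compounds the max bias.  The
  recovery suite asserts the ±15 % band regardless and the M1
  amplitude check fails honestly; rebound amplitudes (window means,
  not maxima) sit near their configured values but fluctuate across
  seeds with few qualifying M1 units.
* **Signed-rank miscalibration at sparse rates.** With a 1.2-Hz
  baseline and 25 trials, the per-trial paired differences are
  zero-inflated with asymmetric granularity (a 60-ms window moves in
  16.7-Hz steps, the 250-ms baseline in 4-Hz steps), violating the
  symmetry null.  On baseline-only cohorts the *suppressed* flag fires
  on ~13 % of units (window empty on all trials while several baseline
  means are nonzero gives an all-negative sign pattern), and the
  *rebounding* flag on ~0.2 % — neither at the nominal 5 %.  The null-
  calibration test asserts the nominal level and fails honestly in
  both directions; the responsiveness false-positive rate (~1 %) is
  stable across seeds.  On cohorts with the configured effect sizes
  the inflation and the ~70 % detection power approximately offset,
  which is why suppressed *fractions* are still recovered.
* The hand-to-S1 distance is a fixed constant (44.3 mm, configurable);
  cortex thickness for depth normalization defaults to a constant
  per recording.
* Multi-unit pooling is taken from upstream sorting labels; the
  generator does not give multi-units distinct rate statistics.
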