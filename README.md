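# triphasic

Stimulus-aligned spike-train analysis of evoked cortical responses in
paired sensory/motor recordings, with a fully seeded synthetic-session
generator so every stage can be verified without real data.

## The problem

Brief (millisecond-scale) peripheral stimulation of the mouse hand
drives a stereotyped population response in hand/forelimb S1 and,
~10 ms later, in M1: a short-latency, large-amplitude **initial peak**,
a window of **suppressed** activity below baseline, and a later,
smaller **rebound** — the *triphasic* pattern.  Quantifying it from
extracellular probe recordings raises a set of small but consequential
analysis decisions: binning and z-scoring against a sparse baseline,
latency read-out conventions, paired nonparametric tests for the late
phases, opto-tag rules for identifying parvalbumin (PV) interneurons,
depth normalization for laminar profiles, and recording-level
aggregation with FDR control.  This package implements that pipeline
as a tested library for electrophysiologists working with
stimulus-locked spike data.

## The model and statistics

For each active unit (single and multi-units pooled), spikes are
binned at Δ = 5 ms in a ±0.5 s window around stimulus onset and
averaged over the (generally 25) trials into a PSTH.  With baseline
mean μ_b and s.d. σ_b over the 50 pre-stimulus bins (−250–0 ms), the
z-trace is z(t) = (r̄(t) − μ_b)/σ_b.  A unit is **stimulus-responsive**
when max z > 2.5 within the response window; onset latency is the
first bin with z > 2.5, duration runs until z first falls below 1, and
peak amplitude is the maximum baseline-subtracted rate within 100 ms.
Because σ_b is granular at ~1 Hz baselines, the *detection* denominator
is floored at the one-spike rate quantum 1/(n_trials·Δ) (see
`docs/methods.md`).  Suppression (110–170 ms) and rebound (190–400 ms;
mean within ±20 ms of the window maximum) are tested per unit by a
Wilcoxon signed rank pairing each trial's window mean against its
baseline mean.  Unit metrics are averaged per recording and then into
grand averages (mean ± n−1 s.d.); group comparisons use signed rank
(n ≥ 6) or paired t, Friedman + Dunn–Šidák for repeated conditions,
Spearman correlations, and Benjamini–Hochberg FDR within declared
families.  Effective propagation speed is pathway distance divided by
latency (mm/ms = m/s).

The synthetic generator draws exact inhomogeneous-Poisson spike trains
(thinning) from a parametric triphasic rate profile — linear rise, 5-ms
plateau at baseline + A, exponential decay, multiplicative suppression,
Gaussian rebound — with presets taken from the measured S1/M1 grand
averages and lognormal/Gaussian between-unit jitter.

## Worked example

```python
from triphasic import pipelines, synth

session, truth = synth.simulate_session(
    synth.s1_population(n_units=40), synth.ProtocolSpec(), seed=7)
df = pipelines.analyze_session(session)
```

Running `python examples/01_simulate_and_detect.py` (the same
computation) prints:

```
units: 40, trials: 25
responsive: 11 detected (27.5%), ground truth 27.5%
mean onset latency:   13.6 ms (configured 14.7 ms)
mean peak amplitude:  92.7 Hz (configured 83.0 Hz)
mean duration:        22.3 ms (configured ~27 ms)
```

The detected responsive fraction matches this draw's ground truth
exactly; the onset grand mean sits within one 5-ms bin of the
configured 14.7 ms; the amplitude read-out (a max statistic over noisy
bins) runs ~10 % hot at 25 trials — a bias the acceptance suite
quantifies rather than hides.  The other scripts in `examples/` cover
the late phases, opto-tagging, laminar profiles, propagation speed and
silencing ratios, and the paired-pulse analysis, one capability each.

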