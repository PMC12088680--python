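"""Paired-pulse excitability: second response normalized to the first.

Simulates a block interleaving single pulses with pairs at 150, 250
and 350 ms lags; during the suppression interval (150 ms) the second
response is generated at half amplitude and the analysis recovers the
normalized ratio near 0.5, returning to ~1 at later lags.
"""

import warnings

from triphasic import pipelines, synth

warnings.simplefilter("ignore")

session, _ = synth.simulate_special_blocks(
    "paired_pulse", synth.s1_population(n_units=60), seed=11,
    protocol=synth.ProtocolSpec(n_trials=80))
results = pipelines.paired_pulse_analysis(session)

print("lag (ms)  first (Hz)  second (Hz)  second/first")
for r in results:
    print(f"{r.lag_ms:7.0f}  {r.first_peak_hz:9.1f}  "
          f"{r.second_peak_hz:10.1f}  {r.normalized_second:11.2f}")
# The 150-ms lag falls inside the post-peak suppression window, where
# the configured generator halves the second response; excitability is
# recovered by 250 ms.
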