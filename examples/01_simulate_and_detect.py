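"""Simulate one S1 recording and detect stimulus-responsive units.

Generates a 40-unit session under the standard protocol (25 hand
photostimuli, 1 s apart), runs the PSTH / z-score / responsiveness
pipeline, and compares detected fractions and latencies with the
generator's ground truth.
"""

import warnings

from triphasic import pipelines, synth

warnings.simplefilter("ignore")

session, truth = synth.simulate_session(
    synth.s1_population(n_units=40), synth.ProtocolSpec(), seed=7)
df = pipelines.analyze_session(session)

resp = df[df["responsive"]]
true_frac = truth.table()["responsive"].mean()

print(f"units: {len(df)}, trials: 25")
print(f"responsive: {len(resp)} detected "
      f"({100 * len(resp) / len(df):.1f}%), "
      f"ground truth {100 * true_frac:.1f}%")
print(f"mean onset latency:  {resp['onset_latency_ms'].mean():5.1f} ms "
      "(configured 14.7 ms)")
print(f"mean peak amplitude: {resp['peak_amplitude_hz'].mean():5.1f} Hz "
      "(configured 83.0 Hz)")
print(f"mean duration:       {resp['duration_ms'].mean():5.1f} ms "
      "(configured ~27 ms)")
# The detected fraction tracks the configured 36.7% responsive share;
# latencies are bin-start times, so they sit within one 5-ms bin of truth.
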