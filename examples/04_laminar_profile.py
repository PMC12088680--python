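"""Depth-resolved (laminar) profile of the evoked initial peak.

Simulates a small paired cohort, bins the responsive units' peak
amplitudes into 20 bins of normalized cortical depth (0 = pia, 1 =
white matter) per recording, and averages across recordings.  The S1
preset biases amplitude to middle layers, the M1 preset to upper
layers — the profile argmax recovers that.
"""

import warnings

import numpy as np

from triphasic import laminar, pipelines, synth

warnings.simplefilter("ignore")

cohort, _ = synth.simulate_cohort(n_recordings=12, seed=12)
unit_df, _, _ = pipelines.analyze_cohort(cohort)

for area in ("S1", "M1"):
    prof = laminar.laminar_profile(unit_df[unit_df["area"] == area], area,
                                   phase="peak")
    peak_bin = np.nanargmax(prof.mean_hz)
    print(f"{area}: strongest evoked activity at normalized depth "
          f"{prof.bin_starts[peak_bin]:.2f}-{prof.bin_starts[peak_bin]+.05:.2f}"
          f" ({prof.mean_hz[peak_bin]:.1f} Hz across "
          f"{prof.n_units[peak_bin]} units)")
    occ = np.isfinite(prof.mean_hz).sum()
    print(f"    occupied depth bins: {occ}/20")
# S1 peaks mid-depth (thalamocortical input zone); M1's configured bias
# is superficial, but with few responsive M1 units per depth bin the
# argmax is noisy -- the cohort-level acceptance checks use more data.
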