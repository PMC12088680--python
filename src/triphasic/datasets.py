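"""Small reference tables for worked examples.

These are printed summary values from an in vivo paired S1/M1
photostimulation study in awake mice — pathway distances, grand-average
onset/peak latencies, and the per-animal integral-firing-rate table
from a four-animal S1-silencing experiment.  They serve as *inputs* to
the package's arithmetic (speed = distance / latency; silencing ratio
= combined / hand), letting the examples and acceptance checks
recompute published-style summaries without any recordings.
"""

from __future__ import annotations

import pandas as pd

#: Estimated pathway distances (mm): hand->S1 via cord (morphometric),
#: S1->M1 (mean Euclidean probe separation).
PATHWAY_DISTANCES_MM = {"hand_to_s1": 44.3, "s1_to_m1": 0.92}

#: Grand-average response latencies (ms) used with the distances above.
RESPONSE_LATENCIES_MS = {
    "s1_onset": 14.7,
    "s1_peak": 21.4,
    "m1_onset": 24.3,
    "m1_peak": 31.2,
}


def silencing_example_integrals() -> pd.DataFrame:
    """Per-animal integral firing rate (Hz*ms, 15-50 ms window).

    Columns: group (s1_all / s1_pv / s1_non_pv / m1_all), recording,
    hand_int (hand stimulation alone), combined_int (hand + S1 PV
    stimulation).
    """
    rows = [
        ("s1_all", "mouse1", 271.1, 225.7),
        ("s1_all", "mouse2", 155.2, 76.0),
        ("s1_all", "mouse3", 94.1, 75.1),
        ("s1_all", "mouse4", 228.4, 165.2),
        ("s1_pv", "mouse1", 355.6, 317.6),
        ("s1_pv", "mouse2", 183.4, 100.7),
        ("s1_pv", "mouse3", 111.4, 96.0),
        ("s1_pv", "mouse4", 308.9, 222.2),
        ("s1_non_pv", "mouse1", 216.4, 166.3),
        ("s1_non_pv", "mouse2", 111.7, 38.0),
        ("s1_non_pv", "mouse3", 66.2, 41.5),
        ("s1_non_pv", "mouse4", 151.6, 110.8),
        ("m1_all", "mouse1", 81.9, 71.4),
        ("m1_all", "mouse2", 46.1, 31.2),
        ("m1_all", "mouse3", 79.8, 63.9),
        ("m1_all", "mouse4", 47.2, 33.6),
    ]
    return pd.DataFrame(rows, columns=["group", "recording", "hand_int",
                                       "combined_int"])


def summarize_silencing_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row silencing ratios plus per-group mean ± n-1 s.d. columns.

    Returns the input with a ``ratio_pct`` column appended, plus
    summary rows (``recording == 'mean'`` / ``'sd'``) per group for the
    hand and combined integrals.
    """
    out = df.copy()
    out["ratio_pct"] = 100.0 * out["combined_int"] / out["hand_int"]
    summaries = []
    for group, g in out.groupby("group", sort=False):
        summaries.append({"group": group, "recording": "mean",
                          "hand_int": g["hand_int"].mean(),
                          "combined_int": g["combined_int"].mean(),
                          "ratio_pct": g["ratio_pct"].mean()})
        summaries.append({"group": group, "recording": "sd",
                          "hand_int": g["hand_int"].std(ddof=1),
                          "combined_int": g["combined_int"].std(ddof=1),
                          "ratio_pct": g["ratio_pct"].std(ddof=1)})
    return pd.concat([out, pd.DataFrame(summaries)], ignore_index=True)
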