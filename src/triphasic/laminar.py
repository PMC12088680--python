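"""Depth-resolved (laminar) response profiles.

Units are sorted into 20 bins of 5 % normalized cortical depth (0 =
pia, 1 = white-matter boundary).  For a given response phase the
per-unit amplitude is averaged within each depth bin inside each
recording, and bins are then averaged across recordings (mean ±
s.e.m.).  Empty bins are flagged (NaN), never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig, DEFAULT_CONFIG

N_DEPTH_BINS = 20


@dataclass
class LaminarProfile:
    """Across-recording laminar profile of one phase's amplitude."""

    area: str
    phase: str
    bin_starts: np.ndarray          # 0.00, 0.05, ... 0.95
    mean_hz: np.ndarray             # NaN where no recording occupies the bin
    sem_hz: np.ndarray
    n_units: np.ndarray             # total units pooled per bin

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area": self.area, "phase": self.phase,
            "bin_start": self.bin_starts, "mean_hz": self.mean_hz,
            "sem_hz": self.sem_hz, "n_units": self.n_units,
        })


def normalize_depth(depth_um: float, cortex_thickness_um: float = 1400.0,
                    ) -> float:
    """Map a depth below the pia to normalized cortical depth [0, 1].

    Out-of-range depths are clipped with a warning; a non-positive
    thickness is an error.
    """
    if cortex_thickness_um <= 0:
        raise ValueError("cortex thickness must be positive")
    r = depth_um / cortex_thickness_um
    if r < 0.0 or r > 1.0:
        warnings.warn(f"depth {depth_um} um outside [0, {cortex_thickness_um}]"
                      " um; clipping", stacklevel=2)
    return float(np.clip(r, 0.0, 1.0))


def depth_bin_index(normalized_depth: float) -> int:
    """Depth bin (0..19) containing a normalized depth; 1.0 maps to 19."""
    return min(int(normalized_depth * N_DEPTH_BINS), N_DEPTH_BINS - 1)


def laminar_profile(unit_table: pd.DataFrame, area: str, phase: str = "peak",
                    ) -> LaminarProfile:
    """Across-recording laminar profile from a per-unit metrics table.

    ``unit_table`` needs columns ``recording_id``, ``normalized_depth``
    and the phase amplitude column (``peak`` ->
    ``laminar_peak_amp_hz``, ``rebound`` -> ``laminar_rebound_amp_hz``);
    rows with NaN amplitude (e.g. units without that phase) are ignored.
    """
    if phase not in ("peak", "rebound"):
        raise ValueError("phase must be 'peak' or 'rebound'")
    col = f"laminar_{phase}_amp_hz"
    df = unit_table.dropna(subset=[col, "normalized_depth"]).copy()
    df["depth_bin"] = [depth_bin_index(d) for d in df["normalized_depth"]]

    per_rec = (df.groupby(["recording_id", "depth_bin"])[col]
               .mean().unstack("depth_bin"))
    per_rec = per_rec.reindex(columns=range(N_DEPTH_BINS))
    counts = (df.groupby("depth_bin")[col].size()
              .reindex(range(N_DEPTH_BINS), fill_value=0))

    mean = per_rec.mean(axis=0, skipna=True).to_numpy()
    n_rec = per_rec.notna().sum(axis=0).to_numpy()
    sd = per_rec.std(axis=0, ddof=1, skipna=True).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.where(n_rec > 1, sd / np.sqrt(np.maximum(n_rec, 1)), np.nan)
    mean = np.where(n_rec > 0, mean, np.nan)

    return LaminarProfile(
        area=area, phase=phase,
        bin_starts=np.arange(N_DEPTH_BINS) / N_DEPTH_BINS,
        mean_hz=mean, sem_hz=sem,
        n_units=counts.to_numpy(),
    )


def profile_similarity(profile_a: LaminarProfile, profile_b: LaminarProfile,
                       min_bins: int = 3) -> Tuple[float, float]:
    """Spearman rank correlation between two profiles' co-occupied bins."""
    a, b = profile_a.mean_hz, profile_b.mean_hz
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < min_bins:
        raise ValueError(
            f"need >= {min_bins} co-occupied depth bins, got {both.sum()}")
    rho, p = sps.spearmanr(a[both], b[both])
    return float(rho), float(p)
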