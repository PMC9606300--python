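"""Turbidity-regime detection for glacial meltwater plumes.

A station's "depth of turbidity change" is the depth at which the
water column transitions from the darkened, sediment-laden surface
layer to clear water below, operationalised as the lower edge of the
deepest 1-m bin whose running-median-smoothed turbidity still reaches
the 0.04 FTU threshold (0 m if no bin does).  The running median (5
bins by default) suppresses single-bin sensor spikes without moving a
plume boundary at the 10-m scales that matter for classification.

Stations are classed Shallow (S, change depth < 10 m), Intermediate
(I, 10-40 m inclusive) or Deep (D, > 40 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .station_io import DepthProfile

__all__ = [
    "TURBIDITY_THRESHOLD_FTU",
    "SHALLOW_MAX_M",
    "DEEP_MIN_M",
    "RegimeAssignment",
    "TurbiditySummary",
    "depth_of_turbidity_change",
    "classify_regime",
    "assign_regime",
    "turbidity_summary",
]

TURBIDITY_THRESHOLD_FTU = 0.04
SHALLOW_MAX_M = 10.0   # S strictly below this
DEEP_MIN_M = 40.0      # D strictly above this


@dataclass(frozen=True)
class RegimeAssignment:
    station_id: str
    turbidity_change_depth: float
    regime: str
    threshold_used: float = TURBIDITY_THRESHOLD_FTU


@dataclass(frozen=True)
class TurbiditySummary:
    mean_turbidity_50m: float
    max_turbidity: float
    depth_of_max_turbidity: float


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def depth_of_turbidity_change(turbidity: DepthProfile,
                              threshold: float = TURBIDITY_THRESHOLD_FTU,
                              smooth_window: int = 5) -> float:
    """Depth (m) of the plume's lower boundary; 0 if never turbid.

    After running-median smoothing, returns the lower bin edge
    (centre + half bin width) of the deepest bin at or above
    ``threshold``.
    """
    prof = turbidity.dropna()
    if len(prof) == 0:
        raise ValueError(f"{turbidity.station_id}: all-missing turbidity profile")
    smoothed = _running_median(prof.values, smooth_window)
    above = np.nonzero(smoothed >= threshold)[0]
    if above.size == 0:
        return 0.0
    depths = prof.depths
    half_bin = 0.5 * float(np.median(np.diff(depths))) if len(prof) > 1 else 0.5
    return float(depths[above[-1]] + half_bin)


def classify_regime(change_depth: float) -> str:
    """S / I / D regime letter from the depth of turbidity change."""
    if change_depth < 0:
        raise ValueError("change depth must be >= 0")
    if change_depth < SHALLOW_MAX_M:
        return "S"
    if change_depth <= DEEP_MIN_M:
        return "I"
    return "D"


def assign_regime(turbidity: DepthProfile,
                  threshold: float = TURBIDITY_THRESHOLD_FTU,
                  smooth_window: int = 5) -> RegimeAssignment:
    """Detect the change depth and classify in one step."""
    d = depth_of_turbidity_change(turbidity, threshold, smooth_window)
    return RegimeAssignment(turbidity.station_id, d, classify_regime(d), threshold)


def turbidity_summary(turbidity: DepthProfile,
                      layer_bottom: float = 50.0) -> TurbiditySummary:
    """Layer-mean turbidity plus the global maximum and its depth.

    The mean covers valid bins with depth <= ``layer_bottom``; the
    maximum is taken over the whole profile, ties resolved to the
    shallowest depth.
    """
    prof = turbidity.dropna()
    if len(prof) == 0:
        raise ValueError(f"{turbidity.station_id}: all-missing turbidity profile")
    in_layer = prof.depths <= layer_bottom
    if not in_layer.any():
        raise ValueError(f"no valid turbidity bins above {layer_bottom} m")
    mean50 = float(prof.values[in_layer].mean())
    imax = int(np.argmax(prof.values))  # argmax returns first (shallowest) tie
    return TurbiditySummary(mean50, float(prof.values[imax]),
                            float(prof.depths[imax]))
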