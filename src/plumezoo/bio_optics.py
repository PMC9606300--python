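"""Light and pigment quantities: euphotic depth, spectrophotometric
chlorophyll-a and fluorescence-maximum summaries.

Euphotic depth is where downwelling PAR falls to 1% of its surface
value.  The surface reference is obtained by log-linear extrapolation
of the two shallowest valid in-water bins to z = 0 (the top metre of a
cast is discarded upstream, and a deck sensor is out of scope), and
the crossing depth is found by linear interpolation in log(PAR); on an
exactly exponential profile PAR0 * exp(-Kd z) this returns
ln(1/fraction)/Kd to machine precision.

Chlorophyll-a from extract absorbance uses the specific-absorption
relation

    chl_a = 1e3 * dOD * V_E / (83 * V_W * l)   [mg m^-3]

with dOD the 665-nm optical density corrected for near-infrared
(750 nm) background, V_E the ethanol extract volume (mL), V_W the
filtered seawater volume (mL) and l the cuvette path (cm); 83 L g^-1
cm^-1 is the chlorophyll-a-specific absorption coefficient in 96%
ethanol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .station_io import DepthProfile

__all__ = [
    "CHL_SPECIFIC_ABSORPTION",
    "EUPHOTIC_FRACTION",
    "ChlSample",
    "FluorescenceSummary",
    "EuphoticDepth",
    "euphotic_depth",
    "chl_from_absorbance",
    "fluorescence_summary",
]

CHL_SPECIFIC_ABSORPTION = 83.0  # L g^-1 cm^-1, chl-a in 96% ethanol
EUPHOTIC_FRACTION = 0.01


@dataclass(frozen=True)
class ChlSample:
    od_665: float
    od_750: float
    extract_volume_ml: float
    filtered_volume_ml: float
    cuvette_path_cm: float = 2.0


@dataclass(frozen=True)
class FluorescenceSummary:
    max_fluorescence: float
    depth_of_max: float
    surface_confined: bool  # maximum within the upper 10 m


@dataclass(frozen=True)
class EuphoticDepth:
    depth: float
    truncated: bool  # profile ended before reaching the fraction

    def __float__(self) -> float:
        return self.depth


def euphotic_depth(par: DepthProfile,
                   fraction: float = EUPHOTIC_FRACTION) -> EuphoticDepth:
    """Depth (m) where PAR falls to ``fraction`` of its surface value.

    Returns the deepest valid depth with ``truncated=True`` when the
    profile never attenuates that far.
    """
    prof = par.dropna()
    pos = prof.values > 0
    if pos.sum() < 2:
        raise ValueError("PAR profile needs >= 2 positive values")
    z = prof.depths[pos]
    logp = np.log(prof.values[pos])
    # log-linear extrapolation of the two shallowest bins to z = 0
    slope = (logp[1] - logp[0]) / (z[1] - z[0])
    log_surface = logp[0] - slope * z[0]
    if not np.isfinite(log_surface):
        raise ValueError("non-positive surface PAR")
    target = log_surface + np.log(fraction)
    if fraction >= 1.0:
        return EuphoticDepth(0.0, False)
    below = np.nonzero(logp <= target)[0]
    if below.size == 0:
        return EuphoticDepth(float(z[-1]), True)
    j = below[0]
    if j == 0:
        # already darker than the target at the first bin: extrapolate up
        z_lo, z_hi, l_lo, l_hi = 0.0, z[0], log_surface, logp[0]
    else:
        z_lo, z_hi, l_lo, l_hi = z[j - 1], z[j], logp[j - 1], logp[j]
    if l_hi == l_lo:
        return EuphoticDepth(float(z_hi), False)
    depth = z_lo + (target - l_lo) * (z_hi - z_lo) / (l_hi - l_lo)
    return EuphoticDepth(float(depth), False)


def chl_from_absorbance(sample: ChlSample) -> float:
    """Chlorophyll-a concentration, mg m^-3, from extract absorbance."""
    if sample.extract_volume_ml <= 0 or sample.filtered_volume_ml <= 0:
        raise ValueError("volumes must be > 0")
    if sample.cuvette_path_cm <= 0:
        raise ValueError("cuvette path must be > 0")
    d_od = sample.od_665 - sample.od_750
    if d_od < 0:
        warnings.warn("negative dOD (turbid blank?) clipped to 0",
                      stacklevel=2)
        d_od = 0.0
    return (1e3 * d_od * sample.extract_volume_ml
            / (CHL_SPECIFIC_ABSORPTION * sample.filtered_volume_ml
               * sample.cuvette_path_cm))


def fluorescence_summary(fluor: DepthProfile) -> FluorescenceSummary:
    """Global fluorescence maximum, its (shallowest) depth, and whether
    it sits in the upper 10 m."""
    prof = fluor.dropna()
    if len(prof) == 0:
        raise ValueError(f"{fluor.station_id}: all-missing fluorescence profile")
    imax = int(np.argmax(prof.values))
    depth = float(prof.depths[imax])
    return FluorescenceSummary(float(prof.values[imax]), depth, depth < 10.0)
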