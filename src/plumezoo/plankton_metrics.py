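"""From particle detections to layer-resolved zooplankton metrics.

The optical counter streams individual detections (depth, equivalent
spherical diameter, attenuance index).  Older *Calanus* copepodites
are selected by the calibrated window 1-2.5 mm ESD (closed) and
attenuance index strictly > 0.4; detections are then converted to
concentrations (counts / sampled volume per 1-m bin) and summarised
per station:

* weighted mean depth (WMD) of the population inside a layer,
  sum(a_i z_i) / sum(a_i) over bin centres;
* mean abundance in the three net-haul layers 0-10, 10-50 and
  50-bottom m;
* the 0-10 m / 10-50 m abundance ratio (surface aggregation index);
* copepodite stage composition shares per layer.

LOPC-derived abundances are individuals m^-3 and UVP-derived
abundances individuals dm^-3 throughout; any conversion between the
two is explicit, never implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ESD_RANGE_MM",
    "AI_MIN",
    "LAYER_BOUNDS_M",
    "STAGES",
    "ParticleRecord",
    "VignetteRecord",
    "AbundanceProfile",
    "LayerAbundance",
    "StageComposition",
    "classify_calanus",
    "concentration_profile",
    "weighted_mean_depth",
    "layer_means",
    "surface_ratio",
    "stage_shares",
]

#: calibrated older-Calanus selection window
ESD_RANGE_MM = (1.0, 2.5)
AI_MIN = 0.4

#: stratified net-haul layer boundaries (surface .. bottom)
LAYER_BOUNDS_M = (10.0, 50.0)
LAYERS = ("0-10", "10-50", "50-bottom")

STAGES = ("nauplii", "CI-CIII", "CIV", "CV", "adult")

VIGNETTE_CATEGORIES = ("copepod", "gelatinous", "detritus", "other")


@dataclass(frozen=True)
class ParticleRecord:
    station_id: str
    depth: float
    esd: float               # mm
    attenuance_index: float  # 0..1

    def __post_init__(self) -> None:
        if self.esd <= 0:
            raise ValueError("ESD must be > 0")
        if not 0.0 <= self.attenuance_index <= 1.0:
            raise ValueError("attenuance index must lie in [0, 1]")


@dataclass(frozen=True)
class VignetteRecord:
    station_id: str
    depth: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in VIGNETTE_CATEGORIES:
            raise ValueError(f"unknown vignette category {self.category!r}")


@dataclass
class AbundanceProfile:
    """Per-bin concentration of one taxon at one station."""

    station_id: str
    taxon: str
    depths: np.ndarray      # bin centres, m
    abundance: np.ndarray   # individuals per unit volume
    units: str = "ind m-3"  # or "ind dm-3" (UVP)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.depths.shape != self.abundance.shape:
            raise ValueError("depths and abundance must align")
        finite = self.abundance[np.isfinite(self.abundance)]
        if finite.size and np.any(finite < 0):
            raise ValueError("abundance must be >= 0")


@dataclass(frozen=True)
class LayerAbundance:
    layer: str         # one of LAYERS
    taxon_or_stage: str
    abundance: float   # NaN flags an empty layer


@dataclass(frozen=True)
class StageComposition:
    """Fractional stage shares per layer; each row sums to 1."""

    layer: str
    shares: dict  # stage -> fraction

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"shares sum to {total}, expected 1")


def classify_calanus(records: list[ParticleRecord],
                     esd_range: tuple[float, float] = ESD_RANGE_MM,
                     ai_min: float = AI_MIN) -> list[ParticleRecord]:
    """Keep detections in the closed ESD window with AI strictly above
    ``ai_min`` — the calibrated older-*Calanus* signature."""
    lo, hi = esd_range
    return [r for r in records
            if lo <= r.esd <= hi and r.attenuance_index > ai_min]


def concentration_profile(counts, volumes, depths, station_id: str = "",
                          taxon: str = "Calanus",
                          units: str = "ind m-3") -> AbundanceProfile:
    """Counts / sampled volume per bin; zero-volume bins are missing."""
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if not counts.shape == volumes.shape == depths.shape:
        raise ValueError("counts, volumes and depths must align")
    bad = (counts > 0) & (volumes <= 0)
    if bad.any():
        raise ValueError(
            f"counts without sampled volume at depths {depths[bad]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(volumes > 0, counts / np.maximum(volumes, 1e-300), np.nan)
    return AbundanceProfile(station_id, taxon, depths, ab, units)


def bin_particles(records: list[ParticleRecord], volumes, depths,
                  station_id: str = "", taxon: str = "Calanus",
                  units: str = "ind m-3") -> AbundanceProfile:
    """Histogram particle detections onto the 1-m grid, then divide by
    the per-bin sampled volume."""
    depths = np.asarray(depths, dtype=float)
    edges = np.concatenate([depths - 0.5, [depths[-1] + 0.5]])
    counts, _ = np.histogram([r.depth for r in records], bins=edges)
    return concentration_profile(counts, volumes, depths, station_id,
                                 taxon, units)


def weighted_mean_depth(profile: AbundanceProfile, layer_top: float = 0.0,
                        layer_bottom: float = 50.0) -> float:
    """Abundance-weighted mean depth over bin centres inside the layer.

    NaN (flagged undefined) when the layer holds no abundance.
    """
    m = ((profile.depths >= layer_top) & (profile.depths <= layer_bottom)
         & np.isfinite(profile.abundance))
    total = profile.abundance[m].sum()
    if not m.any() or total <= 0:
        return float("nan")
    return float((profile.abundance[m] * profile.depths[m]).sum() / total)


def layer_means(profile: AbundanceProfile,
                bottom: float | None = None) -> list[LayerAbundance]:
    """Arithmetic mean abundance in the 0-10, 10-50 and 50-bottom layers.

    Bin membership is by bin centre; a centre sitting exactly on a
    boundary belongs to the shallower layer.  Empty layers are flagged
    with NaN.
    """
    b1, b2 = LAYER_BOUNDS_M
    if bottom is None:
        bottom = float(profile.depths[-1]) + 0.5 if len(profile.depths) else b2
    masks = {
        LAYERS[0]: profile.depths <= b1,
        LAYERS[1]: (profile.depths > b1) & (profile.depths <= b2),
        LAYERS[2]: (profile.depths > b2) & (profile.depths <= bottom),
    }
    out = []
    for layer, m in masks.items():
        m = m & np.isfinite(profile.abundance)
        mean = float(profile.abundance[m].mean()) if m.any() else float("nan")
        out.append(LayerAbundance(layer, profile.taxon, mean))
    return out


def surface_ratio(net: list[LayerAbundance], taxon: str) -> float:
    """abundance(0-10 m) / abundance(10-50 m) for one taxon.

    NaN flags an undefined ratio (zero or missing denominator).
    """
    by_layer = {la.layer: la.abundance for la in net
                if la.taxon_or_stage == taxon}
    for layer in LAYERS[:2]:
        if layer not in by_layer:
            raise ValueError(f"layer {layer!r} missing for taxon {taxon!r}")
    num, den = by_layer[LAYERS[0]], by_layer[LAYERS[1]]
    if not np.isfinite(den) or den == 0:
        return float("nan")
    return float(num / den)


def stage_shares(net: list[LayerAbundance]) -> list[StageComposition]:
    """Per-layer fractional stage composition from net-haul abundances."""
    out = []
    for layer in LAYERS:
        ab = {la.taxon_or_stage: la.abundance for la in net
              if la.layer == layer and la.taxon_or_stage in STAGES}
        if not ab:
            continue
        total = sum(ab.values())
        if total <= 0:
            raise ValueError(f"all-zero stage abundances in layer {layer}")
        out.append(StageComposition(layer,
                                    {s: v / total for s, v in ab.items()}))
    return out
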