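"""Synthetic glacial-plume station bundles.

Emulates the joint structure of a West-Spitsbergen-style summer survey
under three turbidity regimes so that the whole pipeline is testable
without any field data:

* turbidity: background 0.02 FTU plus a logistic plume whose 0.04-FTU
  crossing depth is drawn inside the regime band (Shallow 2-9 m,
  Intermediate 12-35 m, Deep 45-75 m) and whose surface amplitude
  grows from ~0.05-0.1 FTU (S) to ~0.2-0.5 FTU (D); 5% multiplicative
  lognormal sensor noise;
* hydrography: warm, salty ambient water cooled (up to ~2 degC) and
  freshened (up to ~5 salinity units) inside the plume, so meltwater
  lenses stratify the column;
* chlorophyll fluorescence: Gaussian peak, subsurface (15-25 m) in
  clear water, pressed into the top 10 m under thick plumes;
* PAR: Beer-Lambert decay with Kd = k0 + kT * turbidity, tuned so the
  1% euphotic depth comes out near 25 m (S) and near 7 m (D);
* zooplankton: *Calanus*-like particle stream (ESD ~ trunc-normal
  1.6 +/- 0.3 mm on [1, 2.5], high attenuance) over a surface-peaked
  (S, I; e-folding 12 m) or uniform (D) vertical law plus a
  near-bottom diapause maximum, mixed with glacial flour / marine
  snow particles (small, transparent) that track turbidity; Poisson
  counts per 1-m bin with intensity abundance x sampled volume;
* UVP vignette stream (copepods, gelatinous) and stratified net hauls
  (0-10 / 10-50 / 50-bottom) with stage composition ~90% CIV+CV at
  depth and ~75% in the upper layers; gelatinous zooplankton track
  *Calanus* and all but vanish in the Deep regime.

Every bundle is deterministic under (regime, bottom_depth, seed); a
survey spawns independent per-station substreams from one master seed
so station order never matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from datetime import date as _date, time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from .station_io import DepthProfile, StationRecord
from .plankton_metrics import ParticleRecord, VignetteRecord, LayerAbundance
from .turbidity_regimes import TURBIDITY_THRESHOLD_FTU

__all__ = [
    "RegimeScenario",
    "StationBundle",
    "generate_station",
    "generate_survey",
    "write_bundles",
]

BACKGROUND_TURBIDITY = 0.02  # FTU, clear-water floor
PLUME_WIDTH_M = 3.0          # logistic transition scale

#: regime bands for the drawn 0.04-FTU crossing depth (m)
CHANGE_DEPTH_BANDS = {"S": (2.0, 9.0), "I": (12.0, 35.0), "D": (45.0, 75.0)}
#: regime bands for plume surface turbidity (FTU)
SURFACE_TURBIDITY_BANDS = {"S": (0.05, 0.10), "I": (0.10, 0.20),
                           "D": (0.20, 0.50)}
#: regime bands for the fluorescence peak depth (m)
CHL_PEAK_BANDS = {"S": (15.0, 25.0), "I": (8.0, 15.0), "D": (2.0, 8.0)}
#: plausible bottom-depth ranges per regime (survey table spread)
BOTTOM_BANDS = {"S": (90.0, 340.0), "I": (42.0, 340.0), "D": (50.0, 120.0)}

#: light model, tuned once so euphotic depth ~ 25 m (S) and ~ 7 m (D)
KD_CLEAR = 0.15   # m^-1, attenuation of plume-free water
KD_PER_FTU = 1.45  # m^-1 FTU^-1

SURFACE_PAR = 600.0  # umol photons m^-2 s^-1

#: zooplankton vertical-law scales (survey maxima)
CALANUS_SURFACE_PEAK = 5000.0   # ind m^-3, LOPC scale
CALANUS_UNIFORM = 300.0         # ind m^-3, Deep-regime column level
BOTTOM_PEAK = 1000.0            # ind m^-3, diapause maximum
BOTTOM_PEAK_SD_M = 8.0
SURFACE_EFOLD_M = 12.0
COPEPOD_UVP_PEAK = 1000.0       # ind dm^-3
GELATINOUS_PEAK = 20.0          # ind dm^-3; ~0 in the Deep regime

LOPC_BIN_VOLUME_M3 = 0.005      # 49 cm^2 aperture x 1 m
UVP_BIN_VOLUME_DM3 = 0.5        # ~ one half-litre of imaged water per metre

TURBIDITY_NOISE_SD = 0.05       # lognormal sigma, sensor noise
NET_NOISE_SD = 0.2              # lognormal sigma, haul replicate CV

#: stage shares (nauplii, CI-CIII, CIV, CV, adult)
STAGE_SHARES_DEEP = (0.01, 0.07, 0.32, 0.55, 0.05)
STAGE_SHARES_UPPER = (0.05, 0.17, 0.30, 0.45, 0.03)
STAGE_SHARES_D_SURFACE = (0.04, 0.35, 0.25, 0.33, 0.03)
STAGE_NAMES = ("nauplii", "CI-CIII", "CIV", "CV", "adult")


@dataclass(frozen=True)
class RegimeScenario:
    """Ground-truth parameters behind one generated station."""

    regime: str
    bottom_depth: float
    change_depth: float         # where turbidity crosses 0.04 FTU
    surface_turbidity: float    # plume turbidity at z = 0
    plume_width: float
    background_turbidity: float
    cooling: float              # degC removed inside the plume
    freshening: float           # salinity units removed inside the plume
    chl_peak_depth: float
    chl_peak_value: float
    kd_clear: float
    kd_per_ftu: float
    zoo_shape: str              # 'surface' (S, I) or 'uniform' (D)
    calanus_scale: float
    bottom_peak: float
    gelatinous_scale: float
    seed: int

    # ---- noise-free generating laws -------------------------------------
    def plume_profile(self, z: np.ndarray) -> np.ndarray:
        """Logistic plume excess turbidity (FTU) above background."""
        amp = self.surface_turbidity - self.background_turbidity
        tau = TURBIDITY_THRESHOLD_FTU - self.background_turbidity
        # place the logistic so the noise-free crossing sits at change_depth
        z0 = self.change_depth - self.plume_width * np.log(amp / tau - 1.0)
        return amp / (1.0 + np.exp((z - z0) / self.plume_width))

    def turbidity(self, z: np.ndarray) -> np.ndarray:
        return self.background_turbidity + self.plume_profile(z)

    def calanus_abundance(self, z: np.ndarray) -> np.ndarray:
        """ind m^-3 vertical law (surface or uniform shape + bottom peak)."""
        z = np.asarray(z, dtype=float)
        if self.zoo_shape == "surface":
            body = self.calanus_scale * np.exp(-z / SURFACE_EFOLD_M)
        else:
            body = np.full_like(z, self.calanus_scale)
        z_bot = 0.9 * self.bottom_depth
        peak = self.bottom_peak * np.exp(-0.5 * ((z - z_bot)
                                                 / BOTTOM_PEAK_SD_M) ** 2)
        return body + peak

    def expected_wmd(self, layer_top: float = 0.0,
                     layer_bottom: float = 50.0) -> float:
        """Weighted mean depth of the noise-free law on the 1-m bin grid."""
        z = np.arange(1.5, self.bottom_depth, 1.0)
        m = (z >= layer_top) & (z <= layer_bottom)
        a = self.calanus_abundance(z[m])
        return float((a * z[m]).sum() / a.sum())


@dataclass
class StationBundle:
    """Everything the pipeline ingests for one station, plus the truth."""

    record: StationRecord
    profiles: dict[str, DepthProfile]
    particles: list[ParticleRecord] = field(default_factory=list)
    lopc_volumes: np.ndarray | None = None       # m^3 per bin
    vignettes: list[VignetteRecord] = field(default_factory=list)
    uvp_volumes: np.ndarray | None = None        # dm^3 per bin
    nets: list[LayerAbundance] = field(default_factory=list)
    scenario: RegimeScenario | None = None

    @property
    def depths(self) -> np.ndarray:
        return self.profiles["turbidity"].depths


def _draw_scenario(regime: str, bottom_depth: float, seed: int,
                   rng: np.random.Generator) -> RegimeScenario:
    if regime not in CHANGE_DEPTH_BANDS:
        raise ValueError(f"unsupported regime {regime!r}")
    lo, hi = CHANGE_DEPTH_BANDS[regime]
    change = float(rng.uniform(lo, hi))
    change = min(change, bottom_depth - 2.0)
    surf = float(rng.uniform(*SURFACE_TURBIDITY_BANDS[regime]))
    chl_depth = float(rng.uniform(*CHL_PEAK_BANDS[regime]))
    chl_value = float(rng.uniform(1.5, 3.0)) if regime != "D" \
        else float(rng.uniform(0.6, 1.2))
    cooling = float(rng.uniform(1.0, 2.0)) if regime != "S" \
        else float(rng.uniform(0.0, 0.5))
    freshening = float(rng.uniform(3.0, 5.0)) if regime != "S" \
        else float(rng.uniform(0.5, 1.5))
    return RegimeScenario(
        regime=regime, bottom_depth=float(bottom_depth), change_depth=change,
        surface_turbidity=surf, plume_width=PLUME_WIDTH_M,
        background_turbidity=BACKGROUND_TURBIDITY, cooling=cooling,
        freshening=freshening, chl_peak_depth=chl_depth,
        chl_peak_value=chl_value, kd_clear=KD_CLEAR, kd_per_ftu=KD_PER_FTU,
        zoo_shape="uniform" if regime == "D" else "surface",
        calanus_scale=CALANUS_UNIFORM if regime == "D"
        else CALANUS_SURFACE_PEAK,
        bottom_peak=BOTTOM_PEAK,
        gelatinous_scale=0.0 if regime == "D" else GELATINOUS_PEAK,
        seed=int(seed),
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _particle_stream(rng, z, scenario, noise_free=False):
    """Calanus-like + flour/snow particle detections and per-bin volumes."""
    vol = np.full(z.size, LOPC_BIN_VOLUME_M3)
    cal_lambda = scenario.calanus_abundance(z) * vol
    det_lambda = 2.0e4 * scenario.turbidity(z) * vol
    particles: list[ParticleRecord] = []
    cal_counts = cal_lambda.astype(int) if noise_free \
        else rng.poisson(cal_lambda)
    det_counts = det_lambda.astype(int) if noise_free \
        else rng.poisson(det_lambda)
    for zi, nc, nd in zip(z, cal_counts, det_counts):
        if nc:
            esd = _truncnorm(rng, 1.6, 0.3, 1.0, 2.5, nc)
            ai = rng.beta(8.0, 2.0, size=nc)
            depths = rng.uniform(zi - 0.5, zi + 0.5, size=nc)
            particles += [ParticleRecord("", float(d), float(e), float(a))
                          for d, e, a in zip(depths, esd, ai)]
        if nd:
            esd = np.exp(rng.normal(np.log(0.4), 0.5, size=nd))
            ai = rng.beta(2.0, 12.0, size=nd)
            depths = rng.uniform(zi - 0.5, zi + 0.5, size=nd)
            particles += [ParticleRecord("", float(d), float(max(e, 1e-3)),
                                         float(a))
                          for d, e, a in zip(depths, esd, ai)]
    return particles, vol


def _vignette_stream(rng, z, scenario):
    vol = np.full(z.size, UVP_BIN_VOLUME_DM3)
    shape = scenario.calanus_abundance(z) / scenario.calanus_abundance(
        np.array([1.5]))[0]
    # abundance (ind dm^-3) x imaged volume (dm^3) = expected counts per bin
    cop_lambda = COPEPOD_UVP_PEAK * shape * vol
    gel_lambda = scenario.gelatinous_scale * shape * vol
    vignettes: list[VignetteRecord] = []
    for zi, lc, lg in zip(z, cop_lambda, gel_lambda):
        for cat, lam in (("copepod", lc), ("gelatinous", lg)):
            n = rng.poisson(lam)
            for d in rng.uniform(zi - 0.5, zi + 0.5, size=n):
                vignettes.append(VignetteRecord("", float(d), cat))
    return vignettes, vol


def _net_hauls(rng, scenario, noise_free=False) -> list[LayerAbundance]:
    z = np.arange(1.5, scenario.bottom_depth, 1.0)
    a = scenario.calanus_abundance(z)
    gel = scenario.gelatinous_scale * a / max(a[0], 1e-12)
    layers = {
        "0-10": z <= 10.0,
        "10-50": (z > 10.0) & (z <= 50.0),
        "50-bottom": z > 50.0,
    }
    out: list[LayerAbundance] = []
    for layer, m in layers.items():
        if not m.any():
            continue
        noise = 1.0 if noise_free else float(rng.lognormal(0.0, NET_NOISE_SD))
        cal = float(a[m].mean()) * noise
        out.append(LayerAbundance(layer, "Calanus", cal))
        gnoise = 1.0 if noise_free else float(rng.lognormal(0.0, NET_NOISE_SD))
        out.append(LayerAbundance(layer, "gelatinous",
                                  float(gel[m].mean()) * gnoise))
        if layer == "50-bottom":
            shares = STAGE_SHARES_DEEP
        elif layer == "0-10" and scenario.regime == "D":
            shares = STAGE_SHARES_D_SURFACE
        else:
            shares = STAGE_SHARES_UPPER
        for stage, s in zip(STAGE_NAMES, shares):
            out.append(LayerAbundance(layer, stage, cal * s))
    return out


def generate_station(regime: str, bottom_depth: float | None = None,
                     seed: int = 0, station_id: str | None = None,
                     region: str = "ISF", noise_free: bool = False,
                     components: tuple = ("profiles", "particles",
                                          "vignettes", "nets"),
                     ) -> StationBundle:
    """Generate one complete synthetic station bundle.

    Deterministic under (regime, bottom_depth, seed).  ``components``
    selects which data streams to synthesise (profiles are always
    included); ``noise_free=True`` suppresses all observation noise so
    closed-form checks can invert the scenario exactly.
    """
    rng = np.random.default_rng(seed)
    if bottom_depth is None:
        bottom_depth = float(rng.uniform(*BOTTOM_BANDS.get(regime, (60, 200))))
    if bottom_depth < 40.0 or bottom_depth > 350.0:
        raise ValueError("bottom_depth must lie in [40, 350] m")
    scenario = _draw_scenario(regime, bottom_depth, seed, rng)
    sid = station_id or f"SYN-{regime}-{seed}"

    z = np.arange(1.5, bottom_depth, 1.0)
    plume = scenario.plume_profile(z)
    turb = scenario.background_turbidity + plume
    if not noise_free:
        turb = turb * rng.lognormal(0.0, TURBIDITY_NOISE_SD, size=z.size)
    plume_frac = plume / plume.max() if plume.max() > 0 else np.zeros_like(z)

    temp = 1.5 + 4.5 * np.exp(-z / 25.0) - scenario.cooling * plume_frac
    sal = 34.8 - 0.8 * np.exp(-z / 25.0) - scenario.freshening * plume_frac
    if not noise_free:
        temp = temp + rng.normal(0.0, 0.02, size=z.size)
        sal = sal + rng.normal(0.0, 0.01, size=z.size)

    fluor = 0.05 + scenario.chl_peak_value * np.exp(
        -0.5 * ((z - scenario.chl_peak_depth) / 6.0) ** 2)
    if not noise_free:
        fluor = fluor * rng.lognormal(0.0, 0.05, size=z.size)

    kd = scenario.kd_clear + scenario.kd_per_ftu * scenario.turbidity(z)
    # optical depth accumulated from the surface (z[0] sits at 1.5 m)
    od = np.concatenate([[kd[0] * z[0]],
                         kd[0] * z[0] + np.cumsum(0.5 * (kd[1:] + kd[:-1])
                                                  * np.diff(z))])
    par = SURFACE_PAR * np.exp(-od)
    if not noise_free:
        par = par * rng.lognormal(0.0, 0.02, size=z.size)

    profiles = {
        "temperature": DepthProfile(sid, "temperature", z, temp),
        "salinity": DepthProfile(sid, "salinity", z, sal),
        "turbidity": DepthProfile(sid, "turbidity", z, turb),
        "fluorescence": DepthProfile(sid, "fluorescence", z, fluor),
        "par": DepthProfile(sid, "par", z, par),
    }

    bundle = StationBundle(
        record=StationRecord(
            station_id=sid, region=region, regime=regime,
            turbidity_change_depth=scenario.change_depth,
            mean_turbidity_50m=float(turb[z <= 50.0].mean()),
            bottom_depth=float(bottom_depth), date=_date(2019, 7, 27),
            local_time=_time(12, 0), latitude=78.0, longitude=15.0,
        ),
        profiles=profiles, scenario=scenario,
    )
    if "particles" in components:
        particles, vol = _particle_stream(rng, z, scenario, noise_free)
        bundle.particles = [ParticleRecord(sid, p.depth, p.esd,
                                           p.attenuance_index)
                            for p in particles]
        bundle.lopc_volumes = vol
    if "vignettes" in components:
        vignettes, uvol = _vignette_stream(rng, z, scenario)
        bundle.vignettes = [VignetteRecord(sid, v.depth, v.category)
                            for v in vignettes]
        bundle.uvp_volumes = uvol
    if "nets" in components:
        bundle.nets = _net_hauls(rng, scenario, noise_free)
    return bundle


def generate_survey(n_per_regime=(8, 8, 9), seed: int = 0,
                    bottom_depth: float | None = None,
                    null_zoo: bool = False,
                    components: tuple = ("profiles", "particles",
                                         "vignettes", "nets"),
                    ) -> list[StationBundle]:
    """Balanced survey of S/I/D stations with independent substreams.

    ``n_per_regime`` orders counts as (S, I, D).  ``null_zoo=True``
    decouples zooplankton from the regime (every station gets the
    surface-peaked law) for statistical calibration runs.
    """
    n_s, n_i, n_d = n_per_regime
    plan = ["S"] * n_s + ["I"] * n_i + ["D"] * n_d
    children = np.random.SeedSequence(seed).spawn(len(plan))
    bundles = []
    for k, (regime, child) in enumerate(zip(plan, children)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        b = generate_station(regime, bottom_depth, seed=sub_seed,
                             station_id=f"SYN-{regime}{k}",
                             components=components)
        if null_zoo and regime == "D":
            # regenerate zooplankton streams under the surface-peaked law
            null = generate_station("S", b.record.bottom_depth,
                                    seed=sub_seed, station_id=b.record.station_id,
                                    components=components)
            b.particles = null.particles
            b.lopc_volumes = null.lopc_volumes
            b.vignettes = null.vignettes
            b.uvp_volumes = null.uvp_volumes
            b.nets = null.nets
        bundles.append(b)
    return bundles


def write_bundles(bundles: list[StationBundle], out_dir: str | Path) -> None:
    """Write a survey to the CSV store schema station_io reads."""
    from .station_io import write_stations, write_profiles

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stations([b.record for b in bundles], out / "stations.csv")
    all_profiles = [p for b in bundles for p in b.profiles.values()]
    write_profiles(all_profiles, out / "profiles.csv")

    prt = [{"station_id": p.station_id, "depth_m": p.depth, "esd_mm": p.esd,
            "attenuance_index": p.attenuance_index}
           for b in bundles for p in b.particles]
    pd.DataFrame(prt, columns=["station_id", "depth_m", "esd_mm",
                               "attenuance_index"]).to_csv(
        out / "particles.csv", index=False)

    vols = []
    for b in bundles:
        if b.lopc_volumes is not None:
            for z, v in zip(b.depths, b.lopc_volumes):
                vols.append({"station_id": b.record.station_id,
                             "depth_m": z, "volume_m3": v})
    pd.DataFrame(vols, columns=["station_id", "depth_m", "volume_m3"]).to_csv(
        out / "volumes.csv", index=False)

    nets = [{"station_id": b.record.station_id, "layer": la.layer,
             "taxon_stage": la.taxon_or_stage,
             "abundance_ind_m3": la.abundance}
            for b in bundles for la in b.nets]
    pd.DataFrame(nets, columns=["station_id", "layer", "taxon_stage",
                                "abundance_ind_m3"]).to_csv(
        out / "nets.csv", index=False)

    for b in bundles:
        if b.scenario is not None:
            path = out / f"scenario_{b.record.station_id}.json"
            path.write_text(json.dumps(asdict(b.scenario), indent=1))
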