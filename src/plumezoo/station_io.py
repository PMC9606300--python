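"""Reading, writing and gridding of station data.

Raw CTD/optical casts arrive as irregular (depth, value) samples per
variable.  Everything downstream works on 1-m depth bins: the value of
bin [k, k+1) is the arithmetic mean of the samples falling in it, the
bin is addressed by its centre k + 0.5, and the top metre is discarded
to avoid wave action, stray light and bubble artefacts.  Empty bins
stay missing (NaN) — nothing is ever interpolated here.

Station metadata follow one schema (``STATIONS_COLUMNS``); a packaged
fixture carries the 25-station survey table that the rest of the
package uses as its reference metadata set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import date as _date, time as _time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "RawCast",
    "StationRecord",
    "NoDataBelowDiscardDepth",
    "bin_cast",
    "daytime_filter",
    "read_table1_fixture",
    "read_stations",
    "write_stations",
    "read_profiles",
    "write_profiles",
]

#: canonical column order for stations.csv
STATIONS_COLUMNS = [
    "station_id", "region", "regime", "turbidity_change_m",
    "mean_turbidity_ftu", "max_depth_m", "date", "local_time",
    "lat_dd", "lon_dd",
]

#: canonical column order for profiles.csv (long format)
PROFILES_COLUMNS = ["station_id", "variable", "depth_m", "value"]

REGIONS = ("ISF", "KGF", "TOR", "HOR")
REGIMES = ("S", "I", "D")

#: variables that are physically non-negative
NONNEGATIVE_VARIABLES = {"turbidity", "par", "fluorescence"}

#: depth above which samples are discarded before binning
DISCARD_DEPTH_M = 1.0

_TABLE1_SHA256 = "21145c45ea09c798635f46b2ad422f2e3f15f4e61914c3a8bb46c2f24c03664f"


class NoDataBelowDiscardDepth(ValueError):
    """Raised when a cast has no samples below the top-metre discard."""


@dataclass(frozen=True)
class StationRecord:
    """One row of the survey metadata table."""

    station_id: str
    region: str
    regime: str | None
    turbidity_change_depth: float
    mean_turbidity_50m: float
    bottom_depth: float
    date: _date
    local_time: _time
    latitude: float
    longitude: float
    daytime_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.regime is not None and self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.turbidity_change_depth < 0:
            raise ValueError("turbidity_change_depth must be >= 0")
        if self.bottom_depth <= 0:
            raise ValueError("bottom_depth must be > 0")
        if self.turbidity_change_depth > self.bottom_depth:
            raise ValueError("turbidity_change_depth exceeds bottom_depth")


@dataclass
class DepthProfile:
    """A single variable on the 1-m bin grid for one station.

    ``depths`` are strictly increasing bin centres (k + 0.5 for integer
    k >= 1 with the default discard); ``values`` may contain NaN for
    empty bins.
    """

    station_id: str
    variable: str
    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.shape != self.values.shape or self.depths.ndim != 1:
            raise ValueError("depths and values must be 1-d and equally long")
        if self.depths.size and np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.variable in NONNEGATIVE_VARIABLES:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and np.any(finite < 0):
                raise ValueError(f"{self.variable} values must be >= 0")

    def __len__(self) -> int:
        return int(self.depths.size)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def dropna(self) -> "DepthProfile":
        m = self.valid
        return DepthProfile(self.station_id, self.variable,
                            self.depths[m], self.values[m])


@dataclass
class RawCast:
    """Irregular samples per variable, as they come off the wire."""

    station_id: str
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add(self, variable: str, depths, values) -> None:
        d = np.asarray(depths, dtype=float)
        v = np.asarray(values, dtype=float)
        if d.shape != v.shape:
            raise ValueError("depths and values must align")
        self.samples[variable] = (d, v)


def bin_cast(raw: RawCast, bin_size: float = 1.0,
             discard_above: float = DISCARD_DEPTH_M) -> dict[str, DepthProfile]:
    """Average raw samples into regular depth bins, one profile per variable.

    Bins are half-open [k*bin_size, (k+1)*bin_size) and reported at
    their centres; samples shallower than ``discard_above`` are dropped
    first.  Bins with no samples inside the sampled depth span are NaN.
    """
    out: dict[str, DepthProfile] = {}
    for var, (d, v) in raw.samples.items():
        keep = np.isfinite(d) & np.isfinite(v) & (d >= discard_above)
        if not keep.any():
            raise NoDataBelowDiscardDepth(
                f"{raw.station_id}/{var}: no data below discard depth "
                f"{discard_above} m")
        d, v = d[keep], v[keep]
        idx = np.floor(d / bin_size).astype(int)
        k0 = int(np.ceil(discard_above / bin_size))
        kmax = int(idx.max())
        sums = np.bincount(idx, weights=v, minlength=kmax + 1)[k0:]
        counts = np.bincount(idx, minlength=kmax + 1)[k0:]
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        centers = (np.arange(k0, kmax + 1) + 0.5) * bin_size
        out[var] = DepthProfile(raw.station_id, var, centers, means)
    return out


def daytime_filter(
    stations: list[StationRecord],
    window: tuple[_time, _time] = (_time(6, 0), _time(19, 0)),
) -> tuple[list[StationRecord], list[StationRecord]]:
    """Flag stations sampled outside the daytime window.

    Nothing is dropped: every record is returned in ``kept`` with its
    ``daytime_flag`` set, and records outside the closed window are also
    listed in ``flagged`` (mirroring the survey table's asterisks).
    """
    lo, hi = window
    kept: list[StationRecord] = []
    flagged: list[StationRecord] = []
    for rec in stations:
        inside = lo <= rec.local_time <= hi
        rec = replace(rec, daytime_flag=inside)
        kept.append(rec)
        if not inside:
            flagged.append(rec)
    return kept, flagged


def _records_from_frame(df: pd.DataFrame) -> list[StationRecord]:
    recs = []
    for row in df.itertuples(index=False):
        try:
            t = _time.fromisoformat(str(row.local_time))
        except ValueError as exc:
            raise ValueError(
                f"station {row.station_id}: unparseable local_time "
                f"{row.local_time!r}") from exc
        regime = None if pd.isna(row.regime) or row.regime == "" else str(row.regime)
        recs.append(StationRecord(
            station_id=str(row.station_id),
            region=str(row.region),
            regime=regime,
            turbidity_change_depth=float(row.turbidity_change_m),
            mean_turbidity_50m=float(row.mean_turbidity_ftu),
            bottom_depth=float(row.max_depth_m),
            date=_date.fromisoformat(str(row.date)),
            local_time=t,
            latitude=float(row.lat_dd),
            longitude=float(row.lon_dd),
        ))
    return recs


def read_stations(path: str | Path) -> list[StationRecord]:
    """Read a stations.csv into StationRecords."""
    df = pd.read_csv(path, dtype={"station_id": str, "regime": str})
    missing = set(STATIONS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stations table missing columns: {sorted(missing)}")
    return _records_from_frame(df)


def write_stations(records: list[StationRecord], path: str | Path) -> None:
    rows = [{
        "station_id": r.station_id,
        "region": r.region,
        "regime": "" if r.regime is None else r.regime,
        "turbidity_change_m": r.turbidity_change_depth,
        "mean_turbidity_ftu": r.mean_turbidity_50m,
        "max_depth_m": r.bottom_depth,
        "date": r.date.isoformat(),
        "local_time": r.local_time.strftime("%H:%M"),
        "lat_dd": r.latitude,
        "lon_dd": r.longitude,
    } for r in records]
    pd.DataFrame(rows, columns=STATIONS_COLUMNS).to_csv(path, index=False)


def read_table1_fixture(verify: bool = True) -> list[StationRecord]:
    """Load the packaged 25-station survey metadata table.

    With ``verify=True`` the file's SHA-256 is checked against the value
    recorded at packaging time, so silent fixture corruption fails loudly.
    """
    ref = resources.files("plumezoo.data").joinpath("table1_stations.csv")
    raw = ref.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise ValueError(
                f"station fixture checksum mismatch ({digest[:12]}...)")
    from io import BytesIO
    df = pd.read_csv(BytesIO(raw), dtype={"station_id": str, "regime": str})
    return _records_from_frame(df)


def read_profiles(path: str | Path) -> dict[tuple[str, str], DepthProfile]:
    """Read a long-format profiles.csv keyed by (station_id, variable)."""
    df = pd.read_csv(path, dtype={"station_id": str})
    out: dict[tuple[str, str], DepthProfile] = {}
    for (sid, var), g in df.groupby(["station_id", "variable"], sort=False):
        g = g.sort_values("depth_m")
        out[(sid, var)] = DepthProfile(sid, var, g["depth_m"].to_numpy(),
                                       g["value"].to_numpy())
    return out


def write_profiles(profiles, path: str | Path) -> None:
    """Write DepthProfiles (iterable or keyed dict) to long-format CSV."""
    if isinstance(profiles, dict):
        profiles = profiles.values()
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "station_id": p.station_id,
            "variable": p.variable,
            "depth_m": p.depths,
            "value": p.values,
        }))
    pd.concat(frames, ignore_index=True)[PROFILES_COLUMNS].to_csv(path, index=False)
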