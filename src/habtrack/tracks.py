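"""Track containers, cleaning and per-individual migration metrics.

Light-level geolocators give about two fixes per day with large positional
error, and latitude is unreliable for 2-4 weeks around each equinox.  This
module holds the track container used throughout the package, the equinox
filter, the seasonal split (summer = mid-September to mid-May, winter =
mid-May to mid-September) and the migration summary statistics (departure and
return dates, cumulative distance, maximum range, circumpolar status, mean
position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM, normalize_lon

TRACK_COLUMNS = ["datetime", "lon", "lat"]

#: season boundaries: winter is the closed interval [May 16, Sep 15]
WINTER_START = (5, 16)
WINTER_END = (9, 15)

#: equinox anchor dates (month, day)
EQUINOXES = ((3, 20), (9, 22))


@dataclass
class Track:
    """Time-ordered fixes for one individual plus group labels.

    ``data`` has columns datetime (UTC), lon, lat and optionally lon_true,
    lat_true (noise-free simulator truth).  Timestamps are strictly
    increasing; longitudes normalized to (-180, 180].
    """

    individual_id: str
    data: pd.DataFrame
    population: str | None = None
    sex: str | None = None
    outcome: str | None = None
    colony: tuple[float, float] | None = None  # (lon, lat)
    equinox_longitudes: pd.DataFrame | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track data missing columns {missing}")
        df["datetime"] = pd.to_datetime(df["datetime"])
        if not df["datetime"].is_monotonic_increasing or df["datetime"].duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        for col in ("lon", "lon_true"):
            if col in df.columns:
                df[col] = normalize_lon(df[col].to_numpy())
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def lonlat(self) -> np.ndarray:
        return self.data[["lon", "lat"]].to_numpy()

    def with_data(self, data: pd.DataFrame) -> "Track":
        return replace(self, data=data)


def great_circle_km(a, b) -> np.ndarray | float:
    """Haversine great-circle distance in km on a sphere of radius 6371 km.

    ``a`` and ``b`` are (lon, lat) pairs in degrees, or arrays of shape (..., 2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lat_a, lat_b = a[..., 1], b[..., 1]
    if np.any(np.abs(lat_a) > 90) or np.any(np.abs(lat_b) > 90):
        raise ValueError("latitude outside [-90, 90]")
    lon_a, lon_b = np.radians(a[..., 0]), np.radians(b[..., 0])
    phi_a, phi_b = np.radians(lat_a), np.radians(lat_b)
    dphi = phi_b - phi_a
    dlam = lon_b - lon_a
    h = np.sin(dphi / 2) ** 2 + np.cos(phi_a) * np.cos(phi_b) * np.sin(dlam / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _in_window(dates: pd.Series, month: int, day: int, window_days: int) -> np.ndarray:
    """True where a date falls within +/- window_days of (month, day) in its own year."""
    out = np.zeros(len(dates), dtype=bool)
    years = dates.dt.year
    d = dates.dt.normalize()
    for yr in np.unique(years):
        anchor = pd.Timestamp(year=int(yr), month=month, day=day)
        out |= (d >= anchor - pd.Timedelta(days=window_days)) & (
            d <= anchor + pd.Timedelta(days=window_days)
        )
    return out


def filter_equinox(track: Track, window_days: int = 21) -> Track:
    """Drop fixes within +/- window_days of the March 20 / September 22 equinoxes.

    Latitude from light-level geolocation is unusable near the equinoxes; the
    longitudinal series of the removed fixes is retained on the returned track
    (``equinox_longitudes``) because departure/return phenology can still be
    derived from longitudinal movements.
    """
    if not (14 <= window_days <= 28):
        raise ValueError("window_days must be in [14, 28] (2 to 4 weeks)")
    dates = track.data["datetime"]
    mask = np.zeros(len(dates), dtype=bool)
    for month, day in EQUINOXES:
        mask |= _in_window(dates, month, day, window_days)
    removed = track.data.loc[mask, ["datetime", "lon"]].reset_index(drop=True)
    kept = track.data.loc[~mask].reset_index(drop=True)
    if kept.empty:
        warnings.warn(f"equinox filter removed every fix of {track.individual_id}")
    prior = track.equinox_longitudes
    longitudes = pd.concat([prior, removed], ignore_index=True) if prior is not None else removed
    return replace(track, data=kept, equinox_longitudes=longitudes)


def assign_season(when) -> str:
    """'winter' for dates in [May 16, Sep 15] (closed), else 'summer'.

    Summer (mid-September to mid-May) coincides with the breeding season;
    winter is the austral non-breeding core.
    """
    ts = pd.Timestamp(when)
    key = (ts.month, ts.day)
    return "winter" if WINTER_START <= key <= WINTER_END else "summer"


def assign_season_series(when: pd.Series) -> pd.Series:
    ts = pd.to_datetime(when)
    key = ts.dt.month * 100 + ts.dt.day
    lo = WINTER_START[0] * 100 + WINTER_START[1]
    hi = WINTER_END[0] * 100 + WINTER_END[1]
    return pd.Series(np.where((key >= lo) & (key <= hi), "winter", "summer"), index=ts.index)


def unwrap_longitudes(lon: np.ndarray) -> np.ndarray:
    """Cumulative longitude with per-step differences mapped to (-180, 180].

    Makes eastward/westward progress monotone across the dateline so that
    circumpolar trips (cumulative displacement crossing +/-360 deg) are
    detectable.
    """
    lon = np.asarray(lon, dtype=float)
    if lon.size == 0:
        return lon
    steps = normalize_lon(np.diff(lon))
    return lon[0] + np.concatenate([[0.0], np.cumsum(steps)])


def circular_mean_deg(lon: np.ndarray) -> float:
    lam = np.radians(np.asarray(lon, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(lam)), np.mean(np.cos(lam)))))


@dataclass
class MigrationSummary:
    individual_id: str
    departure_date: pd.Timestamp | None
    return_date: pd.Timestamp | None
    non_breeding_days: float | None
    cumulative_distance_km: float
    mean_distance_per_day_km: float
    maximum_range_km: float
    mean_longitude: float
    mean_latitude: float
    circumpolar: bool
    departed: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def migration_summary(
    track: Track,
    colony: tuple[float, float] | None = None,
    departure_threshold_km: float = 500.0,
    sustain_days: float = 2.0,
) -> MigrationSummary:
    """Per-individual migration metrics.

    Departure is the first fix whose colony displacement exceeds
    ``departure_threshold_km`` with every fix of the following ``sustain_days``
    also beyond it (the threshold exceeds 1.5x tag error, so noise alone will
    not trigger it); return is the symmetric scan from the end of the track.
    Circumpolar means the unwrapped longitudinal displacement crosses 360 deg.
    """
    colony = colony if colony is not None else track.colony
    if colony is None:
        raise ValueError("colony coordinates required")
    df = track.data
    span_days = (df["datetime"].iloc[-1] - df["datetime"].iloc[0]).total_seconds() / 86400.0
    if span_days < 14:
        raise ValueError("track shorter than 14 days")

    pts = df[["lon", "lat"]].to_numpy()
    disp = great_circle_km(pts, np.asarray(colony, dtype=float))
    step_km = great_circle_km(pts[:-1], pts[1:]) if len(pts) > 1 else np.array([])
    cumulative = float(np.sum(step_km))
    max_range = float(np.max(disp))

    times = df["datetime"].to_numpy()
    away = disp > departure_threshold_km
    departure = _first_sustained(times, away, sustain_days)
    ret = _first_sustained(times[::-1], away[::-1], sustain_days)
    departed = departure is not None and ret is not None

    lon_unwrapped = unwrap_longitudes(df["lon"].to_numpy())
    net = lon_unwrapped - lon_unwrapped[0]
    circumpolar = bool(np.max(net) >= 360.0 or np.min(net) <= -360.0)

    non_breeding = (
        (pd.Timestamp(ret) - pd.Timestamp(departure)).total_seconds() / 86400.0
        if departed
        else None
    )
    return MigrationSummary(
        individual_id=track.individual_id,
        departure_date=pd.Timestamp(departure) if departed else None,
        return_date=pd.Timestamp(ret) if departed else None,
        non_breeding_days=non_breeding,
        cumulative_distance_km=cumulative,
        mean_distance_per_day_km=cumulative / span_days if span_days > 0 else 0.0,
        maximum_range_km=max_range,
        mean_longitude=circular_mean_deg(df["lon"].to_numpy()),
        mean_latitude=float(np.mean(df["lat"].to_numpy())),
        circumpolar=circumpolar,
        departed=departed,
    )


def _first_sustained(times: np.ndarray, flag: np.ndarray, sustain_days: float):
    """First time t with flag True at t and at every sample within sustain_days after it."""
    horizon = np.timedelta64(int(sustain_days * 86400), "s")
    n = len(times)
    j = 0
    for i in range(n):
        if not flag[i]:
            continue
        j = max(j, i)
        lo = times[i]
        hi = lo + horizon if times[0] <= times[-1] else lo - horizon
        ok = True
        for k in range(i, n):
            inside = (times[k] <= hi) if times[0] <= times[-1] else (times[k] >= hi)
            if not inside:
                break
            if not flag[k]:
                ok = False
                break
        if ok:
            return times[i]
    return None


def summaries_frame(tracks, **kwargs) -> pd.DataFrame:
    """Migration summaries for a collection of tracks as one DataFrame."""
    return pd.DataFrame([migration_summary(t, **kwargs).to_dict() for t in tracks])
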