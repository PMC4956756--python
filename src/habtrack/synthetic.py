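"""Synthetic Southern-Ocean environments and habitat-biased geolocation tracks.

Every downstream stage of the package (utilization distributions, segregation
tests, pseudo-absence generation, habitat models, evaluation) is exercised on
data from this module, so the generator is first-class, seeded and tested.

It emulates the study system: weekly composites of oceanographic covariates on
an equal-area south-polar grid (SST with a poleward-cooling gradient, a
seasonal cycle and mesoscale noise; chlorophyll; sea-level anomaly; eddy
kinetic energy; wind; static bathymetry), a registry of sub-Antarctic breeding
colonies, and individual tracks produced by a habitat-biased correlated random
walk whose preference coefficients are known ground truth.  Positional error
of light-level geolocation (default sd 186 km, two fixes per day) is injected
directly on the true positions; light curves themselves are not simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import SpatialGrid, project, unproject
from .tracks import Track, great_circle_km

DYNAMIC_LAYERS = ("sst", "chl", "sla", "eke", "wind", "sst_std")
STATIC_LAYERS = ("depth", "depth_std")

#: the ten habitat/accessibility covariates of the use-availability design
HABITAT_COVARIATES = ["sst", "sst_std", "chl", "depth", "depth_std", "sla", "eke", "wind"]
DISTANCE_COVARIATES = ["dist_own", "dist_closest"]
ALL_COVARIATES = HABITAT_COVARIATES + DISTANCE_COVARIATES

#: reference (mean, sd) used to standardize covariates inside preference scores
COVARIATE_SCALE = {
    "sst": (6.0, 4.0),
    "sst_std": (0.6, 0.4),
    "chl": (-0.4, 0.35),  # log10 mg m^-3
    "depth": (-3800.0, 900.0),
    "depth_std": (250.0, 200.0),
    "sla": (0.0, 0.06),
    "eke": (250.0, 180.0),
    "wind": (9.0, 2.0),
    "dist_own": (2500.0, 1800.0),
    "dist_closest": (2500.0, 1500.0),
}


# ---------------------------------------------------------------------------
# colonies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColonyRegistry:
    """Breeding-colony registry: name, longitude, latitude (degrees)."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t["name"].duplicated().any():
            raise ValueError("colony names must be unique")
        if np.any(np.abs(t["lat"].to_numpy()) > 90):
            raise ValueError("colony latitude outside [-90, 90]")

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def lonlat(self) -> np.ndarray:
        return self.table[["lon", "lat"]].to_numpy()

    def position(self, name: str) -> tuple[float, float]:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown colony {name!r}")
        return float(row["lon"].iloc[0]), float(row["lat"].iloc[0])

    def distances_km(self, lonlat: np.ndarray) -> np.ndarray:
        """(n_points, n_colonies) great-circle distances."""
        pts = np.asarray(lonlat, dtype=float)[:, None, :]
        return great_circle_km(pts, self.lonlat[None, :, :])

    def dist_own_closest(self, lonlat: np.ndarray, own: str) -> tuple[np.ndarray, np.ndarray]:
        """Distance to the own colony and minimum distance to any other colony."""
        d = self.distances_km(np.atleast_2d(lonlat))
        i = self.names.index(own)
        others = np.delete(d, i, axis=1)
        return d[:, i], others.min(axis=1)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def default_colonies() -> ColonyRegistry:
    """Seven major sub-Antarctic colony groups (approximate positions)."""
    rows = [
        ("south_georgia", -38.05, -54.0),
        ("diego_ramirez", -68.7, -56.5),
        ("marion", 37.75, -46.9),
        ("crozet", 51.8, -46.4),
        ("kerguelen", 70.2, -49.3),
        ("macquarie", 158.9, -54.5),
        ("campbell", 169.2, -52.5),
    ]
    return ColonyRegistry(pd.DataFrame(rows, columns=["name", "lon", "lat"]))


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvironmentConfig:
    """Tunable structure of the synthetic ocean.

    SST follows a linear poleward-cooling trend (``sst_edge`` at 30 S, minus
    ``sst_lapse`` per degree southward) plus a seasonal cycle and AR(1)-evolving
    smooth mesoscale noise.  All noise fields share ``noise_corr_km``.
    """

    sst_edge: float = 16.0  # deg C at 30 S
    sst_lapse: float = 0.35  # deg C per deg latitude
    sst_seasonal_amp: float = 1.5  # deg C
    sst_noise_sd: float = 1.0  # deg C
    chl_log10_mean: float = -0.5
    chl_log10_sd: float = 0.35
    sla_sd: float = 0.06  # m
    eke_scale: float = 250.0  # cm^2 s^-2
    wind_mean: float = 9.0  # m s^-1
    wind_sd: float = 2.0
    depth_relief: float = 2600.0  # m, amplitude of ridge systems
    noise_corr_km: float = 500.0
    week_persistence: float = 0.9
    antarctica_lat: float = -78.0
    north_edge_lat: float = -30.0
    peak_week: int = 5  # week of warmest SST (austral summer)


@dataclass
class EnvironmentGrid:
    """Weekly covariate composites plus static bathymetry on an equal-area grid."""

    grid: SpatialGrid
    weeks: int
    start_date: pd.Timestamp
    dynamic: dict[str, np.ndarray]  # name -> (weeks, n, n)
    static: dict[str, np.ndarray]  # name -> (n, n)
    land_mask: np.ndarray  # (n, n) bool, True on land / outside domain

    def week_index(self, when) -> np.ndarray:
        """Integer week slice for timestamps (0-based from start_date)."""
        ts = pd.to_datetime(pd.Series(np.atleast_1d(when)))
        return ((ts - self.start_date).dt.total_seconds() // (7 * 86400)).to_numpy(int)

    def layer(self, name: str, week: int | None = None) -> np.ndarray:
        if name in self.static:
            return self.static[name]
        if week is None:
            raise ValueError(f"dynamic layer {name!r} needs a week")
        return self.dynamic[name][week]

    def value_at(self, name: str, week, iy, ix) -> np.ndarray:
        """Layer values at cell indices; NaN outside the grid."""
        iy = np.asarray(iy)
        ix = np.asarray(ix)
        n = self.grid.n
        ok = (iy >= 0) & (iy < n) & (ix >= 0) & (ix < n)
        out = np.full(iy.shape, np.nan)
        if name in self.static:
            out[ok] = self.static[name][iy[ok], ix[ok]]
        else:
            w = np.broadcast_to(np.asarray(week), iy.shape)
            okw = ok & (w >= 0) & (w < self.weeks)
            out[okw] = self.dynamic[name][w[okw], iy[okw], ix[okw]]
        return out

    def is_land(self, x, y) -> np.ndarray:
        """Land / out-of-domain test for projected points."""
        iy, ix = self.grid.cell_index(x, y)
        n = self.grid.n
        inside = (iy >= 0) & (iy < n) & (ix >= 0) & (ix < n)
        out = np.ones(np.shape(iy), dtype=bool)
        out[inside] = self.land_mask[iy[inside], ix[inside]]
        return out

    def seasonal_median(self, name: str, weeks: list[int]) -> np.ndarray:
        """Per-cell median of a dynamic layer over a set of week slices."""
        if name in self.static:
            return self.static[name]
        return np.nanmedian(self.dynamic[name][weeks], axis=0)

    def to_dataset(self):
        import xarray as xr

        c = self.grid.coords_km
        data = {}
        for name, arr in self.dynamic.items():
            data[name] = (("week", "y", "x"), arr)
        for name, arr in self.static.items():
            data[name] = (("y", "x"), arr)
        data["land_mask"] = (("y", "x"), self.land_mask.astype("i1"))
        return xr.Dataset(
            data,
            coords={"week": np.arange(self.weeks), "y": c, "x": c},
            attrs={
                "cell_km": self.grid.cell_km,
                "half_extent_km": self.grid.half_extent_km,
                "start_date": str(self.start_date.date()),
                "projection": "south-polar Lambert azimuthal equal-area, R=6371 km",
            },
        )

    def to_netcdf(self, path):
        self.to_dataset().to_netcdf(path, engine="scipy")


def focal_std(arr: np.ndarray, size: int = 3) -> np.ndarray:
    """3x3 focal (moving-window) standard deviation, NaN-aware.

    Cells with no finite neighbours return NaN; output is clipped at 0 to
    absorb negative round-off in E[x^2] - E[x]^2.
    """
    from scipy.ndimage import uniform_filter

    a = np.asarray(arr, dtype=float)
    mask = np.isfinite(a)
    filled = np.where(mask, a, 0.0)
    cnt = uniform_filter(mask.astype(float), size=size, mode="constant")
    s1 = uniform_filter(filled, size=size, mode="constant")
    s2 = uniform_filter(filled**2, size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = s1 / cnt
        m2 = s2 / cnt
        var = np.clip(m2 - m1**2, 0.0, None)
        out = np.sqrt(var)
    out[cnt <= 0] = np.nan
    return out


def _smooth_unit_field(rng: np.random.Generator, n: int, sigma_cells: float) -> np.ndarray:
    """Smooth random field rescaled to unit standard deviation."""
    f = gaussian_filter(rng.standard_normal((n, n)), sigma=sigma_cells, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_environment(
    seed: int,
    weeks: int,
    grid: SpatialGrid | None = None,
    config: EnvironmentConfig | None = None,
    colonies: ColonyRegistry | None = None,
    start_date: str | pd.Timestamp = "2002-09-16",
) -> EnvironmentGrid:
    """Generate a seeded synthetic Southern-Ocean environment.

    The grid must be polar: it has to cover all longitudes down from
    ``config.north_edge_lat``.  SST carries a strictly monotone
    poleward-cooling latitudinal trend, so its spatial mean at 60 S is colder
    than at 40 S in every week by construction.  Chlorophyll is strictly
    positive (log-normal).  Identical seeds reproduce identical fields.
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    cfg = config or EnvironmentConfig()
    grid = grid or SpatialGrid(cell_km=100.0, half_extent_km=6500.0)
    if grid.min_covered_latitude() < cfg.north_edge_lat:
        raise ValueError(
            "grid is not polar: it must cover all longitudes south of "
            f"{cfg.north_edge_lat} deg (inscribed-circle latitude is "
            f"{grid.min_covered_latitude():.1f})"
        )
    colonies = colonies or default_colonies()
    rng = np.random.default_rng(seed)
    n = grid.n
    lon, lat = grid.cell_centers_lonlat()
    sigma_cells = max(cfg.noise_corr_km / grid.cell_km, 0.5)

    # land: everything north of the domain edge, the Antarctic continent, and
    # one cell per colony (so walkers have something to avoid)
    land = (lat > cfg.north_edge_lat) | (lat < cfg.antarctica_lat)
    cx, cy = project(colonies.lonlat[:, 0], colonies.lonlat[:, 1])
    ciy, cix = grid.cell_index(cx, cy)
    land[ciy, cix] = True
    ocean = ~land

    trend = cfg.sst_edge + cfg.sst_lapse * (lat - cfg.north_edge_lat)  # cools southward

    def ar1_stack(sd: float) -> np.ndarray:
        """(weeks, n, n) AR(1)-in-time smooth noise with marginal sd."""
        out = np.empty((weeks, n, n))
        f = _smooth_unit_field(rng, n, sigma_cells)
        a = cfg.week_persistence
        for w in range(weeks):
            if w > 0:
                f = a * f + np.sqrt(1 - a**2) * _smooth_unit_field(rng, n, sigma_cells)
            out[w] = sd * f
        return out

    week_idx = np.arange(weeks)
    seasonal = cfg.sst_seasonal_amp * np.cos(2 * np.pi * (week_idx - cfg.peak_week) / 52.0)
    sst = trend[None] + seasonal[:, None, None] + ar1_stack(cfg.sst_noise_sd)

    # chlorophyll: log-normal around a mid-latitude productivity band
    band = 0.25 * np.exp(-((lat + 50.0) ** 2) / (2 * 8.0**2))
    chl = 10 ** (cfg.chl_log10_mean + band[None] + ar1_stack(cfg.chl_log10_sd))

    sla = ar1_stack(cfg.sla_sd)
    eke = cfg.eke_scale * ar1_stack(1.0) ** 2
    wind = np.clip(cfg.wind_mean + ar1_stack(cfg.wind_sd), 0.0, None)

    # static bathymetry: abyssal plain plus smooth ridge systems
    ridge = np.abs(_smooth_unit_field(rng, n, sigma_cells))
    depth = np.clip(-4800.0 + cfg.depth_relief * ridge, None, -50.0)

    dynamic = {"sst": sst, "chl": chl, "sla": sla, "eke": eke, "wind": wind}
    for name in dynamic:
        dynamic[name][:, land] = np.nan
    depth = depth.copy()
    depth[land] = np.nan

    dynamic["sst_std"] = np.stack([focal_std(sst[w]) for w in range(weeks)])
    static = {"depth": depth, "depth_std": focal_std(depth)}

    return EnvironmentGrid(
        grid=grid,
        weeks=weeks,
        start_date=pd.Timestamp(start_date),
        dynamic=dynamic,
        static=static,
        land_mask=land,
    )


# ---------------------------------------------------------------------------
# preference specification and biased walk
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreferenceSpec:
    """Ground-truth habitat preference driving the biased walk.

    ``weights`` are unitless log-weights applied to covariates standardized by
    :data:`COVARIATE_SCALE`; ``response_fns`` may supply arbitrary smooth
    log-weight curves on the raw covariate instead.  Colony terms:
    ``colony_attraction`` penalizes distance from the own colony (per 1000 km),
    ``colony_avoidance`` penalizes proximity to other colonies
    (avoidance * exp(-dist_closest / scale); the default 1000 km scale makes
    walkers keep roughly 800-1200 km clear of foreign colonies).
    """

    weights: dict[str, float] = field(default_factory=dict)
    response_fns: dict[str, Callable] = field(default_factory=dict)
    colony_attraction: float = 0.0
    colony_avoidance: float = 0.0
    colony_avoidance_scale_km: float = 1000.0
    noise_sd_km: float = 186.0
    fixes_per_day: int = 2
    step_mean_km: float = 190.0
    step_shape: float = 2.0
    turn_sd_rad: float = 0.8
    n_candidates: int = 10
    max_retries: int = 20

    def __post_init__(self):
        if self.noise_sd_km < 0:
            raise ValueError("noise_sd_km must be >= 0")
        for name in list(self.weights) + list(self.response_fns):
            if name not in ALL_COVARIATES:
                raise KeyError(f"unknown covariate {name!r}")

    def score(
        self,
        env: EnvironmentGrid,
        colonies: ColonyRegistry,
        own: str,
        week: int,
        x: np.ndarray,
        y: np.ndarray,
    ) -> np.ndarray:
        """Preference log-weight at candidate endpoints (projected km)."""
        iy, ix = env.grid.cell_index(x, y)
        total = np.zeros(np.shape(x), dtype=float)
        names = set(self.weights) | set(self.response_fns)
        week = int(np.clip(week, 0, env.weeks - 1))
        lon, lat = unproject(x, y)
        pts = np.column_stack([lon, lat])
        d_own, d_closest = colonies.dist_own_closest(pts, own)
        for name in names:
            if name == "dist_own":
                val = d_own
            elif name == "dist_closest":
                val = d_closest
            else:
                val = env.value_at(name, week, iy, ix)
                if name == "chl":
                    val = np.log10(val)
            if name in self.response_fns:
                total = total + self.response_fns[name](val)
            if name in self.weights and self.weights[name] != 0.0:
                m, s = COVARIATE_SCALE[name]
                total = total + self.weights[name] * (val - m) / s
        if self.colony_attraction:
            total = total - self.colony_attraction * d_own / 1000.0
        if self.colony_avoidance:
            total = total - self.colony_avoidance * np.exp(
                -d_closest / self.colony_avoidance_scale_km
            )
        return np.where(np.isfinite(total), total, -np.inf)


def simulate_tracks(
    env: EnvironmentGrid,
    colonies: ColonyRegistry,
    pref: PreferenceSpec,
    n_individuals: int,
    duration_days: int,
    seed: int,
    population: str = "A",
    own_colony: str | None = None,
    start_date: str | pd.Timestamp | None = None,
    id_prefix: str | None = None,
) -> list[Track]:
    """Habitat-biased correlated random walks with geolocation-style noise.

    Each individual starts at its own colony.  At every step ``n_candidates``
    endpoints are drawn from the gamma step-length / wrapped-normal
    turning-angle kernel; candidates on land are rejected and redrawn, and one
    of the valid endpoints is selected with probability proportional to
    exp(preference score).  If every candidate is on land after
    ``max_retries`` redraws the step is widened once (doubled mean length);
    persistent trapping is recorded per individual (``meta['n_trapped']``),
    never raised.  True positions are retained alongside noisy positions
    (isotropic Gaussian error, sd ``noise_sd_km``, in the projected plane).
    """
    if duration_days < 14:
        raise ValueError("duration_days must be >= 14")
    own = own_colony or colonies.names[0]
    start = pd.Timestamp(start_date) if start_date is not None else env.start_date
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else population

    lon0, lat0 = colonies.position(own)
    x0, y0 = project(lon0, lat0)
    n_steps = duration_days * pref.fixes_per_day
    dt = pd.Timedelta(hours=24 / pref.fixes_per_day)
    times = pd.date_range(start, periods=n_steps, freq=dt)
    scale = pref.step_mean_km / pref.step_shape
    K = pref.n_candidates

    tracks: list[Track] = []
    for i in range(n_individuals):
        xs = np.empty(n_steps)
        ys = np.empty(n_steps)
        x, y = x0, y0
        heading = rng.uniform(-np.pi, np.pi)
        n_trapped = 0
        weeks_of = ((times - start).total_seconds() // (7 * 86400)).astype(int)
        for t in range(n_steps):
            chosen = None
            widen = 1.0
            for attempt in range(pref.max_retries + 2):
                if attempt == pref.max_retries + 1:
                    widen = 2.0  # widen the kernel once before giving up
                steps = rng.gamma(pref.step_shape, scale * widen, size=K)
                turns = rng.normal(0.0, pref.turn_sd_rad, size=K)
                head = heading + turns
                cx = x + steps * np.sin(head)
                cy = y + steps * np.cos(head)
                valid = ~env.is_land(cx, cy)
                if valid.any():
                    s = pref.score(env, colonies, own, weeks_of[t], cx[valid], cy[valid])
                    s = s - np.max(s)
                    w = np.exp(s)
                    tot = w.sum()
                    p = w / tot if tot > 0 else np.full(w.size, 1.0 / w.size)
                    j = rng.choice(np.flatnonzero(valid), p=p)
                    chosen = (cx[j], cy[j], float(head[j]))
                    break
            if chosen is None:
                n_trapped += 1
                heading = rng.uniform(-np.pi, np.pi)
            else:
                x, y, heading = chosen
            xs[t], ys[t] = x, y
        noise = rng.normal(0.0, pref.noise_sd_km, size=(n_steps, 2)) if pref.noise_sd_km > 0 else 0.0
        nx = xs + (noise[:, 0] if pref.noise_sd_km > 0 else 0.0)
        ny = ys + (noise[:, 1] if pref.noise_sd_km > 0 else 0.0)
        lon_t, lat_t = unproject(xs, ys)
        lon_n, lat_n = unproject(nx, ny)
        data = pd.DataFrame(
            {
                "datetime": times,
                "lon": lon_n,
                "lat": lat_n,
                "lon_true": lon_t,
                "lat_true": lat_t,
            }
        )
        tracks.append(
            Track(
                individual_id=f"{prefix}{i:03d}",
                data=data,
                population=population,
                colony=(lon0, lat0),
                meta={"n_trapped": n_trapped, "own_colony": own, "seed": seed},
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# group labels
# ---------------------------------------------------------------------------

SEX_LEVELS = {"female", "male"}
OUTCOME_LEVELS = {"successful", "failed"}


def make_grouping_plan(
    individual_ids: list[str],
    population: str | dict[str, str] = "A",
    sex_split: float = 0.5,
    failed_fraction: float = 0.0,
    failed_duration_days: int = 277,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic grouping plan: alternating sexes, first-k failed outcomes."""
    ids = list(individual_ids)
    n = len(ids)
    n_f = int(round(sex_split * n))
    sex = ["female"] * n_f + ["male"] * (n - n_f)
    n_fail = int(round(failed_fraction * n))
    outcome = ["failed"] * n_fail + ["successful"] * (n - n_fail)
    rng = np.random.default_rng(seed)
    rng.shuffle(sex)
    rng.shuffle(outcome)
    pop = [population[i] if isinstance(population, dict) else population for i in ids]
    return pd.DataFrame(
        {
            "individual_id": ids,
            "population": pop,
            "sex": sex,
            "outcome": outcome,
            "failed_duration_days": failed_duration_days,
        }
    )


def apply_group_labels(tracks: list[Track], plan: pd.DataFrame) -> list[Track]:
    """Attach population/sex/outcome labels; truncate failed birds' tracks.

    A "failed" outcome truncates the track to its first ``failed_duration_days``
    days (default 277), mimicking birds that abandon breeding mid-season and
    are tracked for a shorter subsequent period.
    """
    plan = plan.set_index("individual_id")
    missing = [t.individual_id for t in tracks if t.individual_id not in plan.index]
    if missing:
        raise ValueError(f"grouping plan does not cover individuals {missing}")
    bad_sex = set(plan["sex"]) - SEX_LEVELS
    bad_out = set(plan["outcome"]) - OUTCOME_LEVELS
    if bad_sex or bad_out:
        raise ValueError(f"unknown levels: sex={bad_sex or '{}'} outcome={bad_out or '{}'}")
    out = []
    for t in tracks:
        row = plan.loc[t.individual_id]
        data = t.data
        if row["outcome"] == "failed":
            limit = data["datetime"].iloc[0] + pd.Timedelta(days=float(row["failed_duration_days"]))
            data = data[data["datetime"] < limit].reset_index(drop=True)
            if data.empty:
                warnings.warn(f"failure truncation emptied track {t.individual_id}")
        out.append(
            Track(
                individual_id=t.individual_id,
                data=data,
                population=str(row["population"]),
                sex=str(row["sex"]),
                outcome=str(row["outcome"]),
                colony=t.colony,
                meta=dict(t.meta),
            )
        )
    return out


# ---------------------------------------------------------------------------
# record-level use-availability truth (for model calibration tests)
# ---------------------------------------------------------------------------

_SAMPLERS = {
    "sst": lambda r, n: r.normal(6.0, 4.0, n),
    "sst_std": lambda r, n: np.abs(r.normal(0.6, 0.4, n)),
    "chl": lambda r, n: r.normal(-0.4, 0.35, n),
    "depth": lambda r, n: -np.abs(r.normal(3800.0, 900.0, n)),
    "depth_std": lambda r, n: np.abs(r.normal(250.0, 200.0, n)),
    "sla": lambda r, n: r.normal(0.0, 0.06, n),
    "eke": lambda r, n: r.gamma(2.0, 125.0, n),
    "wind": lambda r, n: np.clip(r.normal(9.0, 2.0, n), 0.0, None),
    "dist_own": lambda r, n: r.gamma(2.0, 1250.0, n),
    "dist_closest": lambda r, n: r.gamma(2.0, 1250.0, n),
}


def make_use_availability(
    n_individuals: int = 10,
    records_per_individual: int = 200,
    weeks: int = 20,
    weights: dict[str, float] | None = None,
    response_fns: dict[str, Callable] | None = None,
    intercept: float = 0.0,
    covariates: list[str] | None = None,
    group_factor: str | None = None,
    group_levels: tuple[str, str] = ("female", "male"),
    group_weights: tuple[dict, dict] | None = None,
    years: tuple | None = None,
    year_shifts: tuple | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Record-level use-availability dataset with a known logistic truth.

    Covariates are drawn independently from realistic marginal distributions;
    the response is Bernoulli with logit equal to ``intercept`` plus weighted
    standardized covariates (per-group weights when ``group_weights`` is
    given, plus optional per-year intercept shifts).  This bypasses movement
    simulation entirely and is the right tool for calibrating the model and
    evaluation machinery at known effect sizes.
    """
    rng = np.random.default_rng(seed)
    covariates = covariates or ALL_COVARIATES
    weights = weights or {}
    response_fns = response_fns or {}
    n = n_individuals * records_per_individual
    data = {c: _SAMPLERS[c](rng, n) for c in covariates}
    df = pd.DataFrame(data)
    df["individual_id"] = np.repeat([f"ind{i:03d}" for i in range(n_individuals)], records_per_individual)
    df["week"] = rng.integers(0, weeks, n)
    if group_factor:
        per_ind = np.array([group_levels[i % 2] for i in range(n_individuals)])
        df[group_factor] = np.repeat(per_ind, records_per_individual)
    if years is not None:
        per_ind_year = np.array([years[i % len(years)] for i in range(n_individuals)])
        df["year"] = np.repeat(per_ind_year, records_per_individual)

    eta = np.full(n, float(intercept))
    def add_weights(mask: np.ndarray, w: dict, fns: dict):
        for name, coef in w.items():
            m, s = COVARIATE_SCALE[name]
            eta[mask] += coef * (df.loc[mask, name].to_numpy() - m) / s
        for name, fn in fns.items():
            eta[mask] += fn(df.loc[mask, name].to_numpy())

    if group_factor and group_weights is not None:
        for lvl, w in zip(group_levels, group_weights):
            add_weights((df[group_factor] == lvl).to_numpy(), w, response_fns)
    else:
        add_weights(np.ones(n, dtype=bool), weights, response_fns)
    if years is not None and year_shifts is not None:
        for yr, shift in zip(years, year_shifts):
            eta[(df["year"] == yr).to_numpy()] += shift

    p = 1.0 / (1.0 + np.exp(-eta))
    df["response"] = rng.binomial(1, p)
    return df
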