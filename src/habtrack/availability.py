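"""Pseudo-absence generation and covariate sampling for the use-availability design.

Habitat preference is inferred by contrasting where an animal went (observed
fixes, response 1) with where it could have gone (simulated fixes, response
0).  Availability is defined by the animal's own movement capacity: for each
observed track we extract its empirical step-length and turning-angle
samples and generate correlated random walks (CRW) from the same start point
by jointly resampling (step, turn) pairs — joint resampling preserves the
speed-tortuosity correlation of the parent track.  Pseudo-tracks copy the
parent's timestamps, so observed and simulated locations are matched in time,
and land landings are redrawn.

Both observed and simulated fixes are then annotated with the ten covariates:
SST, SST gradient (3x3 focal sd), log10 chlorophyll, depth, depth gradient,
sea-level anomaly, eddy kinetic energy, wind, and the two accessibility /
competition proxies — great-circle distance to the own colony and to the
closest other colony.  Dynamic layers are sampled from the nearest weekly
composite within +/- 1 week.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import unproject, project
from .synthetic import ALL_COVARIATES, ColonyRegistry, EnvironmentGrid
from .tracks import Track, assign_season_series

NOMINAL_INTERVAL_H = 12.0


@dataclass
class MovementKernel:
    """Empirical per-fix movement samples of one track."""

    individual_id: str
    step_km: np.ndarray  # (m,)
    turn_rad: np.ndarray  # (m,), in (-pi, pi]
    start_xy: tuple[float, float]
    timestamps: pd.Series
    interpolated: bool = False


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return np.where(out == -np.pi, np.pi, out)


def fit_movement_kernel(track: Track, interval_tol: float = 0.25) -> MovementKernel:
    """Empirical step-length and turning-angle samples from a track.

    Steps and headings are computed on projected coordinates.  If fix
    intervals deviate from the nominal 12 h cadence by more than
    ``interval_tol`` (fractional), positions are linearly interpolated onto
    the nominal cadence first, with a warning.
    """
    if len(track) < 10:
        raise ValueError("need at least 10 fixes to fit a movement kernel")
    t = track.data["datetime"]
    x, y = project(track.data["lon"].to_numpy(), track.data["lat"].to_numpy())
    dt_h = np.diff(t.to_numpy()).astype("timedelta64[s]").astype(float) / 3600.0
    interpolated = False
    if np.any(np.abs(dt_h - NOMINAL_INTERVAL_H) > interval_tol * NOMINAL_INTERVAL_H):
        warnings.warn(
            f"irregular fix intervals on {track.individual_id}; interpolating to "
            f"{NOMINAL_INTERVAL_H:g} h cadence"
        )
        sec = (t - t.iloc[0]).dt.total_seconds().to_numpy()
        grid_sec = np.arange(0.0, sec[-1] + 1.0, NOMINAL_INTERVAL_H * 3600.0)
        x = np.interp(grid_sec, sec, x)
        y = np.interp(grid_sec, sec, y)
        t = pd.Series(t.iloc[0] + pd.to_timedelta(grid_sec, unit="s"))
        interpolated = True
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy)
    headings = np.arctan2(dx, dy)
    turns = _wrap_angle(np.diff(headings))
    return MovementKernel(
        individual_id=track.individual_id,
        step_km=steps,
        turn_rad=turns,
        start_xy=(float(x[0]), float(y[0])),
        timestamps=t.reset_index(drop=True),
        interpolated=interpolated,
    )


@dataclass
class PseudoTrack:
    parent_id: str
    sim_index: int
    data: pd.DataFrame  # datetime, lon, lat
    n_forced: int = 0  # steps accepted at nearest ocean cell after retry cap

    def __len__(self) -> int:
        return len(self.data)


def _nearest_ocean(env: EnvironmentGrid, x: float, y: float) -> tuple[float, float]:
    """Centre of the nearest ocean cell (ring search outward from the point)."""
    g = env.grid
    iy, ix = g.cell_index(np.array([x]), np.array([y]))
    iy, ix = int(np.clip(iy[0], 0, g.n - 1)), int(np.clip(ix[0], 0, g.n - 1))
    ocean = ~env.land_mask
    c = g.coords_km
    for r in range(0, g.n):
        y0, y1 = max(iy - r, 0), min(iy + r + 1, g.n)
        x0, x1 = max(ix - r, 0), min(ix + r + 1, g.n)
        sub = ocean[y0:y1, x0:x1]
        if sub.any():
            jy, jx = np.nonzero(sub)
            d2 = (c[y0 + jy] - y) ** 2 + (c[x0 + jx] - x) ** 2
            k = int(np.argmin(d2))
            return float(c[x0 + jx[k]]), float(c[y0 + jy[k]])
    raise RuntimeError("no ocean cell on grid")


def simulate_crw(
    track: Track,
    kernel: MovementKernel,
    n_sim: int,
    env: EnvironmentGrid,
    seed: int = 0,
    max_retries: int = 20,
) -> list[PseudoTrack]:
    """Correlated-random-walk pseudo-tracks matched to a parent track.

    Each simulation starts at the parent's first fix with a uniform random
    initial heading; successive displacements resample (step, turn) pairs
    jointly, with replacement, from the parent's empirical kernel.  Steps
    landing on land are redrawn up to ``max_retries`` times, then accepted at
    the nearest ocean cell (counted in ``n_forced``).  Timestamps are copied
    from the parent, so each pseudo-track has exactly as many fixes.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    times = kernel.timestamps
    T = len(times)
    # joint (step, turn) pairs: turn j follows step j+1, so they are drawn together
    m = len(kernel.turn_rad)
    if m < 1:
        raise ValueError("movement kernel has no (step, turn) pairs")
    out = []
    for s in range(n_sim):
        xs = np.empty(T)
        ys = np.empty(T)
        x, y = kernel.start_xy
        xs[0], ys[0] = x, y
        heading = rng.uniform(-np.pi, np.pi)
        n_forced = 0
        for t in range(1, T):
            placed = False
            for _ in range(max_retries):
                j = rng.integers(0, m)
                h = heading + kernel.turn_rad[j]
                cx = x + kernel.step_km[j + 1] * np.sin(h)
                cy = y + kernel.step_km[j + 1] * np.cos(h)
                if not env.is_land(np.array([cx]), np.array([cy]))[0]:
                    x, y, heading = cx, cy, h
                    placed = True
                    break
            if not placed:
                x, y = _nearest_ocean(env, cx, cy)
                heading = h
                n_forced += 1
            xs[t], ys[t] = x, y
        lon, lat = unproject(xs, ys)
        out.append(
            PseudoTrack(
                parent_id=track.individual_id,
                sim_index=s,
                data=pd.DataFrame({"datetime": times, "lon": lon, "lat": lat}),
                n_forced=n_forced,
            )
        )
    return out


def sample_covariates(
    fixes: pd.DataFrame,
    env: EnvironmentGrid,
    colonies: ColonyRegistry,
    own_colony: str,
    window_weeks: int = 1,
) -> pd.DataFrame:
    """Annotate fixes (datetime, lon, lat) with the ten-covariate vector.

    Dynamic layers use the fix's weekly composite, falling back to the
    nearest composite within ``window_weeks``; fixes with no composite in the
    window are dropped (count reported via a warning).  Chlorophyll is
    log10-transformed.  Records with any missing covariate (e.g. a noisy fix
    displaced onto land) are kept but flagged ``complete = False``.
    """
    df = fixes.reset_index(drop=True).copy()
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    x, y = project(lon, lat)
    iy, ix = env.grid.cell_index(x, y)
    weeks = env.week_index(df["datetime"])

    in_period = np.zeros(len(df), dtype=bool)
    week_used = weeks.copy()
    for off in sorted(range(-window_weeks, window_weeks + 1), key=abs):
        cand = weeks + off
        ok = ~in_period & (cand >= 0) & (cand < env.weeks)
        week_used[ok] = cand[ok]
        in_period |= ok
    n_drop = int((~in_period).sum())
    if n_drop:
        warnings.warn(f"{n_drop} fixes outside the environmental period dropped")
        df = df.loc[in_period].reset_index(drop=True)
        lon, lat, x, y = lon[in_period], lat[in_period], x[in_period], y[in_period]
        iy, ix, week_used = iy[in_period], ix[in_period], week_used[in_period]

    for name in ("sst", "sst_std", "sla", "eke", "wind"):
        df[name] = env.value_at(name, week_used, iy, ix)
    chl = env.value_at("chl", week_used, iy, ix)
    with np.errstate(invalid="ignore"):
        df["chl"] = np.log10(chl)
    df["depth"] = env.value_at("depth", 0, iy, ix)
    df["depth_std"] = env.value_at("depth_std", 0, iy, ix)
    pts = np.column_stack([lon, lat])
    d_own, d_closest = colonies.dist_own_closest(pts, own_colony)
    df["dist_own"] = d_own
    df["dist_closest"] = d_closest
    df["week"] = week_used
    df["season"] = assign_season_series(df["datetime"]).to_numpy()
    df["complete"] = np.isfinite(df[ALL_COVARIATES].to_numpy(float)).all(axis=1)
    return df


def build_use_availability(
    tracks: list[Track],
    env: EnvironmentGrid,
    colonies: ColonyRegistry,
    n_sim: int = 5,
    seed: int = 0,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Full matched use-availability table for a set of tracks.

    For each track: observed fixes get response 1; ``n_sim`` CRW pseudo-tracks
    get response 0.  Before missing-covariate drops the observed:simulated
    record ratio is exactly 1:n_sim per individual.
    """
    frames = []
    for i, track in enumerate(tracks):
        own = track.meta.get("own_colony") if track.meta else None
        if own is None:
            d = colonies.distances_km(np.atleast_2d(np.asarray(track.colony, float)))
            own = colonies.names[int(np.argmin(d[0]))]
        kernel = fit_movement_kernel(track)
        pseudo = simulate_crw(track, kernel, n_sim, env, seed=seed + 1000 * i)
        obs = sample_covariates(track.data[["datetime", "lon", "lat"]], env, colonies, own)
        obs["response"] = 1
        obs["sim_index"] = -1
        batch = [obs]
        for p in pseudo:
            sim = sample_covariates(p.data, env, colonies, own)
            sim["response"] = 0
            sim["sim_index"] = p.sim_index
            batch.append(sim)
        part = pd.concat(batch, ignore_index=True)
        part["individual_id"] = track.individual_id
        part["population"] = track.population
        part["sex"] = track.sex
        part["outcome"] = track.outcome
        frames.append(part)
    records = pd.concat(frames, ignore_index=True)
    if drop_incomplete:
        n_bad = int((~records["complete"]).sum())
        if n_bad:
            warnings.warn(f"dropping {n_bad} records with missing covariates")
        records = records.loc[records["complete"]].reset_index(drop=True)
    return records


def sensitivity_n_sim(
    tracks: list[Track],
    env: EnvironmentGrid,
    colonies: ColonyRegistry,
    covariates: list[str],
    n_sim_values: tuple[int, ...] = (1, 2, 5, 10, 20),
    seed: int = 0,
    **model_kwargs,
) -> pd.DataFrame:
    """Model-coefficient stability across pseudo-absence counts.

    Refits the habitat model at each ``n_sim`` and reports the fitted linear
    predictor's correlation with the largest-``n_sim`` fit on a common record
    set, plus AIC per fit.
    """
    from .model import SplineBinomialGAM

    fits = {}
    records_by_n = {}
    for n_sim in n_sim_values:
        rec = build_use_availability(tracks, env, colonies, n_sim=n_sim, seed=seed)
        m = SplineBinomialGAM(covariates=covariates, **model_kwargs).fit(
            rec[covariates], rec["response"].to_numpy()
        )
        fits[n_sim], records_by_n[n_sim] = m, rec
    ref_n = max(n_sim_values)
    ref_records = records_by_n[ref_n]
    ref_eta = fits[ref_n].decision_function(ref_records[covariates])
    rows = []
    for n_sim in n_sim_values:
        eta = fits[n_sim].decision_function(ref_records[covariates])
        rows.append(
            {
                "n_sim": n_sim,
                "aic": fits[n_sim].aic_,
                "linear_predictor_correlation": float(np.corrcoef(eta, ref_eta)[0, 1]),
                "n_records": len(records_by_n[n_sim]),
            }
        )
    return pd.DataFrame(rows)
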