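"""AUC-based model evaluation, transferability, driver comparison and maps.

AUC — the probability that a randomly drawn presence outscores a randomly
drawn pseudo-absence, ties counted half — is computed per ISO week (how well
does the seasonal model track each week?), per held-out individual
(leave-one-individual-out cross-validation, each individual a fold), and
across sites (a model trained on one population scored on the other's
records).  0.5-0.7 is poor, 0.7-0.9 reasonable, > 0.9 very good.

Driver decomposition refits the model with only habitat covariates and only
distance (accessibility/competition) covariates and compares weekly AUCs with
a paired Wilcoxon signed-rank test.  Suitability maps threshold predicted
probabilities at the ROC cut-off maximizing Youden's J (sensitivity -
false-positive rate), the standard reading of "highest sensitivity and lowest
proportion of false positives".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import roc_auc_score, roc_curve

from .model import SplineBinomialGAM
from .synthetic import ColonyRegistry, EnvironmentGrid
from .grid import unproject
from .tracks import great_circle_km


def auc(scores, labels) -> float:
    """Mann-Whitney AUC; raises if only one class is present."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def _safe_auc(scores, labels) -> float | None:
    try:
        return auc(scores, labels)
    except ValueError:
        return None


def weekly_auc(model: SplineBinomialGAM, records: pd.DataFrame, response_col: str = "response") -> pd.DataFrame:
    """One AUC per week of the records; single-class weeks are skipped."""
    rows = []
    scores = model.decision_function(records)
    for week, idx in records.groupby("week").indices.items():
        y = records[response_col].to_numpy()[idx]
        a = _safe_auc(scores[idx], y)
        rows.append(
            {
                "week": week,
                "auc": np.nan if a is None else a,
                "n_presence": int((y == 1).sum()),
                "n_absence": int((y == 0).sum()),
                "skipped": a is None,
            }
        )
    return pd.DataFrame(rows).sort_values("week").reset_index(drop=True)


def leave_one_individual_out(
    records: pd.DataFrame,
    covariates: list[str],
    response_col: str = "response",
    **model_kwargs,
) -> pd.DataFrame:
    """Leave-one-individual-out cross-validation: one refit + AUC per fold.

    The held-out fold contains the individual's observed fixes (presences)
    and its own simulated fixes (pseudo-absences), so individual differences
    are reflected in the performance spread.
    """
    ids = pd.unique(records["individual_id"])
    if len(ids) < 3:
        raise ValueError("leave-one-individual-out needs >= 3 individuals")
    rows = []
    for ind in ids:
        test = records["individual_id"] == ind
        train = records.loc[~test]
        held = records.loc[test]
        try:
            m = SplineBinomialGAM(covariates=covariates, **model_kwargs).fit(
                train, train[response_col].to_numpy()
            )
            ok = m.converged_
            a = _safe_auc(m.decision_function(held), held[response_col].to_numpy()) if ok else None
        except Exception:
            ok, a = False, None
        rows.append(
            {
                "individual_id": ind,
                "auc": np.nan if a is None else a,
                "n_presence": int((held[response_col] == 1).sum()),
                "n_absence": int((held[response_col] == 0).sum()),
                "converged": ok,
            }
        )
    return pd.DataFrame(rows)


def cross_site_transfer(
    model: SplineBinomialGAM, records_other: pd.DataFrame, response_col: str = "response"
) -> float:
    """Score a model trained on one population on another population's records.

    The other population's records must carry distance covariates computed
    relative to *its own* colony (as produced by ``build_use_availability``);
    transferability then asks whether habitat + accessibility preferences
    learned at one site predict use at the other.
    """
    missing = [c for c in (model.covariates or []) if c not in records_other.columns]
    if missing:
        raise ValueError(f"records missing covariates {missing}")
    return auc(model.decision_function(records_other), records_other[response_col].to_numpy())


@dataclass
class DriverComparison:
    weekly: pd.DataFrame  # week, auc_full, auc_habitat, auc_distance
    tests: pd.DataFrame  # pair, median_difference, wilcoxon_stat, pvalue
    descriptive_only: bool


def driver_comparison(
    records: pd.DataFrame,
    full_covariates: list[str],
    habitat_covariates: list[str],
    distance_covariates: list[str],
    response_col: str = "response",
    test_records: pd.DataFrame | None = None,
    **model_kwargs,
) -> DriverComparison:
    """Full vs habitat-only vs distance-only models, compared on weekly AUC.

    When ``test_records`` is given the three models are fitted on ``records``
    and the weekly AUCs computed on ``test_records`` (typically held-out
    individuals); this guards the comparison against models that merely
    memorize the spatial fingerprint of the training tracks.  With fewer than
    6 common weeks the paired Wilcoxon signed-rank tests are suppressed and
    the comparison is descriptive only.
    """
    y = records[response_col].to_numpy()
    evaluate_on = records if test_records is None else test_records
    fits = {
        "full": SplineBinomialGAM(covariates=full_covariates, **model_kwargs).fit(records, y),
        "habitat": SplineBinomialGAM(covariates=habitat_covariates, **model_kwargs).fit(records, y),
        "distance": SplineBinomialGAM(covariates=distance_covariates, **model_kwargs).fit(records, y),
    }
    weekly = None
    for name, m in fits.items():
        w = weekly_auc(m, evaluate_on, response_col)[["week", "auc"]].rename(
            columns={"auc": f"auc_{name}"}
        )
        weekly = w if weekly is None else weekly.merge(w, on="week")
    weekly = weekly.dropna().reset_index(drop=True)
    descriptive = len(weekly) < 6
    rows = []
    for a, b in (("full", "habitat"), ("full", "distance"), ("habitat", "distance")):
        diff = weekly[f"auc_{a}"] - weekly[f"auc_{b}"]
        stat = p = np.nan
        if not descriptive and np.any(diff != 0):
            stat, p = wilcoxon(diff)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "median_difference": float(diff.median()) if len(diff) else np.nan,
                "wilcoxon_stat": stat,
                "pvalue": p,
            }
        )
    return DriverComparison(weekly=weekly, tests=pd.DataFrame(rows), descriptive_only=descriptive)


# ---------------------------------------------------------------------------
# thresholded prediction maps
# ---------------------------------------------------------------------------


def youden_threshold(scores, labels) -> tuple[float, float]:
    """ROC cut-off maximizing J = sensitivity - false-positive rate.

    Returns (threshold, J); ties broken toward the higher threshold.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined with a single class")
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve thresholds are decreasing: earliest index = highest threshold
    i = int(best[0])
    return float(thr[i]), float(j[i])


@dataclass
class PredictionMap:
    probability: np.ndarray  # (n, n), NaN on land
    suitability: np.ndarray | None  # bool, probability >= threshold
    threshold: float | None
    season: str
    grid_cell_km: float

    def to_dataset(self, grid):
        import xarray as xr

        c = grid.coords_km
        data = {"probability": (("y", "x"), self.probability)}
        if self.suitability is not None:
            data["suitability"] = (("y", "x"), self.suitability.astype("i1"))
        return xr.Dataset(
            data,
            coords={"y": c, "x": c},
            attrs={"season": self.season, "threshold": -1.0 if self.threshold is None else self.threshold},
        )


def threshold_and_map(
    model: SplineBinomialGAM,
    env: EnvironmentGrid,
    season: str,
    records: pd.DataFrame,
    colonies: ColonyRegistry,
    own_colony: str,
    response_col: str = "response",
) -> PredictionMap:
    """Seasonal probability-of-presence map with a Youden-threshold mask.

    Grid covariates are the per-cell medians of the season's weekly
    composites (robust to single-composite outliers); distance covariates are
    computed per cell relative to ``own_colony``.  The threshold is fitted on
    the training records' scores; if their ROC is degenerate only the
    probability map is produced.
    """
    from .tracks import assign_season

    weeks = [
        w
        for w in range(env.weeks)
        if assign_season(env.start_date + pd.Timedelta(weeks=w)) == season
    ]
    if not weeks:
        raise ValueError(f"environment covers no {season!r} weeks")
    g = env.grid
    lon, lat = g.cell_centers_lonlat()
    flat = pd.DataFrame(index=range(g.n_cells))
    for name in ("sst", "sst_std", "chl", "sla", "eke", "wind"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN cells on land
            med = env.seasonal_median(name, weeks)
        flat[name] = np.log10(med.ravel()) if name == "chl" else med.ravel()
    flat["depth"] = env.static["depth"].ravel()
    flat["depth_std"] = env.static["depth_std"].ravel()
    pts = np.column_stack([lon.ravel(), lat.ravel()])
    d_own, d_closest = colonies.dist_own_closest(pts, own_colony)
    flat["dist_own"] = d_own
    flat["dist_closest"] = d_closest

    covs = list(model.covariates or [])
    valid = np.isfinite(flat[covs].to_numpy(float)).all(axis=1) & ~env.land_mask.ravel()
    prob = np.full(g.n_cells, np.nan)
    if valid.any():
        prob[valid] = model.predict_proba(flat.loc[valid])[:, 1]
    prob = prob.reshape(g.shape)

    y = records[response_col].to_numpy()
    suit = thr = None
    if len(np.unique(y)) == 2:
        scores = model.predict_proba(records)[:, 1]
        thr, _ = youden_threshold(scores, y)
        suit = prob >= thr
    else:
        warnings.warn("degenerate ROC on training records; probability map only")
    return PredictionMap(
        probability=prob, suitability=suit, threshold=thr, season=season, grid_cell_km=g.cell_km
    )


# ---------------------------------------------------------------------------
# group-specific smoother test
# ---------------------------------------------------------------------------


@dataclass
class GroupSmootherResult:
    per_individual: pd.DataFrame  # individual_id, auc_shared, auc_grouped
    statistic: float
    pvalue: float
    median_difference: float
    preferred: str  # "group-specific" or "shared"


def group_smoother_test(
    records: pd.DataFrame,
    grouping: str,
    covariates: list[str],
    response_col: str = "response",
    alpha: float = 0.05,
    **model_kwargs,
) -> GroupSmootherResult:
    """Do group-specific smooths (sex or breeding outcome) improve prediction?

    Leave-one-individual-out AUC is computed under the shared-smooth and the
    group-specific-smooth model; the paired differences are tested across
    individuals with a Wilcoxon signed-rank test.  Group-specific smooths are
    preferred iff P < alpha and the median AUC difference is positive.
    """
    counts = records.groupby(grouping)["individual_id"].nunique()
    if len(counts) < 2 or counts.min() < 3:
        raise ValueError("each group level needs >= 3 individuals")
    shared = leave_one_individual_out(records, covariates, response_col, **model_kwargs)
    grouped = leave_one_individual_out(
        records, covariates, response_col, group_by=grouping, **model_kwargs
    )
    merged = shared.merge(grouped, on="individual_id", suffixes=("_shared", "_grouped"))
    merged = merged.dropna(subset=["auc_shared", "auc_grouped"])
    diff = (merged["auc_grouped"] - merged["auc_shared"]).to_numpy()
    if np.all(diff == 0):
        stat, p = np.nan, 1.0
    else:
        stat, p = wilcoxon(diff)
    med = float(np.median(diff))
    preferred = "group-specific" if (p < alpha and med > 0) else "shared"
    return GroupSmootherResult(
        per_individual=merged[["individual_id", "auc_shared", "auc_grouped"]],
        statistic=float(stat) if stat == stat else np.nan,
        pvalue=float(p),
        median_difference=med,
        preferred=preferred,
    )
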