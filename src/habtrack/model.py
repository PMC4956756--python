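"""Binomial additive habitat-preference model with spline smooths.

The use-availability response (1 = observed location, 0 = CRW pseudo-absence)
is modelled as a logistic additive model: each continuous covariate enters
through a fixed-dimension cubic B-spline basis (default 5 basis functions,
knots at covariate quantiles), optionally expanded per level of a grouping
factor (sex or breeding outcome) to give group-specific smooths, plus an
optional categorical year effect.  Fixed-dimension bases keep the AIC
parameter count exact and the fit fully reproducible; they trade some
flexibility against the penalized smooths common in this literature, which
matters little at the smooth effect shapes of use-availability data.

Fitting is maximum likelihood by iteratively reweighted least squares
(statsmodels GLM, binomial family).  Aliased design columns — the spline
partition of unity makes each full basis collinear with the intercept — are
dropped deterministically by QR column pivoting before the fit.

Model selection follows the all-subsets ("dredge") protocol: every covariate
subset is fitted, ranked by AIC, and assigned Akaike weights
exp(-dAIC/2)/sum.  Variable importance is the drop-one deviance fraction:
(deviance without the covariate - full-model deviance) / null deviance, with
covariates above 1% flagged important.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.linalg import qr
from sklearn.base import BaseEstimator, ClassifierMixin

DEFAULT_DF = 5
DEFAULT_DEGREE = 3
IMPORTANCE_THRESHOLD = 0.01  # "important" = explains > 1% of null deviance
SEPARATION_COEF = 30.0


@dataclass
class SplineBasis:
    """Cubic B-spline basis with quantile interior knots, clamped extrapolation."""

    knots: np.ndarray
    degree: int

    @classmethod
    def from_data(cls, x: np.ndarray, df: int, degree: int) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        distinct = np.unique(x)
        if distinct.size < 2:
            raise ValueError("covariate has < 2 distinct values")
        if distinct.size < df:
            df_new = max(distinct.size - 1, 2)
            warnings.warn(f"covariate has {distinct.size} distinct values; basis reduced to {df_new}")
            df = df_new
            degree = min(degree, df - 1)
        n_interior = df - degree - 1
        lo, hi = float(distinct[0]), float(distinct[-1])
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
            # keep knots strictly inside and non-duplicated
            interior = np.clip(interior, lo + 1e-12, hi - 1e-12)
        else:
            interior = np.array([])
        t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        return cls(knots=t, degree=degree)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        xc = np.clip(x, lo, hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[int], list[str]]:
    """Rank-revealing QR with column pivoting; returns kept design and indices."""
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    kept = sorted(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    return X[:, kept], kept, dropped


def _fit_logistic(X: np.ndarray, y: np.ndarray, tol: float, maxiter: int):
    """IRLS logistic fit; returns the statsmodels results object."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=maxiter, tol=tol)


class SplineBinomialGAM(BaseEstimator, ClassifierMixin):
    """Logistic additive model over spline-expanded covariates.

    Parameters
    ----------
    covariates : list of str
        Columns of X entering as smooths.
    df : int
        Basis dimension per smooth (>= 3).
    degree : int
        Spline degree (cubic by default).
    group_by : str or None
        Categorical column; when set, every smooth is expanded per level
        (group-specific habitat preferences).
    year_effect : bool
        Include a categorical effect of the ``year`` column.
    tol, maxiter : IRLS convergence control.

    Attributes (after fit)
    ----------------------
    coef_ : coefficients of the kept (non-aliased) design columns
    aic_, deviance_, null_deviance_, llf_ : fit statistics
    n_params_ : number of estimated coefficients (design rank)
    dropped_columns_ : names of aliased columns removed by QR pivoting
    separation_flag_ : True when coefficients diverged (complete separation)
    """

    def __init__(
        self,
        covariates=None,
        df=DEFAULT_DF,
        degree=DEFAULT_DEGREE,
        group_by=None,
        year_effect=False,
        tol=1e-8,
        maxiter=100,
    ):
        self.covariates = covariates
        self.df = df
        self.degree = degree
        self.group_by = group_by
        self.year_effect = year_effect
        self.tol = tol
        self.maxiter = maxiter

    # -- design ------------------------------------------------------------

    def _check_params(self):
        if not self.covariates:
            return
        if self.df < 3:
            raise ValueError("basis dimension must be >= 3")

    def build_design(self, X: pd.DataFrame, fit: bool = False):
        """Design matrix (intercept + basis blocks), column names, block slices."""
        X = pd.DataFrame(X)
        covs = list(self.covariates or [])
        for c in covs:
            if c not in X.columns:
                raise ValueError(f"covariate {c!r} not in data")
        if fit:
            self.bases_ = {c: SplineBasis.from_data(X[c].to_numpy(), self.df, self.degree) for c in covs}
            if self.group_by is not None:
                levels = sorted(pd.unique(X[self.group_by].astype(str)))
                if len(levels) < 2:
                    raise ValueError("grouping factor needs >= 2 levels")
                self.group_levels_ = levels
            if self.year_effect:
                self.year_levels_ = sorted(pd.unique(X["year"]))
                if len(self.year_levels_) < 2:
                    raise ValueError("year effect needs >= 2 year levels")
        cols = [np.ones(len(X))]
        names = ["intercept"]
        blocks: dict[tuple, slice] = {}
        pos = 1
        for c in covs:
            B = self.bases_[c].design(X[c].to_numpy())
            if self.group_by is not None:
                g = X[self.group_by].astype(str).to_numpy()
                for lvl in self.group_levels_:
                    ind = (g == lvl).astype(float)[:, None]
                    cols.append(B * ind)
                    names += [f"s({c}):{lvl}[{j}]" for j in range(B.shape[1])]
                    blocks[(c, lvl)] = slice(pos, pos + B.shape[1])
                    pos += B.shape[1]
            else:
                cols.append(B)
                names += [f"s({c})[{j}]" for j in range(B.shape[1])]
                blocks[(c, None)] = slice(pos, pos + B.shape[1])
                pos += B.shape[1]
        if self.year_effect:
            yr = X["year"].to_numpy()
            for lvl in self.year_levels_[1:]:
                cols.append((yr == lvl).astype(float)[:, None])
                names.append(f"year[{lvl}]")
                pos += 1
        design = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
        return design, names, blocks

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        self._check_params()
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("response must be binary 0/1")
        design, names, blocks = self.build_design(X, fit=True)
        design_kept, kept, dropped = _drop_aliased(design, names)
        res = _fit_logistic(design_kept, y, self.tol, self.maxiter)
        self.feature_names_ = names
        self.kept_idx_ = kept
        self.dropped_columns_ = dropped
        self.blocks_ = blocks
        self.result_ = res
        self.coef_ = np.asarray(res.params)
        self.n_params_ = len(kept)
        self.llf_ = float(res.llf)
        self.deviance_ = float(res.deviance)
        self.null_deviance_ = float(res.null_deviance)
        self.aic_ = -2.0 * self.llf_ + 2.0 * self.n_params_
        self.converged_ = bool(res.converged)
        self.separation_flag_ = bool(np.max(np.abs(self.coef_)) > SEPARATION_COEF)
        self.classes_ = np.array([0, 1])
        # full-length coefficient vector (zeros at aliased columns)
        beta = np.zeros(len(names))
        beta[kept] = self.coef_
        self._beta_full = beta
        self._train_X = X
        return self

    def _design_for(self, X) -> np.ndarray:
        design, _, _ = self.build_design(pd.DataFrame(X))
        return design[:, self.kept_idx_]

    def decision_function(self, X) -> np.ndarray:
        """Linear predictor (log-odds of use)."""
        return self._design_for(X) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    # -- inspection --------------------------------------------------------

    def response_curve(self, covariate: str, level=None, n: int = 100) -> pd.DataFrame:
        """Centred partial contribution of one smooth, with standard errors.

        The smooth contribution is centred to mean zero over the training
        values of the covariate so curves are comparable across models.
        """
        key = (covariate, level)
        if key not in self.blocks_:
            raise KeyError(f"no smooth for {key}")
        sl = self.blocks_[key]
        basis = self.bases_[covariate]
        xtr = self._train_X[covariate].to_numpy(float)
        grid_x = np.linspace(np.min(xtr), np.max(xtr), n)
        Bg = basis.design(grid_x)
        Bt = basis.design(xtr)
        beta = self._beta_full[sl]
        contrib = Bg @ beta - np.mean(Bt @ beta)
        # standard errors from the covariance of the kept block coefficients
        block_cols = list(range(sl.start, sl.stop))
        kept_pos = {idx: i for i, idx in enumerate(self.kept_idx_)}
        present = [c for c in block_cols if c in kept_pos]
        se = np.zeros(n)
        if present:
            cov = np.asarray(self.result_.cov_params())
            rows = [kept_pos[c] for c in present]
            sub = cov[np.ix_(rows, rows)]
            Bsub = Bg[:, [block_cols.index(c) for c in present]]
            se = np.sqrt(np.einsum("ij,jk,ik->i", Bsub, sub, Bsub))
        return pd.DataFrame({covariate: grid_x, "contribution": contrib, "se": se})


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class CandidateRanking:
    """All-subsets AIC ranking with Akaike weights."""

    table: pd.DataFrame  # columns: subset, k, aic, delta_aic, weight
    non_converged: list[tuple]

    @property
    def best_subset(self) -> tuple:
        return self.table["subset"].iloc[0]

    @property
    def n_models(self) -> int:
        return len(self.table) + len(self.non_converged)


def all_subsets_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: list[str],
    df: int = DEFAULT_DF,
    degree: int = DEFAULT_DEGREE,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> CandidateRanking:
    """Fit every covariate subset (including the null model) and rank by AIC.

    Basis blocks are built once from the full data (quantile knots on all
    records) and reassembled per subset, so every candidate sees identical
    smooth bases.  Subsets whose IRLS fit fails or diverges are excluded from
    the ranking and listed separately.
    """
    if len(covariates) > 12:
        raise ValueError("all-subsets search capped at 12 covariates (2^12 models)")
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y)
    bases = {c: SplineBasis.from_data(X[c].to_numpy(), df, degree) for c in covariates}
    block = {c: bases[c].design(X[c].to_numpy()) for c in covariates}
    ones = np.ones((len(X), 1))
    rows = []
    failed = []
    for r in range(len(covariates) + 1):
        for subset in itertools.combinations(covariates, r):
            design = np.hstack([ones] + [block[c] for c in subset])
            names = ["intercept"] + [f"{c}[{j}]" for c in subset for j in range(block[c].shape[1])]
            design_kept, kept, _ = _drop_aliased(design, names)
            try:
                res = _fit_logistic(design_kept, y, tol, maxiter)
            except Exception:
                failed.append(subset)
                continue
            if not res.converged or np.max(np.abs(res.params)) > SEPARATION_COEF:
                failed.append(subset)
                continue
            aic = -2.0 * float(res.llf) + 2.0 * len(kept)
            rows.append({"subset": subset, "k": len(kept), "aic": aic})
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    w = np.exp(-0.5 * table["delta_aic"].to_numpy())
    table["weight"] = w / w.sum()
    return CandidateRanking(table=table, non_converged=failed)


def deviance_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    covariates: list[str],
    threshold: float = IMPORTANCE_THRESHOLD,
    **model_kwargs,
) -> pd.DataFrame:
    """Drop-one deviance-explained importance per covariate.

    importance(v) = (deviance without v - full deviance) / null deviance.
    Covariates above ``threshold`` (1% by default) are flagged important.
    """
    full = SplineBinomialGAM(covariates=covariates, **model_kwargs).fit(X, y)
    if not full.converged_:
        raise RuntimeError("full model did not converge")
    rows = []
    for v in covariates:
        rest = [c for c in covariates if c != v]
        try:
            reduced = SplineBinomialGAM(covariates=rest, **model_kwargs).fit(X, y)
            imp = (reduced.deviance_ - full.deviance_) / full.null_deviance_
            ok = bool(reduced.converged_)
        except Exception:
            imp, ok = np.nan, False
        rows.append({"covariate": v, "importance": imp, "available": ok})
    out = pd.DataFrame(rows)
    out["important"] = out["importance"] > threshold
    return out


def compare_year_effect(X: pd.DataFrame, y: np.ndarray, covariates: list[str], **model_kwargs) -> float:
    """AIC(with year effect) - AIC(without); negative favours including year."""
    X = pd.DataFrame(X)
    if "year" not in X.columns or len(pd.unique(X["year"])) < 2:
        raise ValueError("year comparison needs >= 2 year levels")
    without = SplineBinomialGAM(covariates=covariates, year_effect=False, **model_kwargs).fit(X, y)
    with_year = SplineBinomialGAM(covariates=covariates, year_effect=True, **model_kwargs).fit(X, y)
    return float(with_year.aic_ - without.aic_)
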