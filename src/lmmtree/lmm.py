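"""Linear mixed-effects fitting: user-level random intercept + random slope.

Thin, opinionated layer over :class:`statsmodels.regression.mixed_linear_model.MixedLM`
for the models this package needs: Gaussian outcome, arbitrary fixed-effect
columns, grouping by user, and a random intercept optionally accompanied by
a random slope on one column (the pre-break time covariate) with an
unstructured 2x2 covariance.

Conventions
-----------
* ``method='ml'`` (maximum likelihood) is the default so that AIC values are
  comparable across fixed-effect structures; REML is available for variance
  estimation but REML likelihoods are never used for model comparison.
* ``n_params`` counts fixed effects plus variance parameters (intercept SD,
  slope SD, their correlation and the residual SD when a random slope is
  present; intercept SD and residual SD otherwise), and
  ``aic = -2 loglik + 2 n_params``.
* Optimizer failure is reported through ``converged=False`` after one
  derivative-free (Powell) restart; it never raises.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr
from statsmodels.regression.mixed_linear_model import MixedLM

from .cohort import VarianceComponents
from .errors import (
    DegenerateGroupingError,
    SchemaError,
    SingularDesignError,
)

__all__ = ["LMMFit", "fit_lmm", "predict_lmm", "fit_ols_reference"]

INTERCEPT = "Intercept"


@dataclass
class LMMFit:
    """Result of one mixed-model fit."""

    beta: pd.Series
    se: pd.Series
    varcomp: VarianceComponents
    blups: pd.DataFrame  # index: user id; columns: 'intercept' (+ 'slope')
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    method: str
    outcome_col: str
    fixed_cols: list[str]
    random_slope_on: str | None
    group_col: str = "user_id"
    pvalues: pd.Series | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "varcomp": vars(self.varcomp),
            "blups": {str(k): list(v) for k, v in self.blups.iterrows()},
            "blup_columns": list(self.blups.columns),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "method": self.method,
            "outcome_col": self.outcome_col,
            "fixed_cols": self.fixed_cols,
            "random_slope_on": self.random_slope_on,
            "group_col": self.group_col,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LMMFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        blups = pd.DataFrame.from_dict(
            payload["blups"], orient="index", columns=payload["blup_columns"]
        )
        blups.index = [_maybe_int(i) for i in blups.index]
        return cls(
            beta=pd.Series(payload["beta"]),
            se=pd.Series(payload["se"]),
            varcomp=VarianceComponents(**payload["varcomp"]),
            blups=blups,
            loglik=payload["loglik"],
            aic=payload["aic"],
            n_obs=payload["n_obs"],
            n_params=payload["n_params"],
            converged=payload["converged"],
            method=payload["method"],
            outcome_col=payload["outcome_col"],
            fixed_cols=payload["fixed_cols"],
            random_slope_on=payload["random_slope_on"],
            group_col=payload["group_col"],
        )


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


def _design_matrix(table: pd.DataFrame, fixed_cols, include_intercept: bool):
    names = ([INTERCEPT] if include_intercept else []) + list(fixed_cols)
    missing = [c for c in fixed_cols if c not in table.columns]
    if missing:
        raise SchemaError(f"design columns missing from table: {missing}")
    cols = [np.ones(len(table))] if include_intercept else []
    cols += [table[c].to_numpy(dtype=float) for c in fixed_cols]
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise SingularDesignError("fewer rows than design columns", collinear=names)
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise SingularDesignError(
            f"fixed-effect design is rank deficient; collinear columns: {bad}",
            collinear=bad,
        )


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    random_slope_on: str | None = "w_pre",
    method: str = "ml",
    group_col: str = "user_id",
    include_intercept: bool = True,
    force_zero_variance: bool = False,
) -> LMMFit:
    """Fit the mixed model ``outcome ~ fixed, (1 [+ slope] | user)``.

    Parameters
    ----------
    fixed : columns of ``table`` entering the fixed-effect design (an
        intercept is prepended unless ``include_intercept=False``).
    random_slope_on : column carrying the random slope (typically ``w_pre``),
        or ``None`` for a random intercept only.
    method : ``'ml'`` or ``'reml'``.
    force_zero_variance : hold all random-effect variances at zero, reducing
        the fit to generalized least squares with iid errors (= OLS); used
        for diagnostics.
    """
    if method not in ("ml", "reml"):
        raise ValueError(f"method must be 'ml' or 'reml', got {method!r}")
    for col in (outcome, group_col):
        if col not in table.columns:
            raise SchemaError(f"column '{col}' not found in table")
    data = table.dropna(subset=[outcome])
    groups = data[group_col].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise DegenerateGroupingError(
            "at least 2 users are required to estimate user-level random effects"
        )
    y = data[outcome].to_numpy(dtype=float)
    X, names = _design_matrix(data, fixed, include_intercept)
    _check_rank(X, names)

    if random_slope_on is not None:
        if random_slope_on not in data.columns:
            raise SchemaError(f"random-slope column '{random_slope_on}' not found")
        exog_re = np.column_stack(
            [np.ones(len(data)), data[random_slope_on].to_numpy(dtype=float)]
        )
        re_names = ["intercept", "slope"]
    else:
        exog_re = np.ones((len(data), 1))
        re_names = ["intercept"]

    if force_zero_variance:
        # the zero-variance limit of the mixed likelihood is the iid Gaussian
        # likelihood, maximized exactly by ordinary least squares
        return _fit_zero_variance(
            y, X, names, groups, re_names, method, outcome, group_col,
            random_slope_on,
        )

    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    reml = method == "reml"
    fit_kwargs: dict = {"reml": reml, "maxiter": 200, "disp": False}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(method="lbfgs", **fit_kwargs)
        converged = bool(getattr(result, "converged", True) and np.isfinite(result.llf))
        if not converged:
            # one derivative-free restart before reporting failure
            result2 = model.fit(method="powell", **fit_kwargs)
            if np.isfinite(result2.llf) and (
                not np.isfinite(result.llf) or result2.llf >= result.llf
            ):
                result = result2
            converged = bool(
                getattr(result, "converged", True) and np.isfinite(result.llf)
            )

    cov_re = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
    sd_int = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    if random_slope_on is not None:
        sd_slope = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        corr = float(cov_re[0, 1] / (sd_int * sd_slope)) if sd_int * sd_slope > 0 else 0.0
        corr = float(np.clip(corr, -1.0, 1.0))
        n_var = 4
    else:
        sd_slope, corr, n_var = 0.0, 0.0, 2
    varcomp = VarianceComponents(
        sd_intercept=sd_int,
        sd_slope_pre=sd_slope,
        corr_int_slope=corr,
        sd_residual=float(np.sqrt(result.scale)),
    )

    uids = pd.unique(groups)
    try:
        re_dict = result.random_effects
        blups = pd.DataFrame(
            {uid: np.asarray(vals, dtype=float) for uid, vals in re_dict.items()},
            index=re_names,
        ).T
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance (e.g. variances fixed at zero):
        # every BLUP is its prior mean, zero
        blups = pd.DataFrame(0.0, index=uids, columns=re_names)

    beta = pd.Series(np.asarray(result.fe_params, dtype=float), index=names)
    se = pd.Series(np.asarray(result.bse_fe, dtype=float), index=names)
    pvalues = pd.Series(np.asarray(result.pvalues, dtype=float)[: len(names)], index=names)
    n_params = len(beta) + n_var
    loglik = float(result.llf)
    return LMMFit(
        beta=beta,
        se=se,
        varcomp=varcomp,
        blups=blups,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        n_obs=int(len(y)),
        n_params=n_params,
        converged=converged,
        method=method,
        outcome_col=outcome,
        fixed_cols=names,
        random_slope_on=random_slope_on,
        group_col=group_col,
        pvalues=pvalues,
    )


def _fit_zero_variance(
    y, X, names, groups, re_names, method, outcome, group_col, random_slope_on
) -> LMMFit:
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    dof = n if method == "ml" else n - k
    sigma2 = ssr / dof
    se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
    if sigma2 > 0:
        loglik = -0.5 * dof * (np.log(2 * np.pi * sigma2) + 1)
        if method == "reml":
            loglik -= 0.5 * np.linalg.slogdet(X.T @ X / sigma2)[1]
        tstat = beta / se
        pvalues = 2 * stats.norm.sf(np.abs(tstat))
    else:  # perfect fit: degenerate likelihood
        loglik, pvalues = np.inf, np.zeros(k)
    n_var = 4 if random_slope_on is not None else 2
    n_params = k + n_var
    return LMMFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        varcomp=VarianceComponents(0.0, 0.0, 0.0, float(np.sqrt(sigma2))),
        blups=pd.DataFrame(0.0, index=pd.unique(groups), columns=re_names),
        loglik=float(loglik),
        aic=float(-2 * loglik + 2 * n_params),
        n_obs=n,
        n_params=n_params,
        converged=True,
        method=method,
        outcome_col=outcome,
        fixed_cols=list(names),
        random_slope_on=random_slope_on,
        group_col=group_col,
        pvalues=pd.Series(pvalues, index=names),
    )


def predict_lmm(fit: LMMFit, table: pd.DataFrame, include_random: bool = True) -> np.ndarray:
    """Predictions from a fitted mixed model.

    ``include_random=False`` returns the fixed part ``X @ beta``;
    ``include_random=True`` adds each known user's predicted random-effect
    contribution (users unseen at fit time contribute zero: the BLUP of an
    unobserved user is its prior mean).
    """
    fixed_cols = [c for c in fit.fixed_cols if c != INTERCEPT]
    X, _ = _design_matrix(table, fixed_cols, include_intercept=INTERCEPT in fit.fixed_cols)
    pred = X @ fit.beta.to_numpy()
    if not include_random or fit.blups.empty:
        return pred
    if fit.group_col not in table.columns:
        raise SchemaError(f"column '{fit.group_col}' not found in table")
    users = table[fit.group_col]
    u0 = users.map(fit.blups["intercept"]).fillna(0.0).to_numpy()
    pred = pred + u0
    if fit.random_slope_on is not None:
        if fit.random_slope_on not in table.columns:
            raise SchemaError(f"random-slope column '{fit.random_slope_on}' not found")
        u1 = users.map(fit.blups["slope"]).fillna(0.0).to_numpy()
        pred = pred + u1 * table[fit.random_slope_on].to_numpy(dtype=float)
    return pred


def fit_ols_reference(table: pd.DataFrame, outcome: str, fixed: list[str],
                      include_intercept: bool = True) -> pd.Series:
    """Plain least-squares coefficients on the same design (diagnostic aid)."""
    data = table.dropna(subset=[outcome])
    X, names = _design_matrix(data, fixed, include_intercept)
    beta, *_ = np.linalg.lstsq(X, data[outcome].to_numpy(dtype=float), rcond=None)
    return pd.Series(beta, index=names)
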