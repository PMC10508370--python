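"""Model selection and out-of-sample evaluation.

Reproduces the study-design decisions around the tree estimator: AIC-based
choice of the breakpoint week (candidates vs. a single-slope model), AIC
over a grid of tree depth caps, user-disjoint 80/20 train/test partitioning,
user-level k-fold cross-validation, and RMSE reporting.  All AIC comparisons
use maximum-likelihood fits so likelihoods are comparable across
fixed-effect structures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CannotSplitError, InvalidConfigError, SchemaError
from .lmm import fit_lmm
from .piecewise import W_PRE, add_piecewise_columns
from .tree import LMMTreeFit, TreeControl, fit_lmm_tree, predict_tree

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "rmse",
    "split_by_user",
    "kfold_by_user",
    "compare_breakpoints",
    "tune_maxdepth",
    "evaluate_model",
]

LINEAR = "linear"


def rmse(observed, predicted) -> float:
    """Root mean squared error, ``sqrt(mean((obs - pred)^2))``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise SchemaError(f"length mismatch: observed {obs.shape} vs predicted {pred.shape}")
    if obs.size == 0:
        raise SchemaError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def split_by_user(
    table: pd.DataFrame, test_fraction: float, seed: int, group_col: str = "user_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """User-disjoint train/test split; ``round(fraction * n_users)`` test users."""
    if not 0 < test_fraction < 1:
        raise InvalidConfigError(f"test_fraction must be in (0, 1), got {test_fraction}")
    users = pd.unique(table[group_col])
    if len(users) < 2:
        raise CannotSplitError("need at least 2 users to split")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(users)
    # round-half-up so 0.2 * 3610 -> 722, not banker's rounding
    n_test = int(np.floor(test_fraction * len(users) + 0.5))
    n_test = min(max(n_test, 1), len(users) - 1)
    test_users = set(shuffled[:n_test])
    mask = table[group_col].isin(test_users)
    return table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)


def kfold_by_user(
    table: pd.DataFrame, k: int, seed: int, group_col: str = "user_id"
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """User-level k-fold partition; fold sizes differ by at most one user."""
    users = pd.unique(table[group_col])
    if k < 2:
        raise InvalidConfigError(f"k must be >= 2, got {k}")
    if k > len(users):
        raise InvalidConfigError(f"k={k} exceeds the number of users ({len(users)})")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(users), k)
    pairs = []
    for fold in folds:
        mask = table[group_col].isin(set(fold))
        pairs.append((table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)))
    return pairs


@dataclass
class BreakpointComparison:
    aic_table: dict[str, float]
    winner: str
    flagged: list[str] = field(default_factory=list)
    tie: bool = False


def compare_breakpoints(
    table: pd.DataFrame,
    outcome: str,
    candidate_breakpoints=(3, 4),
    include_linear: bool = True,
    group_col: str = "user_id",
    week_col: str = "week",
) -> BreakpointComparison:
    """AIC comparison of piecewise breakpoint candidates and a linear model.

    Each candidate is a maximum-likelihood mixed-model fit with the same
    random structure (random intercept + random slope on the first/only time
    covariate).  Non-convergent candidates are flagged and excluded from the
    argmin.  AIC ties are broken toward the model with fewer parameters,
    then listing order.
    """
    models: list[tuple[str, float, float, int]] = []  # name, aic, ll, n_params
    flagged = []
    max_week = table[week_col].max()
    for bp in candidate_breakpoints:
        if not 1 < bp <= max_week:
            raise InvalidConfigError(f"candidate breakpoint {bp} outside observed weeks")
        data = add_piecewise_columns(table, bp, week_col=week_col)
        fit = fit_lmm(data, outcome, ["w_pre", "w_post"], random_slope_on=W_PRE,
                      method="ml", group_col=group_col)
        name = f"break_{bp:g}"
        if not fit.converged:
            flagged.append(name)
            logger.warning("breakpoint candidate %s did not converge; excluded", name)
        models.append((name, fit.aic, fit.loglik, fit.n_params))
    if include_linear:
        data = table.copy()
        data["w_lin"] = data[week_col].to_numpy(float) - 1.0
        fit = fit_lmm(data, outcome, ["w_lin"], random_slope_on="w_lin",
                      method="ml", group_col=group_col)
        if not fit.converged:
            flagged.append(LINEAR)
            logger.warning("single-slope model did not converge; excluded")
        models.append((LINEAR, fit.aic, fit.loglik, fit.n_params))

    aic_table = {name: aic for name, aic, _, _ in models}
    eligible = [(aic, n_params, i, name) for i, (name, aic, _, n_params) in enumerate(models)
                if name not in flagged]
    if not eligible:
        raise InvalidConfigError("no candidate model converged")
    eligible.sort(key=lambda t: (t[0], t[1], t[2]))
    winner = eligible[0][3]
    tie = len(eligible) > 1 and np.isclose(eligible[0][0], eligible[1][0], atol=1e-8)
    return BreakpointComparison(aic_table=aic_table, winner=winner, flagged=flagged, tie=tie)


@dataclass
class DepthSelection:
    aic_table: dict[int, float]
    chosen_maxdepth: int
    fits: dict[int, LMMTreeFit]
    flagged: list[int] = field(default_factory=list)


def tune_maxdepth(
    table: pd.DataFrame,
    outcome: str,
    partitioning_vars: list[str],
    depth_grid=(2, 3, 4, 5),
    control: TreeControl = TreeControl(),
    breakpoint_week: float = 3,
    group_col: str = "user_id",
) -> DepthSelection:
    """Fit one tree per depth cap and select the AIC minimizer.

    Convergence failures at a given depth are flagged and excluded (deeper
    trees can legitimately fail on complex node structures).  AIC ties break
    toward the shallower (simpler) tree.
    """
    if not depth_grid:
        raise InvalidConfigError("depth grid must be non-empty")
    aic_table: dict[int, float] = {}
    fits: dict[int, LMMTreeFit] = {}
    flagged: list[int] = []
    for depth in depth_grid:
        fit = fit_lmm_tree(
            table, outcome, partitioning_vars,
            control=replace(control, maxdepth=depth),
            breakpoint_week=breakpoint_week, group_col=group_col,
        )
        fits[depth] = fit
        aic_table[depth] = fit.aic
        if not fit.converged:
            flagged.append(depth)
            logger.warning("tree with maxdepth=%d did not converge; excluded", depth)
    eligible = sorted(
        (aic_table[d], d) for d in aic_table if d not in flagged
    )
    if not eligible:
        raise InvalidConfigError("no tree depth converged")
    chosen = eligible[0][1]
    return DepthSelection(aic_table=aic_table, chosen_maxdepth=chosen, fits=fits, flagged=flagged)


@dataclass
class EvaluationResult:
    """Train/test and cross-validated performance of the selected model."""

    rmse_train: float
    rmse_test: float
    cv_rmse: list[float]
    cv_rmse_mean: float
    chosen_breakpoint: object  # week number or "linear"
    chosen_maxdepth: int
    aic_table: dict
    n_train_users: int
    n_test_users: int

    def to_json(self, path=None) -> str:
        payload = {k: v for k, v in vars(self).items()}
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_model(
    table: pd.DataFrame,
    outcome: str,
    partitioning_vars: list[str],
    control: TreeControl = TreeControl(),
    candidate_breakpoints=(3, 4),
    depth_grid=(2, 3, 4, 5),
    test_fraction: float = 0.2,
    n_folds: int = 5,
    seed: int = 0,
    group_col: str = "user_id",
) -> tuple[EvaluationResult, LMMTreeFit]:
    """Full selection-and-evaluation pipeline on one cohort.

    1. user-disjoint 80/20 split;
    2. breakpoint chosen on the training data by AIC (piecewise candidates
       plus the single-slope comparator) — the tree stage uses the best
       *piecewise* candidate even when the linear model wins overall;
    3. depth cap chosen by AIC over ``depth_grid`` on the training data;
    4. k-fold user-level cross-validation of the selected configuration;
    5. final refit on the full training set; train RMSE uses the full model
       (including BLUPs), test RMSE uses fixed effects only, since BLUPs are
       undefined for unseen users.
    """
    train, test = split_by_user(table, test_fraction, seed, group_col=group_col)
    bp_cmp = compare_breakpoints(train, outcome, candidate_breakpoints, group_col=group_col)
    if bp_cmp.winner == LINEAR:
        chosen_bp: object = LINEAR
        eligible = {k: v for k, v in bp_cmp.aic_table.items()
                    if k != LINEAR and k not in bp_cmp.flagged}
        tree_bp = float(min(eligible, key=eligible.get).split("_")[1])
    else:
        tree_bp = float(bp_cmp.winner.split("_")[1])
        chosen_bp = int(tree_bp) if tree_bp.is_integer() else tree_bp

    depth_sel = tune_maxdepth(
        train, outcome, partitioning_vars, depth_grid=depth_grid,
        control=control, breakpoint_week=tree_bp, group_col=group_col,
    )
    chosen_control = replace(control, maxdepth=depth_sel.chosen_maxdepth)

    cv_scores = []
    for fold_train, fold_val in kfold_by_user(train, n_folds, seed, group_col=group_col):
        fold_fit = fit_lmm_tree(
            fold_train, outcome, partitioning_vars, control=chosen_control,
            breakpoint_week=tree_bp, group_col=group_col,
        )
        pred = predict_tree(fold_fit, fold_val, include_random=False)
        cv_scores.append(rmse(fold_val[outcome], pred))

    final = depth_sel.fits[depth_sel.chosen_maxdepth]
    pred_train = predict_tree(final, train, include_random=True)
    pred_test = predict_tree(final, test, include_random=False)
    aic_table = dict(bp_cmp.aic_table)
    aic_table.update({f"depth_{d}": a for d, a in depth_sel.aic_table.items()})
    result = EvaluationResult(
        rmse_train=rmse(train[outcome], pred_train),
        rmse_test=rmse(test[outcome], pred_test),
        cv_rmse=cv_scores,
        cv_rmse_mean=float(np.mean(cv_scores)),
        chosen_breakpoint=chosen_bp,
        chosen_maxdepth=depth_sel.chosen_maxdepth,
        aic_table=aic_table,
        n_train_users=int(train[group_col].nunique()),
        n_test_users=int(test[group_col].nunique()),
    )
    return result, final
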