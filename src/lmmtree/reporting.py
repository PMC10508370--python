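"""Back-transformation, node summaries and descriptive statistics.

Training durations are modelled on the log scale, so a node's intercept
back-transforms to minutes as ``exp(b0)`` and a segment slope ``b``
translates into a weekly percent change ``(exp(b) - 1) * 100``.  The module
also emits caterpillar-plot data (node-parameter estimates with Wald
confidence whiskers) and cohort descriptive tables with a Wilcoxon rank-sum
comparison between genders.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import UserProfile
from .errors import DomainError, IncompleteFitError
from .piecewise import W_POST, W_PRE
from .tree import LMMTreeFit

__all__ = [
    "percent_change",
    "backtransform_intercept",
    "caterpillar_data",
    "node_summary",
    "descriptive_table",
]


def percent_change(b: float) -> float:
    """Percent change per week implied by a log-scale slope: (exp(b)-1)*100."""
    if not math.isfinite(b):
        raise DomainError(f"slope must be finite, got {b}")
    return (math.exp(b) - 1.0) * 100.0


def backtransform_intercept(b0: float) -> float:
    """Original-units level implied by a log-scale intercept: exp(b0)."""
    if not math.isfinite(b0):
        raise DomainError(f"intercept must be finite, got {b0}")
    return math.exp(b0)


def caterpillar_data(fit: LMMTreeFit, level: float = 0.95) -> pd.DataFrame:
    """Node-specific fixed effects with Wald confidence intervals.

    One row per (terminal node, parameter) with columns ``node_id``,
    ``parameter``, ``estimate``, ``lower``, ``upper``.  Intervals are naive
    Wald intervals from the joint mixed-model fit; no selection adjustment
    is applied.
    """
    if not 0 < level < 1:
        raise DomainError(f"confidence level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for node in fit.terminal_nodes():
        if not node.coefficients:
            raise IncompleteFitError(f"node {node.node_id} has no coefficients")
        for name, coef in node.coefficients.items():
            if coef.get("se") is None:
                raise IncompleteFitError(
                    f"node {node.node_id} parameter '{name}' has no standard error"
                )
            est, se = coef["estimate"], coef["se"]
            rows.append(
                {
                    "node_id": node.node_id,
                    "parameter": name,
                    "estimate": est,
                    "lower": est - z * se,
                    "upper": est + z * se,
                }
            )
    return pd.DataFrame(rows)


def node_summary(fit: LMMTreeFit, back_transform: bool = False) -> pd.DataFrame:
    """One row per terminal node: subgroup rule, size and trajectory.

    With ``back_transform=True`` (log-scale outcomes such as training
    duration) the intercept is exponentiated into original units and each
    slope is expressed as percent change per week.
    """
    rows = []
    for node in fit.terminal_nodes():
        if not node.coefficients:
            raise IncompleteFitError(f"node {node.node_id} has no coefficients")
        path = fit.tree.rule_path(node.node_id)
        row = {
            "node_id": node.node_id,
            "subgroup": " & ".join(path) if path else "all users",
            "n_obs": node.n_obs,
        }
        for name, coef in node.coefficients.items():
            row[name] = coef["estimate"]
            row[f"{name}_se"] = coef["se"]
            row[f"{name}_pvalue"] = coef["pvalue"]
        if back_transform:
            row["intercept_units"] = backtransform_intercept(row["intercept"])
            row[f"{W_PRE}_pct_change"] = percent_change(row[W_PRE])
            row[f"{W_POST}_pct_change"] = percent_change(row[W_POST])
        rows.append(row)
    return pd.DataFrame(rows)


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples; otherwise the normal
    approximation with continuity and tie correction.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (not ties and max(len(x), len(y)) <= 50) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def descriptive_table(
    profiles: list[UserProfile], variables=("age", "bmi"), by: str = "gender"
) -> pd.DataFrame:
    """Cohort descriptives: overall and per-gender N, median, IQR, range,
    mean, SD, plus a Wilcoxon rank-sum p-value comparing the two genders.

    Median and quartiles use linear interpolation.  The group test is
    skipped (p-value ``NaN``, noted in the ``test`` column) when a group has
    fewer than 2 members.
    """
    df = pd.DataFrame([vars(p) for p in profiles])
    groups = ["overall"] + sorted(df[by].unique())
    rows = []
    for var in variables:
        samples = {g: df.loc[df[by] == g, var].to_numpy(float) for g in groups[1:]}
        if len(samples) == 2 and all(len(v) >= 2 for v in samples.values()):
            pval = _wilcoxon_rank_sum(*samples.values())
            note = "wilcoxon rank-sum"
        else:
            pval, note = float("nan"), "skipped: group too small"
        for g in groups:
            vals = df[var].to_numpy(float) if g == "overall" else samples[g]
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "variable": var,
                    "group": g,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "q1": float(np.quantile(vals, 0.25)),
                    "q3": float(np.quantile(vals, 0.75)),
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "wilcoxon_p": pval,
                    "test": note,
                }
            )
    return pd.DataFrame(rows)
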