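"""Joined two-segment (piecewise linear) time basis.

Weekly trajectories are modelled as two straight lines that meet at a
breakpoint week: one slope for the early training period and one for the
later period.  With the time origin at week 1 (``t = week - 1``) and the
breakpoint at week ``c`` (``c_elapsed = c - 1``), the two covariates are

    w_pre  = min(t, c_elapsed)        # weeks elapsed before the break
    w_post = max(t - c_elapsed, 0)    # weeks elapsed after the break

so that ``w_pre + w_post = t`` and any coefficient triple
``(b0, b_pre, b_post)`` implies a mean trajectory that is continuous at the
break.  The intercept is the expected outcome at week 1.  A breakpoint at or
beyond the last observed week makes ``w_post`` identically zero, which is the
single-slope (purely linear) comparator model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["PiecewiseBasis", "piecewise_design", "add_piecewise_columns"]

#: canonical column names appended to long tables
W_PRE, W_POST = "w_pre", "w_post"


@dataclass(frozen=True)
class PiecewiseBasis:
    """Basis values for one week under a given breakpoint."""

    w_pre: float
    w_post: float
    breakpoint_week: float


def piecewise_design(week, breakpoint_week: float):
    """Evaluate the two-segment basis at ``week``.

    Parameters
    ----------
    week : scalar or array-like
        Week index, 1-based; must be >= 1.
    breakpoint_week : float
        Week at which the slope is allowed to change; must be > 1.

    Returns
    -------
    PiecewiseBasis for scalar input, or an ``(w_pre, w_post)`` pair of
    arrays for array input.
    """
    if breakpoint_week <= 1:
        raise DomainError(f"breakpoint_week must exceed 1, got {breakpoint_week}")
    w = np.asarray(week, dtype=float)
    if np.any(w < 1):
        raise DomainError("week indices must be >= 1 (weeks are 1-based)")
    t = w - 1.0
    c = breakpoint_week - 1.0
    w_pre = np.minimum(t, c)
    w_post = np.maximum(t - c, 0.0)
    if np.isscalar(week) or np.ndim(week) == 0:
        return PiecewiseBasis(float(w_pre), float(w_post), float(breakpoint_week))
    return w_pre, w_post


def add_piecewise_columns(
    table: pd.DataFrame, breakpoint_week: float, week_col: str = "week"
) -> pd.DataFrame:
    """Return a copy of ``table`` with ``w_pre``/``w_post`` columns appended."""
    if week_col not in table.columns:
        from .errors import SchemaError

        raise SchemaError(f"column '{week_col}' not found in table")
    w_pre, w_post = piecewise_design(table[week_col].to_numpy(), breakpoint_week)
    out = table.copy()
    out[W_PRE] = w_pre
    out[W_POST] = w_post
    return out
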