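"""Score-based parameter-instability (structural change) tests.

These tests power the splitting decisions of model-based recursive
partitioning: at a node, the fitted model's per-observation score
contributions are examined for systematic fluctuation along each candidate
partitioning variable.  Under parameter stability the scaled cumulative
score process behaves like a Brownian bridge, giving

* numeric variables — the sup-LM statistic: the maximum of the squared
  process norm ``||W(t)||^2 / (t(1-t))`` over the trimmed range
  ``t in [trim, 1-trim]``, evaluated only at admissible cut points
  (boundaries between distinct values of the variable);
* categorical variables — a chi-square statistic aggregating the squared
  within-category score sums, with ``k * (C-1)`` degrees of freedom for a
  k-parameter model and C categories.

The sup-LM null distribution (a functional of a k-dimensional Brownian
bridge) has no closed form; p-values are interpolated from quantile tables
obtained by large-scale simulation and shipped in
``data/suplm_quantiles.json``: the continuum limit (400,000 replicates of
the bridge functional on a 1024-point grid) anchors n = infinity, and exact
finite-n statistic distributions (100,000 replicates each at several n,
computed exactly as this module computes the statistic) correct the
moderate-sample calibration; for a given sample size the p-value
interpolates between the two bracketing tables linearly in 1/n.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import stats

from .errors import SchemaError

__all__ = ["instability_test", "suplm_statistic", "suplm_pvalue", "catl2_test"]

TRIM = 0.10


@lru_cache(maxsize=1)
def _quantile_table() -> dict:
    path = resources.files("lmmtree.data").joinpath("suplm_quantiles.json")
    with path.open() as fh:
        return json.load(fh)


def _pvalue_from_quantiles(stat: float, q: np.ndarray, probs: np.ndarray) -> float:
    if stat <= q[0]:
        return 1.0
    if stat >= q[-1]:
        # log-linear tail through the last tabulated decade
        i = np.searchsorted(probs, 0.99)
        x, y = q[i:], np.log1p(-probs[i:])
        slope = np.polyfit(x, y, 1)[0]
        return float(np.exp(np.log1p(-probs[-1]) + slope * (stat - q[-1])))
    return float(1.0 - np.interp(stat, q, probs))


def suplm_pvalue(stat: float, k: int, n: int | None = None) -> float:
    """Tail probability of the trimmed sup-LM null distribution.

    ``n`` is the number of score rows entering the statistic; when given,
    the p-value interpolates (linearly in 1/n) between the bracketing
    finite-n quantile tables, with the continuum limit anchoring
    n = infinity.  Beyond the tabulated range the upper tail is extrapolated
    linearly on the log scale.
    """
    table = _quantile_table()
    ks = sorted(int(s) for s in table["limit"])
    if k > max(ks):
        raise ValueError(f"sup-LM table only covers k <= {max(ks)}, got k={k}")
    probs = np.asarray(table["probs"])
    q_limit = np.asarray(table["limit"][str(k)])
    if n is None:
        return _pvalue_from_quantiles(stat, q_limit, probs)
    n_values = sorted(table["n_values"])
    if n <= n_values[0]:
        q = np.asarray(table["finite"][f"{k},{n_values[0]}"])
        return _pvalue_from_quantiles(stat, q, probs)
    if n >= n_values[-1]:
        lo_n, lo_q = n_values[-1], np.asarray(table["finite"][f"{k},{n_values[-1]}"])
        hi_inv, hi_p = 0.0, _pvalue_from_quantiles(stat, q_limit, probs)
    else:
        j = np.searchsorted(n_values, n)
        lo_n = n_values[j - 1]
        hi_n = n_values[j]
        lo_q = np.asarray(table["finite"][f"{k},{lo_n}"])
        hi_inv = 1.0 / hi_n
        hi_p = _pvalue_from_quantiles(stat, np.asarray(table["finite"][f"{k},{hi_n}"]), probs)
    lo_p = _pvalue_from_quantiles(stat, lo_q, probs)
    w = (1.0 / lo_n - 1.0 / n) / (1.0 / lo_n - hi_inv)
    return float((1 - w) * lo_p + w * hi_p)


def _scaled_scores(scores: np.ndarray) -> tuple[np.ndarray, int]:
    """Whiten scores by the outer-product information estimate."""
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    n, k = s.shape
    info = s.T @ s / n
    # root inverse; singular information means the node model is degenerate
    evals, evecs = np.linalg.eigh(info)
    if np.min(evals) <= 1e-12 * np.max(evals):
        return None, k  # type: ignore[return-value]
    root_inv = evecs @ np.diag(evals**-0.5) @ evecs.T
    return s @ root_inv / np.sqrt(n), k


def suplm_statistic(scores: np.ndarray, z: np.ndarray, trim: float = TRIM):
    """Trimmed sup-LM statistic of scores ordered by a numeric variable.

    Returns ``(stat, k)``; ``stat`` is ``nan`` when no admissible cut point
    falls inside the trimmed range or the information matrix is singular.
    """
    z = np.asarray(z)
    if len(z) != len(scores):
        raise SchemaError("scores and z must have equal length")
    w, k = _scaled_scores(scores)
    if w is None:
        return np.nan, k
    order = np.argsort(z, kind="stable")
    zs = z[order]
    cs = np.cumsum(w[order], axis=0)
    n = len(zs)
    i = np.arange(1, n + 1)
    t = i / n
    admissible = (t >= trim) & (t <= 1 - trim)
    # a cut is only possible between distinct z values
    admissible[:-1] &= zs[1:] != zs[:-1]
    admissible[-1] = False
    if not np.any(admissible):
        return np.nan, k
    norm2 = np.sum(cs[admissible] ** 2, axis=1)
    ta = t[admissible]
    return float(np.max(norm2 / (ta * (1 - ta)))), k


def catl2_test(scores: np.ndarray, z: np.ndarray):
    """Chi-square instability statistic for a categorical variable.

    Returns ``(stat, df, pvalue)``.
    """
    z = np.asarray(z)
    if len(z) != len(scores):
        raise SchemaError("scores and z must have equal length")
    w, k = _scaled_scores(scores)
    cats = np.unique(z)
    if w is None or len(cats) < 2:
        return np.nan, 0, 1.0
    n = len(z)
    stat = 0.0
    for c in cats:
        mask = z == c
        s_c = w[mask].sum(axis=0)
        stat += float(s_c @ s_c) / (mask.sum() / n)
    df = k * (len(cats) - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def instability_test(scores: np.ndarray, z: np.ndarray, trim: float = TRIM) -> float:
    """p-value for parameter instability along the variable ``z``.

    ``scores`` is the (n, k) matrix of per-observation model-score
    contributions at the node estimate (they sum to ~0 column-wise).
    Numeric ``z`` uses the trimmed sup-LM test; categorical (non-numeric
    dtype or boolean) ``z`` uses the chi-square category aggregation.
    Variables with fewer than 2 distinct values are untestable (p = 1).
    """
    z = np.asarray(z)
    if len(np.unique(z)) < 2:
        return 1.0
    if z.dtype.kind in "OUSb":
        return catl2_test(scores, z)[2]
    stat, k = suplm_statistic(scores, z, trim=trim)
    if not np.isfinite(stat):
        return 1.0
    if abs(trim - TRIM) > 1e-9:
        raise ValueError(f"p-values are tabulated for trim={TRIM} only")
    return suplm_pvalue(stat, k, n=len(z))
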