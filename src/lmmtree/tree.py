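"""Piecewise linear mixed-effects model trees.

The estimator alternates between two stages until the joint log-likelihood
stabilizes:

1. **Partitioning** — with the current random-effect predictions subtracted
   from the outcome, a model-based recursive partition is grown over the
   user-level moderators.  Each node fits the piecewise trajectory model
   ``y* ~ 1 + w_pre + w_post`` by least squares, tests its parameters for
   instability along every candidate moderator (sup-LM for numeric,
   chi-square category aggregation for binary categorical, Bonferroni across
   moderators), and splits on the most unstable moderator at the point
   minimizing the children's summed residual sum of squares.  Growth stops
   at non-significant instability, the ``minsplit`` size floor, or
   ``maxdepth``.

2. **Mixed-model estimation** — a linear mixed model whose fixed effects are
   terminal-node indicators interacted with ``(1, w_pre, w_post)`` and whose
   random part is a global user-level random intercept plus random slope on
   ``w_pre`` is fitted by maximum likelihood; its BLUPs feed the next
   partitioning pass.

Random effects are strictly global: they are estimated once per alternation
for the whole sample and never re-estimated within nodes, so subgroups
differ only in their fixed-effect trajectories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InvalidConfigError,
    InvalidModeratorError,
    SchemaError,
    UnsupportedModeratorError,
)
from .instability import instability_test
from .lmm import LMMFit, fit_lmm, predict_lmm
from .piecewise import W_POST, W_PRE, add_piecewise_columns

logger = logging.getLogger(__name__)

__all__ = [
    "TreeControl",
    "TreeNode",
    "LMMTreeFit",
    "fit_lmm_tree",
    "grow_mob",
    "find_split",
    "predict_tree",
    "format_tree",
]

N_NODE_PARAMS = 3  # intercept, w_pre, w_post


@dataclass(frozen=True)
class TreeControl:
    """Prepruning and convergence settings for tree growth."""

    alpha: float = 0.05
    bonferroni: bool = True
    minsplit: int = 90
    maxdepth: int = 5
    max_iter: int = 100
    tol: float = 1e-4
    trim: float = 0.10

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.minsplit < 2 * N_NODE_PARAMS:
            raise InvalidConfigError(
                f"minsplit must be >= {2 * N_NODE_PARAMS} "
                f"(twice the node-model parameter count), got {self.minsplit}"
            )
        if self.maxdepth < 1:
            raise InvalidConfigError(f"maxdepth must be >= 1, got {self.maxdepth}")
        if self.max_iter < 1:
            raise InvalidConfigError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol <= 0:
            raise InvalidConfigError(f"tol must be positive, got {self.tol}")


@dataclass
class TreeNode:
    """One node of the recursive partition (root has id 1, children 2k/2k+1)."""

    node_id: int
    n_obs: int
    depth: int
    split_variable: str | None = None
    split_point: object | None = None  # float threshold or frozenset of categories
    children: tuple["TreeNode", "TreeNode"] | None = None
    coefficients: dict | None = None  # name -> {estimate, se, pvalue}
    instability_pvalues: dict | None = None

    @property
    def is_terminal(self) -> bool:
        return self.children is None

    def terminal_nodes(self) -> list["TreeNode"]:
        if self.is_terminal:
            return [self]
        return [t for child in self.children for t in child.terminal_nodes()]

    def rule_path(self, target_id: int, _prefix=()) -> list[str]:
        """Human-readable split conditions from the root to ``target_id``."""
        if self.node_id == target_id:
            return list(_prefix)
        if self.is_terminal:
            return []
        left, right = self.children
        if isinstance(self.split_point, frozenset):
            cond_l = f"{self.split_variable} in {{{', '.join(sorted(self.split_point))}}}"
            cond_r = f"{self.split_variable} not in {{{', '.join(sorted(self.split_point))}}}"
        else:
            cond_l = f"{self.split_variable} <= {self.split_point:g}"
            cond_r = f"{self.split_variable} > {self.split_point:g}"
        return self.children[0].rule_path(target_id, (*_prefix, cond_l)) or \
            self.children[1].rule_path(target_id, (*_prefix, cond_r))


def _route_mask(node: TreeNode, data: pd.DataFrame) -> np.ndarray:
    """Boolean mask of rows going to the *left* child of ``node``."""
    z = data[node.split_variable]
    if isinstance(node.split_point, frozenset):
        return z.isin(node.split_point).to_numpy()
    return (z.to_numpy(dtype=float) <= node.split_point)


def assign_terminal_nodes(tree: TreeNode, data: pd.DataFrame) -> np.ndarray:
    """Terminal node id for every row of ``data``."""
    out = np.empty(len(data), dtype=int)

    def descend(node: TreeNode, idx: np.ndarray):
        if node.is_terminal:
            out[idx] = node.node_id
            return
        if node.split_variable not in data.columns:
            raise SchemaError(f"moderator column '{node.split_variable}' missing")
        left = _route_mask(node, data.iloc[idx])
        descend(node.children[0], idx[left])
        descend(node.children[1], idx[~left])

    descend(tree, np.arange(len(data)))
    return out


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _ssr_profile(X: np.ndarray, y: np.ndarray):
    """SSR of the node model on every prefix/suffix of the (sorted) rows.

    Returns arrays ``ssr_left[i]``/``ssr_right[i]`` for a cut after row i
    (1-based prefix length i+1 ... ), computed from cumulative sufficient
    statistics; singular prefixes fall back to pseudo-inverse solutions.
    """
    n, k = X.shape
    xxt = np.einsum("ni,nj->nij", X, X)
    A = np.cumsum(xxt, axis=0)
    b = np.cumsum(X * y[:, None], axis=0)
    s = np.cumsum(y * y)
    A_tot, b_tot, s_tot = A[-1], b[-1], s[-1]

    def explained(Amat, bvec):
        try:
            sol = np.linalg.solve(Amat, bvec[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack([
                np.linalg.lstsq(Amat[i], bvec[i], rcond=None)[0] for i in range(len(bvec))
            ])
        return np.einsum("ni,ni->n", bvec, sol)

    expl_left = explained(A, b)
    expl_right = explained(A_tot[None] - A, b_tot[None] - b)
    ssr_left = np.maximum(s - expl_left, 0.0)
    ssr_right = np.maximum((s_tot - s) - expl_right, 0.0)
    return ssr_left, ssr_right


def find_split(
    X: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    minsplit: int,
):
    """Best admissible split of a node along one moderator.

    ``X``/``y`` are the node-model design and (adjusted) outcome; ``z`` the
    moderator.  Numeric moderators are scanned exhaustively over midpoints of
    adjacent distinct values; a binary categorical moderator has its single
    split.  The objective is the sum of the two children's node-model
    residual sums of squares; both children must contain at least
    ``minsplit`` observations.  Ties go to the smaller threshold.

    Returns ``(split_point, objective)`` or ``None`` when no admissible
    split exists.
    """
    z = np.asarray(z)
    n = len(z)
    if z.dtype.kind in "OUSb":
        levels = sorted(pd.unique(z))
        if len(levels) != 2:
            return None
        left = frozenset([levels[0]])
        mask = np.isin(z, list(left))
        if mask.sum() < minsplit or (~mask).sum() < minsplit:
            return None
        order = np.argsort(~mask, kind="stable")  # left block first
        ssr_l, ssr_r = _ssr_profile(X[order], y[order])
        cut = int(mask.sum()) - 1
        return left, float(ssr_l[cut] + ssr_r[cut])

    order = np.argsort(z, kind="stable")
    zs = z[order].astype(float)
    ssr_l, ssr_r = _ssr_profile(X[order], y[order])
    i = np.arange(1, n + 1)  # size of the left child for a cut after row i-1
    admissible = (i >= minsplit) & (n - i >= minsplit)
    admissible[:-1] &= zs[1:] != zs[:-1]
    admissible[-1] = False
    if not np.any(admissible):
        return None
    idx = np.flatnonzero(admissible)
    objective = ssr_l[idx] + ssr_r[idx]
    best = idx[int(np.argmin(objective))]  # argmin takes the first = smallest threshold
    threshold = 0.5 * (zs[best] + zs[best + 1])
    return float(threshold), float(objective[int(np.argmin(objective))])


# ---------------------------------------------------------------------------
# model-based tree growth on the adjusted outcome
# ---------------------------------------------------------------------------

def _node_model(X: np.ndarray, y: np.ndarray):
    """OLS fit of the node model; returns (beta, residuals, full_rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta, rank == X.shape[1]

def grow_mob(
    data: pd.DataFrame,
    ystar: np.ndarray,
    partitioning_vars: list[str],
    control: TreeControl,
    group_col: str = "user_id",
    node_id: int = 1,
    depth: int = 1,
) -> TreeNode:
    """Grow a model-based recursive partition on the adjusted outcome.

    ``data`` must carry the basis columns, the moderators and the grouping
    column; ``ystar`` is the outcome with the current random-effect
    predictions removed.  Instability is tested on score contributions
    aggregated within user (cluster-robust): moderators are user-constant,
    and repeated measures from one user are correlated, so observation-level
    fluctuation tests would drastically overstate the evidence for a split.
    """
    X = np.column_stack(
        [np.ones(len(data)), data[W_PRE].to_numpy(float), data[W_POST].to_numpy(float)]
    )
    node = TreeNode(node_id=node_id, n_obs=len(data), depth=depth)
    beta, resid, full_rank = _node_model(X, ystar)
    node.coefficients = {
        name: {"estimate": float(b), "se": None, "pvalue": None}
        for name, b in zip(("intercept", W_PRE, W_POST), beta)
    }
    if not full_rank:
        logger.warning("node %d: rank-deficient node design; forced terminal", node_id)
        return node
    if len(data) < control.minsplit or depth >= control.maxdepth:
        return node

    scores = X * resid[:, None]
    groups = data[group_col].to_numpy()
    uniq, first_idx, inv = np.unique(groups, return_index=True, return_inverse=True)
    agg_scores = np.zeros((len(uniq), X.shape[1]))
    np.add.at(agg_scores, inv, scores)
    testable = [v for v in partitioning_vars if data[v].nunique() > 1]
    pvals = {}
    m = len(testable)
    for v in partitioning_vars:
        if v not in testable:
            pvals[v] = 1.0
            continue
        z_user = data[v].to_numpy()[first_idx]
        p = instability_test(agg_scores, z_user, trim=control.trim)
        pvals[v] = min(1.0, p * m) if control.bonferroni else p
    node.instability_pvalues = pvals
    if not testable:
        return node

    best_var = min(testable, key=lambda v: (pvals[v], partitioning_vars.index(v)))
    if pvals[best_var] >= control.alpha:
        return node
    split = find_split(X, ystar, data[best_var].to_numpy(), control.minsplit)
    if split is None:
        return node
    split_point, _ = split
    node.split_variable = best_var
    node.split_point = split_point
    left_mask = _route_mask(node, data)
    node.children = (
        grow_mob(data[left_mask], ystar[left_mask], partitioning_vars, control,
                 group_col=group_col, node_id=2 * node_id, depth=depth + 1),
        grow_mob(data[~left_mask], ystar[~left_mask], partitioning_vars, control,
                 group_col=group_col, node_id=2 * node_id + 1, depth=depth + 1),
    )
    return node


# ---------------------------------------------------------------------------
# joint fit: alternation between tree growth and mixed-model estimation
# ---------------------------------------------------------------------------

@dataclass
class LMMTreeFit:
    """A fitted piecewise mixed-effects model tree."""

    tree: TreeNode
    lmm: LMMFit
    n_alternations: int
    loglik_trace: list[float]
    converged: bool
    outcome_col: str
    partitioning_vars: list[str]
    breakpoint_week: float
    control: TreeControl
    group_col: str = "user_id"

    @property
    def aic(self) -> float:
        return self.lmm.aic

    @property
    def loglik(self) -> float:
        return self.lmm.loglik

    def terminal_nodes(self) -> list[TreeNode]:
        return self.tree.terminal_nodes()

    def to_json(self, path=None) -> str:
        payload = {
            "tree": _node_to_dict(self.tree),
            "lmm": json.loads(self.lmm.to_json()),
            "n_alternations": self.n_alternations,
            "loglik_trace": self.loglik_trace,
            "converged": self.converged,
            "outcome_col": self.outcome_col,
            "partitioning_vars": self.partitioning_vars,
            "breakpoint_week": self.breakpoint_week,
            "control": vars(self.control),
            "group_col": self.group_col,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LMMTreeFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            tree=_node_from_dict(payload["tree"]),
            lmm=LMMFit.from_json(json.dumps(payload["lmm"])),
            n_alternations=payload["n_alternations"],
            loglik_trace=payload["loglik_trace"],
            converged=payload["converged"],
            outcome_col=payload["outcome_col"],
            partitioning_vars=payload["partitioning_vars"],
            breakpoint_week=payload["breakpoint_week"],
            control=TreeControl(**payload["control"]),
            group_col=payload["group_col"],
        )


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "node_id": node.node_id,
        "n_obs": node.n_obs,
        "depth": node.depth,
        "split_variable": node.split_variable,
        "split_point": (
            sorted(node.split_point) if isinstance(node.split_point, frozenset)
            else node.split_point
        ),
        "coefficients": node.coefficients,
        "instability_pvalues": node.instability_pvalues,
    }
    if node.children is not None:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    sp = d["split_point"]
    if isinstance(sp, list):
        sp = frozenset(sp)
    node = TreeNode(
        node_id=d["node_id"], n_obs=d["n_obs"], depth=d["depth"],
        split_variable=d["split_variable"], split_point=sp,
        coefficients=d["coefficients"], instability_pvalues=d["instability_pvalues"],
    )
    if "children" in d:
        node.children = tuple(_node_from_dict(c) for c in d["children"])
    return node


def _validate_moderators(data: pd.DataFrame, partitioning_vars, group_col: str):
    for v in partitioning_vars:
        if v not in data.columns:
            raise SchemaError(f"moderator column '{v}' missing from table")
        if (data.groupby(group_col, sort=False)[v].nunique(dropna=False) > 1).any():
            raise InvalidModeratorError(
                f"moderator '{v}' is not constant within user"
            )
        if data[v].dtype.kind in "OUSb":
            n_levels = data[v].nunique()
            if n_levels > 2:
                raise UnsupportedModeratorError(
                    f"categorical moderator '{v}' has {n_levels} levels; "
                    "only binary categorical moderators are supported"
                )


def _node_design(data: pd.DataFrame, tree: TreeNode):
    """Terminal-node indicators interacted with (1, w_pre, w_post)."""
    assignment = assign_terminal_nodes(tree, data)
    design = pd.DataFrame(index=data.index)
    cols = []
    for t in tree.terminal_nodes():
        ind = (assignment == t.node_id).astype(float)
        design[f"node{t.node_id}"] = ind
        design[f"node{t.node_id}:{W_PRE}"] = ind * data[W_PRE].to_numpy(float)
        design[f"node{t.node_id}:{W_POST}"] = ind * data[W_POST].to_numpy(float)
        cols += [f"node{t.node_id}", f"node{t.node_id}:{W_PRE}", f"node{t.node_id}:{W_POST}"]
    return design, cols, assignment


def fit_lmm_tree(
    table: pd.DataFrame,
    outcome: str,
    partitioning_vars: list[str],
    control: TreeControl = TreeControl(),
    breakpoint_week: float = 3,
    method: str = "ml",
    group_col: str = "user_id",
) -> LMMTreeFit:
    """Fit a piecewise mixed-effects model tree.

    Alternates tree growth on the random-effect-adjusted outcome with the
    joint mixed-model fit until the log-likelihood changes by less than
    ``control.tol`` (or ``control.max_iter`` alternations); non-convergence
    is reported through ``converged=False``, never raised.
    """
    if outcome not in table.columns:
        raise SchemaError(f"outcome column '{outcome}' not found")
    data = table.dropna(subset=[outcome]).reset_index(drop=True)
    _validate_moderators(data, partitioning_vars, group_col)
    if W_PRE not in data.columns or W_POST not in data.columns:
        data = add_piecewise_columns(data, breakpoint_week)
    y = data[outcome].to_numpy(float)

    random_part = np.zeros(len(data))
    trace: list[float] = []
    tree = None
    fit = None
    converged = False
    n_iter = 0
    for n_iter in range(1, control.max_iter + 1):
        tree = grow_mob(data, y - random_part, partitioning_vars, control,
                        group_col=group_col)
        design, cols, _ = _node_design(data, tree)
        aug = pd.concat([data, design], axis=1)
        fit = fit_lmm(
            aug, outcome, cols, random_slope_on=W_PRE, method=method,
            group_col=group_col, include_intercept=False,
        )
        trace.append(fit.loglik)
        users = data[group_col]
        u0 = users.map(fit.blups["intercept"]).fillna(0.0).to_numpy()
        u1 = users.map(fit.blups["slope"]).fillna(0.0).to_numpy()
        random_part = u0 + u1 * data[W_PRE].to_numpy(float)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < control.tol:
            converged = True
            break

    # final coefficients (with SEs and Wald p-values) come from the joint fit
    for t in tree.terminal_nodes():
        t.coefficients = {}
        for short, col in (
            ("intercept", f"node{t.node_id}"),
            (W_PRE, f"node{t.node_id}:{W_PRE}"),
            (W_POST, f"node{t.node_id}:{W_POST}"),
        ):
            t.coefficients[short] = {
                "estimate": float(fit.beta[col]),
                "se": float(fit.se[col]),
                "pvalue": float(fit.pvalues[col]) if fit.pvalues is not None else None,
            }
    return LMMTreeFit(
        tree=tree,
        lmm=fit,
        n_alternations=n_iter,
        loglik_trace=trace,
        converged=converged and fit.converged,
        outcome_col=outcome,
        partitioning_vars=list(partitioning_vars),
        breakpoint_week=breakpoint_week,
        control=control,
        group_col=group_col,
    )


def predict_tree(fit: LMMTreeFit, newdata: pd.DataFrame, include_random: bool = True) -> np.ndarray:
    """Predict outcomes for ``newdata`` under a fitted tree.

    Rows are routed to their terminal node and the node's piecewise fixed
    effects applied; with ``include_random=True`` the per-user random
    intercept/slope predictions are added for users seen at fit time (unseen
    users get the population prediction).
    """
    data = newdata
    if W_PRE not in data.columns or W_POST not in data.columns:
        data = add_piecewise_columns(data, fit.breakpoint_week)
    design, cols, _ = _node_design(data, fit.tree)
    aug = pd.concat([data.reset_index(drop=True), design.reset_index(drop=True)], axis=1)
    return predict_lmm(fit.lmm, aug, include_random=include_random)


def format_tree(fit: LMMTreeFit, digits: int = 3) -> str:
    """Plain-text rendering of the fitted partition (root at the top)."""
    lines = [
        f"Piecewise mixed-effects model tree: {fit.outcome_col} ~ "
        f"{W_PRE} + {W_POST} | (1 + {W_PRE} | {fit.group_col}) "
        f"| {' + '.join(fit.partitioning_vars)}",
        f"breakpoint week {fit.breakpoint_week:g}; "
        f"{len(fit.terminal_nodes())} terminal node(s); AIC {fit.aic:.2f}",
    ]

    def render(node: TreeNode, indent: str, label: str):
        head = f"{indent}[{node.node_id}] {label} (n={node.n_obs})"
        if node.is_terminal and node.coefficients:
            coefs = ", ".join(
                f"{k}={v['estimate']:.{digits}f}" for k, v in node.coefficients.items()
            )
            head += f": {coefs}"
        lines.append(head)
        if not node.is_terminal:
            if isinstance(node.split_point, frozenset):
                cl = f"{node.split_variable} in {{{', '.join(sorted(node.split_point))}}}"
                cr = f"{node.split_variable} not in {{{', '.join(sorted(node.split_point))}}}"
            else:
                cl = f"{node.split_variable} <= {node.split_point:.{digits}f}"
                cr = f"{node.split_variable} > {node.split_point:.{digits}f}"
            render(node.children[0], indent + "  ", cl)
            render(node.children[1], indent + "  ", cr)

    render(fit.tree, "", "root")
    return "\n".join(lines)
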