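import numpy as np
import pandas as pd
import pytest

import lmmtree as lt
from lmmtree.errors import (
    InvalidConfigError,
    InvalidModeratorError,
    UnsupportedModeratorError,
)
from lmmtree.lmm import LMMFit
from lmmtree.piecewise import add_piecewise_columns
from lmmtree.tree import (
    LMMTreeFit,
    TreeNode,
    assign_terminal_nodes,
    find_split,
    format_tree,
    grow_mob,
)


def _node_X(weeks):
    w_pre = np.minimum(weeks - 1, 2.0)
    w_post = np.maximum(weeks - 3.0, 0.0)
    return np.column_stack([np.ones(len(weeks)), w_pre, w_post])


def _ssr(X, y):
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return float(np.sum((y - X @ beta) ** 2))


def brute_force_split(X, y, z, minsplit):
    """Independent enumeration of every candidate numeric split."""
    best = None
    for lo, hi in zip(np.unique(z)[:-1], np.unique(z)[1:]):
        thr = (lo + hi) / 2
        mask = z <= thr
        if mask.sum() < minsplit or (~mask).sum() < minsplit:
            continue
        obj = _ssr(X[mask], y[mask]) + _ssr(X[~mask], y[~mask])
        if best is None or obj < best[1] - 1e-12:
            best = (thr, obj)
    return best


class TestFindSplit:
    def test_intercept_jump_toy_node(self):
        rng = np.random.default_rng(0)
        z = np.repeat([1.0, 2.0, 3.0, 4.0], 30)
        weeks = np.tile(np.arange(1.0, 9.0), 15)
        X = _node_X(weeks)
        y = np.where(z >= 3, 10.0, 0.0) + 0.01 * rng.standard_normal(len(z))
        got = find_split(X, y, z, minsplit=10)
        assert got is not None and got[0] == 2.5

    def test_tie_prefers_smaller_threshold(self):
        # perfectly symmetric node: every candidate split has the same objective
        z = np.repeat([1.0, 2.0, 3.0], 16)
        weeks = np.tile(np.arange(1.0, 9.0), 6)
        X = _node_X(weeks)
        y = np.zeros(len(z))
        got = find_split(X, y, z, minsplit=8)
        assert got is not None and got[0] == 1.5

    def test_minsplit_blocks_split(self):
        z = np.repeat([1.0, 2.0], 20)
        weeks = np.tile(np.arange(1.0, 9.0), 5)
        got = find_split(_node_X(weeks), np.zeros(40), z, minsplit=25)
        assert got is None

    def test_matches_brute_force_on_random_nodes(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_vals = rng.integers(3, 10)
            z = rng.choice(np.round(rng.normal(40, 10, n_vals), 1), size=160)
            weeks = np.tile(np.arange(1.0, 9.0), 20)
            X = _node_X(weeks)
            y = rng.standard_normal(160) + 0.2 * z
            got = find_split(X, y, z, minsplit=10)
            want = brute_force_split(X, y, z, minsplit=10)
            if want is None:
                assert got is None
            else:
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1], rel=1e-8)

    def test_binary_categorical_split(self):
        z = np.array(["female"] * 80 + ["male"] * 80)
        weeks = np.tile(np.arange(1.0, 9.0), 20)
        X = _node_X(weeks)
        y = np.where(z == "male", 10.0, 0.0)
        got = find_split(X, y, z, minsplit=10)
        assert got is not None and got[0] == frozenset({"female"})


class TestTreeControl:
    def test_invalid_settings_rejected(self):
        with pytest.raises(InvalidConfigError):
            lt.TreeControl(alpha=0.0)
        with pytest.raises(InvalidConfigError):
            lt.TreeControl(minsplit=4)
        with pytest.raises(InvalidConfigError):
            lt.TreeControl(maxdepth=0)


class TestGrowMob:
    def _frame(self, n_users=60, seed=0, gender_shift=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for uid in range(n_users):
            gender = "female" if uid % 2 == 0 else "male"
            base = gender_shift if gender == "male" else 0.0
            for week in range(1, 9):
                rows.append((uid, week, gender, 40 + (uid % 7)))
        df = pd.DataFrame(rows, columns=["user_id", "week", "gender", "age"])
        df = add_piecewise_columns(df, 3)
        y = np.where(df["gender"] == "male", gender_shift, 0.0)
        y = y + 0.1 * rng.standard_normal(len(df))
        return df, y

    def test_small_node_is_terminal(self):
        df, y = self._frame(n_users=10)
        tree = grow_mob(df, y, ["age", "gender"], lt.TreeControl(minsplit=90))
        assert tree.is_terminal

    def test_constant_moderators_terminal(self):
        df, y = self._frame(gender_shift=10.0)
        df["gender"] = "female"
        df["age"] = 50.0
        tree = grow_mob(df, y, ["age", "gender"], lt.TreeControl(minsplit=16))
        assert tree.is_terminal

    def test_gender_shift_splits_on_gender(self):
        df, y = self._frame(gender_shift=10.0)
        tree = grow_mob(df, y, ["age", "gender"], lt.TreeControl(minsplit=16, maxdepth=2))
        assert tree.split_variable == "gender"
        assert tree.instability_pvalues["gender"] < 1e-4
        left, right = tree.children
        assert left.n_obs + right.n_obs == tree.n_obs


class TestFitLMMTree:
    def test_recovers_planted_age_split(self, split_tree_fit):
        root = split_tree_fit.tree
        assert root.split_variable == "age"
        assert 37 <= root.split_point <= 43

    def test_partition_consistency(self, split_cohort, split_tree_fit):
        table, _ = split_cohort
        data = add_piecewise_columns(table, 3)
        ids = assign_terminal_nodes(split_tree_fit.tree, data)
        terminals = {t.node_id: t.n_obs for t in split_tree_fit.terminal_nodes()}
        assert set(np.unique(ids)) == set(terminals)
        assert sum(terminals.values()) == len(data)
        for nid, count in zip(*np.unique(ids, return_counts=True)):
            assert terminals[nid] == count

    def test_loglik_trace_nondecreasing(self, split_tree_fit):
        trace = np.asarray(split_tree_fit.loglik_trace)
        assert np.all(np.diff(trace) >= -10 * split_tree_fit.control.tol)
        assert split_tree_fit.converged

    def test_maxdepth_one_equals_pooled_lmm(self, split_cohort):
        table, _ = split_cohort
        fit = lt.fit_lmm_tree(
            table, "outcome", ["age", "gender", "bmi"],
            control=lt.TreeControl(minsplit=90, maxdepth=1),
        )
        assert len(fit.terminal_nodes()) == 1
        data = add_piecewise_columns(table, 3)
        pooled = lt.fit_lmm(data, "outcome", ["w_pre", "w_post"])
        coefs = fit.tree.coefficients
        assert coefs["intercept"]["estimate"] == pytest.approx(
            pooled.beta["Intercept"], abs=1e-3)
        assert coefs["w_pre"]["estimate"] == pytest.approx(pooled.beta["w_pre"], abs=1e-3)
        pred_tree = lt.predict_tree(fit, table, include_random=False)
        pred_lmm = lt.predict_lmm(pooled, data, include_random=False)
        assert np.allclose(pred_tree, pred_lmm, atol=1e-2)

    def test_zero_variance_reduces_to_plain_mob(self):
        rules = (
            lt.SubgroupRule(lt.TrajectoryParams(5.0, -0.5, 0.0), age=(None, 40.0)),
            lt.SubgroupRule(lt.TrajectoryParams(5.0, 0.5, 0.0), age=(40.0, None)),
        )
        cfg = lt.SimulationConfig(
            n_users=250, seed=5, outcome_kind="pain", subgroup_rules=rules,
            variance=lt.VarianceComponents(0.0, 0.0, 0.0, 0.3),
        )
        table = lt.simulate_cohort(cfg)
        control = lt.TreeControl(minsplit=90, maxdepth=3)
        fit = lt.fit_lmm_tree(table, "outcome", ["age", "gender", "bmi"], control=control)
        data = add_piecewise_columns(table, 3)
        raw_tree = grow_mob(data, data["outcome"].to_numpy(), ["age", "gender", "bmi"],
                            control)

        def structure(node):
            if node.is_terminal:
                return ("leaf",)
            return (node.split_variable, round(float(node.split_point), 6),
                    structure(node.children[0]), structure(node.children[1]))

        assert structure(fit.tree) == structure(raw_tree)

    def test_moderator_validation(self, split_cohort):
        table, _ = split_cohort
        with pytest.raises(InvalidModeratorError):
            lt.fit_lmm_tree(table, "outcome", ["week"])
        bad = table.copy()
        levels = {0: "a", 1: "b", 2: "c"}
        bad["city"] = bad["user_id"].map(lambda u: levels[u % 3])
        with pytest.raises(UnsupportedModeratorError):
            lt.fit_lmm_tree(bad, "outcome", ["city"])

    def test_serialization_round_trip(self, split_cohort, split_tree_fit, tmp_path):
        table, _ = split_cohort
        path = tmp_path / "model.json"
        split_tree_fit.to_json(path)
        loaded = LMMTreeFit.from_json(path)
        a = lt.predict_tree(split_tree_fit, table, include_random=True)
        b = lt.predict_tree(loaded, table, include_random=True)
        assert np.allclose(a, b)
        text = format_tree(loaded)
        assert "age" in text and "terminal node" in text


def _fixture_tree_fit():
    """Hand-built depth-2 tree with printed week-1 pain levels as intercepts."""
    leaves = {
        2: 5.173,
        6: 5.383,
        7: 5.260,
    }
    n2 = TreeNode(node_id=2, n_obs=80, depth=2,
                  coefficients={"intercept": {"estimate": 5.173, "se": 0.1, "pvalue": 0.0},
                                "w_pre": {"estimate": -0.4, "se": 0.1, "pvalue": 0.0},
                                "w_post": {"estimate": 0.0, "se": 0.1, "pvalue": 0.9}})
    n6 = TreeNode(node_id=6, n_obs=80, depth=3,
                  coefficients={"intercept": {"estimate": 5.383, "se": 0.1, "pvalue": 0.0},
                                "w_pre": {"estimate": -0.3, "se": 0.1, "pvalue": 0.0},
                                "w_post": {"estimate": 0.05, "se": 0.1, "pvalue": 0.02}})
    n7 = TreeNode(node_id=7, n_obs=80, depth=3,
                  coefficients={"intercept": {"estimate": 5.260, "se": 0.1, "pvalue": 0.0},
                                "w_pre": {"estimate": -0.5, "se": 0.1, "pvalue": 0.0},
                                "w_post": {"estimate": 0.0, "se": 0.1, "pvalue": 0.3}})
    n3 = TreeNode(node_id=3, n_obs=160, depth=2, split_variable="age",
                  split_point=66.0, children=(n6, n7))
    root = TreeNode(node_id=1, n_obs=240, depth=1, split_variable="age",
                    split_point=17.0, children=(n2, n3))
    beta = {}
    for nid, intercept in leaves.items():
        node = {2: n2, 6: n6, 7: n7}[nid]
        beta[f"node{nid}"] = node.coefficients["intercept"]["estimate"]
        beta[f"node{nid}:w_pre"] = node.coefficients["w_pre"]["estimate"]
        beta[f"node{nid}:w_post"] = node.coefficients["w_post"]["estimate"]
    beta = pd.Series(beta)
    lmm = LMMFit(
        beta=beta, se=pd.Series(0.1, index=beta.index),
        varcomp=lt.VarianceComponents(0, 0, 0, 1),
        blups=pd.DataFrame(columns=["intercept", "slope"]),
        loglik=-100.0, aic=226.0, n_obs=240, n_params=13, converged=True,
        method="ml", outcome_col="outcome", fixed_cols=list(beta.index),
        random_slope_on="w_pre",
    )
    return LMMTreeFit(
        tree=root, lmm=lmm, n_alternations=1, loglik_trace=[-100.0],
        converged=True, outcome_col="outcome",
        partitioning_vars=["age"], breakpoint_week=3,
        control=lt.TreeControl(minsplit=90),
    )


class TestPredictTree:
    def test_week1_prediction_equals_node_intercept(self):
        fit = _fixture_tree_fit()
        newdata = pd.DataFrame(
            {"user_id": [1, 2, 3], "week": [1, 1, 1], "age": [15.0, 50.0, 70.0]}
        )
        pred = lt.predict_tree(fit, newdata, include_random=False)
        assert np.allclose(pred, [5.173, 5.383, 5.260])

    def test_routing_uses_both_levels(self):
        fit = _fixture_tree_fit()
        newdata = pd.DataFrame(
            {"user_id": [1, 2], "week": [3, 3], "age": [60.0, 70.0]}
        )
        pred = lt.predict_tree(fit, newdata, include_random=False)
        assert pred[0] == pytest.approx(5.383 - 0.3 * 2)
        assert pred[1] == pytest.approx(5.260 - 0.5 * 2)

    def test_unseen_user_random_equals_fixed(self, split_cohort, split_tree_fit):
        table, _ = split_cohort
        new = table.head(8).copy()
        new["user_id"] = 99_999
        assert np.allclose(
            lt.predict_tree(split_tree_fit, new, include_random=True),
            lt.predict_tree(split_tree_fit, new, include_random=False),
        )
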