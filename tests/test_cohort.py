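import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lmmtree as lt
from lmmtree.cohort import config_from_yaml
from lmmtree.errors import InvalidConfigError, SchemaError
from lmmtree.piecewise import piecewise_design


def _flat_config(**kwargs):
    defaults = dict(
        n_users=5,
        seed=0,
        outcome_kind="pain",
        trajectory=lt.TrajectoryParams(5.0, 0.0, 0.0),
        variance=lt.VarianceComponents(0.0, 0.0, 0.0, 0.0),
    )
    defaults.update(kwargs)
    return lt.SimulationConfig(**defaults)


class TestGenerateUsers:
    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidConfigError):
            lt.SimulationConfig(n_users=0, seed=1)

    def test_seed_determinism(self):
        cfg = lt.SimulationConfig(n_users=1000, seed=7)
        a = lt.simulate_cohort(cfg)
        b = lt.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_moderator_marginals_match_truncated_normal(self):
        cfg = lt.SimulationConfig(n_users=5000, seed=3)
        users = lt.generate_users(cfg)
        ages = np.array([u.age for u in users])
        m = cfg.moderators
        a, b = (np.array(m.age_range) - m.age_mean) / m.age_sd
        dist = stats.truncnorm(a, b, loc=m.age_mean, scale=m.age_sd)
        assert abs(ages.mean() - dist.mean()) < 3 * dist.std() / np.sqrt(len(ages))
        assert ages.min() >= 15 and ages.max() <= 94
        frac_female = np.mean([u.gender == "female" for u in users])
        assert frac_female == pytest.approx(0.60, abs=0.03)

    def test_profile_invariants(self):
        users = lt.generate_users(lt.SimulationConfig(n_users=500, seed=9))
        ids = [u.user_id for u in users]
        assert len(set(ids)) == len(ids)
        assert all(u.bmi > 0 for u in users)


class TestSimulateOutcome:
    def test_degenerate_generator_constant(self):
        table = lt.simulate_cohort(_flat_config())
        assert np.all(table["outcome"] == 5.0)

    def test_noiseless_pre_slope(self):
        cfg = _flat_config(trajectory=lt.TrajectoryParams(5.0, -0.4, 0.0))
        table = lt.simulate_cohort(cfg)
        wide = table.pivot(index="user_id", columns="week", values="outcome")
        assert np.allclose(wide[3] - wide[1], -0.8)

    def test_week1_variance_closed_form(self):
        cfg = _flat_config(
            n_users=2000,
            variance=lt.VarianceComponents(1.0, 0.0, 0.0, 0.5),
        )
        table = lt.simulate_cohort(cfg)
        v = table.loc[table["week"] == 1, "outcome"].var()
        assert v == pytest.approx(1.25, rel=0.10)  # var(u0) + var(eps)

    def test_moment_recovery_week_means(self):
        cfg = _flat_config(
            n_users=2000,
            trajectory=lt.TrajectoryParams(5.5, -0.35, 0.02),
            variance=lt.VarianceComponents(1.0, 0.15, 0.0, 1.0),
        )
        table = lt.simulate_cohort(cfg)
        for week, grp in table.groupby("week"):
            b = piecewise_design(int(week), cfg.breakpoint_week)
            mean_true = 5.5 - 0.35 * b.w_pre + 0.02 * b.w_post
            se = grp["outcome"].std() / np.sqrt(len(grp))
            assert abs(grp["outcome"].mean() - mean_true) < 3 * se

    def test_unknown_outcome_kind_rejected(self):
        cfg = _flat_config()
        object.__setattr__(cfg, "outcome_kind", "steps")
        with pytest.raises(InvalidConfigError):
            lt.simulate_outcome(lt.generate_users(cfg), cfg)

    def test_log_duration_emits_minutes(self):
        cfg = _flat_config(outcome_kind="log_duration",
                           trajectory=lt.TrajectoryParams(np.log(400), 0.0, 0.0))
        table = lt.simulate_cohort(cfg)
        assert np.allclose(table["minutes"], np.exp(table["outcome"]))
        assert np.allclose(table["minutes"], 400.0)

    def test_clip_to_scale(self):
        cfg = _flat_config(
            n_users=200,
            trajectory=lt.TrajectoryParams(9.5, 0.5, 0.5),
            variance=lt.VarianceComponents(1.0, 0.0, 0.0, 1.0),
            clip_to_scale=True,
        )
        table = lt.simulate_cohort(cfg)
        assert table["outcome"].between(0, 10).all()

    def test_planted_partition_fidelity(self):
        """Noiseless output recovers each subgroup's parameters exactly by OLS."""
        rules = (
            lt.SubgroupRule(lt.TrajectoryParams(4.0, -0.5, 0.1), age=(None, 40.0)),
            lt.SubgroupRule(lt.TrajectoryParams(6.0, 0.3, -0.2), age=(40.0, None)),
        )
        cfg = _flat_config(n_users=50, subgroup_rules=rules)
        table = lt.simulate_cohort(cfg)
        w_pre, w_post = piecewise_design(table["week"].to_numpy(), 3)
        X = np.column_stack([np.ones(len(table)), w_pre, w_post])
        for g, rule in enumerate(rules):
            mask = (table["true_subgroup"] == g).to_numpy()
            if mask.sum() == 0:
                continue
            beta = np.linalg.lstsq(X[mask], table["outcome"][mask], rcond=None)[0]
            assert beta == pytest.approx(
                [rule.params.intercept, rule.params.slope_pre, rule.params.slope_post],
                abs=1e-10,
            )

    def test_overlapping_rules_rejected(self):
        rules = (
            lt.SubgroupRule(lt.TrajectoryParams(4.0, 0, 0), age=(None, 50.0)),
            lt.SubgroupRule(lt.TrajectoryParams(6.0, 0, 0), age=(30.0, None)),
        )
        with pytest.raises(InvalidConfigError):
            lt.simulate_cohort(_flat_config(n_users=200, subgroup_rules=rules))

    def test_missing_self_report_fraction(self):
        cfg = _flat_config(n_users=1000, missing_self_report_frac=0.3)
        table = lt.simulate_cohort(cfg)
        frac = (
            table.groupby("user_id")["outcome"].apply(lambda s: s.isna().all()).mean()
        )
        assert frac == pytest.approx(0.3, abs=0.05)


def _panel(user_id, pains, minutes):
    weeks = np.arange(1, len(pains) + 1)
    return pd.DataFrame(
        {"user_id": user_id, "week": weeks, "outcome": pains, "minutes": minutes}
    )


class TestInclusionFilter:
    def _table(self):
        good = _panel(1, [6] * 8, [400] * 8)          # passes everything
        low_pain = _panel(2, [4] * 8, [400] * 8)      # first pain not > 4
        one_rating = _panel(3, [7] + [np.nan] * 7, [400] * 8)  # < 2 ratings
        boundary = _panel(4, [6] * 8, [361] * 8)      # 361 min > 360: passes
        seven_weeks = _panel(5, [6] * 8, [400] * 7 + [100])    # 7 qualifying weeks
        exactly_360 = _panel(6, [6] * 8, [360] * 8)   # 360 is not "above 6 hours"
        return pd.concat(
            [good, low_pain, one_rating, boundary, seven_weeks, exactly_360],
            ignore_index=True,
        )

    def test_rules_applied_strictly(self):
        kept, counts = lt.apply_inclusion_filter(self._table())
        assert set(kept["user_id"]) == {1, 4}
        assert counts["first_pain"] == 1
        assert counts["min_ratings"] == 1
        assert counts["training"] == 2
        assert counts["retained"] == 2

    def test_idempotent(self):
        once, _ = lt.apply_inclusion_filter(self._table())
        twice, counts = lt.apply_inclusion_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert counts["total_excluded"] == 0

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            lt.apply_inclusion_filter(self._table().drop(columns=["minutes"]))

    def test_inactive_rules_skip_column_requirements(self):
        table = self._table().drop(columns=["minutes"])
        kept, counts = lt.apply_inclusion_filter(
            table, min_weeks=None, min_weekly_minutes=None
        )
        assert "training" not in counts
        assert set(kept["user_id"]) == {1, 2, 4, 5, 6} - {2}


def test_yaml_config_round_trip(tmp_path):
    raw = {
        "n_users": 40,
        "seed": 5,
        "outcome_kind": "log_duration",
        "breakpoint_week": 3,
        "variance": {"sd_intercept": 0.5, "sd_slope_pre": 0.1,
                     "corr_int_slope": 0.2, "sd_residual": 0.8},
        "subgroups": [
            {"age": [None, 40], "intercept": 5.6, "slope_pre": 0.0, "slope_post": -0.1},
            {"age": [40, None], "intercept": 6.1, "slope_pre": 0.1, "slope_post": -0.1},
        ],
    }
    cfg = config_from_yaml(raw)
    assert cfg.variance.corr_int_slope == 0.2
    assert len(cfg.subgroup_rules) == 2
    assert cfg.subgroup_rules[0].age == (None, 40.0)

    import yaml

    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(raw))
    cfg2 = config_from_yaml(path)
    pd.testing.assert_frame_equal(lt.simulate_cohort(cfg), lt.simulate_cohort(cfg2))
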