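"""Synthetic longitudinal cohorts with planted piecewise subgroup structure.

The generator emulates an eight-week posture-biofeedback follow-up panel:
each user contributes one row per week with a self-reported outcome (pain on
a 0-10 numerical rating scale, posture quality on a 0-10 scale, or weekly
training duration modelled on the log-minutes scale), together with the
user-level moderators age, gender and body-mass index.

The outcome for user *i* in week *w* is

    y_iw = b0(g_i) + b_pre(g_i) * w_pre + b_post(g_i) * w_post
           + u0_i + u1_i * w_pre + e_iw

where ``g_i`` is the user's (latent) subgroup determined by moderator
thresholds, ``(u0_i, u1_i)`` is a bivariate Gaussian random intercept and
random slope on the first segment, and ``e_iw`` is Gaussian residual noise.
Training durations are generated on the log scale and exponentiated, giving
the right-skewed weekly-minutes distribution typical of usage data.

Moderator marginals default to the descriptives of the emulated cohort:
age ~ truncated Normal(43.8, 15.8) on [15, 94], BMI ~ truncated
Normal(24.5, 5.0) on [11, 55], gender Bernoulli with 60% women.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, SchemaError
from .piecewise import piecewise_design

__all__ = [
    "UserProfile",
    "TrajectoryParams",
    "VarianceComponents",
    "SubgroupRule",
    "ModeratorDistributions",
    "SimulationConfig",
    "generate_users",
    "simulate_outcome",
    "simulate_cohort",
    "apply_inclusion_filter",
    "config_from_yaml",
]

OUTCOME_KINDS = ("pain", "posture", "log_duration")
GENDERS = ("female", "male")


@dataclass(frozen=True)
class UserProfile:
    """User-level moderators used as partitioning variables."""

    user_id: int
    age: float
    gender: str
    bmi: float

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise InvalidConfigError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not self.bmi > 0:
            raise InvalidConfigError(f"bmi must be positive, got {self.bmi}")


@dataclass(frozen=True)
class TrajectoryParams:
    """Fixed effects of one subgroup: week-1 level and the two segment slopes."""

    intercept: float
    slope_pre: float
    slope_post: float

    def __post_init__(self):
        for name in ("intercept", "slope_pre", "slope_post"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidConfigError(f"{name} must be finite")


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect and residual standard deviations (outcome units)."""

    sd_intercept: float = 0.0
    sd_slope_pre: float = 0.0
    corr_int_slope: float = 0.0
    sd_residual: float = 1.0

    def __post_init__(self):
        if min(self.sd_intercept, self.sd_slope_pre, self.sd_residual) < 0:
            raise InvalidConfigError("standard deviations must be nonnegative")
        if not -1.0 <= self.corr_int_slope <= 1.0:
            raise InvalidConfigError("corr_int_slope must lie in [-1, 1]")

    def cov_matrix(self) -> np.ndarray:
        """2x2 covariance of (random intercept, random pre-break slope)."""
        c = self.corr_int_slope * self.sd_intercept * self.sd_slope_pre
        return np.array(
            [[self.sd_intercept**2, c], [c, self.sd_slope_pre**2]], dtype=float
        )


@dataclass(frozen=True)
class SubgroupRule:
    """One cell of the planted moderator partition.

    A rule matches a user when every stated condition holds.  Numeric
    conditions are half-open intervals ``lo < x <= hi`` (either end may be
    ``None`` for unbounded); the gender condition is a set of categories.
    The rules of a configuration must tile the moderator space: every user
    must match exactly one rule.
    """

    params: TrajectoryParams
    age: tuple[float | None, float | None] | None = None
    bmi: tuple[float | None, float | None] | None = None
    gender: frozenset | None = None

    def matches(self, profile: UserProfile) -> bool:
        for bounds, value in ((self.age, profile.age), (self.bmi, profile.bmi)):
            if bounds is not None:
                lo, hi = bounds
                if lo is not None and not value > lo:
                    return False
                if hi is not None and not value <= hi:
                    return False
        if self.gender is not None and profile.gender not in self.gender:
            return False
        return True

    def describe(self) -> str:
        parts = []
        for name, bounds in (("age", self.age), ("bmi", self.bmi)):
            if bounds is not None:
                lo, hi = bounds
                if lo is not None:
                    parts.append(f"{name} > {lo:g}")
                if hi is not None:
                    parts.append(f"{name} <= {hi:g}")
        if self.gender is not None:
            parts.append("gender in {%s}" % ", ".join(sorted(self.gender)))
        return " & ".join(parts) if parts else "all users"


@dataclass(frozen=True)
class ModeratorDistributions:
    """Marginal distributions of the user-level moderators."""

    age_mean: float = 43.8
    age_sd: float = 15.8
    age_range: tuple[float, float] = (15.0, 94.0)
    bmi_mean: float = 24.5
    bmi_sd: float = 5.0
    bmi_range: tuple[float, float] = (11.0, 55.0)
    p_female: float = 0.60


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one cohort deterministically."""

    n_users: int
    seed: int
    weeks: int = 8
    breakpoint_week: float = 3
    outcome_kind: str = "pain"
    trajectory: TrajectoryParams = TrajectoryParams(5.5, -0.35, 0.02)
    subgroup_rules: tuple[SubgroupRule, ...] = ()
    variance: VarianceComponents = VarianceComponents(1.0, 0.15, 0.0, 1.0)
    moderators: ModeratorDistributions = ModeratorDistributions()
    clip_to_scale: bool = False
    missing_self_report_frac: float = 0.0

    def __post_init__(self):
        if self.n_users < 1:
            raise InvalidConfigError(f"n_users must be >= 1, got {self.n_users}")
        if self.weeks < 2:
            raise InvalidConfigError(f"weeks must be >= 2, got {self.weeks}")
        # breakpoint_week == weeks gives the degenerate single-slope (linear)
        # generator: w_post is identically zero over the observed weeks
        if not 1 < self.breakpoint_week <= self.weeks:
            raise InvalidConfigError(
                f"breakpoint_week must lie in (1, weeks], got {self.breakpoint_week}"
            )
        if not 0.0 <= self.missing_self_report_frac < 1.0:
            raise InvalidConfigError("missing_self_report_frac must be in [0, 1)")
        object.__setattr__(self, "subgroup_rules", tuple(self.subgroup_rules))


def _rngs(config: SimulationConfig) -> tuple[np.random.Generator, ...]:
    """Independent deterministic streams for users / outcomes / missingness."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_users(config: SimulationConfig) -> list[UserProfile]:
    """Draw ``config.n_users`` user profiles from the moderator marginals."""
    rng = _rngs(config)[0]
    m = config.moderators
    n = config.n_users
    age = _truncnorm(rng, m.age_mean, m.age_sd, *m.age_range, size=n)
    bmi = _truncnorm(rng, m.bmi_mean, m.bmi_sd, *m.bmi_range, size=n)
    gender = np.where(rng.random(n) < m.p_female, "female", "male")
    return [
        UserProfile(user_id=i + 1, age=float(age[i]), gender=str(gender[i]), bmi=float(bmi[i]))
        for i in range(n)
    ]


def _params_for(profile: UserProfile, config: SimulationConfig) -> tuple[int, TrajectoryParams]:
    if not config.subgroup_rules:
        return 0, config.trajectory
    hits = [k for k, rule in enumerate(config.subgroup_rules) if rule.matches(profile)]
    if len(hits) != 1:
        raise InvalidConfigError(
            f"subgroup rules must match each user exactly once; user {profile.user_id} "
            f"(age={profile.age:.1f}, gender={profile.gender}, bmi={profile.bmi:.1f}) "
            f"matched {len(hits)} rules"
        )
    return hits[0], config.subgroup_rules[hits[0]].params


def simulate_outcome(users: list[UserProfile], config: SimulationConfig) -> pd.DataFrame:
    """Simulate the weekly panel for the given users.

    Returns a long table with one row per user-week and columns ``user_id``,
    ``week``, ``outcome``, ``age``, ``gender``, ``bmi`` and ``true_subgroup``
    (index of the planted rule).  For ``outcome_kind='log_duration'`` the
    ``outcome`` column is log-minutes and a ``minutes`` column holds the
    exponentiated value.
    """
    if not users:
        raise InvalidConfigError("users must be non-empty")
    if config.outcome_kind not in OUTCOME_KINDS:
        raise InvalidConfigError(
            f"unknown outcome_kind {config.outcome_kind!r}; expected one of {OUTCOME_KINDS}"
        )
    rng = _rngs(config)[1]
    n = len(users)
    weeks = np.arange(1, config.weeks + 1)
    w_pre, w_post = piecewise_design(weeks, config.breakpoint_week)

    cov = config.variance.cov_matrix()
    # eigh factorization admits singular (PSD) covariances, e.g. no random slope
    u = rng.multivariate_normal(np.zeros(2), cov, size=n, method="eigh")
    eps = rng.normal(0.0, config.variance.sd_residual, size=(n, len(weeks)))

    groups = np.empty(n, dtype=int)
    fixed = np.empty((n, len(weeks)))
    for i, profile in enumerate(users):
        g, p = _params_for(profile, config)
        groups[i] = g
        fixed[i] = p.intercept + p.slope_pre * w_pre + p.slope_post * w_post

    y = fixed + u[:, [0]] + u[:, [1]] * w_pre[None, :] + eps
    if config.clip_to_scale and config.outcome_kind in ("pain", "posture"):
        y = np.clip(y, 0.0, 10.0)

    table = pd.DataFrame(
        {
            "user_id": np.repeat([p.user_id for p in users], len(weeks)),
            "week": np.tile(weeks, n),
            "outcome": y.ravel(),
            "age": np.repeat([p.age for p in users], len(weeks)),
            "gender": np.repeat([p.gender for p in users], len(weeks)),
            "bmi": np.repeat([p.bmi for p in users], len(weeks)),
            "true_subgroup": np.repeat(groups, len(weeks)),
        }
    )
    if config.outcome_kind == "log_duration":
        table["minutes"] = np.exp(table["outcome"])
    if config.missing_self_report_frac > 0:
        miss_rng = _rngs(config)[2]
        ids = np.array([p.user_id for p in users])
        drop = ids[miss_rng.random(n) < config.missing_self_report_frac]
        table.loc[table["user_id"].isin(drop), "outcome"] = np.nan
    return table


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Convenience: ``generate_users`` then ``simulate_outcome``."""
    return simulate_outcome(generate_users(config), config)


def apply_inclusion_filter(
    table: pd.DataFrame,
    first_pain_gt: float | None = 4.0,
    min_ratings: int | None = 2,
    min_weeks: int | None = 8,
    min_weekly_minutes: float | None = 360.0,
    pain_col: str = "outcome",
    minutes_col: str = "minutes",
    week_col: str = "week",
    user_col: str = "user_id",
) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort inclusion screen and report per-rule exclusions.

    Rules (each skipped when its threshold is ``None``):

    * ``first_pain``   — pain strictly above ``first_pain_gt`` at the first
      assessment (the earliest week with a non-missing rating);
    * ``min_ratings``  — at least ``min_ratings`` non-missing ratings;
    * ``training``     — at least ``min_weeks`` weeks with strictly more than
      ``min_weekly_minutes`` minutes of training.

    Returns the table restricted to users passing every active rule, and a
    dict of per-rule exclusion counts (rules evaluated marginally, so a user
    failing two rules is counted under both).
    """
    for col, needed in (
        (user_col, True),
        (week_col, min_weeks is not None and min_weekly_minutes is not None),
        (pain_col, first_pain_gt is not None or min_ratings is not None),
        (minutes_col, min_weeks is not None and min_weekly_minutes is not None),
    ):
        if needed and col not in table.columns:
            raise SchemaError(f"inclusion filter requires column '{col}'")

    users = table[user_col].unique()
    keep = pd.Series(True, index=users)
    counts: dict[str, int] = {}

    if first_pain_gt is not None:
        rated = table.dropna(subset=[pain_col]).sort_values(week_col)
        first = rated.groupby(user_col)[pain_col].first()
        ok = first.reindex(users).gt(first_pain_gt).fillna(False)
        counts["first_pain"] = int((~ok).sum())
        keep &= ok
    if min_ratings is not None:
        n_rated = table.groupby(user_col)[pain_col].count()
        ok = n_rated.reindex(users, fill_value=0).ge(min_ratings)
        counts["min_ratings"] = int((~ok).sum())
        keep &= ok
    if min_weeks is not None and min_weekly_minutes is not None:
        qualifying = (
            table[table[minutes_col] > min_weekly_minutes]
            .groupby(user_col)[week_col]
            .nunique()
        )
        ok = qualifying.reindex(users, fill_value=0).ge(min_weeks)
        counts["training"] = int((~ok).sum())
        keep &= ok

    kept_users = keep[keep].index
    counts["total_excluded"] = int(len(users) - len(kept_users))
    counts["retained"] = int(len(kept_users))
    out = table[table[user_col].isin(kept_users)].reset_index(drop=True)
    return out, counts


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _rule_from_dict(d: dict) -> SubgroupRule:
    def interval(v):
        if v is None:
            return None
        lo, hi = v
        return (None if lo is None else float(lo), None if hi is None else float(hi))

    params = TrajectoryParams(
        float(d["intercept"]), float(d["slope_pre"]), float(d["slope_post"])
    )
    gender = d.get("gender")
    if isinstance(gender, str):
        gender = [gender]
    return SubgroupRule(
        params=params,
        age=interval(d.get("age")),
        bmi=interval(d.get("bmi")),
        gender=None if gender is None else frozenset(gender),
    )


def config_from_yaml(source) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file path or mapping."""
    import yaml

    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    kwargs: dict = {
        "n_users": int(raw["n_users"]),
        "seed": int(raw.get("seed", 0)),
    }
    for key in ("weeks", "outcome_kind", "clip_to_scale", "missing_self_report_frac"):
        if key in raw:
            kwargs[key] = raw[key]
    if "breakpoint_week" in raw:
        kwargs["breakpoint_week"] = float(raw["breakpoint_week"])
    if "variance" in raw:
        kwargs["variance"] = VarianceComponents(**raw["variance"])
    if "moderators" in raw:
        kwargs["moderators"] = ModeratorDistributions(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw["moderators"].items()
        })
    if "trajectory" in raw:
        kwargs["trajectory"] = TrajectoryParams(**raw["trajectory"])
    if "subgroups" in raw and raw["subgroups"]:
        kwargs["subgroup_rules"] = tuple(_rule_from_dict(d) for d in raw["subgroups"])
    return SimulationConfig(**kwargs)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
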