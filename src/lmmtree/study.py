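"""Default cohort configurations emulating the posture-biofeedback study.

Each configuration plants the subgroup structure reported for one of the
three weekly outcomes over 8 weeks with a breakpoint at week 3:

* ``log_duration`` — three age subgroups (<=24, 24-37, >37) whose week-1
  levels correspond to roughly 280 / 462 / 470 minutes on the log scale and
  whose second-segment slopes shrink training by about 15% / 12% / 10% per
  week; only the oldest group ramps up during weeks 1-3 (+0.108 per week on
  the log scale, i.e. +11.4%).
* ``pain`` — four age subgroups (<=17, 17-56, 56-66, >66) starting between
  5.2 and 6.2 on the 0-10 numerical rating scale, all improving during
  weeks 1-3 with the youngest and oldest improving fastest, and the 56-66
  group drifting slightly upward afterwards.
* ``posture`` — gender-by-age subgroups (women/men, split at age 40)
  starting between 3.4 and 4.2, men improving faster during weeks 1-3 and
  only the over-40 groups continuing to improve during weeks 3-8.

Where a published figure prints a coefficient it is planted verbatim; the
slopes reported only as "stable" (non-significant) are planted at zero, and
the variance components — which the figures do not print — are set to give
weekly residual scatter of realistic magnitude for 0-10 self-report scales
and log-minutes usage data.
"""

from __future__ import annotations

import math

from .cohort import (
    SimulationConfig,
    SubgroupRule,
    TrajectoryParams,
    VarianceComponents,
)

__all__ = ["study_config", "OUTCOMES"]

OUTCOMES = ("log_duration", "pain", "posture")

_DURATION_RULES = (
    SubgroupRule(TrajectoryParams(math.log(279.5), 0.0, math.log(1 - 0.1452)),
                 age=(None, 24.0)),
    SubgroupRule(TrajectoryParams(math.log(462.2), 0.0, math.log(1 - 0.1219)),
                 age=(24.0, 37.0)),
    SubgroupRule(TrajectoryParams(math.log(469.66), 0.108, math.log(1 - 0.1042)),
                 age=(37.0, None)),
)

_PAIN_RULES = (
    SubgroupRule(TrajectoryParams(5.173, -0.50, 0.0), age=(None, 17.0)),
    SubgroupRule(TrajectoryParams(6.156, -0.30, 0.0), age=(17.0, 56.0)),
    SubgroupRule(TrajectoryParams(5.383, -0.35, 0.06), age=(56.0, 66.0)),
    SubgroupRule(TrajectoryParams(5.260, -0.55, 0.0), age=(66.0, None)),
)

_POSTURE_RULES = (
    SubgroupRule(TrajectoryParams(3.39, 0.20, 0.0),
                 gender=frozenset({"female"}), age=(None, 40.0)),
    SubgroupRule(TrajectoryParams(4.17, 0.25, 0.06),
                 gender=frozenset({"female"}), age=(40.0, None)),
    SubgroupRule(TrajectoryParams(3.50, 0.40, 0.0),
                 gender=frozenset({"male"}), age=(None, 40.0)),
    SubgroupRule(TrajectoryParams(3.96, 0.45, 0.06),
                 gender=frozenset({"male"}), age=(40.0, None)),
)

_VARIANCE = {
    "log_duration": VarianceComponents(0.9, 0.12, 0.0, 1.0),
    "pain": VarianceComponents(1.2, 0.15, 0.0, 1.6),
    "posture": VarianceComponents(1.1, 0.15, 0.0, 1.6),
}

_RULES = {
    "log_duration": _DURATION_RULES,
    "pain": _PAIN_RULES,
    "posture": _POSTURE_RULES,
}


def study_config(outcome: str, n_users: int, seed: int) -> SimulationConfig:
    """Cohort configuration planting the reported subgroup structure."""
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    kind = "log_duration" if outcome == "log_duration" else outcome
    return SimulationConfig(
        n_users=n_users,
        seed=seed,
        weeks=8,
        breakpoint_week=3,
        outcome_kind=kind,
        subgroup_rules=_RULES[outcome],
        variance=_VARIANCE[outcome],
    )
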