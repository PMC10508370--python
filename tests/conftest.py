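import numpy as np
import pandas as pd
import pytest

import lmmtree as lt


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with a single trajectory for everyone (no subgroup structure)."""
    cfg = lt.SimulationConfig(
        n_users=150,
        seed=11,
        outcome_kind="pain",
        trajectory=lt.TrajectoryParams(5.5, -0.35, 0.02),
        variance=lt.VarianceComponents(1.0, 0.15, 0.0, 1.0),
    )
    return lt.simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def split_cohort():
    """Cohort with a strong planted age-40 split in the first-segment slope."""
    rules = (
        lt.SubgroupRule(lt.TrajectoryParams(5.5, -0.5, 0.02), age=(None, 40.0)),
        lt.SubgroupRule(lt.TrajectoryParams(5.5, 0.5, 0.02), age=(40.0, None)),
    )
    cfg = lt.SimulationConfig(
        n_users=300,
        seed=21,
        outcome_kind="pain",
        subgroup_rules=rules,
        variance=lt.VarianceComponents(1.0, 0.1, 0.0, 0.3),
    )
    return lt.simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def split_tree_fit(split_cohort):
    table, _ = split_cohort
    return lt.fit_lmm_tree(
        table, "outcome", ["age", "gender", "bmi"],
        control=lt.TreeControl(minsplit=90, maxdepth=3),
    )
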