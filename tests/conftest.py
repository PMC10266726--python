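import numpy as np
import pytest

from sackcog.instances import Instance, Item, generate_instance_bank


@pytest.fixture(scope="session")
def worked_instance() -> Instance:
    """Three items (v=60,w=10), (v=100,w=20), (v=120,w=30), capacity 50.

    Hand-enumerable: ratios are 6, 5, 4; greedy fills {0, 1} for 160 while
    the optimum is {1, 2} at 220, so the instance has Sahni-k = 2.
    """
    return Instance(
        "worked-3",
        (Item(0, 60, 10), Item(1, 100, 20), Item(2, 120, 30)),
        50,
    )


@pytest.fixture(scope="session")
def instance_bank():
    """Eight generated 10/12-item instances used by simulation tests."""
    return generate_instance_bank(8, seed=42)


@pytest.fixture(scope="session")
def small_bank():
    """Four instances, the scaled-down bank for statistical replicates."""
    return generate_instance_bank(4, seed=42)


@pytest.fixture(scope="session")
def cohort_metrics(instance_bank):
    """One scored 12-participant cohort with the default condition effects."""
    from sackcog.behavior import score_dataset
    from sackcog.simulate import CohortDesign, ConditionEffects, simulate_cohort

    design = CohortDesign(n_participants=12, n_instances=8)
    logs = simulate_cohort(design, ConditionEffects(), instance_bank, seed=7)
    metrics, rejects = score_dataset(logs, instance_bank)
    assert rejects.empty
    return metrics
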