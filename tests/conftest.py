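import numpy as np
import pytest

import protonbdt as p


@pytest.fixture(scope="session")
def config():
    return p.MachineConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Machine with the timing model but no inter-fraction noise."""
    return p.MachineConfig(noise=p.NoiseParams(sigma_floor=0.0, sigma_rel=0.0,
                                               outlier_prob=0.0))


@pytest.fixture(scope="session")
def tiny_plan(config):
    return p.generate_plan(7, 2, 4, 16, config)


@pytest.fixture(scope="session")
def tiny_logs(tiny_plan, config):
    return p.simulate_course(tiny_plan, 3, 8, config)


@pytest.fixture(scope="session")
def tiny_table(tiny_logs, config):
    return p.build_feature_table(tiny_logs, config)


@pytest.fixture(scope="session")
def small_fit(tiny_table):
    """Quick fixed-hyperparameter fit for unit-level model/explain tests."""
    train, test = p.stratified_split(tiny_table, seed=9)
    res = p.DeliveryTimeModel(train).fit(
        seed=10, hyperparameters=dict(n_estimators=30, max_depth=6,
                                      min_samples_leaf=5))
    return train, test, res


@pytest.fixture(scope="session")
def study(config):
    """Full-scale synthetic study: ~50k transitions, tuned forest.

    The backbone of the parameter-recovery, repainting and interplay
    checks; built once per session.
    """
    plan = p.generate_plan(1, 4, 10, 64, config)
    logs = p.simulate_course(plan, 11, 2, config)
    table = p.build_feature_table(logs, config)
    train, test = p.stratified_split(table, seed=3)
    results = p.DeliveryTimeModel(train).fit(seed=4, n_candidates=6)
    return {"plan": plan, "logs": logs, "table": table, "train": train,
            "test": test, "results": results}
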