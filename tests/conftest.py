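import numpy as np
import pandas as pd
import pytest

from neutropipe.io import CountMatrix, SampleTable
from neutropipe.simulate import (
    DESpec,
    ModuleSpec,
    SimulationConfig,
    make_worked_fixture,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def worked_fixture():
    """The deterministic 20-gene / 12-sample micro-cohort."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort shared by slower integration tests."""
    return simulate_cohort(SimulationConfig(seed=42, n_genes=1200))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def two_group_samples():
    def build(n_ref: int, n_case: int) -> SampleTable:
        ids = [f"r{i}" for i in range(n_ref)] + [f"c{i}" for i in range(n_case)]
        return SampleTable(pd.DataFrame({
            "sample_id": ids,
            "group": ["control"] * n_ref + ["cap_admission"] * n_case,
        }))
    return build


@pytest.fixture()
def nb_counts(two_group_samples):
    """Factory for NB count matrices with planted balanced fold changes."""
    def build(seed=0, n_genes=400, n_per_group=30, mu=100.0, phi=0.1,
              n_up=0, n_down=0, lfc=2.0):
        r = np.random.default_rng(seed)
        log2fc = np.zeros(n_genes)
        log2fc[:n_up] = lfc
        log2fc[n_up:n_up + n_down] = -lfc
        x = np.array([0] * n_per_group + [1] * n_per_group)
        mean = mu * np.exp2(log2fc[:, None] * x[None, :])
        rr = 1.0 / phi
        y = r.negative_binomial(rr, rr / (rr + mean))
        cm = CountMatrix([f"g{i:04d}" for i in range(n_genes)],
                         [f"s{i:03d}" for i in range(2 * n_per_group)], y)
        st = SampleTable(pd.DataFrame({
            "sample_id": cm.sample_ids,
            "group": ["control"] * n_per_group + ["cap_admission"] * n_per_group,
        }))
        return cm, st, log2fc
    return build
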