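import numpy as np
import pandas as pd
import pytest

from methtrio import (
    BetaMatrix,
    SimulationConfig,
    TrioDesign,
    TrioSubject,
    generate_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions: 29 subjects, 20k probes, 200 injected probes."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_cohort():
    """Default conditions without injected discordance."""
    return generate_cohort(SimulationConfig(seed=1, n_discordant_probes=0))


@pytest.fixture()
def tiny_matrix():
    """3 probes x 2 trios of hand-set betas."""
    a_pmn, a_lym = np.array([0.1, 0.5, 0.9]), np.array([0.3, 0.2, 0.8])
    b_pmn, b_lym = np.array([0.2, 0.4, 0.8]), np.array([0.1, 0.9, 0.5])
    values = pd.DataFrame(
        {
            "A_buffy": 0.7 * a_pmn + 0.3 * a_lym,
            "A_pmn": a_pmn,
            "A_lymphocyte": a_lym,
            "B_buffy": 0.6 * b_pmn + 0.4 * b_lym,
            "B_pmn": b_pmn,
            "B_lymphocyte": b_lym,
        },
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
    )
    return BetaMatrix(values)


@pytest.fixture()
def tiny_design():
    return TrioDesign(
        (
            TrioSubject("A", "A_buffy", "A_pmn", "A_lymphocyte"),
            TrioSubject("B", "B_buffy", "B_pmn", "B_lymphocyte"),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
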