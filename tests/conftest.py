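import itertools

import numpy as np
import pytest

from eumodel import (
    CycleRecord,
    Dataset,
    ModelSpec,
    ParameterVector,
    ScenarioConfig,
    cycle_probabilities,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """400-cycle null-scenario dataset shared by fitting/inference tests."""
    return simulate_dataset(ScenarioConfig(n_cycles=400, seed=314159))


@pytest.fixture(scope="session")
def effect_dataset() -> Dataset:
    """800-cycle dataset with the patient variable acting in the embryo sub-model."""
    return simulate_dataset(ScenarioConfig(n_cycles=800, beta_ep2=0.8, seed=271828))


def enumerate_k_probability(u: float, e: np.ndarray, k: int) -> float:
    """Brute-force oracle: enumerate the uterine state and all 2^n viability vectors."""
    e = np.asarray(e, dtype=float)
    total = 0.0
    for receptive in (0, 1):
        p_r = u if receptive else 1.0 - u
        for viab in itertools.product((0, 1), repeat=len(e)):
            p_v = np.prod([ej if v else 1.0 - ej for ej, v in zip(e, viab)])
            k_out = receptive * sum(viab)
            if k_out == k:
                total += p_r * p_v
    return float(total)


def enumerate_log_likelihood(data: Dataset, spec: ModelSpec, theta: ParameterVector) -> float:
    """Independent log-likelihood oracle built on the enumeration above."""
    total = 0.0
    for rec in data.records():
        u, e = cycle_probabilities(rec, spec, theta)
        total += np.log(enumerate_k_probability(u, np.asarray(e), rec.k_observed))
    return float(total)


@pytest.fixture
def det_cycle() -> CycleRecord:
    return CycleRecord(
        cycle_id="c1",
        n_transferred=2,
        k_observed=1,
        u_covariates={"U": -0.5, "P": 0.2},
        embryo_covariates=(
            {"Ep": -0.1, "Ee": 3.0},
            {"Ep": -0.1, "Ee": 2.5},
        ),
    )
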