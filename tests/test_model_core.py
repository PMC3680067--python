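"""Core EU probability model: sub-model probabilities, P_ik, log-likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eumodel import (
    CycleRecord,
    Dataset,
    ModelSpec,
    ParameterVector,
    SchemaError,
    ZeroProbabilityError,
    cycle_probabilities,
    k_fold_probability,
    log_likelihood,
)
from eumodel.model import SUBSET_ENUMERATION_CAP, _poisson_binomial_pmf

from conftest import enumerate_k_probability, enumerate_log_likelihood


class TestCycleProbabilities:
    def test_intercept_only_at_zero_gives_half(self):
        rec = CycleRecord("c", 2, 0, {}, ({}, {}))
        u, e = cycle_probabilities(rec, ModelSpec(), ParameterVector((0.0,), (0.0,)))
        assert u == 0.5
        assert e == [0.5, 0.5]

    def test_uterus_linear_predictor(self):
        # logit(u) = 0.1 + 1.0 * (-0.5) = -0.4
        rec = CycleRecord("c", 1, 0, {"U": -0.5}, ({},))
        spec = ModelSpec(u_terms=("U",))
        u, _ = cycle_probabilities(rec, spec, ParameterVector((0.1, 1.0), (0.0,)))
        assert u == pytest.approx(0.4013, abs=5e-5)

    def test_embryo_linear_predictor(self):
        # logit(e) = -3.66 + Ep + Ee = -0.76 with Ep=-0.1, Ee=3.0
        rec = CycleRecord("c", 1, 0, {}, ({"Ep": -0.1, "Ee": 3.0},))
        spec = ModelSpec(e_terms=("Ep", "Ee"))
        _, e = cycle_probabilities(rec, spec, ParameterVector((0.0,), (-3.66, 1.0, 1.0)))
        assert e[0] == pytest.approx(0.3186, abs=1e-4)

    def test_patient_level_covariate_usable_in_embryo_submodel(self, det_cycle):
        spec = ModelSpec(e_terms=("P",))
        _, e = cycle_probabilities(det_cycle, spec, ParameterVector((0.0,), (0.0, 1.0)))
        expected = 1.0 / (1.0 + np.exp(-0.2))
        assert e == pytest.approx([expected, expected])

    def test_missing_covariate_names_cycle_and_covariate(self, det_cycle):
        spec = ModelSpec(u_terms=("age",))
        with pytest.raises(SchemaError, match="age.*c1"):
            cycle_probabilities(det_cycle, spec, ParameterVector((0.0, 1.0), (0.0,)))


class TestKFoldProbability:
    @pytest.mark.parametrize(
        "u, e, k, expected",
        [
            (0.5, [0.5], 0, 0.75),
            (1.0, [1.0, 1.0], 2, 1.0),
            (0.4, [0.3, 0.2], 1, 0.152),  # frozen from the enumeration oracle
            (0.0, [0.9, 0.9], 0, 1.0),
        ],
    )
    def test_known_values(self, u, e, k, expected):
        assert k_fold_probability(u, e, k) == pytest.approx(expected, abs=1e-12)

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            k_fold_probability(0.5, [0.5, 0.5], 3)
        with pytest.raises(ValueError):
            k_fold_probability(0.5, [0.5], -1)

    def test_matches_enumeration_oracle_on_random_draws(self):
        rng = np.random.default_rng(20231109)
        for _ in range(100):
            n = rng.integers(1, 5)
            u = rng.random()
            e = rng.random(n)
            for k in range(n + 1):
                assert k_fold_probability(u, e, k) == pytest.approx(
                    enumerate_k_probability(u, e, k), abs=1e-12
                )

    def test_dp_path_agrees_with_enumeration_path(self):
        # above the enumeration cap the Poisson-binomial recursion takes over
        rng = np.random.default_rng(5)
        e = rng.random(SUBSET_ENUMERATION_CAP + 3)
        pmf = _poisson_binomial_pmf(e)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        for k in (0, 5, len(e)):
            direct = k_fold_probability(0.7, e, k)
            expected = (0.3 if k == 0 else 0.0) + 0.7 * pmf[k]
            assert direct == pytest.approx(expected, abs=1e-12)

    @given(
        u=st.floats(0.0, 1.0),
        e=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalisation(self, u, e):
        total = sum(k_fold_probability(u, e, k) for k in range(len(e) + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(
        u=st.floats(0.01, 0.99),
        e=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=4),
        k=st.integers(0, 4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_permutation_symmetry(self, u, e, k):
        if k > len(e):
            k = len(e)
        shuffled = list(reversed(e))
        assert k_fold_probability(u, e, k) == pytest.approx(
            k_fold_probability(u, shuffled, k), abs=1e-12
        )

    def test_failure_probability_monotone_in_u_and_e(self):
        e = [0.3, 0.4]
        p0 = [k_fold_probability(u, e, 0) for u in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(p0, p0[1:]))
        p0e = [k_fold_probability(0.5, [x, 0.4], 0) for x in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(p0e, p0e[1:]))


class TestLogLikelihood:
    def test_single_det_cycle_closed_form(self):
        # intercept-only, all probabilities 1/2: P(k=0) = 0.5 + 0.5 * 0.25
        data = Dataset.from_records(
            [CycleRecord("a", 2, 0, {}, ({}, {}))]
        )
        ll = log_likelihood(data, ModelSpec(), ParameterVector((0.0,), (0.0,)))
        assert ll == pytest.approx(np.log(0.625), abs=1e-12)

    def test_additive_over_disjoint_splits(self, small_dataset):
        spec = ModelSpec(u_terms=("U",), e_terms=("Ep", "Ee"))
        theta = ParameterVector((0.1, 1.0), (-3.66, 1.0, 1.0))
        whole = log_likelihood(small_dataset, spec, theta)
        half1 = log_likelihood(small_dataset.split(range(0, 200)), spec, theta)
        half2 = log_likelihood(small_dataset.split(range(200, 400)), spec, theta)
        assert whole == pytest.approx(half1 + half2, rel=1e-12)

    def test_matches_enumeration_oracle_on_simulated_data(self, small_dataset):
        spec = ModelSpec(u_terms=("U", "P"), e_terms=("Ep", "Ee", "P"))
        theta = ParameterVector((0.2, 0.9, 0.1), (-3.5, 1.1, 0.9, -0.2))
        sub = small_dataset.split(range(50))
        fast = log_likelihood(sub, spec, theta)
        oracle = enumerate_log_likelihood(sub, spec, theta)
        assert fast == pytest.approx(oracle, abs=1e-10)

    def test_zero_probability_cycle_reported_with_id(self):
        # an observed implantation while the embryo intercept is at -800
        # (viability numerically zero) is structurally impossible
        data = Dataset.from_records([CycleRecord("impossible", 2, 2, {}, ({}, {}))])
        with pytest.raises(ZeroProbabilityError) as err:
            log_likelihood(data, ModelSpec(), ParameterVector((0.0,), (-800.0,)))
        assert "impossible" in str(err.value)


class TestDatasetValidation:
    def test_duplicate_cycle_ids_rejected(self):
        cycles = pd.DataFrame(
            {"cycle_id": [1, 1], "n_transferred": [1, 1], "k_observed": [0, 0]}
        )
        with pytest.raises(ValueError, match="duplicate cycle_id"):
            Dataset(cycles)

    def test_k_exceeding_n_rejected(self):
        cycles = pd.DataFrame(
            {"cycle_id": [1], "n_transferred": [1], "k_observed": [2]}
        )
        with pytest.raises(ValueError, match="k_observed"):
            Dataset(cycles)

    def test_embryo_count_mismatch_names_cycle(self):
        with pytest.raises(ValueError, match="x"):
            CycleRecord("x", 2, 1, {}, ({"Ee": 1.0},))

    def test_records_round_trip(self, det_cycle):
        data = Dataset.from_records([det_cycle])
        (back,) = data.records()
        assert back.cycle_id == det_cycle.cycle_id
        assert back.n_transferred == det_cycle.n_transferred
        assert back.u_covariates == dict(det_cycle.u_covariates)
        assert tuple(back.embryo_covariates) == tuple(det_cycle.embryo_covariates)
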