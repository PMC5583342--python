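"""State-space metapopulation model: the Kolmogorov rate-probability
mapping, rate regressions, connectivity, detection and simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from paleobear.enviro import period_scheme_from_boundaries
from paleobear.metapop import (
    CovariateStack, ExtinctionCoefficients, DispersalParams,
    DetectionCoefficients, extinction_rate, connectivity, colonization_rate,
    rates_to_probabilities, occupancy_transition, detection_probability,
    observation_loglik, simulate_occupancy,
)


def expm_oracle(r_phi, r_gamma, dt):
    """Independent two-state matrix-exponential transition probabilities."""
    q = np.array([[-r_gamma, r_gamma], [r_phi, -r_phi]])
    p = expm(q * dt)
    return p[1, 0], p[0, 1]  # (p_phi, p_gamma)


class TestRatesToProbabilities:
    def test_matches_matrix_exponential(self):
        for rp in (1e-5, 1e-3, 0.1):
            for rg in (2e-5, 5e-4, 0.05):
                for dt in (52.5, 310.0, 3500.0):
                    p_phi, p_gamma = rates_to_probabilities(rp, rg, dt)
                    o_phi, o_gamma = expm_oracle(rp, rg, dt)
                    assert abs(p_phi - o_phi) <= 1e-10
                    assert abs(p_gamma - o_gamma) <= 1e-10

    def test_worked_example(self):
        p_phi, p_gamma = rates_to_probabilities(0.001, 0.0005, 3500.0)
        assert p_phi == pytest.approx(0.66317, abs=1e-5)
        assert p_gamma == pytest.approx(0.33158, abs=1e-5)

    def test_zero_interval(self):
        assert rates_to_probabilities(0.1, 0.2, 0.0) == (0.0, 0.0)

    def test_symmetric_stationary_limit(self):
        p_phi, p_gamma = rates_to_probabilities(0.01, 0.01, 1e9)
        assert p_phi == pytest.approx(0.5)
        assert p_gamma == pytest.approx(0.5)

    def test_stationary_limit_general(self):
        rp, rg = 0.003, 0.001
        p_phi, p_gamma = rates_to_probabilities(rp, rg, 1e9)
        assert p_phi == pytest.approx(rp / (rp + rg))
        assert p_gamma == pytest.approx(rg / (rp + rg))

    def test_small_dt_first_order(self):
        rp, rg, dt = 1e-4, 2e-4, 1e-3
        p_phi, p_gamma = rates_to_probabilities(rp, rg, dt)
        assert p_phi == pytest.approx(rp * dt, rel=1e-3)
        assert p_gamma == pytest.approx(rg * dt, rel=1e-3)

    def test_tiny_exponent_taylor_fallback(self):
        p_phi, p_gamma = rates_to_probabilities(1e-10, 1e-10, 1e-4)
        assert p_phi == pytest.approx(1e-14, rel=1e-6)
        assert p_gamma == pytest.approx(1e-14, rel=1e-6)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            rates_to_probabilities(0.1, 0.1, -1.0)

    def test_vectorized_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(1)
        rp = 10 ** rng.uniform(-5, -1, 200)
        rg = 10 ** rng.uniform(-5, -1, 200)
        dt = rng.choice([52.5, 310, 900, 2250, 3500], 200)
        p_phi, p_gamma = rates_to_probabilities(rp, rg, dt)
        assert np.all((p_phi > 0) & (p_phi < 1))
        assert np.all((p_gamma > 0) & (p_gamma < 1))


def _stack(lu=0.0, npp=0.0, wt=0.0, ele=0.0, shape=(3, 2)):
    mk = lambda v: np.full(shape, float(v))
    stack = CovariateStack(lu=mk(lu), npp=mk(npp), wt=mk(wt), ele=mk(ele))
    stack.standardized = True  # already on effect-size scale for these tests
    return stack


class TestExtinctionRate:
    def test_zero_coefficients_give_unit_rate(self):
        r = extinction_rate(_stack(), ExtinctionCoefficients())
        assert np.allclose(r, 1.0)

    def test_intercept_only(self):
        r = extinction_rate(_stack(), ExtinctionCoefficients(intercept=-3.0))
        assert np.allclose(r, np.exp(-3.0))
        assert r.flat[0] == pytest.approx(0.049787, abs=1e-6)

    def test_monotone_in_land_use(self):
        beta = ExtinctionCoefficients(lu=0.7)
        r1 = extinction_rate(_stack(lu=0.5), beta)
        r2 = extinction_rate(_stack(lu=1.5), beta)
        assert np.all(r2 > r1)

    def test_unstandardized_covariates_rejected(self):
        stack = _stack()
        stack.standardized = False
        with pytest.raises(ValueError, match="standardized"):
            extinction_rate(stack, ExtinctionCoefficients())


class TestConnectivity:
    def test_empty_landscape(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(connectivity(np.zeros(2), d, alpha=1.0), 0.0)

    def test_single_neighbor(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = connectivity(np.array([0, 1]), d, alpha=2.0)
        assert s[0] == pytest.approx(np.exp(-2.0), abs=1e-9)
        assert s[1] == 0.0  # self excluded

    def test_monotone_under_occupancy_gain(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1, 5, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        z = np.array([1, 0, 0, 1, 0, 0])
        s0 = connectivity(z, d, 1.0)
        z2 = z.copy()
        z2[1] = 1
        assert np.all(connectivity(z2, d, 1.0) >= s0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            connectivity(np.zeros(3), np.zeros((2, 2)), 1.0)


class TestColonizationRate:
    def test_no_neighbors_gives_unit_rate(self):
        # log-link without intercept: S = 0 implies r_gamma = exp(0) = 1/yr
        assert colonization_rate(0.0) == 1.0

    def test_worked_example(self):
        assert colonization_rate(0.13534) == pytest.approx(1.1449, abs=1e-4)

    def test_lambda_scales_log_rate(self):
        s = 0.37
        assert np.log(colonization_rate(s, lam=2.0)) == pytest.approx(
            2.0 * np.log(colonization_rate(s, lam=1.0)))


class TestOccupancyTransition:
    @pytest.mark.parametrize("z,p_phi,p_gamma,expected", [
        (1, 0.2, 0.9, 0.8),   # persistence of an occupied cell
        (0, 0.9, 0.3, 0.3),   # colonization of an empty cell
        (1, 1.0, 0.0, 0.0),   # absorbing emptiness
        (0, 1.0, 0.0, 0.0),
    ])
    def test_cases(self, z, p_phi, p_gamma, expected):
        assert occupancy_transition(z, p_phi, p_gamma) == pytest.approx(expected)


class TestDetectionProbability:
    def test_reference_site_single_bone(self):
        beta = DetectionCoefficients(intercept=0.0, nsp=0.7)
        assert detection_probability(1, "settlement", beta) == 0.5

    def test_log_nsp_cancels_intercept(self):
        beta = DetectionCoefficients(intercept=-1.0, nsp=0.5)
        assert detection_probability(np.e ** 2, "settlement", beta) == pytest.approx(0.5)

    def test_increases_with_bone_count(self):
        beta = DetectionCoefficients(intercept=-0.5, nsp=0.4)
        p = detection_probability(np.array([1, 7, 100, 26428]), ["settlement"] * 4, beta)
        assert np.all(np.diff(p) > 0)

    def test_nsp_below_one_rejected(self):
        with pytest.raises(ValueError):
            detection_probability(0, "settlement", DetectionCoefficients())

    def test_nonzero_reference_offset_rejected(self):
        with pytest.raises(ValueError):
            DetectionCoefficients(type_offsets={"settlement": 0.5})


class TestObservationLoglik:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "period", "detected"])

    def test_empty_cell_nondetection_is_free(self):
        z = np.zeros((1, 1), dtype=int)
        ll = observation_loglik(self._records([(0, 0, 0)]), z, np.array([0.7]))
        assert ll == 0.0

    def test_detection_in_occupied_cell(self):
        z = np.ones((1, 1), dtype=int)
        ll = observation_loglik(self._records([(0, 0, 1)]), z, np.array([0.25]))
        assert ll == pytest.approx(np.log(0.25))

    def test_detection_in_empty_cell_impossible(self):
        z = np.zeros((1, 1), dtype=int)
        ll = observation_loglik(self._records([(0, 0, 1)]), z, np.array([0.5]))
        assert ll == -np.inf

    def test_perfect_period_mismatch_impossible(self):
        z = np.ones((1, 2), dtype=int)
        ll = observation_loglik(self._records([(0, 1, 0)]), z, np.array([0.5]),
                                perfect_periods={1})
        assert ll == -np.inf

    def test_unknown_cell_rejected(self):
        z = np.zeros((1, 1), dtype=int)
        with pytest.raises(ValueError, match="cell"):
            observation_loglik(self._records([(5, 0, 0)]), z, np.array([0.5]))


class TestSimulateOccupancy:
    def test_persistent_when_extinction_negligible(self):
        scheme = period_scheme_from_boundaries([(0, 10), (10, 20), (20, 30)])
        stack = _stack(shape=(4, 3))
        d = np.ones((4, 4)) - np.eye(4)
        lat = simulate_occupancy(stack, ExtinctionCoefficients(intercept=-30.0),
                                 DispersalParams(alpha=1.0), 1.0, scheme, d,
                                 np.random.default_rng(0))
        assert lat.z.all()

    def test_marginal_transition_frequencies(self):
        # thousands of isolated cells: empirical extinction fraction ~ p_phi
        n = 3_000
        scheme = period_scheme_from_boundaries([(0, 1), (1, 2)])
        stack = _stack(shape=(n, 2))
        d = np.full((n, n), 1e9)
        np.fill_diagonal(d, 0.0)
        beta = ExtinctionCoefficients(intercept=0.0)  # r_phi = 1/yr
        lat = simulate_occupancy(stack, beta, DispersalParams(alpha=1.0), 1.0,
                                 scheme, d, np.random.default_rng(5))
        # isolated cells have S=0 so r_gamma = 1/yr; dt = 1 yr
        p_phi, _ = rates_to_probabilities(1.0, 1.0, 1.0)
        emp = 1.0 - lat.z[:, 1].mean()  # all cells start occupied
        se = np.sqrt(p_phi * (1 - p_phi) / n)
        assert abs(emp - p_phi) < 3 * se

    def test_reproducible_given_seed(self):
        scheme = period_scheme_from_boundaries([(0, 10), (10, 20)])
        stack = _stack(shape=(9, 2))
        d = np.ones((9, 9)) - np.eye(9)
        a = simulate_occupancy(stack, ExtinctionCoefficients(), DispersalParams(2.0),
                               0.5, scheme, d, np.random.default_rng(7))
        b = simulate_occupancy(stack, ExtinctionCoefficients(), DispersalParams(2.0),
                               0.5, scheme, d, np.random.default_rng(7))
        assert np.array_equal(a.z, b.z)


class TestRecordTypes:
    def test_arch_record_invariants(self):
        from paleobear.metapop import ArchRecord
        rec = ArchRecord(record_id=1, site_id=1, cell_id=0, period=0,
                         detected=1, nsp_total=7, site_type="cave")
        assert rec.nsp_total == 7
        with pytest.raises(ValueError, match="nsp_total"):
            ArchRecord(record_id=1, site_id=1, cell_id=0, period=0,
                       detected=0, nsp_total=0, site_type="cave")
        with pytest.raises(ValueError, match="site type"):
            ArchRecord(record_id=1, site_id=1, cell_id=0, period=0,
                       detected=0, nsp_total=3, site_type="temple")
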