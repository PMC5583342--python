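"""MCMC engine: latent-state correctness against brute-force enumeration,
prior recovery, bookkeeping, diagnostics, pooling and scenarios."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from paleobear.enviro import period_scheme_from_boundaries
from paleobear.metapop import CovariateStack, connectivity
from paleobear.inference import (
    MCMCConfig, ScenarioFactorial, SCENARIO_FACTORIAL, FitData,
    PosteriorDraws, impute_site_type, update_latent_occupancy, run_mcmc,
    convergence_diagnostics, pool_scenarios, apply_asian_colonization_scenario,
)

RECORD_COLS = ["record_id", "site_id", "site_type", "period", "cell_id",
               "nsp_total", "detected"]


def empty_records():
    return pd.DataFrame(columns=RECORD_COLS)


def small_fitdata(n=4, n_periods=3, records=None, grid=(2, 2)):
    rng = np.random.default_rng(0)
    shape = (n, n_periods)
    cov = CovariateStack(lu=rng.normal(size=shape), npp=rng.normal(size=shape),
                         wt=rng.normal(size=shape), ele=rng.normal(size=shape))
    d = np.ones((n, n)) - np.eye(n)
    scheme = period_scheme_from_boundaries(
        [(i * 10, (i + 1) * 10) for i in range(n_periods)])
    return FitData(cov=cov, distances=d,
                   records=records if records is not None else empty_records(),
                   scheme=scheme, grid_shape=grid)


class TestBookkeeping:
    def test_study_configuration_retention(self):
        cfg = MCMCConfig(n_chains=10, n_iter=4500, burn_in=2000, thinning=25)
        assert cfg.retained_per_chain == 100
        assert cfg.total_retained == 1000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thinning=0)

    def test_actual_run_matches_retention(self):
        data = small_fitdata()
        cfg = MCMCConfig(n_chains=2, n_iter=40, burn_in=10, thinning=3, seed=1)
        draws = run_mcmc(data, cfg)
        assert draws.n_chains == 2
        assert draws.n_draws == cfg.retained_per_chain == 10


class TestImputeSiteType:
    def test_degenerate_column(self, rng):
        freq = np.zeros((7, 2))
        freq[0, 0] = 5.0
        assert impute_site_type(0, freq, rng) == "settlement"

    def test_two_type_frequencies(self, rng):
        freq = np.zeros((7, 1))
        freq[0, 0] = freq[1, 0] = 0.5
        n = 10_000
        hits = sum(impute_site_type(0, freq, rng) == "settlement"
                   for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_counts_behave_as_probabilities(self, rng):
        freq = np.zeros((7, 1))
        freq[:3, 0] = [2.0, 1.0, 1.0]
        n = 8000
        draws = [impute_site_type(0, freq, rng) for _ in range(n)]
        p_settlement = draws.count("settlement") / n
        assert abs(p_settlement - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_all_zero_column_rejected(self, rng):
        with pytest.raises(ValueError, match="period 0"):
            impute_site_type(0, np.zeros((7, 2)), rng)


def enumeration_posterior(r_phi, alpha, psi1, dts, det):
    """Brute-force posterior over all 2-cell x 3-period occupancy histories.

    ``det`` is a list of (cell, period, y, p) fixed-probability records.
    Transition probabilities come from the independent matrix-exponential
    oracle, not from the package's Kolmogorov mapping.
    """
    k01 = np.exp(-alpha * 1.0)  # two cells at distance 1
    probs = {}
    for hist in itertools.product((0, 1), repeat=6):
        z = np.array(hist).reshape(2, 3)
        p = 1.0
        for s in range(2):
            p *= psi1 if z[s, 0] == 1 else 1 - psi1
        for t in range(2):
            for s in range(2):
                s_conn = k01 * z[1 - s, t]
                rg = np.exp(s_conn)
                q = np.array([[-rg, rg], [r_phi[s, t], -r_phi[s, t]]])
                pm = expm(q * dts[t])
                # row 0 = empty, row 1 = occupied; column 1 = occupied next
                p1 = pm[z[s, t], 1]
                p *= p1 if z[s, t + 1] == 1 else 1 - p1
        for (s, t, y, pdet) in det:
            mu = z[s, t] * pdet
            p *= mu if y == 1 else 1 - mu
        probs[hist] = p
    total = sum(probs.values())
    return {h: v / total for h, v in probs.items()}


class TestLatentStateGibbs:
    def test_certain_detection_pins_occupancy(self):
        records = pd.DataFrame(
            [(0, 0, "settlement", 0, 0, 10, 1)], columns=RECORD_COLS)
        data = small_fitdata(records=records)
        cfg = MCMCConfig(n_chains=1, n_iter=30, burn_in=10, thinning=2, seed=2)
        draws = run_mcmc(data, cfg)
        assert np.all(draws.z[:, :, 0, 0] == 1)

    def test_gibbs_matches_enumeration(self):
        # 2 cells, 3 periods, fixed parameters; oracle = exhaustive
        # enumeration over the 64 occupancy histories
        r_phi = np.array([[0.8, 1.5], [0.5, 0.9]])
        alpha, psi1 = 1.0, 0.6
        dts = np.array([1.0, 2.0])
        det = [(0, 1, 0, 0.7), (1, 2, 0, 0.5)]
        exact = enumeration_posterior(r_phi, alpha, psi1, dts, det)

        kernel = np.exp(-alpha * (np.ones((2, 2)) - np.eye(2)))
        np.fill_diagonal(kernel, 0.0)
        det_ll1 = np.zeros((2, 3))
        for (s, t, y, p) in det:
            det_ll1[s, t] += np.log(p) if y == 1 else np.log1p(-p)
        rng = np.random.default_rng(11)
        z = np.zeros((2, 3), dtype=np.int8)
        counts = {}
        n_sweeps = 20_000
        for _ in range(n_sweeps):
            update_latent_occupancy(z, r_phi, kernel, psi1, dts, det_ll1, rng)
            key = tuple(z.ravel())
            counts[key] = counts.get(key, 0) + 1
        tv = 0.5 * sum(abs(counts.get(h, 0) / n_sweeps - p)
                       for h, p in exact.items())
        assert tv < 0.03

    def test_inconsistent_perfect_records_rejected(self):
        records = pd.DataFrame([
            (0, 0, "range_map", 2, 0, 1, 1),
            (1, 1, "range_map", 2, 0, 1, 0),
        ], columns=RECORD_COLS)
        with pytest.raises(ValueError, match="inconsistent"):
            small_fitdata(records=records)

    def test_unknown_cell_rejected(self):
        records = pd.DataFrame(
            [(0, 0, "settlement", 0, 99, 5, 0)], columns=RECORD_COLS)
        with pytest.raises(ValueError, match="cell"):
            small_fitdata(records=records)


@pytest.fixture(scope="module")
def prior_draws():
    data = small_fitdata()
    cfg = MCMCConfig(n_chains=2, n_iter=2000, burn_in=400, thinning=2, seed=7,
                     prior_only=True)
    return run_mcmc(data, cfg)


class TestPriorRecovery:
    def test_alpha_reproduces_gamma_prior_moments(self, prior_draws):
        import arviz as az
        # with no records the marginal posterior of alpha is Gamma(3, 1)
        arr = prior_draws.params["alpha"]
        ess = float(az.ess(az.convert_to_dataset(arr))["x"])
        flat = arr.reshape(-1)
        se_mean = flat.std() / np.sqrt(ess)
        assert abs(flat.mean() - 3.0) < 3 * se_mean + 0.05
        assert abs(flat.var() - 3.0) < 1.0

    def test_inclusion_probabilities_match_prior(self, prior_draws):
        import arviz as az
        for path, arr in ((p, prior_draws.params[f"I_{p}"])
                          for p in ("phi~lu", "wt~ele", "lu~ele")):
            ess = max(float(az.ess(az.convert_to_dataset(arr))["x"]), 10.0)
            se = 0.5 / np.sqrt(ess)
            assert abs(arr.mean() - 0.5) < 3 * se + 0.02, path

    def test_psi1_uniform_prior_recovered(self, prior_draws):
        flat = prior_draws.pooled("psi1")
        assert abs(flat.mean() - 0.5) < 0.06
        assert abs(flat.var() - 1 / 12) < 0.02


class TestReproducibility:
    def test_identical_seeds_identical_draws(self):
        data = small_fitdata()
        cfg = MCMCConfig(n_chains=2, n_iter=60, burn_in=20, thinning=2, seed=5)
        a = run_mcmc(data, cfg)
        b = run_mcmc(data, cfg)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k]), k
        assert np.array_equal(a.z, b.z)


class TestConvergenceDiagnostics:
    def _draws_from(self, arr_dict):
        cfg = MCMCConfig(n_chains=2, n_iter=10, burn_in=5, thinning=1)
        return PosteriorDraws(params=arr_dict, z=None, config=cfg,
                              chain_seeds=[0, 1])

    def test_iid_chains_converged(self, rng):
        draws = self._draws_from({"x": rng.normal(size=(4, 1000))})
        diag = convergence_diagnostics(draws)
        assert diag.loc[0, "rhat"] < 1.01
        assert not diag.loc[0, "warn"]

    def test_disjoint_chains_flagged(self, rng):
        arr = rng.normal(size=(2, 500))
        arr[1] += 10.0
        diag = convergence_diagnostics(self._draws_from({"x": arr}))
        assert diag.loc[0, "rhat"] > 1.1
        assert diag.loc[0, "warn"]

    def test_ar1_effective_sample_size(self, rng):
        rho, n = 0.5, 4000
        chains = np.empty((4, n))
        for c in range(4):
            x = np.empty(n)
            x[0] = rng.normal()
            eps = rng.normal(size=n) * np.sqrt(1 - rho ** 2)
            for i in range(1, n):
                x[i] = rho * x[i - 1] + eps[i]
            chains[c] = x
        diag = convergence_diagnostics(self._draws_from({"x": chains}))
        expected = 4 * n * (1 - rho) / (1 + rho)
        assert abs(diag.loc[0, "ess"] - expected) / expected < 0.2
        assert diag.loc[0, "lag1_autocorr"] == pytest.approx(rho, abs=0.05)

    def test_single_chain_rejected(self, rng):
        draws = self._draws_from({"x": rng.normal(size=(1, 100))})
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics(draws)


class TestScenarioPooling:
    def _fake(self, value, label, n_chains=2, n_draws=10):
        cfg = MCMCConfig(n_chains=n_chains, n_iter=n_draws + 1, burn_in=0,
                         thinning=1)
        return PosteriorDraws(
            params={"x": np.full((n_chains, n_draws), value)}, z=None,
            config=cfg, chain_seeds=list(range(n_chains)), scenario=label)

    def test_four_scenarios_concatenate(self):
        pooled = pool_scenarios([self._fake(v, s.label) for v, s in
                                 zip((1.0, 2.0, 3.0, 4.0), SCENARIO_FACTORIAL)])
        assert pooled.pooled("x").shape == (80,)
        assert pooled.pooled("x").mean() == pytest.approx(2.5)
        assert len(pooled.scenario_labels) == 8

    def test_labels_survive(self):
        pooled = pool_scenarios([self._fake(1, "lu=constant,asia=no"),
                                 self._fake(2, "lu=constant,asia=yes")])
        assert pooled.scenario_labels[0] == "lu=constant,asia=no"
        assert pooled.scenario_labels[-1] == "lu=constant,asia=yes"

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            pool_scenarios([self._fake(1, "a", n_draws=10),
                            self._fake(2, "b", n_draws=5)])

    def test_explicit_downsampling(self):
        pooled = pool_scenarios([self._fake(1, "a", n_draws=10),
                                 self._fake(2, "b", n_draws=5)],
                                allow_downsample=True)
        assert pooled.n_draws == 5


class TestAsianColonizationScenario:
    def test_no_flag_leaves_sources_empty(self):
        data = apply_asian_colonization_scenario(small_fitdata(), "no")
        assert not data.source_cells.any()

    def test_missing_grid_shape_rejected(self):
        data = small_fitdata()
        data = FitData(cov=data.cov, distances=data.distances,
                       records=empty_records(), scheme=data.scheme,
                       grid_shape=None)
        with pytest.raises(ValueError, match="grid_shape"):
            apply_asian_colonization_scenario(data, "yes")

    def test_strip_is_eastern_column_and_pinned(self):
        data = apply_asian_colonization_scenario(small_fitdata(), "yes")
        # 2x2 grid: cells 1 and 3 form the eastern column
        assert data.source_cells.tolist() == [False, True, False, True]
        assert data.pin[1].all() and data.pin[3].all()
        assert np.all(data.pin_val[1] == 1)

    def test_source_adds_kernel_weight_to_neighbors(self):
        # a permanently occupied source at distance 1 with alpha = 2
        # contributes exactly e^-2 to the adjacent cell's connectivity
        data = apply_asian_colonization_scenario(small_fitdata(), "yes")
        z = data.source_cells.astype(int)  # only sources occupied
        s = connectivity(z, data.distances, alpha=2.0)
        assert s[0] == pytest.approx(2 * np.exp(-2.0))  # two sources at d=1
        empty = connectivity(np.zeros(4, dtype=int), data.distances, 2.0)
        assert np.allclose(empty, 0.0)
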