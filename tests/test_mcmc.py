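"""Sampler validity: initialization, determinism, prior recovery, diagnostics."""

import numpy as np
import pytest
from scipy import stats

import sealbycatch as sb
from sealbycatch.mcmc import ChainResult, diagnostics


class TestInitializeState:
    def test_finite_log_posterior(self, fixture_dataset, default_priors):
        state = sb.initialize_state(fixture_dataset, default_priors, seed=1)
        assert np.isfinite(sb.log_posterior(state, fixture_dataset, default_priors))

    def test_deterministic(self, fixture_dataset, default_priors):
        a = sb.initialize_state(fixture_dataset, default_priors, seed=1)
        b = sb.initialize_state(fixture_dataset, default_priors, seed=1)
        assert a.n_total == b.n_total
        assert np.array_equal(a.n_area, b.n_area)
        assert np.array_equal(a.log_catchability, b.log_catchability, equal_nan=True)

    def test_naive_moment_estimate_for_e1_trap(self, fixture_dataset, default_priors):
        state = sb.initialize_state(fixture_dataset, default_priors, seed=0)
        a = fixture_dataset.area_ids.index("E1")
        lc_original = state.log_catchability[a, 0] + np.log(default_priors.effort_scaling)
        # y / (N_a * E_sample) with N_a at the rounded prior expectation
        assert lc_original == pytest.approx(np.log(104 / (2125 * 2458)), abs=0.05)

    def test_allocation_sums_and_dominates_observations(self, fixture_dataset, default_priors):
        state = sb.initialize_state(fixture_dataset, default_priors, seed=0)
        assert state.n_area.sum() == int(np.rint(state.n_total))
        y = fixture_dataset.bycatch_sampled().sum(axis=1)
        assert np.all(state.n_area[:-1] >= y)


class TestRunMcmc:
    def test_bit_identical_given_seed(self, fixture_dataset, default_priors):
        config = sb.RunConfig(
            seed=9, n_chains=2, n_iterations=800, n_burnin=400, thinning=2
        )
        a = sb.run_mcmc(fixture_dataset, default_priors, config)
        b = sb.run_mcmc(fixture_dataset, default_priors, config)
        assert np.array_equal(a.n_total, b.n_total)
        assert np.array_equal(a.n_area, b.n_area)
        assert np.array_equal(a.log_catchability, b.log_catchability, equal_nan=True)
        assert np.array_equal(a.log_post, b.log_post)

    def test_zero_post_burnin_iterations(self, fixture_dataset, default_priors):
        config = sb.RunConfig(seed=1, n_chains=1, n_iterations=500, n_burnin=500)
        chain = sb.run_mcmc(fixture_dataset, default_priors, config)
        assert chain.n_draws == 0
        assert chain.metadata["n_iterations"] == 500

    def test_stored_draws_have_finite_log_posterior(self, fixture_chain):
        assert np.all(np.isfinite(fixture_chain.log_post))
        assert all(0 <= v <= 1 for v in fixture_chain.acceptance_rates.values())

    def test_allocation_invariant_holds_along_chain(self, fixture_chain, fixture_dataset):
        totals = np.rint(fixture_chain.flat("n_total")).astype(int)
        sums = fixture_chain.flat("n_area").sum(axis=1)
        assert np.array_equal(totals, sums)
        y = fixture_dataset.bycatch_sampled().sum(axis=1)
        assert np.all(fixture_chain.flat("n_area")[:, :-1] >= y)

    def test_save_load_round_trip(self, fixture_dataset, default_priors, tmp_path):
        config = sb.RunConfig(seed=2, n_chains=2, n_iterations=600, n_burnin=300, thinning=3)
        chain = sb.run_mcmc(fixture_dataset, default_priors, config)
        chain.save(tmp_path / "draws")
        back = ChainResult.load(tmp_path / "draws")
        assert np.allclose(back.n_total, chain.n_total)
        assert np.array_equal(back.n_area, chain.n_area)
        assert np.allclose(back.log_catchability, chain.log_catchability, equal_nan=True)
        assert back.composition_labels == chain.composition_labels


@pytest.fixture(scope="module")
def prior_chain(fixture_dataset, default_priors):
    config = sb.RunConfig(
        seed=17, n_chains=2, n_iterations=12_000, n_burnin=3_000, thinning=3
    )
    return sb.run_mcmc(
        fixture_dataset, default_priors, config, include_likelihood=False
    )


class TestPriorRecovery:
    """With the likelihood disabled the sampler must reproduce its priors
    (the standard MCMC validity check).  Agreement is tested on the
    probability scale: the empirical CDF at the oracle's deciles must match
    the decile level within Monte-Carlo error scaled by the effective
    sample size."""

    @staticmethod
    def _check_deciles(samples, oracle_quantiles, ess):
        levels = np.arange(0.1, 0.95, 0.1)
        for p, q in zip(levels, oracle_quantiles):
            f = np.mean(samples <= q)
            se = np.sqrt(p * (1 - p) / ess)
            assert abs(f - p) < 4 * se + 0.005, f"decile {p}: {f}"

    def _ess(self, chain, name):
        return float(chain.diagnostics.loc[name, "ess_bulk"])

    def test_n_total_marginal(self, prior_chain, default_priors):
        q = stats.lognorm(
            s=default_priors.n_total_log_scale,
            scale=np.exp(default_priors.n_total_log_location),
        ).ppf(np.arange(0.1, 0.95, 0.1))
        self._check_deciles(
            prior_chain.flat("n_total"), q, self._ess(prior_chain, "n_total")
        )

    def test_sigma2_marginal(self, prior_chain, default_priors):
        q = stats.invgamma(
            default_priors.sigma2_df / 2,
            scale=default_priors.sigma2_df * default_priors.sigma2_scale / 2,
        ).ppf(np.arange(0.1, 0.95, 0.1))
        self._check_deciles(
            prior_chain.flat("sigma2"), q, self._ess(prior_chain, "sigma2")
        )

    def test_log_catchability_marginal(self, prior_chain, default_priors):
        # marginal of one ln C is a scale mixture; use a large direct
        # Monte-Carlo oracle for its deciles
        rng = np.random.default_rng(0)
        n = 400_000
        s2 = default_priors.sigma2_df / rng.chisquare(default_priors.sigma2_df, n)
        s2 *= default_priors.sigma2_scale
        mu = rng.normal(default_priors.mu_c_location, default_priors.mu_c_scale, n)
        oracle = rng.normal(mu, np.sqrt(s2))
        q = np.quantile(oracle, np.arange(0.1, 0.95, 0.1))
        a = prior_chain.area_ids.index("E1")
        samples = prior_chain.flat("log_catchability")[:, a, 0]
        self._check_deciles(samples, q, self._ess(prior_chain, "log_c_trap_E1"))

    def test_allocation_marginal_tracks_dirichlet_multinomial(
        self, prior_chain, default_priors
    ):
        # F2's allocation share should follow its Beta marginal closely
        share = (
            prior_chain.flat("n_area")[:, 4] / prior_chain.flat("n_area").sum(axis=1)
        )
        s = default_priors.dirichlet_scale
        q = stats.beta(s * 0.30, s * 0.70).ppf(np.arange(0.1, 0.95, 0.1))
        self._check_deciles(share, q, self._ess(prior_chain, "n_F2"))


class TestDiagnostics:
    @staticmethod
    def _make_chain(n_total_arrays, seed=0):
        """Minimal one-area ChainResult holding the given (C, D) n_total."""
        arr = np.asarray(n_total_arrays, dtype=float)
        c, d = arr.shape
        rng = np.random.default_rng(seed)
        sampled = np.array([[True, False]])
        return ChainResult(
            n_total=arr,
            n_area=rng.integers(100, 200, size=(c, d, 2)),
            log_catchability=np.where(
                sampled[None, None], rng.standard_normal((c, d, 1, 2)), np.nan
            ),
            mu=rng.standard_normal((c, d)),
            sigma2=np.exp(rng.standard_normal((c, d))),
            log_post=np.zeros((c, d)),
            seed=seed,
            acceptance_rates={},
            area_ids=["A1"],
            countries=["X"],
            composition_labels=["A1", "outside"],
            effort_scaling=1e-4,
            sampled_mask=sampled,
        )

    def test_white_noise_ess_close_to_sample_size(self):
        rng = np.random.default_rng(1)
        chain = self._make_chain(rng.standard_normal((2, 2000)))
        table = diagnostics([chain])
        n = 4000
        assert 0.7 * n < table.loc["n_total", "ess_bulk"] < 1.3 * n
        assert table.loc["n_total", "rhat"] == pytest.approx(1.0, abs=0.01)
        assert not table.loc["n_total", "flagged"]

    def test_identical_chains_are_not_flagged(self):
        rng = np.random.default_rng(2)
        row = rng.standard_normal(1500)
        chain = self._make_chain(np.stack([row, row]))
        table = diagnostics([chain])
        assert table.loc["n_total", "rhat"] < 1.05

    def test_shifted_chains_are_flagged(self):
        rng = np.random.default_rng(3)
        chain = self._make_chain(
            np.stack([rng.standard_normal(1000), rng.standard_normal(1000) + 5.0])
        )
        table = diagnostics([chain])
        assert table.loc["n_total", "flagged"]

    def test_unequal_lengths_rejected(self):
        a = self._make_chain(np.zeros((1, 100)))
        b = self._make_chain(np.zeros((1, 50)))
        with pytest.raises(ValueError):
            diagnostics([a, b])

    def test_fixture_chains_converge(self, fixture_chain):
        assert not fixture_chain.diagnostics["flagged"].any()
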