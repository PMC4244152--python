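"""Competing-risks probabilities, the survey likelihood and the joint posterior."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sealbycatch as sb
from sealbycatch.likelihood import ModelState, PosteriorTerms


def _random_state(data, priors, rng) -> ModelState:
    """A feasible random state for oracle comparisons."""
    n_total = float(rng.uniform(25_000, 45_000))
    total = int(np.rint(n_total))
    base = priors.dirichlet_base
    n_area = rng.multinomial(total, base)
    y = data.bycatch_sampled().sum(axis=1)
    n_area[: data.n_areas] = np.maximum(n_area[: data.n_areas], y)
    n_area[-1] += total - n_area.sum()
    lc = np.where(data.sampled_mask(), rng.normal(-4.0, 1.5, size=(data.n_areas, 2)), np.nan)
    return ModelState(
        n_total=n_total,
        n_area=n_area,
        log_catchability=lc,
        mu=float(rng.normal(-4, 1)),
        sigma2=float(rng.uniform(0.3, 4.0)),
    )


class TestBycatchProbabilities:
    def test_no_exposure_means_certain_survival(self):
        deaths, surv = sb.bycatch_probabilities(np.array([1e-6, 2e-6]), np.zeros(2))
        assert surv == 1.0
        assert np.all(deaths == 0)

    def test_single_gear_closed_form(self):
        # one gear: P(death) = 1 - exp(-C*E)
        deaths, surv = sb.bycatch_probabilities(np.array([1.5e-6]), np.array([58_863.0]))
        assert deaths[0] == pytest.approx(-np.expm1(-1.5e-6 * 58_863), rel=1e-12)
        assert deaths[0] == pytest.approx(0.08451, abs=5e-5)

    def test_equal_hazards_split_evenly(self):
        deaths, surv = sb.bycatch_probabilities(
            np.array([2e-6, 1e-6]), np.array([1000.0, 2000.0])
        )
        assert deaths[0] == pytest.approx(deaths[1], rel=1e-12)
        assert deaths.sum() == pytest.approx(1 - surv, rel=1e-12)

    @given(
        lc=st.lists(st.floats(-18, -2), min_size=1, max_size=3),
        le=st.lists(st.floats(0, 12), min_size=3, max_size=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_property(self, lc, le):
        c = np.exp(np.array(lc))
        e = np.exp(np.array(le[: len(lc)]))
        deaths, surv = sb.bycatch_probabilities(c, e)
        assert deaths.sum() + surv == pytest.approx(1.0, abs=1e-12)
        assert np.all(deaths >= 0) and 0 <= surv <= 1

    def test_monotone_in_catchability_and_effort(self):
        base = sb.bycatch_probabilities(np.array([1e-6, 1e-6]), np.array([5e4, 5e4]))[0]
        up_c = sb.bycatch_probabilities(np.array([2e-6, 1e-6]), np.array([5e4, 5e4]))[0]
        up_e = sb.bycatch_probabilities(np.array([1e-6, 1e-6]), np.array([1e5, 5e4]))[0]
        assert up_c[0] > base[0] and up_e[0] > base[0]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sb.bycatch_probabilities(np.array([1e-6]), np.array([-1.0]))
        with pytest.raises(ValueError):
            sb.bycatch_probabilities(np.array([0.0]), np.array([10.0]))


class TestMemorylessFactorization:
    """Splitting the year's effort into a surveyed and a remaining phase and
    exposing survivors sequentially must give the same distribution of
    (deaths by gear, survivors) as a single exposure to the total effort,
    when both gears are split in the same proportion."""

    @staticmethod
    def _direct_pmf(n, c, e):
        deaths, surv = sb.bycatch_probabilities(c, e)
        p = np.append(deaths, surv)
        out = {}
        for d1 in range(n + 1):
            for d2 in range(n + 1 - d1):
                s = n - d1 - d2
                out[(d1, d2)] = math.exp(
                    stats.multinomial(n, p).logpmf([d1, d2, s])
                )
        return out

    @pytest.mark.parametrize("n,frac", [(6, 0.3), (12, 0.5), (20, 0.21)])
    def test_sequential_equals_direct(self, n, frac):
        c = np.array([3e-5, 1.2e-5])
        e = np.array([9_000.0, 4_000.0])
        direct = self._direct_pmf(n, c, e)
        pmf1 = self._direct_pmf(n, c, frac * e)
        sequential = {k: 0.0 for k in direct}
        for (a1, a2), p1 in pmf1.items():
            s1 = n - a1 - a2
            pmf2 = self._direct_pmf(s1, c, (1 - frac) * e)
            for (b1, b2), p2 in pmf2.items():
                sequential[(a1 + b1, a2 + b2)] += p1 * p2
        for k in direct:
            assert sequential[k] == pytest.approx(direct[k], abs=1e-12)


class TestSurveyLogLikelihood:
    def test_small_case_matches_multinomial_oracle(self, fixture_dataset, default_priors):
        terms = PosteriorTerms(fixture_dataset, default_priors)
        a = fixture_dataset.area_ids.index("S2")  # both gears sampled
        lc = np.array([np.log(2.0), np.log(1.0)])  # scaled units
        es = terms.e_sampled[a]
        deaths, surv = sb.bycatch_probabilities(np.exp(lc), es)
        n_a = 100
        y = fixture_dataset.bycatch_sampled()[a]
        oracle = stats.multinomial(n_a, np.append(deaths, surv)).logpmf(
            np.append(y, n_a - y.sum())
        )
        assert terms.loglik_area(a, n_a, lc) == pytest.approx(float(oracle), rel=1e-10)

    def test_single_gear_area_reduces_to_binomial(self, fixture_dataset, default_priors):
        # S1 has only gill sampled: the multinomial collapses to a binomial
        # with success probability 1 - exp(-h); with y = 0 it would further
        # collapse to N_a * ln(survival)
        terms = PosteriorTerms(fixture_dataset, default_priors)
        a = fixture_dataset.area_ids.index("S1")
        lc = np.array([np.nan, -1.0])
        h = np.exp(-1.0) * terms.e_sampled[a, 1]
        n_a, y = 50, 20
        expected = (
            math.lgamma(n_a + 1)
            - math.lgamma(y + 1)
            - math.lgamma(n_a - y + 1)
            + y * np.log(-np.expm1(-h))
            - h * (n_a - y)
        )
        assert terms.loglik_area(a, n_a, lc) == pytest.approx(expected, rel=1e-10)

    def test_impossible_state_returns_neg_inf(self, fixture_dataset, default_priors):
        terms = PosteriorTerms(fixture_dataset, default_priors)
        a = fixture_dataset.area_ids.index("E1")  # y = 104
        assert terms.loglik_area(a, 50, np.array([-1.0, np.nan])) == -np.inf

    def test_unsampled_area_contributes_nothing(self, fixture_dataset, default_priors):
        terms = PosteriorTerms(fixture_dataset, default_priors)
        a = fixture_dataset.area_ids.index("F3")
        assert terms.loglik_area(a, 700, np.array([np.nan, np.nan])) == 0.0

    def test_unimodal_in_log_catchability(self, fixture_dataset, default_priors):
        terms = PosteriorTerms(fixture_dataset, default_priors)
        a = fixture_dataset.area_ids.index("E1")
        grid = np.linspace(np.log(1e-8), np.log(1e-3), 120) - np.log(1e-4)
        vals = [terms.loglik_area(a, 2000, np.array([g, np.nan])) for g in grid]
        peak = int(np.argmax(vals))
        assert 0 < peak < len(grid) - 1
        assert all(b >= a for a, b in zip(vals[: peak - 1], vals[1:peak]))
        assert all(b <= a for a, b in zip(vals[peak:-1], vals[peak + 1 :]))


class TestLogPosterior:
    def test_matches_independent_sum_of_terms(self, fixture_dataset, default_priors):
        """Re-coded oracle: scipy distributions, different assembly order."""
        data, priors = fixture_dataset, default_priors
        rng = np.random.default_rng(21)
        sampled = data.sampled_mask()
        es = data.efforts_sampled() * priors.effort_scaling
        y = data.bycatch_sampled()
        for _ in range(10):
            st_ = _random_state(data, priors, rng)
            oracle = stats.lognorm(
                s=priors.n_total_log_scale, scale=np.exp(priors.n_total_log_location)
            ).logpdf(st_.n_total)
            oracle += float(
                stats.dirichlet_multinomial(
                    priors.dirichlet_scale * priors.dirichlet_base,
                    int(np.rint(st_.n_total)),
                ).logpmf(st_.n_area)
            )
            oracle += stats.norm(st_.mu, np.sqrt(st_.sigma2)).logpdf(
                st_.log_catchability[sampled]
            ).sum()
            oracle += stats.norm(priors.mu_c_location, priors.mu_c_scale).logpdf(st_.mu)
            oracle += stats.invgamma(
                priors.sigma2_df / 2, scale=priors.sigma2_df * priors.sigma2_scale / 2
            ).logpdf(st_.sigma2)
            for a in range(data.n_areas):
                g = np.flatnonzero(sampled[a])
                if g.size == 0:
                    continue
                deaths, surv = sb.bycatch_probabilities(
                    np.exp(st_.log_catchability[a, g]), es[a, g]
                )
                counts = np.append(y[a, g], st_.n_area[a] - y[a, g].sum())
                oracle += stats.multinomial(
                    int(st_.n_area[a]), np.append(deaths, surv)
                ).logpmf(counts)
            ours = sb.log_posterior(st_, data, priors)
            assert ours == pytest.approx(float(oracle), rel=1e-9)

    def test_infeasible_allocation_is_impossible(self, fixture_dataset, default_priors):
        rng = np.random.default_rng(5)
        st_ = _random_state(fixture_dataset, default_priors, rng)
        st_.n_area[0] = 10  # fewer seals than observed by-catch in E1
        st_.n_area[-1] += 0  # sum now broken too; both paths give -inf
        assert sb.log_posterior(st_, fixture_dataset, default_priors) == -np.inf

    def test_prior_only_when_no_data(self, fixture_dataset, default_priors):
        rng = np.random.default_rng(6)
        st_ = _random_state(fixture_dataset, default_priors, rng)
        terms = PosteriorTerms(fixture_dataset, default_priors, include_likelihood=False)
        full = PosteriorTerms(fixture_dataset, default_priors)
        assert terms.log_posterior(st_) == pytest.approx(
            full.log_posterior(st_) - full.loglik_all(st_).sum(), rel=1e-9
        )


class TestExpectedTotalBycatch:
    def test_zero_catchability(self, fixture_dataset):
        n = 34_000 * fixture_dataset.prop_expected_vector(False)
        assert sb.expected_total_bycatch(0.0, fixture_dataset, n) == 0.0

    def test_manual_sum_oracle(self, fixture_dataset):
        n = 34_000 * fixture_dataset.prop_expected_vector(False)
        c = 3e-6
        manual = 0.0
        for i, r in enumerate(fixture_dataset.records):
            e = r.trap.total_effort + r.gill.total_effort
            manual += n[i] * (1 - math.exp(-c * e))
        assert sb.expected_total_bycatch(c, fixture_dataset, n) == pytest.approx(manual)

    def test_monotone_in_catchability(self, fixture_dataset):
        n = 34_000 * fixture_dataset.prop_expected_vector(False)
        vals = [
            sb.expected_total_bycatch(c, fixture_dataset, n)
            for c in (1e-7, 1e-6, 1e-5, 1e-4)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))
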