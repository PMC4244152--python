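"""Competing-risks by-catch likelihood and the joint log posterior.

A seal in sub-area ``a`` faces additive hazards from the gears fished
there: with catchability ``C_g`` and effort ``E_g`` the total hazard is
``h = sum_g C_g E_g``, the probability of surviving the year is
``exp(-h)`` (exponential "lifetime" in effort units), and the probability
of dying in gear ``g`` is the competing-risks share
``(C_g E_g / h) * (1 - exp(-h))``.  Given the average number of seals
``N_a`` present, the vector (deaths per gear, survivors) is multinomial.
The survey likelihood applies these probabilities at the *sampled* efforts
only; total efforts enter through the posterior-predictive layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import StudyDataset
from .priors import PriorSpec, dirichlet_multinomial_log_pmf, sigma2_log_prior

__all__ = [
    "ModelState",
    "bycatch_probabilities",
    "survey_log_likelihood",
    "log_posterior",
    "expected_total_bycatch",
    "PosteriorTerms",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelState:
    """One point in parameter space.

    ``log_catchability`` is an (n_areas, 2) array on the *down-scaled*
    effort scale with NaN in slots that carry no sampled effort; ``n_area``
    has one extra trailing entry for the residual "outside study area"
    category and must sum to ``round(n_total)``.
    """

    n_total: float
    n_area: np.ndarray  # int, shape (n_areas + 1,)
    log_catchability: np.ndarray  # float, shape (n_areas, 2), NaN if unsampled
    mu: float
    sigma2: float

    def copy(self) -> "ModelState":
        return ModelState(
            n_total=self.n_total,
            n_area=self.n_area.copy(),
            log_catchability=self.log_catchability.copy(),
            mu=self.mu,
            sigma2=self.sigma2,
        )

    def catchability(self, effort_scaling: float) -> np.ndarray:
        """Catchabilities in original effort units (NaN where unsampled)."""
        return np.exp(self.log_catchability) * effort_scaling


def bycatch_probabilities(
    catchabilities: np.ndarray, efforts: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-gear death probabilities and the survival probability.

    Zero-effort gears get death probability 0; with no exposure at all the
    survival probability is exactly 1.  The probabilities always sum to 1.
    """
    c = np.asarray(catchabilities, dtype=float)
    e = np.asarray(efforts, dtype=float)
    if np.any(e < 0):
        raise ValueError("efforts must be >= 0")
    if np.any((e > 0) & (c <= 0)):
        raise ValueError("catchability must be > 0 wherever effort is > 0")
    hazards = np.where(e > 0, c * e, 0.0)
    h = hazards.sum()
    if h == 0:
        return np.zeros_like(hazards), 1.0
    total_death = -np.expm1(-h)
    deaths = hazards / h * total_death
    return deaths, float(np.exp(-h))


class PosteriorTerms:
    """Precomputed arrays and term-wise evaluation of the log posterior.

    The sampler keeps one instance and re-evaluates only the terms a block
    proposal touches.  ``tie`` maps a (area_index, gear_index) slot to
    another slot whose log-catchability it copies before the likelihood is
    evaluated (used for the F2 counterfactual refit).
    """

    def __init__(
        self,
        data: StudyDataset,
        priors: PriorSpec,
        include_likelihood: bool = True,
        tie: dict[tuple[int, int], tuple[int, int]] | None = None,
    ) -> None:
        self.data = data
        self.priors = priors
        self.include_likelihood = include_likelihood
        self.y = data.bycatch_sampled()
        self.e_sampled = data.efforts_sampled() * priors.effort_scaling
        self.e_total = data.efforts_total() * priors.effort_scaling
        self.sampled = data.sampled_mask()
        self.tie = dict(tie or {})
        for dst, src in self.tie.items():
            if not self.sampled[src]:
                raise ValueError(f"tie source {src} carries no sampled effort")
        # slots that are free parameters (sampled and not tied)
        self.param_mask = self.sampled.copy()
        for dst in self.tie:
            self.param_mask[dst] = False
        # slots whose data enter the likelihood (sampled, incl. tied dst)
        self.lik_mask = self.sampled.copy()
        for dst in self.tie:
            self.lik_mask[dst] = True
        self.n_areas = data.n_areas
        # per-area scalar views for the sampler's hot path
        self._gears = [
            [int(g) for g in np.flatnonzero(self.lik_mask[a])]
            for a in range(self.n_areas)
        ]
        self._y_sub = [
            [float(self.y[a, g]) for g in gs] for a, gs in enumerate(self._gears)
        ]
        self._es_sub = [
            [float(self.e_sampled[a, g]) for g in gs]
            for a, gs in enumerate(self._gears)
        ]
        self._y_lgamma = [
            sum(math.lgamma(y + 1.0) for y in ys) for ys in self._y_sub
        ]
        self._y_tot = [sum(ys) for ys in self._y_sub]
        self.ysum = self.y.sum(axis=1)
        # constants of the scaled inverse-chi-squared hyperprior
        a = priors.sigma2_df / 2.0
        b = priors.sigma2_df * priors.sigma2_scale / 2.0
        self._s2_shape = a
        self._s2_rate = b
        self._s2_logconst = a * math.log(b) - math.lgamma(a)
        self.base = priors.dirichlet_base
        self.alpha = priors.dirichlet_scale * self.base / self.base.sum()
        self.a0 = float(self.alpha.sum())

    # -- individual terms --------------------------------------------------

    def resolved_log_c(self, state: ModelState) -> np.ndarray:
        if not self.tie:
            return state.log_catchability
        lc = state.log_catchability.copy()
        for dst, src in self.tie.items():
            lc[dst] = lc[src]
        return lc

    def loglik_area(self, a: int, n_a: int, log_c_row) -> float:
        """Scalar-math multinomial log pmf for one area (sampler hot path)."""
        gears = self._gears[a]
        if not gears:
            return 0.0
        es = self._es_sub[a]
        ys = self._y_sub[a]
        h = 0.0
        hazards = []
        for i, g in enumerate(gears):
            hz = math.exp(log_c_row[g]) * es[i]
            hazards.append(hz)
            h += hz
        y_tot = self._y_tot[a]
        if h == 0.0:
            return 0.0 if y_tot == 0 else -math.inf
        s_a = n_a - y_tot
        if s_a < 0:
            return -math.inf
        log_total_death = math.log(-math.expm1(-h))
        log_h = math.log(h)
        ll = (
            math.lgamma(n_a + 1.0)
            - math.lgamma(s_a + 1.0)
            - self._y_lgamma[a]
            - h * s_a
        )
        for i, y in enumerate(ys):
            if y:
                if hazards[i] == 0.0:
                    return -math.inf
                ll += y * (math.log(hazards[i]) - log_h + log_total_death)
        return ll

    def loglik_all(self, state: ModelState) -> np.ndarray:
        lc = self.resolved_log_c(state)
        return np.array(
            [
                self.loglik_area(a, int(state.n_area[a]), lc[a])
                for a in range(self.n_areas)
            ]
        )

    def log_prior_n_total(self, n_total: float) -> float:
        if n_total <= 0:
            return -np.inf
        p = self.priors
        z = (np.log(n_total) - p.n_total_log_location) / p.n_total_log_scale
        return float(
            -np.log(n_total) - np.log(p.n_total_log_scale) - 0.5 * (_LOG_2PI + z * z)
        )

    def log_prior_allocation(self, n_area: np.ndarray, n_total: float) -> float:
        total = int(np.rint(n_total))
        if n_area.sum() != total or np.any(n_area < 0):
            return -np.inf
        return dirichlet_multinomial_log_pmf(
            n_area, total, self.base, self.priors.dirichlet_scale
        )

    def log_prior_c_entries(self, state: ModelState) -> np.ndarray:
        """Gaussian log-density of each free log-catchability given (mu, sigma2)."""
        lc = state.log_catchability[self.param_mask]
        z2 = (lc - state.mu) ** 2 / state.sigma2
        return -0.5 * (_LOG_2PI + np.log(state.sigma2) + z2)

    def log_hyperprior_mu(self, mu: float) -> float:
        p = self.priors
        z = (mu - p.mu_c_location) / p.mu_c_scale
        return float(-np.log(p.mu_c_scale) - 0.5 * (_LOG_2PI + z * z))

    def log_hyperprior_sigma2(self, sigma2: float) -> float:
        # closed form of the scaled inverse-chi-squared density; agrees
        # with priors.sigma2_log_prior (asserted in the test suite)
        if sigma2 <= 0:
            return -math.inf
        return (
            self._s2_logconst
            - (self._s2_shape + 1.0) * math.log(sigma2)
            - self._s2_rate / sigma2
        )

    # -- full evaluation ---------------------------------------------------

    def log_posterior(self, state: ModelState) -> float:
        lp = self.log_prior_n_total(state.n_total)
        if not np.isfinite(lp):
            return -np.inf
        lp += self.log_prior_allocation(state.n_area, state.n_total)
        if not np.isfinite(lp):
            return -np.inf
        if state.sigma2 <= 0:
            return -np.inf
        lp += self.log_prior_c_entries(state).sum()
        lp += self.log_hyperprior_mu(state.mu)
        lp += self.log_hyperprior_sigma2(state.sigma2)
        if self.include_likelihood:
            lp += self.loglik_all(state).sum()
        return float(lp)


def survey_log_likelihood(
    record, state: ModelState, data: StudyDataset, priors: PriorSpec
) -> float:
    """Multinomial survey log-likelihood of a single sub-area record."""
    terms = PosteriorTerms(data, priors)
    a = data.area_ids.index(record.area_id)
    return terms.loglik_area(a, int(state.n_area[a]), state.log_catchability[a])


def log_posterior(state: ModelState, data: StudyDataset, priors: PriorSpec) -> float:
    """Joint log posterior density (unnormalised) of a model state."""
    return PosteriorTerms(data, priors).log_posterior(state)


def expected_total_bycatch(
    catchability: float, data: StudyDataset, n_expected: np.ndarray
) -> float:
    """Deterministic expected yearly by-catch at a common catchability.

    Applies ``1 - exp(-C * (E_trap + E_gill))`` with *total* efforts to the
    expected number of seals in each sub-area.  Used for the elicitation
    worked example linking expert by-catch guesses to catchability values.
    """
    if catchability < 0:
        raise ValueError("catchability must be >= 0")
    n_expected = np.asarray(n_expected, dtype=float)
    if n_expected.shape != (data.n_areas,):
        raise ValueError("n_expected must have one entry per sub-area")
    efforts = (data.efforts_total() * data.active_mask()).sum(axis=1)
    return float(np.sum(n_expected * -np.expm1(-catchability * efforts)))
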