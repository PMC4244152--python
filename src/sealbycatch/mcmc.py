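"""Blockwise random-walk Metropolis-Hastings sampler for the by-catch model.

Update blocks per iteration:

* the log-catchabilities of each sub-area jointly (Gaussian random walk);
* the hyperparameters (mu, log sigma2) jointly, with the log-scale
  Jacobian in the acceptance ratio;
* the continuous total population on the log scale, with the induced
  change in round(n_total) absorbed by the residual "outside study area"
  count so the allocation always sums exactly to round(n_total);
* several paired integer transfers between two allocation categories,
  which preserve the sum and respect the feasibility bound
  n_area >= observed by-catch.

Proposal scales adapt towards the target acceptance rate during burn-in
(Robbins-Monro on the log scale) and are frozen afterwards, so the kept
part of the chain is a time-homogeneous Metropolis-Hastings chain.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import RunConfig, StudyDataset
from .likelihood import ModelState, PosteriorTerms
from .priors import PriorSpec

__all__ = [
    "ChainResult",
    "SamplerDivergenceError",
    "initialize_state",
    "run_mcmc",
    "diagnostics",
]

RHAT_FLAG_THRESHOLD = 1.05
_DIVERGENCE_LIMIT = 10_000


class SamplerDivergenceError(RuntimeError):
    pass


class InitializationError(RuntimeError):
    pass


@dataclass
class ChainResult:
    """Post-burn-in, thinned draws from one or more chains.

    Array fields have a leading (chain, draw) shape; ``log_catchability``
    is stored on the down-scaled effort scale with NaN in slots that are
    not model parameters.  ``flat(name)`` concatenates chains.
    """

    n_total: np.ndarray  # (C, D)
    n_area: np.ndarray  # (C, D, n_areas + 1) int
    log_catchability: np.ndarray  # (C, D, n_areas, 2)
    mu: np.ndarray  # (C, D)
    sigma2: np.ndarray  # (C, D)
    log_post: np.ndarray  # (C, D)
    seed: int
    acceptance_rates: dict[str, float]
    area_ids: list[str]
    countries: list[str]
    composition_labels: list[str]
    effort_scaling: float
    sampled_mask: np.ndarray  # (n_areas, 2) bool
    metadata: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    @property
    def n_chains(self) -> int:
        return self.n_total.shape[0]

    @property
    def n_draws(self) -> int:
        return int(self.n_total.shape[0] * self.n_total.shape[1])

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def catchability_draws(self, gear: int, area: int, original_scale: bool = True) -> np.ndarray:
        lc = self.flat("log_catchability")[:, area, gear]
        return np.exp(lc) * (self.effort_scaling if original_scale else 1.0)

    # -- scalar view used for diagnostics and persistence ------------------

    def scalar_arrays(self) -> dict[str, np.ndarray]:
        """Named (chain, draw) arrays for every scalar parameter."""
        out = {"n_total": self.n_total, "mu": self.mu, "sigma2": self.sigma2}
        for k, label in enumerate(self.composition_labels):
            out[f"n_{label}"] = self.n_area[:, :, k]
        gears = ("trap", "gill")
        for a, area in enumerate(self.area_ids):
            for g in range(2):
                if self.sampled_mask[a, g]:
                    out[f"log_c_{gears[g]}_{area}"] = self.log_catchability[:, :, a, g]
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        n_chains, n_draws = self.n_total.shape
        cols["chain"] = np.repeat(np.arange(n_chains), n_draws)
        cols["draw"] = np.tile(np.arange(n_draws), n_chains)
        for name, arr in self.scalar_arrays().items():
            cols[name] = arr.reshape(-1)
        cols["log_post"] = self.log_post.reshape(-1)
        return pd.DataFrame(cols)

    def save(self, prefix: str | Path) -> None:
        """Persist draws as CSV plus a JSON metadata sidecar."""
        import json

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        meta = {
            "seed": self.seed,
            "acceptance_rates": self.acceptance_rates,
            "area_ids": self.area_ids,
            "countries": self.countries,
            "composition_labels": self.composition_labels,
            "effort_scaling": self.effort_scaling,
            "sampled_mask": self.sampled_mask.astype(int).tolist(),
            "metadata": self.metadata,
        }
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "ChainResult":
        import json

        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        chains = sorted(df["chain"].unique())
        n_draws = int((df["chain"] == chains[0]).sum())
        n_areas = len(meta["area_ids"])
        labels = meta["composition_labels"]
        sampled = np.asarray(meta["sampled_mask"], dtype=bool)

        def stack(col: str) -> np.ndarray:
            return np.stack(
                [df.loc[df["chain"] == c, col].to_numpy() for c in chains]
            )

        n_area = np.stack(
            [stack(f"n_{label}") for label in labels], axis=-1
        ).astype(np.int64)
        lc = np.full((len(chains), n_draws, n_areas, 2), np.nan)
        gears = ("trap", "gill")
        for a, area in enumerate(meta["area_ids"]):
            for g in range(2):
                if sampled[a, g]:
                    lc[:, :, a, g] = stack(f"log_c_{gears[g]}_{area}")
        return cls(
            n_total=stack("n_total"),
            n_area=n_area,
            log_catchability=lc,
            mu=stack("mu"),
            sigma2=stack("sigma2"),
            log_post=stack("log_post"),
            seed=meta["seed"],
            acceptance_rates=meta["acceptance_rates"],
            area_ids=meta["area_ids"],
            countries=meta["countries"],
            composition_labels=labels,
            effort_scaling=meta["effort_scaling"],
            sampled_mask=sampled,
            metadata=meta["metadata"],
        )


def initialize_state(
    data: StudyDataset, priors: PriorSpec, seed: int
) -> ModelState:
    """Deterministic feasible starting point with finite log posterior.

    Total population starts at its prior mean, the allocation at the
    rounded prior expectation (repaired to sum exactly and to dominate the
    observed by-catch), log-catchabilities at the naive moment estimate
    ln(y / (N_a * E_sample)) where by-catch was observed and at the
    hyper-prior median otherwise, and (mu, sigma2) at their prior medians.
    The seed only disambiguates repeated calls; the construction itself is
    deterministic.
    """
    del seed  # deterministic construction; kept for interface symmetry
    terms = PosteriorTerms(data, priors)
    n_total = priors.n_total_prior_mean
    total = int(np.rint(n_total))
    base = priors.dirichlet_base / priors.dirichlet_base.sum()
    n_area = np.rint(total * base).astype(np.int64)
    ysum = terms.ysum
    n_area[: data.n_areas] = np.maximum(n_area[: data.n_areas], ysum)
    n_area[-1] += total - n_area.sum()  # repair the sum via the residual
    if n_area[-1] < 0:
        raise InitializationError("observed by-catch exceeds the prior population")
    lc = np.full((data.n_areas, 2), np.nan)
    sampled = data.sampled_mask()
    es = data.efforts_sampled() * priors.effort_scaling
    for a in range(data.n_areas):
        for g in range(2):
            if not sampled[a, g]:
                continue
            y = terms.y[a, g]
            if y > 0:
                lc[a, g] = np.log(y / (n_area[a] * es[a, g]))
            else:
                lc[a, g] = priors.mu_c_location
    sigma2_median = float(
        stats.invgamma.ppf(0.5, a=priors.sigma2_df / 2,
                           scale=priors.sigma2_df * priors.sigma2_scale / 2)
    )
    state = ModelState(
        n_total=float(n_total),
        n_area=n_area,
        log_catchability=lc,
        mu=priors.mu_c_location,
        sigma2=sigma2_median,
    )
    if not np.isfinite(terms.log_posterior(state)):
        raise InitializationError("could not construct a finite starting point")
    return state


class _BlockScale:
    """Robbins-Monro adapted proposal scale for one block."""

    def __init__(self, value: float, target: float, adapt: bool):
        self.log_value = np.log(value)
        self.target = target
        self.adapt = adapt
        self.t = 0

    @property
    def value(self) -> float:
        return float(np.exp(self.log_value))

    def update(self, accepted: bool) -> None:
        if not self.adapt:
            return
        self.t += 1
        gamma = 1.0 / (10.0 + self.t) ** 0.6
        self.log_value += gamma * ((1.0 if accepted else 0.0) - self.target)

    def freeze(self) -> None:
        self.adapt = False


def _single_chain(
    data: StudyDataset,
    priors: PriorSpec,
    config: RunConfig,
    rng: np.random.Generator,
    include_likelihood: bool,
    tie: dict[tuple[int, int], tuple[int, int]] | None,
):
    terms = PosteriorTerms(data, priors, include_likelihood, tie)
    state = initialize_state(data, priors, config.seed)
    if tie:
        lc = state.log_catchability
        for dst, src in terms.tie.items():
            lc[dst] = np.nan  # tied slot is not a parameter
    n_areas = data.n_areas
    n_cat = n_areas + 1
    alpha = terms.alpha
    alpha_l = [float(x) for x in alpha]

    # cached terms
    ll = terms.loglik_all(state) if include_likelihood else np.zeros(n_areas)
    lp_c = terms.log_prior_c_entries(state)
    lp_dm = terms.log_prior_allocation(state.n_area, state.n_total)
    lp_nt = terms.log_prior_n_total(state.n_total)
    lp_mu = terms.log_hyperprior_mu(state.mu)
    lp_s2 = terms.log_hyperprior_sigma2(state.sigma2)

    param_mask = terms.param_mask
    c_areas = [a for a in range(n_areas) if param_mask[a].any()]
    c_gears = {a: [int(g) for g in np.flatnonzero(param_mask[a])] for a in c_areas}
    # index of each free slot within the flattened lp_c vector
    flat_index = np.full((n_areas, 2), -1, dtype=int)
    flat_index[param_mask] = np.arange(param_mask.sum())
    c_flat = {a: [int(flat_index[a, g]) for g in c_gears[a]] for a in c_areas}
    # likelihood rows affected by each area's C block (tied slots follow
    # their source)
    dependents = {a: {a} for a in c_areas}
    for dst, src in terms.tie.items():
        dependents.setdefault(src[0], {src[0]}).add(dst[0])

    scales = {f"c_{data.area_ids[a]}": _BlockScale(0.3, config.target_acceptance, config.adapt)
              for a in c_areas}
    scales["hyper"] = _BlockScale(0.15, config.target_acceptance, config.adapt)
    scales["n_total"] = _BlockScale(0.02, config.target_acceptance, config.adapt)
    scales["transfer"] = _BlockScale(200.0, config.target_acceptance, config.adapt)

    min_area = np.concatenate([terms.ysum, [0]])  # feasibility floor per category

    LOG_2PI = math.log(2.0 * math.pi)

    def norm_logpdf_terms(values: np.ndarray, mu: float, sigma2: float) -> np.ndarray:
        return -0.5 * (LOG_2PI + np.log(sigma2) + (values - mu) ** 2 / sigma2)

    log_s2 = math.log(state.sigma2)
    inv_s2 = 1.0 / state.sigma2

    n_keep = (config.n_iterations - config.n_burnin) // config.thinning
    kept = {
        "n_total": np.empty(n_keep),
        "n_area": np.empty((n_keep, n_cat), dtype=np.int64),
        "log_c": np.full((n_keep, n_areas, 2), np.nan),
        "mu": np.empty(n_keep),
        "sigma2": np.empty(n_keep),
        "log_post": np.empty(n_keep),
    }
    acc = {name: [0, 0] for name in ("c", "hyper", "n_total", "transfer")}
    consecutive_bad = 0
    k_idx = 0

    for it in range(config.n_iterations):
        in_burnin = it < config.n_burnin
        count = not in_burnin
        any_finite_proposal = False

        # --- per-area catchability blocks ---------------------------------
        mu_cur = state.mu
        lc_full = state.log_catchability
        for a in c_areas:
            gears = c_gears[a]
            sc = scales[f"c_{data.area_ids[a]}"]
            step = sc.value
            z = rng.standard_normal(len(gears))
            old_vals = [float(lc_full[a, g]) for g in gears]
            props = [old_vals[i] + step * float(z[i]) for i in range(len(gears))]
            for i, g in enumerate(gears):
                lc_full[a, g] = props[i]
            resolved = terms.resolved_log_c(state)
            delta = 0.0
            new_ll = {}
            for d in dependents[a]:
                v = (
                    terms.loglik_area(d, int(state.n_area[d]), resolved[d])
                    if include_likelihood
                    else 0.0
                )
                new_ll[d] = v
                delta += v - ll[d]
            new_lpc = []
            for i, x in enumerate(props):
                v = -0.5 * (LOG_2PI + log_s2 + (x - mu_cur) ** 2 * inv_s2)
                new_lpc.append(v)
                delta += v - lp_c[c_flat[a][i]]
            if math.isfinite(delta):
                any_finite_proposal = True
            if math.log(rng.random()) < delta:
                for d, v in new_ll.items():
                    ll[d] = v
                for i, k in enumerate(c_flat[a]):
                    lp_c[k] = new_lpc[i]
                accepted = True
            else:
                for i, g in enumerate(gears):
                    lc_full[a, g] = old_vals[i]
                accepted = False
            sc.update(accepted)
            if count:
                acc["c"][0] += accepted
                acc["c"][1] += 1

        # --- hyperparameter block (mu, log sigma2) -------------------------
        sc = scales["hyper"]
        z = rng.standard_normal(2)
        mu_new = state.mu + sc.value * z[0]
        lsig_new = np.log(state.sigma2) + sc.value * z[1]
        sig2_new = float(np.exp(lsig_new))
        lc_free = state.log_catchability[param_mask]
        new_lp_c = norm_logpdf_terms(lc_free, mu_new, sig2_new)
        new_lp_mu = terms.log_hyperprior_mu(mu_new)
        new_lp_s2 = terms.log_hyperprior_sigma2(sig2_new)
        delta = (
            (new_lp_c - lp_c).sum()
            + new_lp_mu
            - lp_mu
            + new_lp_s2
            - lp_s2
            + (lsig_new - np.log(state.sigma2))  # log-walk Jacobian
        )
        if np.isfinite(delta):
            any_finite_proposal = True
        if np.log(rng.random()) < delta:
            state.mu, state.sigma2 = float(mu_new), sig2_new
            lp_c, lp_mu, lp_s2 = new_lp_c, new_lp_mu, new_lp_s2
            log_s2 = math.log(sig2_new)
            inv_s2 = 1.0 / sig2_new
            accepted = True
        else:
            accepted = False
        sc.update(accepted)
        if count:
            acc["hyper"][0] += accepted
            acc["hyper"][1] += 1

        # --- total population ----------------------------------------------
        sc = scales["n_total"]
        nt_new = float(state.n_total * np.exp(sc.value * rng.standard_normal()))
        delta_round = int(np.rint(nt_new)) - int(np.rint(state.n_total))
        res_new = state.n_area[-1] + delta_round
        if res_new < 0:
            accepted = False
            any_finite_proposal = True  # a finite-density rejection, not divergence
        else:
            total_old = int(state.n_area.sum())
            total_new = total_old + delta_round
            res_old = int(state.n_area[-1])
            lg = math.lgamma
            a0 = terms.a0
            a_res = alpha_l[-1]
            dm_delta = (
                lg(total_new + 1.0) - lg(total_old + 1.0)
                - lg(total_new + a0) + lg(total_old + a0)
                + lg(res_new + a_res) - lg(res_new + 1.0)
                - lg(res_old + a_res) + lg(res_old + 1.0)
            )
            new_lp_nt = terms.log_prior_n_total(nt_new)
            delta = (
                new_lp_nt
                - lp_nt
                + dm_delta
                + math.log(nt_new)
                - math.log(state.n_total)
            )
            if math.isfinite(delta):
                any_finite_proposal = True
            if math.log(rng.random()) < delta:
                state.n_total = nt_new
                state.n_area[-1] = res_new
                lp_nt = new_lp_nt
                lp_dm += dm_delta
                accepted = True
            else:
                accepted = False
        sc.update(accepted)
        if count:
            acc["n_total"][0] += accepted
            acc["n_total"][1] += 1

        # --- paired allocation transfers -----------------------------------
        sc = scales["transfer"]
        kmax = max(1, int(np.rint(sc.value)))
        lg = math.lgamma
        for _ in range(config.n_area_transfers):
            i = int(rng.integers(n_cat))
            j = int(rng.integers(n_cat - 1))
            if j >= i:
                j += 1
            k = int(rng.integers(1, kmax + 1))
            nai = int(state.n_area[i])
            naj = int(state.n_area[j])
            ni_new = nai - k
            nj_new = naj + k
            if ni_new < min_area[i]:
                accepted = False
            else:
                dm_delta = (
                    lg(ni_new + alpha_l[i]) - lg(ni_new + 1.0)
                    - lg(nai + alpha_l[i]) + lg(nai + 1.0)
                    + lg(nj_new + alpha_l[j]) - lg(nj_new + 1.0)
                    - lg(naj + alpha_l[j]) + lg(naj + 1.0)
                )
                delta = dm_delta
                new_ll_i = new_ll_j = None
                if include_likelihood:
                    resolved = terms.resolved_log_c(state)
                    if i < n_areas:
                        new_ll_i = terms.loglik_area(i, ni_new, resolved[i])
                        delta += new_ll_i - ll[i]
                    if j < n_areas:
                        new_ll_j = terms.loglik_area(j, nj_new, resolved[j])
                        delta += new_ll_j - ll[j]
                if math.isfinite(delta):
                    any_finite_proposal = True
                if math.log(rng.random()) < delta:
                    state.n_area[i] = ni_new
                    state.n_area[j] = nj_new
                    if new_ll_i is not None:
                        ll[i] = new_ll_i
                    if new_ll_j is not None:
                        ll[j] = new_ll_j
                    lp_dm += dm_delta
                    accepted = True
                else:
                    accepted = False
            sc.update(accepted)
            if count:
                acc["transfer"][0] += accepted
                acc["transfer"][1] += 1

        if not any_finite_proposal:
            consecutive_bad += 1
            if consecutive_bad >= _DIVERGENCE_LIMIT:
                raise SamplerDivergenceError(
                    "no finite-posterior move found in "
                    f"{_DIVERGENCE_LIMIT} consecutive iterations"
                )
        else:
            consecutive_bad = 0

        if it + 1 == config.n_burnin:
            for s in scales.values():
                s.freeze()

        if not in_burnin and (it - config.n_burnin) % config.thinning == 0 and k_idx < n_keep:
            # refresh the accumulated allocation term to avoid drift
            lp_dm = terms.log_prior_allocation(state.n_area, state.n_total)
            kept["n_total"][k_idx] = state.n_total
            kept["n_area"][k_idx] = state.n_area
            kept["log_c"][k_idx] = state.log_catchability
            kept["mu"][k_idx] = state.mu
            kept["sigma2"][k_idx] = state.sigma2
            kept["log_post"][k_idx] = (
                lp_nt + lp_dm + lp_c.sum() + lp_mu + lp_s2 + ll.sum()
            )
            k_idx += 1

    rates = {
        name: (c[0] / c[1] if c[1] else float("nan")) for name, c in acc.items()
    }
    return kept, rates


def run_mcmc(
    data: StudyDataset,
    priors: PriorSpec,
    config: RunConfig,
    include_likelihood: bool = True,
    tie: dict[tuple[int, int], tuple[int, int]] | None = None,
) -> ChainResult:
    """Run the blockwise Metropolis-Hastings sampler.

    Chains are seeded independently from ``config.seed``; identical inputs
    give bit-identical output.  ``include_likelihood=False`` samples the
    prior alone (used for the prior-recovery validity check).  ``tie`` maps
    a (area, gear) slot to another slot whose catchability it shares, for
    counterfactual refits.
    """
    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_kept = []
    rates_per_chain = []
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        kept, rates = _single_chain(data, priors, config, rng, include_likelihood, tie)
        all_kept.append(kept)
        rates_per_chain.append(rates)
    elapsed = time.perf_counter() - t0

    def stack(key: str) -> np.ndarray:
        return np.stack([k[key] for k in all_kept])

    mean_rates = {
        name: float(np.mean([r[name] for r in rates_per_chain]))
        for name in rates_per_chain[0]
    }
    result = ChainResult(
        n_total=stack("n_total"),
        n_area=stack("n_area"),
        log_catchability=stack("log_c"),
        mu=stack("mu"),
        sigma2=stack("sigma2"),
        log_post=stack("log_post"),
        seed=config.seed,
        acceptance_rates=mean_rates,
        area_ids=data.area_ids,
        countries=data.countries,
        composition_labels=data.composition_labels,
        effort_scaling=priors.effort_scaling,
        sampled_mask=PosteriorTerms(data, priors, tie=tie).param_mask,
        metadata={
            "n_iterations": config.n_iterations,
            "n_burnin": config.n_burnin,
            "thinning": config.thinning,
            "n_chains": config.n_chains,
            "elapsed_seconds": elapsed,
            "include_likelihood": include_likelihood,
            "tie": [[list(d), list(s)] for d, s in (tie or {}).items()],
        },
    )
    if result.n_total.shape[1] > 3:
        try:
            result.diagnostics = diagnostics([result])
        except Exception as exc:  # diagnostics must never sink a run
            warnings.warn(f"diagnostics failed: {exc}")
    return result


def diagnostics(chains: Sequence[ChainResult]) -> pd.DataFrame:
    """Split potential-scale-reduction and effective sample size per parameter.

    Accepts either one multi-chain result or several results of equal
    length (their chains are pooled).  Parameters with split-Rhat above
    1.05 are flagged.
    """
    import logging

    import arviz as az

    logging.getLogger("arviz").setLevel(logging.ERROR)  # 1-chain shape nag
    if len(chains) == 0:
        raise ValueError("need at least one chain")
    lengths = {c.n_total.shape[1] for c in chains}
    if len(lengths) != 1:
        raise ValueError("all chains must have equal length")
    merged: dict[str, np.ndarray] = {}
    for name in chains[0].scalar_arrays():
        merged[name] = np.concatenate(
            [c.scalar_arrays()[name] for c in chains], axis=0
        )
    idata = az.from_dict(posterior=merged)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name in merged:
        r = float(rhat[name].values)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess_bulk": float(ess[name].values),
                "flagged": bool(r > RHAT_FLAG_THRESHOLD),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
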