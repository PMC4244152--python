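"""Posterior-predictive by-catch, summaries, sensitivity and scenario runs.

The survey likelihood only explains the by-catch reported by interviewed
fishermen.  The remaining yearly by-catch is predicted per posterior draw
by exposing the survivors of the sampled effort to the remaining effort
(total minus sampled) under the same competing-risks model.  In sub-areas
with no sampled effort for a gear (trap nets in F3, S1 and S3) the
catchability itself is unknown and is drawn from the hierarchical layer
ln C ~ N(mu, sigma2) at each draw's hyperparameters.  The total by-catch
is the observed survey by-catch plus all predicted components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GEARS, RunConfig, StudyDataset, ValidationError
from .mcmc import ChainResult, run_mcmc
from .priors import PriorSpec

__all__ = [
    "BycatchDraws",
    "posterior_predictive",
    "predict_uninterviewed",
    "predict_unsurveyed",
    "predict_total",
    "summarize",
    "default_sensitivity_grid",
    "run_sensitivity",
    "run_f2_counterfactual",
]


@dataclass
class BycatchDraws:
    """Posterior-predictive by-catch samples plus the fixed survey counts.

    ``predicted`` holds one integer count per draw, sub-area and gear;
    ``observed`` the survey by-catch (constant across draws).  Aggregations
    add the observed count to the predicted component draw-by-draw, so the
    total draw is always (survey total) + (predicted components).
    """

    predicted: np.ndarray  # (n_draws, n_areas, 2) int
    observed: np.ndarray  # (n_areas, 2) int
    area_ids: list[str]
    countries: list[str]
    include: str = "all"
    predictive_log_catchability: np.ndarray | None = None  # original scale, NaN if n/a

    @property
    def n_draws(self) -> int:
        return self.predicted.shape[0]

    @property
    def observed_total(self) -> int:
        return int(self.observed.sum())

    def total(self) -> np.ndarray:
        return self.observed_total + self.predicted.sum(axis=(1, 2))

    def by_area(self, area_id: str) -> np.ndarray:
        a = self.area_ids.index(area_id)
        return self.observed[a].sum() + self.predicted[:, a, :].sum(axis=1)

    def by_country(self, country: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.countries) if c == country]
        if not idx:
            raise KeyError(country)
        return self.observed[idx].sum() + self.predicted[:, idx, :].sum(axis=(1, 2))

    def by_gear(self, gear: str) -> np.ndarray:
        g = GEARS.index(gear)
        return self.observed[:, g].sum() + self.predicted[:, :, g].sum(axis=1)

    def trap_share(self) -> np.ndarray:
        return self.by_gear("trap") / self.total()


def posterior_predictive(
    chain: ChainResult,
    data: StudyDataset,
    seed: int,
    include: str = "all",
) -> BycatchDraws:
    """Sample predicted by-catch for each posterior draw.

    ``include`` selects the exposures: "sampled" (remaining effort of
    gears with survey information — the uninterviewed fishermen),
    "unsampled" (gears with no survey information, catchability drawn from
    the hierarchy), or "all" (both, competing jointly within each
    sub-area).
    """
    if include not in ("all", "sampled", "unsampled"):
        raise ValueError(f"unknown include mode {include!r}")
    if chain.n_draws == 0:
        raise ValueError("chain has no draws")
    rng = np.random.default_rng(seed)
    scaling = chain.effort_scaling

    lc = chain.flat("log_catchability").copy()  # scaled units
    for dst, src in chain.metadata.get("tie", []):
        lc[:, dst[0], dst[1]] = lc[:, src[0], src[1]]
    n_area = chain.flat("n_area")[:, : data.n_areas]
    mu = chain.flat("mu")
    sd = np.sqrt(chain.flat("sigma2"))
    n_draws = lc.shape[0]

    y = data.bycatch_sampled()
    ysum = y.sum(axis=1)
    es = data.efforts_sampled()
    et = data.efforts_total()
    if np.any(et - es < -1e-9):
        raise ValidationError("total effort below sampled effort")
    active = data.active_mask()
    known = data.sampled_mask()
    tied_dst = {tuple(d) for d, _ in chain.metadata.get("tie", [])}
    unsampled = active & ~known

    # effort each slot contributes to prediction, in scaled units
    exposure = np.zeros_like(et)
    if include in ("all", "sampled"):
        exposure[known] = (et - es)[known] * scaling
    if include in ("all", "unsampled"):
        exposure[unsampled] = et[unsampled] * scaling

    # hierarchical predictive catchability where the survey is silent
    pred_lc = np.full((n_draws, data.n_areas, 2), np.nan)
    for a in range(data.n_areas):
        for g in range(2):
            if unsampled[a, g]:
                draw = rng.normal(mu, sd)
                lc[:, a, g] = draw
                pred_lc[:, a, g] = draw + np.log(scaling)

    predicted = np.zeros((n_draws, data.n_areas, 2), dtype=np.int64)
    for a in range(data.n_areas):
        gears = np.flatnonzero(exposure[a] > 0)
        if gears.size == 0:
            continue
        survivors = n_area[:, a] - ysum[a]
        # log-space shares keep huge predictive hazards from overflowing
        log_hz = lc[:, a, gears] + np.log(exposure[a, gears])  # (D, G)
        m = log_hz.max(axis=1, keepdims=True)
        w = np.exp(log_hz - m)
        w_sum = w.sum(axis=1)
        with np.errstate(over="ignore"):
            h = np.exp(m[:, 0]) * w_sum
        death_total = -np.expm1(-h)  # -> 1 when the hazard saturates
        pvals = np.empty((n_draws, gears.size + 1))
        pvals[:, :-1] = w / w_sum[:, None] * death_total[:, None]
        # rounding can push the survival cell to -1e-16 when death saturates
        pvals[:, -1] = np.clip(1.0 - pvals[:, :-1].sum(axis=1), 0.0, 1.0)
        counts = rng.multinomial(survivors.astype(np.int64), pvals)
        predicted[:, a, gears] = counts[:, :-1]

    return BycatchDraws(
        predicted=predicted,
        observed=y,
        area_ids=data.area_ids,
        countries=data.countries,
        include=include,
        predictive_log_catchability=pred_lc,
    )


def predict_uninterviewed(chain: ChainResult, data: StudyDataset, seed: int) -> BycatchDraws:
    """Predicted by-catch of fishermen that were not interviewed (gears with
    survey information, remaining effort)."""
    return posterior_predictive(chain, data, seed, include="sampled")


def predict_unsurveyed(chain: ChainResult, data: StudyDataset, seed: int) -> BycatchDraws:
    """Predicted by-catch where no survey information exists for a gear
    (trap nets in F3, S1 and S3): catchability drawn from the hierarchy."""
    return posterior_predictive(chain, data, seed, include="unsampled")


def predict_total(chain: ChainResult, data: StudyDataset, seed: int) -> BycatchDraws:
    """Joint prediction over all remaining exposures (headline totals)."""
    return posterior_predictive(chain, data, seed, include="all")


def summarize(
    draws: BycatchDraws,
    levels: tuple[float, ...] = (0.05, 0.5, 0.8, 0.95),
    round_to: int | None = None,
) -> pd.DataFrame:
    """Posterior summary table per sub-area, country, gear and in total.

    Quantiles use the standard linear-interpolation order-statistic rule
    (numpy's default).  The ``trap_share`` row is the posterior mean (and
    quantiles) of the per-draw fraction of by-catch taken by trap nets.
    ``round_to`` optionally rounds count summaries for reporting.
    """
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    components: dict[str, np.ndarray] = {}
    for area in draws.area_ids:
        components[area] = draws.by_area(area)
    for country in dict.fromkeys(draws.countries):
        components[country] = draws.by_country(country)
    for gear in GEARS:
        components[gear] = draws.by_gear(gear)
    components["total"] = draws.total()
    components["trap_share"] = draws.trap_share()

    rows = []
    for name, x in components.items():
        row = {"component": name, "mean": float(np.mean(x)), "median": float(np.median(x))}
        for lv in levels:
            row[f"q{lv:g}"] = float(np.quantile(x, lv))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("component")
    if round_to:
        counts = table.index != "trap_share"
        table.loc[counts] = (table.loc[counts] / round_to).round() * round_to
    return table


def default_sensitivity_grid(priors: PriorSpec) -> dict[str, PriorSpec]:
    """The standard perturbation grid for prior-sensitivity runs.

    Population prior mean halved and increased by 50%; expected proportion
    of F2, S1 and S2 moved +/-30% (renormalised); catchability hyper-mean
    scale doubled and halved.
    """
    grid: dict[str, PriorSpec] = {}
    for factor in (1.5, 0.5):
        grid[f"n_total_mean_x{factor:g}"] = priors.replace(
            n_total_log_location=priors.n_total_log_location + float(np.log(factor))
        )
    for area in ("F2", "S1", "S2"):
        k = priors.dirichlet_labels.index(area)
        for factor in (1.3, 0.7):
            base = priors.dirichlet_base.copy()
            base[k] *= factor
            base /= base.sum()
            grid[f"prop_{area}_x{factor:g}"] = priors.replace(dirichlet_base=base)
    for factor in (2.0, 0.5):
        grid[f"mu_scale_x{factor:g}"] = priors.replace(
            mu_c_scale=priors.mu_c_scale * factor
        )
    return grid


def run_sensitivity(
    data: StudyDataset,
    priors: PriorSpec,
    config: RunConfig,
    perturbations: dict[str, PriorSpec] | None = None,
    predict_seed: int = 0,
) -> pd.DataFrame:
    """Refit the model under each perturbed prior and compare total by-catch.

    Returns one row per run (including the baseline) with total-by-catch
    summaries and the relative change of the median against the baseline.
    """
    if perturbations is None:
        perturbations = default_sensitivity_grid(priors)
    runs = {"baseline": priors, **perturbations}
    rows = []
    base_median = None
    for name, spec in runs.items():
        chain = run_mcmc(data, spec, config)
        table = summarize(predict_total(chain, data, predict_seed))
        total = table.loc["total"]
        if base_median is None:
            base_median = total["median"]
        rows.append(
            {
                "run": name,
                "median": total["median"],
                "mean": total["mean"],
                "q0.05": total["q0.05"],
                "q0.95": total["q0.95"],
                "median_rel_change": total["median"] / base_median - 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("run")


def run_f2_counterfactual(
    chain: ChainResult,
    data: StudyDataset,
    seed: int = 0,
    donors: tuple[str, ...] = ("F1", "S2"),
    mode: str = "refit",
    priors: PriorSpec | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """What if F2's trap-net catchability resembled F1's or Sweden's?

    The survey reports implausibly few by-caught seals in F2 relative to
    its effort and seal abundance, suggesting under-reporting.  Two
    scenario definitions are provided:

    * ``mode="refit"`` (default): refit the model with F2's trap
      catchability *tied to* the donor area's parameter, so the F2 survey
      data informs the shared catchability; then re-predict.  One row per
      donor — the spread over donors brackets the counterfactual total.
      Requires ``priors`` and ``config``.
    * ``mode="replace"``: keep the baseline fit and only replace F2's trap
      catchability draw-by-draw with the same draw's donor value (donor
      chosen uniformly per draw), then re-predict.  This ignores the F2
      survey evidence about the counterfactual catchability.

    Returns a table with Finland and total summaries per scenario plus the
    baseline, and the mean Finland increment over baseline.
    """
    base = summarize(predict_total(chain, data, seed))
    rows = [
        {
            "scenario": "baseline",
            "finland_median": base.loc["Finland", "median"],
            "finland_mean": base.loc["Finland", "mean"],
            "total_median": base.loc["total", "median"],
            "total_mean": base.loc["total", "mean"],
            "total_q0.05": base.loc["total", "q0.05"],
            "total_q0.95": base.loc["total", "q0.95"],
            "finland_increment_mean": 0.0,
        }
    ]
    f2 = data.area_ids.index("F2")
    trap = GEARS.index("trap")

    def scenario_row(name: str, table: pd.DataFrame) -> dict:
        return {
            "scenario": name,
            "finland_median": table.loc["Finland", "median"],
            "finland_mean": table.loc["Finland", "mean"],
            "total_median": table.loc["total", "median"],
            "total_mean": table.loc["total", "mean"],
            "total_q0.05": table.loc["total", "q0.05"],
            "total_q0.95": table.loc["total", "q0.95"],
            "finland_increment_mean": float(
                table.loc["Finland", "mean"] - base.loc["Finland", "mean"]
            ),
        }

    if mode == "refit":
        if priors is None or config is None:
            raise ValueError("refit mode needs priors and config")
        for donor in donors:
            d = data.area_ids.index(donor)
            tie = None if d == f2 else {(f2, trap): (d, trap)}
            refit = run_mcmc(data, priors, config, tie=tie)
            table = summarize(predict_total(refit, data, seed))
            rows.append(scenario_row(f"tied_to_{donor}", table))
    elif mode == "replace":
        rng = np.random.default_rng(seed)
        modified = ChainResult(
            n_total=chain.n_total,
            n_area=chain.n_area,
            log_catchability=chain.log_catchability.copy(),
            mu=chain.mu,
            sigma2=chain.sigma2,
            log_post=chain.log_post,
            seed=chain.seed,
            acceptance_rates=chain.acceptance_rates,
            area_ids=chain.area_ids,
            countries=chain.countries,
            composition_labels=chain.composition_labels,
            effort_scaling=chain.effort_scaling,
            sampled_mask=chain.sampled_mask,
            metadata=chain.metadata,
        )
        donor_idx = np.array([data.area_ids.index(dnr) for dnr in donors])
        shape = chain.n_total.shape
        pick = donor_idx[rng.integers(len(donor_idx), size=shape)]
        c_idx, d_idx = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
        )
        modified.log_catchability[:, :, f2, trap] = chain.log_catchability[
            c_idx, d_idx, pick, trap
        ]
        table = summarize(predict_total(modified, data, seed))
        rows.append(scenario_row("replace_pooled", table))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).set_index("scenario")
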