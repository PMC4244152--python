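"""Prior construction from elicited quantile and coverage constraints.

Every prior in the model is specified by a small number of interpretable
constraints rather than raw hyperparameters:

* total population surviving non-by-catch mortality: log-normal with its
  5% quantile at the 2012 moult count (a conservative minimum, 28000) and
  its 95% quantile at the count divided by the low counting efficiency
  (28255/0.70 -> 40000, an optimistic maximum);
* allocation of the population over sub-areas: Dirichlet-multinomial whose
  base composition is the expected proportion column of the survey table
  (plus the residual "outside study area" share) and whose scale is
  calibrated so the marginal for the largest sub-area (F2) puts 90% prior
  mass between its minimum and maximum proportion estimates;
* catchability hierarchy: log-catchabilities of all gears and sub-areas
  share a Gaussian population layer ln C ~ N(mu, sigma2); the hyper-mean mu
  is Gaussian with median catchability 1.5e-6 and 95% below 1e-5 (original
  effort units) and the across-area variance sigma2 is scaled
  inverse-chi-squared with 4 degrees of freedom and scale 1.

Efforts are down-scaled by 1e-4 inside the likelihood for numerical
convenience; the mu hyperprior location is shifted accordingly, and all
reported catchabilities are transformed back to original units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, special, stats

from .data import RESIDUAL_LABEL, StudyDataset

__all__ = [
    "PriorSpec",
    "lognormal_from_quantiles",
    "normal_from_median_and_quantile",
    "calibrate_dirichlet_scale",
    "dirichlet_multinomial_log_pmf",
    "sigma2_log_prior",
    "sigma2_cv_quantiles",
    "build_default_priors",
]

DEFAULT_EFFORT_SCALING = 1e-4


@dataclass(frozen=True)
class PriorSpec:
    """All hyperparameters of the hierarchical by-catch model.

    ``mu_c_location``/``mu_c_scale`` parameterise the Gaussian hyperprior on
    the population mean log-catchability *in down-scaled effort units*
    (effort multiplied by ``effort_scaling``); multiply a catchability drawn
    on that scale by ``effort_scaling`` to return to original units.
    """

    n_total_log_location: float
    n_total_log_scale: float
    dirichlet_base: np.ndarray  # composition incl. residual category, sums to 1
    dirichlet_labels: tuple[str, ...]
    dirichlet_scale: float
    mu_c_location: float
    mu_c_scale: float
    sigma2_df: float = 4.0
    sigma2_scale: float = 1.0
    effort_scaling: float = DEFAULT_EFFORT_SCALING

    def __post_init__(self) -> None:
        base = np.asarray(self.dirichlet_base, dtype=float)
        object.__setattr__(self, "dirichlet_base", base)
        if base.ndim != 1 or len(base) != len(self.dirichlet_labels):
            raise ValueError("dirichlet_base and dirichlet_labels disagree")
        if np.any(base <= 0) or abs(base.sum() - 1.0) > 1e-9:
            raise ValueError("dirichlet_base must be a positive composition")
        for name in ("dirichlet_scale", "n_total_log_scale", "mu_c_scale",
                     "sigma2_df", "sigma2_scale", "effort_scaling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_total_prior_mean(self) -> float:
        return float(
            np.exp(self.n_total_log_location + 0.5 * self.n_total_log_scale**2)
        )

    def replace(self, **kwargs) -> "PriorSpec":
        return dataclasses.replace(self, **kwargs)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dirichlet_base"] = [float(x) for x in self.dirichlet_base]
        d["dirichlet_labels"] = list(self.dirichlet_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        d["dirichlet_base"] = np.asarray(d["dirichlet_base"], dtype=float)
        d["dirichlet_labels"] = tuple(d["dirichlet_labels"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PriorSpec":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


def lognormal_from_quantiles(
    q_low: float, q_high: float, p_low: float = 0.05, p_high: float = 0.95
) -> tuple[float, float]:
    """Log-normal (location, scale on the log axis) matching two quantiles.

    Solves ``P(X <= q_low) = p_low`` and ``P(X <= q_high) = p_high`` for a
    log-normal X.  With ``q_low == q_high`` the scale degenerates to zero
    (point mass).
    """
    if q_low <= 0 or q_high <= 0:
        raise ValueError("quantile values must be positive")
    if q_low > q_high:
        raise ValueError("q_low must not exceed q_high")
    if not 0 < p_low < p_high < 1:
        raise ValueError("need 0 < p_low < p_high < 1")
    z_low, z_high = stats.norm.ppf([p_low, p_high])
    location = (z_high * np.log(q_low) - z_low * np.log(q_high)) / (z_high - z_low)
    scale = (np.log(q_high) - np.log(q_low)) / (z_high - z_low)
    return float(location), float(scale)


def normal_from_median_and_quantile(
    median_value: float, q_value: float, p: float
) -> tuple[float, float]:
    """Gaussian on the log scale with exp(location)=median and a tail constraint.

    Returns (location, scale) such that ``P(exp(X) < q_value) = p``.  Used
    for the catchability hyper-mean, whose constraints are stated on the
    original (positive) catchability scale.
    """
    if median_value <= 0 or q_value <= 0:
        raise ValueError("median_value and q_value must be positive")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if q_value == median_value:
        return float(np.log(median_value)), 0.0
    z = stats.norm.ppf(p)
    if (q_value > median_value) != (z > 0):
        raise ValueError(
            "inconsistent constraint: quantile on the wrong side of the median"
        )
    scale = (np.log(q_value) - np.log(median_value)) / z
    return float(np.log(median_value)), float(scale)


def _beta_coverage(s: float, b: float, lower: float, upper: float) -> float:
    return float(
        stats.beta.cdf(upper, s * b, s * (1 - b))
        - stats.beta.cdf(lower, s * b, s * (1 - b))
    )


class CalibrationError(RuntimeError):
    pass


def calibrate_dirichlet_scale(
    base: np.ndarray,
    index: int,
    lower: float,
    upper: float,
    target_coverage: float = 0.90,
    bracket: tuple[float, float] = (1.0, 1e6),
) -> float:
    """Dirichlet scale s such that the marginal Beta for one category puts
    ``target_coverage`` mass in (lower, upper).

    The marginal of category ``index`` under Dirichlet(s*base) is
    Beta(s*b, s*(1-b)); its coverage of an interval containing b is
    monotone increasing in s, so a scalar root-find suffices.
    """
    base = np.asarray(base, dtype=float)
    b = base[index] / base.sum()
    if not lower < b < upper:
        raise ValueError("interval must contain the base proportion")
    lo, hi = bracket
    f = lambda s: _beta_coverage(s, b, lower, upper) - target_coverage
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            "target coverage not bracketed: achievable range is "
            f"[{flo + target_coverage:.4f}, {fhi + target_coverage:.4f}] "
            f"for s in {bracket}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-6, rtol=1e-10))


def dirichlet_multinomial_log_pmf(
    counts: np.ndarray, total: int, base: np.ndarray, s: float
) -> float:
    """Exact log pmf of the Dirichlet-multinomial with parameters (total, s*base)."""
    counts = np.asarray(counts)
    base = np.asarray(base, dtype=float)
    if counts.shape != base.shape:
        raise ValueError("counts and base must have the same length")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if counts.sum() != total:
        raise ValueError(f"counts sum to {counts.sum()}, expected total {total}")
    alpha = s * base / base.sum()
    a0 = alpha.sum()
    return float(
        special.gammaln(total + 1)
        - special.gammaln(counts + 1).sum()
        + special.gammaln(a0)
        - special.gammaln(total + a0)
        + (special.gammaln(counts + alpha) - special.gammaln(alpha)).sum()
    )


def sigma2_log_prior(sigma2: float, df: float = 4.0, scale: float = 1.0) -> float:
    """Log-density of the scaled inverse-chi-squared prior on sigma2.

    Parameterised so that df*scale/sigma2 ~ chi-squared(df); equivalently
    sigma2 ~ InvGamma(df/2, df*scale/2).
    """
    if df <= 0 or scale <= 0:
        raise ValueError("df and scale must be positive")
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    out = stats.invgamma.logpdf(sigma2, a=df / 2.0, scale=df * scale / 2.0)
    return float(out) if out.ndim == 0 else out


def sigma2_cv_quantiles(
    df: float = 4.0, scale: float = 1.0, probs: tuple[float, ...] = (0.05, 0.5, 0.95)
) -> np.ndarray:
    """Quantiles of the implied log-normal coefficient of variation.

    The across-area CV of catchability implied by a log-normal spread
    sigma2 is sqrt(exp(sigma2) - 1); since that map is monotone, CV
    quantiles follow directly from sigma2 quantiles.
    """
    s2 = stats.invgamma.ppf(probs, a=df / 2.0, scale=df * scale / 2.0)
    return np.sqrt(np.expm1(s2))


def build_default_priors(
    data: StudyDataset,
    effort_scaling: float = DEFAULT_EFFORT_SCALING,
    calibration_area: str = "F2",
    target_coverage: float = 0.90,
) -> PriorSpec:
    """Assemble the full prior specification from the study dataset.

    The population prior treats the moult count itself as a conservative
    minimum (5% quantile, 28000 after rounding) and the count divided by
    the low counting efficiency as an optimistic maximum (95% quantile,
    28255/0.70 -> 40000).
    """
    q_low = round(data.counted_seals, -3)
    q_high = round(data.counted_seals / data.count_efficiency_low, -3)
    n_loc, n_scale = lognormal_from_quantiles(q_low, q_high, 0.05, 0.95)

    base = data.prop_expected_vector(include_residual=True)
    labels = tuple(data.composition_labels)
    cal = data.by_area(calibration_area)
    lower = min(cal.prop_spring, cal.prop_fall)
    upper = max(cal.prop_spring, cal.prop_fall)
    s = calibrate_dirichlet_scale(
        base, data.area_ids.index(calibration_area), lower, upper, target_coverage
    )

    mu_loc, mu_scale = normal_from_median_and_quantile(1.5e-6, 1e-5, 0.95)
    # shift to down-scaled effort units: C_scaled = C / effort_scaling
    mu_loc -= np.log(effort_scaling)

    return PriorSpec(
        n_total_log_location=n_loc,
        n_total_log_scale=n_scale,
        dirichlet_base=base,
        dirichlet_labels=labels,
        dirichlet_scale=s,
        mu_c_location=float(mu_loc),
        mu_c_scale=float(mu_scale),
        sigma2_df=4.0,
        sigma2_scale=1.0,
        effort_scaling=effort_scaling,
    )
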