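"""Constructing every prior from its stated constraints.

Shows the quantile-matching elicitation utilities: the log-normal
population prior, the Gaussian hyper-prior on mean log-catchability, the
Dirichlet scale calibrated so F2's allocation band (25-35% of the
population) carries 90% prior mass, and the coefficient-of-variation band
implied by the inverse-chi-squared variance hyper-prior.
"""

import numpy as np

import sealbycatch as sb
from sealbycatch.priors import sigma2_cv_quantiles

data = sb.load_table1_fixture()

loc, scale = sb.lognormal_from_quantiles(28_000, 40_000, 0.05, 0.95)
print(f"population prior: location {loc:.3f}, log-scale {scale:.4f}, "
      f"median {np.exp(loc):.0f}, mean {np.exp(loc + scale**2 / 2):.0f}")

mloc, mscale = sb.normal_from_median_and_quantile(1.5e-6, 1e-5, 0.95)
print(f"catchability hyper-mean: median {np.exp(mloc):.2e}, "
      f"log-scale {mscale:.3f} (95% below 1e-5)")

base = data.prop_expected_vector(include_residual=True)
s = sb.calibrate_dirichlet_scale(base, data.area_ids.index("F2"), 0.25, 0.35, 0.90)
print(f"Dirichlet scale s = {s:.1f} (90% of F2's allocation mass in 25-35%)")

lo, med, hi = sigma2_cv_quantiles(4.0, 1.0)
print(f"implied across-area catchability CV: median {med:.2f}, "
      f"central 90% band ({lo:.2f}, {hi:.2f})")

print(
    "\nmeaning: every hyperparameter is solved from an interpretable "
    "constraint (a quantile, a median, a coverage), so the prior can be "
    "audited claim by claim against the elicitation interviews."
)
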