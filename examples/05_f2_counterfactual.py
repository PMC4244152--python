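"""The F2 under-reporting counterfactual.

Sub-area F2 holds ~30% of the seal population and a third of all trap-net
effort, yet interviewed fishermen reported only 5 by-caught seals — a
catchability more than ten times below every other surveyed area.  This
script refits the model with F2's trap catchability tied to a donor area
(F1, then S2) and shows how much the Finnish and total by-catch would
rise if F2's true catchability resembled its neighbours'.
"""

import sealbycatch as sb
from sealbycatch.predict import run_f2_counterfactual

data = sb.load_table1_fixture()
priors = sb.build_default_priors(data)
config = sb.RunConfig(seed=9, n_chains=1, n_iterations=12_000, n_burnin=5_000, thinning=4)

baseline = sb.run_mcmc(data, priors, config)
table = run_f2_counterfactual(
    baseline, data, seed=10, donors=("F1", "S2"), mode="refit",
    priors=priors, config=config,
)
print(table.round(0).to_string())
print(
    "\nmeaning: tying F2's trap catchability to F1 or S2 adds a few hundred "
    "seals to Finland's estimate and moves the total posterior mean towards "
    "~2200-2400 — the plausible range if F2's low report reflects "
    "under-reporting rather than genuinely safer gear."
)
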