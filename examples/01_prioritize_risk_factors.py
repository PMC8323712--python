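"""Rank correlated lipoprotein traits by marginal inclusion probability.

Simulates a GWAS summary-statistic study of five correlated lipoprotein
traits (ApoB truly causal for the binary outcome, effect 0.14 log-odds per
SD) and runs Bayesian model averaging over all multivariable MR models.
The MIP column is the posterior probability that each trait belongs to the
true causal model; permutation p-values and BH-corrected q-values follow.
"""

from lipomr import preset_config, simulate_panel
from lipomr.mr_bma import BMAConfig, run_mr_bma

panel, ld, truth = simulate_panel(preset_config("major-lipids", seed=1))
print(f"simulated {panel.n_variants} instruments x {panel.n_exposures} exposures; "
      f"true causal: {[e for e, t in zip(truth.exposures, truth.theta_true) if t]}")

result = run_mr_bma(panel, BMAConfig(n_permutations=999, seed=1), with_permutation=True)
print(result.table.to_string(index=False, float_format="%.4f"))
print(f"\ntop-ranked exposure: {result.top_exposure} "
      f"(MIP {result.mip[result.top_exposure]:.3f}) — a high MIP with a small "
      "corrected p marks the trait most likely to drive outcome risk.")
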