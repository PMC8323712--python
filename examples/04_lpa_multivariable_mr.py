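"""Lp(a)-style MR: a locus-concentrated exposure, with and without
adjustment for a correlated polygenic trait.

Simulates 15 strong Lp(a)-like instruments (true effect 0.12 log-odds per
SD) alongside an ApoB-like exposure, then compares univariable IVW with
multivariable MR adjusting for ApoB. Agreement between the two estimates
indicates the Lp(a) association is not mediated by ApoB.
"""

import numpy as np

from lipomr import ivw, mvmr, preset_config, simulate_panel

panel, ld, truth = simulate_panel(preset_config("lpa", seed=1))
uni = ivw(panel.select_exposures(["Lpa"]), effects="random")
multi = {m.exposure: m for m in mvmr(panel, effects="random")}

print(f"true Lp(a) effect: OR {np.exp(truth.theta_true[0]):.3f} per SD")
print(f"univariable IVW:   OR {uni.odds_ratio:.3f} "
      f"(95% CI {np.exp(uni.ci_low):.3f}-{np.exp(uni.ci_high):.3f}, p={uni.pvalue:.2e})")
m = multi["Lpa"]
print(f"MVMR adj. ApoB:    OR {m.odds_ratio:.3f} "
      f"(95% CI {np.exp(m.ci_low):.3f}-{np.exp(m.ci_high):.3f}, p={m.pvalue:.2e})")
print("\nno attenuation after adjustment -> the exposure acts independently "
      "of the adjusted trait.")
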