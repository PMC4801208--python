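"""MR instrument power and the Wald-ratio causal estimator.

Evaluates the analytic power of the consortium's gene-score instrument at the
study design (65,000 participants, 8% AF, 5% lipid variance explained, odds
ratio 0.80 per lipid SD) and shows the Wald ratio that converts a score-AF
log-HR and a score-lipid slope into a causal log-HR per lipid SD.
"""

import numpy as np

from lipidmr import PowerSpec, mr_power, wald_ratio

spec = PowerSpec(n_total=65_000, case_fraction=0.08, instrument_r2=0.05,
                 or_per_sd=0.80, alpha=0.05)
print(f"design: n={spec.n_total}, K={spec.case_fraction}, "
      f"R2={spec.instrument_r2}, OR={spec.or_per_sd}/SD")
print(f"analytic instrument power = {100 * mr_power(spec):.1f}%")

# a hypothetical score-AF association and the instrument's score-lipid slope
beta_zy, se_zy = -0.050, 0.014   # log-HR of AF per 1 SD of gene score
beta_zx, se_zx = np.sqrt(0.05), 0.004  # lipid SDs per score SD (= sqrt(R2))
est, se = wald_ratio(beta_zy, se_zy, beta_zx, se_zx)
print(f"Wald ratio: causal log-HR per lipid SD = {est:.3f} (SE {se:.3f}), "
      f"HR = {np.exp(est):.3f} [{np.exp(est - 1.96 * se):.3f}, "
      f"{np.exp(est + 1.96 * se):.3f}]")
print("(the score-AF estimate divided by the score-lipid slope; valid only "
      "if the score affects AF through lipids alone)")
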