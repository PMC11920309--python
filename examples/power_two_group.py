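"""Power analysis for the comparison of two unpaired ROC curves.

Alcohol group with true AUC 0.60 (signal mean 0.38) versus a control
group with true AUC 0.70 (signal mean 0.78), 100 participants per group,
2 + 2 items each.  The effect size is the AUC difference of 0.10.
"""

import aucpower as ap

config = ap.PowerConfig(
    design="two_unpaired",
    spec1=ap.BinormalSpec(mu_signal=0.38),
    spec2=ap.BinormalSpec(mu_signal=0.78),
    sesoi=0.10,
    n_sims=1000,
    seed=1,
)
report = ap.run_power(config)
print(report.to_table())
print(
    "\nWith 100 participants per group and only 4 items each, a true AUC "
    "difference of 0.10 is detected (95% CI of the difference excludes 0) "
    "in about three quarters of studies - under the conventional 0.80 "
    "threshold, so more items or participants are needed."
)
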