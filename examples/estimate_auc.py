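"""Map binormal parameters to the AUC they imply.

The signal-mean slider of a power analysis: under the equal-variance
binormal model the continuous AUC is Phi(mu_signal / sqrt(2)), and the
6-level discretized empirical AUC stays very close to it.
"""

import aucpower as ap

for mu in (0.0, 0.11, 0.38, 0.57, 0.78, 1.0):
    spec = ap.BinormalSpec(mu_signal=mu)
    closed = ap.closed_form_auc(spec)
    emp = ap.estimate_auc_empirical(spec, n_items=10_000, rng_seed=0)
    print(
        f"mu_signal = {mu:4.2f}: continuous AUC = {closed:.4f}, "
        f"empirical 6-level AUC = {emp:.4f} (displays as {emp:.2f})"
    )
print(
    "\nA signal mean of 0.38 therefore corresponds to a target AUC of 0.60, "
    "0.57 to 0.65, 0.78 to 0.70 and 1.0 to 0.75."
)
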