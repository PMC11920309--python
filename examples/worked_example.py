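"""Rating-based ROC analysis of the built-in alcohol/placebo experiment.

Builds both groups' ROC curves from the embedded frequency tables,
estimates each AUC with a DeLong 95% CI, and compares the groups.
"""

import aucpower as ap

tables = ap.alcohol_placebo_example()
expanded = {g: ap.expand_frequency_table(t) for g, t in tables.items()}

for group, data in expanded.items():
    curve = ap.compute_roc(data)
    est = ap.auc_ci(data)
    print(f"\n{group} group ({data.n_signal} old + {data.n_noise} new items)")
    for thr, f, t in zip(curve.thresholds, curve.fpr[1:-1], curve.tpr[1:-1]):
        print(f"  rating >= {int(thr)}: TPR = {t:.2f}, FPR = {f:.2f}")
    print(f"  AUC = {est.auc:.2f}, 95% CI [{est.ci95[0]:.2f}; {est.ci95[1]:.2f}]")

delta = ap.unpaired_delta_ci(expanded["alcohol"], expanded["placebo"])
print(
    f"\nAUC difference (alcohol - placebo): {delta.delta:.2f}, "
    f"95% CI [{delta.ci95[0]:.2f}; {delta.ci95[1]:.2f}]"
)
print(
    "The interval excludes 0: discriminability is reliably worse in the "
    "alcohol group than in the placebo group."
)
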