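# Methods

## Data-generating model

Each simulated observation is a latent memory/evidence strength drawn from
the binormal signal-detection model: noise items from `N(mu_noise,
sd_noise)` and signal items from `N(mu_signal, sd_signal)`. Defaults are
`mu_noise = 0`, `sd_signal = sd_noise = 1`, so the experiment's effect size
is carried entirely by `mu_signal` and the continuous AUC is
`Phi(mu_signal / sqrt(2))`. Unequal variances (bowed, asymmetric ROC
curves) are supported by setting the SDs directly. A design is described by
`BinormalSpec`: participants × items-per-participant per class, a K-level
rating scale (default 6), an optional pairing correlation `rho`, and a
`continuous` flag that skips discretization.

Participant structure is generated and recorded (`participant_id`) but
deliberately ignored by inference: all observations are pooled and treated
as independent, matching the common practice of aggregating confidence
ratings across participants before a group-level ROC analysis. Power
estimates therefore apply to that aggregated analysis, not to a
mixed-model analysis that respects clustering.

## Discretization onto the 1..K scale

Real confidence ratings are ordinal, so latent values are redistributed
onto 1..K per dataset. How to place the K−1 cutpoints is a genuine design
choice; two per-dataset rules are implemented:

- **`quantile` (default)** — pool all latent values of the dataset and cut
  at the K-quantiles, giving K equal-count bins. This preserves the AUC
  almost exactly (attenuation < 0.01 for the effect sizes of interest):
  with 10,000 items per class, signal means 0.11 / 0.38 / 0.57 / 0.78 /
  1.0 yield discrete AUCs displaying as 0.53 / 0.60 / 0.65 / 0.70 / 0.75.
- **`equal_width`** — split the pooled [min, max] into K equal-width
  intervals. Because the pooled range is driven by extreme draws, most
  mass collapses into the central bins and the AUC attenuates noticeably
  (e.g. ≈ 0.727 instead of 0.75 at a signal mean of 1.0).

The quantile rule is the default because it keeps the mean→AUC mapping
faithful to the continuous model, which is what a user dialing in a target
AUC expects; the equal-width rule is retained as a switch
(`disc_rule="equal_width"`) for sensitivity analyses.

## Estimation and intervals

- **AUC**: trapezoidal area under the cumulative-threshold ROC polyline;
  exactly the tie-corrected Mann–Whitney statistic (ties count ½). Score
  direction is fixed (higher = more signal-like) and never auto-flipped,
  so sign-reversed estimates in power runs count as failures rather than
  being silently corrected.
- **DeLong variance**: midrank placement values; `var = S10/m + S01/n`
  with sample variances (denominator count−1). The point estimate is
  computed through the rank statistic so it is bit-for-bit identical to
  the ROC-module AUC.
- **Unpaired ΔAUC**: `SE = sqrt(V1 + V2)`. This is algebraically the SE
  implied by the unpaired DeLong z statistic but remains defined at
  ΔAUC = 0, which equivalence simulations hit constantly.
- **Paired ΔAUC**: `var = V1 + V2 − 2·cov`, covariance from the paired
  placement components aligned by `pairing_id`; clipped at 0 against
  negative rounding.
- **Wald intervals** use fixed z = 1.96 (95%) and 1.645 (90%) at
  alpha = 0.05 — the conventional printed quantiles — and exact normal
  quantiles for any other alpha. Bounds are *not* clamped to [0, 1]:
  decision rules operate on raw bounds because clamping biases equivalence
  decisions near the boundary.
- **Partial AUC** is reported raw (no standardization), integrated with
  linear interpolation of TPR at range boundaries; it is additive over
  adjacent ranges to 1e-12. pAUC inference uses a stratified percentile
  bootstrap (cases and controls resampled separately within each group,
  class sizes preserved; default 2000 replicates, deterministic given a
  seed).

## Power simulation

`run_power` spawns one independent RNG substream per simulated dataset
from the master seed (`numpy.random.SeedSequence`), so reports are
byte-identical across runs and order-independent. Each dataset is
generated, estimated (DeLong for full curves, bootstrap for partial
ranges) and passed through all three decision rules; power is the success
proportion and its Monte-Carlo SE is `sqrt(p(1−p)/n_sims)`.

Choices worth noting:

- **Two-group orientation.** The difference is oriented so the
  group with the larger continuous (truth) AUC comes first, making the
  minimum-effect test directional: it fires when the *lower* 95% bound of
  the hypothesized-positive difference exceeds the SESOI. A two-sided
  "CI excludes the SESOI" reading would also fire on effects *smaller*
  than the SESOI, which contradicts the point of a minimum-effect test.
- **Single-curve equivalence region** is symmetric about chance:
  (1−SESOI, SESOI). This is the only reading under which equivalence
  power at a true AUC of 0.5 is high (≈ 0.93 with 100 participants and
  2+2 items) rather than trivially zero.
- **Degenerate datasets** (a class with < 2 observations after
  generation, or zero DeLong variance from perfect separation or total
  ties) count as decision = false for all three tests and are reported in
  `n_degenerate` — conservative power, no silent drops.
- **Partial-AUC power** is implemented for two-group comparisons (the
  difference has an unambiguous null of 0); the defaults are scaled down
  (`n_sims=200`, `n_boot=500`) because a full-fidelity bootstrap power
  run is orders of magnitude more expensive than the DeLong path. Full
  runs are reachable through the config.

## Calibration

At the decision boundaries the rules behave as designed, with one
asymmetry worth knowing: NHST at a true AUC of 0.5 rejects at ≈ alpha
(0.03–0.07 observed at 1000 simulations), and the TOST equivalence rule
passes at ≤ ~0.05–0.075 when the true effect sits exactly at the SESOI.
The one-sided minimum-effect rule at the boundary fires at ≈ alpha/2
(~2.5%), as expected for a one-sided test run at the two-sided interval's
level; intuitions that place it at 5% assume a two-sided rule.

One documented two-group equivalence figure (power 0.80 for ΔAUC = 0,
100 per group, 2+2 items, SESOI 0.10) is not reproducible under any
reading of the TOST rule consistent with the single-curve results; this
implementation yields ≈ 0.60 there. The single-curve equivalence powers
(≈ 0.93 at AUC 0.50, ≈ 0.80 at AUC 0.53) anchor the rule instead.

## Problem sizes used in the test suite

Deterministic checks run on the embedded 1000+1000-observation example.
Stochastic checks use 1000 simulations for power values and calibration
(Monte-Carlo SE ≤ ~0.016), 10,000 bootstrap replicates for the
DeLong-vs-bootstrap SE oracle, 10,000–50,000 items per class for
AUC-mapping checks, and a 200-simulation × 500-replicate partial-AUC
power run. Power values are verified to ±0.05, which covers 3× the
binomial Monte-Carlo SE plus residual discretization ambiguity.

## Limitations

- Latent distributions are normal only; AUC estimates are known to be
  robust to moderate non-normality, but skewed or mixture latents are an
  extension hook, not implemented.
- Inference ignores participant clustering (see above); with few
  participants and many items, CIs will be anti-conservative for designs
  analyzed at the participant level.
- No smoothed/binormal-fitted ROC curves, no CI bands along the curve
  (coordinate export only), no sample-size search — users sweep configs.
- Wald CIs can exceed [0, 1] near the boundaries by construction; clamp
  for display only.
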