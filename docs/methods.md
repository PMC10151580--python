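# Methods

## Statistical model

All inference is built on the Pearson product-moment coefficient computed
on pairwise-complete observations. For a pair with n complete samples the
test statistic is

    t = |r| sqrt(n - 2) / sqrt(1 - r^2),

referred to Student's t with df = n − 2. Rather than reporting p-values,
the pipeline inverts the two-sided quantile once per df:

    r_crit(alpha, df) = t_crit / sqrt(t_crit^2 + df),

and flags a pair iff |r| ≥ r_crit. Both routes (t-space and r-space) are
algebraically identical; a property test asserts they agree on every
screened pair. The quantile comes from `scipy.stats.t.isf`, i.e. numerical
inversion of the regularized incomplete beta function. At the motivating
design's full overlap (n = 6, df = 4, α = 0.01 two-sided) the threshold
is t = 4.604, |r| ≥ 0.91719; at reduced overlap (n = 4, df = 2) it is
|r| ≥ 0.99. When a minimum significant magnitude is *quoted* (report
tables, acceptance output) it is truncated at the 5th decimal — the
conservative direction for a lower bound; comparisons always use full
precision.

Working at a fixed strict per-pair α with no multiple-testing correction
is a deliberate design choice: with 4 df, α = 0.01 already demands
|r| ≥ 0.92, and the screen reports the number of tests performed so a
user can apply their own correction. The type-I calibration test
(50,000 independent Gaussian pairs at n = 6) confirms the realized null
rejection rate is 0.01 within Monte-Carlo error.

### Partial correlations and the mediation call

First-order partials use the closed form

    r_xy.z = (r_xy - r_xz r_yz) / (sqrt(1 - r_xz^2) sqrt(1 - r_yz^2)),

computed on the triple-complete sample set of each triad (at least 4
samples required). An independent oracle — correlating the least-squares
residuals of x on z and y on z — agrees with the closed form to 1e-9 over
random triples; this equivalence is asserted in the tests rather than
assumed.

No significance test is attached to a partial: at 6 samples the sampling
distribution of a first-order partial is too wide to referee, so only
magnitudes are compared. The verbal classification uses two thresholds,
both configurable:

- `drop_threshold = 0.30` — a partial below this counts as collapsed;
- `retain_threshold = 0.50` — a partial at/above this counts as retained.

A triad is `mediated-by-m` when the partial *not* involving m collapses
while both partials involving m are retained; `direct` when no mediator
qualifies but some partial is retained; `indeterminate` otherwise
(including the ambiguous two-mediator case). The defaults were chosen so
that a published verbal pattern of "0.11 is poor, −0.71 and −0.60 are
strong" maps onto collapsed/retained; they are not estimated from data.

### Dixon's Q outlier test

Per factor, the classic r10 statistic on the sorted pooled values
(pooling both diagnosis groups, since screens also pool them):

    q_high = (x(n) - x(n-1)) / (x(n) - x(1)),
    q_low  = (x(2) - x(1)) / (x(n) - x(1)),

the larger of the two compared with Rorabacher's (1991) two-tailed
critical value for the chosen confidence level (default Q99%; 0.740 at
n = 6). At most one value is flagged per factor and flagging is one-pass
(no iterative re-testing after removal). Ties sort stably by value then
sample ID, and an exact q_low = q_high tie tests the high side — an
arbitrary but documented choice. The default exclusion policy is
`drop-value`: the flagged cell becomes missing and the factor's
availability shrinks, which automatically tightens that factor's
per-pair threshold (fewer df). `drop-factor` and `keep` are available,
and the report always shows flagged factors' correlations both with and
without the outlier.

## Data handling

Missing values are a single `NA` token in files and NaN in memory;
deletion is pairwise-complete for marginals and triple-complete for
partials — the only defensible option when one factor may be observed in
only 4 of 6 samples. Harmonization restricts all layers to the samples
common to every layer and the metadata, in metadata row order
(deterministic outputs); it is idempotent and value-preserving. The
chlorpromazine-equivalent dose of a control subject missing from the
metadata is imputed as 0 mg/day (the convention that controls are
unmedicated); a missing dose for a case is an error, never imputed.

The packaged subject table carries the 6 subjects' diagnosis, age, sex,
post-mortem interval, illness duration and cause of death. Five of the
six PMIs are ≤ 17 h; the sixth (42 h) is large but below the Q99%
critical value, so it is retained — a worked illustration of why the QC
uses a strict confidence level.

## Synthetic cohorts

The generator emulates the target design: n_scz + n_con samples
(default 3 + 3), layers of 2 / 7 / 17 factors, and clinical covariates
(ages 60–90, PMIs 4–20 h, SCZ doses uniform on 200–800 mg/day CPeq —
typical maintenance antipsychotic doses — controls at 0). One factor per
layer can be planted:

- **mediated**: x = a·z + ε, y = b·z + ε with the latent driver z written
  into the third layer;
- **direct**: a genuine x→y edge with an independent z;
- **confounded**: x and y both driven by standardized CPeq with no direct
  link;
- **null**: everything independent Gaussian.

All planted factors are standardized to unit population variance, so the
loadings a, b *are* population correlations and recovery targets are
analytic: r_xz → a, r_yz → b, r_xy → ab. Residual SDs default to
sqrt(1 − loading²); an explicit `noise_sd` overrides this (loadings then
stop being correlations). Group shifts are additive offsets on the
planted factors of case samples, scalar or per layer. Randomness uses one
root seed with per-label substreams (layer name hashed into a
`SeedSequence`), so resizing one layer never perturbs another — asserted
by test. A truth record (JSON) stores every planted parameter, withheld
sample and original value under an injected outlier; tests read the truth
record rather than reverse-engineering the generator.

What the generator does **not** emulate: heteroscedastic or count-based
noise (RNA-seq), batch effects, or realistic inter-factor correlation
inside a layer. Passing tests therefore demonstrate the statistics and
plumbing are correct under the design's idealized assumptions, not that
real lipidomics/transcriptomics data meet those assumptions.

## Problem sizes and what the tests show

- Large-n recovery runs use cohorts of n = 1000 (500 + 500) over 100
  seeds: the full screen → triad → mediation chain finds the planted
  triad and names the correct mediator in ≈100% of seeds, and never
  calls a direct-edge cohort mediated. Roughly one seed in six also
  yields one spurious extra triad — the expected false-positive load of
  167 uncorrected tests at α = 0.01, concentrated by the fact that both
  planted factors are near-copies of the driver.
- At the design size n = 6, single-seed outcomes are unstable by
  construction (the demo cohort in `analysis/` classifies its planted
  triad as `direct`); the suite therefore asserts only distributional
  properties at n = 6 — medians over ≥ 40 seeds of |partial| vs
  |marginal| — never single-seed classifications.
- Type-I calibration uses 50,000 vectorized null pairs; the partial-
  correlation oracle uses 1,000 random triples of length 4–50.

These sizes keep the full suite around a minute on one CPU while leaving
Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

- The mediation call is a magnitude heuristic, not causal inference: no
  Sobel test, bootstrap CI or structural model (out of scope by design).
- Only first-order partials are computed; a triad with two simultaneous
  strong confounders is classified `indeterminate` rather than resolved.
- Dixon critical values are tabulated for n = 3–30; larger cohorts
  should use a different outlier test.
- The screen never corrects across pairs; downstream users get the test
  count and must decide for themselves.
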