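# Methods

## Data model

The unit of analysis is a *path record*: one examined predictor → outcome
relationship from one study dataset, carrying the standardized coefficient
β (optional), sample size n, the primary study's binary significance
label, a country label (with the reserved value `multiple` for
multi-country samples), and optional theory tags. Construct names are
harmonized through a many-to-one alias → canonical merge map applied in a
single pass (no transitive chains; maps must be written in
canonical-target form). Paths examined fewer than 3 times are excluded
from both analyses; excluded paths are logged with their counts.

Records lacking β stay in the weight analysis but cannot enter the
meta-analysis. The two analyses therefore legitimately draw on different
record subsets — the packaged fixtures themselves show a path examined 78
times of which 77 effects were poolable.

## Weight analysis

`W = S/E` per path, computed in exact rational arithmetic and reported to
3 decimals. Classification is a total function of (W, E) with inclusive
boundaries: **best** requires W ≥ 0.800 *and* E ≥ 5; **promising** is
W = 1 with E < 5; **well-utilized** is E ≥ 5 with W < 0.800; the residual
class (E < 5, W < 1) is labelled **experimental**, a name this package
supplies because reporting needs a total classification.

## Effect transforms

β → r uses `r = β + 0.05λ` with λ = 1 for *all* β by default; a flag
restores the original convention (λ = 0 for negative β). Conversions with
|r| ≥ 0.95 are rejected rather than clamped — at that magnitude the
approximation is not credible and the input is more likely already on the
correlation or z scale. Fisher z = atanh(r) with SE = 1/√(n−3); n ≥ 4 is
enforced at effect construction. All arithmetic is double precision;
rounding happens only in report layers.

Where a study table supplies both a rounded SE column and n, effects are
built from n at full precision. On the packaged fixture this choice
reproduces the reference Egger coefficients to the third decimal, whereas
the rounded SE column shifts the intercept by 0.05.

## Pooling

Fixed-effect weights are `wᵢ = 1/SEᵢ²`; `Q = Σ wᵢ(zᵢ − ẑ)²` with
per-study components exposed (they sum to Q exactly). τ² is the one-step
DerSimonian–Laird moment estimator, truncated at zero, never iterated.
Random-effects weights are `1/(SEᵢ² + τ²)`. The 95% CI uses the normal
quantile 1.959964 (not t), matching z-score / two-tailed-P reporting;
`I² = max(0, (Q−(k−1))/Q)·100`. Back-transforms use tanh, which preserves
interval order. Subgroup pooling estimates τ² separately within each
group (no common-τ² option); the default partition is China vs all other
countries. k ≥ 2 is required per pooled set, k ≥ 3 for bias diagnostics.

## Publication-bias diagnostics

The Egger test is **unweighted** OLS of the standard normal deviate on
precision (the weighted variant is out of scope); coefficient SEs are
classical, p-values and CIs use t with k − 2 df, and an intercept with
p < .10 flags asymmetry. Funnel data are orientation-free (points,
center, normal-quantile contours); plotting conventions live in report
scripts.

Trim-and-fill follows Duval–Tweedie: iteratively pool the untrimmed set
(fixed-effect center), rank all studies about the center, estimate the
number k0 of missing studies, trim the k0 most extreme same-flank
effects, and repeat until k0 stabilises (cap 50 iterations); the trimmed
effects are then mirrored about the final center with their donors' SEs
and the augmented set is re-pooled with random effects, τ² re-estimated.
Both the L0 moment estimator and the run-based R0 estimator are
available (default L0); the trimming flank defaults to the sign of the
Kendall rank correlation between centered effects and SEs. Ties in |rank|
follow scipy's midrank convention; k0 is capped at k − 1.

On the packaged 77-study fixture the L0 estimator finds k0 = 0 — as does
R's `metafor::trimfill` on the same input — while the R0 estimator with
right-flank trimming imputes ~16 left-flank studies and shrinks the
pooled r from 0.337 to ≈0.255. The reference analysis (run with a
spreadsheet tool whose algorithm is unpublished) reported only that the
adjusted estimate is "slightly smaller"; the directional behavior is
reproduced by the R0 route, and the package treats the estimator as an
explicit, documented choice.

## Synthetic corpora

`generate_corpus` draws, per study, a true effect
zᵢ ~ N(atanh(true_r), τ²), a sample size uniform on `n_range`, and an
observed zᵢ' ~ N(zᵢ, 1/(nᵢ−3)); β is reconstructed as tanh(zᵢ') − 0.05 so
the pipeline's conversion inverts it exactly. Significance labels use the
two-tailed Fisher-z test at α = .05 — real primary studies use
heterogeneous tests, but this stand-in makes the significant fraction
equal an analytic power calculation, which the tests exploit. Selective
publication suppresses each nonsignificant study with probability
`bias_prob` (significant studies are never suppressed). Defaults
(true_r = 0.34, τ = 0.25, 77 studies, n ∈ [67, 1292], bias_prob = 0)
mirror the observed corpus of the most-examined path. Corpora are
bit-reproducible given the seed; multi-edge corpora spawn per-edge
substreams from the base seed.

What the generator does *not* emulate: correlated paths within one
dataset (a real study reports many β from one sample), moderator-driven
heterogeneity, non-normal effect distributions, and rounding of reported
β to 2–3 decimals. Passing recovery and coverage tests therefore
validate the estimators under the model's own assumptions, not
robustness to these real-data features.

## Verification against the reference tables

The packaged 77-row effect table reproduces the reference Egger
regression (intercept 0.384 vs 0.381, SE 1.544, slope 0.327, SE 0.081)
and the subgroup results (China r 0.339 vs 0.340, I² 92.975 vs 92.984;
others 0.335 vs 0.336, I² 94.354 vs 94.355) at 3-decimal fidelity.

The overall summary row is the exception, and the discrepancy is in the
reference tables themselves: the reference's own printed per-study Q
components sum to 1221.361, not the printed summary Q of 1212.594, and
the gap equals one study's component (the z = 0.236, n = 725 row;
pooling the other 76 rows reproduces the summary almost exactly while
the printed I² back-solves to k = 77). Honest pooling of all 77 printed
studies gives Q = 1221.385, r = 0.337 (CI 0.294–0.379), I² = 93.778%;
the corresponding two acceptance tests assert the published values at
their printed precision and are expected to fail, documenting the
inconsistency rather than papering over it.

## Numerical and design choices

- Exact rational comparison for classification thresholds (0.800, W = 1)
  and the 0.700 graph-thickness rule (inclusive, following the stricter
  of the two stated conventions).
- DL pooling cross-checked in tests against an independently coded
  direct-summation oracle (≤ 1e-10 at k ≤ 5) and against
  `metafor::rma(method="DL")` via Rscript on a 10-study instance.
- Property suite sizes: 500 replicates for DL recovery and CI coverage
  at (true_r 0.34, τ 0.25, k 77); 100 replicates for Egger null
  calibration at 40 studies; 20 seeded corpora for the
  selective-publication detection rate. These sizes give Monte-Carlo
  standard errors comfortably below the asserted margins.
- Manifests from `run_full_analysis` contain no timestamps, so identical
  inputs + config produce byte-identical reports (asserted by checksum).

## Limitations

- The β → r + 0.05 conversion is a crude approximation; alternatives
  (partial-correlation reconstruction, t-statistic conversions) are out
  of scope.
- One-step DL is known to under-cover at high τ²; the coverage test
  tolerates 90–98% rather than nominal 95%. REML, Paule–Mandel and
  Hartung–Knapp variants are not implemented.
- Trim-and-fill assumes the funnel's asymmetry is caused by suppression;
  under genuine heterogeneity (I² > 90% here) its k0 is diagnostic, not
  an estimate of truly missing studies.
- The weight statistic treats each examination as exchangeable evidence;
  it ignores sample size, effect magnitude, and study quality.
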