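# Methods

## The model

The package analyses long-format EMA data — persons × days × beeps ×
items — with a node-wise multilevel vector autoregression of order 1 and
two Gaussian-graphical-model layers on top of it.

For node j the mixed model is

    y_j(t) = β_j0 + Σ_k β_jk · c_k(t−1) + Σ_{k≠j} b_jk · m_k(i) + u_i + ε_j(t)

where c_k(t−1) = y_k(t−1) − ȳ_k^(i) is the lagged value of node k
centered at person i's mean, m_k(i) = ȳ_k^(i) is that person mean (a
level-2 predictor), and u_i ~ N(0, τ²) is a random person intercept.
Only fixed temporal effects are estimated: with a few dozen usable
occasions per person, person-specific slope matrices are not
identifiable with useful precision, and the population matrix B = (β_jk)
is the estimand of interest.  Estimation is restricted maximum
likelihood (statsmodels `MixedLM`); if a node model will not converge or
yields non-finite standard errors it is refitted with L-BFGS and, failing
that, falls back to pooled OLS with the fallback recorded in the
diagnostics.  A random-intercept variance estimated at the τ² = 0
boundary is kept (predicted intercepts are then 0) and flagged.

Three networks derive from the node models:

* **Temporal**: B itself; entry [j, k] is the directed effect of node k
  at t−1 on node j at t, the diagonal the autoregressions.  Each entry
  has its own Wald p-value.
* **Contemporaneous**: partial correlations of the residuals
  (observed − fixed part − predicted person intercept).  Each residual
  series is regressed on all the others over complete-case rows; the two
  directional coefficients of a pair are combined as
  ρ_jk = sign(γ_{j←k})·√(γ_{j←k}·γ_{k←j}), which reproduces the
  partial-correlation identity of the inverted covariance exactly on a
  single sample (the arithmetic mean does not).  Directional OLS
  p-values are retained for the display rule.
* **Between-subject**: the level-2 slopes b_jk, standardised by the
  ratio of person-mean SDs so they sit on a correlation scale, averaged
  over the two directions of each pair.  If the two directions disagree
  in sign the edge is set to 0 and flagged — averaging across
  conflicting signs would fabricate an effect neither regression
  supports.  The same sign rule applies to the contemporaneous
  combination (whose geometric mean would otherwise be undefined).

### Lag construction

Lags are taken only between *consecutive scheduled beeps of the same
day*.  The overnight interval (last beep → next morning) is about three
times the nominal sampling interval, so no prediction is formed across
it; likewise beep 1 → beep 3 is not a valid lag when beep 2 was missed,
because the fixed-interval interpretation of B would be violated.  With
complete data each person contributes n_days × (beeps_per_day − 1) rows.

Person means are computed over *all* non-missing occasions of an item,
not only occasions entering the lagged design: they estimate the
stationary means, and this choice is stable under missingness.  A
consequence is that centered lagged predictors average only
approximately (not exactly) to zero per person.

### Missing data

Nothing is imputed.  A fully missed beep (no non-skippable item
observed) removes both lag pairs it participates in; partially missing
occasions stay in the design, and each node model applies its own
complete-case rule (rows with a missing outcome or any missing
predictor are dropped for that model only).  The contemporaneous step
uses rows where all m residuals exist.

### Standardisation and p-values

By default all items are z-scored on the pooled mean/SD of the design's
outcome rows before fitting, so coefficients are comparable to
correlation-scale effect sizes and the conventional |r| > .1 display
threshold is meaningful; raw-scale fitting is available by flag.

p-values are two-sided Wald tests with a standard normal reference (the
simplest defensible default at these sample sizes).  A crude
within/between degrees-of-freedom split is switchable
(`pvalue_method="t"`): level-1 slopes use residual df, level-2 slopes
use (persons − level-2 parameters).  Measured under a null truth (100
persons × 56 occasions), the two references give per-edge displayed
false-positive rates of ≈ 0.065 and ≈ 0.061 for the between network;
see "Known limitations".  The node-model implementation was verified
against an independent lme4 REML fit (coefficients to 6 decimals, SEs
to ~1e−5; frozen in the test suite).

### Display rules and centralities

An edge is displayed when |weight| exceeds the magnitude threshold
(default .1) and is significant at the p threshold (default .05).
Undirected edges carry two directional p-values; the default 'or'-rule
requires one of them, the 'and'-rule both.  Filtering is
non-destructive — every edge keeps a `displayed` flag.

Strength centrality is the sum of absolute edge weights at a node,
expected influence the signed sum; temporal networks distinguish
incoming (row) and outgoing (column) variants.  Autoregressive
self-loops are drawn as edges but excluded from centrality sums by
default; the flag is exposed and the policy recorded in the output,
since either convention is found in practice.  z-scaling uses the n−1
SD across nodes; with only 15 nodes the convention is visible, so it is
fixed and recorded, and constant columns are returned as zeros with a
flag.

## The synthetic-data generator

The generator is the estimator's mirror image — the minimal process for
which all three estimated networks have exact truths:

    μ_i ~ MVN(μ, Σ_between),   y_t = μ_i + B(y_{t−1} − μ_i) + ε_t,
    ε_t ~ MVN(0, s²·Θ⁻¹)

iterated across **all** occasions in temporal order (the process crosses
day boundaries; only the estimator discards overnight lags), after a
50-step burn-in so recording starts near stationarity.  True networks:
B; the standardised negative off-diagonal of Θ; the partial correlations
implied by Σ_between.

Random truths (`make_truth`) draw a sparse signed B (diagonal always
present, positive; spectral radius rescaled to ≤ 0.9 if needed) and
sparse unit-diagonal precision matrices Ω = I − W for the other two
layers, so true partial correlations equal the drawn weights unless a
uniform shrink is needed to keep the minimum eigenvalue above 0.05.
`empty_truth` gives the all-null reference point.

Default scale parameters emulate 0–100 slider data: grand mean 50,
within-person residual SD 18, between-person mean SD 12 — pooled SDs
then land near the low-to-mid 20s typical of affect/eating EMA items.
Missingness is MCAR at the beep level (default rate 0.15, matching
≈ 85% compliance when prompts expire after an hour), plus extra
item-level missingness for the skippable eating item (default 0.223,
the share of answered beeps without an eating episode in the motivating
design).  Clipping to the slider range is off by default because the
estimation theory assumes Gaussian data; when emulating raw sliders it
can be switched on and the clipped fraction is reported.

What the generator does **not** emulate: floor/ceiling effects of real
sliders (e.g. items whose median is 0), non-Gaussian and skewed
residuals, diurnal cycles across the four daily prompts, missingness
that depends on state (the MCAR assumption), and person-specific
temporal dynamics.  Passing recovery tests therefore show that the
estimator recovers its own generative model at realistic sizes — not
that real slider data meet its assumptions.

## Problem sizes used in tests and the acceptance script

* Recovery benchmark: m = 6, 150 persons, 100 occasions/person, |weights|
  = 0.2, edge density 0.4, no missingness.  Density 0.4 (~6 of 15
  pairwise links) keeps the between-network weight correlation — computed
  over only 15 pairs with pcor sampling noise ≈ 1/√150 ≈ 0.08 — a
  meaningful statistic; sparser draws can leave 1–3 between edges, for
  which no estimator produces a stable 15-point correlation.  Measured
  here: temporal ≈ 0.99, contemporaneous ≈ 0.99, between ≈ 0.8.
* Null error control: m = 6, 100 persons, 56 occasions, 20 seeds.
* Study scale: m = 15, 84 persons, 56 occasions, 15% missed beeps,
  truth density 0.2; specificity averaged over 5 seeds (per-seed values
  rest on ~80 true-zero between pairs and are noisy).  Measured:
  specificity 1.0 / 1.0 / ≈ 0.92, between sensitivity ≈ 0.4 — the
  expected weak spot at 84 person means.
* Single-person and long-series oracles use 300–2500 days so that OLS
  noise is well inside the asserted tolerances.

## Known limitations

* **'Or'-rule false positives.**  Under a null truth, temporal and
  contemporaneous networks display essentially no false edges (their
  weight sampling SEs ≈ 0.013–0.015 make |r| > .1 a many-sigma event),
  but between-network edges are estimated from ~100 person means with
  SE ≈ 0.1, so the magnitude threshold adds nothing beyond significance
  and the per-edge displayed false-positive rate equals the 'or'-rule
  union of two nearly identical ~5% tests: measured ≈ 0.06–0.07.  This
  is a structural property of the display convention, not of the
  implementation (the two directional Wald statistics correlate ≈ 0.99
  under the null, and the rate is insensitive to the normal-vs-t
  reference choice).  Users who need strict 5% per-edge control for
  between networks should use the 'and'-rule or a lower p threshold.
* Between-network sensitivity at N ≈ 84 is low (≈ 0.3–0.4 at density
  0.2 with weights 0.1–0.3); reported, not asserted.
* The Wald-normal reference is mildly anticonservative for level-2
  effects in small samples; the 't' option is a crude, not a
  Satterthwaite, correction.
* `pcor_from_precision` takes a covariance (inverting internally); it
  refuses non-SPD input rather than regularising.
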