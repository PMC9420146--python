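# Methods

## Problem and model

Larval instars are discrete: the sclerotized head capsule cannot grow
within an instar, so head-capsule width (HCW) is approximately normal
within an instar and multimodal across a mixed field sample. The package
models a sample of per-larva widths (μm) as a k-component univariate
Gaussian mixture and reads k, the number of fitted components, as the
number of instars. Downstream, the classical morphometric checks —
within-instar coefficient of variation, Brooks' growth ratio, Crosby's
growth rule, and Dyar's log-linear rule — guard against a mixture fit that
merged or split an instar.

Assumptions: measurement error and individual variation are symmetric and
roughly normal within an instar; instars do not overlap so heavily that
their density sum becomes unimodal (in that case no method based on the
marginal HCW distribution can separate them); the sample pools all instars
present at collection time, so component weights reflect stage composition,
not cohort survival.

## Fitting

The mixture is fitted by maximum likelihood with EM on the raw values, not
by curve fitting to a histogram. Raw-data ML is independent of bin width —
a tuning knob that materially changes histogram shape at n ≈ 400 — and its
log-likelihood supports BIC model selection. A histogram mode
(`fit_mixture_histogram`) is provided for users who want the
curve-through-histogram procedure familiar from graphing software: k
scaled Gaussians (amplitude, centre, width each) are least-squares fitted
to bin counts at bin centres, and amplitudes are converted to mixing
weights via area (w ∝ amplitude·σ) and renormalized. The amplitude
parameterization is deliberate: it matches what peak-fitting software
optimizes, and the normalization afterwards maps it onto the probabilistic
model.

Numerical choices for EM:

* **Initialization** — component means at the (i+0.5)/k sample quantiles,
  pooled sample SD for every component, equal weights. Deterministic, so a
  given seed gives a bit-identical fit.
* **SD floor, 1 μm** — component SDs are bounded below at 1 μm (below the
  precision of stereo-microscope measurement) via a constrained M-step.
  Clamping to the boundary is the constrained maximizer, so the EM
  ascent property is preserved; the per-iteration log-likelihood trace is
  stored on the model and asserted non-decreasing in the tests.
* **Restarts** — a degenerate run (a component losing essentially all
  responsibility mass, or tied means) restarts from seeded jittered means,
  at most 10 times, then errors. The restart path is exercised rarely on
  realistic data; it exists for adversarial inputs such as heavy
  duplication.
* **Convergence** — |Δ log-likelihood| < 1e-8 within 500 iterations;
  the `converged` flag records the outcome either way.

## Choosing k

BIC = −2·loglik + (3k−1)·ln n over a user-set range (default 1–5), ties
toward smaller k. The per-k BIC table is attached to the selected model
and printed in text reports so a user can replicate the visual
peak-counting judgement the field traditionally applies. BIC's complexity
penalty at n = 401 (≈ 18 per extra component) is large against the
marginal likelihood gain of splitting a well-separated instar, which is
why recovery on the reference preset selects k = 3 essentially always.

## Boundaries and assignment

The dividing point between adjacent instars is the intersection of the two
weighted component curves: the solution of
w₁N(x|μ₁,σ₁²) = w₂N(x|μ₂,σ₂²) strictly between the means. In log space
this is quadratic in x (linear for equal σ); of the up-to-two roots the
one inside (μ₁, μ₂) is kept. With distinct means and the weighted
parameterization exactly one root lies inside whenever the curves cross
there; the both-inside case is guarded by preferring the root nearer the
midpoint, and the no-root case (possible under extreme weight imbalance)
raises an error that names the pair and suggests the unweighted mode.
Intersecting *unweighted* curves is available by flag, since peak-fitting
practice is ambiguous about whether displayed curves carry mixing weights.
An independent 0.01 μm grid search of the density crossing backs the
closed form in the tests (agreement within 0.1 μm on random valid pairs).

Assignment intervals are open-left/closed-right: a width exactly at a
boundary joins the lower instar. The rule is arbitrary; it is fixed and
documented so partitions are reproducible.

## Validation statistics

Per-instar SD uses the n−1 denominator (small morphometric samples;
ddof 1), CV = 100·s/x̄, SE = s/√n. Brooks' index is the ratio of successive
instar means; Crosby's index the relative change of successive Brooks
indices. The criteria are strict inequalities: CV < 15 % and
|Crosby| < 0.1, both configurable. The Crosby criterion applies to the
magnitude — a small negative value (growth ratio slightly decreasing)
supports the instar count exactly as a small positive one does, and the
reference analysis itself reports a negative value (−0.0598) as passing.

Dyar's rule is checked by OLS of ln(x̄ₙ) on instar number (scipy
`linregress`); R², the F statistic (df 1, k−2; computed as the squared
slope t statistic), and the two-sided p-value are reported. With k = 3
points the F test has a single denominator degree of freedom and the
p-value carries almost no information, so it is reported and never used as
a gate. For the reference means 365.0/473.7/578.0 μm the recomputed F is
166.6, not the 170.8 sometimes quoted alongside R² = 0.994; F at this
configuration is numerically fragile under rounding of the means, R² is
not, which is why only R² is treated as a reproducible quantity.

## Synthetic data

`spec_from_table1()` encodes the published per-instar summaries of the
*R. maculosus* sample: counts 65/145/191 (n = 401), means
365.0/473.7/578.0 μm, SDs from the printed CVs (sd = cv·x̄/100:
19.345/24.917/25.316 μm), and a 300–650 μm window matching the printed
observed range. The generator draws exactly the requested count per
component (stratified; a multinomial mode exists behind a flag for pooled
collections) from one seeded stream consumed in ascending-mean order, and
enforces the window by rejection rather than clipping, preserving
within-window normality. Whether the published range reflects hard limits
or merely observed extrema is unknowable; the window trims under 1 % of
any component's mass, so either reading changes the moments by well under
1 %.

What the generator does **not** emulate: measurement rounding,
between-collection-date cohort drift within an instar, sampling bias
toward larger (easier to find) larvae, and any non-normal within-instar
shape. Passing recovery tests therefore demonstrate that the estimation
pipeline inverts its own generative model at the study's sample size and
separation — not that three instars would be recovered from arbitrarily
messy field data.

## Problem sizes in the tests

Recovery tests use 200 replicate datasets (n = 401) for the model-count
selection rate and 50 replicates for parameter recovery and index
stability — enough replicates that the Monte-Carlo error on a selection
rate bounded at 95 % is a couple of percentage points, while keeping the
default suite comfortably quick. The moment-convergence check scales the
preset counts ×100 and compares sample moments against exact
truncated-normal moments: means at 0.5 % relative, SDs at three standard
errors of an SD estimate (3/√(2n)), since SD sampling error at those
counts exceeds 0.5 %.

## Known limitations

* Instar counts from marginal HCW mixtures are unidentifiable when
  adjacent instars overlap strongly; BIC then prefers fewer components
  and no warning can be raised from the data alone.
* The EM fitter is univariate by design; a second measurement axis
  (e.g. body length) would need a different tool.
* Histogram-mode fits inherit bin-width sensitivity and are provided for
  procedural fidelity, not recommended for inference.
* The criteria thresholds (15 %, 0.1) are field conventions, not derived
  quantities; the package treats them as configuration.
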