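# Methods

## Model

Subjects complete a 16-item questionnaire; item responses (0–4) are summed
to a total score in [0, 64]. Disease status is unobserved — no gold
standard exists — so the score vector is modelled as a two-component normal
mixture with latent per-subject indicators:

- zᵢ ~ Bernoulli(π), π ~ Beta(α, β) with α = β = 1 by default;
- xᵢ | zᵢ = 1 ~ N(μ⁺, σ⁺²), xᵢ | zᵢ = 0 ~ N(μ⁻, σ⁻²);
- μ± ~ N(μ₀±, σ_μ±²); σ± ~ Uniform(l±, u±).

Integer totals enter the continuous likelihood as-is (no jitter or interval
censoring). The diseased component is identified as the one with the larger
mean — clinically, affected subjects score higher — enforced by swapping
components (together with z → 1−z, π → 1−π) whenever a sweep leaves
μ⁺ ≤ μ⁻.

Sensitivity and specificity at an integer cut-off c under the "positive ⇔
score ≥ c" convention are deterministic functions of the component
parameters, evaluated per retained draw:

    Se(c) = 1 − Φ((c − μ⁺)/σ⁺),  Sp(c) = Φ((c − μ⁻)/σ⁻).

They are *not* estimated from latent-label counts: with ~22 expected cases
in a 215-subject sample, count-based estimates cannot resolve one-point
cut-off differences. The Youden index J(c) = Se(c) + Sp(c) − 1 is maximised
over the integer grid 0..64 (ties to the smallest cut-off). The ROC uses
the binormal form ROC(t) = Φ(a + bΦ⁻¹(t)), a = (μ⁺−μ⁻)/σ⁺, b = σ⁻/σ⁺, with
closed-form AUC = Φ(a/√(1+b²)) averaged over draws; a trapezoidal
empirical variant (integer cut-offs at posterior-mean parameters) and an
ECDF route for labelled data are provided as cross-checks.

## Sampling

One sweep updates, in order: the latent labels (exact Bernoulli
conditional), π (conjugate Beta), each component mean (conjugate normal),
and each component SD by random-walk Metropolis on log σ (the uniform prior
on σ breaks conjugacy; the log-scale proposal carries a Jacobian term). A
component emptied of members has its mean refreshed from the prior and its
SD held, which prevents numerical collapse early in the chain. The σ
proposal scales (initial 0.1) adapt every 100 burn-in sweeps toward a
20–50% acceptance band, then freeze so the retained chain is a proper
Markov chain. Defaults: 5,000 burn-in, 20,000 kept draws, thinning 1,
single chain, all seeded and fully reproducible. Monte Carlo standard
errors use batch means with ⌊√n⌋ batches; per-parameter summaries report
posterior mean, SD, MC error and central 95% intervals.

## Prior policies

**Anchored (default).** Low-prevalence two-component normal mixtures are
weakly identified at a few hundred observations: the likelihood has a ridge
along which the diseased component widens, slides toward the bulk, and
absorbs the healthy upper tail (π inflates to ~0.16 and Se(20) collapses to
~0.7 on study-like data; the same ridge appears in the marginal-posterior
ensemble sampler and in the EM maximum-likelihood solution, so it is a
property of the likelihood, not of the sampler). The questionnaire, however,
ships with an accepted clinical rule — total above 23 suggests disease — and
that rule is genuine prior knowledge, routinely exploited in latent-class
analyses without a gold standard. The anchored policy converts it into
hyperparameters: split the sample at the conventional cut-off; centre each
component-mean prior at its side's conditional mean with prior SD 2 score
units (about the standard error of a small group mean on this scale); bound
each σ by Uniform(0.5, 2 × the side's conditional SD), floored at 3, so a
latent class cannot be dispersed far beyond its conventional proxy group.
If one side of the split is nearly empty the anchor falls back to an outer
decile with a wide scale bound.

**Vague.** `MixturePriors()` gives quartile-centred mean priors with SD 100
and σ ~ U(0.5, 30) for both components. Useful for sensitivity analysis and
for large, well-separated samples; on study-sized data it leaves the
posterior on the ridge described above, and accuracy summaries become
diffuse and prevalence-inflated. Conclusions at n ≈ 200 therefore hinge on
the anchoring assumption; this is stated prominently rather than hidden.

## Synthetic data

The generator draws Bernoulli(π) labels and normal scores per class, then
rounds to the nearest integer and clips to [0, 64] (real totals are
integers; a `continuous` mode skips rounding). The study-like preset
concatenates a male stratum (n = 86, prevalence 4/86, components
N(9.84, 5.81²)/N(26.75, 2.75²)) and a female stratum (n = 129, prevalence
18/129, N(12.59, 6.14²)/N(29.89, 7.10²)); pooled this gives prevalence
22/215 and components consistent with N(11.42, 6.14²)/N(29.32, 6.59²).
Each stratum uses a deterministic substream of the single seed. A
`fixed_margin` option draws exactly round(πn) cases for deterministic
case counts.

What the generator does *not* emulate: item-level response patterns (only
totals), covariate effects (sex enters only through separate strata, BMI
not at all), any departure from normality within class — real symptom
scores are often right-skewed and may show a gap near the conventional
threshold that makes the true mixture easier to separate than the normal
model. Passing tests on synthetic data therefore demonstrate correctness
of the machinery under the stated mixture, not robustness to real-data
misspecification.

Rounding and clipping slightly shrink the realized healthy-component SD
(clipping at 0 moves ~2.6% of that component's mass), so sampler
calibration checks generate in `continuous` mode, where model and
generator match exactly.

## Numerical and design choices

- **Cut-off conventions.** Optimisation and reporting use "positive ⇔
  score ≥ c"; the conventional strict rule ("above 23") is available as
  `greater_than` in `classify_fixed_cutoff`. Both appear in practice and
  must coexist.
- **Near-flat Youden index.** At the study-like generating parameters
  J(20) − J(21) ≈ 0.003; the maximiser is intrinsically unstable between
  19 and 21 across realisations (an oracle using the true labels shows the
  same split). Single-dataset cut-off selections one point apart should be
  read as equivalent.
- **Report table.** Per-stratum rows show Se/Sp at cut-offs 17–23 with one
  pooled SD per criterion (the mean of per-cut-off posterior SDs) — a
  deliberate condensation convention — plus the binormal posterior-mean
  AUC.
- **Degenerate inputs.** All-identical scores raise an unidentifiability
  error; fewer than 4 scores, or fewer than 100 kept draws, are rejected;
  prevalence outside (0,1) in the generator yields a degenerate
  single-class dataset with a warning.
- **Chain sizes.** The pipeline default (5,000 + 20,000 sweeps, seconds at
  n = 215 in vectorised form) drives the acceptance script; the test suite
  uses shorter chains (600–1,500 burn-in, 2,000–6,000 kept draws) chosen so
  that posterior-mean Monte Carlo error is an order of magnitude below
  every tolerance being asserted.
- **Calibration evidence.** With matched continuous generation at
  n = 2,000, 95% credible intervals cover every generating parameter in
  19–20 of 20 seeded replicates, and posterior means sit within 2 posterior
  SDs of truth for typical seeds.

## Limitations

- A single continuous test, two classes, conditional normality — no
  Hui-Walter multi-test structures, covariate-adjusted ROC, or model
  comparison.
- The anchored policy assumes the conventional rule is at least roughly
  informative about the latent classes; if it were badly wrong, the priors
  would propagate that error, and the vague policy should be used as a
  sensitivity check.
- AUC is reported from the binormal closed form (plus an empirical
  trapezoid); semi-parametric ROC estimators are out of scope, and
  binormal AUCs on well-separated components are typically higher than
  semi-parametric estimates on the same data.
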