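# latentroc

Bayesian latent-class estimation of the diagnostic accuracy of a continuous
test score **when no gold standard exists**, with ROC/AUC summaries and
Youden-optimal cut-off selection.

The motivating application is the Nijmegen questionnaire for hyperventilation
syndrome (HVS): 16 symptom items rated 0–4, summed to a total score in
[0, 64]. There is no reference diagnosis for HVS, so the usual route to
sensitivity and specificity (compare against the truth) is closed. Instead,
each subject's disease status is treated as a latent variable and the observed
scores x₁,…,xₙ as a two-component normal mixture:

    xᵢ | zᵢ=1 ~ N(μ⁺, σ⁺²)        (diseased)
    xᵢ | zᵢ=0 ~ N(μ⁻, σ⁻²)        (healthy)
    zᵢ ~ Bernoulli(π),   π ~ Beta(1, 1)
    μ± ~ N(μ₀±, σ_μ±²),  σ± ~ U(l±, u±)

fitted by Gibbs sampling (Metropolis on log σ). Accuracy at an integer
cut-off c (positive ⇔ score ≥ c) follows per posterior draw:

    Se(c) = 1 − Φ((c − μ⁺)/σ⁺),   Sp(c) = Φ((c − μ⁻)/σ⁻)

with the Youden index J(c) = Se(c) + Sp(c) − 1 maximised over c = 0..64, and
the binormal ROC/AUC in closed form, AUC = Φ(a/√(1+b²)) with
a = (μ⁺−μ⁻)/σ⁺, b = σ⁻/σ⁺.

Because low-prevalence normal mixtures are weakly identified at study-sized
n, the default priors are *anchored* on the questionnaire's established
clinical rule (total above 23 suggests HVS): component-mean priors centred at
the conditional means of that conventional split, and per-component uniform
σ bounds scaled from its conditional SDs. Fully vague priors remain available
(`MixturePriors()`); see `docs/methods.md` for the rationale and caveats.

A synthetic-data module generates labelled integer scores from the mixture,
including a "study-like" preset (n = 215: 86 men with ~4 cases, 129 women
with ~18 cases) so the entire pipeline is testable without any real data.

## Worked example

```python
import latentroc as lr

data = lr.generate_study_like(seed=1)     # 215 subjects, labels known
draws = lr.fit_latent_mixture(data)       # anchored priors, 5k burn-in + 20k draws
best, j = lr.youden_optimal_cutoff(draws)
se, se_sd = lr.sensitivity_at_cutoff(draws, best)
sp, sp_sd = lr.specificity_at_cutoff(draws, best)
roc = lr.roc_and_auc(draws)
print(f"posterior prevalence: {draws.pi.mean():.3f} (sd {draws.pi.std():.3f})")
print(f"optimal cut-off (Youden): {best}  J = {j:.3f}")
print(f"sensitivity at {best}: {se:.3f} (sd {se_sd:.3f})")
print(f"specificity at {best}: {sp:.3f} (sd {sp_sd:.3f})")
print(f"binormal AUC: {roc.auc_mean:.3f} (sd {roc.auc_sd:.3f})")
```

prints

```
posterior prevalence: 0.096 (sd 0.029)
optimal cut-off (Youden): 21  J = 0.859
sensitivity at 21: 0.905 (sd 0.070)
specificity at 21: 0.954 (sd 0.015)
binormal AUC: 0.979 (sd 0.018)
```

The fitted prevalence (~10%) matches this dataset's generating rate; the
selected cut-off lands at 21 here and at 20 for other seeds — the Youden
index is nearly flat between 19 and 21, so neighbouring cut-offs are
statistically indistinguishable at this sample size.

The same pipeline runs from the shell:

```
latentroc run --simulate --seed 1 --outdir report/      # or --input scores.csv
latentroc simulate --seed 1 --out scores.csv
```

`run` writes an accuracy table (TSV, per-stratum Se/Sp at cut-offs 17–23
with posterior SDs and AUC), a JSON summary, the posterior draws as CSV and
a run log; with `--stratify-by sex` male, female and pooled models are
fitted with independent chains.

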