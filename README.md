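# mirbayes

Bayesian miRNA target prediction that fuses two independent lines of
evidence about whether an mRNA *g* is a target of a miRNA *m*:

1. a **sequence-level prediction score** *s* from any sequence-based
   predictor (e.g. SVMicrO), summarizing miRNA:mRNA pairing evidence, and
2. the **log fold change** *e* of *g* in a miRNA transfection experiment.

Most practice calls targets as the intersection of sequence-predicted
positives and down-regulated genes. But mRNA down-regulation is neither
necessary nor sufficient for miRNA targeting — the primary mode of
silencing is translational inhibition — so the intersection filter
discards genuine targets that are not down-regulated. `mirbayes` instead
models the evidence probabilistically and never hard-filters on fold
change.

## Model

With *t* ∈ {0, 1} the target indicator, a Naïve Bayes factorization
(assuming *e* ⊥ *s* given *t*) gives

    p(t = 1 | e, s) ∝ α(e) · β(s)

- **β(s) = p(t=1 | s)** is a logistic calibration
  β(s) = 1/(1 + exp(−(a₀ + a₁·s))) fitted by (ridge-penalized) maximum
  likelihood on labeled scores.
- **α(e) = p(t=1 | e)** comes from a two-component Bayesian Gaussian
  mixture over genome-wide fold changes,
  p(e) = π₊ N(e; μ₊, σ²₊) + π₋ N(e; μ₋, σ²₋),
  fitted by **variational Bayes EM** under conjugate priors:
  Normal-Inverse-Gamma NIG(μ, κ, α, β) on each component's (mean,
  variance) and Dirichlet(γ₊, γ₋) on the weights. Because the target
  component holds only ~1% of genes, its prior is made *informative*: the
  conjugate NIG posterior of verified-target fold changes. The defaults
  are NIG(0, 0.2, 0.2, 0.2) and Dirichlet(200, 20000) — a miRNA regulates
  on the order of 200 of ~20000 genes.
  With point estimates θ̂ from the fit,

      α(e) = π̂₊ N(e; μ̂₊, σ̂²₊) / (π̂₊ N(e; μ̂₊, σ̂²₊) + π̂₋ N(e; μ̂₋, σ̂²₋))

  clamped to a constant above e = 0.5 (the positive component's heavier
  tail otherwise makes α ramp back up for strongly *up*-regulated genes,
  which contradicts the biology).

Genes present in both evidence sources are ranked by α·β. Evaluation
utilities provide precision–recall curves over every rank cut,
cumulative fold-change curves over top-k predictions, and the
intersection ("overlap") baseline for comparison.

## Worked example

Everything runs on synthetic data shaped like the real study (1%
positives; positive scores N(0.75, 0.5) vs negative N(−0.75, 0.5);
positive fold changes N(−0.5, 0.5) vs negative N(0, 0.4); second
parameters are variances):

```sh
mirbayes simulate --out-dir sim --seed 0
mirbayes calibrate --scores labeled.tsv --out logistic.json   # (score, label) TSV
mirbayes predict --expression sim/expression.tsv --scores sim/scores.tsv \
    --logistic-params logistic.json --verified sim/verified.tsv --out pred.tsv
mirbayes evaluate --predictions pred.tsv --truth sim/labels.tsv --out pr.tsv
```

The same pipeline from Python:

```python
from mirbayes import (SimulationConfig, LabeledScoreSet, simulate_dataset,
                      simulate_verified_targets, fit_logistic, predict_targets)

ds = simulate_dataset(SimulationConfig(seed=0))
cal = simulate_dataset(SimulationConfig(seed=5000))
logistic = fit_logistic(LabeledScoreSet(cal.scores, cal.labels))
records, fit = predict_targets(ds.to_expression_profile(), ds.to_score_table(),
                               logistic, simulate_verified_targets(seed=1000))
th = fit.theta_hat
print(f"pos N({th.mu_pos:.4f}, {th.var_pos:.4f}) w={th.pi_pos:.2%}  "
      f"neg N({th.mu_neg:.4f}, {th.var_neg:.4f}) w={th.pi_neg:.2%}")
top = records[0]
print(top.gene_id, f"alpha={top.alpha:.3f} beta={top.beta:.3f} combined={top.combined:.4f}")
```

prints

```
pos N(-0.4689, 0.4533) w=0.99%  neg N(-0.0005, 0.4068) w=99.01%
G000078 alpha=0.145 beta=0.367 combined=0.0532
```

i.e. the mixture fit recovers the generating parameters — the weak
positive component sits near μ₊ = −0.5, σ²₊ = 0.5 at ~1% weight despite
being buried under 99% negatives — and the top-ranked gene combines a
strong sequence score with clear down-regulation. On these simulations
the combined ranking's PR area exceeds both the score-only and the
expression-only rankings in 20/20 seeded replicates.

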