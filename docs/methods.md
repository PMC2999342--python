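# Methods

## Problem and model

For a fixed miRNA, each gene *g* carries two measurements: a
sequence-level prediction score *s* (from any external sequence-based
predictor; producing it is out of scope here) and a log fold change *e*
from a transfection experiment. With the target indicator
*t* ∈ {0, 1}, the fused score is the Naïve Bayes product

p(t=1 | e, s) ∝ α(e) · β(s),

valid under conditional independence of *e* and *s* given *t*. The two
measurements are of course correlated in reality; the factorization is
a deliberate simplification that keeps both models univariate, and the
product is reported unnormalized — the normalization constant would
require the marginal p(t=1), affects neither ranking nor thresholding,
and is therefore dropped.

### Score calibration β(s)

β(s) = 1/(1 + exp(−(a₀ + a₁ s))), fitted by minimizing the binary
cross-entropy with an L2 penalty λ/2·(a₀² + a₁²), λ = 1e−6 by default.
The penalty covers the intercept as well as the slope; at this
magnitude it changes the fit only in the quasi-separable regime, where
it keeps the optimum finite. Optimization is BFGS with an analytic
gradient from the starting point (0, 0); the objective is strictly
convex for λ > 0, so the optimizer's choice is immaterial. Exactly
separable data with λ = 0 is rejected with an error rather than
returning a diverging solution. A practical consequence of fitting on
heavily imbalanced training data (hundreds of verified targets against
thousands of negatives) is that β stays far below 1 even at the top of
the score range — the sequence evidence alone cannot assert targethood.

### Fold-change mixture and priors

Genome-wide fold changes are modeled i.i.d. from a two-component
Gaussian mixture: a weak positive (target) component and a dominant
negative component,

p(e) = π₊ N(e; μ₊, σ²₊) + π₋ N(e; μ₋, σ²₋),  π₊ + π₋ = 1.

Conjugate priors: NIG(μ, κ, α, β) on each component's (mean, variance),
meaning μ|σ² ~ N(μ, σ²/κ) and σ² ~ Inv-Gamma(α, β), and a Dirichlet on
the weights. Defaults, all on the log-fold-change scale:

| parameter | default | role |
|---|---|---|
| noninformative NIG | (0, 0.2, 0.2, 0.2) | negative component prior; base for the positive prior |
| Dirichlet (γ₊, γ₋) | (200, 20000) | a miRNA regulates ~200 of ~20000 genes; prior weight mean ≈ 1% |
| verified-target set | 209 values | conjugate evidence that makes the positive prior informative |
| negative init variance | 5 | initialization spread of the negative component |
| clamp threshold | 0.5 | where α(e) becomes constant |

With π₊ ≈ 1%, the positive component is essentially unidentifiable from
the mixture likelihood alone (many near-equivalent solutions bury it
under the negative bulk). The informative prior resolves this: the
positive prior is the exact conjugate NIG posterior of the
noninformative prior after observing the fold changes of verified
targets — mu' = (κμ + Nē)/(κ+N), κ' = κ+N, α' = α+N/2,
β' = β + ½Σ(eᵢ−ē)² + κN(ē−μ)²/(2(κ+N)). With N = 209 values this
anchors the positive component's location and scale while the weight
prior keeps π₊ near 1%.

One stated default, a negative-component σ of 5, is ambiguous between a
prior scale and an initialization value; both readings are
noninformative and the fit is insensitive to the choice. Here it is
used as the initialization variance of the negative component, and the
negative prior proper stays at the noninformative NIG.

### VBEM

The posterior over (z, π, μ±, σ²±) is approximated by the mean-field
factorization q(z) q(π) q(μ₊, σ²₊) q(μ₋, σ²₋), optimized by coordinate
ascent on the ELBO. All factors are conjugate, so both steps are closed
form and this is the unique mean-field solution for the model:

- **VBE** — responsibilities r_i ∝ exp(E[log π_k] + E[log N(e_i; μ_k, σ²_k)])
  with E[log π_k] = ψ(γ_k) − ψ(Σγ) and
  E[log N] = −½log 2π − ½(log β − ψ(α)) − ½((α/β)(e−m)² + 1/κ),
  normalized pairwise in log space.
- **VBM** — Dirichlet counts γ_k = γ_k,0 + Σr_ik and a weighted
  conjugate NIG update per component with effective count Σr_ik,
  weighted mean, and weighted scatter.

Numerical choices:

- **Initialization** is deterministic: responsibilities from point
  Gaussians at the positive prior's location (variance from the prior
  when proper) and at mean 0 with variance 5 for the negative
  component, weighted by the Dirichlet prior means. Anchoring the
  positive component at a negative location fixes the label assignment,
  so no label-switching handling is needed.
- **Convergence** when the relative ELBO change drops below 1e−8
  (default) or after 500 iterations. The ELBO is computed after every
  full VBE+VBM sweep and asserted non-decreasing to 1e−8 relative; a
  decrease raises an error with the offending state, since coordinate
  ascent guarantees monotonicity and a violation means a numerical bug.
  On the default 20000-gene simulation the fit converges in ~15
  iterations, well under a second.
- **Point estimates** are variational posterior means (MMSE): μ̂ = m,
  σ̂² = β/(α−1) (the mode β/(α+1) is substituted in the degenerate case
  α ≤ 1, unreachable with more than two effective observations), and
  π̂_k = γ_k/Σγ. Posterior means were chosen over MAP for smoothness;
  at these sample sizes the two are indistinguishable.
- **Degenerate inputs**: fewer than 2 genes or any non-finite fold
  change is rejected up front.

### α(e) and ranking

α(e) is the posterior positive-component probability under the plug-in
point estimates. Because σ̂²₊ > σ̂²₋, the raw curve is monotone
decreasing over the down-regulated range but ramps back up for large
positive fold changes — an artifact of the heavier positive tail that
would reward up-regulation. α is therefore held constant at its value
at e = 0.5 for all e > 0.5; the threshold is configurable and the
constant is evaluated exactly at the threshold so α stays continuous.
The 0.5 is interpreted on the same log scale as the input fold changes
(assumed log2; the method itself is scale-agnostic).

Ranking is by descending α·β with deterministic tie-breaks: more
negative fold change first, then lexicographic gene id. Genes present
in only one evidence source are excluded rather than imputed.

## Synthetic data

The generator emulates the study conditions the method was validated
under: 200 positive genes (1%) with scores from N(0.75, 0.5) and fold
changes from N(−0.5, 0.5), 19800 negatives with N(−0.75, 0.5) and
N(0, 0.4) — second parameters are variances throughout — plus
209-value verified-target sets drawn from the positive fold-change
distribution, since verified targets are by definition draws from the
positive population. Scores and fold changes are independent given the
label, matching both the fusion model's assumption and the fact that
only marginals are specified. Gene ids are zero-padded for
deterministic tie-breaks.

What the generator does *not* emulate: probe-level microarray noise and
normalization artifacts, correlation between sequence score and
expression response, non-Gaussian fold-change tails, and any sequence
content. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not performance
on real transfection arrays.

## Evaluation

Precision–recall is computed at every rank cut (precision = TP/k,
recall = TP/|truth|) with no interpolation; the PR area uses the
trapezoid rule over recall. Baselines: score-only (rank by s
descending), expression-only (rank by e ascending — most down-regulated
first), and the overlap method (predict s ≥ score_cut AND e ≤ down_cut
as a single set; defaults down_cut = 0 and a score cut at the β = 0.5
equivalent, both configurable since no canonical values exist). The
cumulative fold curve sums an auxiliary per-gene measurement (e.g.
protein-level down-fold) over the top-k ranked genes, skipping genes
without a measurement.

On the default simulation the combined ranking's PR area dominates both
single-evidence baselines in essentially every replicate, and the
overlap baseline's recall is structurally capped below the combined
method's at matched precision: any true target with e > down_cut is
unrecoverable by the intersection filter at any score threshold.

## Problem sizes and determinism

The test suite and the acceptance script use the study's native sizes —
20000 genes per replicate, 20 seeded replicates, 209-value verified
sets — since a full fit takes well under a second. All randomness flows
through explicit integer seeds (NumPy `default_rng`); fits themselves
are deterministic given the data.

## Known limitations

- Single miRNA per run; no joint modeling across experiments or
  hierarchical sharing between miRNAs.
- The combined score is an unnormalized product, comparable within a
  run but not an absolute probability.
- Exactly K = 2 components; strongly bimodal negative populations
  (e.g. batch effects) violate the model.
- The independence assumption ignores the known correlation between
  good seed matches and stronger mRNA degradation; in practice Naïve
  Bayes fusion degrades gracefully under such correlation but the
  combined score's calibration suffers before its ranking does.
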