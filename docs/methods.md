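# Methods

## The problem

Verbal autopsy (VA) surveys record a binary symptom vector
`X_i ∈ {0,1}^p` for each death, collected by interviewing caregivers
where medical certification of the cause is unavailable. Given a
training set of deaths with reference causes `Y_i ∈ {1..C}` and a
target set with symptoms only, two quantities are wanted for the target
population: individual posterior cause assignments `p(Y_i | X_i)` and
the cause-specific mortality fractions (CSMF) `p(Y)`. The two
populations are linked by a label-shift assumption: `p(X | Y)` is
shared, while the prevalences `π^(1)` (training) and `π^(0)` (target)
may differ and are estimated separately.

## Models

All three models are probabilistic decompositions of the conditional
probability tensor `p(X | Y = c)` built from per-cause, per-class
Bernoulli symptom profiles `φ_ckj`.

**PARAFAC** (latent class model): a K-component mixture of independent
Bernoulli products,

    p(x | c) = Σ_k λ_ck Π_j φ_ckj^{x_j} (1 − φ_ckj)^{1−x_j}.

**r-group independent PARAFACs**: symptoms are partitioned into `r`
groups by a cause-specific indicator `s_cj ∈ {1..r}`, and each group
carries its own latent class `Z_is ∈ {1..K}` with weights `λ_cs`:

    p(x | c) = Π_s Σ_k λ_csk Π_{j: s_cj=s} Bern(x_j; φ_ckj).

Groups are independent given the cause; dependence within a group is
arbitrary for large enough K.

**Collapsed Tucker (c-Tucker)**: the joint weights over the r group
indicators are themselves PARAFAC-factorized through an upper-level
class `H_i ∈ {1..h}`:

    λ_c,k1..kr = Σ_l ν_cl Π_s ψ_clsk_s,

which induces dependence *between* symptom groups while keeping the
number of free profile parameters at `p·K` per cause. Expressing the
same distribution with a flat PARAFAC would need `K^r` classes and
`p·K^r` profile parameters. The models nest: c-Tucker with `h=1` is the
grouped model, and `h=r=1` is PARAFAC; with `r=p` it reaches the
standard Tucker decomposition, which we do not treat separately.

Hierarchically, a death is generated as `Y ~ Cat(π^(g))`,
`H | Y=c ~ Cat(ν_c)`, `Z_s | H=l, Y=c ~ Cat(ψ_cls)`,
`X_j | Y=c, Z_{s_cj}=k ~ Bern(φ_ckj)`. Likelihood evaluation always
uses the factorized form (cost `O(h·r·K + p·K)` per death), never the
`K^r`-term expansion; a brute-force enumeration oracle exists for
`p ≤ 16` and is used only in tests.

## Priors and hyperparameters

| parameter | prior | default | notes |
|---|---|---|---|
| π^(0), π^(1) | Dir(α, …, α) | α = 1 | flat over causes |
| φ_ckj | Beta(a_φ, b_φ) | (1, 1) | non-informative |
| ν_c | Dir(1/h, …, 1/h) | — | shrinks unused upper classes |
| ξ_c (group weights) | Dir(1/r, …, 1/r) | — | shrinks unused groups |
| ψ_cls | Dir(b_1, …, b_K) | b = 1 | class weights per (cause, upper class, group) |
| λ_cs (grouped) | Dir(a_1, …, a_K) | a = 1 | |

The `1/h` and `1/r` scalings are part of the model; the remaining
hyperparameters default to 1 (symmetric, non-informative) and are
exposed on `ModelConfig`. `K_1 = … = K_r` is enforced: groups share one
class budget K.

## Posterior computation

Gibbs sampling with exact conjugate or categorical full conditionals.
Sweep order for c-Tucker: `Y → Z → H → π → ν → ψ → φ → s → ξ`; for the
grouped model: `Y → Z → λ → π → φ → s → ξ` (PARAFAC is the grouped
model with r = 1, where the degenerate `s` and `ξ` updates are
skipped). Any systematic scan order is valid; one fixed order keeps
runs reviewable. Default chain length 3000 sweeps with 1000 discarded
as burn-in, no thinning, one chain (independent seeded chains can be
pooled).

Numerical choices:

* φ is clamped to `[1e-12, 1 − 1e-12]` before logs: Beta posterior
  draws can reach the float underflow region when a class accumulates
  thousands of one-sided observations.
* Categorical draws use the Gumbel-max trick on unnormalized log
  masses — exact, vectorizable, and free of per-row normalization.
  Ties have probability zero; the argmax's first-index convention is
  the de-facto tie-break.
* The per-death group log-likelihood tables are computed in single
  precision (the resulting logits are accurate to ~1e-5, far below any
  statistical effect on the chain); all conjugate counts and parameter
  draws are double precision.
* Initialization is over-dispersed and cheap: `Z, H, s` uniform,
  target `Y` uniform, all other parameters drawn from their priors.
* Missing symptom entries (an optional mask) are skipped in every
  likelihood product and excluded from the φ counts — exact
  marginalization because factors are conditionally independent given
  the latent state.
* Empty structures are well-defined: a group with no symptoms under a
  cause draws its Z from the weight prior alone; a cause with no
  current deaths draws all its parameters from their priors; a fully
  empty dataset reproduces every prior (this is tested).
* Label switching is not corrected during sampling. Cause prediction
  and CSMF estimation are invariant to it. Interpretation summaries
  report posterior means without relabeling, which is adequate when
  classes are well separated; a single representative draw can be used
  instead when in doubt.

Given a seed, chains are bit-reproducible.

## Prediction and estimation

Individual probabilities are Monte-Carlo frequencies of the imputed
target labels across stored draws; the top cause is the row argmax with
ties to the lowest index (determinism). The CSMF point estimate is the
posterior mean of `π^(0)` with equal-tailed 95% intervals; the
imputed-label-frequency estimator is also exposed (the two coincide as
n₀ grows and differ only by the Dirichlet prior's smoothing).

## Synthetic data

The generator emulates the VA study conditions and is itself first
class, tested code. Defaults: C = 20 causes, p = 80 symptoms, 2000
training and 1000 target deaths, data generated ancestrally from the
c-Tucker model with K = 3, r = 5, h = 3, `ν_cl = 1/h`, and
`π^(g) ~ Dir(1,…,1)` independently per domain.

* The group matrix is cyclic: row c lists r sequential blocks of
  `g = p/r` symptoms, shifted by one symptom per cause
  (`s_cj = ⌊((j − c) mod p)/g⌋` 0-based). Every row holds exactly g
  symptoms per group. An alternative reading (shift by g per cause)
  exists but is not the default because it breaks the one-step cyclic
  pattern.
* Class-weight concentrations `β_cls` are integers drawn uniformly on
  [1, 10] (inclusive), so group/class signal strength varies widely
  across causes.
* Low signal-to-noise: only symptoms whose group index falls in the
  informative set (groups 3–5 of 5 by default) have cause-specific
  profiles; the rest share one class-dependent profile across causes.
  For r < 3 every group is informative.
* Scenario I is pure label shift (`p(X|Y)` shared across domains);
  Scenario II draws `ψ` independently per domain, so every fitted model
  is deliberately misspecified.

What the generator does **not** emulate: questionnaire skip patterns,
item missingness (the model supports masks, the generator never emits
them), demographic covariates, physician-coding noise, or the empirical
marginal frequencies of any real questionnaire. Passing recovery tests
therefore show correctness of the inference machinery under the model's
own assumptions, not field performance on real VA data.

A resampling utility builds train/target replicates from any fully
labeled dataset (80% resampled with replacement as training, the
held-out rest resampled to a fresh `Dir(1,…,1)` target prevalence),
mirroring how gold-standard datasets are used; causes absent from the
held-out pool have their target mass renormalized away with a warning.

## Evaluation and interpretation

* **CSMF accuracy** `1 − Σ_c |π̂_c − π_c| / (2(1 − min_c π_c))`, in
  [0, 1]; **top-cause accuracy** is plain agreement of the argmax cause.
* **Utilization diagnostics**: a group's utilization is the fraction
  of stored draws in which any (cause, symptom) cell occupies it; the
  "group variation" used to choose r is operationalized as the share of
  all (cause, symptom, draw) assignment mass per group — an
  interpretive choice, flagged as such. A class counts as utilized in
  a draw when it holds at least 5% of deaths (threshold configurable,
  mirroring the 5%-of-draws cutoff at the group level). The advisory
  rule returns the smallest r reaching 95% of mass and the smallest
  per-group K covering 80% of utilized classes.
* **Anchors**: per group, symptoms sorted by posterior assignment
  probability, ties by empirical `p(X_j = 1 | Y = c)`, then index;
  groups ordered by decreasing mean empirical conditional frequency
  averaged over *all* member symptoms (averaging over only the
  displayed ones was the ambiguous alternative).
* **Cause dendrogram**: dissimilarity `1 − ARI` between the posterior
  modal symptom partitions of two causes, average-linkage agglomeration
  (configurable; average linkage is the standard choice for
  similarity-derived dissimilarities). ARI can be negative, so
  dissimilarities may exceed 1; they are not clipped.
* **Expanded profiles**: full enumeration of the `K^r` class tuples
  with joint weights `Σ_l ν_cl Π_s ψ_cls,k_s` (they sum to 1), refused
  beyond 2^20 tuples without an explicit cap.

## Problem sizes used in the shipped checks

The recovery experiment in the test suite runs five Scenario-I
replicates at the full study dimensions (C=20, p=80, n=3000, 3000
sweeps) and asserts that the correctly specified c-Tucker fit achieves
higher mean CSMF accuracy than a flat PARAFAC with K=5, reproducing the
qualitative ordering of interest; `scripts/acceptance.py` runs two
replicates of the same experiment by default. Unit-level checks use
small instances (p ≤ 10) where brute-force enumeration over all latent
configurations and all 2^p symptom patterns is exact.

## Known limitations

* Interpretation summaries average over draws without relabeling
  latent classes; under weak separation the utilization and profile
  summaries blur across switched labels.
* The dimension-selection rule is advisory and conservative; when the
  posterior spreads mass over exchangeable groupings it will not shrink
  r aggressively. WAIC/LOO-style selection is deliberately out of
  scope.
* No convergence diagnostics gate the output; chains of the default
  length mix well on the simulated conditions but real datasets should
  be checked (the draws are exposed arrays, directly usable with
  `arviz`).
* Only binary symptoms are supported; categorical or continuous items
  and standard (non-collapsed) Tucker decomposition are out of scope.
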