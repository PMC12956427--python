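# vatensor

Dimension-grouped Bayesian tensor decomposition for verbal autopsy
(VA) data: probabilistic cause-of-death assignment and cause-specific
mortality fraction (CSMF) estimation under label shift, with
interpretable latent symptom structure.

## Who this is for

Verbal autopsies — structured interviews with caregivers of the
deceased — are the main source of cause-of-death information where
medical certification is absent. Statistical VA methods model the
conditional distribution of the binary symptom vector `X ∈ {0,1}^p`
given the cause `Y ∈ {1..C}` on a labeled training set, then infer
individual causes `p(Y | X)` and the population CSMF `p(Y)` in an
unlabeled target population whose cause distribution may differ
(label shift). This package is for biostatisticians and VA
methodologists who want latent class models that stay accurate with
many symptoms while remaining interpretable.

## The models

All three decompose `p(X | Y=c)` through Bernoulli symptom profiles
`φ_ckj` and differ in how latent classes are organized:

* **PARAFAC** — the classical latent class model,
  `p(x|c) = Σ_k λ_ck Π_j Bern(x_j; φ_ckj)`;
* **r-group independent PARAFACs** — symptoms are partitioned into
  `r` cause-specific groups `s_cj`, each with its own latent class
  `Z_is` and weights `λ_cs`;
* **collapsed Tucker (c-Tucker)** — the joint weights over the group
  classes are PARAFAC-factorized through an upper-level class `H_i`:
  `λ_c,k1..kr = Σ_l ν_cl Π_s ψ_clsk_s`, inducing between-group
  dependence with only `p·K` profile parameters per cause (a flat
  PARAFAC expressing the same structure needs `p·K^r`).

Posterior inference is by Gibbs sampling with exact conjugate updates;
symptom grouping `s` is learned from data under a `Dir(1/r)` prior.
See `docs/methods.md` for the full model, priors, and numerical
choices.

## Worked example

```python
import numpy as np
from vatensor import (ModelConfig, SimulationConfig, cause_posterior,
                      csmf_accuracy, generate_dataset, run_chain,
                      top_cause_accuracy)

sim = SimulationConfig(C=6, p=20, K=2, r=4, h=2,
                       n_train=800, n_target=400, scenario="I", seed=42)
data, truth = generate_dataset(sim)          # 400 deaths unlabeled
cfg = ModelConfig(model="ctucker", K=2, r=4, h=2,
                  n_iter=1200, n_burnin=400, seed=7)
samples = run_chain(data, cfg)
post = cause_posterior(samples)

y_true = truth.Y[truth.D == 0]
pi_true = np.bincount(y_true, minlength=6) / y_true.size
print(top_cause_accuracy(post.top_cause, y_true))  # 0.745
print(csmf_accuracy(post.csmf, pi_true))           # 0.930
```

The two numbers are the standard VA metrics: the fraction of target
deaths whose most probable cause matches the hidden truth, and the
rescaled L1 agreement between the estimated and true target CSMF
(1 = perfect, 0 = point mass on the rarest cause). `post.csmf` also
carries equal-tailed 95% credible intervals per cause.

The `examples/` directory holds short narrative scripts, one per
capability: simulate–fit–evaluate, latent-structure interpretation
(anchor symptoms, marginal class weights, expanded profiles),
dimension selection from posterior utilization, and the cause
dendrogram. A thin CLI covers the same pipeline from the shell:

```bash
vatensor simulate --scenario I --seed 1 --out data/run1
vatensor fit --model ctucker --K 3 --r 5 --h 3 --data data/run1.csv --out fits/run1
vatensor predict --samples fits/run1.npz --out preds/run1
vatensor evaluate --pred preds/run1 --truth data/run1_truth.yaml
```

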