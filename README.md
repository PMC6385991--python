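# ordinalgs

Genomic prediction of **ordinal traits** (disease scores, lodging, grain
colour, discretised agronomic traits) across multiple environments, for
plant-breeding researchers who want to benchmark a Bayesian threshold model
against standard machine-learning classifiers under a realistic
incomplete-trial cross-validation.

The package provides three predictors behind one evaluation harness:

* **TGBLUP** — Bayesian threshold genomic best linear unbiased prediction
  with genotype-by-environment (G×E) interaction, fitted by a from-scratch
  Gibbs sampler with liability augmentation;
* **MLP** — a feedforward neural network (1–3 ReLU hidden layers, dropout,
  softmax/sigmoid output) on environment + genomic-Cholesky features;
* **SVM** — a one-vs-one soft-margin SVM with radial kernel on the same
  features;

plus a synthetic multi-environment trial generator with known truth, CV2
fivefold cross-validation, and the PCCC metric (percentage of cases
correctly classified).

## The model

The ordinal category y_ij ∈ {1..C} of line j in environment i is generated
by a latent Gaussian liability

```
l_ij = E_i + g_j + gE_ij + ε_ij,   ε_ij ~ N(0, 1),
y_ij = c  ⇔  γ_{c-1} < l_ij < γ_c          (γ_0 = −∞, γ_C = +∞)
```

with fixed environment effects E_i, genomic effects
**g** ~ N(0, G₁σ²_g) where G₁ = WWᵀ/m is the genomic relationship matrix of
column-standardised marker dosages W, and interaction effects
**gE** ~ N(0, (I_I ⊗ G₁)σ²_gE) — environments independent, so the G×E
covariance is block-diagonal with one G₁ block per environment.  Cell
probabilities follow the cumulative probit link: with
η_ij(c) = γ_c − E_i − g_j − gE_ij,

```
π_ij(1) = Φ(η_ij(1)),   π_ij(c) = Φ(η_ij(c)) − Φ(η_ij(c−1)),
π_ij(C) = 1 − Φ(η_ij(C−1)).
```

Identification fixes the residual variance at 1 and γ₁ at 0; variance
components carry weakly informative scaled-inverse-χ² priors.  The MLP and
SVM see each line through its row of the Cholesky factor L₁ of G₁ (so the
feature Gram matrix reproduces G₁), concatenated with environment one-hots
and, in the interaction ("I") variant, the environment ⊗ Cholesky block;
the "WI" variant omits it.

Evaluation follows the **CV2** scheme: observed (environment, line) cells —
not whole lines — are split into five folds stratified by environment, so a
line predicted in one environment usually remains observed in others, as in
incomplete multi-environment trials.  Hyperparameters (MLP units/layers/
epochs; SVM cost T and kernel γ) are tuned inside each training fold only.

## Worked example

```python
import numpy as np
from ordinalgs import (SyntheticConfig, simulate_markers, simulate_trial,
                       MarkerMatrix, KernelSet, TGBLUPConfig, ThresholdGBLUP)
from ordinalgs.evaluation import (make_cv2_folds, run_benchmark, summarize,
                                  TGBLUPModel)

cfg = SyntheticConfig(I=3, J=120, m=250, seed=7)   # sg2=0.6, sge2=0.2 defaults
rng = np.random.default_rng(cfg.seed)
markers = MarkerMatrix(line_ids=cfg.line_ids,
                       raw=simulate_markers(cfg.J, cfg.m, cfg.maf_range, rng))
kernels = KernelSet.from_markers(markers, I=cfg.I)
table, truth = simulate_trial(cfg, kernels.G1, rng)

res = ThresholdGBLUP(table, kernels,
                     config=TGBLUPConfig(n_iter=4000, burn_in=1000, seed=1)).fit()
print(res.summary().round(3))
```

prints (288 observed cells of the 3×120 grid; truth σ²_g = 0.6,
σ²_gE = 0.2, E = (−0.5, 0, 0.5), γ = (0, 1)):

```
parameter   mean    sd    q05    q95
 sigma_g2  0.630 0.228  0.331  1.092
sigma_ge2  0.599 0.268  0.301  1.070
    E[E1] -0.602 0.172 -0.885 -0.314
    E[E2] -0.137 0.143 -0.367  0.093
    E[E3]  0.432 0.140  0.210  0.672
  gamma_1  0.000 0.000  0.000  0.000
  gamma_2  0.969 0.113  0.787  1.151
```

The genomic variance, environment effects and the free threshold are
recovered well at this size; the interaction variance is the hardest
parameter — its posterior is wide and sits above the truth here, which is
typical for threshold models on a few hundred ordinal cells (see
`docs/methods.md`).  A cross-validated comparison of the interaction (I)
and main-effects (WI) variants:

```python
plan  = make_cv2_folds(table, k=5, seed=cfg.seed)
bench = run_benchmark(table, kernels,
                      {"TGBLUP": TGBLUPModel(TGBLUPConfig(n_iter=2000, burn_in=600))},
                      plan, variants=("I", "WI"))
print(summarize(bench).means.groupby("variant")["mean_pccc"].mean())
# variant
# I     52.25
# WI    54.93
```

At this weak-interaction setting the two variants are statistically
indistinguishable (the Bayes-optimal rate for this replicate is ≈ 66%);
with σ²_gE ≥ σ²_g the I variant pulls ahead on average.

The same pipeline is scriptable from a shell:

```bash
ordinalgs simulate  --config run.yaml --out sim/
ordinalgs benchmark --phenotypes sim/phenotypes.tsv --markers sim/markers.tsv \
                    --models TGBLUP,MLP,SVM --variants I,WI --out folds.tsv
ordinalgs summarize --results folds.tsv --out summary/
```

All files are plain TSV with a provenance header (package version, seed,
config hash).

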