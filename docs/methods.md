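# Methods

## Model

One ordinal trait is modelled per fit.  The observed category y_ij ∈ {1..C}
of line j (j = 1..J) in environment i (i = 1..I) arises from a latent
liability

l_ij = E_i + g_j + gE_ij + ε_ij,  ε_ij ~ N(0, 1) iid,

cut at ordered thresholds γ_1 < … < γ_{C−1}: y_ij = c when
γ_{c−1} < l_ij < γ_c (γ_0 = −∞, γ_C = +∞).  Equivalently, with
η_ij(c) = γ_c − E_i − g_j − gE_ij, the category probabilities are the
probit differences π_ij(1) = Φ(η_ij(1)), π_ij(c) = Φ(η_ij(c)) − Φ(η_ij(c−1)),
π_ij(C) = 1 − Φ(η_ij(C−1)).

Effects and priors:

* E_i — fixed environment effects, flat prior;
* g = (g_1..g_J)ᵀ ~ N(0, G₁·σ²_g), with G₁ = W Wᵀ/m the genomic
  relationship matrix of column-standardised dosages (population-SD
  scaling, so diag(G₁) averages 1 and σ²_g is per unit relationship);
* gE ~ N(0, (I_I ⊗ G₁)·σ²_gE) — independent across environments, each
  environment block equal to G₁.  G₂ = I_I ⊗ G₁ is never materialised;
  covariance access is by block;
* σ²_g, σ²_gE ~ Scaled-Inv-χ²(df = 5, S = 0.7).

**Identification.** Adding a constant to every γ_c and every E_i leaves the
likelihood invariant, as does rescaling all parameters jointly with the
residual SD.  We fix the residual variance at 1 and γ_1 = 0; environment
effects are then free.  For C = 2 the single threshold stays at 0 and only
E_i moves the cut-point.

**Prior scale.** S = 0.7 places the prior *mode* of each variance at
df·S/(df+2) = 0.5, i.e. half of the unit residual variance per random term
— the only self-consistent reading of "weakly informative, half the
liability variance to the random terms" (each term's share of the implied
liability variance 0.5+0.5+1 is then a quarter).  With df = 5 the prior
mean is 1.17 and the right tail is heavy; consequences are discussed under
*Known limitations*.

## Gibbs sampler

Per iteration, in order:

1. **Liabilities.** Observed cells: l_ij ~ N(μ_ij, 1) truncated to
   (γ_{y−1}, γ_y), μ_ij = E_i + g_j + gE_ij.  The truncated draw uses
   inverse-CDF sampling in log space (`log_ndtr`/`ndtri_exp`, far-tail
   intervals reflected first), so means tens of SDs outside the interval
   still give finite draws strictly inside it.
   *Unobserved* grid cells get unconstrained N(μ_ij, 1) draws — see
   *Complete-grid augmentation* below.
2. **Thresholds** (C ≥ 3).  Albert–Chib uniform conditionals:
   γ_c ~ U(max liab in category c, min liab in category c+1); empty
   categories borrow bounds from occupied neighbours with a logged warning.
   This update mixes slowly for large n, which the default chain length
   compensates.
3. **Effects.**  Exact Gaussian full conditionals of the linear mixed model
   on the liabilities.  E_i is its least-squares conditional; g and each
   environment's gE block are updated in the eigenbasis G₁ = U Λ Uᵀ
   (one decomposition per fit), where the complete grid makes the
   conditional precisions diagonal: I + 1/(σ²_g λ_k) for g,
   1 + 1/(σ²_gE λ_k) per gE block.  Null eigencomponents (λ_k = 0, e.g. the
   centring direction of standardised markers) are pinned to 0 by the prior.
4. **Variances.**  Conjugate scaled-inverse-χ² draws with rank-aware
   degrees of freedom: σ²_g uses df + r and quadratic form Σ g̃²_k/λ_k over
   the r positive eigencomponents; σ²_gE analogously with df + I·r.

Defaults: 12,000 iterations, 2,000 burn-in, thinning 5 (tests and the
acceptance script use shorter chains, 2,500–6,000 iterations, at which the
posterior summaries are already stable for the sizes involved).  A
split-chain potential-scale-reduction diagnostic on σ²_g warns — not fails
— above 1.1.  Initial thresholds come from the probit of the empirical
cumulative category frequencies, shifted so γ_1 = 0.

**Complete-grid augmentation.**  Liabilities are imputed for *all* I×J grid
cells, not only the observed ones.  Unobserved cells contribute no
truncation (their liability is a prior-predictive draw given the current
parameters), so the augmented posterior marginalises back to the correct
posterior; the payoff is a balanced design in which every effect update is
diagonal in the eigenbasis (no per-iteration Cholesky of a J×J precision),
and gE draws at unobserved cells come out of the sampler as exact
posterior-predictive draws — which is precisely what prediction needs.

**Prediction.**  For each retained draw, every grid cell's probability
vector is computed from the drawn (γ, E, g, gE) through the probit link and
averaged across draws (posterior predictive); the predicted class is the
argmax with lowest-index tie-break.  Test cells must reference lines
present in G₁ and environments present in training.

**Validation routes.**  The sampler is checked against four independent
oracles in the test suite: closed-form GBLUP conditional means
(componentwise, 4 MC SE); conjugate variance moments; a 2-D quadrature of
the exact (σ²_g, σ²_gE) posterior on continuous liabilities in the
eigenbasis; and a Geweke-style successive-conditional run on a J=10 tiny
instance whose σ²_g marginal must reproduce the prior.  (During
development the full categorical posterior was additionally reproduced by
an independent JAGS implementation of the same model.)

## Machine-learning baselines

Both operate on the feature rows of `assemble_features`: environment
one-hot (I columns) ∥ line row of the Cholesky factor L₁ of G₁ + jitter
(J columns) ∥ optionally one-hot(env) ⊗ L₁-row (I·J columns) — the row of
the Cholesky factor of I⊗G₁, making the feature Gram matrix reproduce the
model covariance.  The jitter ladder {0, 1e-10, 1e-8, 1e-6, 1e-4} handles
rank-deficient G₁ (duplicated genotypes).

**MLP.** 1–3 hidden ReLU layers, shared units per layer, inverted dropout
(default rate 0.2), output softmax (sigmoid for C = 2), categorical
cross-entropy, Adam (lr 1e-3, batch 32) — implemented in numpy with
explicit forward/backward passes.  The last 20% of the shuffled training
rows form the inner validation split; the returned weights are those of the
epoch (≤ 100) with minimum validation loss, which searches the epoch grid
in a single run.  The (layers × units) grid is units 10..490 step 40 by
default (step 20 behind `--full-grid`, 75 candidates); selection is by
minimum inner-validation loss, ties to fewer layers then fewer units.
Optimizer, batch size, learning rate and dropout rate are package defaults
— the benchmark protocol leaves them open.

**SVM.** One binary soft-margin machine per unordered class pair (lower
class coded +1), radial kernel K(x,x′) = exp(−γ‖x−x′‖²), cost T.  The
printed kernel form some sources give without the square on the coordinate
differences is a typographical slip; the standard squared form (as in
e1071/libsvm) is implemented.  Prediction counts "+1" votes over all
K(K−1)/2 machines; ties break by the larger sum of signed decision values,
then the lower class index.  (T, γ) are tuned on the grid
T ∈ {1, 1.2, 1.4, 1.6, 1.8, 2}, γ ∈ {1e-4, 2e-4, 2.5e-4, 3e-4} by 10-fold
inner CV (stratified when class counts allow; unstratified with a warning
otherwise), ties to smaller T then smaller γ.  The binary quadratic
programs are delegated to scikit-learn's SMO; the kernel, pairing, voting,
tie-breaks and tuning protocol are this package's.  Features are used as
produced, without re-standardisation.

## Evaluation

`make_cv2_folds` assigns each observed (environment, line, trait) cell to
one of k = 5 folds, stratified by environment (sizes within a stratum
differ by ≤ 1; strata smaller than k fall back to uniform assignment with a
warning).  Because cells — not lines — are held out, a test line typically
remains observed in other environments, emulating incomplete
multi-environment trials.  Per fold, models are fitted/tuned on training
cells only and PCCC = 100·#correct/n is computed per (trait, environment).
`summarize` reports fold means, SE = SD/√k, normal CIs
(mean ± z_{1−α/2}·SE, α = 0.05 by default, exposed), CI-overlap flags, and
relative differences 100·(A−B)/B.  Test cells in an environment absent
from training are skipped with a warning — unseen environments are never
predicted.

## Synthetic generator

`simulate_markers` draws J×m dosages, column j ~ Binomial(2, p_j) with
p_j ~ U(maf_range); constant columns are resampled (capped, then an error
naming the column).  `simulate_trial` draws g, gE and residuals with
exactly the model's covariance structure, cuts liabilities at the
configured thresholds, removes a uniform fraction of cells, and records the
full truth (effects, liabilities, exact per-cell probabilities, hence the
Bayes-oracle classifier).  Default design: I = 3 environments
(E = −0.5, 0, 0.5), J = 300 lines, m = 500 markers with MAF in (0.2, 0.45),
C = 3 categories with thresholds (0, 1) giving unequal class frequencies
(≈ 0.5/0.27/0.23 at E = 0), σ²_g = 0.6, σ²_gE = 0.2 against the unit
residual, and 20% of cells unobserved — a mid-sized managed-environment
wheat-nursery-like setting.

`discretize_trait` converts a continuous trait to categories per
environment at given quantile levels — (1/3, 2/3) for three categories,
(0.5) for two, (0.2, 0.45, 0.7, 0.9) for five — using linear-interpolation
("type 7") empirical quantiles; values equal to a boundary fall in the
lower category.  The boundary rule is exposed because tie handling at
quantile boundaries is a convention, not something the discretisation
levels determine.

**What the generator does not emulate:** linkage disequilibrium, family or
pedigree structure, genotyping error, and structured (trial-design)
missingness.  Markers are independent Binomial draws, so off-diagonal
entries of G₁ are O(1/√m) — lines are essentially unrelated.  Passing
tests therefore demonstrate correctness of the machinery and calibration
under the model's own assumptions, *not* the accuracy levels achievable on
real breeding panels, where family structure makes both g and gE far more
transferable across cells.

## Numerical choices

* Eigenvalues of G₁ below λ_max·1e-10 are treated as exact zeros (rank
  deduction in variance updates, zero-pinned effect components).
* Truncated-normal sampling is inverse-CDF in log space with reflection;
  draws are nudged strictly inside open intervals via `nextafter`.
* Degenerate threshold conditionals (empty categories, zero-width
  intervals) fall back to neighbour-derived bounds with warnings rather
  than failing mid-chain.
* All stochastic operations take an explicit `numpy` Generator or integer
  seed; one named generator per run makes every artefact bit-reproducible.
* The benchmark loop derives per-(trait, variant, fold, model) seeds from
  the plan seed by hashing, so adding or removing a model does not shift
  another model's stream.

## Known limitations

* **Posterior-mean bias of variance components at moderate size.**  With a
  few hundred ordinal cells the liability scale is only weakly pinned, the
  (σ²_g, σ²_gE) posterior is wide and right-skewed, and its mean typically
  sits above the generating value (replicated experiments at J = 300,
  I = 3, C = 3 show a mean upward bias of ≈ 0.2 on σ²_g = 0.6 with 90% CI
  coverage ≈ 85%).  This is a property of the exact posterior — verified
  against quadrature on continuous liabilities and an independent MCMC
  implementation — not of the sampler; posterior medians are closer to the
  truth.  Report intervals, not point means, at these sizes.
* **Held-out PCCC sits several points below the Bayes oracle** at the
  default design (gap ≈ 7 points at J = 300): the oracle knows each test
  cell's gE exactly, while under independent markers that effect is nearly
  unpredictable from other cells.  The gap narrows as J grows or as real
  relatedness structure enters G₁.
* For the same reason, the PCCC advantage of the interaction variant under
  strong simulated G×E is small (≈ +0.5 points at σ²_gE = 2σ²_g) and not
  won in every replicate, even though its direction is stable.
* The threshold update is the plain Albert–Chib conditional; for data sets
  with tens of thousands of cells a Metropolis–Hastings threshold update
  would mix faster.
* Single trait per fit; no missing-marker imputation (inputs must be
  complete); unseen environments are never predicted.
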