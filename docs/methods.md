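# Methods

## Model

`autospot` models the binary disease status y_i of each tissue spot with a
restricted autologistic regression. Conditional on its neighbors,

    logit P(y_i = 1 | y_{N(i)}) = β'x_i + β₀ + (η / |N(i)|) Σ_{j∈N(i)} y_j + U_cg,

with N(i) the set of spots within Euclidean distance δ of spot i (a tie at
exactly δ is a neighbor). The single coupling η ≥ 0 encodes isotropic spatial
dependence; dividing by |N(i)| makes boundary spots — which have fewer
neighbors — carry a proportionally weaker total coupling. Isolated spots
(|N(i)| = 0) have the spatial term defined as 0, keeping the likelihood
finite.

**Pseudo-likelihood.** The fitted objective is the product of these per-spot
conditional Bernoulli terms. This is the single most consequential modeling
choice in the package: the joint distribution of a binary Markov random
field has an intractable normalizing constant, and the product of
conditionals (Besag's pseudo-likelihood) avoids it entirely. On layouts with
constant neighbor count — the torus layout the simulator offers — the
conditionals are exactly those of a joint Ising law with edge weight η/4 and
fields β'x_i, so "pseudo" and true likelihood coincide up to the usual
pseudo-likelihood efficiency loss, and exact enumeration oracles are
possible. On bounded grids the conditionals are not self-consistent with any
joint law; they remain the standard spatial-statistics approximation.
Maximum pseudo-likelihood is consistent for autologistic models, but the
per-dataset sampling variability of η̂ is large on small lattices (SD ≈ 0.65
at 400 spots with strong expression fields); single-slice coupling estimates
should be read accordingly.

**Intercept.** The printed model family has no intercept; real tissues have
base disease rates far from 50%, and without an intercept the coupling term
absorbs the base rate. An intercept with a diffuse N(0, 10²) prior, exempt
from the spike-and-slab, is therefore included by default
(`include_intercept=False` disables it).

## Priors

Gene coefficients carry the normal-mixture-of-inverse-gamma (NMIG)
spike-and-slab hierarchy:

    β_k | ι_k, τ_k² ~ N(0, ι_k τ_k²)       (ι_k τ_k² is a variance)
    ι_k | w ~ (1−w) δ_{v₀} + w δ_1
    τ_k⁻² ~ Gamma(b₁, b₂)                  (shape/rate, so τ_k² is inverse-gamma)
    w ~ Uniform(0, 1),   η ~ Uniform(0, c₁)

Defaults: c₁ = 10, v₀ = 0.005, b₁ = b₂ = 5 — weakly informative (slab scale
near 1 on the log-expression scale), all configurable. With multiple slices,
U_c ~ MVN(0, Σ_c) where Σ_c has diagonal σ_c², off-diagonals σ_c²ρ
(exchangeable) or σ_c²ρ^|s−t| (AR(1)); σ_c⁻² ~ Gamma(b₃, b₄) with
b₃ = b₄ = 2 and ρ ~ Uniform(b₅, b₆) with (0, 0.99) as the default bounds,
intersected with the positive-definiteness region for the chosen structure.
The nonignorable observation model's coefficients γ get diffuse N(0, 10²)
priors.

## Inference

Both backends operate on one unconstrained parameterization with analytic
gradients (`_posterior.py`): η and w via scaled logits, τ² and σ² via logs
(each with its Jacobian), ρ via a logit onto its valid interval. The
discrete spike indicators are marginalized out of the coefficient prior —
log[(1−w)N(β;0,v₀τ²) + wN(β;0,τ²)] — because gradient-based samplers cannot
carry discrete states; the posterior inclusion probability of gene k is
recovered afterwards as the per-draw conditional slab probability
w·N(β;0,τ²) / [w·N(β;0,τ²) + (1−w)·N(β;0,v₀τ²)], averaged over draws. The
gradients are verified against central finite differences in the test suite
with every model feature active.

**NUTS.** A slice-variant No-U-Turn sampler with dual-averaging step-size
adaptation (target acceptance 0.8), a diagonal metric estimated once from
the middle of warmup, trajectory doubling capped at depth 10, and a
divergence flagged when the Hamiltonian error exceeds 1000. Divergence
fractions above 5% produce a warning in the diagnostics, never a failure.

**ADVI.** Mean-field Gaussian on the unconstrained space, optimized by Adam
with reparameterized ELBO gradients (entropy handled analytically). The
variational mean is initialized at the MAP point (a cheap L-BFGS run on the
same objective), which removes most of the burn-in; posterior draws are then
sampled from the fitted q. Mean-field ADVI is known to underestimate
posterior spread on correlated posteriors; the NUTS backend is the reference
when credible-interval width matters.

**MAP.** `fit_map` exposes the L-BFGS mode directly. With η fixed at 0 and a
near-flat slab it reproduces a plain logistic regression fit to well under
0.02 per coefficient (checked against an independent IRLS/GLM fit).

**Missing labels.** Missing spots contribute no Bernoulli term for their own
label; their labels enter as latent conditioning values for their neighbors.
They are resampled by data augmentation: each missing spot k draws
y_k ~ Bernoulli(μ*_k) with μ*_k the current disease fraction among its
neighbors (observed and imputed alike), isolated spots falling back on the
slice-wide observed rate. Under the nonignorable mode the spot's own
observation term P(R_k = 0 | y_k) reweights the two outcomes, and the
γ-likelihood over all spots joins the posterior. Augmentation interleaves
with sampling on a fixed schedule — every 25 NUTS draws, every 50 ADVI
iterations — treating the labels as fixed in between; the schedule is a
declared choice, and the MCAR check (ignorable vs γ₁-pinned nonignorable vs
complete-data fits agreeing on β) is part of the acceptance suite.

Summaries are equal-tailed credible intervals (not HPD), sample SDs with
denominator n−1, and standardized effects |mean|/SD (flagged NaN, not
infinite, for degenerate constant draws). Convergence diagnostics (split-
chain R̂ with threshold 1.01, ESS) come from arviz and are reported for the
NUTS backend; they do not apply to iid variational draws.

## Synthetic data

The generator (`simulator.py`) emulates the structure this model family is
built for: grid-like spot layouts at a few hundred spots per slice, multiple
slices per donor with correlated random effects, spatially autocorrelated
binary labels, and missingness that is either MCAR or spatially clumped and
outcome-dependent.

* **Layouts.** `torus` (wrap-around distance, every spot has 4 neighbors)
  is used wherever an exactness oracle is wanted, because there the Gibbs
  chain targets a known Ising joint; `grid` is the realistic bounded layout.
* **Labels** are drawn by random-scan Gibbs sweeps of the conditional model,
  returning the final sweep's state. The default is 1000 sweeps: at the
  package's standard study conditions (20×20 torus, expression fields with
  SD ≈ 2.2, η = 1) shorter chains measurably under-disperse the spatial
  coupling (replicate-mean MPLE η̂ ≈ 0.84 after 200 sweeps vs 0.98 after
  1000, truth 1.0), so the longer default buys stationarity at negligible
  cost (the sweep kernel is numba-jitted with a pure-python fallback of
  identical semantics; all randomness is pre-drawn from the seeded
  generator, so results are bit-for-bit reproducible either way).
* **Expression** is iid standard normal by default; `"spatial"` produces
  smooth Gaussian fields (noise repeatedly averaged with neighborhood means,
  re-standardized), and `"lognormal_counts"` mimics a count pipeline with
  log1p. Spatially smooth expression is the condition under which ignoring
  the label coupling visibly biases coefficients — with spatially white
  expression the omitted-term attenuation and the neighbor-feedback
  inflation nearly cancel, which is itself informative about when the naive
  model fails.
* **Missingness.** MCAR masks spots independently; the nonignorable
  mechanism Gibbs-samples the observation field from its own autologistic
  law, producing clustered, outcome-dependent holes.

What the generator does **not** emulate: count overdispersion, cell-type
mixtures, platform noise, image registration error, or batch effects beyond
the slice-level random intercept. Passing tests on synthetic data therefore
demonstrates correctness of the estimator under the model's own assumptions
and its stated robustness properties — not performance on any real assay.

## Study conditions used by the tests and the acceptance script

Problem sizes are deliberately desk-scale, chosen so the full pipeline runs
in minutes: a 10-spot ring for quadrature oracles; 400-spot lattices (d = 50
genes, 5 truly nonzero at |β| = 1, η = 1, 10 replicates) for recovery; 20
replicates at η = 2 for the naive-model comparison; 1600 spots for the
interaction scan (power at β_int = 1.5, size under the null); 500 donors for
realized random-effect correlations. "Bias" is used in its statistical
sense: the replicate-mean of (estimate − truth) per parameter. Per-replicate
absolute error of η̂ is dominated by sampling variability at these lattice
sizes (SD ≈ 0.65) and is not the quantity the recovery checks bound.

## Numerical choices

* Probabilities inside log-likelihoods are clipped to [1e−12, 1 − 1e−12]
  (`MU_FLOOR`), so a label opposing a saturated prediction contributes
  log(1e−12) rather than −∞.
* Out-of-support parameter states return a −∞ log-prior sentinel rather
  than raising, so samplers reject gracefully.
* Gene-ranking ties are broken by gene name; `rank_genes` is invariant to
  common positive rescaling of the draws.
* Interaction columns are products of log-scale expression centered on
  observed spots before multiplication, limiting collinearity with main
  effects; interaction coefficients share the spike-and-slab prior family.
* Prediction uses plug-in posterior means by default (fast); a flag switches
  to averaging over thinned posterior draws. Gibbs prediction/imputation use
  100 burn-in sweeps and 400 retained by default, all configurable.
* Initialization: β at 0, η at c₁/2, w at 0.5, τ² at 1, missing labels at
  the observed-neighborhood majority (slice rate as fallback).
* Duplicate spot coordinates are an error, never merged silently; gene
  filtering keeps totals ≥ the threshold (a total of exactly 300 survives
  the default filter); log transform is the natural log of (count + 1); no
  library-size normalization is applied by default.
* Gene sets are intersected within each donor and then across donors, since
  a joint fit shares β and needs one common gene list.

## Known limitations

* The pseudo-likelihood ignores the MRF normalizing constant; credible
  intervals inherit the usual pseudo-likelihood optimism on bounded grids.
* Mean-field ADVI underestimates posterior correlations and hence some SDs;
  standardized effects from ADVI are slightly anti-conservative (the null
  retention rate of the interaction scan is monitored in the acceptance
  suite precisely for this reason).
* η is assumed spatially constant and isotropic; anisotropic or spatially
  varying couplings are out of scope.
* The data-augmentation law for missing labels uses only neighborhood label
  fractions (expression at missing spots is unobserved by construction), so
  imputation quality degrades where missing regions are large and deep.
* k-nearest-neighbor graphs are not offered; for single-cell-resolution
  platforms choose δ so that a neighborhood holds a few dozen cells.
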