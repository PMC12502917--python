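# autospot

Bayesian spatial autologistic spike-and-slab modeling of disease status in
spatial transcriptomics.

## The problem

Spatial transcriptomics assays (10X Visium and relatives) measure gene
expression at spots laid out across a tissue section, and pathologists can
label each spot as diseased or healthy. Which genes' expression actually
tracks the disease? Ordinary logistic regression of the spot labels on
expression ignores a dominant feature of tissue: disease status is spatially
contiguous, so neighboring spots carry correlated labels. Ignoring that
correlation biases coefficient estimates and miscalibrates uncertainty —
especially because expression itself is spatially smooth.

`autospot` is for statisticians and computational biologists who want
spot-level disease-association analysis that treats the spatial coupling as
part of the model, handles multiple slices per donor, tolerates missing
tissue regions, and yields calibrated gene rankings, gene–gene interaction
scans, predictions for unlabeled tissue and imputation of missing labels.

## The model

For spot *i* with expression vector x_i and binary disease label y_i, the
conditional (autologistic) model is

    logit P(y_i = 1 | y_{N(i)}) = β'x_i + (η / |N(i)|) Σ_{j ∈ N(i)} y_j + U_cg

where N(i) = {j : ||s_i − s_j|| ≤ δ} is the neighbor set under radius δ
(δ = 1 on a unit grid gives rook adjacency), η ≥ 0 is a single isotropic
spatial coupling divided by the neighbor count to absorb boundary effects,
and U_cg is an optional random intercept for slice g of donor c with
exchangeable or AR(1) correlation across a donor's slices. The likelihood is
the product of these conditionals (a pseudo-likelihood); the joint MRF
normalizing constant is never computed.

Gene coefficients get a normal-mixture-of-inverse-gamma (NMIG)
spike-and-slab prior:

    β_k | ι_k, τ_k² ~ N(0, ι_k τ_k²),   ι_k ∈ {v₀, 1},
    P(ι_k = 1) = w,  τ_k⁻² ~ Gamma(b₁, b₂),  w ~ Uniform(0, 1)

so negligible coefficients are shrunk into the narrow spike (scale v₀τ²)
while real effects live in the slab. Missing spots can be modeled as
ignorable (MCAR) or nonignorable through an observation model
logit P(R_i = 1) = γ₀ + γ₁y_i + γ₂·(observed-neighbor fraction), with
missing labels resampled by data augmentation from the disease fraction of
their neighborhoods.

Two inference backends share one analytically differentiated posterior (the
spike indicators are marginalized): a No-U-Turn sampler for accuracy, and
mean-field ADVI for speed. Genes are ranked by the standardized effect
|posterior mean| / posterior SD.

## Worked example

```python
import numpy as np
from autospot import (SimulationConfig, simulate_study, ModelConfig,
                      fit_advi, rank_genes)
from autospot.simulator import layout_graph

sim = SimulationConfig(layout="torus", L=20, d=50, n_true=5, eta_true=1.0, seed=0)
study = simulate_study(sim)                      # 400 spots, 50 genes, 5 real
graph = layout_graph(sim)

summary = fit_advi(study, [graph], ModelConfig(), n_iter=6000, seed=100)
top = rank_genes(summary, k=5)
print(top.table[["gene", "mean", "sd", "std_effect"]].round(3))
print("eta_hat =", round(summary.eta_mean, 3))
```

Output:

```
  gene   mean     sd  std_effect
0   g2  1.089  0.133       8.190
1   g3 -0.910  0.145       6.271
2   g1 -0.791  0.128       6.162
3   g4  0.836  0.153       5.475
4   g0  0.786  0.152       5.182
eta_hat = 0.174
```

All five truly associated genes (g0–g4, true |β| = 1) head the ranking with
standardized effects of 5–8, while the 45 noise genes are shrunk toward zero
by the spike. The spatial coupling estimate on a single 400-spot slice is
noisy (its sampling SD is about 0.65 at these conditions); across seeds it
is unbiased for the generating value of 1.

The same pipeline is available from the shell:

```
autospot simulate --config sim.yaml --out data/ --seed 0
autospot fit data/ --backend advi --out fit/ --seed 1
autospot rank fit/ --out rank/ --k 30
autospot predict data/ fit/ --out pred/
autospot impute data/ --out imp/
```

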