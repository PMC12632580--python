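# Methods

## The problem

Targeted in-situ spatial transcriptomics assays (MERFISH/Xenium/seqFISH
class) measure a panel of a few hundred genes G′ at single-cell resolution
with 2-D coordinates, while a dissociated scRNA-seq reference from the
same tissue measures the full gene set G ⊃ G′ without spatial context.
`spimpute` fits one generative model to both datasets and uses it to
predict, for every spatial cell, the expression of genes the spatial assay
never measured — together with a per-gene and per-cell score saying how
much each prediction should be trusted.

## Generative model

Each cell n carries a latent state z_n ~ N(0, I_d) shared between
modalities, plus a binary modality flag s_n (0 = scRNA-seq, 1 = spatial).
A neural decoder f_η maps (z_n, s_n) to a probability simplex
ρ_n over the full gene set — the cell's normalized expression
frequencies.

* scRNA-seq counts: x_ng ~ ZINB(ℓ_n ρ_ng, θ_g, π_ng), where the
  log-library ℓ_n is latent with a lognormal prior matched to the
  empirical mean/variance of the observed log totals, θ_g are per-gene
  inverse dispersions, and the dropout logits π come from a second decoder
  head f_ν(z, s). A plain-NB likelihood is available
  (`ModelConfig.likelihood_sc = "nb"`).
* Spatial counts: x′_ng′ ~ NB(ℓ′_n ρ′_ng′, θ′_g′), with ρ′ the simplex
  renormalized to the measured panel and ℓ′_n the *observed* cell total —
  spatial assays have small technical library variation, so ℓ′ is data,
  not a random variable. Renormalization over the panel is the default;
  `renormalize_rho(..., over_panel=False)` restores the plain subset,
  which differs only by the panel's total frequency mass.

## Inference

Amortized variational inference with diagonal-Gaussian posteriors.
scRNA-seq cells use a shared MLP encoder on log1p counts (plus a one-hot
modality covariate) with four heads: z mean/log-variance and ℓ
mean/log-variance. Spatial cells run the same encoder body on their panel
counts zero-padded into the G-dimensional input space, and additionally a
graph-attention (GAT) branch over the k-nearest-neighbor graph of their
coordinates: features F_S(x′) are projected by W, attention coefficients
α_ij are the softmax of LeakyReLU(aᵀ[ĥ_i ‖ ĥ_j]) over the neighborhood
including the cell itself, and the aggregated output z′ is fused
residually, z_s = z + z′. Mini-batches of spatial cells rebuild their k-NN
subgraph *within the sampled batch* (node sampling), which keeps training
O(batch²) and matches the neighborhoods the encoder will see at full-data
inference time.

The objective is the sum of the two modalities' ELBOs (reconstruction
minus the closed-form diagonal-Gaussian KL terms; one reparameterized
sample per step), with a linear KL warm-up, plus an adversarial term: a
small MLP classifier predicts the modality from z and its cross-entropy is
back-propagated to the encoders through a gradient-reversal op with weight
λ, pulling the two latent clouds together.

### The adversarial balance

With a single optimizer and a uniform learning rate, the reversed
encoders outrun the classifier: the classifier CE climbs *above* ln 2
(the encoders make it anti-predict by relabeling clusters rather than
mixing them) and the latent clouds stay linearly separable. The classifier
parameter group therefore trains at `adv_lr_scale` (default 20×) times the
base learning rate, which keeps its CE pinned near the ln 2 equilibrium,
where maximizing the CE is a proxy for minimizing the modality divergence.
This is an optimizer detail — the objective is unchanged — and it is what
makes a post-hoc modality classifier measurably worse at λ = 1 than at
λ = 0.

### Optimization defaults

d = 10 latent dimensions; encoder/decoder hidden layers (128, 128); one
attention head on 32-dimensional GAT features; k = 10 neighbors; Adam at
lr 1e-3, batch size 256, 200 epochs, KL warm-up 20 epochs, λ = 1,
global gradient-norm clipping at 10. Log-variance heads are bounded to
(−4, 4) by a scaled tanh and the scRNA-seq library head is centered on the
empirical prior mean, both for early-training stability. Training is
deterministic given `ModelConfig.seed`; if the loss turns non-finite the
last epoch's checkpoint is restored and training stops.

Gradients come from a small reverse-mode autodiff engine inside the
package (`spimpute._autodiff`) operating on numpy arrays, with exactly the
primitives the model needs (including `gammaln` for the NB terms and a
gradient-reversal op); its gradients are tested against central finite
differences.

## Anchor genes

Before fitting, shared genes can be filtered by pseudo-bulk agreement:
per-cell-type mean profiles (cells normalized to total 1 first — a
documented deviation that stops library depth from dominating; switch off
with `normalize=False`) are correlated across modalities per gene, and
genes with Pearson r > 0.5 and two-sided p < 0.05 over the M ≥ 3 shared
cell types are kept. Without labels the filter is skipped and all shared
genes train the spatial head. Constant profiles get r = 0, p = 1, not
kept. A Spearman mode exists but is discouraged — with a handful of cell
types rank correlations are rarely significant and the training set
collapses.

## Imputation and condition transfer

For each spatial cell, z is drawn `n_samples` times (default 25) from the
fused posterior built on the full-data graph, decoded with s = 1, and the
decoded frequencies are averaged; the reported value is the NB mean rate
ℓ′_n · ρ_g — a continuous prediction, not a sampled count. `n_samples = 0`
decodes the posterior mean (deterministic). `transfer_decode` instead
decodes the spatial latents with the *scRNA-seq* head (s = 0) and scales
by the reference encoder's per-cell library posterior: when the reference
carries a perturbation or disease condition, this projects that condition
onto the spatial cells. The per-cell (rather than dataset-constant)
library scale is deliberate: it preserves each cell's depth, keeping
transferred values rank-consistent with standard imputation.

## Uncertainty

Gene score δ_g = 1 − median over L posterior-predictive NB resamples of
the cosine between the resampled across-cell vector and the predicted
mean vector; cell score δ_c is the transpose construction. L defaults to
min(⌊N′/10⌋, 100). Counts are nonnegative so δ ∈ [0, 1]; an all-zero
resample contributes cosine 0 (maximal uncertainty) and an all-zero mean
gives δ = 1 with a warning. Genes in the spatial training panel use the
fitted θ′; imputed genes fall back to the scRNA-seq θ. The conventional
filter keeps items strictly below the median δ (ties excluded). Cosine is
the only distance offered; Euclidean versions of this score discriminate
poorly. Sampling is around the posterior-mean rates rather than around a
single posterior z draw — the rates are what imputation reports, so the
score measures the count noise a user would actually face.

## Evaluation panel

Per-gene across-cell metrics: Spearman correlation (Pearson of mid-ranks);
a single-window SSIM on vectors scaled by their own maximum with the
literal stabilizers C1 = 0.01 and C2 = 0.03 (exposed as parameters; note
these are the printed constants, not the squared image-processing
convention); RMSE of population-SD z-scores; and the Jensen–Shannon
divergence (natural log, so disjoint supports give exactly ln 2) of the
cell-normalized distributions. Clustering quality: scanpy preprocessing
(total-count normalize, log1p, top-2000 HVGs, PCA, 15-NN graph), Louvain
communities via igraph's multilevel algorithm, then NMI/ARI against known
labels and the label silhouette on the PCA embedding mapped to [0, 1] as
(ASW + 1)/2.

Spatially variable (SV) genes: Moran's I with row-standardized binary
k-NN weights, z = (I − E[I])/√V(I) with E[I] = −1/(n−1) and the
normality-assumption closed form for V(I), one-sided normal p (a
permutation fallback is provided); and a SpatialDE-style Gaussian-process
likelihood ratio with a squared-exponential kernel over a lengthscale
grid, noise-to-signal δ grid, closed-form profiled mean and variance, and
a χ²(1) upper-tail p. The χ² convention is anti-conservative for positive
llr but the boundary (llr = 0, roughly half to two-thirds of null draws)
puts an atom at p = 1, so the null is conservative overall; the 5% tail
is at nominal level. Dense solves are limited to 2,000 cells.

## Synthetic data

`simulate_paired` generates both modalities from the model's own
assumptions so every stage is testable without downloads: a Gaussian
mixture over cell types in latent space (component SD 1.5, within-type SD
0.8); a fixed random linear map + softmax to gene frequencies; lognormal
libraries; ZINB scRNA-seq counts with one global dropout logit (the
simplest testable choice); NB spatial counts over a random strict-subset
panel; and spatial autocorrelation injected by convex-combining each
spatial cell's latent with its coordinate-k-NN mean (weight
`spatial_smoothness`) — an O(n·k) stand-in for a Gaussian process that
matches the model's own neighborhood assumption. Ground truth (latents,
frequencies, held-out NB rates, dispersions, generative libraries) is
retained.

Defaults are the package's reference study conditions: 2,000 reference
cells, 1,500 spatial cells, 400 genes, a 250-gene panel, 10 latent
dimensions, 5 cell types, smoothness 0.3, dropout logit −2 (~12% excess
zeros), dispersions Uniform(2, 20), libraries lognormal(7.6, 0.4²) —
about 2,000 transcripts per cell, a realistic imaging-assay depth. These
sizes keep a full CPU fit around a minute while leaving enough cells per
gene for stable rank correlations.

What the generator does *not* emulate: real panel design (markers chosen
per tissue), segmentation errors and transcript misassignment, spatial
domains with sharp boundaries, batch effects within a modality, or
mismatched populations between reference and tissue. Passing the recovery
bar on this generator shows the inference machinery can invert the
model's own generative process at realistic depth and size — it does not
certify performance on any particular real assay.

## Held-out evaluation protocol

The shared genes that survive the anchor filter are split 70/30 by a
seeded permutation (train size = round(0.7·n)); the model trains with the
spatial head restricted to the 70%, then imputes the 30% and compares to
the generative NB rates by per-gene Spearman correlation. At the
reference conditions this recovers the held-out genes at mean SCC ≈ 0.95
(the package's acceptance bar is 0.5, with 0.3 for every one of three
simulation seeds), and genes below the median δ_g are imputed measurably
better than genes above it — the calibration property the uncertainty
score exists for.

## Known limitations

Single CPU, dense numpy: practical up to a few thousand cells per
modality and a few hundred genes; no minibatched inference at prediction
time. One global ZINB dropout logit in the generator (gene-specific
structure untested). The LSH neighbor mode is a seed-pinned
random-projection bucketing meant for robustness comparisons, not speed.
The GP SV test's χ²(1) p-values are anti-conservative for llr > 0; use
the Moran permutation fallback where calibration matters.
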