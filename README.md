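# spimpute

Joint probabilistic imputation of unmeasured gene expression in targeted
spatial transcriptomics (MERFISH / Xenium / seqFISH-class assays) from a
scRNA-seq reference of the same tissue, with sampling-based per-gene and
per-cell uncertainty scores.

Targeted in-situ assays measure a panel of a few hundred genes G′ per cell
with 2-D coordinates; a dissociated scRNA-seq reference measures the full
gene set G ⊃ G′ without coordinates. `spimpute` is for analysts who have
both and want the spatial dataset extended to the full transcriptome — to
find more marker genes, spatially variable genes, or to project a
perturbed/diseased reference condition onto the tissue — while knowing
which imputed genes and cells to trust.

## Model

Both modalities share a latent cell state z ~ N(0, I_d). A decoder maps
(z, s) — s the modality flag — to a probability simplex ρ over G (the
cell's normalized gene frequencies), and counts are overdispersed:

* scRNA-seq:  x_ng ~ ZINB(ℓ_n ρ_ng, θ_g, π_ng), latent log-library
  ℓ_n ~ logNormal(μ, σ²) matched to the data;
* spatial:    x′_ng′ ~ NB(ℓ′_n ρ′_ng′, θ′_g′), with ρ′ renormalized to the
  panel and ℓ′_n the observed cell total.

Inference is amortized and variational: a shared MLP encoder (panel counts
zero-padded for spatial cells) plus, for spatial cells, a graph-attention
branch over the coordinate k-NN graph fused residually (z_s = z + z′);
training maximizes the two-modality ELBO with an adversarial modality
classifier coupled through gradient reversal to align the latent clouds.
Imputed values are posterior-mean NB rates ℓ′·ρ_g. Uncertainty is
δ = 1 − median cosine between posterior-predictive NB resamples and the
predicted mean vector, per gene (δ_g) and per cell (δ_c); genes below the
median δ_g are the trustworthy half.

The package also ships the evaluation panel used to judge imputation
(per-gene Spearman/SSIM/RMSE-of-z-scores/Jensen–Shannon; Louvain
clustering agreement; Moran's I and Gaussian-process spatially-variable
gene tests) and a synthetic paired-data generator with retained ground
truth, so the whole pipeline is testable at desk scale. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from spimpute import (SimulationConfig, simulate_paired, select_anchor_genes,
                      SpatialImputationModel, ModelConfig, split_genes, scc)
from spimpute.anchors import AnchorReport

# paired synthetic data: 100-gene reference, 60-gene spatial panel
paired, truth = simulate_paired(SimulationConfig(
    n_sc=400, n_sp=300, n_genes=100, panel_size=60, seed=0))
anchors = select_anchor_genes(paired)
print(f"anchor filter kept {len(anchors.kept_genes)} of "
      f"{len(anchors.table)} shared genes")

# hold out 30% of the anchor genes, train on the rest
train, test = split_genes(list(anchors.kept_genes), train_frac=0.7, seed=0)
table = anchors.table.loc[train].copy()
table["kept"] = True
model = SpatialImputationModel(
    paired, anchors=AnchorReport(table=table, r_min=0.5, p_max=0.05),
    config=ModelConfig(epochs=60, seed=0))
results = model.fit()
print(results.summary())

# impute the held-out genes and score them against the generative rates
imputed = results.impute(targets=test, n_samples=25, seed=0)
gene_idx = {g: i for i, g in enumerate(paired.sc.gene_names)}
rates = np.stack([truth.spatial_library
                  * truth.rho[truth.n_sc:, gene_idx[g]] for g in test], axis=1)
sccs = [scc(rates[:, j], imputed.imputed[:, j]) for j in range(len(test))]
print(f"held-out genes: {len(test)}; mean SCC vs true rates: {np.mean(sccs):.3f}")

report = results.uncertainty(targets=test, seed=0)
med = np.median(report.delta_gene)
low = np.mean([s for s, d in zip(sccs, report.delta_gene) if d < med])
high = np.mean([s for s, d in zip(sccs, report.delta_gene) if d > med])
print(f"mean SCC, low-uncertainty half: {low:.3f}; high half: {high:.3f}")
```

Output:

```
anchor filter kept 58 of 60 shared genes
Joint spatial imputation model
==============================================
reference genes (G):        100
spatial training genes:     41
latent dimension:           10
scRNA-seq likelihood:       ZINB
epochs trained:             60
final ELBO (scRNA-seq):     -272.07
final ELBO (spatial):       -144.32
final adversarial CE:       0.588
held-out genes: 17; mean SCC vs true rates: 0.835
mean SCC, low-uncertainty half: 0.839; high half: 0.824
```

The anchor filter drops the two panel genes whose pseudo-bulk profiles
disagree between modalities; 41 of the kept genes train the spatial head
and 17 are hidden. After 60 epochs the hidden genes are recovered at mean
rank correlation 0.84 against the ground-truth NB rates, the adversarial
cross-entropy sits near ln 2 ≈ 0.69 (modalities mixed in latent space),
and the low-uncertainty half of the genes is imputed better than the
high-uncertainty half — the property the δ_g score exists for.

The same pipeline runs from the shell:

```sh
spimpute simulate --seed 0 --out data/
spimpute anchors  --sc data/sc --sp data/sp --out anchors.csv
spimpute fit      --sc data/sc --sp data/sp --anchors anchors.csv \
                  --seed 0 --out model/
spimpute impute   --model model/ --sp data/sp --targets missing \
                  --out imputed.csv
spimpute uncertainty --model model/ --sp data/sp --out uncertainty.csv
spimpute evaluate --truth truth.csv --pred imputed.csv \
                  --coords data/sp/coordinates.csv --out report.json
```

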