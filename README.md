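# stimpute

Conditional denoising-diffusion imputation of unmeasured genes in spatial
transcriptomics (ST) data, guided by an scRNA-seq reference.

Targeted spatial assays (osmFISH, MERFISH, seqFISH, STARmap, ...) resolve
where cells are but measure tens to hundreds of genes; dissociated
scRNA-seq measures the whole transcriptome but loses position. `stimpute`
learns gene–gene dependency structure from the reference and uses the
genes the two modalities share as the conditional of a denoising
diffusion model, generating values for the genes the spatial assay never
measured — without dragging the output into the reference's batch space.

## Model

Training diffuses the (perturbed) reference `x̂0` to a random timestep,

    x̂_t = √γ_t · x̂0 + √(1−γ_t) · ε,    γ_t = Π_{i≤t} α_i  (cosine schedule),

splices the clean shared-gene entries back in via the binary gene mask
`m` (`x̂_t' = x̂0⊙m + x̂_t⊙(1−m)`), and trains a denoiser to recover `ε`
on the unique-gene entries with the loss

    MSE(ε(1−m), ε'(1−m)) + α · KL( q(ε'(1−m)) ‖ N(0,1) ).

The conditional `x̂0⊙m` is enriched by a bidirectional peephole-LSTM read
over a transcriptional-similarity ordering of the cells; the denoiser is
a transformer whose attention is computed along the *gene* axis
(cross-covariance attention, `V·softmax_cols(KᵀQ/√d_k)`, a genes × genes
attention map) with local patch interaction and feed-forward sublayers.
Inference starts from noise, re-imposes the measured ST values on shared
entries at every reverse step, and returns the full gene panel for every
ST cell. See `docs/methods.md` for the complete description, including
the evaluation suite (SPCC/SSIM/RMSE/JS, Leiden-clustering ARI/AMI/NMI/
homogeneity, and the AS rank aggregate) and the paired-data simulator.

Everything runs on CPU: the networks are implemented on NumPy with a
small reverse-mode autodiff engine contained in the package.

## Worked example

```python
import numpy as np
from stimpute import (SimConfig, simulate_pair, lognorm, build_gene_mask,
                      TrainConfig, train, impute, evaluate_genes)

# paired data with planted gene modules: 30-gene reference, 70% shared
pair = simulate_pair(SimConfig(n_ref_cells=120, n_st_cells=60, n_genes=30,
                               n_modules=3, shared_fraction=0.7,
                               noise_sd=0.05, seed=0))
ref   = lognorm(pair.reference,   target_sum=30)
obs   = lognorm(pair.st_observed, target_sum=pair.st_observed.n_genes)
truth = lognorm(pair.st_truth,    target_sum=30)

mask = build_gene_mask(ref, obs)          # 21 shared, 9 unique genes
cp = train(ref, mask, TrainConfig(max_iters=800, batch_size=48,
                                  learning_rate=1e-3, T=100, n_blocks=2,
                                  n_heads=4, width=32, encoder_hidden=32,
                                  encoder_layers=1, seed=0))
imp = impute(obs, cp, seed=0, n_draws=4)  # all 30 genes for the 60 ST cells

held = [g for g in ref.gene_names if g not in set(mask.shared_genes)]
ii, ti = imp.gene_index(), truth.gene_index()
table = evaluate_genes(
    np.column_stack([imp.values[:, ii[g]] for g in held]),
    np.column_stack([truth.values[:, ti[g]] for g in held]), held)
print(table.head(3).round(3).to_string(index=False))
print(table.mean(numeric_only=True).round(3).to_dict())
```

Output:

```
 gene  spcc  ssim  rmse    js
g0003 0.925 0.934 0.362 0.001
g0004 0.702 0.733 0.666 0.001
g0008 0.821 0.842 0.564 0.001
{'spcc': 0.825, 'ssim': 0.828, 'rmse': 0.54, 'js': 0.001}
```

Each row scores one *held-out* gene — a gene the model never saw in the
ST conditional — against its measured values: rank correlation (SPCC) and
structural similarity (SSIM) near 1 and a small distribution divergence
(JS) mean the generated expression tracks the truth across cells; RMSE is
on per-gene z-scores. The training loss fell from 2.31 to 0.05 over the
800 iterations (`cp.loss_trajectory`).

A command-line interface mirrors the library:

```bash
stimpute simulate --config cfg.yaml --out sim/
stimpute train    --reference sim/reference.tsv --st sim/st_observed.tsv --out run/
stimpute impute   --st sim/st_observed.tsv --checkpoint run/checkpoint.npz --out imp/
stimpute crossval --reference sim/reference.tsv --st sim/st_observed.tsv --out cv/
stimpute evaluate --truth sim/st_truth.tsv --pred imp/imputed.tsv --out eval/
```

Every run writes a `manifest.json` with the config hash, seed and input
checksums, so completed runs are exactly reproducible.

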