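# Methods

`stimpute` imputes genes that a targeted spatial-transcriptomics (ST)
assay did not measure, using a dissociated scRNA-seq reference from the
same tissue as the carrier of gene–gene dependency structure. This note
documents the model, its numerical choices, the synthetic data the tests
run on, and the limits of what those tests show.

## Model

### Masked conditional diffusion

Let `x0` be the reference expression matrix (cells × genes, after
preprocessing) and `m` a binary mask whose columns are 1 for genes shared
with the ST assay and 0 for genes unique to the reference. Training uses a
variance-preserving forward chain

    x_t = sqrt(γ_t) x0 + sqrt(1 − γ_t) ε,   ε ~ N(0, I),
    γ_t = Π_{i≤t} α_i,

with the cumulative retention `γ_t` following the cosine law
`γ_t = f(t)/f(0)`, `f(u) = cos²(((u/T + s)/(1 + s))·π/2)`, offset
`s = 0.008`, and per-step `α_t = γ_t/γ_{t−1}` clipped into (1e−6, 0.9999)
with `γ` recomputed from the clipped `α` so the product identity holds
exactly. `T` defaults to 1000 (configurable; the desk-scale studies use
200).

Each training iteration draws a cell batch, perturbs it with elementwise
Gaussian noise (sd 0.1 on the log-normalized scale — the perturbation
de-emphasizes absolute levels in favor of gene–gene relationships), draws
`t ~ U(1, T)` and `ε`, diffuses, and splices the clean shared-gene entries
back in:

    x̂_t' = x̂0 ⊙ m + x̂_t ⊙ (1 − m).

A denoiser predicts `ε` from `x̂_t'`, the encoded conditional
`y' = enc(x̂0 ⊙ m)` and the timestep. The loss is evaluated only on
unique-gene entries:

    loss = MSE(ε(1−m), ε'(1−m)) + α · KL( q(ε'(1−m)) ‖ N(0, 1) ),

where the KL term moment-matches a Gaussian to the predicted masked noise
(`μ̂`, `σ̂`) and evaluates the closed form
`KL = ½(σ̂² + μ̂² − 1 − log σ̂²)`; an empirical-histogram estimator exists
behind `kl_estimator="histogram"` for reporting (it contributes no
gradient). `α = 2.8` for low-dimensional prediction tasks and `0.02`
above 500 genes, matching the batch-size/width switch at the same cutoff
(batch 2048/width 512 below, batch 512/width 1024 above).

### Condition encoder

The masked conditional is read as a sequence of cells by a bidirectional
peephole LSTM (hidden 128 × 2 layers by default; diagonal peephole
weights, a config flag disables them). Per cell the forward and backward
states are concatenated and projected back to gene width. Two choices
here were made where the design was genuinely open:

* **Residual enrichment.** The encoder output is
  `y' = cond + W_p · BiLSTM(cond)` with `W_p` zero-initialized: the
  recurrent branch starts as the identity and can only add information.
  Routing the conditional exclusively through a learned bottleneck
  measurably handicapped the full model against its own "w/o BiLSTM"
  ablation.
* **Cell ordering.** Cells are not a sequence; the recurrence is only
  meaningful when adjacent items are related. By default cells are
  ordered by their projection onto the first principal axis of the
  masked conditional (deterministic; a transcriptional-similarity
  stand-in for spatial adjacency), with `cell_order="given"` preserving
  file/batch order. A reversal-equivariance test documents the
  consequence of ordering: reversing the sequence swaps the direction
  halves of the states.

Under the "w/o BiLSTM" ablation the condition path is the raw masked
conditional, unchanged.

### Cross-covariance attention denoiser

The denoiser lifts `x̂_t'` to model width and applies `n_blocks` (default
6) pre-normalized residual blocks. Attention is computed along the
*feature* axis: per head,

    XCA(Q, K, V) = V · softmax_cols(KᵀQ / sqrt(d_k)),

so the attention map has shape (features × features) and each column sums
to one — it scores gene–gene (channel) interactions rather than cell–cell
similarity. Queries are projected from the running signal; keys and
values from the conditional embedding plus a sinusoidal-MLP timestep
embedding broadcast to every cell row. Heads are concatenated and mixed
by `W_O`. Each block then applies a local patch interaction (LPI) —
two depthwise window-3 convolutions along the feature axis with a SiLU
between, replicate padding so constants are preserved — and a two-layer
feed-forward network (hidden 2× width, SiLU). The "w/o XCA" ablation
replaces the feature-axis attention with standard cell-axis
self-attention; the two "diffusion + single component" control variants
additionally drop the KL term (α = 0).

All networks run on a small reverse-mode autodiff engine over NumPy
written for this package (`_autodiff.py`); the LSTM recurrence is a fused
graph node whose hand-derived backward pass is property-tested against
the composite per-step path and finite differences.

### Training and sampling

AdamW (decoupled weight decay 0.01), learning rate 1e−4 by default with
linear warmup over the first 5% of iterations and a cosine decay to a
10% floor; global gradient-norm clipping at 1.0; an exponential moving
average of the weights (adaptive decay up to 0.999) is what inference
uses — the last raw iterate of a diffusion model is noticeably noisier
than the averaged trajectory.

Inference zero-fills unique genes in the ST matrix to form the fixed
conditional `y`, encodes it once, starts from `x_T ~ N(0, I)` and
iterates the reverse update; at every step the state is re-composed with
`y` on shared entries. The reverse update is applied in the equivalent
x̂0-parameterized posterior-mean form with the implied `x̂0` clipped to
the training-data value range. This is algebraically identical to the
ε-form update whenever the clip does not bind, and is the standard guard
against the near-degenerate cosine tail (at small `T` the final `α_t`
approaches its clip floor, so un-clamped denoiser error would be amplified
by `1/sqrt(α_t)` and the chain diverges — observed before the guard was
added). The last step adds no noise. `n_steps < T` runs a strided
subsample of the schedule. `n_draws > 1` averages independent reverse
trajectories for point prediction; distribution-level comparisons score
draws individually, since averaging shrinks the generated marginal's
variance.

### Preprocessing

Both modalities are library-size normalized to a common per-cell total
and log1p-transformed (`lognorm`, the default; `raw` is available). The
desk-scale studies set the target total to the matrix's own gene count so
per-gene values have mean ≈ 1 before log1p and both modalities share a
value scale. Gene matching is exact and case-sensitive by default.

## Evaluation

Per-gene similarity: Spearman correlation (average ranks under ties);
vector SSIM on min–max-scaled values with C1 = 0.01, C2 = 0.03 (constants
are conventions on the unit range; a constant vector is kept at its level,
clipped to [0,1]); RMSE on per-gene z-scores (raw-scale fallback with a
warning when a vector has zero variance); Jensen–Shannon divergence
(natural log, bounded by ln 2) between the vectors normalized over cells.
`js_histogram` compares value distributions of different cohort sizes via
20 shared bins. Clustering agreement: Leiden on PCA(≤50)/kNN(15) graphs
(scanpy), scored with ARI, AMI (arithmetic-mean normalization), NMI
(geometric-mean normalization) and homogeneity; a single-cluster truth
returns homogeneity 1 with a warning. The AS aggregate ranks methods
within every (dataset, metric) cell — lower-is-better metrics reversed,
ties averaged — and reports each method's mean rank.

Cross-validation holds out gene folds: each fold's shared genes are
relabeled unique, the model is retrained without them in the conditional
(default; a `shared_backbone` mode trains once and re-masks at inference,
labeled in reports), their values are imputed and scored against
measurements. Gene-level metrics therefore never score a conditioning
gene.

## Synthetic data

`simulate_pair` draws a linear module/factor model: each gene loads
dominantly (weight U(0.55, 0.85)) on one of `n_modules` latent programs
with Dirichlet-distributed spill-over on the rest, so a held-out gene is
better predicted from all shared genes than from its module's mean alone;
cells belong to one of `n_celltypes` whose module-activity profiles are
scaled per cell by a log-normal fluctuation (cv 0.3); expression is the
loading-activity product plus N(0, noise_sd), rectified at zero. The ST
truth uses the reference's loadings; the observation keeps a
`shared_fraction` gene subset, applies a per-gene multiplicative
distortion `exp(batch_shift · δ_g)`, `δ_g ~ N(0,1)` (additive in log
space; `shift_target` chooses which modality carries it) and independent
dropout zeroing. Optional planted spatial patterns (vertical/horizontal
stripes, blob, diagonal band; amplitude 3) act on ST cells' unit-square
coordinates.

What the generator does *not* emulate: platform chemistry (probe
efficiency, segmentation error), spatial autocorrelation of cell types,
count noise (values are continuous), and structured batch effects.
Passing the recovery studies shows the pipeline learns and transfers
planted linear dependency structure at desk scale; it does not certify
performance on real cross-platform data.

## Desk-scale studies

Problem sizes were chosen so each study runs in minutes on one CPU:
200 reference cells, 100 ST cells, 50 genes, 4 modules, 70% shared,
noise sd 0.05; model 2 blocks × 4 heads × width 64, encoder hidden 64 × 1
layer, T = 200, 2000 iterations, batch 64, lr 1e−3 (scaled up from the
full-size default in proportion to the shorter schedule), 4 sampling
draws. Three seeded repeats.

* **Recovery**: mean held-out-gene Spearman of the imputation must beat
  the cell-mean predictor and the oracle-informed module-mean predictor.
* **Batch alignment**: with the reference distorted per-gene at scale
  0.5, the imputed matrix's per-gene histogram-JS to the measured truth
  must be smaller than the distorted reference's on shared genes — the
  output must live in the ST batch space, not the reference's. On
  held-out genes alone, a per-gene i.i.d. distortion is not identifiable
  from shared genes (the conditional inherits the gene's own shift), so
  parity is the ceiling there; both numbers are reported.
* **Ablation ordering**: the full configuration's recovery should not be
  worse than "w/o BiLSTM" or "w/o XCA". Under exchangeable synthetic
  cells the recurrence contributes little information, so this ordering
  is expected to be a small, not a dramatic, margin.

## Known limitations

* CPU-only: full-size settings (1200 epochs, width 1024, thousands of
  cells) are out of reach; the package is faithful in structure, not in
  throughput, to the reference configuration.
* The ε-parameterized loss weights all timesteps equally; very small `t`
  contributes high-variance gradients (intrinsic to the parameterization).
* The recurrence ordering is a heuristic; with real spatial coordinates a
  1-D spatial projection may be preferable to the transcriptional one.
* `GeneMask` constrains batch effects handling to what conditioning and
  the reference perturbation provide; no explicit batch-correction step
  is applied.
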