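"""Paired scRNA-seq / spatial-transcriptomics simulator.

The generator emulates the assumption the imputation model relies on: the
two modalities share a latent gene-gene dependency structure, so unmeasured
genes are predictable from measured ones.

Generative model (linear module/factor model, rectified at zero):

* Each gene has a *dominant* latent module plus Dirichlet-distributed
  spill-over loadings on the remaining modules, so a held-out gene carries
  information beyond its single-module mean.
* Each cell belongs to one of ``n_celltypes``; a cell's module activities
  are its type's mean profile times a per-cell log-normal fluctuation,
  which induces within-module gene-gene correlation across cells.
* ``expression = max(0, activities @ loadings.T + N(0, noise_sd))``.
* ``st_truth`` uses the same loadings as the reference (same tissue).
* ``st_observed`` keeps only a ``shared_fraction`` subset of genes, gets a
  per-gene multiplicative batch distortion ``exp(batch_shift * delta_g)``
  (additive in log space), and dropout zeroing.

Not emulated: platform chemistry (probe efficiency, segmentation error),
spatial autocorrelation beyond optional planted patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import ExpressionMatrix, Modality

_PATTERNS = ("stripe_h", "stripe_v", "blob", "band")


@dataclass
class SimConfig:
    n_ref_cells: int = 200
    n_st_cells: int = 100
    n_genes: int = 50
    n_modules: int = 4
    shared_fraction: float = 0.7
    batch_shift: float = 0.0
    shift_target: str = "st"  # which modality carries the batch distortion
    dropout_rate: float = 0.0
    noise_sd: float = 0.05
    n_celltypes: int = 3
    spatial_patterns: list[tuple[int, str]] = field(default_factory=list)
    pattern_amplitude: float = 3.0
    dominant_weight_range: tuple[float, float] = (0.55, 0.85)
    activity_cv: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_ref_cells, self.n_st_cells, self.n_genes) < 1:
            raise ValueError("cell/gene counts must be positive")
        if not 0.0 < self.shared_fraction < 1.0:
            raise ValueError("shared_fraction must lie in (0, 1)")
        if self.shared_fraction * self.n_genes < 2:
            raise ValueError("need at least 2 shared genes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_shift < 0:
            raise ValueError("batch_shift must be >= 0")
        if self.n_modules > self.n_genes or self.n_modules < 1:
            raise ValueError("n_modules must lie in 1..n_genes")
        if self.n_celltypes < 1:
            raise ValueError("n_celltypes must be >= 1")
        if self.shift_target not in ("st", "reference"):
            raise ValueError("shift_target must be 'st' or 'reference'")
        for gi, pat in self.spatial_patterns:
            if not 0 <= gi < self.n_genes:
                raise ValueError(f"pattern gene index {gi} out of range")
            if pat not in _PATTERNS:
                raise ValueError(f"unknown pattern {pat!r}; one of {_PATTERNS}")


@dataclass
class SimPair:
    reference: ExpressionMatrix
    st_truth: ExpressionMatrix
    st_observed: ExpressionMatrix
    labels: np.ndarray          # cell type per ST cell
    ref_labels: np.ndarray      # cell type per reference cell
    module_of_gene: np.ndarray  # dominant module per gene
    shared_genes: list[str]
    st_coords: np.ndarray       # (n_st_cells, 2) in the unit square

    def __iter__(self):
        # (reference, st_truth, st_observed, labels) unpacking
        return iter((self.reference, self.st_truth, self.st_observed, self.labels))


def _expression(
    loadings: np.ndarray,
    type_means: np.ndarray,
    types: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    act = type_means[types] * rng.lognormal(0.0, cfg.activity_cv, (len(types), cfg.n_modules))
    x = act @ loadings.T + rng.normal(0.0, cfg.noise_sd, (len(types), loadings.shape[0]))
    return np.maximum(x, 0.0)


def simulate_pair(cfg: SimConfig) -> SimPair:
    """Generate (reference, st_truth, st_observed, labels); deterministic given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # gene -> dominant module (round-robin), loadings with Dirichlet spill-over
    module_of_gene = np.arange(cfg.n_genes) % cfg.n_modules
    lo, hi = cfg.dominant_weight_range
    loadings = np.zeros((cfg.n_genes, cfg.n_modules))
    for g in range(cfg.n_genes):
        w = rng.uniform(lo, hi)
        loadings[g, module_of_gene[g]] = w
        if cfg.n_modules > 1:
            others = [m for m in range(cfg.n_modules) if m != module_of_gene[g]]
            loadings[g, others] = (1.0 - w) * rng.dirichlet(0.5 * np.ones(len(others)))
        else:
            loadings[g, 0] = 1.0

    type_means = rng.uniform(0.2, 1.8, (cfg.n_celltypes, cfg.n_modules))
    ref_types = rng.integers(0, cfg.n_celltypes, cfg.n_ref_cells)
    st_types = rng.integers(0, cfg.n_celltypes, cfg.n_st_cells)

    ref_vals = _expression(loadings, type_means, ref_types, cfg, rng)
    st_vals = _expression(loadings, type_means, st_types, cfg, rng)

    # spatial coordinates and optional planted patterns (ST only)
    coords = rng.uniform(0.0, 1.0, (cfg.n_st_cells, 2))
    for gi, pat in cfg.spatial_patterns:
        st_vals[:, gi] = _apply_pattern(st_vals[:, gi], coords, pat, cfg.pattern_amplitude)

    # batch distortion: per-gene log-space offsets, drawn once per seed and
    # scaled by batch_shift so distortion grows monotonically with the knob
    delta = rng.standard_normal(cfg.n_genes)

    n_shared = max(2, int(round(cfg.shared_fraction * cfg.n_genes)))
    shared_idx = np.sort(rng.choice(cfg.n_genes, size=n_shared, replace=False))

    gene_names = [f"g{i:04d}" for i in range(cfg.n_genes)]
    shared_genes = [gene_names[i] for i in shared_idx]

    if cfg.shift_target == "reference":
        ref_vals = ref_vals * np.exp(cfg.batch_shift * delta)[None, :]

    obs = st_vals[:, shared_idx].copy()
    if cfg.shift_target == "st":
        obs = obs * np.exp(cfg.batch_shift * delta[shared_idx])[None, :]
    if cfg.dropout_rate > 0:
        keep = rng.random(obs.shape) >= cfg.dropout_rate
        obs = obs * keep

    ref = ExpressionMatrix(
        values=ref_vals,
        gene_names=gene_names,
        cell_names=[f"ref_cell{i:05d}" for i in range(cfg.n_ref_cells)],
        modality=Modality.SCRNA,
    )
    st_cells = [f"st_cell{i:05d}" for i in range(cfg.n_st_cells)]
    truth = ExpressionMatrix(
        values=st_vals, gene_names=gene_names, cell_names=st_cells, modality=Modality.ST
    )
    observed = ExpressionMatrix(
        values=obs, gene_names=shared_genes, cell_names=st_cells, modality=Modality.ST
    )
    return SimPair(
        reference=ref,
        st_truth=truth,
        st_observed=observed,
        labels=st_types,
        ref_labels=ref_types,
        module_of_gene=module_of_gene,
        shared_genes=shared_genes,
        st_coords=coords,
    )


def _apply_pattern(
    col: np.ndarray, coords: np.ndarray, pattern: str, amp: float
) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    if pattern == "stripe_v":
        active = x < 0.5
    elif pattern == "stripe_h":
        active = y < 0.5
    elif pattern == "blob":
        active = (x - 0.5) ** 2 + (y - 0.5) ** 2 < 0.09
    else:  # band: diagonal stripe
        active = np.abs(x - y) < 0.2
    out = col.copy()
    out[active] = out[active] * amp
    return out


def planted_correlation_check(
    reference: ExpressionMatrix, module_of_gene: np.ndarray
) -> dict:
    """Mean |pairwise r| within modules vs between modules.

    Returns ``{"within": per-module means, "between": float or None}``;
    ``between`` is None in the degenerate single-module case.
    """
    r = np.corrcoef(reference.values, rowvar=False)
    modules = np.unique(module_of_gene)
    within = {}
    for m in modules:
        idx = np.flatnonzero(module_of_gene == m)
        if len(idx) < 2:
            within[int(m)] = np.nan
            continue
        sub = np.abs(r[np.ix_(idx, idx)])
        within[int(m)] = float(sub[np.triu_indices(len(idx), 1)].mean())
    if len(modules) == 1:
        return {"within": within, "between": None}
    mask_between = module_of_gene[:, None] != module_of_gene[None, :]
    iu = np.triu_indices(len(module_of_gene), 1)
    between_vals = np.abs(r[iu])[mask_between[iu]]
    return {"within": within, "between": float(between_vals.mean())}
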