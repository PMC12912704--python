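"""Expression-matrix containers, validation, file formats, masks and CV splits.

Conventions
-----------
Matrices are oriented cells-in-rows, genes-in-columns everywhere; every
reader normalizes to this orientation.  Gene matching between modalities is
exact and case-sensitive by default (``case_fold=True`` opts into folding).

Supported on-disk formats:

``tsv``
    Tab-separated matrix, header row = gene names, first column = cell names.
``mtx_triplet``
    MatrixMarket coordinate file ``<stem>.mtx`` with text sidecars
    ``<stem>_genes.txt`` and ``<stem>_cells.txt`` (one name per line).
``h5_container``
    HDF5 annotated-matrix container (h5ad): dense/sparse ``X`` with
    ``obs_names`` (cells) and ``var_names`` (genes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class Modality(str, Enum):
    SCRNA = "scrna"
    ST = "st"


class ValidationError(ValueError):
    """Raised when an expression matrix violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values, shape (n_cells, n_genes), with names."""

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    modality: Modality = Modality.SCRNA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        if not isinstance(self.modality, Modality):
            self.modality = Modality(self.modality)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_genes == 0 or n_cells == 0:
            raise ValidationError("empty expression matrix")
        if len(self.gene_names) != n_genes:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {n_genes} columns"
            )
        if len(self.cell_names) != n_cells:
            raise ValidationError(
                f"{len(self.cell_names)} cell names for {n_cells} rows"
            )
        dupes = _duplicates(self.gene_names)
        if dupes:
            raise ValidationError(f"duplicate gene names: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValidationError("negative expression values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}


def _duplicates(names: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for n in names:
        (dupes if n in seen else seen).add(n)
    return dupes


@dataclass
class GeneMask:
    """Binary cells × genes indicator over the reference gene axis.

    A column is all-ones when the gene is measured in both modalities
    (shared; it conditions the model) and all-zeros when it is unique to
    the reference (it is imputed).
    """

    m: np.ndarray
    shared_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.float64)
        if not np.isin(self.m, (0.0, 1.0)).all():
            raise ValidationError("mask entries must be 0 or 1")
        if self.m.ndim != 2:
            raise ValidationError("mask must be 2-D (cells x genes)")
        col_const = np.all(self.m == self.m[:1, :], axis=0)
        if not col_const.all():
            raise ValidationError("each mask column must be constant across cells")

    @property
    def column(self) -> np.ndarray:
        """The per-gene 0/1 row (mask columns are constant by invariant)."""
        return self.m[0]

    @property
    def n_shared(self) -> int:
        return int(self.column.sum())

    @property
    def n_unique(self) -> int:
        return self.m.shape[1] - self.n_shared


def build_gene_mask(
    reference: ExpressionMatrix, st: ExpressionMatrix, case_fold: bool = False
) -> GeneMask:
    """Mask over the reference gene axis: 1 where the gene is also in `st`."""
    key = (lambda g: g.casefold()) if case_fold else (lambda g: g)
    st_genes = {key(g) for g in st.gene_names}
    col = np.array([1.0 if key(g) in st_genes else 0.0 for g in reference.gene_names])
    shared = [g for g, v in zip(reference.gene_names, col) if v == 1.0]
    if not shared:
        raise ValidationError("no shared genes between reference and ST matrices")
    m = np.broadcast_to(col, (reference.n_cells, reference.n_genes)).copy()
    return GeneMask(m=m, shared_genes=shared)


@dataclass
class SplitPlan:
    """Gene-holdout cross-validation plan: gene name -> fold index."""

    fold_assignments: dict[str, int]
    k: int

    def fold_genes(self, fold: int) -> list[str]:
        return [g for g, f in self.fold_assignments.items() if f == fold]


def make_cv_splits(mask: GeneMask, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition shared genes into k balanced folds, deterministic given seed.

    Each fold's genes are relabeled "unique" (held out from the ST
    conditional) in that fold's run, so their imputations can be scored
    against measured values.
    """
    genes = list(mask.shared_genes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} shared genes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    assignments = {genes[int(idx)]: int(i % k) for i, idx in enumerate(order)}
    return SplitPlan(fold_assignments=assignments, k=k)


# ----------------------------------------------------------------------
# readers / writers

_FORMATS = ("tsv", "mtx_triplet", "h5_container")


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".mtx") else path
    return stem + "_genes.txt", stem + "_cells.txt"


def read_expression(
    path: str, format: str, modality: Modality | str = Modality.SCRNA
) -> ExpressionMatrix:
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=np.float64)
        genes, cells = list(df.columns), list(df.index)
    elif format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if sp.issparse(mat) else mat, dtype=np.float64
        )
        gpath, cpath = _sidecar_paths(path)
        genes = _read_names(gpath)
        cells = _read_names(cpath)
    else:
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        values = np.asarray(x.todense() if sp.issparse(x) else x, dtype=np.float64)
        genes, cells = list(adata.var_names), list(adata.obs_names)
    return ExpressionMatrix(
        values=values, gene_names=genes, cell_names=cells, modality=modality
    )


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def write_expression(x: ExpressionMatrix, path: str, format: str) -> None:
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; one of {_FORMATS}")
    x.validate()
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
    if format == "tsv":
        df = pd.DataFrame(x.values, index=x.cell_names, columns=x.gene_names)
        df.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        if not path.endswith(".mtx"):
            raise ValueError("mtx_triplet paths must end in .mtx")
        scipy.io.mmwrite(path, sp.coo_matrix(x.values))
        gpath, cpath = _sidecar_paths(path)
        _write_names(gpath, x.gene_names)
        _write_names(cpath, x.cell_names)
    else:
        import anndata as ad

        adata = ad.AnnData(
            X=x.values.copy(),
            obs=pd.DataFrame(index=pd.Index(x.cell_names, name="cell")),
            var=pd.DataFrame(index=pd.Index(x.gene_names, name="gene")),
        )
        adata.write_h5ad(path)


def _write_names(path: str, names: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(names) + "\n")


# ----------------------------------------------------------------------
# preprocessing

def lognorm(x: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize each cell to `target_sum` total, then log1p.

    Applied identically to both modalities before training so the model
    sees relative expression rather than depth.  Cells with zero total are
    left at zero.
    """
    totals = x.values.sum(axis=1, keepdims=True)
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals), where=totals > 0
    )
    vals = np.log1p(x.values * scale)
    return ExpressionMatrix(
        values=vals,
        gene_names=list(x.gene_names),
        cell_names=list(x.cell_names),
        modality=x.modality,
    )
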