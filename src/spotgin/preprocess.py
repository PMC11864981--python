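"""Normalization, covariate regression and variable-gene selection.

Counts are scaled per spot to a constant total (10,000 by default) and
natural-log transformed with a pseudocount of one:
``v_gs = ln(1 + scale_total * c_gs / sum_g c_gs)``. Optional per-gene OLS
regression removes batch and mitochondrial/ribosomal-fraction covariates;
the top-variance genes (up to 5,000) feed the graph features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_SCALE_TOTAL = 10_000.0
DEFAULT_N_HVG = 5_000


@dataclass
class NormalizedMatrix:
    """Log-normalized genes x spots expression with selected variable genes."""

    values: np.ndarray  # genes x spots, natural-log scale
    gene_ids: np.ndarray
    barcodes: np.ndarray
    scale_total: float = DEFAULT_SCALE_TOTAL
    hvg_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("values shape does not match gene/barcode lists")

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (pos < 0).any():
            missing = [g for g, p in zip(gene_ids, pos) if p < 0]
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return pos

    def hvg_values(self) -> np.ndarray:
        """Rows of `values` for the selected variable genes, in hvg order."""
        if not len(self.hvg_ids):
            raise ValueError("no variable genes selected; run select_hvg first")
        return self.values[self.gene_index(self.hvg_ids)]


def normalize_log(counts, gene_ids, barcodes,
                  scale_total: float = DEFAULT_SCALE_TOTAL) -> NormalizedMatrix:
    """Scale each spot to ``scale_total`` transcripts and apply ln(1+x).

    Raises if any spot has zero total counts; drop those at load time
    (:meth:`spotgin.datasets.SpotDataset.drop_zero_spots`).
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    totals = dense.sum(axis=0)
    if (totals <= 0).any():
        bad = int((totals <= 0).sum())
        raise ValueError(
            f"{bad} spots with zero total UMIs; drop them at load "
            "(SpotDataset.drop_zero_spots) before normalizing")
    values = np.log1p(scale_total * dense / totals)
    return NormalizedMatrix(values=values, gene_ids=gene_ids, barcodes=barcodes,
                            scale_total=scale_total)


def normalize_dataset(dataset, scale_total: float = DEFAULT_SCALE_TOTAL) -> NormalizedMatrix:
    return normalize_log(dataset.counts, dataset.gene_ids, dataset.barcodes,
                         scale_total=scale_total)


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Intercept + one-hot batches + numeric columns; drops collinear columns."""
    columns: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype == object or str(series.dtype) == "category":
            levels = sorted(series.astype(str).unique())
            for lev in levels[1:]:  # reference level folded into intercept
                columns.append((series.astype(str) == lev).to_numpy(float))
                names.append(f"{col}[{lev}]")
        else:
            columns.append(series.to_numpy(float))
            names.append(col)
    X = np.column_stack(columns)
    # drop collinear columns greedily, keeping the intercept
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


def regress_covariates(nm: NormalizedMatrix,
                       covariates: pd.DataFrame) -> NormalizedMatrix:
    """Remove covariate effects per gene by OLS, keeping each gene's intercept.

    ``covariates`` is indexed/aligned to spots; string columns are one-hot
    encoded (first level as reference), numeric columns used as-is. The
    returned matrix is residuals + fitted intercept, so gene means are
    preserved up to the covariate fit.
    """
    if len(covariates) != len(nm.barcodes):
        raise ValueError("covariate table not aligned to spots")
    X, names = _design_matrix(covariates)
    Y = nm.values.T  # spots x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = (resid + beta[0]).T  # add back per-gene intercept
    return NormalizedMatrix(values=out, gene_ids=nm.gene_ids,
                            barcodes=nm.barcodes, scale_total=nm.scale_total,
                            hvg_ids=list(nm.hvg_ids))


def select_hvg(nm: NormalizedMatrix, n: int = DEFAULT_N_HVG) -> list:
    """Top-``n`` genes by variance of normalized values.

    Ties are broken lexicographically by gene id; if fewer than ``n`` genes
    exist all are returned. The selection is stored on the matrix
    (``hvg_ids``) and also returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    var = nm.values.var(axis=1)
    order = sorted(range(len(var)), key=lambda i: (-var[i], str(nm.gene_ids[i])))
    hvg = [nm.gene_ids[i] for i in order[:n]]
    nm.hvg_ids = hvg
    return hvg


def select_hvg_joint(nms: list, n: int = DEFAULT_N_HVG) -> list:
    """One shared variable-gene list for several sections.

    Variance is computed over the pooled spots of all matrices (which must
    share the gene universe) so downstream node features align across
    sections; the list is written to every matrix and returned. The
    criterion is label-free.
    """
    if not nms:
        raise ValueError("no matrices given")
    first = nms[0]
    for nm in nms[1:]:
        if not np.array_equal(nm.gene_ids, first.gene_ids):
            raise ValueError("matrices do not share a gene universe")
    pooled = np.concatenate([nm.values for nm in nms], axis=1)
    joint = NormalizedMatrix(values=pooled, gene_ids=first.gene_ids,
                             barcodes=np.arange(pooled.shape[1]).astype(str),
                             scale_total=first.scale_total)
    hvg = select_hvg(joint, n)
    for nm in nms:
        nm.hvg_ids = list(hvg)
    return hvg
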