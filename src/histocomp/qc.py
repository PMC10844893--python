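"""Single-cell QC, normalization and marker-based cell-type annotation.

QC keeps cells with at least ``min_genes`` detected genes and a
mitochondrial fraction of at most ``max_mito`` (a cell is discarded only when
its fraction exceeds the threshold), then keeps genes detected in more than
``min_cells`` cells — the gene filter is computed on the post-cell-filter
matrix. Annotation scores each cell against a marker panel by the mean
z-scored expression of the panel's markers and assigns the argmax type.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import EmptyResultError, MissingGeneError, NormalizationError
from .panels import DEFAULT_MARKER_PANEL

MITO_PREFIXES = ("MT-",)


def mito_fraction(adata: AnnData, prefixes: Sequence[str] = MITO_PREFIXES) -> pd.Series:
    """Per-cell fraction of counts on mitochondrial genes (by name prefix)."""
    is_mito = adata.var_names.str.startswith(tuple(prefixes))
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, np.where(is_mito)[0]].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.Series(frac, index=adata.obs_names, name="mito_fraction")


def apply_qc_filters(adata: AnnData, min_genes: int = 200, min_cells: int = 3,
                     max_mito: float = 0.10,
                     mito_prefixes: Sequence[str] = MITO_PREFIXES) -> AnnData:
    """Filter cells then genes.

    Cells are retained when they detect at least ``min_genes`` genes and
    their mitochondrial fraction is not higher than ``max_mito``; genes are
    then retained when detected in strictly more than ``min_cells`` of the
    surviving cells.
    """
    X = sp.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    frac = mito_fraction(adata, mito_prefixes).to_numpy()
    keep_cells = (detected >= min_genes) & (frac <= max_mito)
    if not keep_cells.any():
        raise EmptyResultError("QC removed every cell")
    out = adata[keep_cells].copy()
    per_gene = np.asarray((sp.csc_matrix(out.X) > 0).sum(axis=0)).ravel()
    keep_genes = per_gene > min_cells
    if not keep_genes.any():
        raise EmptyResultError("QC removed every gene")
    out = out[:, keep_genes].copy()
    out.obs["mito_fraction"] = frac[keep_cells]
    return out


def normalize_log1p(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size normalize each cell to ``scale`` counts, then log1p (base e).

    Raw counts are kept in ``layers['counts']``.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[np.where(totals == 0)[0][0]]
        raise NormalizationError(f"cell {bad!r} has zero total counts")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    scaled = sp.diags(scale / totals) @ X
    scaled.data = np.log1p(scaled.data)
    out.X = scaled.tocsr()
    return out


def center_batches(adata: AnnData, batch_key: str = "batch") -> AnnData:
    """Optional per-batch gene-median centering of the normalized matrix."""
    out = adata.copy()
    X = np.asarray(out.X.todense() if sp.issparse(out.X) else out.X, dtype=float)
    for _, idx in out.obs.groupby(batch_key, observed=True).indices.items():
        X[idx] -= np.median(X[idx], axis=0, keepdims=True)
    out.X = X
    return out


def score_cell_types(adata: AnnData,
                     panel: Mapping[str, Sequence[str]] = DEFAULT_MARKER_PANEL
                     ) -> pd.DataFrame:
    """Cells x types matrix of mean z-scored marker expression.

    Expects log-normalized input. Genes with zero variance contribute a zero
    z-score; panel types with no marker present in the matrix are dropped.
    """
    present = {ct: [g for g in genes if g in adata.var_names]
               for ct, genes in panel.items()}
    present = {ct: genes for ct, genes in present.items() if genes}
    if not present:
        raise MissingGeneError("no marker of any panel type found in the matrix")
    all_markers = sorted({g for genes in present.values() for g in genes})
    sub = adata[:, all_markers].X
    M = np.asarray(sub.todense() if sp.issparse(sub) else sub, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(Z, index=adata.obs_names, columns=all_markers)
    scores = pd.DataFrame(
        {ct: zdf[genes].mean(axis=1) for ct, genes in present.items()})
    return scores[sorted(scores.columns)]


def assign_cell_type(scores: pd.DataFrame) -> pd.Series:
    """Argmax type per cell; ties broken by lexicographic type name."""
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("cell-type scores must be finite")
    ordered = scores[sorted(scores.columns)]
    return ordered.idxmax(axis=1).rename("cell_type")
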