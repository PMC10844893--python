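"""Moving-average copy-number inference and tumour-cell calling.

A light-weight analogue of expression-based CNV inference: per-gene log2
ratios of each epithelial cell against the mean of normal epithelial
reference cells, smoothed by a centered moving average along genome order
within each chromosome and clipped. Cells whose mean squared window
deviation ("burden") exceeds the reference mean by ``k`` standard deviations
are called tumour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import EmptyResultError, HistocompError


@dataclass
class CNVProfile:
    """Smoothed per-cell log2 ratio profiles over genome-ordered windows."""

    values: pd.DataFrame       # cells x ordered genes (window centers)
    window_map: pd.DataFrame   # per gene: chromosome, span_start, span_end
    window: int
    reference_cells: list


@dataclass
class TumourCall:
    flags: pd.Series           # cell -> bool
    burden: pd.Series          # cell -> mean squared window deviation
    threshold: float


def genome_order_from_var(var: pd.DataFrame) -> pd.DataFrame:
    """Genome order table (chromosome, position) from a var frame."""
    return var[["chromosome", "position"]].copy()


def read_genome_order(path) -> pd.DataFrame:
    """Read a BED-like TSV: chromosome, position, gene."""
    df = pd.read_csv(path, sep="\t", names=["chromosome", "position", "gene"],
                     header=None, comment="#")
    return df.set_index("gene")


def _centered_mean(A: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, truncated at the edges."""
    half = window // 2
    n = A.shape[1]
    cs = np.cumsum(np.concatenate([np.zeros((A.shape[0], 1)), A], axis=1), axis=1)
    idx = np.arange(n)
    starts = np.maximum(idx - half, 0)
    ends = np.minimum(idx + half + 1, n)
    return (cs[:, ends] - cs[:, starts]) / (ends - starts)


def compute_cnv_profile(adata: AnnData, reference_cells: Sequence[str],
                        order: pd.DataFrame | None = None, window: int = 51,
                        clip: float = 3.0, eps: float = 1.0,
                        exclude_chroms: Sequence[str] = ("chrM",)) -> CNVProfile:
    """Smoothed log2 expression ratios against a normal reference.

    ``adata`` must be log1p-normalized (``normalize_log1p`` output); ratios
    are computed on the linear normalized scale with pseudocount ``eps``,
    centered so the reference cells average to zero per gene, then averaged
    over ``window`` genes within each chromosome, median-centered per cell
    (large gains shift a cell's library total, which depresses every other
    window; the median restores the diploid baseline) and clipped to
    ``±clip``.
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise EmptyResultError("reference cell set is empty")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if order is None:
        order = genome_order_from_var(adata.var)
    order = order.loc[[g for g in adata.var_names if g in order.index]]
    # the mitochondrial contig tracks contamination, not copy number
    order = order[~order["chromosome"].isin(exclude_chroms)]
    order = order.sort_values(["chromosome", "position"])
    genes = order.index.to_list()

    X = adata[:, genes].X
    lin = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    lin = np.expm1(lin)
    ref_rows = adata.obs_names.get_indexer(reference_cells)
    if (ref_rows < 0).any():
        missing = [c for c, i in zip(reference_cells, ref_rows) if i < 0]
        raise KeyError(f"reference cells not in matrix: {missing[:5]}")
    ref_mean = lin[ref_rows].mean(axis=0)
    ratio = np.log2((lin + eps) / (ref_mean + eps))
    ratio -= ratio[ref_rows].mean(axis=0)   # center by reference

    smooth = np.empty_like(ratio)
    spans = np.empty((len(genes), 2), dtype=int)
    chroms = order["chromosome"].to_numpy()
    pos = 0
    for chrom in pd.unique(chroms):
        block = np.where(chroms == chrom)[0]
        smooth[:, block] = _centered_mean(ratio[:, block], window)
        half = window // 2
        local = np.arange(len(block))
        spans[block, 0] = block[np.maximum(local - half, 0)]
        spans[block, 1] = block[np.minimum(local + half, len(block) - 1)]
        pos += len(block)
    smooth -= np.median(smooth, axis=1, keepdims=True)
    smooth = np.clip(smooth, -clip, clip)

    values = pd.DataFrame(smooth, index=adata.obs_names, columns=genes)
    window_map = pd.DataFrame(
        {"chromosome": chroms,
         "span_start": [genes[i] for i in spans[:, 0]],
         "span_end": [genes[i] for i in spans[:, 1]]},
        index=genes)
    return CNVProfile(values=values, window_map=window_map, window=window,
                      reference_cells=reference_cells)


def cnv_burden(profile: CNVProfile) -> pd.Series:
    """Mean squared window deviation per cell."""
    return (profile.values ** 2).mean(axis=1).rename("cnv_burden")


def call_tumour_cells(profile: CNVProfile,
                      reference_cells: Sequence[str] | None = None,
                      k: float = 2.0) -> TumourCall:
    """Flag cells whose CNV burden exceeds mean + k·sd of reference burdens."""
    reference_cells = list(reference_cells or profile.reference_cells)
    burden = cnv_burden(profile)
    ref = burden.loc[reference_cells]
    sd = float(ref.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise HistocompError("degenerate reference: zero variance in burdens")
    threshold = float(ref.mean()) + k * sd
    flags = (burden > threshold).rename("is_tumour")
    return TumourCall(flags=flags, burden=burden, threshold=threshold)
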