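"""Spatial platforms: AOI QC, normalization and differential expression.

DSP AOIs are normalized by surface area and then by the per-AOI geometric
mean of the IgG isotype controls (computed after the area scaling, so the
IgG division also absorbs collection-efficiency differences between AOIs);
Visium spots by library size + log1p. Differential expression is a
two-sided pooled-variance Student t-test on log2 values with the discovery
rule "linear fold change > 1.5 and BH FDR < .05" (strict inequalities).
Pooling matters at the DSP design size of two AOIs per group: Welch's
Satterthwaite df degenerates towards 1 there, flooring the attainable
p-value near 0.02 however large the effect, whereas the pooled test keeps
its nominal n1+n2-2 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, MissingGeneError, NormalizationError

REGIONS = ("normal", "lepidic", "acinar")
COMPARTMENTS = ("PanCK+", "CD31+", "CD45+")

#: Default AOI QC thresholds (the platform vendor's criteria are
#: study-specific; these are configurable minima on the recorded metadata).
DEFAULT_DSP_QC = {
    "min_nuclei_count": 20,
    "min_surface_area": 1600.0,
    "min_total_counts": 1e4,
}


@dataclass
class AOIMatrix:
    """Expression (genes x AOIs, IgG controls included) with AOI metadata."""

    expression: pd.DataFrame
    meta: pd.DataFrame           # index aoi; roi, region, compartment, surface_area, nuclei_count
    igg_controls: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.meta.index):
            self.meta = self.meta.loc[self.expression.columns]

    def subset(self, mask: pd.Series) -> "AOIMatrix":
        keep = self.meta.index[mask.loc[self.meta.index]]
        return AOIMatrix(self.expression[keep], self.meta.loc[keep],
                         list(self.igg_controls))


def dsp_qc(aois: AOIMatrix,
           thresholds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-AOI pass/fail with every failed criterion listed.

    Returns a frame indexed by AOI with a boolean ``passed`` column and a
    ``reasons`` column holding a comma-separated list of failed criteria.
    """
    thr = dict(DEFAULT_DSP_QC)
    if thresholds:
        thr.update(thresholds)
    for col in ("nuclei_count", "surface_area"):
        if col not in aois.meta.columns:
            raise MissingGeneError(f"AOI metadata missing required field {col!r}")
    totals = aois.expression.sum(axis=0)
    rows = []
    for aoi in aois.meta.index:
        reasons = []
        if aois.meta.at[aoi, "nuclei_count"] < thr["min_nuclei_count"]:
            reasons.append("nuclei_count")
        if aois.meta.at[aoi, "surface_area"] < thr["min_surface_area"]:
            reasons.append("surface_area")
        if totals[aoi] < thr["min_total_counts"]:
            reasons.append("total_counts")
        rows.append({"passed": not reasons, "reasons": ",".join(reasons)})
    return pd.DataFrame(rows, index=aois.meta.index)


def dsp_normalize(aois: AOIMatrix) -> AOIMatrix:
    """Area + IgG-background normalization.

    Every feature (IgG controls included) is divided by the AOI surface
    area; each AOI is then divided by the geometric mean of its
    area-scaled IgG controls, and the control features are dropped.
    """
    igg = [g for g in aois.igg_controls if g in aois.expression.index]
    if not igg:
        raise MissingGeneError("no IgG control features present")
    area = aois.meta["surface_area"].astype(float)
    if (area <= 0).any():
        raise NormalizationError("non-positive surface area")
    scaled = aois.expression.div(area, axis=1)
    igg_vals = scaled.loc[igg]
    if (igg_vals <= 0).any().any():
        bad = igg_vals.columns[(igg_vals <= 0).any(axis=0)][0]
        raise NormalizationError(
            f"AOI {bad!r} has a non-positive IgG control value; geometric mean undefined")
    geomean = np.exp(np.log(igg_vals).mean(axis=0))
    out = scaled.drop(index=igg).div(geomean, axis=1)
    return AOIMatrix(out, aois.meta.copy(), [])


def visium_normalize(spots: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size scale each spot (column) to ``scale`` counts, then log1p."""
    totals = spots.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise NormalizationError(f"spot {bad!r} has zero total counts")
    return np.log1p(spots.mul(scale / totals, axis=1))


def differential_expression(values: pd.DataFrame, group_a: Sequence[str],
                            group_b: Sequence[str], eps: float = 1.0,
                            values_are_log: bool = False,
                            fc: float = 1.5, fdr: float = 0.05) -> pd.DataFrame:
    """Pooled-variance two-sample t-test per gene of group A vs group B.

    ``values`` is genes x samples on a linear scale (set ``values_are_log``
    when passing log-transformed data). The t-test runs on log2(x + eps);
    the reported ``ratio`` is (linear mean A + eps) / (linear mean B + eps).
    P-values are BH-adjusted over all tested genes and ``passed`` marks the
    up-regulated discovery rule ratio > fc and FDR < fdr (strict).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise EmptyResultError("each group needs at least two samples")
    A = values[group_a].to_numpy(dtype=float)
    B = values[group_b].to_numpy(dtype=float)
    # t is scale-invariant, so natural-log input can be tested as-is
    linA, linB = (np.expm1(A), np.expm1(B)) if values_are_log else (A, B)
    logA, logB = (A, B) if values_are_log else (np.log2(A + eps), np.log2(B + eps))

    t, p = stats.ttest_ind(logA, logB, axis=1, equal_var=True)
    # identical, zero-variance groups: define t=0, p=1
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    mean_a, mean_b = linA.mean(axis=1), linB.mean(axis=1)
    ratio = (mean_a + eps) / (mean_b + eps)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "ratio": ratio,
        "log2fc": np.log2(ratio), "t": t, "p": p, "fdr": q,
    }, index=values.index)
    table["passed"] = (table["ratio"] > fc) & (table["fdr"] < fdr)
    return table


def filter_degs(table: pd.DataFrame, fc: float = 1.5, fdr: float = 0.05) -> list[str]:
    """Up-regulated genes with ratio strictly > fc and FDR strictly < fdr."""
    if table.empty:
        return []
    keep = (table["ratio"] > fc) & (table["fdr"] < fdr)
    return table.index[keep].to_list()
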