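"""Subtype scoring of tumour cells and per-patient composition estimates.

The module score of a signature in a cell is the mean log-normalized
expression of the signature genes minus the mean of control genes sampled,
for each signature gene, from the same average-expression bin. Because a
signature gene's bin reflects its population average (which includes the
cells that over-express it), cells lacking the programme score below zero —
this is what makes the parameter-free three-way rule work: a tumour cell is
called lepidic or acinar by the larger positive score, and "other" when
neither score is positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import EmptyResultError, MissingGeneError
from .signatures import SignatureSet

SUBTYPES = ("lepidic", "acinar", "other")


def module_score(adata: AnnData, signature: SignatureSet | Sequence[str],
                 n_bins: int = 25, n_ctrl: int = 50, seed: int = 0) -> pd.Series:
    """Control-bin module score of one signature per cell.

    Expects log-normalized input. Genes are binned into ``n_bins``
    equal-frequency bins of mean expression; each signature gene draws
    ``n_ctrl`` control genes from its own bin (signature genes excluded
    from the control pool where possible). Deterministic given ``seed``.
    """
    genes = list(signature.genes) if isinstance(signature, SignatureSet) else list(signature)
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise MissingGeneError("no signature gene present in the matrix")
    X = adata.X
    M = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    means = pd.Series(M.mean(axis=0), index=adata.var_names)
    bins = pd.qcut(means.rank(method="first"), q=min(n_bins, len(means)),
                   labels=False)
    rng = np.random.default_rng(seed)
    sig_set = set(present)
    ctrl_cols: list[int] = []
    for g in present:
        pool = bins.index[(bins == bins[g]) & (~bins.index.isin(sig_set))]
        if len(pool) == 0:
            pool = bins.index[(bins == bins[g]) & (bins.index != g)]
        if len(pool) == 0:
            continue
        chosen = rng.choice(len(pool), size=n_ctrl, replace=True)
        ctrl_cols.extend(adata.var_names.get_indexer(pool[chosen]))
    if not ctrl_cols:
        raise EmptyResultError("no control genes could be sampled")
    sig_idx = adata.var_names.get_indexer(present)
    score = M[:, sig_idx].mean(axis=1) - M[:, ctrl_cols].mean(axis=1)
    name = signature.subtype if isinstance(signature, SignatureSet) else "score"
    return pd.Series(score, index=adata.obs_names, name=name)


def classify_cells(lepidic: pd.Series, acinar: pd.Series,
                   threshold: float = 0.0) -> pd.Series:
    """Three-way call per tumour cell.

    Argmax of the two scores when the maximum exceeds ``threshold``;
    "other" otherwise, including exact ties of positive scores.
    """
    scores = pd.DataFrame({"lepidic": lepidic, "acinar": acinar})
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    calls = pd.Series("other", index=scores.index, name="subtype")
    lep, aci = scores["lepidic"], scores["acinar"]
    calls[(lep > threshold) & (lep > aci)] = "lepidic"
    calls[(aci > threshold) & (aci > lep)] = "acinar"
    return calls


def patient_composition(calls: pd.Series, patients: pd.Series) -> pd.DataFrame:
    """Per-patient (lepidic, acinar, other) frequencies over tumour cells.

    Patients present in ``patients`` but with zero classified cells are
    omitted from the result (reported missing, not zero).
    """
    df = pd.DataFrame({"subtype": calls, "patient": patients.loc[calls.index]})
    counts = (df.groupby("patient", observed=True)["subtype"]
                .value_counts().unstack(fill_value=0))
    for s in SUBTYPES:
        if s not in counts.columns:
            counts[s] = 0
    comp = counts[list(SUBTYPES)].div(counts.sum(axis=1), axis=0)
    return comp


_PATTERN = re.compile(r"([A-Za-z][A-Za-z ]*?)\s*\((\d+(?:\.\d+)?)%\)")

_COMPONENT_MAP = {
    "acinar": "acinar",
    "lepidic": "lepidic",
    "micropapillary": "other",
    "complex glandular structures": "other",
    "solid": "other",
    "papillary": "other",
}


def parse_pathology(text: str) -> dict[str, float]:
    """Parse '"Acinar (50%), lepidic (50%)"' into subtype percentages.

    Growth patterns other than lepidic/acinar fold into "other"; any
    unstated remainder up to 100% is added to "other".
    """
    out = {"lepidic": 0.0, "acinar": 0.0, "other": 0.0}
    total = 0.0
    for name, pct in _PATTERN.findall(text):
        key = _COMPONENT_MAP.get(name.strip().lower())
        if key is None:
            raise ValueError(f"unknown growth pattern {name!r}")
        out[key] += float(pct)
        total += float(pct)
    if total > 100.0 + 1e-9:
        raise ValueError(f"pathology percentages sum to {total} > 100: {text!r}")
    out["other"] += 100.0 - total
    return out


def load_pathology_table() -> pd.DataFrame:
    """Bundled 11-patient clinicopathology reference table.

    Returns raw fields plus parsed (lepidic, acinar, other) proportions.
    """
    with resources.files("histocomp.data").joinpath("pathology_cohort.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("patient")
    parsed = (df["pathology"].map(parse_pathology).apply(pd.Series)
              .astype(float) / 100.0)
    return pd.concat([df, parsed], axis=1)


def concordance_with_pathology(pred: pd.DataFrame,
                               pathology: pd.DataFrame) -> dict:
    """Compare predicted compositions with pathologist percentages.

    Both inputs are patient x (lepidic, acinar, other). Returns per-patient
    absolute differences, the per-class mean absolute error, and the
    across-patient Spearman rank correlation of the lepidic fraction.
    """
    from .survival import spearman_exact

    unmatched = sorted(set(pred.index) ^ set(pathology.index))
    if unmatched:
        raise KeyError(f"patient ids do not match: {unmatched}")
    path = pathology.loc[pred.index, list(SUBTYPES)]
    diffs = (pred[list(SUBTYPES)] - path).abs()
    corr = spearman_exact(pred["lepidic"].to_numpy(), path["lepidic"].to_numpy())
    return {
        "per_patient_abs_diff": diffs,
        "mae": diffs.mean(axis=0).to_dict(),
        "lepidic_rank_rho": corr["rho"],
        "lepidic_rank_p": corr["p"],
    }
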