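"""Signature derivation and generic gene-set utilities.

Subtype-specific gene sets come from set algebra on up-regulated DEG lists
(genes up in one subtype versus normal and not up in the other subtype),
then the two platforms' lists are intersected to form the final signature.
Also provides one-sided hypergeometric over-representation analysis and a
preranked weighted Kolmogorov–Smirnov enrichment score with a
gene-set-permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, MissingGeneError


@dataclass
class SignatureSet:
    """Final signature of one subtype with per-platform provenance."""

    subtype: str
    genes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)   # gene -> {"dsp": bool, "visium": bool}

    def __len__(self) -> int:
        return len(self.genes)


def subtype_specific_genes(deg_subtype_up: Iterable[str],
                           deg_other_up: Iterable[str]) -> set[str]:
    """Genes up-regulated in this subtype and not in the other one."""
    return set(deg_subtype_up) - set(deg_other_up)


def cross_platform_intersect(subtype: str, dsp_genes: Iterable[str],
                             visium_genes: Iterable[str],
                             dsp_log2fc: Mapping[str, float] | None = None
                             ) -> SignatureSet:
    """Intersect per-platform subtype-specific sets into the final signature.

    Genes are ordered by descending DSP log2 fold change when provided,
    alphabetically otherwise. An empty intersection is valid but warned
    about.
    """
    common = set(dsp_genes) & set(visium_genes)
    if not common:
        warnings.warn(f"empty cross-platform intersection for {subtype!r}",
                      stacklevel=2)
    if dsp_log2fc is not None:
        genes = sorted(common, key=lambda g: (-dsp_log2fc.get(g, -np.inf), g))
    else:
        genes = sorted(common)
    return SignatureSet(subtype=subtype, genes=genes,
                        provenance={g: {"dsp": True, "visium": True} for g in genes})


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file into name -> gene set (description field ignored)."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = {g for g in parts[2:] if g}
            if genes:
                collection[parts[0]] = genes
    return collection


def ora_hypergeometric(query: Iterable[str],
                       collection: Mapping[str, Iterable[str]],
                       universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    p = P(X >= overlap) with population = universe, successes = set ∩
    universe, draws = |query|; BH-adjusted across the collection.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        outside = sorted(query - universe)[:5]
        raise MissingGeneError(f"query genes outside universe: {outside}")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        genes = set(genes) & universe
        overlap = len(genes & query)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(genes), N))
        rows.append({"set": name, "set_size": len(genes), "overlap": overlap,
                     "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def _running_es(order: np.ndarray, scores: np.ndarray, member: np.ndarray,
                weight: float) -> float:
    """ES of one ranking: extremum of the weighted KS running sum."""
    w = np.abs(scores) ** weight
    hit = np.where(member, w, 0.0)
    hit_cum = np.cumsum(hit) / hit.sum()
    n_miss = (~member).sum()
    miss_cum = np.cumsum(~member) / n_miss
    running = hit_cum - miss_cum
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked_es(ranking: pd.Series, gene_set: Iterable[str],
                      weight: float = 1.0, n_perm: int = 999,
                      seed: int = 0) -> dict:
    """Preranked enrichment score with a gene-set-permutation p-value.

    ``ranking`` maps gene -> score; genes are ordered by decreasing score.
    ES is the signed extremum of the weighted KS running sum (weight
    exponent 1 by default). The two-sided p-value is the fraction of
    ``n_perm`` random same-size gene sets whose |ES| reaches |ES observed|.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    gene_set = set(gene_set)
    member = ranking.index.isin(gene_set)
    if not member.any():
        raise EmptyResultError("gene set shares no genes with the ranking")
    if member.all():
        raise EmptyResultError("gene set covers the whole ranking; ES undefined")
    order = np.argsort(-ranking.to_numpy(), kind="stable")
    scores = ranking.to_numpy()[order]
    member = member[order]
    es = _running_es(order, scores, member, weight)

    rng = np.random.default_rng(seed)
    size = int(member.sum())
    n = len(ranking)
    hits = 0
    for _ in range(n_perm):
        perm_member = np.zeros(n, dtype=bool)
        perm_member[rng.choice(n, size=size, replace=False)] = True
        if abs(_running_es(order, scores, perm_member, weight)) >= abs(es) - 1e-12:
            hits += 1
    return {"es": es, "p": (hits + 1) / (n_perm + 1), "n_perm": n_perm,
            "set_size": size}
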