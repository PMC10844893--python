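"""Synthetic multi-platform LUAD datasets with planted ground truth.

Emulates the data regime of a spatial + single-cell study of lung
adenocarcinoma histological subtypes:

* ``simulate_scrna`` — droplet scRNA-seq of paired tumour/normal samples per
  patient: gamma–Poisson counts, ten planted cell types, tumour epithelial
  cells split into lepidic/acinar/other growth patterns at per-patient
  ground-truth proportions, a planted chromosome-segment copy gain in all
  tumour cells, and mitochondrial contamination via reserved ``MT-`` genes.
* ``simulate_dsp`` — GeoMx-style areas of illumination (AOI): for each region
  (normal/lepidic/acinar) a small number of pathologist-drawn ROIs, each
  segmented into PanCK+/CD31+/CD45+ compartments, measured as deep aggregate
  counts with IgG isotype-control features for background normalization.
* ``simulate_visium`` — spot-level counts with region labels.
* ``simulate_survival_cohort`` — proportional-hazards survival times with
  age/sex/smoking covariates and optional expression covariates.

Subtype signature genes and the copy-number segment are shared across
platforms through the config seed, so cross-platform intersection has a
well-defined planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .config import IGG_CONTROLS, MT_GENES, SimConfig
from .errors import ConfigError
from .panels import DEFAULT_MARKER_PANEL

SUBTYPES = ("lepidic", "acinar", "other")
REGIONS = ("normal", "lepidic", "acinar")
COMPARTMENTS = ("PanCK+", "CD31+", "CD45+")

# Cell-type mixture of the non-tumour fraction of each sample. Tumour samples
# are immune-rich; normal lung keeps a large epithelial share.
_TUMOUR_SAMPLE_MIX = {
    "T cells": 0.30, "Macrophages": 0.20, "Fibroblasts": 0.10,
    "NK cells": 0.08, "B cells": 0.08, "ECs": 0.08, "EPs": 0.06,
    "DC": 0.04, "Neutrophils": 0.04, "Mast cells": 0.02,
}
_NORMAL_SAMPLE_MIX = {
    "EPs": 0.30, "T cells": 0.20, "Macrophages": 0.12, "ECs": 0.10,
    "Fibroblasts": 0.10, "NK cells": 0.06, "B cells": 0.06,
    "DC": 0.03, "Neutrophils": 0.02, "Mast cells": 0.01,
}

# log-normal base-mean parameters (single-cell scale, counts/cell)
_SC_BASE_MEDIAN, _SC_BASE_SIGMA = 2.0, 1.0
_SIG_BASE_MEDIAN, _SIG_BASE_SIGMA = 4.0, 0.5     # signatures arise from detectable genes
# lineage markers are near-binary in real tissue: almost silent outside
# their own cell type, tens of counts inside it
_MARKER_BASE_MEDIAN, _MARKER_BASE_SIGMA = 0.02, 0.3

_COMPARTMENT_TYPES = {
    "PanCK+": ("EPs",),
    "CD31+": ("ECs",),
    "CD45+": ("T cells", "B cells", "NK cells", "Macrophages", "DC",
              "Neutrophils", "Mast cells"),
}


@dataclass
class GroundTruth:
    """Planted truth of one simulated cohort."""

    cell_class: pd.Series            # cell -> lepidic/acinar/other or cell type
    tumour_flags: pd.Series          # cell -> bool
    signature_genes: dict            # subtype -> list of genes
    compositions: dict               # patient -> (lepidic, acinar, other) planted draw
    cnv_segment_genes: list = field(default_factory=list)
    survival_beta: dict | None = None

    def to_json(self, path) -> None:
        payload = {
            "cell_class": self.cell_class.to_dict(),
            "tumour_flags": {k: bool(v) for k, v in self.tumour_flags.items()},
            "signature_genes": {k: list(v) for k, v in self.signature_genes.items()},
            "compositions": {k: list(v) for k, v in self.compositions.items()},
            "cnv_segment_genes": list(self.cnv_segment_genes),
            "survival_beta": self.survival_beta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class GeneUniverse:
    """Gene names, genome order and planted signature assignment."""

    var: pd.DataFrame                # index gene; columns chromosome, position, is_mito
    signature_genes: dict            # subtype -> list
    cnv_genes: list                  # genes inside the planted segment


@dataclass
class VisiumMatrix:
    """Spot-level counts with region labels (genes x spots)."""

    counts: pd.DataFrame
    region: pd.Series


def _nb(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma–Poisson draw with Var = mu + phi mu^2."""
    size = 1.0 / phi
    p = size / (size + np.asarray(mu, dtype=float))
    return rng.negative_binomial(size, p)


def build_gene_universe(config: SimConfig) -> GeneUniverse:
    """Lay out the gene panel on a synthetic genome and plant signatures.

    Generic genes come first in genome order, then the marker panel, with the
    13 mitochondrial genes on chrM. Non-mito genes are assigned to
    chromosomes in consecutive blocks so the copy-number segment is a
    contiguous stretch of one chromosome. Signature genes are sampled from
    generic genes outside the segment (disjoint between subtypes).
    """
    markers = [g for genes in DEFAULT_MARKER_PANEL.values() for g in genes]
    n_reserved = len(markers) + len(MT_GENES)
    n_generic = config.n_genes - n_reserved
    chrom, seg_start, seg_end = config.cnv_segment
    if n_generic < 2 * config.n_signature_genes_per_subtype + (seg_end - seg_start):
        raise ConfigError(
            f"n_genes={config.n_genes} too small for {n_reserved} reserved genes, "
            f"2x{config.n_signature_genes_per_subtype} signature genes and the "
            f"{seg_end - seg_start}-gene CNV segment")

    width = len(str(n_generic))
    generic = [f"G{i + 1:0{width}d}" for i in range(n_generic)]
    ordered = generic + markers
    chroms, positions = [], []
    for i in range(len(ordered)):
        chroms.append(f"chr{i // config.chrom_block_size + 1}")
        positions.append(i % config.chrom_block_size)
    var = pd.DataFrame(
        {"chromosome": chroms + ["chrM"] * len(MT_GENES),
         "position": positions + list(range(len(MT_GENES))),
         "is_mito": [False] * len(ordered) + [True] * len(MT_GENES)},
        index=ordered + list(MT_GENES))
    var.index.name = "gene"

    on_chrom = var.index[var["chromosome"] == chrom]
    if len(on_chrom) < seg_end:
        raise ConfigError(f"cnv_segment end {seg_end} exceeds {chrom} size {len(on_chrom)}")
    cnv_genes = list(on_chrom[seg_start:seg_end])

    rng = np.random.default_rng([config.seed, 0])
    eligible = [g for g in generic if g not in set(cnv_genes)]
    chosen = rng.choice(len(eligible), size=2 * config.n_signature_genes_per_subtype,
                        replace=False)
    picked = [eligible[i] for i in chosen]
    k = config.n_signature_genes_per_subtype
    signature_genes = {"lepidic": sorted(picked[:k]), "acinar": sorted(picked[k:])}
    return GeneUniverse(var=var, signature_genes=signature_genes, cnv_genes=cnv_genes)


def _base_means(rng: np.random.Generator, universe: GeneUniverse,
                median: float, sigma: float,
                elevate_signatures: bool = False) -> np.ndarray:
    """Gene base means.

    With ``elevate_signatures`` (single-cell depth, where the log-normal
    tail would leave some genes undetectable) signature genes are drawn
    from a detectable range; at aggregate depths every gene is detectable
    and an elevated signature share would distort library-size
    normalization, so they follow the common distribution.
    """
    var = universe.var
    n = len(var)
    scale = median / _SC_BASE_MEDIAN
    base = rng.lognormal(np.log(median), sigma, size=n)
    sig = set(universe.signature_genes["lepidic"]) | set(universe.signature_genes["acinar"])
    idx = var.index.get_indexer([g for g in var.index if g in sig])
    sig_median = _SIG_BASE_MEDIAN * scale if elevate_signatures else median
    sig_sigma = _SIG_BASE_SIGMA if elevate_signatures else min(sigma, _SIG_BASE_SIGMA)
    base[idx] = rng.lognormal(np.log(sig_median), sig_sigma, size=len(idx))
    markers = [g for genes in DEFAULT_MARKER_PANEL.values() for g in genes]
    midx = var.index.get_indexer(markers)
    base[midx] = rng.lognormal(np.log(_MARKER_BASE_MEDIAN * scale), _MARKER_BASE_SIGMA,
                               size=len(midx))
    return base


def _marker_fc_row(universe: GeneUniverse, cell_types: Sequence[str],
                   log2fc: float) -> np.ndarray:
    """Fold-change vector elevating the markers of the given cell types."""
    fc = np.ones(len(universe.var))
    for ct in cell_types:
        idx = universe.var.index.get_indexer(DEFAULT_MARKER_PANEL[ct])
        fc[idx] *= 2.0 ** log2fc
    return fc


def simulate_scrna(config: SimConfig) -> tuple[AnnData, GroundTruth]:
    """Simulate the paired tumour/normal single-cell cohort.

    Returns an :class:`anndata.AnnData` (cells x genes, sparse integer
    counts; ``obs`` holds patient/tissue/batch) and the planted
    :class:`GroundTruth`. Deterministic given ``config.seed``.
    """
    universe = build_gene_universe(config)
    rng = np.random.default_rng([config.seed, 1])
    var = universe.var
    n_genes = len(var)
    base = _base_means(rng, universe, _SC_BASE_MEDIAN, _SC_BASE_SIGMA,
                       elevate_signatures=True)

    mt_mask = var["is_mito"].to_numpy()
    mt_weights = rng.dirichlet(np.full(mt_mask.sum(), 5.0))

    sig_idx = {s: var.index.get_indexer(universe.signature_genes[s])
               for s in ("lepidic", "acinar")}
    cnv_idx = var.index.get_indexer(universe.cnv_genes)

    type_fc = {ct: _marker_fc_row(universe, [ct], config.marker_log2fc)
               for ct in DEFAULT_MARKER_PANEL}

    cells, mus = [], []
    cell_class, tumour_flags, compositions = {}, {}, {}
    n_tumour_sample = int(round(config.n_cells_per_patient * config.tumour_sample_fraction))
    n_tumour_cells = int(round(n_tumour_sample * config.tumour_purity))

    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        comp = config.compositions[p]
        compositions[patient] = comp
        patient_factor = float(np.exp(rng.normal(0.0, config.patient_effect_sigma)))

        # tumour sample: tumour epithelium at the planted composition + stroma/immune
        subtype_counts = rng.multinomial(n_tumour_cells, comp)
        plan = []   # (tissue, class, is_tumour)
        for subtype, k in zip(SUBTYPES, subtype_counts):
            plan += [("tumour", subtype, True)] * int(k)
        rest = n_tumour_sample - n_tumour_cells
        mix_types = list(_TUMOUR_SAMPLE_MIX)
        mix_counts = rng.multinomial(rest, list(_TUMOUR_SAMPLE_MIX.values()))
        for ct, k in zip(mix_types, mix_counts):
            plan += [("tumour", ct, False)] * int(k)
        # normal sample
        n_normal = config.n_cells_per_patient - n_tumour_sample
        mix_counts = rng.multinomial(n_normal, list(_NORMAL_SAMPLE_MIX.values()))
        for ct, k in zip(list(_NORMAL_SAMPLE_MIX), mix_counts):
            plan += [("normal", ct, False)] * int(k)

        for i, (tissue, klass, is_tum) in enumerate(plan):
            cid = f"{patient}_{'T' if tissue == 'tumour' else 'N'}_{i:05d}"
            cells.append((cid, patient, tissue))
            cell_class[cid] = klass
            tumour_flags[cid] = is_tum
            lib = float(np.exp(rng.normal(0.0, config.library_sigma)))
            mu = base * lib * patient_factor
            if is_tum:
                mu = mu * type_fc["EPs"]
                if klass in sig_idx:
                    mu[sig_idx[klass]] *= 2.0 ** config.planted_log2fc
                mu[cnv_idx] *= 2.0 ** config.cnv_gain_log2
            else:
                mu = mu * type_fc[klass]
            # mitochondrial contamination: MT genes carry fraction f of the cell
            f = rng.uniform(*config.mito_fraction_range)
            mu[mt_mask] = mu[~mt_mask].sum() * f / (1.0 - f) * mt_weights
            mus.append(mu)

    mu_mat = np.vstack(mus)
    counts = _nb(rng, mu_mat, config.nb_dispersion)
    if config.dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)

    obs = pd.DataFrame([{"patient": p, "tissue": t, "batch": p}
                        for (_, p, t) in cells],
                       index=[c for (c, _, _) in cells])
    obs.index.name = "cell"
    adata = AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var.copy())
    truth = GroundTruth(
        cell_class=pd.Series(cell_class, name="cell_class"),
        tumour_flags=pd.Series(tumour_flags, name="is_tumour"),
        signature_genes=universe.signature_genes,
        compositions=compositions,
        cnv_segment_genes=universe.cnv_genes,
    )
    return adata, truth


def simulate_dsp(config: SimConfig):
    """Simulate DSP AOIs: ROIs x {PanCK+, CD31+, CD45+} compartments.

    Defaults give six ROIs (two per region) and 18 AOIs. Region signatures
    are planted only in PanCK+ (tumour-epithelium) AOIs; compartment
    identity is reflected by elevated lineage markers. Counts include the
    IgG isotype controls scaled, like every gene, by AOI area and a
    per-AOI collection efficiency — the background that IgG normalization
    is meant to remove.
    """
    from .spatial import AOIMatrix  # local import: spatial does not import simulate

    universe = build_gene_universe(config)
    rng = np.random.default_rng([config.seed, 2])
    var = universe.var
    base = _base_means(rng, universe, config.dsp_base_median, config.dsp_base_sigma)
    sig_idx = {s: var.index.get_indexer(universe.signature_genes[s])
               for s in ("lepidic", "acinar")}
    mean_area = float(np.mean(config.area_range))

    records, columns = [], {}
    roi_counter = 0
    for region in REGIONS:
        for _ in range(config.n_rois_per_region):
            roi_counter += 1
            roi_id = f"ROI{roi_counter:02d}"
            for compartment in COMPARTMENTS:
                aoi_id = f"{roi_id}_{compartment.rstrip('+')}"
                area = rng.uniform(*config.area_range)
                nuclei = int(rng.integers(config.nuclei_range[0], config.nuclei_range[1] + 1))
                eff = float(np.exp(rng.normal(0.0, config.aoi_efficiency_sigma)))
                lib = (area / mean_area) * eff
                fc = _marker_fc_row(universe, _COMPARTMENT_TYPES[compartment],
                                    config.marker_log2fc)
                mu = base * fc
                if compartment == "PanCK+" and region in sig_idx:
                    mu = mu.copy()
                    mu[sig_idx[region]] *= 2.0 ** config.planted_log2fc
                gene_counts = _nb(rng, mu * lib, config.dsp_nb_dispersion)
                igg_counts = _nb(rng, np.full(len(IGG_CONTROLS), config.igg_mean * lib),
                                 config.dsp_nb_dispersion)
                columns[aoi_id] = np.concatenate([gene_counts, igg_counts])
                records.append({"aoi": aoi_id, "roi": roi_id, "region": region,
                                "compartment": compartment, "surface_area": area,
                                "nuclei_count": nuclei})

    expr = pd.DataFrame(columns, index=list(var.index) + list(IGG_CONTROLS), dtype=float)
    expr.index.name = "gene"
    meta = pd.DataFrame(records).set_index("aoi")
    return AOIMatrix(expression=expr, meta=meta, igg_controls=list(IGG_CONTROLS))


def simulate_visium(config: SimConfig) -> VisiumMatrix:
    """Simulate Visium-like spots with region labels (genes x spots)."""
    universe = build_gene_universe(config)
    rng = np.random.default_rng([config.seed, 3])
    var = universe.var
    base = _base_means(rng, universe, config.visium_base_median, config.visium_base_sigma)
    sig_idx = {s: var.index.get_indexer(universe.signature_genes[s])
               for s in ("lepidic", "acinar")}

    spot_ids, regions, mus = [], [], []
    for region in REGIONS:
        mu_region = base.copy()
        if region in sig_idx:
            mu_region[sig_idx[region]] *= 2.0 ** config.planted_log2fc
        for i in range(config.n_spots_per_region):
            spot_ids.append(f"{region}_spot{i + 1:03d}")
            regions.append(region)
            lib = float(np.exp(rng.normal(0.0, config.library_sigma)))
            mus.append(mu_region * lib)
    counts = _nb(rng, np.vstack(mus), config.visium_nb_dispersion)
    if config.dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)
    df = pd.DataFrame(counts.T, index=var.index, columns=spot_ids, dtype=float)
    return VisiumMatrix(counts=df, region=pd.Series(regions, index=spot_ids, name="region"))


def simulate_survival_cohort(n: int, beta: Mapping[str, float] | None = None,
                             seed: int = 0, baseline_hazard: float = 0.1,
                             censor_rate: float = 0.05,
                             binary: Sequence[str] = ()) -> pd.DataFrame:
    """Simulate a survival cohort under proportional hazards.

    Event times are exponential with hazard ``baseline_hazard *
    exp(x . beta)``; censoring is an independent exponential. ``age`` (years),
    ``sex`` and ``smoking`` (0/1) are always generated; any other name in
    ``beta`` becomes a standard-normal expression covariate (or Bernoulli(0.5)
    if listed in ``binary``). Age enters the linear predictor as
    ``(age - 65) / 10``.
    """
    if n <= 0:
        raise ConfigError("cohort size must be positive")
    beta = dict(beta or {})
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.normal(65.0, 8.0, size=n),
        "sex": rng.integers(0, 2, size=n),
        "smoking": rng.integers(0, 2, size=n),
    }, index=[f"S{i + 1:05d}" for i in range(n)])
    df.index.name = "patient"
    for name in beta:
        if name in df.columns:
            continue
        if name in binary:
            df[name] = rng.integers(0, 2, size=n)
        else:
            df[name] = rng.normal(0.0, 1.0, size=n)
    lp = np.zeros(n)
    for name, coef in beta.items():
        x = df[name].to_numpy(dtype=float)
        if name == "age":
            x = (x - 65.0) / 10.0
        lp += coef * x
    hazard = baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / censor_rate, size=n)
    df.insert(0, "event", (event_time <= censor_time).astype(int))
    df.insert(0, "time", np.minimum(event_time, censor_time))
    return df
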