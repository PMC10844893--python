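"""End-to-end workflows tying the stages together.

``derive_signatures`` runs the two spatial platforms from simulation to the
final cross-platform signature sets; ``recover_compositions`` runs the
single-cell arm (QC, annotation, CNV tumour calling, module scoring,
classification) and returns predicted versus planted per-patient subtype
compositions.
"""

from __future__ import annotations

import pandas as pd

from .cnv import call_tumour_cells, compute_cnv_profile
from .config import SimConfig
from .qc import apply_qc_filters, assign_cell_type, normalize_log1p, score_cell_types
from .scoring import classify_cells, module_score, patient_composition
from .signatures import SignatureSet, cross_platform_intersect, subtype_specific_genes
from .simulate import build_gene_universe, simulate_dsp, simulate_scrna, simulate_visium
from .spatial import (differential_expression, dsp_normalize, dsp_qc,
                      filter_degs, visium_normalize)


def derive_signatures(config: SimConfig) -> dict:
    """Simulate DSP + Visium and derive the final signature sets.

    For each platform: normalize, test lepidic-vs-normal and
    acinar-vs-normal (up-regulated rule: fold change > 1.5, FDR < .05),
    make each subtype's list specific by removing genes also up in the
    other subtype, then intersect platforms.
    """
    dsp = simulate_dsp(config)
    qc_table = dsp_qc(dsp)
    dsp = dsp.subset(qc_table["passed"])
    norm = dsp_normalize(dsp)
    panck = norm.meta[norm.meta["compartment"] == "PanCK+"]
    aois = {r: panck.index[panck["region"] == r].to_list()
            for r in ("normal", "lepidic", "acinar")}
    dsp_tables = {
        s: differential_expression(norm.expression, aois[s], aois["normal"])
        for s in ("lepidic", "acinar")}

    vis = simulate_visium(config)
    vis_norm = visium_normalize(vis.counts)
    spots = {r: vis.region.index[vis.region == r].to_list()
             for r in ("normal", "lepidic", "acinar")}
    vis_tables = {
        s: differential_expression(vis_norm, spots[s], spots["normal"],
                                   values_are_log=True)
        for s in ("lepidic", "acinar")}

    dsp_up = {s: set(filter_degs(dsp_tables[s])) for s in ("lepidic", "acinar")}
    vis_up = {s: set(filter_degs(vis_tables[s])) for s in ("lepidic", "acinar")}
    signatures = {}
    for s, o in (("lepidic", "acinar"), ("acinar", "lepidic")):
        dsp_specific = subtype_specific_genes(dsp_up[s], dsp_up[o])
        vis_specific = subtype_specific_genes(vis_up[s], vis_up[o])
        signatures[s] = cross_platform_intersect(
            s, dsp_specific, vis_specific,
            dsp_log2fc=dsp_tables[s]["log2fc"].to_dict())

    truth = build_gene_universe(config).signature_genes
    return {"signatures": signatures, "dsp_tables": dsp_tables,
            "visium_tables": vis_tables, "truth_signatures": truth}


def recover_compositions(config: SimConfig,
                         signatures: dict[str, SignatureSet] | None = None,
                         cnv_k: float = 2.0) -> dict:
    """Single-cell arm: from raw counts to per-patient subtype proportions.

    When ``signatures`` is omitted the planted signature sets are used.
    Truth compositions are the realized planted class frequencies among
    each patient's tumour cells.
    """
    adata, truth = simulate_scrna(config)
    if signatures is None:
        signatures = {s: SignatureSet(subtype=s, genes=list(truth.signature_genes[s]))
                      for s in ("lepidic", "acinar")}

    filtered = apply_qc_filters(adata)
    norm = normalize_log1p(filtered)
    types = assign_cell_type(score_cell_types(norm))
    ep_cells = types.index[types == "EPs"]
    eps = norm[ep_cells].copy()
    reference = [c for c in ep_cells if eps.obs.at[c, "tissue"] == "normal"]
    profile = compute_cnv_profile(eps, reference)
    call = call_tumour_cells(profile, k=cnv_k)
    tumour_cells = call.flags.index[call.flags]
    tumour = norm[[c for c in tumour_cells]].copy()

    lep = module_score(tumour, signatures["lepidic"], seed=config.seed)
    aci = module_score(tumour, signatures["acinar"], seed=config.seed + 1)
    calls = classify_cells(lep, aci)
    pred = patient_composition(calls, tumour.obs["patient"])

    truth_tumour = truth.cell_class[truth.tumour_flags]
    true_comp = patient_composition(
        truth_tumour.rename("subtype"),
        adata.obs["patient"].loc[truth_tumour.index])
    return {"predicted": pred, "truth": true_comp, "calls": calls,
            "tumour_call": call, "cell_types": types, "ground_truth": truth,
            "scores": pd.DataFrame({"lepidic": lep, "acinar": aci})}
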