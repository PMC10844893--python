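"""AOI QC/normalization and the FC>1.5 & FDR<.05 discovery rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

import histocomp as hc
from histocomp.errors import EmptyResultError, MissingGeneError, NormalizationError
from histocomp.spatial import AOIMatrix


def _tiny_aois():
    expr = pd.DataFrame(
        {"A1": [8.0, 6.0, 2.0, 2.0], "A2": [10.0, 2.0, 4.0, 1.0],
         "A3": [3.0, 9.0, 1.0, 4.0]},
        index=["G1", "G2", "IgG1", "IgG2a"])
    meta = pd.DataFrame(
        {"roi": ["R1", "R1", "R2"], "region": ["normal", "lepidic", "acinar"],
         "compartment": ["PanCK+", "PanCK+", "PanCK+"],
         "surface_area": [1.0, 2.0, 4.0], "nuclei_count": [100, 120, 90]},
        index=["A1", "A2", "A3"])
    return AOIMatrix(expression=expr, meta=meta, igg_controls=["IgG1", "IgG2a"])


def test_dsp_qc_flags_failed_criteria():
    aois = _tiny_aois()
    aois.meta.loc["A2", "nuclei_count"] = 5
    table = hc.dsp_qc(aois, {"min_nuclei_count": 20, "min_surface_area": 0,
                             "min_total_counts": 0})
    assert not table.loc["A2", "passed"]
    assert table.loc["A2", "reasons"] == "nuclei_count"
    assert table["passed"].sum() == 2


def test_dsp_qc_vacuous_thresholds_all_pass():
    table = hc.dsp_qc(_tiny_aois(), {"min_nuclei_count": -np.inf,
                                     "min_surface_area": -np.inf,
                                     "min_total_counts": -np.inf})
    assert table["passed"].all()


def test_dsp_qc_missing_metadata_raises():
    aois = _tiny_aois()
    aois.meta = aois.meta.drop(columns=["nuclei_count"])
    with pytest.raises(MissingGeneError, match="nuclei_count"):
        hc.dsp_qc(aois)


def test_dsp_normalize_hand_oracle():
    """A1: area 1 -> values unchanged; IgG geomean sqrt(2*2)=2 -> G1 = 8/2."""
    out = hc.dsp_normalize(_tiny_aois())
    assert list(out.expression.index) == ["G1", "G2"]
    np.testing.assert_allclose(out.expression.at["G1", "A1"], 4.0)
    # A2: area 2 -> scaled (5, 1, 2, 0.5); geomean IgG = 1 -> G1 = 5
    np.testing.assert_allclose(out.expression.at["G1", "A2"], 5.0)
    # A3: area 4 -> scaled (.75, 2.25, .25, 1); geomean = .5 -> G2 = 4.5
    np.testing.assert_allclose(out.expression.at["G2", "A3"], 4.5)


def test_dsp_normalize_scale_invariance():
    aois = _tiny_aois()
    base = hc.dsp_normalize(aois)
    scaled = _tiny_aois()
    scaled.expression["A2"] *= 7.3
    out = hc.dsp_normalize(scaled)
    pd.testing.assert_frame_equal(base.expression, out.expression)


def test_dsp_normalize_zero_igg_raises():
    aois = _tiny_aois()
    aois.expression.at["IgG1", "A1"] = 0.0
    with pytest.raises(NormalizationError, match="A1"):
        hc.dsp_normalize(aois)


def test_visium_normalize_mirrors_log1p():
    spots = pd.DataFrame({"s1": [1.0, 1.0, 2.0], "s2": [2.0, 0.0, 2.0]},
                         index=["a", "b", "c"])
    out = hc.visium_normalize(spots, scale=4)
    np.testing.assert_allclose(out["s1"], [np.log(2), np.log(2), np.log(3)])
    np.testing.assert_allclose(np.expm1(out).sum(axis=0), 4.0)
    spots["s3"] = 0.0
    with pytest.raises(NormalizationError, match="s3"):
        hc.visium_normalize(spots)


def test_identical_groups_null_identity():
    vals = pd.DataFrame(np.tile([[3.0, 5.0, 3.0, 5.0]], (10, 1)),
                        index=[f"g{i}" for i in range(10)],
                        columns=["a1", "a2", "b1", "b2"])
    table = hc.differential_expression(vals, ["a1", "a2"], ["b1", "b2"])
    assert (table["t"] == 0).all()
    assert (table["p"] == 1).all()
    assert not table["passed"].any()


def test_group_size_below_two_raises():
    vals = pd.DataFrame(np.ones((4, 3)), columns=["a1", "b1", "b2"])
    with pytest.raises(EmptyResultError):
        hc.differential_expression(vals, ["a1"], ["b1", "b2"])


def test_deg_recovers_planted_genes_dsp(default_cfg):
    aois = hc.simulate_dsp(default_cfg)
    truth = hc.simulate.build_gene_universe(default_cfg).signature_genes
    norm = hc.dsp_normalize(aois)
    meta = norm.meta[norm.meta["compartment"] == "PanCK+"]
    ga = meta.index[meta["region"] == "lepidic"].to_list()
    gb = meta.index[meta["region"] == "normal"].to_list()
    table = hc.differential_expression(norm.expression, ga, gb)
    up = set(hc.filter_degs(table))
    want = set(truth["lepidic"])
    tp = len(up & want)
    assert tp / max(len(up), 1) >= 0.9      # precision
    assert tp / len(want) >= 0.9            # recall


def _bh_oracle(pvals):
    """Step-up: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        best = min(best, m * pvals[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(best, 1.0)
    return q


def test_bh_matches_oracle_on_all_permutations_of_six():
    base = [0.01, 0.02, 0.03, 0.04, 0.2, 0.9]
    for perm in itertools.permutations(base):
        p = np.array(perm)
        got = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, _bh_oracle(p), atol=1e-12)


def test_bh_stated_example():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], 0.04)


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12))
def test_bh_matches_oracle_property(pvals):
    p = np.array(pvals)
    got = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(got, _bh_oracle(p), atol=1e-12)


def test_filter_degs_strict_boundaries():
    table = pd.DataFrame({"ratio": [1.6, 1.5, 2.0, 1.7],
                          "fdr": [0.01, 0.01, 0.05, 0.049]},
                         index=["keep", "ratio_at_cut", "fdr_at_cut", "keep2"])
    assert hc.filter_degs(table) == ["keep", "keep2"]
    assert hc.filter_degs(pd.DataFrame()) == []


def test_null_generator_fdr_control():
    """No planted signal: the discovery rule fires at most at nominal rate."""
    fracs = []
    for seed in range(40):
        cfg = hc.SimConfig(planted_log2fc=0.0, seed=3000 + seed)
        norm = hc.dsp_normalize(hc.simulate_dsp(cfg))
        meta = norm.meta[norm.meta["compartment"] == "PanCK+"]
        ga = meta.index[meta["region"] == "lepidic"].to_list()
        gb = meta.index[meta["region"] == "normal"].to_list()
        fracs.append(hc.differential_expression(norm.expression, ga, gb)["passed"].mean())
    mc_se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert np.mean(fracs) <= 0.05 + 2 * mc_se
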