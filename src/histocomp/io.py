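"""Plain-text readers/writers for the pipeline's on-disk formats.

scRNA matrices travel as a Matrix Market triplet (genes x cells) with
``features.tsv``/``barcodes.tsv`` and a cell-metadata TSV; AOI and spot
matrices as dense TSVs with metadata sidecars; signatures as two-column
TSV plus a provenance JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

from .signatures import SignatureSet
from .spatial import AOIMatrix


def save_scrna(adata: AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", sp.csc_matrix(adata.X.T))
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")
    adata.var.to_csv(outdir / "gene_meta.tsv", sep="\t")


def load_scrna(indir) -> AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(mmread(indir / "matrix.mtx").T)
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(cells, name="cell"))
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    gene_meta = indir / "gene_meta.tsv"
    if gene_meta.exists():
        var = pd.read_csv(gene_meta, sep="\t", index_col=0)
    return AnnData(X=X, obs=obs, var=var)


def save_aoi_matrix(aois: AOIMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aois.expression.to_csv(outdir / "aoi_expression.tsv", sep="\t")
    aois.meta.to_csv(outdir / "aoi_meta.tsv", sep="\t")
    (outdir / "igg_controls.txt").write_text("\n".join(aois.igg_controls) + "\n")


def load_aoi_matrix(indir) -> AOIMatrix:
    indir = Path(indir)
    expr = pd.read_csv(indir / "aoi_expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(indir / "aoi_meta.tsv", sep="\t", index_col=0)
    igg_path = indir / "igg_controls.txt"
    igg = [l for l in igg_path.read_text().splitlines() if l] if igg_path.exists() else []
    return AOIMatrix(expression=expr, meta=meta, igg_controls=igg)


def save_visium(vis, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vis.counts.to_csv(outdir / "spot_counts.tsv", sep="\t")
    vis.region.rename("region").to_csv(outdir / "spot_regions.tsv", sep="\t")


def load_visium(indir):
    from .simulate import VisiumMatrix
    indir = Path(indir)
    counts = pd.read_csv(indir / "spot_counts.tsv", sep="\t", index_col=0)
    region = pd.read_csv(indir / "spot_regions.tsv", sep="\t", index_col=0)["region"]
    return VisiumMatrix(counts=counts, region=region)


def save_genome_order(var: pd.DataFrame, path) -> None:
    """BED-like TSV: chromosome, position, gene."""
    out = var[["chromosome", "position"]].copy()
    out["gene"] = out.index
    out.to_csv(path, sep="\t", index=False, header=False)


def save_signatures(signatures: dict[str, SignatureSet], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"gene": g, "subtype": name}
            for name, sig in signatures.items() for g in sig.genes]
    pd.DataFrame(rows, columns=["gene", "subtype"]).to_csv(
        outdir / "signatures.tsv", sep="\t", index=False)
    provenance = {name: sig.provenance for name, sig in signatures.items()}
    (outdir / "signature_provenance.json").write_text(json.dumps(provenance, indent=1))


def load_signatures(path) -> dict[str, SignatureSet]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for subtype, grp in df.groupby("subtype"):
        out[subtype] = SignatureSet(subtype=subtype, genes=grp["gene"].to_list(),
                                    provenance={})
    return out
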