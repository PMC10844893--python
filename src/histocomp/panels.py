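"""Default marker panel for major lung cell types.

Ten lineages with their characteristic markers: endothelial (ECs),
epithelial (EPs), fibroblasts, macrophages, NK, dendritic cells, neutrophils,
T cells, B cells (including CD18, kept as listed in the source panel) and
mast cells.
"""

DEFAULT_MARKER_PANEL: dict[str, tuple[str, ...]] = {
    "ECs": ("CLDN5", "VWF", "PECAM1"),
    "EPs": ("EPCAM", "KRT19", "CDH1", "KRT18", "TPPP3"),
    "Fibroblasts": ("DCN", "COL1A1", "COL1A2"),
    "Macrophages": ("MARCO", "MSR1", "MRC1"),
    "NK cells": ("KLRD1", "NKG7"),
    "DC": ("CLEC9A", "CD1C"),
    "Neutrophils": ("S100A8", "S100A9"),
    "T cells": ("CD2", "CD3D", "CD3E", "CD3G"),
    "B cells": ("CD79A", "CD79B", "CD18"),
    "Mast cells": ("GATA2",),
}
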