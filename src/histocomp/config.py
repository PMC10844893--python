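"""Simulation configuration.

``SimConfig`` fixes every free parameter of the synthetic cohort: gene-panel
size, per-patient cell numbers, planted effect sizes (subtype signatures and
a copy-number gain), platform noise levels, and the ground-truth histological
composition of each patient. One config drives the single-cell, DSP-like and
Visium-like generators so that planted truths are consistent across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .errors import ConfigError

#: Default per-patient (lepidic, acinar, other) ground-truth proportions.
#: Acinar-predominant mixtures with a minority lepidic and a small residual
#: component, the regime reported for resected early-stage LUAD cohorts.
DEFAULT_COMPOSITIONS: tuple[tuple[float, float, float], ...] = (
    (0.50, 0.30, 0.20),
    (0.20, 0.60, 0.20),
    (0.70, 0.20, 0.10),
    (0.10, 0.80, 0.10),
    (0.40, 0.40, 0.20),
    (0.30, 0.50, 0.20),
    (0.60, 0.30, 0.10),
    (0.25, 0.55, 0.20),
)

MT_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

IGG_CONTROLS = ("IgG1", "IgG2a", "IgG2b")


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-platform LUAD study.

    Counts are gamma–Poisson (negative binomial) with gene-level base means
    drawn log-normal; ``nb_dispersion`` is the inverse-size parameter phi in
    Var = mu + phi * mu^2. Subtype signatures are planted as a multiplicative
    ``2**planted_log2fc`` shift, the copy-number gain as ``2**cnv_gain_log2``
    over a contiguous genome-ordered segment.
    """

    n_genes: int = 800
    n_cells_per_patient: int = 1250
    n_patients: int = 8
    n_signature_genes_per_subtype: int = 40
    planted_log2fc: float = 1.5
    nb_dispersion: float = 0.4
    dropout_rate: float = 0.1
    mito_fraction_range: tuple[float, float] = (0.02, 0.12)
    cnv_gain_log2: float = 1.0
    cnv_segment: tuple[str, int, int] = ("chr1", 20, 220)
    truth_compositions: tuple[tuple[float, float, float], ...] = DEFAULT_COMPOSITIONS
    seed: int = 0

    # --- single-cell cohort structure ---
    tumour_sample_fraction: float = 0.5   # share of each patient's cells from tumour tissue
    tumour_purity: float = 0.8            # tumour-epithelial share of the tumour sample
    marker_log2fc: float = 10.0           # on/off lineage markers: ~0.02 -> ~20 counts
    library_sigma: float = 0.3            # per-cell log-normal library size spread
    patient_effect_sigma: float = 0.15    # scalar per-patient batch offset (log scale)

    # --- DSP (GeoMx-like) AOIs: deep aggregate measurements ---
    n_rois_per_region: int = 2
    dsp_nb_dispersion: float = 5e-4
    dsp_base_median: float = 50000.0
    dsp_base_sigma: float = 0.8
    igg_mean: float = 5000.0
    area_range: tuple[float, float] = (16000.0, 60000.0)   # um^2
    nuclei_range: tuple[int, int] = (80, 400)
    aoi_efficiency_sigma: float = 0.3     # per-AOI staining/collection efficiency

    # --- Visium-like spots ---
    n_spots_per_region: int = 100
    visium_nb_dispersion: float = 0.3
    visium_base_median: float = 30.0
    visium_base_sigma: float = 1.0

    # --- genome layout ---
    chrom_block_size: int = 250

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_cells_per_patient", "n_patients",
                     "n_signature_genes_per_subtype"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.planted_log2fc < 0:
            raise ConfigError("planted_log2fc must be >= 0")
        if self.nb_dispersion <= 0 or self.dsp_nb_dispersion <= 0 or self.visium_nb_dispersion <= 0:
            raise ConfigError("dispersion parameters must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigError("dropout_rate must be in [0, 1]")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if not 0.0 < self.tumour_sample_fraction <= 1.0:
            raise ConfigError("tumour_sample_fraction must be in (0, 1]")
        if not 0.0 < self.tumour_purity <= 1.0:
            raise ConfigError("tumour_purity must be in (0, 1]")
        chrom, start, end = self.cnv_segment
        if not (0 <= start < end):
            raise ConfigError("cnv_segment indices must satisfy 0 <= start < end")
        if len(self.truth_compositions) < self.n_patients:
            raise ConfigError(
                f"truth_compositions has {len(self.truth_compositions)} entries "
                f"for {self.n_patients} patients")
        for comp in self.truth_compositions[: self.n_patients]:
            if len(comp) != 3 or any(p < 0 or p > 1 for p in comp):
                raise ConfigError(f"invalid composition {comp!r}")
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ConfigError(f"composition {comp!r} does not sum to 1")

    @property
    def compositions(self) -> tuple[tuple[float, float, float], ...]:
        return tuple(tuple(c) for c in self.truth_compositions[: self.n_patients])

    def to_yaml(self, path) -> None:
        d = asdict(self)
        # YAML round-trips tuples as lists; normalise on load instead
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("mito_fraction_range", "area_range", "nuclei_range", "cnv_segment"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "truth_compositions" in d:
            d["truth_compositions"] = tuple(tuple(c) for c in d["truth_compositions"])
        return cls(**d)
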