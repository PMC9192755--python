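"""Shared constants and tunable parameter blocks.

All image quantities are in pixels unless noted; stain amounts are in
optical-density (OD) units, i.e. -log10 of transmitted fraction, where
Beer-Lambert makes stain contributions additive.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage import color

# --- H-DAB stain basis -----------------------------------------------------
# Published hematoxylin / DAB OD basis (Ruifrok & Johnston) as shipped with
# scikit-image; third row is the residual direction completing the frame.
# Rows are unit-normalized so deconvolved planes are in comparable OD units.
_raw = np.asarray(color.rgb_from_hdx, dtype=float)
STAIN_BASIS_HDX: np.ndarray = _raw / np.linalg.norm(_raw, axis=1, keepdims=True)
del _raw

# Mean membrane DAB OD assigned to each ordinal staining grade.  The 1+/2+/3+
# grades are pathology conventions with no published numeric definition, so
# these anchors are fixed here and shared by the renderer and the default
# positivity cut points below.
INTENSITY_OD = {0: 0.05, 1: 0.30, 2: 0.60, 3: 0.90}

# Positivity cut points: midpoints between adjacent grade anchors, frozen.
# A membrane p90 DAB OD in [T1, T2) is read as 1+, etc.; >= T1 is positive.
OD_CUT_T1 = 0.175
OD_CUT_T2 = 0.45
OD_CUT_T3 = 0.75

# Faint hematoxylin wash over all tissue background.
BACKGROUND_H_OD = 0.05

ANNOTATION_ROLES = ("include", "exclude", "train_tumor", "train_stroma")

CELL_CLASSES = ("tumor", "macrophage", "lymphocyte", "other")
TRUTH_CLASSES = (
    "tumor",
    "tissue_macrophage",
    "alveolar_macrophage",
    "lymphocyte",
    "stromal_other",
)

# Fixed-order feature vector consumed by every classifier.  Order matters:
# models refuse to predict when the hash of this list differs from the one
# recorded at training time.
FEATURE_COLUMNS = (
    "nucleus_area",
    "equiv_diameter",
    "eccentricity",
    "solidity",
    "h_od_mean",
    "h_od_var",
    "mem_dab_mean",
    "mem_dab_p90",
    "cyto_dab_mean",
    "ring_completeness",
    "local_density",
)


def feature_hash(columns=FEATURE_COLUMNS) -> str:
    return hashlib.sha256(";".join(columns).encode()).hexdigest()[:16]


DEFAULT_MICRONS_PER_PIXEL = 0.5  # 20X desk-scale raster


@dataclass(frozen=True)
class SegmentationParams:
    """Nucleus detection and cell-construction parameters."""

    smoothing_sigma: float = 1.0      # px, Gaussian blur of the H plane
    od_threshold: float = 0.25        # H OD above which a pixel is nuclear
    min_area: int = 8                 # px^2, discard smaller components
    max_area: int = 900               # px^2, discard larger components
    min_solidity: float = 0.6
    peak_min_distance: int = 3        # px, watershed seed separation
    ring_width: int = 2               # px, membrane annulus width
    cyto_width: int = 3               # px, cytoplasm annulus beyond the ring
    density_radius: float = 25.0      # px, neighborhood for local density

    def validate(self) -> None:
        if self.min_area >= self.max_area:
            raise ValueError(
                f"degenerate area bounds: min_area={self.min_area} >= "
                f"max_area={self.max_area}"
            )
        if self.ring_width <= 0:
            raise ValueError("ring_width must be positive")


@dataclass(frozen=True)
class QCConfig:
    """Image quality gate thresholds (calibrated on synthetic fixtures)."""

    focus_min_laplacian_var: float = 3.0   # variance of Laplacian, 8-bit units
    tile: int = 64                         # px, tile size for blankness scan
    blank_tile_std_max: float = 1.0        # a tile this flat is "blank"
    blank_tile_mean_min: float = 245.0     # ...if it is also this bright
    blank_area_frac_max: float = 0.30
    saturation_frac_max: float = 0.30      # fraction of pixels at 0 or 255


@dataclass(frozen=True)
class PositivityConfig:
    """Ordinal PD-L1 intensity cut points on membrane p90 DAB OD."""

    t1: float = OD_CUT_T1
    t2: float = OD_CUT_T2
    t3: float = OD_CUT_T3

    def validate(self) -> None:
        if not (self.t1 < self.t2 < self.t3):
            raise ValueError(
                f"cut points must be strictly increasing, got "
                f"({self.t1}, {self.t2}, {self.t3})"
            )


@dataclass(frozen=True)
class CriteriaConfig:
    """Validation pass criteria."""

    identification_rate_min: float = 0.90
    fpr_max: float = 0.10
    fnr_max: float = 0.20
    sample_pass_fraction_min: float = 0.90
    bin_concordance_min: float = 0.90
    icc_min: float = 0.60
    pearson_r_min: float = 0.80


@dataclass
class RunConfig:
    """Full run configuration serialized into every output directory."""

    seed: int = 0
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCConfig = field(default_factory=QCConfig)
    positivity: PositivityConfig = field(default_factory=PositivityConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    compartment_family: str = "random_forest"
    immune_families: tuple = ("random_forest", "logistic")
    denominator_policy: str = "raw"
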