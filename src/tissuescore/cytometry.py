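"""From RGB IHC pixels to a table of cells with stain and morphology features.

Pipeline: Beer-Lambert optical-density conversion and color deconvolution
onto the H-DAB basis; hematoxylin-plane nucleus segmentation (smoothing,
thresholding, watershed split of touching nuclei); construction of a
membrane ring and cytoplasm annulus around each nucleus by label-constrained
dilation; and the fixed-order "cellular biofeature" vector every downstream
classifier consumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

from .config import FEATURE_COLUMNS, STAIN_BASIS_HDX, SegmentationParams
from .slideio import AnnotationSet, SlideImage


@dataclass
class StainPlanes:
    hematoxylin_od: np.ndarray
    dab_od: np.ndarray
    residual_od: np.ndarray
    basis: np.ndarray


@dataclass
class CellImage:
    """A cell table plus the pixel-level masks it was measured from."""

    cells: pd.DataFrame
    nucleus_labels: np.ndarray    # label image, 0 = background
    cell_labels: np.ndarray       # nucleus + ring + cytoplasm partition
    label_of_cell: np.ndarray     # label id per table row


@dataclass
class BackgroundReport:
    mean_dab_od: float
    acceptable: bool
    n_pixels: int


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """OD = -log10((p + 1) / 256) per channel."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def separate_stains(img: SlideImage, stain_basis: np.ndarray | None = None
                    ) -> StainPlanes:
    """Decompose an RGB image into hematoxylin / DAB / residual OD planes.

    ``stain_basis`` rows are the unit RGB-OD signatures of the stains; the
    default is the published H-DAB basis.  Non-negativity by clipping.
    """
    basis = np.asarray(stain_basis if stain_basis is not None
                       else STAIN_BASIS_HDX, dtype=float)
    if basis.shape != (3, 3):
        raise ValueError("stain basis must be 3x3")
    if abs(np.linalg.det(basis)) < 1e-8:
        raise ValueError("singular stain basis")
    od = rgb_to_od(img.pixels)
    conc = od.reshape(-1, 3) @ np.linalg.inv(basis)
    conc = conc.reshape(od.shape)
    # stain amounts are physical and clipped at zero; the residual plane is
    # a signed remainder and stays unclipped so reconstruction is exact
    np.clip(conc[..., :2], 0.0, None, out=conc[..., :2])
    return StainPlanes(hematoxylin_od=conc[..., 0], dab_od=conc[..., 1],
                       residual_od=conc[..., 2], basis=basis)


def detect_nuclei(planes: StainPlanes,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei on the hematoxylin plane.

    Returns a label image of disjoint nuclear masks (0 = background):
    Gaussian smoothing, OD threshold, distance-transform watershed to split
    touching nuclei, then area/solidity filtering.
    """
    p = params or SegmentationParams()
    p.validate()
    smooth = ndi.gaussian_filter(planes.hematoxylin_od, p.smoothing_sigma)
    mask = smooth > p.od_threshold
    mask = remove_small_objects(mask, max_size=p.min_area - 1)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(distance, min_distance=p.peak_min_distance,
                           labels=ndi.label(mask)[0], exclude_border=False)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, seeds, mask=mask)

    out = np.zeros_like(labels)
    next_id = 1
    for r in regionprops(labels):
        if not (p.min_area <= r.area <= p.max_area):
            continue
        if r.solidity < p.min_solidity:
            continue
        out[labels == r.label] = next_id
        next_id += 1
    return out


def _grouped_values(values: np.ndarray, labels: np.ndarray, n_labels: int):
    """Per-label 1-D value arrays, via a single argsort of the label map."""
    flat_l = labels.ravel()
    sel = flat_l > 0
    lab = flat_l[sel]
    val = values.ravel()[sel]
    order = np.argsort(lab, kind="stable")
    lab, val = lab[order], val[order]
    bounds = np.searchsorted(lab, np.arange(1, n_labels + 2))
    return [val[bounds[i]:bounds[i + 1]] for i in range(n_labels)]


def build_cells(planes: StainPlanes, nuclei: np.ndarray,
                params: SegmentationParams | None = None,
                slide_id: str = "") -> CellImage:
    """Measure the feature vector of every detected nucleus.

    The membrane ring is the nucleus dilated by ``ring_width`` px minus the
    nucleus, clipped where neighboring cells compete (label-constrained
    partition); the cytoplasm annulus extends ``cyto_width`` px further.
    Rows are ordered deterministically by (y, x).
    """
    p = params or SegmentationParams()
    p.validate()
    n = int(nuclei.max())
    empty = pd.DataFrame(columns=["cell_id", "slide_id", "x", "y",
                                  *FEATURE_COLUMNS, "compartment",
                                  "pdl1_bin", "cell_class",
                                  "macrophage_subtype"])
    if n == 0:
        return CellImage(cells=empty, nucleus_labels=nuclei,
                         cell_labels=nuclei.copy(),
                         label_of_cell=np.array([], dtype=int))

    ring_part = expand_labels(nuclei, distance=p.ring_width)
    cell_part = expand_labels(nuclei, distance=p.ring_width + p.cyto_width)
    ring_labels = np.where(nuclei == 0, ring_part, 0)
    cyto_labels = np.where(ring_part == 0, cell_part, 0)

    h = planes.hematoxylin_od
    d = planes.dab_od
    h_in_nuc = _grouped_values(h, nuclei, n)
    d_in_ring = _grouped_values(d, ring_labels, n)
    d_in_cyto = _grouped_values(d, cyto_labels, n)

    props = {r.label: r for r in regionprops(nuclei)}
    rows = []
    for lab in range(1, n + 1):
        r = props[lab]
        cy, cx = r.centroid
        hv = h_in_nuc[lab - 1]
        rv = d_in_ring[lab - 1]
        cv = d_in_cyto[lab - 1]
        eq_d = r.equivalent_diameter_area
        eq_r = eq_d / 2.0
        ideal_ring = np.pi * ((eq_r + p.ring_width) ** 2 - eq_r ** 2)
        rows.append((
            lab, cx, cy,
            float(r.area), float(eq_d),
            float(r.eccentricity), float(r.solidity),
            float(hv.mean()), float(hv.var()),
            float(rv.mean()) if len(rv) else 0.0,
            float(np.percentile(rv, 90)) if len(rv) else 0.0,
            float(cv.mean()) if len(cv) else 0.0,
            float(min(len(rv) / max(ideal_ring, 1.0), 1.5)),
            0.0,  # local_density filled below
        ))
    df = pd.DataFrame(rows, columns=["label", "x", "y", *FEATURE_COLUMNS])

    xy = df[["x", "y"]].to_numpy()
    tree = cKDTree(xy)
    df["local_density"] = [len(ix) - 1 for ix in
                           tree.query_ball_point(xy, p.density_radius)]

    df = df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)
    label_of_cell = df.pop("label").to_numpy()
    df.insert(0, "cell_id", np.arange(len(df)))
    df.insert(1, "slide_id", slide_id)
    df["compartment"] = "unassigned"
    df["pdl1_bin"] = -1
    df["cell_class"] = "unassigned"
    df["macrophage_subtype"] = ""
    return CellImage(cells=df, nucleus_labels=nuclei, cell_labels=cell_part,
                     label_of_cell=label_of_cell)


def measure_background(planes: StainPlanes, cell_image: CellImage,
                       annotations: AnnotationSet,
                       od_threshold_1plus: float = 0.175) -> BackgroundReport:
    """Mean DAB OD outside all cell masks, inside inclusion regions.

    Acceptable iff below the 1+ OD threshold (background must stay under
    1+ staining intensity).
    """
    from .compartments import rasterize_roles
    include, exclude = rasterize_roles(annotations,
                                       planes.dab_od.shape)
    sel = include & ~exclude & (cell_image.cell_labels == 0)
    if not sel.any():
        raise ValueError("no background pixels inside inclusion regions")
    mean = float(planes.dab_od[sel].mean())
    return BackgroundReport(mean_dab_od=mean,
                            acceptable=mean < od_threshold_1plus,
                            n_pixels=int(sel.sum()))
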