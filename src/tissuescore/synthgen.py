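"""Synthetic brightfield IHC slides with complete cell-level ground truth.

The generator emulates a PD-L1 (22C3)-stained NSCLC section at desk scale:
tumor cells clustered into nests inside a tumor region, stromal cells and
immune cells (tissue/alveolar macrophages, lymphocytes) outside and within,
hematoxylin-counterstained nuclei and DAB membrane rings whose optical
density increases with the ordinal staining grade.  Rendering happens in
optical-density space and is converted to RGB through Beer-Lambert with the
fixed H-DAB basis, so color deconvolution is exactly invertible at zero
noise.  Paired dual-immunofluorescence images, serial sections and simulated
manual reader scores are generated from the same ground truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import BACKGROUND_H_OD, INTENSITY_OD, STAIN_BASIS_HDX, TRUTH_CLASSES

IF_PANELS = {
    "macrophage": ("CD68", "CD163"),
    "lymphocyte": ("CD3", "CD20"),
}

# Nucleus radius ranges (px) by cell class; lymphocytes are guaranteed
# smaller than tumor cells and macrophages larger -- the morphological
# separability the downstream classifiers rely on.
_RADIUS = {
    "tumor": (5.0, 6.5),
    "stromal_other": (3.5, 4.5),
    "lymphocyte": (2.4, 3.2),
    "tissue_macrophage": (6.5, 8.0),
    "alveolar_macrophage": (8.0, 9.5),
}
# Nuclear hematoxylin OD by class (lymphocytes have dense chromatin).
_NUCLEAR_OD = {
    "tumor": 0.9,
    "stromal_other": 1.0,
    "lymphocyte": 1.3,
    "tissue_macrophage": 0.7,
    "alveolar_macrophage": 0.65,
}
_ECCENTRIC = {"stromal_other": 0.55}  # minor/major axis ratio; others round

TRUTH_COLUMNS = (
    "cell_id", "x", "y", "nucleus_radius", "cell_class",
    "pdl1_intensity", "compartment", "if_markers",
)


@dataclass(frozen=True)
class GroundTruthCell:
    id: int
    center: tuple  # (x, y)
    nucleus_radius: float
    cell_class: str
    pdl1_intensity: int
    compartment: str
    if_markers: frozenset = frozenset()


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Study conditions for one synthetic slide."""

    width: int = 512
    height: int = 512
    n_tumor_cells: int = 250
    n_stromal_cells: int = 150
    n_macrophages: int = 30
    n_lymphocytes: int = 40
    true_tps: float = 30.0            # percent of tumor cells >= 1+
    background_intensity: float = 0.1  # fraction of the 1+ DAB OD
    stain_noise_sd: float = 0.05       # OD units, per pixel per stain
    seed: int = 0
    # generator-internal knobs with fixed defaults
    n_nests: int = 3
    alveolar_fraction: float = 0.4     # of macrophages
    immune_positive_rate: float = 0.3  # P(immune cell is PD-L1 positive)
    intratumoral_macrophage_frac: float = 0.3
    intratumoral_lymphocyte_frac: float = 0.2

    def validate(self) -> None:
        if not (0.0 <= self.true_tps <= 100.0):
            raise ValueError(f"true_tps must be in [0, 100], got {self.true_tps}")
        for name in ("n_tumor_cells", "n_stromal_cells", "n_macrophages",
                     "n_lymphocytes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.background_intensity < 1.0):
            raise ValueError("background_intensity must be in [0, 1)")
        if self.stain_noise_sd < 0:
            raise ValueError("stain_noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedReaderModel:
    """Gaussian reader model for manual TPS scores.

    score = clip(true_tps + bias + reader_offset + read_noise, 0, 100)
    with reader_offset ~ N(0, per_reader_sd) drawn once per reader and
    read_noise ~ N(0, between_read_sd) drawn per (sample, reader, read).
    """

    bias: float = 0.0
    between_read_sd: float = 2.0
    per_reader_sd: float = 1.0
    n_readers: int = 3
    n_reads: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.between_read_sd < 0 or self.per_reader_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        if self.n_readers < 1 or self.n_reads < 1:
            raise ValueError("n_readers and n_reads must be >= 1")


@dataclass(frozen=True)
class IFPair:
    """Two-channel immunofluorescence raster with its true alignment.

    ``transform_true`` maps IF pixel coordinates into brightfield pixel
    coordinates: bf = R(p - c) + c + (dx, dy), rotation about image center c.
    """

    channels: np.ndarray          # (2, H, W) float32
    panel: str                    # "macrophage" or "lymphocyte"
    markers: tuple                # marker name per channel
    dx: float
    dy: float
    rotation: float

    @property
    def center(self):
        h, w = self.channels.shape[1:]
        return ((w - 1) / 2.0, (h - 1) / 2.0)


class CanvasOverflowError(ValueError):
    """Requested cell counts exceed what the canvas can hold."""


# --------------------------------------------------------------------------
# placement

def _grid_sites(mask: np.ndarray, spacing: float, rng: np.random.Generator):
    """Jittered square-grid sites at the True pixels of ``mask``."""
    h, w = mask.shape
    ys = np.arange(spacing / 2, h - spacing / 4, spacing)
    xs = np.arange(spacing / 2, w - spacing / 4, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.uniform(-2.0, 2.0, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 2, w - 3)
    pts[:, 1] = np.clip(pts[:, 1], 2, h - 3)
    ix = pts.astype(int)
    keep = mask[ix[:, 1], ix[:, 0]]
    return pts[keep]


def _nest_layout(spec: SyntheticSlideSpec):
    """Deterministic nest centers as canvas fractions."""
    fracs = [(0.30, 0.32), (0.70, 0.30), (0.46, 0.72), (0.78, 0.72),
             (0.22, 0.72)][: max(1, spec.n_nests)]
    return [(fx * spec.width, fy * spec.height) for fx, fy in fracs]


def _disk_mask(shape, centers, radius):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    m = np.zeros(shape, bool)
    for cx, cy in centers:
        m |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    return m


def _place_cells(spec: SyntheticSlideSpec, rng: np.random.Generator):
    """Return per-class (x, y) positions plus nest geometry.

    Tumor cells sit on a jittered grid inside circular nests; stromal and
    most immune cells on a sparser grid outside; alveolar macrophages in the
    airspace annulus just outside nest borders (tumor compartment).
    """
    shape = (spec.height, spec.width)
    centers = _nest_layout(spec)
    # spacing keeps membrane rings of neighboring cells from overlapping
    tumor_spacing, stroma_spacing = 17.5, 15.0

    n_intra_mac = int(round(spec.n_macrophages
                            * (1 - spec.alveolar_fraction)
                            * spec.intratumoral_macrophage_frac))
    n_alveolar = int(round(spec.n_macrophages * spec.alveolar_fraction))
    n_tissue_mac = spec.n_macrophages - n_alveolar
    n_intra_lym = int(round(spec.n_lymphocytes * spec.intratumoral_lymphocyte_frac))
    need_in_nest = spec.n_tumor_cells + n_intra_mac + n_intra_lym

    # grow nest radius until the grid holds the requested in-nest cells
    max_r = 0.38 * min(spec.width, spec.height)
    nest_r = None
    for r in np.arange(40.0, max_r + 1e-9, 4.0):
        inner = _disk_mask(shape, centers, r - 8)
        sites = _grid_sites(inner, tumor_spacing, rng)
        if len(sites) >= need_in_nest:
            nest_r = r
            nest_sites = sites
            break
    if nest_r is None:
        raise CanvasOverflowError(
            f"cannot place {need_in_nest} in-nest cells at spacing "
            f"{tumor_spacing} px within nests of radius <= {max_r:.0f} px on a "
            f"{spec.width}x{spec.height} canvas; enlarge the canvas or reduce "
            f"counts"
        )
    nest_mask = _disk_mask(shape, centers, nest_r)
    airspace = _disk_mask(shape, centers, nest_r + 16) & ~nest_mask
    stroma_mask = ~_disk_mask(shape, centers, nest_r + 18)

    stroma_sites = _grid_sites(stroma_mask, stroma_spacing, rng)
    air_sites = _grid_sites(airspace, 18.0, rng)

    n_stroma_needed = (spec.n_stromal_cells
                       + (n_tissue_mac - n_intra_mac)
                       + (spec.n_lymphocytes - n_intra_lym))
    if len(stroma_sites) < n_stroma_needed:
        raise CanvasOverflowError(
            f"cannot place {n_stroma_needed} stromal-region cells at spacing "
            f"{stroma_spacing} px on a {spec.width}x{spec.height} canvas with "
            f"{len(stroma_sites)} available sites"
        )
    if len(air_sites) < n_alveolar:
        raise CanvasOverflowError(
            f"cannot place {n_alveolar} alveolar macrophages in the airspace "
            f"annulus ({len(air_sites)} sites)"
        )

    rng.shuffle(nest_sites)
    rng.shuffle(stroma_sites)
    rng.shuffle(air_sites)

    out = {}
    i = 0
    out["tumor"] = nest_sites[i:i + spec.n_tumor_cells]; i += spec.n_tumor_cells
    intra_mac = nest_sites[i:i + n_intra_mac]; i += n_intra_mac
    intra_lym = nest_sites[i:i + n_intra_lym]

    j = 0
    stroma_mac = stroma_sites[j:j + (n_tissue_mac - n_intra_mac)]
    j += n_tissue_mac - n_intra_mac
    stroma_lym = stroma_sites[j:j + (spec.n_lymphocytes - n_intra_lym)]
    j += spec.n_lymphocytes - n_intra_lym
    out["stromal_other"] = stroma_sites[j:j + spec.n_stromal_cells]

    out["tissue_macrophage"] = (
        np.vstack([intra_mac, stroma_mac]) if n_tissue_mac else
        np.empty((0, 2)))
    out["lymphocyte"] = (
        np.vstack([intra_lym, stroma_lym]) if spec.n_lymphocytes else
        np.empty((0, 2)))
    out["alveolar_macrophage"] = air_sites[:n_alveolar]

    tumor_region = _disk_mask(shape, centers, nest_r + 17)
    return out, centers, nest_r, tumor_region


def _assign_intensities(spec, classes, rng):
    """Ordinal PD-L1 grade per cell; exact positive tumor count."""
    n = len(classes)
    grades = np.zeros(n, dtype=int)
    tumor_ix = np.flatnonzero(classes == "tumor")
    n_pos = int(round(spec.true_tps / 100.0 * len(tumor_ix)))
    pos_ix = rng.choice(tumor_ix, size=n_pos, replace=False)
    grades[pos_ix] = rng.choice([1, 2, 3], size=n_pos, p=[0.40, 0.35, 0.25])
    immune = np.isin(classes, ["tissue_macrophage", "alveolar_macrophage",
                               "lymphocyte"])
    im_ix = np.flatnonzero(immune)
    pos = rng.random(len(im_ix)) < spec.immune_positive_rate
    grades[im_ix[pos]] = rng.choice([1, 2], size=pos.sum(), p=[0.6, 0.4])
    return grades


def _assign_markers(classes, rng):
    markers = []
    for c in classes:
        if c in ("tissue_macrophage", "alveolar_macrophage"):
            pick = rng.choice(3, p=[0.4, 0.3, 0.3])
            markers.append((frozenset({"CD68"}), frozenset({"CD163"}),
                            frozenset({"CD68", "CD163"}))[pick])
        elif c == "lymphocyte":
            pick = rng.choice(3, p=[0.5, 0.3, 0.2])
            markers.append((frozenset({"CD3"}), frozenset({"CD20"}),
                            frozenset({"CD3", "CD20"}))[pick])
        else:
            markers.append(frozenset())
    return markers


def build_ground_truth(spec: SyntheticSlideSpec) -> tuple:
    """Place cells and assign classes/grades; no rendering.

    Returns (truth DataFrame with TRUTH_COLUMNS, nest centers, nest radius).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sites, centers, nest_r, _tumor_region = _place_cells(spec, rng)

    rows = []
    for cls in TRUTH_CLASSES:
        pts = sites.get(cls, np.empty((0, 2)))
        lo, hi = _RADIUS[cls]
        radii = rng.uniform(lo, hi, size=len(pts))
        comp = ("tumor" if cls in ("tumor", "alveolar_macrophage") else None)
        for (x, y), r in zip(pts, radii):
            rows.append((x, y, r, cls, comp))
    # intratumoral immune picked up by nest membership
    df = pd.DataFrame(rows, columns=["x", "y", "nucleus_radius", "cell_class",
                                     "compartment"])
    d2 = np.full(len(df), np.inf)
    for cx, cy in centers:
        d2 = np.minimum(d2, (df.x - cx) ** 2 + (df.y - cy) ** 2)
    in_nest = d2 <= nest_r ** 2
    df.loc[df.compartment.isna() & in_nest, "compartment"] = "tumor"
    df.loc[df.compartment.isna(), "compartment"] = "stroma"

    classes = df.cell_class.to_numpy()
    df["pdl1_intensity"] = _assign_intensities(spec, classes, rng)
    df["if_markers"] = _assign_markers(classes, rng)
    df = df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)
    df.insert(0, "cell_id", np.arange(len(df)))
    return df, centers, nest_r


# --------------------------------------------------------------------------
# rendering

def od_to_rgb(h_od: np.ndarray, dab_od: np.ndarray) -> np.ndarray:
    """Beer-Lambert composition of H and DAB OD planes into an 8-bit RGB image."""
    od_rgb = (h_od[..., None] * STAIN_BASIS_HDX[0]
              + dab_od[..., None] * STAIN_BASIS_HDX[1])
    pix = np.round(256.0 * np.power(10.0, -od_rgb) - 1.0)
    return np.clip(pix, 0, 255).astype(np.uint8)


def _render(truth: pd.DataFrame, spec: SyntheticSlideSpec,
            noise_rng: np.random.Generator) -> np.ndarray:
    shape = (spec.height, spec.width)
    h_od = np.full(shape, BACKGROUND_H_OD, dtype=float)
    dab_od = np.full(shape, spec.background_intensity * INTENSITY_OD[1],
                     dtype=float)

    ecc_angle = np.random.default_rng(spec.seed + 1).uniform(
        0, math.pi, size=len(truth))
    H, W = shape
    for i, row in enumerate(truth.itertuples(index=False)):
        r = row.nucleus_radius
        cy, cx = row.y, row.x
        # local window covering the membrane ring
        ext = int(math.ceil(r + 2.0)) + 1
        y0, y1 = max(0, int(cy) - ext), min(H, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(W, int(cx) + ext + 1)
        ly, lx = np.mgrid[y0:y1, x0:x1]
        dy, dx = ly - cy, lx - cx
        d2 = dx * dx + dy * dy
        ratio = _ECCENTRIC.get(row.cell_class)
        if ratio is not None:
            a = ecc_angle[i]
            u = dx * math.cos(a) + dy * math.sin(a)
            v = -dx * math.sin(a) + dy * math.cos(a)
            nucleus = (u / r) ** 2 + (v / max(1.5, r * ratio)) ** 2 <= 1.0
        else:
            nucleus = d2 <= r * r
        h_od[y0:y1, x0:x1][nucleus] += _NUCLEAR_OD[row.cell_class]

        mem_od = INTENSITY_OD[int(row.pdl1_intensity)]
        outer = d2 <= (r + 2.0) ** 2
        if row.cell_class in ("tissue_macrophage", "alveolar_macrophage",
                              "lymphocyte"):
            # immune cells show membrane AND cytoplasm staining
            dab_od[y0:y1, x0:x1][outer] += mem_od
        else:
            dab_od[y0:y1, x0:x1][outer & ~(d2 <= r * r)] += mem_od

    if spec.stain_noise_sd > 0:
        h_od += noise_rng.normal(0.0, spec.stain_noise_sd, size=shape)
        dab_od += noise_rng.normal(0.0, spec.stain_noise_sd, size=shape)
    np.clip(h_od, 0.0, None, out=h_od)
    np.clip(dab_od, 0.0, None, out=dab_od)
    return od_to_rgb(h_od, dab_od)


def _square(cx, cy, half, w, h):
    cx = min(max(cx, half + 2.0), w - half - 3.0)
    cy = min(max(cy, half + 2.0), h - half - 3.0)
    x0, x1 = cx - half, cx + half
    y0, y1 = cy - half, cy + half
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]])


def _annotations(spec, truth, centers, nest_r):
    from .slideio import AnnotationSet  # local import to avoid cycle
    w, h = spec.width, spec.height
    polys = [("include", np.array([[1.0, 1.0], [w - 2.0, 1.0],
                                   [w - 2.0, h - 2.0], [1.0, h - 2.0],
                                   [1.0, 1.0]]))]
    cx, cy = centers[0]
    polys.append(("train_tumor", _square(cx, cy, 52, w, h)))
    # stroma training square: around the stromal cell with the most stromal
    # neighbors, away from nests -- a representative analyst circle
    stroma = truth[truth.cell_class == "stromal_other"]
    if len(stroma):
        from scipy.spatial import cKDTree
        xy = stroma[["x", "y"]].to_numpy()
        counts = np.array([len(ix) for ix in
                           cKDTree(xy).query_ball_point(xy, 62.0)])
        d2 = np.full(len(stroma), np.inf)
        for nx, ny in centers:
            d2 = np.minimum(d2, (xy[:, 0] - nx) ** 2 + (xy[:, 1] - ny) ** 2)
        counts = np.where(d2 > (nest_r + 80.0) ** 2, counts, -1)
        best = stroma.iloc[int(np.argmax(counts))]
        polys.append(("train_stroma", _square(best.x, best.y, 62, w, h)))
    return AnnotationSet(slide_id=f"synthetic-{spec.seed}", polygons=polys)


def generate_slide(spec: SyntheticSlideSpec):
    """Render one synthetic slide.

    Returns ``(SlideImage, truth DataFrame, AnnotationSet)``.  The truth
    table has one row per cell (TRUTH_COLUMNS); exactly
    ``round(true_tps/100 * n_tumor_cells)`` tumor cells carry grade >= 1.
    Identical spec (including seed) yields bit-identical output.
    """
    from .slideio import SlideImage
    truth, centers, nest_r = build_ground_truth(spec)
    noise_rng = np.random.default_rng(spec.seed + 10_000)
    pixels = _render(truth, spec, noise_rng)
    img = SlideImage(pixels=pixels, microns_per_pixel=0.5,
                     slide_id=f"synthetic-{spec.seed}")
    ann = _annotations(spec, truth, centers, nest_r)
    return img, truth, ann


# --------------------------------------------------------------------------
# immunofluorescence

def generate_if_pair(truth: pd.DataFrame, panel: str, shape: tuple,
                     offset=(0.0, 0.0, 0.0), seed: int = 0,
                     blob_sigma: float = 2.5) -> IFPair:
    """Render the dual-IF counterpart of a slide's ground truth.

    ``offset = (dx, dy, rotation)`` is the rigid transform carrying IF
    coordinates into brightfield coordinates (rotation about image center);
    it is recorded on the returned pair as the registration oracle.
    """
    if panel not in IF_PANELS:
        raise ValueError(f"unknown panel {panel!r}; one of {sorted(IF_PANELS)}")
    h, w = shape
    dx, dy, rot = offset
    if abs(dx) > 0.1 * w or abs(dy) > 0.1 * h:
        raise ValueError("offset magnitude exceeds 10% of image extent")
    rng = np.random.default_rng(seed)
    markers = IF_PANELS[panel]
    chans = np.full((2, h, w), 0.02, dtype=np.float32)
    chans += rng.normal(0, 0.005, size=chans.shape).astype(np.float32)

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cos, sin = math.cos(rot), math.sin(rot)
    yy, xx = np.mgrid[0:h, 0:w]
    for ci, marker in enumerate(markers):
        sel = truth[[marker in m for m in truth.if_markers]]
        for row in sel.itertuples(index=False):
            # invert bf = R(p-c)+c+t  ->  p = R^T(bf - c - t) + c
            bx, by = row.x - cx - dx, row.y - cy - dy
            px = cos * bx + sin * by + cx
            py = -sin * bx + cos * by + cy
            if not (0 <= px < w and 0 <= py < h):
                continue
            y0, y1 = max(0, int(py) - 8), min(h, int(py) + 9)
            x0, x1 = max(0, int(px) - 8), min(w, int(px) + 9)
            g = np.exp(-(((xx[y0:y1, x0:x1] - px) ** 2
                          + (yy[y0:y1, x0:x1] - py) ** 2)
                         / (2 * blob_sigma ** 2)))
            chans[ci, y0:y1, x0:x1] += g.astype(np.float32)
    return IFPair(channels=chans, panel=panel, markers=markers,
                  dx=dx, dy=dy, rotation=rot)


# --------------------------------------------------------------------------
# serial sections and readers

def generate_serial_sections(spec: SyntheticSlideSpec, n_sections: int,
                             section_jitter_sd: float, seed: int = 0):
    """Emulate consecutive serial sections of one tissue block.

    All sections share the underlying cell population; each gets small
    independent positional jitter (and 1% cell dropout when jitter > 0).
    Returns a list of ``(SlideImage, truth DataFrame, AnnotationSet)``.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    from .slideio import SlideImage
    base_truth, centers, nest_r = build_ground_truth(spec)
    out = []
    for s in range(n_sections):
        truth = base_truth.copy()
        if section_jitter_sd > 0:
            rng = np.random.default_rng([seed, s])
            truth["x"] = np.clip(
                truth.x + rng.normal(0, section_jitter_sd, len(truth)),
                2, spec.width - 3)
            truth["y"] = np.clip(
                truth.y + rng.normal(0, section_jitter_sd, len(truth)),
                2, spec.height - 3)
            keep = rng.random(len(truth)) > 0.01
            truth = truth[keep].reset_index(drop=True)
        noise_rng = np.random.default_rng(spec.seed + 10_000)
        pixels = _render(truth, spec, noise_rng)
        img = SlideImage(pixels=pixels, microns_per_pixel=0.5,
                         slide_id=f"synthetic-{spec.seed}-s{s}")
        out.append((img, truth, _annotations(spec, truth, centers, nest_r)))
    return out


def generate_reader_scores(true_tps_list, model: SimulatedReaderModel
                           ) -> pd.DataFrame:
    """Simulated manual TPS reads: columns sample, reader, read, score."""
    model.validate()
    if len(true_tps_list) == 0:
        raise ValueError("true_tps_list is empty")
    rng = np.random.default_rng(model.seed)
    offsets = rng.normal(0.0, model.per_reader_sd, size=model.n_readers)
    rows = []
    for si, t in enumerate(true_tps_list):
        for r in range(model.n_readers):
            noise = rng.normal(0.0, model.between_read_sd, size=model.n_reads)
            for k in range(model.n_reads):
                score = float(np.clip(t + model.bias + offsets[r] + noise[k],
                                      0.0, 100.0))
                rows.append((si, r, k, score))
    return pd.DataFrame(rows, columns=["sample", "reader", "read", "score"])


def truth_to_cells(truth: pd.DataFrame) -> list:
    """Materialize GroundTruthCell dataclasses from a truth table."""
    return [GroundTruthCell(id=int(r.cell_id), center=(float(r.x), float(r.y)),
                            nucleus_radius=float(r.nucleus_radius),
                            cell_class=r.cell_class,
                            pdl1_intensity=int(r.pdl1_intensity),
                            compartment=r.compartment,
                            if_markers=frozenset(r.if_markers))
            for r in truth.itertuples(index=False)]
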