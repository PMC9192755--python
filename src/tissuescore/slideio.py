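"""Readers/writers for slide rasters, annotations, cell and score tables,
plus the image quality gate that precedes any analysis.

Formats: RGB slides as PNG or TIFF; dual-IF pairs as 2-page float TIFF;
annotations as GeoJSON FeatureCollections (polygon features with a ``role``
property from a fixed vocabulary); cell/truth/score tables as CSV.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .config import ANNOTATION_ROLES, DEFAULT_MICRONS_PER_PIXEL, QCConfig


@dataclass
class SlideImage:
    pixels: np.ndarray                      # (H, W, 3) uint8
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    slide_id: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"slide image must have 3 channels, got shape "
                f"{self.pixels.shape}")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")


@dataclass
class AnnotationSet:
    slide_id: str
    polygons: list = field(default_factory=list)  # (role, (N,2) float array)

    def by_role(self, role: str):
        return [p for r, p in self.polygons if r == role]


class SchemaError(ValueError):
    """A file violates the documented artifact schema."""


# --------------------------------------------------------------------------
# rasters

def read_slide_image(path, microns_per_pixel: float | None = None,
                     slide_id: str | None = None) -> SlideImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SchemaError(
            f"{path.name}: expected an RGB raster, got shape {arr.shape}")
    return SlideImage(pixels=arr.astype(np.uint8),
                      microns_per_pixel=microns_per_pixel
                      or DEFAULT_MICRONS_PER_PIXEL,
                      slide_id=slide_id or path.stem)


def write_slide_image(img: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        Image.fromarray(img.pixels).save(path)


def write_if_pair(channels: np.ndarray, path) -> None:
    """Two-channel float raster as a 2-page TIFF."""
    tifffile.imwrite(path, np.asarray(channels, dtype=np.float32))


def read_if_pair(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise SchemaError(
            f"{Path(path).name}: expected a 2-page TIFF, got shape {arr.shape}")
    return arr.astype(np.float32)


# --------------------------------------------------------------------------
# annotations (GeoJSON)

def write_annotations(ann: AnnotationSet, path) -> None:
    feats = []
    for role, poly in ann.polygons:
        ring = np.asarray(poly, dtype=float)
        if not np.array_equal(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[:1]])
        feats.append({
            "type": "Feature",
            "properties": {"role": role, "slide_id": ann.slide_id},
            "geometry": {"type": "Polygon",
                         "coordinates": [ring.tolist()]},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=1))


def read_annotations(path) -> AnnotationSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    slide_id = ""
    polys = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        role = props.get("role")
        if role not in ANNOTATION_ROLES:
            raise SchemaError(
                f"feature {i}: unknown role {role!r}; vocabulary is "
                f"{list(ANNOTATION_ROLES)}")
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise SchemaError(f"feature {i}: geometry must be Polygon")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        # closed ring: >= 3 distinct vertices plus the closing repeat
        if len(ring) < 4 or not np.array_equal(ring[0], ring[-1]):
            raise SchemaError(
                f"feature {i}: polygon ring must be closed with >= 3 vertices")
        slide_id = props.get("slide_id", slide_id)
        polys.append((role, ring))
    return AnnotationSet(slide_id=slide_id, polygons=polys)


def full_frame_annotations(width: int, height: int,
                           slide_id: str = "") -> AnnotationSet:
    ring = np.array([[0.0, 0.0], [width - 1.0, 0.0],
                     [width - 1.0, height - 1.0], [0.0, height - 1.0],
                     [0.0, 0.0]])
    return AnnotationSet(slide_id=slide_id, polygons=[("include", ring)])


# --------------------------------------------------------------------------
# tables

_CELL_REQUIRED = ("cell_id", "x", "y")


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _CELL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cell table missing columns {missing}")
    if df.cell_id.duplicated().any():
        raise SchemaError(f"{path}: duplicate cell_id values")
    return df


def write_truth_table(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["if_markers"] = [";".join(sorted(m)) for m in out.if_markers]
    out.to_csv(path, index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["if_markers"] = [frozenset(m.split(";")) - {""}
                        for m in df.if_markers.astype(str)]
    return df


def write_score_table(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"sample", "score"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: score table needs columns {sorted(need)}")
    return df


# --------------------------------------------------------------------------
# quality check

@dataclass
class QCReport:
    passed: bool
    reasons: list
    focus_metric: float
    blank_area_fraction: float
    saturation_fraction: float


def quality_check_image(img: SlideImage, thresholds: QCConfig | None = None
                        ) -> QCReport:
    """Gate a slide on focus, blank/artifact area, and saturation.

    Focus is a variance-of-Laplacian metric on the grayscale image; blank
    area is the fraction covered by bright near-constant tiles (glass, large
    artifacts); saturation the fraction of pixels pinned at 0 or 255.
    """
    qc = thresholds or QCConfig()
    gray = img.pixels.astype(float).mean(axis=2)
    lap = (-4 * gray
           + np.roll(gray, 1, 0) + np.roll(gray, -1, 0)
           + np.roll(gray, 1, 1) + np.roll(gray, -1, 1))
    focus = float(lap[1:-1, 1:-1].var())

    t = qc.tile
    h, w = gray.shape
    blank_tiles = total_tiles = 0
    for y0 in range(0, h - t + 1, t):
        for x0 in range(0, w - t + 1, t):
            tile = gray[y0:y0 + t, x0:x0 + t]
            total_tiles += 1
            if tile.std() < qc.blank_tile_std_max and \
                    tile.mean() > qc.blank_tile_mean_min:
                blank_tiles += 1
    blank_frac = blank_tiles / max(1, total_tiles)

    sat = float(np.mean((img.pixels == 0) | (img.pixels == 255)))

    reasons = []
    if focus < qc.focus_min_laplacian_var:
        reasons.append("focus")
    if blank_frac > qc.blank_area_frac_max:
        reasons.append("blank/artifact area")
    if sat > qc.saturation_frac_max:
        reasons.append("saturation")
    return QCReport(passed=not reasons, reasons=reasons, focus_metric=focus,
                    blank_area_fraction=blank_frac, saturation_fraction=sat)
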