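"""PD-L1 positivity calling and Tumor Proportion Score (TPS).

TPS = 100 x (tumor cells with >= 1+ membrane PD-L1 staining) / (all tumor
cells), binned at the pembrolizumab therapy cut-offs: < 1% no therapy,
>= 1% therapy, >= 50% high-expression therapy.  Per-cell positivity is an
ordinal grade from the 90th percentile of membrane-ring DAB OD against
three monotone cut points; scoring is fully deterministic, so repeated
runs on the same image agree exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import circle_perimeter

from .config import PositivityConfig, RunConfig
from .cytometry import build_cells, detect_nuclei, separate_stains
from .slideio import AnnotationSet, SlideImage, quality_check_image

BIN_NO_THERAPY = "no_therapy_lt1"
BIN_THERAPY = "therapy_ge1"
BIN_THERAPY_HIGH = "therapy_high_ge50"

IMMUNE_CLASSES = ("macrophage", "lymphocyte")


@dataclass
class TPSResult:
    slide_id: str
    n_tumor_cells: int
    n_positive_tumor_cells: int
    tps: float                      # percent; nan when unscorable
    bin: str | None
    denominator_policy: str
    unscorable: bool = False
    reason: str = ""


@dataclass
class ScoreOutput:
    result: TPSResult
    cells: pd.DataFrame
    markup: np.ndarray | None


def classify_pdl1_positivity(cells: pd.DataFrame,
                             config: PositivityConfig | None = None
                             ) -> pd.DataFrame:
    """Set the ordinal pdl1_bin from membrane p90 DAB OD.

    Half-open convention: OD in [t1, t2) is 1+, etc.; an OD exactly at a
    cut point lands in the higher bin.  Positive means bin >= 1.
    """
    cfg = config or PositivityConfig()
    cfg.validate()
    out = cells.copy()
    od = out.mem_dab_p90.to_numpy()
    out["pdl1_bin"] = np.searchsorted(
        np.array([cfg.t1, cfg.t2, cfg.t3]), od, side="right")
    return out


def bin_tps(tps: float) -> str:
    if not (0.0 <= tps <= 100.0):
        raise ValueError(f"TPS outside [0, 100]: {tps}")
    if tps >= 50.0:
        return BIN_THERAPY_HIGH
    if tps >= 1.0:
        return BIN_THERAPY
    return BIN_NO_THERAPY


def compute_tps(cells: pd.DataFrame, policy: str = "raw",
                slide_id: str = "") -> TPSResult:
    """TPS over tumor-compartment cells.

    ``raw`` counts every tumor-compartment cell in the denominator;
    ``immune_corrected`` first removes cells predicted macrophage or
    lymphocyte, counting only tumor cells.  A zero denominator flags the
    result unscorable rather than erroring.
    """
    if policy not in ("raw", "immune_corrected"):
        raise ValueError(f"unknown denominator policy {policy!r}")
    if (cells.pdl1_bin < 0).any():
        raise ValueError("pdl1_bin not assigned; run classify_pdl1_positivity")
    denom = cells[cells.compartment == "tumor"]
    if policy == "immune_corrected":
        denom = denom[~denom.cell_class.isin(IMMUNE_CLASSES)]
    n = len(denom)
    npos = int((denom.pdl1_bin >= 1).sum())
    if n == 0:
        return TPSResult(slide_id=slide_id, n_tumor_cells=0,
                         n_positive_tumor_cells=0, tps=float("nan"),
                         bin=None, denominator_policy=policy,
                         unscorable=True, reason="zero tumor-cell denominator")
    tps = 100.0 * npos / n
    return TPSResult(slide_id=slide_id, n_tumor_cells=n,
                     n_positive_tumor_cells=npos, tps=tps, bin=bin_tps(tps),
                     denominator_policy=policy)


def render_markup(img: SlideImage, cells: pd.DataFrame) -> np.ndarray:
    """Overlay: PD-L1-positive cells circled red, negative blue."""
    out = img.pixels.copy()
    h, w = out.shape[:2]
    scored = cells[cells.compartment == "tumor"]
    for row in scored.itertuples(index=False):
        color = (220, 30, 30) if row.pdl1_bin >= 1 else (40, 60, 220)
        rad = int(round(row.equiv_diameter / 2.0 + 2))
        rr, cc = circle_perimeter(int(round(row.y)), int(round(row.x)),
                                  rad, shape=(h, w))
        out[rr, cc] = color
    return out


def score_slide(img: SlideImage, annotations: AnnotationSet | None,
                compartment_model, config: RunConfig | None = None,
                immune_models=None, markup: bool = True) -> ScoreOutput:
    """Full scoring pipeline for one slide.

    QC gate -> stain separation -> nucleus detection -> feature extraction
    -> compartment assignment -> positivity classification -> (optional
    immune-cell prediction) -> TPS.  Inference has no randomness: identical
    inputs give bit-identical results.
    """
    from .compartments import assign_compartments

    cfg = config or RunConfig()
    qc = quality_check_image(img, cfg.qc)
    if not qc.passed:
        res = TPSResult(slide_id=img.slide_id, n_tumor_cells=0,
                        n_positive_tumor_cells=0, tps=float("nan"), bin=None,
                        denominator_policy=cfg.denominator_policy,
                        unscorable=True,
                        reason="QC failure: " + ", ".join(qc.reasons))
        return ScoreOutput(result=res, cells=pd.DataFrame(), markup=None)

    planes = separate_stains(img)
    nuclei = detect_nuclei(planes, cfg.segmentation)
    ci = build_cells(planes, nuclei, cfg.segmentation, slide_id=img.slide_id)
    cells = assign_compartments(ci.cells, compartment_model, annotations)
    cells = classify_pdl1_positivity(cells, cfg.positivity)
    if immune_models is not None:
        from .immune import predict_immune_cells
        cells = predict_immune_cells(cells, immune_models)
    else:
        cells["cell_class"] = np.where(cells.compartment == "tumor",
                                       "tumor", "other")
    result = compute_tps(cells, cfg.denominator_policy, slide_id=img.slide_id)
    mk = render_markup(img, cells) if markup else None
    return ScoreOutput(result=result, cells=cells, markup=mk)
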