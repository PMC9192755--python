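"""Synthetic validation studies: cohort-level compositions of the slide
generator and the scoring pipeline used to verify the assay's acceptance
criteria (specificity/sensitivity at cell level, TPS recovery and
reportable range, immune-count accuracy and precision).

Every study takes a single integer seed and derives all per-slide seeds
from it, so a study is exactly reproducible end to end.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import (
    CompartmentModel,
    assign_compartments,
    fit_compartment_model,
    harvest_training_cells,
)
from .config import RunConfig
from .cytometry import CellImage, build_cells, detect_nuclei, separate_stains
from .immune import (
    ImmuneModels,
    _dedupe_blobs,
    count_if_positive_cells,
    detect_if_blobs,
    fit_immune_model,
    fit_subtype_head,
    label_from_if,
    match_cells,
    predict_immune_cells,
    register_if_to_brightfield,
)
from .pdl1_scoring import classify_pdl1_positivity, compute_tps
from .synthgen import (
    SyntheticSlideSpec,
    build_ground_truth,
    generate_if_pair,
    generate_serial_sections,
    generate_slide,
)
from .validation import (
    PrecisionResult,
    cell_level_metrics,
    icc_precision,
    icc_simulation_ci,
)


def analyze_slide(img, config: RunConfig | None = None) -> CellImage:
    """Stain separation -> nucleus detection -> feature extraction."""
    cfg = config or RunConfig()
    planes = separate_stains(img)
    nuclei = detect_nuclei(planes, cfg.segmentation)
    return build_cells(planes, nuclei, cfg.segmentation, slide_id=img.slide_id)


def train_compartment_on_slide(spec: SyntheticSlideSpec, seed: int = 0,
                               config: RunConfig | None = None
                               ) -> CompartmentModel:
    """Finalize the tumor/stroma model on one development slide."""
    cfg = config or RunConfig()
    img, _truth, ann = generate_slide(spec)
    ci = analyze_slide(img, cfg)
    labeled = harvest_training_cells(ci.cells, ann)
    return fit_compartment_model(labeled, seed=seed,
                                 family=cfg.compartment_family)


def score_synthetic_slide(spec: SyntheticSlideSpec, model: CompartmentModel,
                          config: RunConfig | None = None,
                          immune_models: ImmuneModels | None = None):
    """Generate + score one slide; returns (TPSResult, cells, truth)."""
    cfg = config or RunConfig()
    img, truth, ann = generate_slide(spec)
    ci = analyze_slide(img, cfg)
    cells = assign_compartments(ci.cells, model, ann)
    cells = classify_pdl1_positivity(cells, cfg.positivity)
    if immune_models is not None:
        cells = predict_immune_cells(cells, immune_models)
    else:
        cells["cell_class"] = np.where(cells.compartment == "tumor",
                                       "tumor", "other")
    res = compute_tps(cells, cfg.denominator_policy, slide_id=img.slide_id)
    return res, cells, truth


# --------------------------------------------------------------------------
# Part-1-style cohort: cell-level specificity/sensitivity + TPS recovery

def run_scoring_cohort(n_slides: int = 20, seed: int = 0,
                       tps_values=None, config: RunConfig | None = None):
    """Score a synthetic cohort against its ground truth.

    One compartment model is finalized on a development slide and applied
    unchanged to every cohort slide (thresholds never change after
    development).  Returns (per-slide DataFrame, CellLevelMetrics).
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    base = int(rng.integers(1, 2**20))
    model = train_compartment_on_slide(
        SyntheticSlideSpec(seed=base + 1000), seed=seed, config=cfg)
    if tps_values is None:
        tps_values = rng.uniform(0, 95, size=n_slides)
    samples = []
    rows = []
    for i in range(n_slides):
        spec = SyntheticSlideSpec(seed=base + i,
                                  true_tps=float(tps_values[i]))
        res, cells, truth = score_synthetic_slide(spec, model, cfg)
        samples.append((cells, truth))
        tumor_truth = truth[truth.cell_class == "tumor"]
        rows.append({
            "slide": i, "true_tps": spec.true_tps, "tps": res.tps,
            "bin": res.bin, "n_tumor_detected": res.n_tumor_cells,
            "n_tumor_true": len(tumor_truth),
        })
    metrics = cell_level_metrics(samples, criteria=cfg.criteria)
    df = pd.DataFrame(rows).merge(metrics.per_sample, left_on="slide",
                                  right_on="sample")
    return df, metrics


def tps_sweep(seed: int = 0, config: RunConfig | None = None) -> pd.DataFrame:
    """Reportable-range sweep: true TPS 0..95 in steps of 5, plus an
    all-positive slide."""
    grid = list(np.arange(0.0, 100.0, 5.0)) + [100.0]
    df, _ = run_scoring_cohort(n_slides=len(grid), seed=seed,
                               tps_values=grid, config=config)
    return df


# --------------------------------------------------------------------------
# Part-3-style immune studies

def _if_offset(rng):
    return (float(rng.uniform(-8, 8)), float(rng.uniform(-8, 8)),
            float(rng.uniform(-0.02, 0.02)))


def _immune_spec(seed, n_mac, n_lym):
    return SyntheticSlideSpec(seed=seed, n_macrophages=int(n_mac),
                              n_lymphocytes=int(n_lym))


def train_immune_models(seed: int = 0, n_train: int = 5, n_verify: int = 2,
                        config: RunConfig | None = None) -> ImmuneModels:
    """Train macrophage/lymphocyte classifiers via the IF label-transfer path.

    Training slides are imaged, their dual-IF counterparts rendered with
    unknown (to the estimator) rigid offsets, co-registered, matched
    cell-to-cell, and labeled from marker positivity; candidate model
    families are then fitted and selected by count agreement on a disjoint
    verification set.  The tissue/alveolar subtype head is trained on the
    generator's subtype labels of the same training slides.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    base = int(rng.integers(2**20, 2**21))
    tables = {"macrophage": [], "lymphocyte": []}
    subtype_rows = []
    for i in range(n_train):
        spec = _immune_spec(base + i, 40, 50)
        img, truth, _ = generate_slide(spec)
        ci = analyze_slide(img, cfg)
        for panel in ("macrophage", "lymphocyte"):
            pair = generate_if_pair(truth, panel,
                                    (spec.height, spec.width),
                                    offset=_if_offset(rng),
                                    seed=base + 100 + i)
            tr = register_if_to_brightfield(pair, ci.cells)
            blobs = _dedupe_blobs(detect_if_blobs(pair))
            matches, _, _ = match_cells(ci.cells, blobs, tr)
            tables[panel].append(label_from_if(ci.cells, blobs, matches,
                                               panel))
        # subtype labels transferred from generator truth by position
        from .validation import _mutual_match
        pairs = _mutual_match(ci.cells[["x", "y"]].to_numpy(),
                              truth[["x", "y"]].to_numpy(), 5.0)
        mac_truth = truth.cell_class.isin(
            ["tissue_macrophage", "alveolar_macrophage"]).to_numpy()
        sel = pairs[mac_truth[pairs[:, 1]]]
        sub = ci.cells.iloc[sel[:, 0]].copy()
        sub["subtype_label"] = [
            "alveolar" if truth.cell_class.iloc[t] == "alveolar_macrophage"
            else "tissue" for t in sel[:, 1]]
        subtype_rows.append(sub)

    verification = {"macrophage": [], "lymphocyte": []}
    for i in range(n_verify):
        spec = _immune_spec(base + 500 + i, 30, 40)
        img, truth, _ = generate_slide(spec)
        ci = analyze_slide(img, cfg)
        verification["macrophage"].append(
            (ci.cells, int(truth.cell_class.isin(
                ["tissue_macrophage", "alveolar_macrophage"]).sum())))
        verification["lymphocyte"].append(
            (ci.cells, int((truth.cell_class == "lymphocyte").sum())))

    mac = fit_immune_model(pd.concat(tables["macrophage"]),
                           verification["macrophage"], "macrophage",
                           families=cfg.immune_families, seed=seed)
    lym = fit_immune_model(pd.concat(tables["lymphocyte"]),
                           verification["lymphocyte"], "lymphocyte",
                           families=cfg.immune_families, seed=seed)
    subtype = fit_subtype_head(pd.concat(subtype_rows), seed=seed)
    from .config import feature_hash
    return ImmuneModels(macrophage=mac, lymphocyte=lym, subtype=subtype,
                        subtype_feature_hash=feature_hash())


def run_immune_accuracy_study(models: ImmuneModels, n_samples: int = 30,
                              seed: int = 0,
                              config: RunConfig | None = None
                              ) -> pd.DataFrame:
    """Predicted vs IF-derived immune counts over a synthetic cohort.

    Macrophage counts vary over 0-80 and lymphocyte counts over 0-120
    across the cohort; each sample contributes the classifier's predicted
    counts on the brightfield image and the stain-identified counts from
    its two dual-IF pairs.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    base = int(rng.integers(2**21, 2**22))
    rows = []
    for i in range(n_samples):
        frac = i / max(n_samples - 1, 1)
        n_mac = int(round(80 * frac))
        n_lym = int(round(120 * frac))
        spec = _immune_spec(base + i, n_mac, n_lym)
        img, truth, _ = generate_slide(spec)
        ci = analyze_slide(img, cfg)
        cells = ci.cells.copy()
        cells["compartment"] = "stroma"
        cells = classify_pdl1_positivity(cells, cfg.positivity)
        cells = predict_immune_cells(cells, models)
        pm = generate_if_pair(truth, "macrophage", (spec.height, spec.width),
                              offset=_if_offset(rng), seed=base + 200 + i)
        pl = generate_if_pair(truth, "lymphocyte", (spec.height, spec.width),
                              offset=_if_offset(rng), seed=base + 400 + i)
        rows.append({
            "sample": i,
            "true_macrophages": int(truth.cell_class.isin(
                ["tissue_macrophage", "alveolar_macrophage"]).sum()),
            "true_lymphocytes": int((truth.cell_class == "lymphocyte").sum()),
            "pred_macrophages": int((cells.cell_class == "macrophage").sum()),
            "pred_lymphocytes": int((cells.cell_class == "lymphocyte").sum()),
            "if_macrophages": count_if_positive_cells(pm, "both"),
            "if_lymphocytes": count_if_positive_cells(pl, "both"),
        })
    return pd.DataFrame(rows)


def run_immune_precision_study(models: ImmuneModels, n_samples: int = 20,
                               n_sections: int = 3,
                               jitter_sd: float = 1.0, seed: int = 0,
                               n_sim: int = 1000,
                               config: RunConfig | None = None) -> dict:
    """ICC of predicted immune counts across serial sections.

    Each sample is one tissue block cut into ``n_sections`` synthetic
    serial sections; predicted macrophage and lymphocyte counts per section
    form the sample x repeat tables whose ICCs (with simulated 95% CIs)
    quantify precision.  Returns {"macrophage": PrecisionResult, ...}.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    base = int(rng.integers(2**22, 2**23))
    mac_tab = np.zeros((n_samples, n_sections))
    lym_tab = np.zeros((n_samples, n_sections))
    for i in range(n_samples):
        n_mac = int(rng.integers(10, 80))
        n_lym = int(rng.integers(15, 120))
        spec = _immune_spec(base + i, n_mac, n_lym)
        sections = generate_serial_sections(spec, n_sections, jitter_sd,
                                            seed=base + 300 + i)
        for s, (img, _truth, _ann) in enumerate(sections):
            ci = analyze_slide(img, cfg)
            cells = ci.cells.copy()
            cells["compartment"] = "stroma"
            cells = classify_pdl1_positivity(cells, cfg.positivity)
            cells = predict_immune_cells(cells, models)
            mac_tab[i, s] = (cells.cell_class == "macrophage").sum()
            lym_tab[i, s] = (cells.cell_class == "lymphocyte").sum()
    out = {}
    for name, tab in (("macrophage", mac_tab), ("lymphocyte", lym_tab)):
        res = icc_precision(tab)
        out[name] = icc_simulation_ci(res, n_sim=n_sim, seed=seed + 7)
    return out
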