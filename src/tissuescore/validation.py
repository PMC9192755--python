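"""CLIA-style validation statistics for the digital assay.

Cell-level sensitivity/specificity against ground truth, treatment-bin
accuracy concordance, precision as an intraclass correlation from a
two-way random-effects variance decomposition with a parametric-simulation
95% CI, Bonferroni-corrected Pearson concordance, average percent error,
and a four-parameter validation report.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .config import CriteriaConfig

RELIABILITY_BINS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"))


# --------------------------------------------------------------------------
# cell-level specificity / sensitivity

@dataclass
class CellLevelMetrics:
    per_sample: pd.DataFrame    # identification_rate, fpr, fnr, passed
    pass_fraction: float
    passed: bool
    criteria: CriteriaConfig


def _mutual_match(pred_xy: np.ndarray, truth_xy: np.ndarray,
                  max_dist: float):
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return np.empty((0, 2), dtype=int)
    pt = cKDTree(pred_xy)
    tt = cKDTree(truth_xy)
    d_pt, nn_pt = tt.query(pred_xy)
    d_tp, nn_tp = pt.query(truth_xy)
    pairs = [(p, int(nn_pt[p])) for p in range(len(pred_xy))
             if nn_tp[nn_pt[p]] == p and d_pt[p] <= max_dist]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def cell_level_metrics(samples, match_dist: float = 5.0,
                       criteria: CriteriaConfig | None = None
                       ) -> CellLevelMetrics:
    """Identification rate and positivity FPR/FNR per sample.

    ``samples`` is a list of (predicted cells, truth table) pairs; cells
    are matched mutual-nearest-neighbor within ``match_dist`` px.  Among
    matched cells, FPR is the fraction of truly PD-L1-negative cells called
    positive and FNR the fraction of truly positive cells called negative.
    A sample passes when identification >= 90%, FPR <= 10% and FNR <= 20%;
    the cohort passes when >= 90% of samples do.
    """
    crit = criteria or CriteriaConfig()
    rows = []
    for i, (pred, truth) in enumerate(samples):
        if len(truth) == 0:
            warnings.warn(f"sample {i}: zero true cells, excluded")
            continue
        pairs = _mutual_match(pred[["x", "y"]].to_numpy(),
                              truth[["x", "y"]].to_numpy(), match_dist)
        ident = len(pairs) / len(truth)
        fpr = fnr = np.nan
        if len(pairs):
            pred_pos = (pred.pdl1_bin.to_numpy()[pairs[:, 0]] >= 1)
            true_pos = (truth.pdl1_intensity.to_numpy()[pairs[:, 1]] >= 1)
            n_neg = int((~true_pos).sum())
            n_pos = int(true_pos.sum())
            if n_neg:
                fpr = float((pred_pos & ~true_pos).sum() / n_neg)
            if n_pos:
                fnr = float((~pred_pos & true_pos).sum() / n_pos)
        ok = (ident >= crit.identification_rate_min
              and (np.isnan(fpr) or fpr <= crit.fpr_max)
              and (np.isnan(fnr) or fnr <= crit.fnr_max))
        rows.append((i, ident, fpr, fnr, ok))
    df = pd.DataFrame(rows, columns=["sample", "identification_rate",
                                     "false_positive_rate",
                                     "false_negative_rate", "passed"])
    if len(df) == 0:
        raise ValueError("no sample had any true cells")
    frac = float(df.passed.mean())
    return CellLevelMetrics(per_sample=df, pass_fraction=frac,
                            passed=frac >= crit.sample_pass_fraction_min,
                            criteria=crit)


# --------------------------------------------------------------------------
# accuracy concordance

def accuracy_concordance(digital_tps, manual_tps, cutoff: float = 1.0,
                         pass_fraction: float = 0.9):
    """Fraction of samples on the same side of the treatment cut-off."""
    digital = np.asarray(digital_tps, dtype=float)
    manual = np.asarray(manual_tps, dtype=float)
    if digital.shape != manual.shape:
        raise ValueError(
            f"length mismatch: {digital.shape} vs {manual.shape}")
    same = (digital >= cutoff) == (manual >= cutoff)
    frac = float(same.mean())
    return frac, frac >= pass_fraction


# --------------------------------------------------------------------------
# precision (ICC)

@dataclass
class PrecisionResult:
    variance_components: dict        # raw sigma^2: sample, repeat, residual
    proportions: dict                # normalized to sum 1
    icc: float                       # 1 - (repeat + residual proportions)
    icc_prose: float                 # 1 - repeat proportion (prose variant)
    ci95: tuple | None
    n_simulations: int
    n_samples: int
    n_repeats: int
    reliability: str
    passed: bool
    degenerate: bool = False

    def with_ci(self, ci95, n_simulations, icc_min=0.6) -> "PrecisionResult":
        passed = self.icc >= icc_min and ci95[0] >= icc_min
        return PrecisionResult(
            variance_components=self.variance_components,
            proportions=self.proportions, icc=self.icc,
            icc_prose=self.icc_prose, ci95=ci95,
            n_simulations=n_simulations, n_samples=self.n_samples,
            n_repeats=self.n_repeats, reliability=self.reliability,
            passed=passed, degenerate=self.degenerate)


def _reliability(icc: float) -> str:
    for hi, name in RELIABILITY_BINS:
        if icc < hi:
            return name
    return "excellent"


def _anova_components(table: np.ndarray):
    """Method-of-moments variance components for a balanced two-way
    (sample x repeat) crossed design with one observation per cell."""
    n, k = table.shape
    grand = table.mean()
    row_m = table.mean(axis=1)
    col_m = table.mean(axis=0)
    ss_s = k * ((row_m - grand) ** 2).sum()
    ss_r = n * ((col_m - grand) ** 2).sum()
    # residual SS computed directly (not by subtraction) so a table with
    # identical repeat columns yields exactly zero
    ss_e = ((table - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    ms_s = ss_s / (n - 1)
    ms_r = ss_r / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    var_e = max(ms_e, 0.0)
    var_s = max((ms_s - ms_e) / k, 0.0)
    var_r = max((ms_r - ms_e) / n, 0.0)
    return var_s, var_r, var_e


def icc_precision(table) -> PrecisionResult:
    """ICC of a sample x repeat score table.

    The random-effects decomposition attributes variance to unique samples,
    the repeat (assessment day), and residual error; the ICC is
    1 - (repeat proportion + residual proportion), i.e. the sample-variance
    proportion; negative moment estimates are truncated at zero before
    normalization.  A constant table is degenerate and yields ICC 1 by
    convention.  Reliability categories: < 0.5 poor, < 0.75 moderate,
    < 0.9 good, else excellent.
    """
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy(dtype=float)
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 repeats")
    n, k = table.shape
    var_s, var_r, var_e = _anova_components(table)
    # flush float dust (e.g. bit-identical repeat columns) to exact zero
    tol = 1e-12 * max(var_s, var_r, var_e, 1e-300)
    var_s, var_r, var_e = (0.0 if v < tol else v
                           for v in (var_s, var_r, var_e))
    total = var_s + var_r + var_e
    degenerate = total <= 0.0
    if degenerate:
        props = {"sample": 1.0, "repeat": 0.0, "residual": 0.0}
    else:
        props = {"sample": var_s / total, "repeat": var_r / total,
                 "residual": var_e / total}
    icc = 1.0 - (props["repeat"] + props["residual"])
    return PrecisionResult(
        variance_components={"sample": var_s, "repeat": var_r,
                             "residual": var_e},
        proportions=props, icc=icc, icc_prose=1.0 - props["repeat"],
        ci95=None, n_simulations=0, n_samples=n, n_repeats=k,
        reliability=_reliability(icc), passed=icc >= 0.6,
        degenerate=degenerate)


def icc_simulation_ci(result: PrecisionResult, n_sim: int = 1000,
                      seed: int = 0, icc_min: float = 0.6
                      ) -> PrecisionResult:
    """Parametric-simulation 95% CI around the ICC estimate.

    Simulates ``n_sim`` score tables at the observed design (same number of
    samples and repeats) from the fitted normal variance components, refits
    the ICC on each, and takes the percentile 2.5/97.5 interval.
    Deterministic given seed.
    """
    vc = result.variance_components
    if all(v <= 0 for v in vc.values()):
        raise ValueError("all variance components are zero; CI undefined")
    n, k = result.n_samples, result.n_repeats
    rng = np.random.default_rng(seed)
    s = rng.normal(0, np.sqrt(vc["sample"]), size=(n_sim, n, 1))
    r = rng.normal(0, np.sqrt(vc["repeat"]), size=(n_sim, 1, k))
    e = rng.normal(0, np.sqrt(vc["residual"]), size=(n_sim, n, k))
    tables = s + r + e

    grand = tables.mean(axis=(1, 2), keepdims=True)
    row_m = tables.mean(axis=2, keepdims=True)
    col_m = tables.mean(axis=1, keepdims=True)
    ss_s = k * ((row_m - grand) ** 2).sum(axis=(1, 2))
    ss_r = n * ((col_m - grand) ** 2).sum(axis=(1, 2))
    ss_tot = ((tables - grand) ** 2).sum(axis=(1, 2))
    ms_s = ss_s / (n - 1)
    ms_r = ss_r / (k - 1)
    ms_e = (ss_tot - ss_s - ss_r) / ((n - 1) * (k - 1))
    var_e = np.maximum(ms_e, 0.0)
    var_s = np.maximum((ms_s - ms_e) / k, 0.0)
    var_r = np.maximum((ms_r - ms_e) / n, 0.0)
    total = var_s + var_r + var_e
    icc = np.where(total > 0, var_s / np.where(total > 0, total, 1.0), 1.0)
    ci = (float(np.percentile(icc, 2.5)), float(np.percentile(icc, 97.5)))
    return result.with_ci(ci, n_sim, icc_min)


# --------------------------------------------------------------------------
# concordance

@dataclass
class ConcordanceResult:
    pairs: list                   # (name, r, p, significant)
    alpha_corrected: float        # exact family_alpha / n_comparisons
    alpha_reported: float         # rounded to 3 decimals for reporting
    bin_concordance_fraction: float | None = None


def pearson_concordance(score_pairs, n_comparisons: int | None = None,
                        family_alpha: float = 0.05) -> ConcordanceResult:
    """Pearson r with Bonferroni-corrected significance per pair.

    ``score_pairs`` is a list of (name, x, y).  The corrected threshold is
    family_alpha / n_comparisons exactly; it is rounded to 3 decimals only
    for reporting (0.05/3 reports as 0.017), never for the decision.
    """
    if n_comparisons is None:
        n_comparisons = len(score_pairs)
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    alpha = family_alpha / n_comparisons
    out = []
    for name, x, y in score_pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3 or len(x) != len(y):
            raise ValueError(
                f"{name}: need >= 3 paired observations, got {len(x)}/{len(y)}")
        r, p = stats.pearsonr(x, y)
        out.append((name, float(r), float(p), bool(p < alpha)))
    return ConcordanceResult(pairs=out, alpha_corrected=alpha,
                             alpha_reported=round(alpha, 3))


def average_percent_error(predicted, truth) -> float:
    """Mean over samples of 100 x (predicted - truth) / truth.

    Negative values mean under-prediction.  Samples with zero truth are
    excluded with a warning; all-zero truth is an error.
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch")
    nz = truth != 0
    if not nz.any():
        raise ValueError("all truth counts are zero")
    if (~nz).any():
        warnings.warn(f"{int((~nz).sum())} samples with zero truth excluded")
    return float(np.mean(100.0 * (predicted[nz] - truth[nz]) / truth[nz]))


# --------------------------------------------------------------------------
# report

def validation_report(cell_metrics: CellLevelMetrics | None = None,
                      background_acceptable_fraction: float | None = None,
                      bin_concordance_fraction: float | None = None,
                      precision: PrecisionResult | None = None,
                      criteria: CriteriaConfig | None = None) -> dict:
    """Four-row validation report (Specificity / Sensitivity / Accuracy /
    Precision) as a JSON-serializable dict; missing inputs are listed and
    the report is emitted as partial."""
    crit = criteria or CriteriaConfig()
    rows = []
    missing = []

    def row(parameter, definition, observed, criterion, passed):
        rows.append({"parameter": parameter, "definition": definition,
                     "observed": observed, "criterion": criterion,
                     "passed": passed})

    if cell_metrics is not None:
        spec_frac = float(np.mean(
            (cell_metrics.per_sample.identification_rate
             >= crit.identification_rate_min)
            & (cell_metrics.per_sample.false_positive_rate.fillna(0)
               <= crit.fpr_max)))
        row("Analytical Specificity",
            "cells identified only when true; PD-L1-negative cells called "
            "negative (FPR <= 10%)",
            spec_frac,
            f">= {crit.sample_pass_fraction_min:.0%} of samples",
            spec_frac >= crit.sample_pass_fraction_min)
        sens_parts = (cell_metrics.per_sample.identification_rate
                      >= crit.identification_rate_min) \
            & (cell_metrics.per_sample.false_negative_rate.fillna(0)
               <= crit.fnr_max)
        sens_frac = float(np.mean(sens_parts))
        if background_acceptable_fraction is not None:
            sens_ok = (sens_frac >= crit.sample_pass_fraction_min
                       and background_acceptable_fraction
                       >= crit.sample_pass_fraction_min)
        else:
            sens_ok = sens_frac >= crit.sample_pass_fraction_min
        row("Analytical Sensitivity",
            "cells identified when present; PD-L1-positive cells called "
            "positive (FNR <= 20%); background under 1+ intensity",
            sens_frac, f">= {crit.sample_pass_fraction_min:.0%} of samples",
            sens_ok)
    else:
        missing += ["Analytical Specificity", "Analytical Sensitivity"]

    if bin_concordance_fraction is not None:
        row("Accuracy",
            "digital and manual TPS agree on the treatment decision "
            "(TPS >= 1% vs < 1%)",
            bin_concordance_fraction,
            f">= {crit.bin_concordance_min:.0%} of samples",
            bin_concordance_fraction >= crit.bin_concordance_min)
    else:
        missing.append("Accuracy")

    if precision is not None:
        ci_ok = precision.ci95 is not None and precision.ci95[0] >= crit.icc_min
        row("Precision",
            "ICC of repeated scoring >= 0.6 with 95% CI lower bound >= 0.6",
            {"icc": precision.icc, "ci95": precision.ci95},
            f"ICC >= {crit.icc_min} (point and CI)",
            precision.icc >= crit.icc_min and ci_ok)
    else:
        missing.append("Precision")

    return {"rows": rows, "missing": missing,
            "all_passed": bool(rows) and not missing
            and all(r["passed"] for r in rows)}


def report_to_text(report: dict) -> str:
    lines = [f"{'Parameter':<26} {'Pass':<6} Observed"]
    for r in report["rows"]:
        lines.append(f"{r['parameter']:<26} "
                     f"{'PASS' if r['passed'] else 'FAIL':<6} "
                     f"{r['observed']}")
    for m in report["missing"]:
        lines.append(f"{m:<26} {'--':<6} missing input")
    return "\n".join(lines)


def report_round_trip(report: dict, path) -> dict:
    from pathlib import Path
    Path(path).write_text(json.dumps(report, indent=1))
    return json.loads(Path(path).read_text())
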