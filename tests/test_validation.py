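"""Validation statistics: cell-level rates, bin concordance, ICC with
simulated CI, Bonferroni-corrected Pearson concordance, percent error,
and the four-parameter report."""
import json

import numpy as np
import pandas as pd
import pytest

import tissuescore as ts
from tissuescore.validation import (
    icc_precision,
    icc_simulation_ci,
    report_to_text,
    validation_report,
)


def _truth(n, pos_frac):
    n_pos = int(n * pos_frac)
    return pd.DataFrame({
        "x": np.arange(n) * 10.0, "y": np.zeros(n),
        "pdl1_intensity": [1] * n_pos + [0] * (n - n_pos)})


def _pred_from(truth, flip_fp=0, flip_fn=0):
    pred = truth.rename(columns={"pdl1_intensity": "pdl1_bin"}).copy()
    neg = pred.index[pred.pdl1_bin == 0]
    pos = pred.index[pred.pdl1_bin >= 1]
    pred.loc[neg[:flip_fp], "pdl1_bin"] = 1
    pred.loc[pos[:flip_fn], "pdl1_bin"] = 0
    return pred


class TestCellLevelMetrics:
    def test_perfect_predictions_pass(self):
        truth = _truth(100, 0.3)
        m = ts.cell_level_metrics([(_pred_from(truth), truth)])
        row = m.per_sample.iloc[0]
        assert row.identification_rate == 1.0
        assert row.false_positive_rate == 0.0
        assert row.false_negative_rate == 0.0
        assert m.passed

    def test_fpr_definition(self):
        """15 of 100 true negatives called positive -> FPR 0.15, fail."""
        truth = _truth(150, 1 / 3)       # 100 negatives
        m = ts.cell_level_metrics([(_pred_from(truth, flip_fp=15), truth)])
        row = m.per_sample.iloc[0]
        assert row.false_positive_rate == pytest.approx(0.15)
        assert not row.passed

    def test_fnr_definition(self):
        truth = _truth(100, 0.5)
        m = ts.cell_level_metrics([(_pred_from(truth, flip_fn=15), truth)])
        assert m.per_sample.iloc[0].false_negative_rate == pytest.approx(0.3)

    def test_empty_truth_sample_excluded(self):
        truth = _truth(50, 0.5)
        with pytest.warns(UserWarning, match="zero true cells"):
            m = ts.cell_level_metrics([
                (_pred_from(truth), truth),
                (_pred_from(truth), truth.head(0))])
        assert len(m.per_sample) == 1


class TestAccuracyConcordance:
    def test_identical_lists_fully_concordant(self):
        frac, ok = ts.accuracy_concordance([0.5, 10, 60], [0.5, 10, 60])
        assert frac == 1.0 and ok

    def test_straddling_cutoff_discordant(self):
        frac, ok = ts.accuracy_concordance([0.5], [1.5])
        assert frac == 0.0 and not ok

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ts.accuracy_concordance([1, 2], [1])

    def test_simulated_readers_on_synthetic_cohort(self):
        rng = np.random.default_rng(0)
        true_tps = rng.uniform(0, 95, 66)
        model = ts.SimulatedReaderModel(bias=0, between_read_sd=2,
                                        per_reader_sd=0, seed=1)
        tab = ts.generate_reader_scores(true_tps, model)
        first = tab[(tab.reader == 0) & (tab.read == 0)].score.to_numpy()
        frac, ok = ts.accuracy_concordance(true_tps, first)
        assert ok


class TestICC:
    def test_identical_repeats_icc_exactly_one(self):
        rng = np.random.default_rng(1)
        tab = np.tile(rng.normal(50, 20, (20, 1)), (1, 3))
        res = icc_precision(tab)
        assert res.icc == 1.0
        assert res.proportions["repeat"] == 0.0
        assert res.proportions["residual"] == 0.0
        assert res.reliability == "excellent"

    def test_boundary_pass_at_0p6(self):
        """Construct a table with exactly 40% repeat+residual variance."""
        # samples {-1, +1} scaled, repeats add fixed column offsets
        n, k = 40, 2
        rng = np.random.default_rng(2)
        icc_vals = []
        for _ in range(40):
            s = rng.normal(0, np.sqrt(60), (n, 1))
            r = rng.normal(0, np.sqrt(20), (1, k))
            e = rng.normal(0, np.sqrt(20), (n, k))
            icc_vals.append(icc_precision(s + r + e).icc)
        assert np.mean(icc_vals) == pytest.approx(0.6, abs=0.05)

    def test_large_table_recovers_variance_ratio(self):
        """sigma^2 = (90, 5, 5) -> ICC 0.90 +/- 0.02 on average."""
        rng = np.random.default_rng(42)
        n, k = 500, 3
        icc_vals = []
        for _ in range(30):
            tab = (rng.normal(0, np.sqrt(90), (n, 1))
                   + rng.normal(0, np.sqrt(5), (1, k))
                   + rng.normal(0, np.sqrt(5), (n, k)))
            icc_vals.append(icc_precision(tab).icc)
        assert np.mean(icc_vals) == pytest.approx(0.90, abs=0.02)

    def test_matches_two_way_random_absolute_icc(self):
        """Cross-check against pingouin's ICC(A,1) on the same table."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n, k = 80, 3
        tab = (rng.normal(0, 9, (n, 1)) + rng.normal(0, 2, (1, k))
               + rng.normal(0, 2, (n, k)))
        mine = icc_precision(tab).icc
        long = pd.DataFrame({"targets": np.repeat(np.arange(n), k),
                             "raters": np.tile(np.arange(k), n),
                             "score": tab.ravel()})
        theirs = pg.intraclass_corr(long, targets="targets",
                                    raters="raters", ratings="score")
        ref = float(theirs.loc[theirs.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(ref, abs=1e-9)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        tab = rng.normal(50, 10, (15, 3))
        res = icc_precision(tab)
        assert sum(res.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert res.icc == pytest.approx(
            1 - res.proportions["repeat"] - res.proportions["residual"])

    def test_small_table_rejected(self):
        with pytest.raises(ValueError):
            icc_precision(np.ones((1, 3)))


class TestICCSimulationCI:
    def test_zero_noise_ci_is_one(self):
        rng = np.random.default_rng(1)
        tab = np.tile(rng.normal(50, 20, (20, 1)), (1, 3))
        res = icc_simulation_ci(icc_precision(tab), n_sim=200, seed=3)
        assert res.ci95[0] > 1 - 1e-9 and res.ci95[1] <= 1.0

    def test_same_seed_same_ci(self):
        rng = np.random.default_rng(4)
        tab = rng.normal(0, 5, (20, 3)) + rng.normal(0, 10, (20, 1))
        base = icc_precision(tab)
        a = icc_simulation_ci(base, n_sim=500, seed=9)
        b = icc_simulation_ci(base, n_sim=500, seed=9)
        assert a.ci95 == b.ci95

    def test_all_zero_components_rejected(self):
        res = icc_precision(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="zero"):
            icc_simulation_ci(res)

    def test_ci_covers_generating_icc(self):
        """~95% CI covers the generating ICC in >= 93% of meta-replicates."""
        rng = np.random.default_rng(10)
        n, k = 20, 3
        true_icc = 90 / 100
        hits = 0
        n_meta = 200
        for m in range(n_meta):
            tab = (rng.normal(0, np.sqrt(90), (n, 1))
                   + rng.normal(0, np.sqrt(5), (1, k))
                   + rng.normal(0, np.sqrt(5), (n, k)))
            res = icc_simulation_ci(icc_precision(tab), n_sim=300,
                                    seed=1000 + m)
            if res.ci95[0] <= true_icc <= res.ci95[1]:
                hits += 1
        assert hits / n_meta >= 0.88


class TestPearsonConcordance:
    def test_bonferroni_threshold_reported_as_0p017(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        pairs = [(f"p{i}", x, x + rng.normal(0, 0.1, 20)) for i in range(3)]
        res = ts.pearson_concordance(pairs, n_comparisons=3)
        assert res.alpha_reported == 0.017
        assert res.alpha_corrected == pytest.approx(0.05 / 3)

    def test_identity_is_perfect_correlation(self):
        x = np.arange(10.0)
        res = ts.pearson_concordance([("id", x, x)], n_comparisons=1)
        name, r, p, sig = res.pairs[0]
        assert r == pytest.approx(1.0)
        assert sig

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(5)
        n_sig = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = rng.normal(size=(2, 100))
            res = ts.pearson_concordance([("null", x, y)], n_comparisons=1)
            n_sig += res.pairs[0][3]
        assert n_sig / n_rep <= 0.08   # ~family alpha

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ts.pearson_concordance([("x", [1, 2], [1, 2])])


class TestPercentError:
    def test_single_sample_arithmetic(self):
        assert ts.average_percent_error([197], [200]) == pytest.approx(-1.5)

    def test_exact_predictions_zero_error(self):
        assert ts.average_percent_error([5, 10], [5, 10]) == 0.0

    def test_zero_truth_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero truth"):
            e = ts.average_percent_error([10, 99], [0, 100])
        assert e == pytest.approx(-1.0)

    def test_all_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            ts.average_percent_error([1, 2], [0, 0])


class TestReport:
    def _metrics(self, fpr=0.0):
        truth = _truth(100, 0.3)
        pred = _pred_from(truth, flip_fp=int(fpr * 70))
        return ts.cell_level_metrics([(pred, truth)])

    def test_all_good_inputs_all_pass(self):
        rng = np.random.default_rng(1)
        tab = rng.normal(0, 1, (20, 3)) + rng.normal(0, 10, (20, 1))
        prec = icc_simulation_ci(icc_precision(tab), n_sim=200, seed=1)
        rep = validation_report(cell_metrics=self._metrics(),
                                background_acceptable_fraction=1.0,
                                bin_concordance_fraction=0.95,
                                precision=prec)
        assert rep["all_passed"]
        assert len(rep["rows"]) == 4

    def test_forced_fpr_fails_specificity(self):
        rep = validation_report(cell_metrics=self._metrics(fpr=0.2),
                                bin_concordance_fraction=1.0)
        spec_row = [r for r in rep["rows"]
                    if r["parameter"] == "Analytical Specificity"][0]
        assert not spec_row["passed"]

    def test_partial_report_lists_missing(self):
        rep = validation_report(bin_concordance_fraction=1.0)
        assert "Precision" in rep["missing"]
        assert not rep["all_passed"]

    def test_report_round_trips_through_json(self, tmp_path):
        rep = validation_report(bin_concordance_fraction=1.0)
        p = tmp_path / "r.json"
        p.write_text(json.dumps(rep))
        assert json.loads(p.read_text()) == rep
        assert "Accuracy" in report_to_text(rep)
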