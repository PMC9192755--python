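"""IF co-registration, cell matching, label transfer, model selection and
immune-cell prediction."""
import numpy as np
import pandas as pd
import pytest

import tissuescore as ts
from tissuescore.config import FEATURE_COLUMNS
from tissuescore.immune import (
    FeatureHashError,
    RegistrationError,
    _dedupe_blobs,
    detect_if_blobs,
    immune_counts,
)
from tissuescore.studies import analyze_slide
from tissuescore.synthgen import build_ground_truth, generate_if_pair


@pytest.fixture(scope="module")
def bf_and_truth():
    spec = ts.SyntheticSlideSpec(seed=21, n_macrophages=35, n_lymphocytes=45)
    img, truth, _ = ts.generate_slide(spec)
    return analyze_slide(img), truth


class TestRegistration:
    @pytest.mark.parametrize("offset", [(0, 0, 0), (5, -3, 0.01)])
    def test_recovers_generator_transform(self, bf_and_truth, offset):
        ci, truth = bf_and_truth
        pair = generate_if_pair(truth, "macrophage", (512, 512),
                                offset=offset, seed=4)
        tr = ts.register_if_to_brightfield(pair, ci.cells)
        assert abs(tr.dx - offset[0]) < 0.5
        assert abs(tr.dy - offset[1]) < 0.5
        assert abs(tr.rotation - offset[2]) < 0.005

    def test_robust_to_half_blobs_missing(self, bf_and_truth):
        ci, truth = bf_and_truth
        rng = np.random.default_rng(0)
        # drop half of the marker-bearing cells before rendering
        macs = truth[truth.cell_class.isin(
            ["tissue_macrophage", "alveolar_macrophage"])]
        keep = truth.drop(macs.sample(frac=0.5, random_state=1).index)
        pair = generate_if_pair(keep, "macrophage", (512, 512),
                                offset=(4, 6, 0.0), seed=5)
        tr = ts.register_if_to_brightfield(pair, ci.cells)
        assert abs(tr.dx - 4) < 1.0 and abs(tr.dy - 6) < 1.0

    def test_too_few_blobs_rejected(self, bf_and_truth):
        ci, truth = bf_and_truth
        lonely = truth[truth.cell_class == "tumor"].head(2)
        pair = generate_if_pair(lonely, "macrophage", (512, 512), seed=6)
        with pytest.raises(RegistrationError, match="blobs"):
            ts.register_if_to_brightfield(pair, ci.cells)


class TestMatching:
    def test_identity_perfect_matching(self):
        pts = pd.DataFrame({"x": [10.0, 50.0, 90.0], "y": [10.0, 50.0, 90.0]})
        blobs = pts.assign(markers=[frozenset({"CD68"})] * 3)
        tr = ts.RigidTransform(0, 0, 0)
        m, ub, ui = ts.match_cells(pts, blobs, tr, max_dist=2)
        assert len(m) == 3 and not ub and not ui

    def test_extra_blob_left_unmatched(self):
        cells = pd.DataFrame({"x": [10.0, 50.0], "y": [10.0, 50.0]})
        blobs = pd.DataFrame({"x": [10.0, 50.0, 200.0],
                              "y": [10.0, 50.0, 200.0],
                              "markers": [frozenset({"CD68"})] * 3})
        m, ub, ui = ts.match_cells(cells, blobs, ts.RigidTransform(0, 0, 0),
                                   max_dist=2)
        assert len(m) == 2 and ui == [2]

    def test_most_marker_cells_matched(self, bf_and_truth):
        ci, truth = bf_and_truth
        pair = generate_if_pair(truth, "macrophage", (512, 512),
                                offset=(3, -2, 0.005), seed=7)
        tr = ts.register_if_to_brightfield(pair, ci.cells)
        blobs = _dedupe_blobs(detect_if_blobs(pair))
        m, _, _ = ts.match_cells(ci.cells, blobs, tr, max_dist=5)
        n_marked = truth.cell_class.isin(
            ["tissue_macrophage", "alveolar_macrophage"]).sum()
        assert len(m) >= 0.95 * n_marked


class TestLabelTransfer:
    def _setup(self):
        cells = pd.DataFrame({"x": [0.0, 10.0, 20.0], "y": [0.0] * 3})
        blobs = pd.DataFrame({
            "x": [0.0, 20.0], "y": [0.0, 0.0],
            "markers": [frozenset({"CD163"}), frozenset({"CD3"})]})
        matches = pd.DataFrame({"bf_index": [0, 2], "if_index": [0, 1],
                                "distance": [0.0, 0.0]})
        return cells, blobs, matches

    def test_cd163_only_is_macrophage(self):
        cells, blobs, matches = self._setup()
        out = ts.label_from_if(cells, blobs, matches, "macrophage")
        assert out.immune_label.iloc[0] == "macrophage"

    def test_unmatched_cell_is_negative(self):
        cells, blobs, matches = self._setup()
        out = ts.label_from_if(cells, blobs, matches, "macrophage")
        assert out.immune_label.iloc[1] == "non-macrophage"

    def test_foreign_marker_is_negative_under_panel(self):
        cells, blobs, matches = self._setup()
        out = ts.label_from_if(cells, blobs, matches, "macrophage")
        assert out.immune_label.iloc[2] == "non-macrophage"  # CD3 blob


class TestModelSelection:
    def _train_ver(self, immune_models):
        spec = ts.SyntheticSlideSpec(seed=31, n_macrophages=30,
                                     n_lymphocytes=30)
        img, truth, _ = ts.generate_slide(spec)
        ci = analyze_slide(img)
        from tissuescore.validation import _mutual_match
        pairs = _mutual_match(ci.cells[["x", "y"]].to_numpy(),
                              truth[["x", "y"]].to_numpy(), 5.0)
        lab = ci.cells.iloc[pairs[:, 0]].copy()
        is_mac = truth.cell_class.to_numpy()[pairs[:, 1]]
        lab["immune_label"] = np.where(
            np.isin(is_mac, ["tissue_macrophage", "alveolar_macrophage"]),
            "macrophage", "non-macrophage")
        true_count = int((lab.immune_label == "macrophage").sum())
        return lab, [(lab, true_count)]

    def test_constant_model_never_beats_discriminative(self, immune_models):
        train, ver = self._train_ver(immune_models)
        model = ts.fit_immune_model(
            train, ver, "macrophage",
            families=("constant_negative", "random_forest"), seed=0)
        assert model.family == "random_forest"
        rep = dict(zip(model.selection_report.family,
                       model.selection_report.verification_error))
        assert rep["constant_negative"] == 100.0

    def test_selection_deterministic(self, immune_models):
        train, ver = self._train_ver(immune_models)
        m1 = ts.fit_immune_model(train, ver, "macrophage", seed=5)
        m2 = ts.fit_immune_model(train, ver, "macrophage", seed=5)
        assert m1.family == m2.family
        pd.testing.assert_frame_equal(m1.selection_report,
                                      m2.selection_report)

    def test_empty_verification_rejected(self, immune_models):
        train, _ = self._train_ver(immune_models)
        with pytest.raises(ValueError, match="verification"):
            ts.fit_immune_model(train, [], "macrophage")


class TestPrediction:
    def test_no_immune_cells_low_false_positives(self, immune_models):
        spec = ts.SyntheticSlideSpec(seed=41, n_macrophages=0,
                                     n_lymphocytes=0)
        img, truth, _ = ts.generate_slide(spec)
        cells = analyze_slide(img).cells.copy()
        cells["compartment"] = "stroma"
        cells = ts.classify_pdl1_positivity(cells)
        cells = ts.predict_immune_cells(cells, immune_models)
        n_imm = cells.cell_class.isin(["macrophage", "lymphocyte"]).sum()
        assert n_imm <= 0.10 * len(cells)

    def test_counts_near_truth(self, immune_models):
        spec = ts.SyntheticSlideSpec(seed=42, n_macrophages=40,
                                     n_lymphocytes=60)
        img, truth, _ = ts.generate_slide(spec)
        cells = analyze_slide(img).cells.copy()
        cells["compartment"] = "stroma"
        cells = ts.classify_pdl1_positivity(cells)
        cells = ts.predict_immune_cells(cells, immune_models)
        n_mac = (cells.cell_class == "macrophage").sum()
        assert abs(n_mac - 40) <= 0.10 * 40 + 2

    def test_prediction_never_touches_pdl1_bin(self, immune_models):
        spec = ts.SyntheticSlideSpec(seed=43)
        img, _t, _ = ts.generate_slide(spec)
        cells = analyze_slide(img).cells.copy()
        cells["compartment"] = "stroma"
        cells = ts.classify_pdl1_positivity(cells)
        before = cells.pdl1_bin.copy()
        after = ts.predict_immune_cells(cells, immune_models)
        assert (after.pdl1_bin.to_numpy() == before.to_numpy()).all()

    def test_positive_macrophage_in_positive_tally(self, immune_models):
        spec = ts.SyntheticSlideSpec(seed=44, n_macrophages=40,
                                     immune_positive_rate=1.0)
        img, _t, _ = ts.generate_slide(spec)
        cells = analyze_slide(img).cells.copy()
        cells["compartment"] = "stroma"
        cells = ts.classify_pdl1_positivity(cells)
        cells = ts.predict_immune_cells(cells, immune_models)
        tally = immune_counts(cells)
        mac = tally[tally.cell_class == "macrophage"]
        pos = mac[mac.pdl1_status == "positive"]["count"].sum()
        assert pos >= 0.7 * mac["count"].sum()

    def test_feature_hash_mismatch_refused(self, immune_models, analyzed):
        import dataclasses
        bad = dataclasses.replace(immune_models.macrophage,
                                  feature_hash="stale")
        with pytest.raises(FeatureHashError):
            bad.predict(analyzed.cells)


class TestIFCounting:
    def test_blank_channel_counts_zero(self):
        truth, _, _ = build_ground_truth(
            ts.SyntheticSlideSpec(seed=2, n_lymphocytes=0))
        pair = generate_if_pair(truth, "lymphocyte", (512, 512), seed=1)
        assert ts.count_if_positive_cells(pair, "both") == 0

    def test_lymphocyte_count_near_truth(self):
        truth, _, _ = build_ground_truth(
            ts.SyntheticSlideSpec(seed=3, n_lymphocytes=30))
        pair = generate_if_pair(truth, "lymphocyte", (512, 512), seed=2)
        assert abs(ts.count_if_positive_cells(pair, "both") - 30) <= 2

    def test_double_positive_counted_once(self):
        truth = pd.DataFrame({
            "cell_id": [0], "x": [100.0], "y": [100.0],
            "nucleus_radius": [8.0], "cell_class": ["tissue_macrophage"],
            "pdl1_intensity": [0], "compartment": ["stroma"],
            "if_markers": [frozenset({"CD68", "CD163"})]})
        pair = generate_if_pair(truth, "macrophage", (256, 256), seed=3)
        assert ts.count_if_positive_cells(pair, "both") == 1
        assert ts.count_if_positive_cells(pair, "CD68") == 1

    def test_unknown_channel_rejected(self):
        truth, _, _ = build_ground_truth(ts.SyntheticSlideSpec(seed=2))
        pair = generate_if_pair(truth, "macrophage", (512, 512), seed=1)
        with pytest.raises(ValueError, match="channel"):
            ts.count_if_positive_cells(pair, "CD3")
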