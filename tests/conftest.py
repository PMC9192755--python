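"""Shared fixtures: one default synthetic slide analyzed end to end, plus
trained compartment and immune models.  Session-scoped because rendering
and training dominate test runtime."""
from __future__ import annotations

import numpy as np
import pytest

import tissuescore as ts
from tissuescore.studies import analyze_slide, train_immune_models


@pytest.fixture(scope="session")
def default_spec():
    return ts.SyntheticSlideSpec(seed=1, true_tps=40.0)


@pytest.fixture(scope="session")
def default_slide(default_spec):
    """(SlideImage, truth DataFrame, AnnotationSet) for the default spec."""
    return ts.generate_slide(default_spec)


@pytest.fixture(scope="session")
def analyzed(default_slide):
    """CellImage of the default slide."""
    img, _truth, _ann = default_slide
    return analyze_slide(img)


@pytest.fixture(scope="session")
def compartment_model(analyzed, default_slide):
    _img, _truth, ann = default_slide
    labeled = ts.harvest_training_cells(analyzed.cells, ann)
    return ts.fit_compartment_model(labeled, seed=0)


@pytest.fixture(scope="session")
def scored_cells(analyzed, default_slide, compartment_model):
    _img, _truth, ann = default_slide
    cells = ts.assign_compartments(analyzed.cells, compartment_model, ann)
    return ts.classify_pdl1_positivity(cells)


@pytest.fixture(scope="session")
def immune_models():
    return train_immune_models(seed=3, n_train=3, n_verify=2)


@pytest.fixture(scope="session")
def matched_pairs(scored_cells, default_slide):
    """Mutual-NN (pred_index, truth_index) pairs on the default slide."""
    from tissuescore.validation import _mutual_match
    _img, truth, _ann = default_slide
    pairs = _mutual_match(scored_cells[["x", "y"]].to_numpy(),
                          truth[["x", "y"]].to_numpy(), 5.0)
    return pairs
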