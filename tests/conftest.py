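"""Shared fixtures: the default synthetic truth and small fitted panels."""

import warnings

import numpy as np
import pytest

import healthmarkov as hm


@pytest.fixture(scope="session")
def truth():
    return hm.make_default_truth(seed=1)


@pytest.fixture(scope="session")
def small_panel(truth):
    return hm.simulate_panel(truth, 300, seed=3)


@pytest.fixture(scope="session")
def small_model(small_panel):
    return hm.LatentHealthModel(small_panel)


@pytest.fixture(scope="session")
def small_fit(small_model):
    """One converged EM fit on the 300-individual panel, labelled."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = small_model.fit(init="kmeans", tol=1e-6, max_iter=200, seed=0)
    assert res.converged
    return res.label_states()


@pytest.fixture(scope="session")
def short_panel(truth):
    """A 5-year panel: short enough for brute-force path enumeration."""
    return hm.simulate_panel(truth, 40, design=hm.PanelDesign(n_years=5), seed=7)


@pytest.fixture(scope="session")
def short_arrays(truth, short_panel):
    return short_panel.to_arrays(truth.covariates)


@pytest.fixture(scope="session")
def calibrated_specs(truth):
    specs, _ = hm.calibrate_all(truth)
    return specs


@pytest.fixture(scope="session")
def ref_row():
    """Baseline good-health transition row for men at 75."""
    return np.array([0.87, 0.07, 0.04, 0.02])
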