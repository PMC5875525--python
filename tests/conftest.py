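"""Shared fixtures: rendered phantom volumes are expensive, so the
standard CT-like and CBCT-like renders (and their analysis sessions)
are computed once per test run."""

from __future__ import annotations

import pytest

from acrqa.metrics import run_session
from acrqa.synthetic import cbct_preset, ct_preset, render_phantom


@pytest.fixture(scope="session")
def ct_render():
    cfg = ct_preset(seed=11)
    series, truth = render_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def cbct_render():
    cfg = cbct_preset(seed=12)
    series, truth = render_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def noiseless_render():
    cfg = ct_preset(seed=13, noise_sigma=0.0)
    series, truth = render_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def ct_session(ct_render):
    _, series, _ = ct_render
    return run_session(series)


@pytest.fixture(scope="session")
def cbct_session(cbct_render):
    _, series, _ = cbct_render
    return run_session(series)


@pytest.fixture(scope="session")
def noiseless_session(noiseless_render):
    _, series, _ = noiseless_render
    return run_session(series)
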