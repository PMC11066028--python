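"""Shared fixtures.

The demo pipeline (12-protein synthetic panel, reduced network) is expensive
(a few minutes of CPU), so it runs once per session and its report/artifacts
are shared by the end-to-end and acceptance tests.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from cellfp.pipeline import run_pipeline

DEMO_SEED = 1


@pytest.fixture(scope="session")
def demo_report():
    """Full pipeline run on the demo configuration (seed 1)."""
    t0 = time.time()
    report = run_pipeline({"seed": DEMO_SEED})
    report["wall_time_s"] = time.time() - t0
    return report


@pytest.fixture(scope="session")
def demo_artifacts(demo_report):
    return demo_report["artifacts"]


@pytest.fixture(scope="session")
def demo_model(demo_artifacts):
    return demo_artifacts["model"]


@pytest.fixture(scope="session")
def demo_crops(demo_artifacts):
    return demo_artifacts["crops"]


@pytest.fixture(scope="session")
def demo_panel(demo_artifacts):
    return demo_artifacts["panel"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
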