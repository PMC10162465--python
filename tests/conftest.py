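"""Shared fixtures.

The session-scoped ``small_pipeline`` fixture runs the full feature
extraction once on a reduced synthetic block and is shared by every test
that needs end-to-end artifacts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from koopstream import PipelineConfig, run_pipeline
from koopstream.synthetic import SynthParams, simulate_block

#: reduced-scale study conditions used across the suite
SMALL = dict(block_duration=60.0, seed=1)


@pytest.fixture(scope="session")
def small_block():
    params = SynthParams(**SMALL)
    timeline, rec = simulate_block(params)
    return params, timeline, rec


@pytest.fixture(scope="session")
def small_pipeline(small_block):
    params, timeline, rec = small_block
    cfg = PipelineConfig(s=199, n_eigs=60, n_perm=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = run_pipeline(rec, cfg, timeline)
    return params, timeline, rec, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
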