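"""Shared fixtures: one default synthetic site, preprocessed once."""

from __future__ import annotations

import numpy as np
import pytest

import ptbmetab as p


@pytest.fixture(scope="session")
def cork_cohort():
    """Default study-condition cohort (planted trio + bleeding effect)."""
    cfg = p.cork_like_config(seed=7)
    clinical, m15, m20 = p.generate_cohort(cfg)
    return cfg, clinical, m15, m20


@pytest.fixture(scope="session")
def normalized(cork_cohort):
    _, _, m15, m20 = cork_cohort
    n15 = p.standard_pipeline(m15)
    n20 = p.standard_pipeline(m20)
    return n15, n20


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small no-effect cohort for fast calibration-style checks."""
    cfg = p.null_config(seed=11, n_cases=20, n_compounds=12,
                        contaminant_compounds=())
    clinical, m15, m20 = p.generate_cohort(cfg)
    return cfg, clinical, m15, m20


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
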