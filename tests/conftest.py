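"""Shared fixtures: synthetic cohorts at the scales the test suite uses.

Expensive artifacts (the 300-subject cohort and its 50-model pooled clock)
are session-scoped so the recovery experiments compute them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytoclock.synthetic import SimConfig, generate_cohort, inject_missingness
from cytoclock.preprocess import compute_balancing_weights
from cytoclock.impute import ImputationSpec, generate_ensemble
from cytoclock.clock import fit_clock_ensemble


@pytest.fixture(scope="session")
def small_cohort():
    """120-subject complete cohort for cheap structural checks."""
    cfg = SimConfig(n_subjects=120, seed=7)
    visits, panel, volumes, truth = generate_cohort(cfg)
    return cfg, visits, panel, volumes, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """The 300-subject cohort of the clock-recovery experiment (seed 0)."""
    cfg = SimConfig(n_subjects=300, seed=0)
    visits, panel, volumes, truth = generate_cohort(cfg)
    missing = inject_missingness(panel, cfg, visits=visits)
    return cfg, visits, panel, missing, volumes, truth


@pytest.fixture(scope="session")
def pooled_clock_50(recovery_cohort):
    """Pooled clock over M=50 imputations of the recovery cohort."""
    cfg, visits, panel, missing, volumes, truth = recovery_cohort
    weights = compute_balancing_weights(visits["age"])
    ensemble = generate_ensemble(
        missing, ImputationSpec(n_imputations=50, seed=0), weights,
        sex=visits["sex"])
    pooled = fit_clock_ensemble(ensemble, visits["age"], weights,
                                visits["subject_id"], seed=0)
    return pooled, ensemble


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
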