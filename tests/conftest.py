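"""Shared fixtures: small synthetic cohorts and fitted models.

Everything is generated programmatically with fixed seeds; fitting the
OC-SVM ensembles is the slow part, so fitted objects are session-scoped.
"""

from __future__ import annotations

import dataclasses

import pytest

from aortanorm import (
    LEVELS,
    SyntheticConfig,
    fit_linear_model,
    fit_qscore_ensemble,
    generate_healthy,
)


@pytest.fixture(scope="session")
def base_config() -> SyntheticConfig:
    return SyntheticConfig(n=400, seed=7)


@pytest.fixture(scope="session")
def healthy_cohort(base_config):
    return generate_healthy(base_config)


@pytest.fixture(scope="session")
def held_out_cohort(base_config):
    return generate_healthy(dataclasses.replace(base_config, n=300, seed=8))


@pytest.fixture(scope="session")
def z_models(healthy_cohort):
    return {lv: fit_linear_model(healthy_cohort, lv) for lv in LEVELS}


@pytest.fixture(scope="session")
def global_ensemble(healthy_cohort):
    return fit_qscore_ensemble(healthy_cohort, "global")


@pytest.fixture(scope="session")
def local_ensembles(healthy_cohort):
    return {
        lv: fit_qscore_ensemble(healthy_cohort, f"local:{lv}") for lv in LEVELS
    }
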