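"""Shared fixtures: synthetic runs at the study's acquisition design.

The default run reproduces the acquisition conditions the pipeline is built
for: 4 batches, 200 study injections, a pooled QC after every 10 study
samples, one blank per 10, 20 replicate pairs, 20% multiplicative drift and
8% lognormal measurement noise.  Session scope keeps the suite fast; all
fixtures are pure functions of their fixed seeds.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from lipidqc import (
    RunParameters,
    build_injection_sequence,
    extract_run,
    make_synthetic_database,
    normalize,
    simulate_run,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

SEED = 11


@pytest.fixture(scope="session")
def default_db():
    return make_synthetic_database(n_lipids=30, n_internal_standards=5, seed=SEED)


@pytest.fixture(scope="session")
def default_plan():
    return build_injection_sequence(
        n_study=200, n_batches=4, qc_interval=10, blank_interval=10,
        n_duplicate_pairs=20, seed=SEED,
    )


@pytest.fixture(scope="session")
def default_run(default_db, default_plan):
    params = RunParameters(seed=SEED)
    truth, eics = simulate_run(default_db, default_plan, params)
    return default_db, default_plan, params, truth, eics


@pytest.fixture(scope="session")
def default_matrices(default_run):
    db, plan, params, truth, eics = default_run
    raw, calibrations = extract_run(eics, plan, db)
    normalized, audit = normalize(raw)
    return raw, normalized, audit, calibrations


@pytest.fixture(scope="session")
def small_noise_free_run():
    """A compact noise- and drift-free run for exactness checks."""
    db = make_synthetic_database(n_lipids=8, n_internal_standards=4, seed=SEED + 1)
    plan = build_injection_sequence(
        n_study=40, n_batches=2, qc_interval=5, blank_interval=5,
        n_duplicate_pairs=4, seed=SEED + 1,
    )
    params = RunParameters(
        noise_cv=0.0, baseline_level=0.0, baseline_noise=0.0,
        drift_amplitude=0.0, batch_scale_sigma=0.0, carryover_fraction=0.0,
        seed=SEED + 1,
    )
    truth, eics = simulate_run(db, plan, params)
    return db, plan, params, truth, eics
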