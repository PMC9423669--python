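"""Shared fixtures: small synthetic slides and cached experiment runs.

Expensive end-to-end runs (two-phase training, phenotype cohort) are
session-scoped so several tests can assert different properties of the
same run.
"""

from dataclasses import replace

import numpy as np
import pytest

from rollmap.pipeline import (run_phenotype_experiment,
                              run_two_phase_experiment, sample_tissue_blocks,
                              tissue_map_geometry)
from rollmap.synthetic import DEFAULT_PROFILES, SpiralGeometry, generate_slide

GEOM = SpiralGeometry(size=512, turns=2.5)


@pytest.fixture(scope="session")
def dss_slide():
    return generate_slide(DEFAULT_PROFILES["DSS"], GEOM, seed=3)


@pytest.fixture(scope="session")
def tissue_slide():
    """Thick-stripe slide so every tissue category admits pure 32px blocks."""
    return generate_slide(DEFAULT_PROFILES["DSS"], tissue_map_geometry(), seed=3)


@pytest.fixture(scope="session")
def control_tissue_slide():
    return generate_slide(DEFAULT_PROFILES["Control"], tissue_map_geometry(),
                          seed=4)


@pytest.fixture(scope="session")
def control_slide():
    return generate_slide(DEFAULT_PROFILES["Control"], GEOM, seed=4)


@pytest.fixture(scope="session")
def fixed_fraction_slide():
    """DSS-like slide with the involved fraction pinned to exactly 0.4."""
    prof = replace(DEFAULT_PROFILES["DSS"], involved_fraction_mean=0.4,
                   involved_fraction_sd=0.0)
    return generate_slide(prof, GEOM, seed=3)


@pytest.fixture(scope="session")
def tissue_training_data(tissue_slide, control_tissue_slide):
    Xa, ya = sample_tissue_blocks(tissue_slide, n_per_class=60, seed=1)
    Xb, yb = sample_tissue_blocks(control_tissue_slide, n_per_class=40, seed=2)
    return np.concatenate([Xa, Xb]), np.concatenate([ya, yb])


@pytest.fixture(scope="session")
def tissue_model(tissue_training_data):
    from rollmap.tissue import train_tissue_model
    X, y = tissue_training_data
    return train_tissue_model(X, y, seed=0)


@pytest.fixture(scope="session")
def two_phase_runs():
    """Full two-phase experiment for three seeds."""
    return {seed: run_two_phase_experiment(seed=seed) for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def phenotype_run():
    return run_phenotype_experiment(seed=7)
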