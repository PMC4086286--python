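import numpy as np
import pandas as pd
import pytest

from hvtime.normalization import apply_model, normalize_matrix
from hvtime.simulate import SimulationConfig, generate_timecourse

SINGLE_ARM = dict(n_genes=2000, treatments=("treated",))


@pytest.fixture(scope="session")
def small_sim():
    """Default-conditions single-arm time course: 2,000 genes, 2 reps x 5 groups."""
    cfg = SimulationConfig(seed=11, **SINGLE_ARM)
    matrix, truth = generate_timecourse(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def normalized_sim(small_sim):
    cfg, matrix, truth = small_sim
    return cfg, matrix, truth, normalize_matrix(matrix)


@pytest.fixture(scope="session")
def null_sim():
    """Clean null: 2,000 expressed genes, no HV, no artifacts, no distortion."""
    cfg = SimulationConfig(
        seed=77,
        n_genes=2000,
        treatments=("treated",),
        background_fraction=0.0,
        hv_fraction=0.0,
        artifact_fraction=0.0,
        identity_distortions=True,
    )
    matrix, truth = generate_timecourse(cfg)
    norm = apply_model(matrix, truth.background_model)
    return cfg, matrix, truth, norm


@pytest.fixture()
def pair_groups():
    """2 replicates x 5 (treatment, time) groups — the default design."""
    return [("treated", t) for t in (0.0, 0.5, 1.0, 2.0, 3.0) for _ in range(2)]
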