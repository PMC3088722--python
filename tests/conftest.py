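"""Shared fixtures: small simulated studies and a large shared site universe."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mirshift.simulate import SimulationConfig, simulate_study, simulate_utrs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A low-noise, fully-shared-target study small enough for unit tests."""
    cfg = SimulationConfig(
        n_genes=600, n_targets=50, delta=1.0, replicate_sd=0.1,
        shared_fraction=1.0, seed=11,
    )
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def calibration_universe():
    """One fixed 10,000-gene UTR universe with 300 planted targets.

    Shared by the calibration and effect-recovery checks, which redraw only
    the expression layer per repetition.
    """
    cfg = SimulationConfig(n_genes=10_000, n_targets=300, seed=101)
    rng = np.random.default_rng(cfg.seed)
    utrs, truth_sites = simulate_utrs(cfg, rng)
    targets = sorted({s.gene_id for s in truth_sites})
    return cfg, utrs, targets
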