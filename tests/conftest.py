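"""Shared fixtures: simulated scenarios and pipeline runs are expensive,
so they are session-scoped and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from epichannel.io_formats import AnalysisConfig
from epichannel.pipeline import run_contrast
from epichannel.qc_filtering import run_filter_chain
from epichannel.synthetic_data import (
    SimulationParams,
    null_params,
    simulate_scenario,
)

SCENARIO_SEED = 101


@pytest.fixture(scope="session")
def default_scenario():
    """The default study: 5,000 CpGs, 100 planted pop-effects, genotypes."""
    return simulate_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_result(default_scenario, default_config):
    """Full decrease-contrast pipeline on the default scenario."""
    sc = default_scenario
    return run_contrast(
        sc.matrix, sc.sheet, sc.variants, sc.layout.genes, default_config
    )


@pytest.fixture(scope="session")
def channel_truth(default_scenario, default_result):
    """Channel table joined with planted ground truth."""
    return default_result.channel_table.merge(
        default_scenario.truth.sites[["chrom", "pos", "planted_class"]],
        on=["chrom", "pos"],
    )


@pytest.fixture(scope="session")
def null_run():
    """No-effect calibration scenario, filtered, with the wild comparison."""
    from epichannel import diffmeth

    sc = simulate_scenario(null_params(), seed=202)
    cfg = AnalysisConfig()
    filtered, _ = run_filter_chain(sc.matrix, sc.sheet, sc.variants, cfg)
    wild = diffmeth.compare_groups(filtered, sc.sheet, "KIE20", "NYN6", cfg)
    within = diffmeth.compare_groups(filtered, sc.sheet, "ctrl20", "within6", cfg)
    trans = diffmeth.compare_groups(filtered, sc.sheet, "ctrl20", "trans6", cfg)
    return sc, cfg, filtered, wild, within, trans


@pytest.fixture(scope="session")
def power_run():
    """Planted |delta| = 30 pp exactly, n = 15/group, coverage 30, rho 0.01."""
    from epichannel import diffmeth

    params = SimulationParams(delta_wild_fixed=30.0)
    sc = simulate_scenario(params, seed=303)
    cfg = AnalysisConfig()
    filtered, _ = run_filter_chain(sc.matrix, sc.sheet, sc.variants, cfg)
    wild = diffmeth.compare_groups(filtered, sc.sheet, "KIE20", "NYN6", cfg)
    return sc, wild


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
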