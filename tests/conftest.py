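"""Shared fixtures.

The heavy session-scoped fixtures run the Monte Carlo under the study
conditions used throughout the quantitative checks: 20,000 particles and
3 replicates (seed 0, replicate r using seed r).  Lighter unit tests
build their own small ensembles.
"""

from __future__ import annotations

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import mexdiff as m

SUITE_PARTICLES = 20_000
SUITE_REPLICATES = 3
SUITE_SEED = 0


@pytest.fixture(scope="session")
def geometry() -> m.EmbryoGeometry:
    return m.EmbryoGeometry()


def _suite_config(base: m.SimConfig, duration: float) -> m.SimConfig:
    return dataclasses.replace(
        base,
        n_particles=SUITE_PARTICLES,
        n_replicates=SUITE_REPLICATES,
        duration=duration,
        rng_seed=SUITE_SEED,
    )


@pytest.fixture(scope="session")
def mex6_runs(geometry):
    """Default MEX-6 condition, 30 min horizon, snapshots every 150 s."""
    species, rates, _, cfg = m.default_mex6_params()
    cfg = _suite_config(cfg, 1800.0)
    out = list(np.arange(0.0, 1801.0, 150.0))
    return m.run_replicates(cfg, geometry, species, rates, output_times=out)


@pytest.fixture(scope="session")
def mex6_series(mex6_runs, geometry):
    return m.gradient_timeseries(mex6_runs, geometry)


@pytest.fixture(scope="session")
def null_runs(geometry):
    """Spatially uniform kinase equal to the phosphatase rate (no asymmetry)."""
    species, _, _, cfg = m.default_mex6_params()
    rates = m.RateField(0.005, 0.005, 0.005)
    cfg = _suite_config(cfg, 1200.0)
    out = list(np.arange(0.0, 1201.0, 300.0))
    return m.run_replicates(cfg, geometry, species, rates, output_times=out)


@pytest.fixture(scope="session")
def scaled_steady_gradients(geometry):
    """Steady gradient for joint rate scales 0.5, 1, 2.

    Each condition runs to the same scaled horizon (3600 s / scale) so
    that all are equally equilibrated relative to their own kinetics.
    """
    from mexdiff.sensitivity import steady_gradient_of_runs

    species, rates, _, cfg = m.default_mex6_params()
    result = {}
    for scale in (0.5, 1.0, 2.0):
        duration = 3600.0 / scale
        cfg_s = _suite_config(cfg, duration)
        out = list(np.linspace(0.0, duration, 13))
        runs = m.run_replicates(
            cfg_s, geometry, species, rates.scaled(scale), output_times=out
        )
        g, sd, _ = steady_gradient_of_runs(runs, geometry, tail_frac=0.25)
        result[scale] = (g, sd)
    return result


@pytest.fixture(scope="session")
def klow_scenarios(geometry):
    """Anterior-kinase smoothing scenarios (MEX-5), multipliers 1/1.5/2/4."""
    species, rates, _, cfg = m.default_mex5_params()
    cfg = _suite_config(cfg, 1800.0)
    return m.run_klow_scenarios(
        (1.0, 1.5, 2.0, 4.0),
        geometry=geometry,
        species=species,
        base_rates=rates,
        config=cfg,
    )
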