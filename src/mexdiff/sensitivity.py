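"""In-silico parameter experiments.

Three experiments probe how the kinase/phosphatase rate field shapes the
steady-state gradient:

* **Joint rate scaling** — multiplying all three rates by a constant
  changes only the kinetics of gradient formation, not the steady state,
  because the stationary slow/fast balance depends only on the
  kinase-to-phosphatase ratio.
* **Rate scan** — with the anterior kinase rate fixed, a grid over the
  posterior kinase rate and the phosphatase rate maps how the slow/fast
  balance (and hence the steady gradient) responds.
* **Anterior-kinase smoothing scenarios** — raising the anterior kinase
  rate (multipliers 1, 1.5, 2, 4; posterior rate fixed) emulates a longer
  posterior PAR domain: the anterior slow fraction drops, and the total
  gradient smooths out, becoming nearly flat at the 4x multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, DomainError
from .geometry_params import (
    EmbryoGeometry,
    RateField,
    SimConfig,
    SpeciesParams,
    default_mex5_params,
)
from .readouts import (
    ConcentrationProfile,
    GradientSeries,
    anterior_slow_fraction,
    concentration_profile,
    gradient_timeseries,
    steady_state_gradient,
)
from .simulator import Trajectory, run_replicates

__all__ = [
    "scale_rates",
    "ScanResult",
    "run_rate_scan",
    "ScenarioResult",
    "ScenarioSet",
    "run_klow_scenarios",
    "steady_gradient_of_runs",
]

DEFAULT_UPP_GRID = (0.002, 0.0035, 0.005, 0.0065)
DEFAULT_PHOSP_GRID = (0.0025, 0.005, 0.0075)
DEFAULT_KLOW_MULTIPLIERS = (1.0, 1.5, 2.0, 4.0)


def scale_rates(rates: RateField, factor: float) -> RateField:
    """All three rates multiplied by a positive constant."""
    if factor <= 0:
        raise DomainError("scale factor must be positive")
    return rates.scaled(factor)


def steady_gradient_of_runs(
    runs: Sequence[Trajectory],
    geometry: EmbryoGeometry,
    n_bins: int = 30,
    tail_frac: float = 0.1,
) -> tuple[float, float, bool]:
    """Replicate-mean steady-state gradient of a set of runs."""
    series = gradient_timeseries(runs, geometry, n_bins=n_bins)
    return steady_state_gradient(series, tail_frac=tail_frac)


@dataclass(frozen=True)
class ScanResult:
    """Steady-state gradient over a (k_upp, k_phosp) grid.

    Cells with ``k_upp < k_kinase_low`` are invalid (NaN, flagged in
    ``valid``) and are not simulated.
    """

    axis_upp: np.ndarray
    axis_phosp: np.ndarray
    steady_gradient: np.ndarray
    steady_gradient_sd: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.axis_upp), len(self.axis_phosp))
        for m in (self.steady_gradient, self.steady_gradient_sd, self.valid):
            if m.shape != shape:
                raise ConfigError("scan matrices must match axis lengths")
        if np.any(self.steady_gradient_sd[self.valid] < 0):
            raise ConfigError("SD must be non-negative")


def run_rate_scan(
    base: RateField,
    upp_values: Sequence[float] = DEFAULT_UPP_GRID,
    phosp_values: Sequence[float] = DEFAULT_PHOSP_GRID,
    geometry: EmbryoGeometry | None = None,
    species: SpeciesParams | None = None,
    config: SimConfig | None = None,
    n_bins: int = 30,
) -> ScanResult:
    """Steady gradient (mean ± SD over replicates) per grid cell.

    ``base.k_kinase_low`` is held fixed across the grid.
    """
    if len(upp_values) == 0 or len(phosp_values) == 0:
        raise ConfigError("scan grids must be non-empty")
    if geometry is None:
        geometry = EmbryoGeometry()
    if species is None or config is None:
        sp5, _, _, cfg5 = default_mex5_params()
        species = species or sp5
        config = config or cfg5

    n_u, n_p = len(upp_values), len(phosp_values)
    mean = np.full((n_u, n_p), np.nan)
    sd = np.full((n_u, n_p), np.nan)
    valid = np.zeros((n_u, n_p), dtype=bool)
    for i, k_upp in enumerate(upp_values):
        for j, k_phosp in enumerate(phosp_values):
            if k_upp < base.k_kinase_low:
                continue
            rates = RateField(base.k_kinase_low, k_upp, k_phosp)
            runs = run_replicates(config, geometry, species, rates)
            g, g_sd, _ = steady_gradient_of_runs(runs, geometry, n_bins=n_bins)
            mean[i, j], sd[i, j] = g, g_sd
            valid[i, j] = True
    return ScanResult(
        axis_upp=np.asarray(upp_values, dtype=float),
        axis_phosp=np.asarray(phosp_values, dtype=float),
        steady_gradient=mean,
        steady_gradient_sd=sd,
        valid=valid,
    )


@dataclass(frozen=True)
class ScenarioResult:
    """One anterior-kinase multiplier scenario."""

    multiplier: float
    rates: RateField
    series: GradientSeries
    steady_gradient: float
    steady_gradient_sd: float
    profiles: dict[str, ConcentrationProfile]
    anterior_slow_fraction: float


@dataclass(frozen=True)
class ScenarioSet:
    """Results for all anterior-kinase multipliers, in input order."""

    scenarios: tuple[ScenarioResult, ...]

    @property
    def multipliers(self) -> np.ndarray:
        return np.array([s.multiplier for s in self.scenarios])

    @property
    def steady_gradients(self) -> np.ndarray:
        return np.array([s.steady_gradient for s in self.scenarios])

    @property
    def anterior_slow_fractions(self) -> np.ndarray:
        return np.array([s.anterior_slow_fraction for s in self.scenarios])


def run_klow_scenarios(
    multipliers: Sequence[float] = DEFAULT_KLOW_MULTIPLIERS,
    geometry: EmbryoGeometry | None = None,
    species: SpeciesParams | None = None,
    base_rates: RateField | None = None,
    config: SimConfig | None = None,
    n_bins: int = 30,
) -> ScenarioSet:
    """Anterior-kinase smoothing scenarios (MEX-5 presets by default).

    Each multiplier m >= 1 scales the anterior kinase rate
    (``k_kinase_low * m``) with the posterior rate and phosphatase rate
    fixed.  Per scenario: the replicate-aggregated gradient time series,
    the steady-state slow/fast/total profiles (counts pooled over
    replicates at the final snapshot), and the anterior slow-state
    fraction.

    Raises
    ------
    ConfigError
        If a multiplier is < 1 or pushes the anterior rate above the
        posterior rate.
    """
    if geometry is None:
        geometry = EmbryoGeometry()
    sp5, rates5, _, cfg5 = default_mex5_params()
    species = species or sp5
    base_rates = base_rates or rates5
    config = config or cfg5

    scenarios = []
    for m in multipliers:
        if m < 1:
            raise ConfigError("multipliers must be >= 1 (smoothing direction)")
        k_low = base_rates.k_kinase_low * m
        if k_low > base_rates.k_kinase_upp:
            raise ConfigError(
                f"multiplier {m} pushes the anterior kinase rate ({k_low:.4g}/s) "
                f"above the posterior rate ({base_rates.k_kinase_upp:.4g}/s)"
            )
        rates = RateField(k_low, base_rates.k_kinase_upp, base_rates.k_phosp)
        runs = run_replicates(config, geometry, species, rates)
        series = gradient_timeseries(runs, geometry, n_bins=n_bins)
        g, g_sd, _ = steady_state_gradient(series)
        profiles = {
            comp: _mean_profile(runs, geometry, n_bins, comp)
            for comp in ("slow", "fast", "total")
        }
        asf = float(
            np.mean([anterior_slow_fraction(tr.final, geometry) for tr in runs])
        )
        scenarios.append(
            ScenarioResult(
                multiplier=float(m),
                rates=rates,
                series=series,
                steady_gradient=g,
                steady_gradient_sd=g_sd,
                profiles=profiles,
                anterior_slow_fraction=asf,
            )
        )
    return ScenarioSet(scenarios=tuple(scenarios))


def _mean_profile(
    runs: Sequence[Trajectory],
    geometry: EmbryoGeometry,
    n_bins: int,
    component: str,
) -> ConcentrationProfile:
    """Replicate-averaged final-snapshot profile of one component."""
    profs = [
        concentration_profile(tr.final, geometry, n_bins, component) for tr in runs
    ]
    values = np.nanmean(np.stack([p.values for p in profs]), axis=0)
    counts = np.sum(np.stack([p.counts for p in profs]), axis=0)
    return ConcentrationProfile(
        bin_centers=profs[0].bin_centers,
        values=values,
        species_component=component,
        convention=profs[0].convention,
        counts=counts,
        n_total=sum(p.n_total for p in profs),
    )
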