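"""Embryo geometry and model parameters for the differential-diffusion model.

The one-cell *C. elegans* embryo is modelled as a 3D ellipsoid centred at
the origin with

* ``x`` along the anterior--posterior (AP) axis,
* ``y`` along the dorso-ventral axis,
* ``z`` along the left--right (imaging) axis; concentration readouts use a
  central slab ``|z| <= slice_thickness / 2``.

The AP *coordinate* runs from 0 at the anterior pole to ``2 * semi_axis_ap``
at the posterior pole; the normalised coordinate ``x_hat = ap / (2a)`` in
[0, 1] is the abscissa for all gradient fits.

Two kinetic states are modelled per protein: a *slow*, dephosphorylated,
RNA-bound state and a *fast*, PAR-1-phosphorylated state.  The kinase rate
increases linearly from ``k_kinase_low`` at the anterior pole to
``k_kinase_upp`` at the posterior pole; the phosphatase rate ``k_phosp`` is
spatially uniform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .exceptions import ConfigError, DomainError

__all__ = [
    "EmbryoGeometry",
    "SpeciesParams",
    "RateField",
    "SteadyStateFractions",
    "SimConfig",
    "ModelSetup",
    "default_mex6_params",
    "default_mex5_params",
    "kinase_rate_at",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class EmbryoGeometry:
    """Ellipsoidal embryo with a central readout slab.

    Default semi-axes (25, 15, 15) µm give a ~50 µm long embryo, typical of
    the one-cell stage.  The gradient statistic is computed on normalised
    coordinates, so absolute size mostly affects timescales.

    Parameters
    ----------
    semi_axis_ap, semi_axis_dv, semi_axis_lr:
        Ellipsoid semi-axes in µm (AP, dorso-ventral, left-right).
    slice_thickness:
        Thickness in µm of the central slab used for concentration
        profiles (epifluorescence-midplane-like readout).
    voxel_edge:
        Edge length in µm of the voxel columns used when binning particle
        counts along the AP axis.
    """

    semi_axis_ap: float = 25.0
    semi_axis_dv: float = 15.0
    semi_axis_lr: float = 15.0
    slice_thickness: float = 5.0
    voxel_edge: float = 1.0

    def __post_init__(self) -> None:
        if min(self.semi_axis_ap, self.semi_axis_dv, self.semi_axis_lr) <= 0:
            raise ConfigError("all ellipsoid semi-axes must be positive")
        if not (0 < self.slice_thickness <= 2 * self.semi_axis_lr):
            raise ConfigError(
                "slice_thickness must lie in (0, 2*semi_axis_lr] "
                f"(got {self.slice_thickness})"
            )
        if self.voxel_edge <= 0:
            raise ConfigError("voxel_edge must be positive")

    @property
    def ap_length(self) -> float:
        """Full anterior-to-posterior length (2a) in µm."""
        return 2.0 * self.semi_axis_ap

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact ellipsoid membership for centred coordinates.

        Parameters
        ----------
        points:
            Array of shape (n, 3) or (3,) in µm, centred frame.

        Returns
        -------
        Boolean array (or scalar) — True where
        ``(x/a)^2 + (y/b)^2 + (z/c)^2 <= 1``.
        """
        p = np.asarray(points, dtype=float)
        q = (
            (p[..., 0] / self.semi_axis_ap) ** 2
            + (p[..., 1] / self.semi_axis_dv) ** 2
            + (p[..., 2] / self.semi_axis_lr) ** 2
        )
        return q <= 1.0

    def ap_coordinate(self, x_centered: np.ndarray) -> np.ndarray:
        """Map centred x to the AP coordinate (0 = anterior pole)."""
        return np.asarray(x_centered, dtype=float) + self.semi_axis_ap

    def normalized_ap(self, x_centered: np.ndarray) -> np.ndarray:
        """Map centred x to the normalised AP coordinate x_hat in [0, 1]."""
        return self.ap_coordinate(x_centered) / self.ap_length


@dataclass(frozen=True)
class SpeciesParams:
    """Per-protein diffusivities and random-walk step speeds.

    The simulator moves each molecule a fixed distance ``v * dt`` per step
    in a uniformly random direction; ``v = sqrt(6 D / dt)`` makes the
    per-step mean-squared displacement equal ``6 D dt`` (see
    :func:`mexdiff.diffusivity.velocity_from_diffusivity`).
    """

    name: str
    D_slow: float
    D_fast: float
    v_slow: float
    v_fast: float

    def __post_init__(self) -> None:
        if not (0 <= self.D_slow < self.D_fast):
            raise ConfigError("require 0 <= D_slow < D_fast")
        if not (self.v_slow < self.v_fast):
            raise ConfigError("require v_slow < v_fast")

    @classmethod
    def from_diffusivities(
        cls, name: str, D_slow: float, D_fast: float, timestep: float
    ) -> "SpeciesParams":
        """Build a species with step speeds derived from diffusivities."""
        from .diffusivity import velocity_from_diffusivity

        return cls(
            name=name,
            D_slow=D_slow,
            D_fast=D_fast,
            v_slow=velocity_from_diffusivity(D_slow, timestep),
            v_fast=velocity_from_diffusivity(D_fast, timestep),
        )

    def with_timestep(self, timestep: float) -> "SpeciesParams":
        """Recompute step speeds for a new timestep, preserving D."""
        return SpeciesParams.from_diffusivities(
            self.name, self.D_slow, self.D_fast, timestep
        )

    def velocity_consistency(self, timestep: float) -> float:
        """Max relative deviation of stored speeds from sqrt(6 D / dt)."""
        from .diffusivity import velocity_from_diffusivity

        devs = []
        for D, v in ((self.D_slow, self.v_slow), (self.D_fast, self.v_fast)):
            v_ref = velocity_from_diffusivity(D, timestep)
            if v_ref == 0 and v == 0:
                devs.append(0.0)
            else:
                devs.append(abs(v - v_ref) / max(v_ref, 1e-300))
        return max(devs)


@dataclass(frozen=True)
class RateField:
    """Kinase/phosphatase rate profile.

    ``k_kinase_low`` applies at the anterior pole and ``k_kinase_upp`` at
    the posterior pole, with linear interpolation in between; ``k_phosp``
    is uniform in space.  All rates in 1/s.
    """

    k_kinase_low: float
    k_kinase_upp: float
    k_phosp: float

    def __post_init__(self) -> None:
        if min(self.k_kinase_low, self.k_kinase_upp, self.k_phosp) < 0:
            raise ConfigError("rates must be non-negative")
        if self.k_kinase_low > self.k_kinase_upp:
            raise ConfigError("require k_kinase_low <= k_kinase_upp")

    def scaled(self, factor: float) -> "RateField":
        """All three rates multiplied by a positive constant."""
        if factor <= 0:
            raise DomainError("scale factor must be positive")
        return RateField(
            self.k_kinase_low * factor,
            self.k_kinase_upp * factor,
            self.k_phosp * factor,
        )


@dataclass(frozen=True)
class SteadyStateFractions:
    """Measured steady-state slow-state occupancies at the two poles.

    Defaults (70% anterior, 50% posterior) are the fluorescence-correlation-
    spectroscopy values used throughout the model; complements give the
    fast-state fractions.
    """

    frac_slow_anterior: float = 0.70
    frac_slow_posterior: float = 0.50

    def __post_init__(self) -> None:
        for f in (self.frac_slow_anterior, self.frac_slow_posterior):
            if not (0.0 <= f <= 1.0):
                raise ConfigError("fractions must lie in [0, 1]")


InitialStateRule = Literal["uniform_half", "local_equilibrium"]
SwitchProbRule = Literal["exact_exponential", "linearized"]
BoundaryRule = Literal["reflect", "reject", "redraw"]


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo run configuration.

    duration defaults to 1200 s (the 20-minute steady-state readout time);
    n_replicates defaults to 5 as in the published averaging convention.
    The 0.75 s timestep is the value at which the step-speed conversion
    ``v = sqrt(6 D / dt)`` reproduces the tabulated velocities.
    """

    n_particles: int = 50_000
    timestep: float = 0.75
    duration: float = 1200.0
    n_replicates: int = 5
    rng_seed: int = 0
    initial_state_rule: InitialStateRule = "uniform_half"
    switch_prob_rule: SwitchProbRule = "exact_exponential"
    boundary_rule: BoundaryRule = "reflect"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        if self.timestep <= 0:
            raise ConfigError("timestep must be positive")
        if self.duration < self.timestep:
            raise ConfigError("duration must be >= timestep")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.initial_state_rule not in ("uniform_half", "local_equilibrium"):
            raise ConfigError(f"unknown initial_state_rule {self.initial_state_rule!r}")
        if self.switch_prob_rule not in ("exact_exponential", "linearized"):
            raise ConfigError(f"unknown switch_prob_rule {self.switch_prob_rule!r}")
        if self.boundary_rule not in ("reflect", "reject", "redraw"):
            raise ConfigError(f"unknown boundary_rule {self.boundary_rule!r}")


@dataclass(frozen=True)
class ModelSetup:
    """Bundle of everything needed to run one simulation condition."""

    species: SpeciesParams
    rates: RateField
    fractions: SteadyStateFractions
    config: SimConfig
    geometry: EmbryoGeometry = field(default_factory=EmbryoGeometry)


def default_mex6_params() -> tuple[SpeciesParams, RateField, SteadyStateFractions, SimConfig]:
    """Default MEX-6 parameter set.

    Slow/fast diffusivities 0.01 and 1.81 µm²/s (from the two-region FRAP
    decomposition); kinase 0.001 s⁻¹ (anterior) to 0.005 s⁻¹ (posterior),
    phosphatase 0.005 s⁻¹.  The posterior kinase rate equals the
    phosphatase rate, which is what makes the posterior steady-state
    slow fraction 50%.  Step speeds are derived from the diffusivities at
    the default 0.75 s timestep (0.28 and 3.81 µm/s, matching the
    tabulated 0.29 / 3.80 within rounding).
    """
    config = SimConfig()
    species = SpeciesParams.from_diffusivities("MEX-6", 0.01, 1.81, config.timestep)
    rates = RateField(k_kinase_low=0.001, k_kinase_upp=0.005, k_phosp=0.005)
    fractions = SteadyStateFractions(0.70, 0.50)
    return species, rates, fractions, config


def default_mex5_params() -> tuple[SpeciesParams, RateField, SteadyStateFractions, SimConfig]:
    """Default MEX-5 parameter set.

    Slow/fast diffusivities 0.03 and 3.00 µm²/s.  The posterior kinase rate
    is 0.0055 s⁻¹, the value used in the kinase-profile-smoothing
    scenarios; the anterior value and the phosphatase rate match MEX-6.
    """
    config = SimConfig()
    species = SpeciesParams.from_diffusivities("MEX-5", 0.03, 3.00, config.timestep)
    rates = RateField(k_kinase_low=0.001, k_kinase_upp=0.0055, k_phosp=0.005)
    fractions = SteadyStateFractions(0.70, 0.50)
    return species, rates, fractions, config


def kinase_rate_at(
    ap_coordinate: float | np.ndarray,
    rates: RateField,
    geometry: EmbryoGeometry,
) -> float | np.ndarray:
    """Linearly interpolated kinase rate at an AP coordinate.

    The rate equals ``k_kinase_low`` at AP coordinate 0 (anterior pole) and
    ``k_kinase_upp`` at the posterior pole, increasing linearly in between.

    Raises
    ------
    DomainError
        If any coordinate falls outside [0, AP length].
    """
    ap = np.asarray(ap_coordinate, dtype=float)
    L = geometry.ap_length
    if np.any(ap < 0) or np.any(ap > L):
        raise DomainError(f"AP coordinate outside [0, {L}] µm")
    out = rates.k_kinase_low + (rates.k_kinase_upp - rates.k_kinase_low) * ap / L
    if np.isscalar(ap_coordinate) or np.ndim(ap_coordinate) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Configuration file I/O
#
# Flat, human-editable YAML schema with one section per component:
#   geometry:  semi_axis_ap, semi_axis_dv, semi_axis_lr, slice_thickness, voxel_edge
#   species:   name, D_slow, D_fast, v_slow, v_fast
#   rates:     k_kinase_low, k_kinase_upp, k_phosp
#   fractions: frac_slow_anterior, frac_slow_posterior
#   sim:       n_particles, timestep, duration, n_replicates, rng_seed,
#              initial_state_rule, switch_prob_rule
# ---------------------------------------------------------------------------

_SECTIONS = {
    "geometry": EmbryoGeometry,
    "species": SpeciesParams,
    "rates": RateField,
    "fractions": SteadyStateFractions,
    "sim": SimConfig,
}


def setup_to_dict(setup: ModelSetup) -> dict:
    """Serialise a full model setup to a plain nested dict of scalars."""
    return {
        "geometry": dataclasses.asdict(setup.geometry),
        "species": dataclasses.asdict(setup.species),
        "rates": dataclasses.asdict(setup.rates),
        "fractions": dataclasses.asdict(setup.fractions),
        "sim": dataclasses.asdict(setup.config),
    }


def setup_from_dict(data: dict) -> ModelSetup:
    """Inverse of :func:`setup_to_dict`; validates every field."""
    missing = set(_SECTIONS) - set(data)
    if missing:
        raise ConfigError(f"configuration missing sections: {sorted(missing)}")
    return ModelSetup(
        geometry=EmbryoGeometry(**data["geometry"]),
        species=SpeciesParams(**data["species"]),
        rates=RateField(**data["rates"]),
        fractions=SteadyStateFractions(**data["fractions"]),
        config=SimConfig(**data["sim"]),
    )


def save_config(setup: ModelSetup, path: str | Path) -> None:
    """Write a model setup as YAML (round-trips bit-exactly)."""
    Path(path).write_text(yaml.safe_dump(setup_to_dict(setup), sort_keys=True))


def load_config(path: str | Path) -> ModelSetup:
    """Load a model setup written by :func:`save_config`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return setup_from_dict(data)
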