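"""Monte Carlo particle engine.

Each molecule performs an isotropic fixed-speed random walk inside the
ellipsoidal embryo and stochastically switches between a slow and a fast
kinetic state.  Per timestep each particle

1. attempts a displacement of length ``v_state * dt`` in a direction drawn
   uniformly on the sphere; a displacement crossing the boundary is
   specularly reflected off the ellipsoid surface (default rule).  Two
   alternative boundary rules are available: ``reject`` (stay put — a
   Metropolis move that also preserves the uniform equilibrium but damps
   near-wall mobility) and ``redraw`` (resample the direction until the
   step stays inside).  The redraw rule is *not* measure-preserving: it
   systematically depletes the boundary layer (by ~8% of total mass at
   the fast step length) and is kept only for comparison;
2. switches state at its post-move position: slow -> fast with probability
   ``1 - exp(-k(x) dt)`` where ``k(x)`` is the linearly graded kinase
   rate, and fast -> slow with probability ``1 - exp(-k_phosp dt)``.

Runs are deterministic given the seed; replicate ``r`` uses ``seed + r``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError
from .geometry_params import (
    EmbryoGeometry,
    RateField,
    SimConfig,
    SpeciesParams,
    kinase_rate_at,
)

__all__ = [
    "SLOW",
    "FAST",
    "Ensemble",
    "Trajectory",
    "init_ensemble",
    "step",
    "run_simulation",
    "run_replicates",
]

SLOW = np.uint8(0)
FAST = np.uint8(1)


@dataclass(frozen=True)
class Ensemble:
    """Positions and kinetic states of all molecules at one time point.

    positions are (n, 3) centred coordinates in µm; states are 0 (slow)
    or 1 (fast).
    """

    positions: np.ndarray
    states: np.ndarray
    time: float
    species: str

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ConfigError("positions must have shape (n, 3)")
        if self.states.shape != (self.positions.shape[0],):
            raise ConfigError("states must have one entry per particle")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def slow_fraction(self) -> float:
        return float(np.mean(self.states == SLOW))

    def select(self, component: str) -> np.ndarray:
        """Boolean mask for a component: 'slow', 'fast' or 'total'."""
        if component == "total":
            return np.ones(self.n_particles, dtype=bool)
        if component == "slow":
            return self.states == SLOW
        if component == "fast":
            return self.states == FAST
        raise ConfigError(f"unknown component {component!r}")


@dataclass(frozen=True)
class Trajectory:
    """Ordered ensemble snapshots from one simulation run."""

    snapshots: tuple[Ensemble, ...]
    config_hash: str
    seed: int

    def __post_init__(self) -> None:
        times = self.times
        if len(times) == 0 or times[0] != 0.0:
            raise ConfigError("trajectory must start with a t = 0 snapshot")
        if np.any(np.diff(times) <= 0):
            raise ConfigError("snapshot times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def final(self) -> Ensemble:
        return self.snapshots[-1]


def _config_hash(config: SimConfig, geometry: EmbryoGeometry,
                 species: SpeciesParams, rates: RateField) -> str:
    text = repr((config, geometry, species, rates))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # A zero norm has probability zero; guard anyway.
    norm[norm == 0] = 1.0
    return v / norm


def sample_uniform_in_ellipsoid(
    rng: np.random.Generator, n: int, geometry: EmbryoGeometry
) -> np.ndarray:
    """Rejection-sample n points uniformly inside the ellipsoid."""
    semi = np.array(
        [geometry.semi_axis_ap, geometry.semi_axis_dv, geometry.semi_axis_lr]
    )
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        # pi/6 ~ 52% of the bounding box is inside; draw ~2x the deficit.
        batch = max(2 * (n - filled), 16)
        cand = rng.uniform(-1.0, 1.0, size=(batch, 3)) * semi
        good = cand[geometry.contains(cand)]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def init_ensemble(
    config: SimConfig,
    geometry: EmbryoGeometry,
    rates: RateField,
    species: str = "",
    rng: np.random.Generator | None = None,
) -> Ensemble:
    """Initial ensemble: uniform positions, states per the configured rule.

    ``uniform_half`` marks each particle slow with probability 1/2
    (spatially unbiased — no initial gradient); ``local_equilibrium``
    marks it slow with the stationary occupancy of the local two-state
    switch, ``k_phosp / (k_phosp + k(x))``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    pos = sample_uniform_in_ellipsoid(rng, config.n_particles, geometry)
    if config.initial_state_rule == "uniform_half":
        p_slow = np.full(config.n_particles, 0.5)
    else:
        k = kinase_rate_at(geometry.ap_coordinate(pos[:, 0]), rates, geometry)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_slow = np.where(
                (k + rates.k_phosp) > 0, rates.k_phosp / (k + rates.k_phosp), 0.5
            )
    states = np.where(rng.random(config.n_particles) < p_slow, SLOW, FAST).astype(np.uint8)
    return Ensemble(positions=pos, states=states, time=0.0, species=species)


def _reflect_into_ellipsoid(
    pos: np.ndarray,
    prop: np.ndarray,
    geometry: EmbryoGeometry,
    max_bounces: int = 5,
) -> np.ndarray:
    """Specularly reflect proposed displacements off the ellipsoid surface.

    For each displacement that exits the ellipsoid, the boundary crossing
    point is found by solving the quadratic in scaled coordinates, the
    remaining displacement is mirrored about the surface normal there,
    and the procedure repeats (rarely needed) up to ``max_bounces``.
    Unresolved cases fall back to rejecting the move.
    """
    semi = np.array(
        [geometry.semi_axis_ap, geometry.semi_axis_dv, geometry.semi_axis_lr]
    )
    out = prop.copy()
    origin = pos.copy()
    bad = ~geometry.contains(out)
    for _ in range(max_bounces):
        if not bad.any():
            break
        i = np.flatnonzero(bad)
        p0, p1 = origin[i], out[i]
        d = p1 - p0
        u0, du = p0 / semi, d / semi
        a = np.einsum("ij,ij->i", du, du)
        b = 2.0 * np.einsum("ij,ij->i", u0, du)
        c = np.einsum("ij,ij->i", u0, u0) - 1.0
        disc = np.maximum(b * b - 4.0 * a * c, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(a > 0, (-b + np.sqrt(disc)) / (2.0 * a), 0.0)
        s = np.clip(s, 0.0, 1.0)
        hit = p0 + s[:, None] * d
        normal = hit / semi**2
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        rest = (1.0 - s)[:, None] * d
        rest -= 2.0 * np.einsum("ij,ij->i", rest, normal)[:, None] * normal
        out[i] = hit + rest
        origin[i] = hit
        bad[i] = ~geometry.contains(out[i])
    if bad.any():
        out[bad] = pos[bad]
    return out


def step(
    ensemble: Ensemble,
    species: SpeciesParams,
    rates: RateField,
    geometry: EmbryoGeometry,
    timestep: float,
    rng: np.random.Generator,
    switch_prob_rule: str = "exact_exponential",
    boundary_rule: str = "reflect",
    max_redraws: int = 100,
) -> Ensemble:
    """Advance the ensemble by one timestep (move, then switch)."""
    n = ensemble.n_particles
    step_len = np.where(
        ensemble.states == FAST, species.v_fast, species.v_slow
    ) * timestep

    new_pos = ensemble.positions + _random_unit_vectors(rng, n) * step_len[:, None]
    if boundary_rule == "reflect":
        new_pos = _reflect_into_ellipsoid(ensemble.positions, new_pos, geometry)
    elif boundary_rule == "reject":
        bad = ~geometry.contains(new_pos)
        new_pos[bad] = ensemble.positions[bad]
    elif boundary_rule == "redraw":
        bad = ~geometry.contains(new_pos)
        attempts = 0
        while bad.any() and attempts < max_redraws:
            idx = np.flatnonzero(bad)
            cand = (
                ensemble.positions[idx]
                + _random_unit_vectors(rng, len(idx)) * step_len[idx, None]
            )
            ok = geometry.contains(cand)
            new_pos[idx[ok]] = cand[ok]
            bad[idx] = ~ok
            attempts += 1
        if bad.any():
            new_pos[bad] = ensemble.positions[bad]
    else:
        raise ConfigError(f"unknown boundary_rule {boundary_rule!r}")

    # State switching at the post-move position.
    ap = np.clip(geometry.ap_coordinate(new_pos[:, 0]), 0.0, geometry.ap_length)
    k_kin = kinase_rate_at(ap, rates, geometry)
    if switch_prob_rule == "exact_exponential":
        p_sf = -np.expm1(-np.asarray(k_kin) * timestep)
        p_fs = -np.expm1(-rates.k_phosp * timestep)
    elif switch_prob_rule == "linearized":
        p_sf = np.asarray(k_kin) * timestep
        p_fs = rates.k_phosp * timestep
    else:
        raise ConfigError(f"unknown switch_prob_rule {switch_prob_rule!r}")

    u = rng.random(n)
    slow = ensemble.states == SLOW
    states = ensemble.states.copy()
    states[slow & (u < p_sf)] = FAST
    states[~slow & (u < p_fs)] = SLOW

    return Ensemble(
        positions=new_pos,
        states=states,
        time=ensemble.time + timestep,
        species=ensemble.species,
    )


def run_simulation(
    config: SimConfig,
    geometry: EmbryoGeometry,
    species: SpeciesParams,
    rates: RateField,
    output_times: Sequence[float] | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Run one Monte Carlo realisation and return snapshots.

    Step speeds are (re)derived from the species diffusivities at the
    configured timestep, so changing the timestep preserves D.  Output
    times are snapped to the nearest step; a t = 0 snapshot is always
    included.  Deterministic given the seed (default ``config.rng_seed``).
    """
    if seed is None:
        seed = config.rng_seed
    dt = config.timestep
    n_steps = int(round(config.duration / dt))
    if output_times is None:
        # ~20 evenly spaced snapshots by default
        stride = max(1, n_steps // 20)
        out_idx = set(range(stride, n_steps + 1, stride)) | {n_steps}
    else:
        out_idx = set()
        for t_out in output_times:
            if t_out < 0 or t_out > config.duration + 0.5 * dt:
                raise ConfigError(
                    f"output time {t_out} outside [0, duration={config.duration}]"
                )
            out_idx.add(int(round(t_out / dt)))
        out_idx.discard(0)

    sp = species.with_timestep(dt)
    rng = np.random.default_rng(seed)
    ens = init_ensemble(config, geometry, rates, species=sp.name, rng=rng)
    snapshots = [ens]
    for i in range(1, n_steps + 1):
        ens = step(
            ens, sp, rates, geometry, dt, rng,
            switch_prob_rule=config.switch_prob_rule,
            boundary_rule=config.boundary_rule,
        )
        if i in out_idx:
            snapshots.append(ens)
    return Trajectory(
        snapshots=tuple(snapshots),
        config_hash=_config_hash(config, geometry, sp, rates),
        seed=seed,
    )


def run_replicates(
    config: SimConfig,
    geometry: EmbryoGeometry,
    species: SpeciesParams,
    rates: RateField,
    output_times: Sequence[float] | None = None,
    n_replicates: int | None = None,
) -> list[Trajectory]:
    """Run independent replicates; replicate r uses seed ``rng_seed + r``."""
    if n_replicates is None:
        n_replicates = config.n_replicates
    return [
        run_simulation(
            config, geometry, species, rates, output_times,
            seed=config.rng_seed + r,
        )
        for r in range(n_replicates)
    ]
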