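"""Diffusivity algebra for the two-state differential-diffusion model.

A protein interconverting between a slow (dephosphorylated, RNA-bound) and
a fast (phosphorylated) state has, on FRAP timescales, a region-averaged
diffusivity that is the occupancy-weighted mixture of the two component
diffusivities:

    D_average = f_slow * D_slow + (1 - f_slow) * D_fast

Measuring D_average in two regions (anterior / posterior) with known,
different slow-state occupancies gives a 2x2 linear system whose unique
solution is the (D_slow, D_fast) pair fed to the Monte Carlo simulator.

The simulator represents diffusion as a fixed-speed isotropic random walk;
the step speed that reproduces a diffusivity D at timestep dt is
``v = sqrt(6 D / dt)`` (per-step MSD = (v dt)^2 = 6 D dt).

The stationary occupancy of the slow state for a two-state switch with
kinase rate k (slow->fast) and phosphatase rate k_p (fast->slow), absent
transport, is ``k_p / (k_p + k)`` — only the kinase-to-phosphatase ratio
matters, which is why jointly rescaling all rates leaves the steady-state
gradient unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DomainError, FrapFitError, SingularSystemError

__all__ = [
    "RegionDiffusivity",
    "average_diffusivity",
    "split_diffusivities",
    "velocity_from_diffusivity",
    "local_equilibrium_slow_fraction",
    "FrapFit",
    "fit_frap_recovery",
    "write_diffusivity_table",
    "read_diffusivity_table",
]

#: Half-time coefficient for a uniform circular bleach spot:
#: D = SOUMPASIS_COEF * radius**2 / t_half  (Soumpasis half-time relation
#: for 2D diffusive recovery of a uniform disc).
SOUMPASIS_COEF = 0.224


@dataclass(frozen=True)
class RegionDiffusivity:
    """A region-averaged diffusivity with its slow-state occupancy."""

    region: Literal["anterior", "posterior"]
    D_average: float
    frac_slow: float

    def __post_init__(self) -> None:
        if self.D_average < 0:
            raise DomainError("D_average must be non-negative")
        if not (0.0 <= self.frac_slow <= 1.0):
            raise DomainError("frac_slow must lie in [0, 1]")


def average_diffusivity(D_slow: float, D_fast: float, frac_slow: float) -> float:
    """Occupancy-weighted mixture diffusivity.

    Forward form of the two-region decomposition; used as the inversion
    oracle for :func:`split_diffusivities`.
    """
    if not (0.0 <= frac_slow <= 1.0):
        raise DomainError("frac_slow must lie in [0, 1]")
    return frac_slow * D_slow + (1.0 - frac_slow) * D_fast


def split_diffusivities(
    anterior: RegionDiffusivity, posterior: RegionDiffusivity
) -> tuple[float, float]:
    """Solve the two-region mixture system for (D_slow, D_fast).

    Solves::

        f_A * D_slow + (1 - f_A) * D_fast = D_A
        f_P * D_slow + (1 - f_P) * D_fast = D_P

    Raises
    ------
    SingularSystemError
        If the two slow fractions are identical (system has no unique
        solution).

    Warns
    -----
    UserWarning
        If the solution has a negative component or D_slow > D_fast
        (physically inconsistent inputs).
    """
    fa, fp = anterior.frac_slow, posterior.frac_slow
    if math.isclose(fa, fp, rel_tol=0.0, abs_tol=1e-12):
        raise SingularSystemError(
            f"identical slow fractions ({fa}) in both regions: cannot separate "
            "slow and fast diffusivities"
        )
    A = np.array([[fa, 1.0 - fa], [fp, 1.0 - fp]])
    b = np.array([anterior.D_average, posterior.D_average])
    D_slow, D_fast = np.linalg.solve(A, b)
    if D_slow < 0 or D_fast < 0:
        warnings.warn(
            f"mixture inversion gave a negative diffusivity (D_slow={D_slow:.4g}, "
            f"D_fast={D_fast:.4g}); inputs are physically inconsistent",
            stacklevel=2,
        )
    if D_slow > D_fast:
        warnings.warn(
            "mixture inversion gave D_slow > D_fast; check region labelling",
            stacklevel=2,
        )
    return float(D_slow), float(D_fast)


def velocity_from_diffusivity(D: float, timestep: float) -> float:
    """Fixed-speed random-walk step speed for diffusivity D.

    ``v = sqrt(6 D / dt)``: a walker moving a distance v*dt per step in a
    uniformly random 3D direction has per-step mean-squared displacement
    6*D*dt, i.e. ensemble MSD(t) = 6*D*t exactly (directions independent).
    """
    if D < 0:
        raise DomainError("diffusivity must be non-negative")
    if timestep <= 0:
        raise DomainError("timestep must be positive")
    return math.sqrt(6.0 * D / timestep)


def local_equilibrium_slow_fraction(k_kinase: float, k_phosp: float) -> float:
    """Stationary slow-state occupancy of the two-state switch.

    Returns ``k_phosp / (k_phosp + k_kinase)``; depends only on the
    kinase-to-phosphatase ratio.

    Raises
    ------
    DomainError
        If both rates are zero (equilibrium undefined) or either negative.
    """
    if k_kinase < 0 or k_phosp < 0:
        raise DomainError("rates must be non-negative")
    total = k_kinase + k_phosp
    if total == 0:
        raise DomainError("both rates zero: stationary occupancy undefined")
    return k_phosp / total


# ---------------------------------------------------------------------------
# FRAP recovery fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapFit:
    """Result of a FRAP half-time fit.

    Attributes
    ----------
    D:
        Estimated diffusivity, µm²/s.
    t_half:
        Recovery half-time, s.
    low_confidence:
        True when the recovery was poorly sampled (half-recovery not
        reached inside the measurement window).
    diagnostics:
        Intermediate quantities: pre-bleach level, bleach depth, mobile
        fraction, fitted parameters.
    """

    D: float
    t_half: float
    low_confidence: bool
    diagnostics: dict

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.D


def _hyperbolic_recovery(t: np.ndarray, f_inf: float, t_half: float) -> np.ndarray:
    return f_inf * t / (t_half + t)


def fit_frap_recovery(
    times: Sequence[float],
    intensities: Sequence[float],
    bleach_radius: float,
) -> FrapFit:
    """Estimate a diffusivity from a FRAP recovery curve.

    The curve must contain a pre-bleach plateau, a bleach drop and at
    least 10 post-bleach samples.  The normalised recovery
    ``F(t) = (I(t) - I_post) / (I_pre - I_post)`` is fitted with the
    hyperbolic approximation ``F(t) = F_inf * t / (t_half + t)`` and the
    half-time converted to a diffusivity with the uniform-disc relation
    ``D = 0.224 * r^2 / t_half``.

    Raises
    ------
    FrapFitError
        If no bleach drop is present, the curve does not recover, or the
        fit fails; ``diagnostics`` on the exception carries intermediate
        quantities.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or len(t) < 12:
        raise FrapFitError("curve must be 1D with at least 12 samples")
    if bleach_radius <= 0:
        raise DomainError("bleach_radius must be positive")

    # Bleach frame = largest single-frame drop.
    drops = np.diff(y)
    i_bleach = int(np.argmin(drops)) + 1
    pre = y[:i_bleach]
    post_t = t[i_bleach:] - t[i_bleach]
    post_y = y[i_bleach:]
    diag = {"i_bleach": i_bleach, "n_post": len(post_y)}
    if len(pre) < 1 or len(post_y) < 10:
        raise FrapFitError("need a pre-bleach plateau and >= 10 post-bleach samples", diag)

    i_pre = float(np.mean(pre))
    i_post = float(post_y[0])
    depth = i_pre - i_post
    diag.update(pre_bleach=i_pre, post_bleach=i_post, bleach_depth=depth)
    if depth <= 0.05 * max(abs(i_pre), 1e-12):
        raise FrapFitError("no bleach drop detected", diag)

    frac = (post_y - i_post) / depth  # normalised recovery, 0 at bleach
    tail = float(np.mean(frac[-max(3, len(frac) // 10):]))
    diag["recovered_fraction"] = tail
    if tail < 0.1:
        raise FrapFitError("curve does not recover (immobile or D ~ 0)", diag)

    # Half-recovery crossing (relative to the recovered plateau) seeds the fit.
    half_level = 0.5 * tail
    above = np.nonzero(frac >= half_level)[0]
    t_half_guess = float(post_t[above[0]]) if len(above) else float(post_t[-1])
    t_half_guess = max(t_half_guess, float(post_t[1] - post_t[0]))

    try:
        popt, _ = curve_fit(
            _hyperbolic_recovery,
            post_t,
            frac,
            p0=[max(tail, 0.5), t_half_guess],
            bounds=([0.0, 1e-9], [1.5, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FrapFitError(f"recovery fit failed: {exc}", diag) from exc
    f_inf, t_half = float(popt[0]), float(popt[1])
    diag.update(mobile_fraction=f_inf, t_half=t_half)

    # Half recovery never reached inside the window -> extrapolated fit.
    low_confidence = bool(np.max(frac) < 0.5 or t_half > post_t[-1])
    D = SOUMPASIS_COEF * bleach_radius**2 / t_half
    return FrapFit(D=D, t_half=t_half, low_confidence=low_confidence, diagnostics=diag)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["region", "D_average", "frac_slow", "D_slow", "D_fast"]


def write_diffusivity_table(
    path: str | Path,
    anterior: RegionDiffusivity,
    posterior: RegionDiffusivity,
    D_slow: float,
    D_fast: float,
) -> None:
    """Write a two-row CSV of region measurements plus the decomposition."""
    df = pd.DataFrame(
        {
            "region": [anterior.region, posterior.region],
            "D_average": [anterior.D_average, posterior.D_average],
            "frac_slow": [anterior.frac_slow, posterior.frac_slow],
            "D_slow": [D_slow, D_slow],
            "D_fast": [D_fast, D_fast],
        }
    )
    df.to_csv(path, index=False)


def read_diffusivity_table(
    path: str | Path,
) -> tuple[RegionDiffusivity, RegionDiffusivity, float, float]:
    """Read a CSV written by :func:`write_diffusivity_table`."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"diffusivity table missing columns: {sorted(missing)}")
    regions = {}
    for _, row in df.iterrows():
        regions[row["region"]] = RegionDiffusivity(
            region=row["region"],
            D_average=float(row["D_average"]),
            frac_slow=float(row["frac_slow"]),
        )
    if set(regions) != {"anterior", "posterior"}:
        raise DomainError("table must contain exactly an anterior and a posterior row")
    return (
        regions["anterior"],
        regions["posterior"],
        float(df["D_slow"].iloc[0]),
        float(df["D_fast"].iloc[0]),
    )
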