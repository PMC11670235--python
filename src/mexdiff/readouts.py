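"""Quantitative readouts: slice concentration profiles and the AP gradient.

Two readouts turn particle ensembles (or intensity images) into numbers:

* **Concentration profile** — particles inside a central slab
  ``|z| <= slice_thickness/2`` are binned along the normalised AP
  coordinate.  Two conventions are available:

  - ``"count"``: per-bin particle count divided by the *total* number of
    simulated particles (the raw molecules-per-voxel-over-total
    convention; bins of the total component sum to the slab fraction,
    <= 1);
  - ``"density"`` (default): the count fraction additionally divided by
    the exact in-embryo volume of the bin's slab column, rescaled by the
    embryo volume.  A spatially uniform ensemble then yields a flat
    profile despite the elliptical cross-section (geometric chord
    correction).

  Bins whose slab column lies outside the ellipsoid are marked absent
  (NaN), not zero.

* **Gradient statistic** — the ordinary-least-squares slope of the
  mean-normalised profile versus the normalised AP coordinate
  (dIntensity/dx per embryo length).  Reported with the convention that
  an anterior-rich distribution gives a *positive* value; the raw signed
  slope is also available.  The outermost 5% of the AP axis is excluded
  from the fit by default (partial-voxel pole artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ComparisonError, ConfigError, InsufficientDataError
from .geometry_params import EmbryoGeometry
from .simulator import SLOW, Ensemble, Trajectory

__all__ = [
    "ConcentrationProfile",
    "GradientFit",
    "GradientSeries",
    "concentration_profile",
    "gradient_from_profile",
    "gradient_timeseries",
    "steady_state_gradient",
    "compare_series",
    "ComparisonResult",
    "profile_from_image",
    "gradient_from_image",
    "anterior_slow_fraction",
    "slab_column_volumes",
]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Per-bin normalised concentration along the AP axis.

    ``bin_centers`` are normalised AP coordinates in [0, 1]; absent bins
    (slab column outside the embryo) hold NaN.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    species_component: str
    convention: str
    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if self.bin_centers.shape != self.values.shape:
            raise ConfigError("bin_centers and values must have equal shape")


@dataclass(frozen=True)
class GradientFit:
    """OLS fit of a profile; ``value`` is anterior-rich-positive."""

    value: float
    raw_slope: float
    intercept: float
    stderr: float
    n_bins_used: int

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class GradientSeries:
    """Gradient statistic versus time (or stage), with replicate spread."""

    times: np.ndarray
    gradient: np.ndarray
    spread: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.gradient) == len(self.spread)):
            raise ConfigError("times, gradient and spread must have equal length")
        if np.any(self.spread < 0):
            raise ConfigError("spread must be non-negative")


def slab_column_volumes(
    geometry: EmbryoGeometry, edges_hat: np.ndarray, n_sub: int = 40
) -> np.ndarray:
    """In-embryo volume (µm³) of each AP bin's slab column.

    The cross-section at centred coordinate x is an ellipse with semi-axes
    b' = b*s, c' = c*s where s = sqrt(1 - (x/a)^2), truncated at
    |z| <= slice_thickness/2; its area has the closed form
    ``2 b' c' (asin(u) + u sqrt(1-u^2))`` with ``u = min(h/c', 1)``.
    Volumes are obtained by trapezoidal integration of the area along x.
    """
    a, b, c = geometry.semi_axis_ap, geometry.semi_axis_dv, geometry.semi_axis_lr
    h = geometry.slice_thickness / 2.0

    def area(x: np.ndarray) -> np.ndarray:
        s2 = np.clip(1.0 - (x / a) ** 2, 0.0, None)
        s = np.sqrt(s2)
        bp, cp = b * s, c * s
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(cp > 0, np.minimum(h / np.where(cp > 0, cp, 1.0), 1.0), 0.0)
        return 2.0 * bp * cp * (np.arcsin(u) + u * np.sqrt(1.0 - u**2))

    vols = np.empty(len(edges_hat) - 1)
    for i in range(len(vols)):
        x0 = (edges_hat[i] * 2.0 - 1.0) * a
        x1 = (edges_hat[i + 1] * 2.0 - 1.0) * a
        xs = np.linspace(x0, x1, n_sub)
        vols[i] = np.trapezoid(area(xs), xs)
    return vols


def concentration_profile(
    ensemble: Ensemble,
    geometry: EmbryoGeometry,
    n_bins: int = 30,
    component: str = "total",
    convention: str = "density",
) -> ConcentrationProfile:
    """Bin slab particles of one component along the normalised AP axis.

    Raises
    ------
    ConfigError
        If ``n_bins < 2`` or the convention/component is unknown.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    if convention not in ("density", "count"):
        raise ConfigError(f"unknown convention {convention!r}")

    half = geometry.slice_thickness / 2.0
    in_slab = np.abs(ensemble.positions[:, 2]) <= half
    sel = in_slab & ensemble.select(component)
    x_hat = geometry.normalized_ap(ensemble.positions[sel, 0])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(x_hat, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    vols = slab_column_volumes(geometry, edges)
    absent = vols <= 0.0

    frac = counts / ensemble.n_particles
    if convention == "count":
        values = frac.astype(float)
    else:
        v_embryo = (4.0 / 3.0) * np.pi * (
            geometry.semi_axis_ap * geometry.semi_axis_dv * geometry.semi_axis_lr
        )
        values = np.where(absent, np.nan, frac * v_embryo / np.where(absent, 1.0, vols))
    values = np.where(absent, np.nan, values)

    return ConcentrationProfile(
        bin_centers=centers,
        values=values,
        species_component=component,
        convention=convention,
        counts=counts,
        n_total=ensemble.n_particles,
    )


def _ols_gradient(
    centers: np.ndarray, values: np.ndarray, edge_exclude: float
) -> GradientFit:
    keep = np.isfinite(values) & (centers >= edge_exclude) & (centers <= 1.0 - edge_exclude)
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 occupied bins inside the fit window (got {int(keep.sum())})"
        )
    x = centers[keep]
    y = values[keep]
    mean = float(np.mean(y))
    if mean <= 0:
        raise InsufficientDataError("profile mean is not positive; cannot normalise")
    y = y / mean
    res = stats.linregress(x, y)
    return GradientFit(
        value=-float(res.slope),
        raw_slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        n_bins_used=int(keep.sum()),
    )


def gradient_from_profile(
    profile: ConcentrationProfile, edge_exclude: float = 0.05
) -> GradientFit:
    """OLS slope of the mean-normalised profile versus x_hat.

    Returns a :class:`GradientFit` whose ``value`` is the slope magnitude
    with the anterior-rich-positive sign convention (``value`` =
    ``-raw_slope``).  Requires at least 3 occupied bins inside the fit
    window.
    """
    return _ols_gradient(profile.bin_centers, profile.values, edge_exclude)


def gradient_timeseries(
    trajectories: Trajectory | Sequence[Trajectory],
    geometry: EmbryoGeometry,
    n_bins: int = 30,
    component: str = "total",
    convention: str = "density",
    edge_exclude: float = 0.05,
) -> GradientSeries:
    """Gradient statistic per snapshot, aggregated over replicates.

    Accepts a single trajectory or a list of replicate trajectories with
    identical snapshot times; returns mean and (ddof=1) SD per time.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if len(trajectories) == 0:
        raise ConfigError("need at least one trajectory")
    times = trajectories[0].times
    for tr in trajectories[1:]:
        if not np.allclose(tr.times, times):
            raise ConfigError("replicate trajectories must share snapshot times")

    per_rep = np.empty((len(trajectories), len(times)))
    for r, tr in enumerate(trajectories):
        for j, snap in enumerate(tr.snapshots):
            prof = concentration_profile(snap, geometry, n_bins, component, convention)
            per_rep[r, j] = gradient_from_profile(prof, edge_exclude).value
    mean = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if len(trajectories) > 1 else np.zeros_like(mean)
    return GradientSeries(times=times, gradient=mean, spread=sd)


def steady_state_gradient(
    series: GradientSeries, tail_frac: float = 0.1
) -> tuple[float, float, bool]:
    """Steady-state gradient: mean over the final fraction of the series.

    Returns ``(value, sd, drifting)`` where ``sd`` is the mean replicate
    spread over the tail and ``drifting`` flags a residual linear trend
    across the tail larger than that spread.
    """
    n = len(series.times)
    k = max(2, int(np.ceil(tail_frac * n)))
    t = series.times[-k:]
    g = series.gradient[-k:]
    sd = float(np.mean(series.spread[-k:]))
    value = float(np.mean(g))
    slope = float(np.polyfit(t, g, 1)[0]) if len(t) > 1 else 0.0
    change = abs(slope * (t[-1] - t[0]))
    drifting = change > max(sd, 1e-3)
    return value, sd, drifting


@dataclass(frozen=True)
class ComparisonResult:
    """Per-time residuals (sim - reference) and their RMS."""

    times: np.ndarray
    residuals: np.ndarray
    rms: float


def compare_series(sim: GradientSeries, reference: GradientSeries) -> ComparisonResult:
    """Residuals between two gradient series on their common time support.

    Both series are linearly interpolated onto the union of their time
    points inside the overlap; no fitting is performed.

    Raises
    ------
    ComparisonError
        If the time ranges are disjoint.
    """
    lo = max(sim.times.min(), reference.times.min())
    hi = min(sim.times.max(), reference.times.max())
    if lo > hi:
        raise ComparisonError("series have disjoint time ranges")
    grid = np.union1d(sim.times, reference.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    g_sim = np.interp(grid, sim.times, sim.gradient)
    g_ref = np.interp(grid, reference.times, reference.gradient)
    resid = g_sim - g_ref
    return ComparisonResult(times=grid, residuals=resid, rms=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# Image-based readout (synthetic epifluorescence-like frames)
# ---------------------------------------------------------------------------


def profile_from_image(
    pixels: np.ndarray, mask: np.ndarray, n_bins: int = 30
) -> ConcentrationProfile:
    """Mean in-mask intensity per normalised-AP bin of a 2D image.

    The image x axis (columns) is the AP axis; x_hat for a column is its
    centre position relative to the image width.  Bins without mask
    pixels are absent (NaN).
    """
    if pixels.shape != mask.shape or pixels.ndim != 2:
        raise ConfigError("pixels and mask must be 2D arrays of equal shape")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    ny, nx = pixels.shape
    x_hat_cols = (np.arange(nx) + 0.5) / nx
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(x_hat_cols, edges) - 1, 0, n_bins - 1)

    values = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        cols = idx == b
        m = mask[:, cols]
        if m.any():
            values[b] = float(pixels[:, cols][m].mean())
            counts[b] = int(m.sum())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ConcentrationProfile(
        bin_centers=centers,
        values=values,
        species_component="total",
        convention="intensity",
        counts=counts,
        n_total=int(mask.sum()),
    )


def gradient_from_image(
    pixels: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 30,
    edge_exclude: float = 0.05,
) -> GradientFit:
    """Gradient statistic of a 2D intensity image (convenience wrapper)."""
    return gradient_from_profile(profile_from_image(pixels, mask, n_bins), edge_exclude)


def anterior_slow_fraction(
    ensemble: Ensemble, geometry: EmbryoGeometry, region_frac: float = 0.2
) -> float:
    """Fraction of slow-state molecules among those in the anterior region.

    The region is ``x_hat <= region_frac`` (default: the anterior-most
    20% of the AP axis).
    """
    if not (0 < region_frac <= 1):
        raise ConfigError("region_frac must lie in (0, 1]")
    x_hat = geometry.normalized_ap(ensemble.positions[:, 0])
    region = x_hat <= region_frac
    if not region.any():
        raise InsufficientDataError("no particles in the anterior region")
    return float(np.mean(ensemble.states[region] == SLOW))
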