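"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without any
experimental download:

* graded embryo *images* — a linear AP intensity ramp inside an
  elliptical mask plus additive noise, emulating midplane
  epifluorescence frames;
* staged gradient *time series* — per-embryo slopes drawn around
  stage-mean values, emulating stage-resolved bar plots;
* *FRAP recovery curves* — free particles at a known diffusivity with a
  cylindrical bleach column, recording the bleach-region mean.

All generators are fully deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .diffusivity import velocity_from_diffusivity
from .exceptions import ConfigError, DomainError
from .geometry_params import EmbryoGeometry
from .readouts import GradientSeries
from .simulator import (
    Ensemble,
    _random_unit_vectors,
    _reflect_into_ellipsoid,
    sample_uniform_in_ellipsoid,
)

__all__ = [
    "SyntheticImage",
    "SyntheticFrapCurve",
    "make_gradient_image",
    "make_staged_series",
    "make_frap_curve",
    "render_ensemble_image",
    "DEFAULT_STAGE_SLOPES",
    "write_image",
    "read_image",
    "write_frap_curve",
    "read_frap_curve",
]

#: Monotone stage template for the gradient statistic, ending at the
#: steady-state scale 0.55 (stages of the first cell division).
DEFAULT_STAGE_SLOPES: Mapping[str, float] = {
    "Relax. at P": 0.10,
    "PC": 0.25,
    "PNM": 0.38,
    "PNC": 0.47,
    "NEBD": 0.55,
}


@dataclass(frozen=True)
class SyntheticImage:
    """A 2D intensity frame with its embryo mask and generating truth."""

    pixels: np.ndarray
    mask: np.ndarray
    pixel_size: float
    truth: dict

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape or self.pixels.ndim != 2:
            raise ConfigError("pixels and mask must be 2D arrays of equal shape")
        if np.any(self.pixels < 0):
            raise ConfigError("intensities must be non-negative")


@dataclass(frozen=True)
class SyntheticFrapCurve:
    """A FRAP recovery curve with known generating diffusivity."""

    times: np.ndarray
    intensities: np.ndarray
    bleach_time: float
    bleach_radius: float
    truth_D: float
    seed: int


def make_gradient_image(
    slope: float,
    noise_sd: float,
    geometry: EmbryoGeometry | None = None,
    pixel_size: float = 0.5,
    mean_intensity: float = 100.0,
    seed: int = 0,
) -> SyntheticImage:
    """Render a linear AP intensity gradient inside an elliptical mask.

    Noiseless intensity ``I(x_hat) = mean * (1 + slope * (0.5 - x_hat))``
    inside the mask (anterior-rich for positive slope), zero outside;
    independent Gaussian noise with SD ``noise_sd * mean`` is added
    in-mask and the result clipped at zero.

    Raises
    ------
    DomainError
        If ``|slope| >= 2`` (negative noiseless intensity) or
        ``noise_sd < 0``.
    """
    if abs(slope) >= 2:
        raise DomainError("|slope| must be < 2 to keep intensities positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if geometry is None:
        geometry = EmbryoGeometry()
    a, b = geometry.semi_axis_ap, geometry.semi_axis_dv
    nx = int(round(2 * a / pixel_size))
    ny = int(round(2 * b / pixel_size))
    x = (np.arange(nx) + 0.5) * pixel_size - a
    y = (np.arange(ny) + 0.5) * pixel_size - b
    xx, yy = np.meshgrid(x, y)
    mask = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    x_hat = (xx + a) / (2 * a)
    clean = mean_intensity * (1.0 + slope * (0.5 - x_hat))

    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd * mean_intensity, size=clean.shape)
    pixels = np.where(mask, np.clip(noisy, 0.0, None), 0.0)
    truth = {
        "slope": float(slope),
        "baseline": float(mean_intensity),
        "noise_model": "additive_gaussian",
        "noise_sd": float(noise_sd),
        "pixel_size": float(pixel_size),
        "seed": int(seed),
    }
    return SyntheticImage(pixels=pixels, mask=mask, pixel_size=pixel_size, truth=truth)


def make_staged_series(
    stage_slopes: Mapping[str, float] | None = None,
    per_embryo_sd: float = 0.08,
    n_embryos: int = 10,
    seed: int = 0,
) -> GradientSeries:
    """Staged gradient series: per-embryo slopes around stage means.

    Stage order follows the mapping's insertion order; times are the
    stage indices.  With a single embryo and zero SD the series equals
    the stage means exactly.  Spread is the ddof=1 sample SD (zero for a
    single embryo).
    """
    if stage_slopes is None:
        stage_slopes = DEFAULT_STAGE_SLOPES
    if n_embryos < 1:
        raise ConfigError("n_embryos must be >= 1")
    if per_embryo_sd < 0:
        raise ConfigError("per_embryo_sd must be non-negative")
    rng = np.random.default_rng(seed)
    labels = tuple(stage_slopes)
    means = np.array([stage_slopes[s] for s in labels], dtype=float)
    draws = rng.normal(means[:, None], per_embryo_sd, size=(len(labels), n_embryos))
    gradient = draws.mean(axis=1)
    spread = draws.std(axis=1, ddof=1) if n_embryos > 1 else np.zeros(len(labels))
    if per_embryo_sd == 0:
        gradient = means.copy()
    return GradientSeries(
        times=np.arange(len(labels), dtype=float),
        gradient=gradient,
        spread=spread,
        labels=labels,
    )


def make_frap_curve(
    truth_D: float,
    bleach_radius: float = 5.0,
    sampling: float = 0.2,
    noise_sd: float = 0.0,
    duration: float = 120.0,
    n_particles: int = 60_000,
    n_prebleach: int = 5,
    geometry: EmbryoGeometry | None = None,
    seed: int = 0,
) -> SyntheticFrapCurve:
    """Simulate a FRAP experiment on freely diffusing particles.

    Particles diffuse (no state switching) at ``truth_D`` inside the
    ellipsoid via the fixed-speed random walk; those initially inside the
    central cylindrical bleach column ``x^2 + y^2 <= r^2`` are marked
    dark at t = 0 and the bleach-region mean brightness is recorded at
    every sampling interval.  Gaussian noise of SD ``noise_sd`` (on the
    0..1 intensity scale) is added to the readout.
    """
    if truth_D < 0:
        raise DomainError("truth_D must be non-negative")
    if geometry is None:
        geometry = EmbryoGeometry()
    rng = np.random.default_rng(seed)
    pos = sample_uniform_in_ellipsoid(rng, n_particles, geometry)
    step_len = velocity_from_diffusivity(truth_D, sampling) * sampling

    def in_region(p: np.ndarray) -> np.ndarray:
        return p[:, 0] ** 2 + p[:, 1] ** 2 <= bleach_radius**2

    bright = ~in_region(pos)  # bleach at t = 0
    n_post = int(round(duration / sampling))
    times = np.concatenate(
        [(-np.arange(n_prebleach, 0, -1)) * sampling, np.arange(n_post + 1) * sampling]
    )
    intensities = np.empty(len(times))
    intensities[:n_prebleach] = 1.0  # pre-bleach plateau

    for i in range(n_post + 1):
        if i > 0 and step_len > 0:
            prop = pos + _random_unit_vectors(rng, n_particles) * step_len
            pos = _reflect_into_ellipsoid(pos, prop, geometry)
        region = in_region(pos)
        intensities[n_prebleach + i] = float(np.mean(bright[region]))

    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=len(intensities))
    return SyntheticFrapCurve(
        times=times,
        intensities=intensities,
        bleach_time=0.0,
        bleach_radius=bleach_radius,
        truth_D=truth_D,
        seed=seed,
    )


def render_ensemble_image(
    ensemble: Ensemble,
    geometry: EmbryoGeometry,
    pixel_size: float = 1.0,
) -> SyntheticImage:
    """Project slab particles of an ensemble into a 2D count image.

    Particles with ``|z| <= slice_thickness/2`` are histogrammed into
    (x, y) pixels, emulating a midplane fluorescence frame.  The analysis
    mask is the ellipse shrunk so that the slab is fully contained in the
    embryo at every mask pixel (uniform optical depth); at the default
    geometry this trims only a ~1.4% rim.
    """
    a, b, c = geometry.semi_axis_ap, geometry.semi_axis_dv, geometry.semi_axis_lr
    half = geometry.slice_thickness / 2.0
    in_slab = np.abs(ensemble.positions[:, 2]) <= half
    pts = ensemble.positions[in_slab]

    nx = int(round(2 * a / pixel_size))
    ny = int(round(2 * b / pixel_size))
    counts, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0], bins=[ny, nx], range=[[-b, b], [-a, a]]
    )
    x = (np.arange(nx) + 0.5) * pixel_size - a
    y = (np.arange(ny) + 0.5) * pixel_size - b
    xx, yy = np.meshgrid(x, y)
    shrink = 1.0 - (half / c) ** 2  # slab fully inside the ellipsoid
    mask = (xx / a) ** 2 + (yy / b) ** 2 <= shrink
    truth = {
        "source": "ensemble",
        "time_s": float(ensemble.time),
        "species": ensemble.species,
        "pixel_size": float(pixel_size),
    }
    return SyntheticImage(pixels=counts, mask=mask, pixel_size=pixel_size, truth=truth)


# ---------------------------------------------------------------------------
# File I/O: TIFF images with YAML truth sidecars, CSV curves
# ---------------------------------------------------------------------------


def write_image(image: SyntheticImage, path: str | Path) -> None:
    """Write a synthetic image as 32-bit TIFF plus a YAML truth sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".yaml")
    meta = dict(image.truth)
    meta["pixel_size"] = image.pixel_size
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_image(path: str | Path, geometry: EmbryoGeometry | None = None) -> SyntheticImage:
    """Read a TIFF written by :func:`write_image`; mask rebuilt from shape."""
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    truth = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    pixel_size = float(truth.get("pixel_size", 1.0))
    ny, nx = pixels.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    a, b = nx / 2.0, ny / 2.0
    mask = ((xx + 0.5 - a) / a) ** 2 + ((yy + 0.5 - b) / b) ** 2 <= 1.0
    return SyntheticImage(pixels=pixels, mask=mask, pixel_size=pixel_size, truth=truth)


def write_frap_curve(curve: SyntheticFrapCurve, path: str | Path) -> None:
    """Write a FRAP curve as CSV (time_s, intensity)."""
    pd.DataFrame({"time_s": curve.times, "intensity": curve.intensities}).to_csv(
        path, index=False
    )


def read_frap_curve(
    path: str | Path,
    bleach_radius: float,
    truth_D: float = float("nan"),
    seed: int = -1,
) -> SyntheticFrapCurve:
    """Read a CSV written by :func:`write_frap_curve`."""
    df = pd.read_csv(path)
    return SyntheticFrapCurve(
        times=df["time_s"].to_numpy(dtype=float),
        intensities=df["intensity"].to_numpy(dtype=float),
        bleach_time=0.0,
        bleach_radius=bleach_radius,
        truth_D=truth_D,
        seed=seed,
    )
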