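"""Independent continuum oracle for the two-state switch-diffusion model.

Solves the 1D anterior-posterior reduction of the reaction-diffusion
system by the method of lines, with the ellipse cross-sectional area
entering the transport operator (flux form ``(1/A) d/dx (A D dc/dx)``)
and no-flux boundaries:

    dc_s/dt = (1/A) d/dx (A D_s dc_s/dx) - k(x) c_s + k_p c_f
    dc_f/dt = (1/A) d/dx (A D_f dc_f/dx) + k(x) c_s - k_p c_f

This is a continuum description of the same model the Monte Carlo engine
samples, derived and solved completely independently of it (scipy BDF
integrator on a finite-volume grid), so agreement between the two is a
meaningful cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp


def solve_gradient(
    D_slow: float,
    D_fast: float,
    k_low: float,
    k_upp: float,
    k_phosp: float,
    times: list[float],
    semi_ap: float = 25.0,
    semi_dv: float = 15.0,
    semi_lr: float = 15.0,
    nx: int = 150,
    edge_exclude: float = 0.05,
) -> dict[str, np.ndarray]:
    """Gradient statistic of total/slow/fast profiles at the given times.

    Returns a dict with keys ``total``, ``slow``, ``fast`` (anterior-rich
    positive, same convention as the package readout) and
    ``anterior_slow_fraction`` (area-weighted, x_hat <= 0.2).
    """
    L = 2.0 * semi_ap
    x = np.linspace(0.0, L, nx)
    dx = x[1] - x[0]
    s2 = np.clip(1.0 - ((x - semi_ap) / semi_ap) ** 2, 1e-9, None)
    area = np.pi * semi_dv * semi_lr * s2
    k = k_low + (k_upp - k_low) * x / L
    area_face = 0.5 * (area[1:] + area[:-1])

    def transport(D: float, c: np.ndarray) -> np.ndarray:
        flux = D * area_face * np.diff(c) / dx
        div = np.zeros(nx)
        div[1:-1] = (flux[1:] - flux[:-1]) / dx
        div[0] = flux[0] / dx
        div[-1] = -flux[-1] / dx
        return div / area

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        cs, cf = y[:nx], y[nx:]
        react = k * cs - k_phosp * cf
        return np.concatenate(
            [transport(D_slow, cs) - react, transport(D_fast, cf) + react]
        )

    y0 = np.concatenate([0.5 * np.ones(nx), 0.5 * np.ones(nx)])
    t_eval = sorted(set(float(t) for t in times))
    sol = solve_ivp(
        rhs, (0.0, max(t_eval)), y0, t_eval=t_eval, method="BDF",
        rtol=1e-6, atol=1e-9,
    )
    x_hat = x / L
    keep = (x_hat >= edge_exclude) & (x_hat <= 1.0 - edge_exclude)
    out: dict[str, list[float]] = {"total": [], "slow": [], "fast": [],
                                   "anterior_slow_fraction": []}
    for i in range(len(t_eval)):
        cs, cf = sol.y[:nx, i], sol.y[nx:, i]
        for name, c in (("total", cs + cf), ("slow", cs), ("fast", cf)):
            g = -stats.linregress(x_hat[keep], c[keep] / c[keep].mean()).slope
            out[name].append(float(g))
        ant = x_hat <= 0.2
        w = area[ant]
        out["anterior_slow_fraction"].append(
            float(np.sum(cs[ant] * w) / np.sum((cs + cf)[ant] * w))
        )
    return {k: np.asarray(v) for k, v in out.items()}
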