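"""Synthetic umbrella-sampling data with analytic ground truth.

Used to validate the WHAM machinery: samples are drawn *exactly* (inverse
CDF on a fine grid) from the biased Boltzmann densities of known model
potentials, so the reconstructed profile can be compared against the
analytic free energy without any dynamics in between.
"""

from __future__ import annotations

from typing import Callable, List, Tuple

import numpy as np

from .units import KB
from .wham import UmbrellaWindow

__all__ = ["double_well", "sample_biased_1d", "double_well_windows",
           "separable_2d_windows", "analytic_profile_1d"]


def double_well(barrier_kt: float = 5.0, half_width: float = 5.0,
                temperature: float = 300.0) -> Callable[[np.ndarray], np.ndarray]:
    """Symmetric double well ``U(x) = Eb ((x/a)^2 - 1)^2`` (kcal/mol).

    ``barrier_kt`` is the barrier height in k_BT; minima sit at ``x = ±a``.
    """
    eb = barrier_kt * KB * temperature
    a = half_width

    def u(x):
        return eb * ((np.asarray(x) / a) ** 2 - 1.0) ** 2

    return u


def sample_biased_1d(potential: Callable, k: float, center: float, n: int,
                     rng: np.random.Generator, x_range: Tuple[float, float],
                     temperature: float = 300.0, n_grid: int = 4001) -> np.ndarray:
    """Exact inverse-CDF samples from ``exp(-beta (U(x) + k (x-c)^2))``."""
    beta = 1.0 / (KB * temperature)
    x = np.linspace(*x_range, n_grid)
    logp = -beta * (potential(x) + k * (x - center) ** 2)
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, x)


def double_well_windows(seed: int, n_windows: int = 12, n_total: int = 200000,
                        barrier_kt: float = 5.0, half_width: float = 5.0,
                        k_spring: float = 0.15,
                        temperature: float = 300.0) -> Tuple[List[UmbrellaWindow], Callable]:
    """Umbrella windows across the double well plus its analytic potential."""
    rng = np.random.default_rng(seed)
    u = double_well(barrier_kt, half_width, temperature)
    span = 1.5 * half_width
    centers = np.linspace(-span, span, n_windows)
    n_per = n_total // n_windows
    x_range = (-2.0 * half_width, 2.0 * half_width)
    windows = [UmbrellaWindow(cv_names=("x",), k=k_spring, center=c,
                              samples=sample_biased_1d(u, k_spring, c, n_per, rng,
                                                       x_range, temperature),
                              temperature=temperature)
               for c in centers]
    return windows, u


def separable_2d_windows(seed: int, n_windows: int = 6, n_per: int = 4000,
                         kx: float = 0.05, ky: float = 0.05,
                         temperature: float = 300.0):
    """Windows over a separable quadratic potential U = ax x^2 + ay y^2.

    Gaussian sampling is exact here; returns (windows, (ax, ay)).
    """
    rng = np.random.default_rng(seed)
    ax, ay = 0.02, 0.03          # kcal/mol/A^2
    beta = 1.0 / (KB * temperature)
    windows = []
    centers = np.linspace(-8.0, 8.0, n_windows)
    for cx in centers:
        for cy in centers:
            # biased density stays Gaussian: combine curvatures and means
            sx = 1.0 / np.sqrt(2.0 * beta * (ax + kx))
            sy = 1.0 / np.sqrt(2.0 * beta * (ay + ky))
            mx = kx * cx / (ax + kx)
            my = ky * cy / (ay + ky)
            xs = rng.normal(mx, sx, n_per)
            ys = rng.normal(my, sy, n_per)
            windows.append(UmbrellaWindow(
                cv_names=("x", "y"), k=(kx, ky), center=(cx, cy),
                samples=np.stack([xs, ys], axis=1), temperature=temperature))
    return windows, (ax, ay)


def analytic_profile_1d(potential: Callable, bin_edges: np.ndarray,
                        temperature: float = 300.0) -> np.ndarray:
    """Bin-averaged analytic free energy (k_BT, min 0) for comparison."""
    beta = 1.0 / (KB * temperature)
    F = np.empty(len(bin_edges) - 1)
    for i, (a, b) in enumerate(zip(bin_edges[:-1], bin_edges[1:])):
        xs = np.linspace(a, b, 41)
        F[i] = -np.log(np.trapezoid(np.exp(-beta * potential(xs)), xs))
    return F - F.min()
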