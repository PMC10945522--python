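"""Weighted histogram analysis (WHAM) for umbrella-sampled free energies.

Reconstructs 1D/2D free-energy profiles (in k_BT units) from harmonically
biased windows, computes reweighted observable averages, and combines
independent replicas into per-bin error bars.  The bias convention matches
:mod:`chromion.restraints`: ``U_w(x) = k (x - center)^2`` per dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .units import KB

__all__ = ["UmbrellaWindow", "FreeEnergyProfile", "wham", "wham2d",
           "reweight_observable", "independent_error", "binding_free_energy"]


@dataclass
class UmbrellaWindow:
    """Samples of one biased simulation window.

    ``samples`` has shape (N,) for 1D or (N, d) for d-dimensional CVs;
    ``k`` and ``center`` are scalars or length-d sequences.  Bias energy:
    ``sum_dim k_d (x_d - c_d)^2`` (kcal/mol).
    """

    cv_names: Tuple[str, ...]
    k: np.ndarray
    center: np.ndarray
    samples: np.ndarray
    temperature: float = 300.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.samples.shape[0] == 1 and self.samples.shape[1] > 1 \
                and np.isscalar(self.k):
            self.samples = self.samples.T
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        d = self.samples.shape[1]
        self.k = np.broadcast_to(np.atleast_1d(np.asarray(self.k, float)), (d,)).copy()
        self.center = np.broadcast_to(np.atleast_1d(np.asarray(self.center, float)),
                                      (d,)).copy()
        if isinstance(self.cv_names, str):
            self.cv_names = (self.cv_names,)

    @property
    def ndim(self) -> int:
        return self.samples.shape[1]

    def bias_energy(self, points: np.ndarray) -> np.ndarray:
        """Bias energy (kcal/mol) at CV points of shape (..., d)."""
        pts = np.atleast_2d(points)
        return np.sum(self.k * (pts - self.center) ** 2, axis=-1)


@dataclass
class FreeEnergyProfile:
    """Free energy over a 1D or 2D grid, in k_BT, minimum shifted to 0.

    Bins never visited by any window are NaN (undefined, not interpolated).
    """

    bin_centers: Tuple[np.ndarray, ...]
    free_energy: np.ndarray
    counts: np.ndarray
    error: Optional[np.ndarray] = None
    window_free_energies: Optional[np.ndarray] = None
    temperature: float = 300.0

    @property
    def ndim(self) -> int:
        return len(self.bin_centers)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            if self.ndim == 1:
                fh.write("# cv\tfree_energy_kBT\tcounts\n")
                for x, f, c in zip(self.bin_centers[0], self.free_energy, self.counts):
                    fh.write(f"{x:.6f}\t{f:.6f}\t{int(c)}\n")
            else:
                fh.write("# cv1\tcv2\tfree_energy_kBT\tcounts\n")
                for i, x in enumerate(self.bin_centers[0]):
                    for j, y in enumerate(self.bin_centers[1]):
                        fh.write(f"{x:.6f}\t{y:.6f}\t{self.free_energy[i, j]:.6f}\t"
                                 f"{int(self.counts[i, j])}\n")


def _edges_to_centers(edges):
    return 0.5 * (edges[:-1] + edges[1:])


def _check_overlap(windows, hists):
    if len(windows) < 2:
        return
    occupied = [h > 0 for h in hists]
    for i, occ in enumerate(occupied):
        if not any(np.any(occ & other) for j, other in enumerate(occupied) if j != i):
            raise ValueError(f"window {i} (center {windows[i].center}) shares no "
                             f"occupied bin with any other window")
    order = np.argsort([w.center[0] for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            warnings.warn(f"adjacent windows {a} and {b} share no occupied bin; "
                          f"the profile may be disconnected there")


def _wham_nd(windows: Sequence[UmbrellaWindow], edges: Sequence[np.ndarray],
             tolerance: float, max_iter: int):
    d = windows[0].ndim
    T = windows[0].temperature
    for w in windows:
        if w.ndim != d:
            raise ValueError("windows have inconsistent CV dimensionality")
        if abs(w.temperature - T) > 1e-9:
            raise ValueError("windows must share one temperature")
    beta = 1.0 / (KB * T)
    edges = [np.asarray(e, float) for e in edges]
    centers = [_edges_to_centers(e) for e in edges]
    shape = tuple(len(c) for c in centers)

    hists = []
    for w in windows:
        h, _ = np.histogramdd(w.samples, bins=edges)
        hists.append(h)
    _check_overlap(windows, hists)

    n_tot = np.sum(hists, axis=0)                       # (bins,)
    N = np.array([w.samples.shape[0] for w in windows], float)
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)   # (B, d)
    bias = np.array([np.exp(-beta * w.bias_energy(pts)) for w in windows])  # (W, B)

    f = np.zeros(len(windows))                          # -ln <exp(-beta U)> offsets
    flat_n = n_tot.ravel()
    for it in range(max_iter):
        denom = (N * np.exp(f)) @ bias                  # (B,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, flat_n / denom, 0.0)
        z = bias @ p                                    # (W,)
        f_new = -np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise RuntimeError(f"WHAM failed to converge: residual {delta:.3e} "
                           f"k_BT after {max_iter} iterations")

    denom = (N * np.exp(f)) @ bias
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where((flat_n > 0) & (denom > 0), flat_n / denom, np.nan)
        F = -np.log(p)
    F = F.reshape(shape)
    F -= np.nanmin(F)
    return FreeEnergyProfile(bin_centers=tuple(centers), free_energy=F,
                             counts=n_tot.reshape(shape),
                             window_free_energies=f, temperature=T)


def wham(windows: Sequence[UmbrellaWindow], bins: np.ndarray,
         tolerance: float = 1e-7, max_iter: int = 100000) -> FreeEnergyProfile:
    """Self-consistent 1D WHAM over bin edges ``bins``.

    Iterates the coupled histogram/offset equations until the maximum change
    in window free energies falls below ``tolerance`` (k_BT); the profile is
    normalized to minimum 0.
    """
    return _wham_nd(windows, [np.asarray(bins, float)], tolerance, max_iter)


def wham2d(windows: Sequence[UmbrellaWindow], grid: Sequence[np.ndarray],
           tolerance: float = 1e-7, max_iter: int = 100000) -> FreeEnergyProfile:
    """2D WHAM over ``grid = (edges_x, edges_y)`` with per-dimension biases."""
    if len(grid) != 2:
        raise ValueError("grid must provide two edge arrays")
    return _wham_nd(windows, list(grid), tolerance, max_iter)


def reweight_observable(windows: Sequence[UmbrellaWindow],
                        observables: Sequence[np.ndarray],
                        bins: np.ndarray) -> Tuple[float, float]:
    """Unbiased ensemble average of an observable sampled alongside the CV.

    ``observables[i]`` must align sample-by-sample with ``windows[i]``.
    Returns ``(expectation, standard_error)`` with the error from the
    weighted effective sample size.
    """
    if len(observables) != len(windows):
        raise ValueError("need one observable series per window")
    prof = _wham_nd(windows, [np.asarray(bins, float)]
                    if windows[0].ndim == 1 else list(bins), 1e-10, 200000)
    f = prof.window_free_energies
    beta = 1.0 / (KB * windows[0].temperature)
    N = np.array([w.samples.shape[0] for w in windows], float)

    all_w, all_o = [], []
    for i, (w, obs) in enumerate(zip(windows, observables)):
        obs = np.asarray(obs, float)
        if obs.shape[0] != w.samples.shape[0]:
            raise ValueError(f"window {i}: observable length {obs.shape[0]} != "
                             f"sample length {w.samples.shape[0]}")
        denom = np.zeros(w.samples.shape[0])
        for j, wj in enumerate(windows):
            denom += N[j] * np.exp(f[j] - beta * wj.bias_energy(w.samples))
        all_w.append(1.0 / denom)
        all_o.append(obs)
    wts = np.concatenate(all_w)
    obs = np.concatenate(all_o)
    wts = wts / wts.sum()
    mean = float(np.sum(wts * obs))
    n_eff = 1.0 / np.sum(wts ** 2)
    var = float(np.sum(wts * (obs - mean) ** 2))
    return mean, float(np.sqrt(var / max(n_eff, 1.0)))


def independent_error(profiles: Sequence[FreeEnergyProfile]) -> np.ndarray:
    """Per-bin standard deviation across independent (normalized) estimates."""
    if len(profiles) < 2:
        raise ValueError("need at least two independent profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.ndim != ref.ndim or any(
                len(a) != len(b) or not np.allclose(a, b)
                for a, b in zip(p.bin_centers, ref.bin_centers)):
            raise ValueError("profiles are on different grids")
    stack = np.stack([p.free_energy for p in profiles])
    return np.std(stack, axis=0)


def binding_free_energy(profile: FreeEnergyProfile,
                        plateau_range: Tuple[float, float],
                        min_counts: int = 1) -> float:
    """Binding free energy (k_BT): plateau at large separation minus the
    global minimum.  Invariant to the profile normalization convention.

    Bins with fewer than ``min_counts`` samples are treated as undefined,
    so a near-empty edge bin cannot masquerade as a deep minimum.
    """
    x = profile.bin_centers[0]
    F = np.where(profile.counts >= min_counts, profile.free_energy, np.nan)
    mask = (x >= plateau_range[0]) & (x <= plateau_range[1]) & np.isfinite(F)
    if not np.any(mask):
        raise ValueError("no defined bins in the plateau range")
    return float(np.nanmean(F[mask]) - np.nanmin(F))
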