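"""Compiled pair-interaction kernels.

Tight loops over precomputed pair lists, JIT-compiled with numba.  Each
kernel accumulates forces in place and returns the term energy; ``box <= 0``
means open boundaries, otherwise cubic minimum-image convention.  The
functional forms mirror the reference implementations in
:mod:`chromion.potentials` exactly.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["lj_kernel", "wca_kernel", "ion_pair_kernel", "coulomb_kernel",
           "ewald_real_kernel"]


@njit(cache=True)
def _mi(d, box):
    if box > 0.0:
        for k in range(3):
            d[k] -= box * np.rint(d[k] / box)
    return d


@njit(cache=True)
def lj_kernel(x, ii, jj, eps, sig, cut_factor, global_cut, box, F):
    """LJ with minimum at sigma, cut and shifted at min(cut_factor*sigma, global_cut)."""
    e = 0.0
    d = np.empty(3)
    for p in range(ii.shape[0]):
        a, b = ii[p], jj[p]
        for k in range(3):
            d[k] = x[a, k] - x[b, k]
        _mi(d, box)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        rc = cut_factor * sig[p]
        if rc > global_cut:
            rc = global_cut
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        if r < 1e-6:
            return np.nan
        s6 = (sig[p] / r) ** 6
        sc6 = (sig[p] / rc) ** 6
        e += eps[p] * (s6 * s6 - 2.0 * s6) - eps[p] * (sc6 * sc6 - 2.0 * sc6)
        dudr = -12.0 * eps[p] / r * (s6 * s6 - s6)
        coef = -dudr / r
        for k in range(3):
            f = coef * d[k]
            F[a, k] += f
            F[b, k] -= f
    return e


@njit(cache=True)
def wca_kernel(x, ii, jj, eps, sig, box, F):
    e = 0.0
    d = np.empty(3)
    for p in range(ii.shape[0]):
        a, b = ii[p], jj[p]
        for k in range(3):
            d[k] = x[a, k] - x[b, k]
        _mi(d, box)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if r2 >= sig[p] * sig[p]:
            continue
        r = np.sqrt(r2)
        if r < 1e-6:
            return np.nan
        s6 = (sig[p] / r) ** 6
        e += eps[p] * (s6 * s6 - 2.0 * s6) + eps[p]
        dudr = -12.0 * eps[p] / r * (s6 * s6 - s6)
        coef = -dudr / r
        for k in range(3):
            f = coef * d[k]
            F[a, k] += f
            F[b, k] -= f
    return e


@njit(cache=True)
def ion_pair_kernel(x, ii, jj, eps, sig, rm, sw, H1, r1, s1, H2, r2g, s2,
                    cutoff, box, F):
    """Charged-pair short-range term: WCA core + Gaussian well + hydration."""
    e = 0.0
    d = np.empty(3)
    for p in range(ii.shape[0]):
        a, b = ii[p], jj[p]
        for k in range(3):
            d[k] = x[a, k] - x[b, k]
        _mi(d, box)
        rr2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if rr2 >= cutoff * cutoff:
            continue
        r = np.sqrt(rr2)
        if r < 1e-6:
            return np.nan
        u = 0.0
        dudr = 0.0
        if r < sig[p]:
            s6 = (sig[p] / r) ** 6
            u += eps[p] * (s6 * s6 - 2.0 * s6) + eps[p]
            dudr += -12.0 * eps[p] / r * (s6 * s6 - s6)
        g = -eps[p] * np.exp(-((r - rm[p]) ** 2) / (2.0 * sw[p] * sw[p]))
        u += g
        dudr += -g * (r - rm[p]) / (sw[p] * sw[p])
        g = H1[p] * np.exp(-((r - r1[p]) ** 2) / (2.0 * s1[p] * s1[p]))
        u += g
        dudr += -g * (r - r1[p]) / (s1[p] * s1[p])
        g = H2[p] * np.exp(-((r - r2g[p]) ** 2) / (2.0 * s2[p] * s2[p]))
        u += g
        dudr += -g * (r - r2g[p]) / (s2[p] * s2[p])
        e += u
        coef = -dudr / r
        for k in range(3):
            f = coef * d[k]
            F[a, k] += f
            F[b, k] -= f
    return e


@njit(cache=True)
def coulomb_kernel(x, ii, jj, qq, scale, F):
    """Open-boundary direct Coulomb over a precomputed pair list."""
    e = 0.0
    d = np.empty(3)
    for p in range(ii.shape[0]):
        a, b = ii[p], jj[p]
        for k in range(3):
            d[k] = x[a, k] - x[b, k]
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        r = np.sqrt(r2)
        e += scale * qq[p] / r
        coef = scale * qq[p] / (r2 * r)
        for k in range(3):
            f = coef * d[k]
            F[a, k] += f
            F[b, k] -= f
    return e


@njit(cache=True)
def ewald_recip_kernel(x, q, kvecs, kfac, volume, F):
    """Reciprocal-space Ewald sum: energy and forces (tin-foil boundary)."""
    n = x.shape[0]
    nk = kvecs.shape[0]
    e = 0.0
    c = np.empty(n)
    s = np.empty(n)
    for m in range(nk):
        kx, ky, kz = kvecs[m, 0], kvecs[m, 1], kvecs[m, 2]
        sr = 0.0
        si = 0.0
        for i in range(n):
            ph = kx * x[i, 0] + ky * x[i, 1] + kz * x[i, 2]
            c[i] = np.cos(ph)
            s[i] = np.sin(ph)
            sr += q[i] * c[i]
            si += q[i] * s[i]
        e += kfac[m] * (sr * sr + si * si)
        for i in range(n):
            coef = q[i] / volume * kfac[m] * (s[i] * sr - c[i] * si)
            F[i, 0] += coef * kx
            F[i, 1] += coef * ky
            F[i, 2] += coef * kz
    return e / (2.0 * volume)


@njit(cache=True)
def ewald_real_kernel(x, q, box, alpha, r_cut, F):
    """Real-space Ewald part: erfc-screened pair sum with minimum image."""
    n = x.shape[0]
    e = 0.0
    d = np.empty(3)
    sqrt_pi = np.sqrt(np.pi)
    for a in range(n):
        for b in range(a + 1, n):
            for k in range(3):
                d[k] = x[a, k] - x[b, k]
            _mi(d, box)
            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            if r2 > r_cut * r_cut:
                continue
            r = np.sqrt(r2)
            qq = q[a] * q[b]
            erfc_ar = math.erfc(alpha * r)
            e += qq * erfc_ar / r
            coef = qq * (erfc_ar / r2
                         + 2.0 * alpha / sqrt_pi * np.exp(-alpha * alpha * r2) / r)
            for k in range(3):
                f = coef * d[k] / r
                F[a, k] += f
                F[b, k] -= f
    return e
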