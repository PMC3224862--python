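"""Independent oracles used by the test suite.

Each oracle takes a computational route different from the library code it
checks: numerical quadrature instead of the closed-form field, a null-space
quadratic solve instead of the weights formula, a slow explicit DFT instead
of pooled rFFT spectra, dense grid search instead of polynomial root finding,
and explicit 2^n enumeration instead of the convolution-based sign-rank
distribution.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import null_space

MU0 = 4.0e-7 * np.pi


def oracle_dipole_field(point, dipole_pos, moment_vec, h=5e-4):
    """Numerical external field of a dipole in a spherical conductor (center 0).

    Volume currents in a spherically symmetric conductor contribute no radial
    field, so the radial component outside equals that of the primary (bare)
    dipole alone.  The magnetic scalar potential is recovered by quadrature
    of the primary radial field along the outward ray, and the full field by
    central finite differences of the potential.
    """
    point = np.asarray(point, dtype=float)
    r0 = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(moment_vec, dtype=float)

    def potential(p):
        rn = np.linalg.norm(p)
        rhat = p / rn
        qxr0_rhat = np.dot(np.cross(q, r0), rhat)

        def integrand(s):
            return -1.0 / (4.0 * np.pi) * qxr0_rhat / np.linalg.norm(s * rhat - r0) ** 3

        val, _ = quad(integrand, rn, np.inf, epsabs=1e-30, epsrel=1e-11, limit=200)
        return val

    b = np.zeros(3)
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        b[i] = -MU0 * (potential(point + e) - potential(point - e)) / (2.0 * h)
    return b


def oracle_min_variance_weights(L, C_reg):
    """Unit-gain minimum-variance weights by null-space elimination.

    Minimize w^T C_reg w subject to w . L = 1: write w = w0 + N y with
    w0 = L / (L.L) and N a basis of the orthogonal complement of L, and solve
    the unconstrained normal equations for y.
    """
    L = np.asarray(L, dtype=float)
    w0 = L / np.dot(L, L)
    N = null_space(L[None, :])
    y = np.linalg.solve(N.T @ C_reg @ N, -N.T @ C_reg @ w0)
    return w0 + N @ y


def oracle_band_coherence(x, y, delta, f_lo, f_hi, fs, imaginary=False):
    """Band-pooled (imaginary) coherence via an explicit O(N^2) DFT."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    seg_len = int(round(delta * fs))
    n_seg = len(x) // seg_len
    t = np.arange(seg_len)
    vals = []
    for k in range(n_seg):
        xs = x[k * seg_len : (k + 1) * seg_len]
        ys = y[k * seg_len : (k + 1) * seg_len]
        sxy = 0.0 + 0.0j
        sxx = 0.0
        syy = 0.0
        for j in range(seg_len // 2 + 1):
            f = j * fs / seg_len
            if not (f_lo <= f <= f_hi):
                continue
            basis = np.exp(-2j * np.pi * j * t / seg_len)
            X = np.sum(xs * basis)
            Y = np.sum(ys * basis)
            sxy += X * np.conj(Y)
            sxx += abs(X) ** 2
            syy += abs(Y) ** 2
        c = sxy / np.sqrt(sxx * syy)
        vals.append(abs(c.imag) if imaginary else abs(c))
    return float(np.mean(vals))


def oracle_orientation_grid(variance_fn, step_deg=0.1):
    """Argmax of a variance function over a dense delta grid in [0, pi)."""
    deltas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    vals = np.array([variance_fn(d) for d in deltas])
    return float(deltas[np.argmax(vals)])


def oracle_wilcoxon_exact(differences):
    """Two-sided exact signed-rank p by literal enumeration of sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=n)
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))
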