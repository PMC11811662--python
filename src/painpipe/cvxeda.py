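"""Tonic/phasic decomposition of EDA by convex sparse deconvolution.

The skin-conductance signal is modeled as

    y = phasic + tonic + residual,
    phasic = p ⊛ h,    p ≥ 0 sparse (sudomotor driver),
    tonic  = B·l + C·d (cubic B-spline every 10 s + offset and drift),

where h is the two-time-constant Bateman impulse response
``exp(-t/tau1) - exp(-t/tau0)`` (tau0 = 0.7 s rise, tau1 = 2.0 s decay),
normalized to unit peak.  The decomposition solves the convex program

    minimize  0.5·||p⊛h + B·l + C·d - y||²  +  alpha·1ᵀp  +  0.5·gamma·||l||²
    subject to  p ≥ 0,

an L1-regularized nonnegative deconvolution, with L-BFGS-B on the
bound-constrained smooth equivalent (the L1 term is linear on p ≥ 0).
Because h ≥ 0 and p ≥ 0, the phasic component is nonnegative elementwise,
and the residual is defined as the exact remainder, so additivity holds to
machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal as sps
from scipy.interpolate import BSpline

from .types import Signal

log = logging.getLogger("painpipe")


@dataclass
class PhasicDecomposition:
    tonic: np.ndarray
    phasic: np.ndarray
    residual: np.ndarray
    driver: np.ndarray | None = None
    method: str = "convex"

    @property
    def total(self) -> np.ndarray:
        return self.tonic + self.phasic + self.residual


def bateman_kernel(fs: float, tau0: float = 0.7, tau1: float = 2.0,
                   duration_s: float = 20.0) -> np.ndarray:
    t = np.arange(0, duration_s, 1.0 / fs)
    h = np.exp(-t / tau1) - np.exp(-t / tau0)
    peak = h.max()
    return h / peak if peak > 0 else h


def _spline_basis(n: int, fs: float, knot_spacing_s: float = 10.0) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots every ~10 s."""
    t = np.arange(n) / fs
    span = t[-1] if n > 1 else 1.0
    n_int = max(1, int(np.floor(span / knot_spacing_s)))
    interior = np.linspace(0, span, n_int + 1)
    knots = np.concatenate(([interior[0]] * 3, interior, [interior[-1]] * 3))
    n_coef = len(knots) - 4
    basis = np.empty((n, n_coef))
    for j in range(n_coef):
        c = np.zeros(n_coef)
        c[j] = 1.0
        basis[:, j] = BSpline(knots, c, 3, extrapolate=False)(t)
    return np.nan_to_num(basis)


def eda_decompose(eda: Signal, alpha: float = 8e-4, gamma: float = 1e-2,
                  tau0: float = 0.7, tau1: float = 2.0,
                  max_iter: int = 400) -> PhasicDecomposition:
    """Decompose a preprocessed EDA signal (>= 10 s) into tonic + phasic."""
    y = eda.samples
    n = y.size
    if n / eda.fs < 10.0:
        raise ValueError("EDA segment shorter than 10 s")
    if np.allclose(y, 0.0):
        z = np.zeros(n)
        return PhasicDecomposition(z, z.copy(), z.copy(), z.copy())

    h = bateman_kernel(eda.fs, tau0, tau1)
    B = _spline_basis(n, eda.fs)
    C = np.column_stack([np.ones(n), np.arange(n) / n])
    nb, nc = B.shape[1], C.shape[1]
    h_rev = h[::-1]

    def unpack(z):
        return z[:n], z[n:n + nb], z[n + nb:]

    def fg(z):
        p, l, d = unpack(z)
        phasic = sps.fftconvolve(p, h)[:n]
        e = phasic + B @ l + C @ d - y
        f = 0.5 * e @ e + alpha * p.sum() + 0.5 * gamma * l @ l
        # gradient wrt p is correlation of e with h
        gp = sps.fftconvolve(e, h_rev)[h.size - 1:h.size - 1 + n] + alpha
        gl = B.T @ e + gamma * l
        gd = C.T @ e
        return f, np.concatenate([gp, gl, gd])

    z0 = np.zeros(n + nb + nc)
    z0[-2] = float(np.median(y))
    bounds = [(0.0, None)] * n + [(None, None)] * (nb + nc)
    try:
        res = optimize.minimize(fg, z0, jac=True, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": max_iter})
        p, l, d = unpack(res.x)
        phasic = sps.fftconvolve(p, h)[:n]
        tonic = B @ l + C @ d
        residual = y - tonic - phasic
        return PhasicDecomposition(tonic, phasic, residual, p)
    except Exception as exc:  # pragma: no cover - defensive fallback
        log.warning("convex EDA decomposition failed (%s); "
                    "falling back to median-filter tonic", exc)
        return _fallback_decompose(y, eda.fs)


def _fallback_decompose(y: np.ndarray, fs: float) -> PhasicDecomposition:
    k = int(round(8.0 * fs))
    k += (k + 1) % 2  # odd kernel
    tonic = sps.medfilt(y, min(k, y.size - (1 - y.size % 2)))
    phasic = np.clip(y - tonic, 0.0, None)
    residual = y - tonic - phasic
    return PhasicDecomposition(tonic, phasic, residual, method="fallback")
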