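"""Bingham distribution on the unit-quaternion sphere S^3.

The Bingham density is the Gaussian analogue on S^3 (and hence on SO(3)
through the antipodal double cover):

    p(v) = exp(v^T M Z M^T v) / C(Z),   v in S^3,

with orthogonal principal axes M (4x4) and diagonal concentrations
Z = diag(z_1..z_4).  The density is invariant under adding a constant to all
z_i; the gauge used throughout this package fixes max(Z) = 0, so the density
peaks at 1/C(Z) along the principal axis.  All integrals are over the full
sphere with the surface measure dS (total 2 pi^2); antipodal symmetry is
automatic because the exponent is quadratic.

The normalizing constant (a confluent hypergeometric function of matrix
argument) is evaluated by adaptive Gauss-Legendre quadrature in
hyperspherical angles; sampling uses the angular-central-Gaussian rejection
envelope of Kent, Ganeiber & Mardia.
"""

from __future__ import annotations

import numpy as np
from functools import lru_cache

from scipy.optimize import brentq, least_squares

from .constants import S3_VOLUME
from .errors import (ConcentrationOverflowError, DegenerateFitError,
                     QuadratureError)

__all__ = [
    "log_normalizer", "scatter_moments", "fit_concentrations",
    "sample_bingham", "CONCENTRATION_FLOOR",
]

#: Concentrations are clamped at this floor; below it the density is so
#: sharp that the fit is effectively a delta along the principal axis.
CONCENTRATION_FLOOR = -200.0


@lru_cache(maxsize=16)
def _gl(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _s3_grid(order: int):
    """Tensor Gauss-Legendre grid over hyperspherical angles of S^3.

    v = (cos a, sin a cos b, sin a sin b cos c, sin a sin b sin c),
    a, b in [0, pi], c in [0, 2 pi]; dS = sin^2 a sin b da db dc.
    Returns (V, w): points (N x 4) and quadrature weights summing to 2 pi^2.
    """
    x, wx = _gl(order)
    a = 0.5 * np.pi * (x + 1.0)
    wa = 0.5 * np.pi * wx
    c = np.pi * (x + 1.0)
    wc = np.pi * wx

    sa = np.sin(a)
    A, B, C = np.meshgrid(a, a, c, indexing="ij")
    V = np.stack([
        np.cos(A),
        np.sin(A) * np.cos(B),
        np.sin(A) * np.sin(B) * np.cos(C),
        np.sin(A) * np.sin(B) * np.sin(C),
    ], axis=-1).reshape(-1, 4)
    # weight = (wa_i sin^2 a_i)(wa_j sin a_j)(wc_k)
    W = ((wa * sa**2)[:, None, None]
         * (wa * sa)[None, :, None]
         * wc[None, None, :]).reshape(-1)
    return V, W


def _quadrature(z: np.ndarray, order: int):
    V, W = _s3_grid(order)
    zmax = float(np.max(z))
    expo = (V**2) @ (np.asarray(z, float) - zmax)
    f = np.exp(expo)
    c = float(W @ f)
    second = (W[:, None] * f[:, None] * V**2).sum(axis=0)
    return c, second / c, zmax


def log_normalizer(z, rtol: float = 1e-9, return_moments: bool = False):
    """log of C(Z) = Int_{S^3} exp(sum z_i v_i^2) dS, adaptively refined.

    ``z`` is the diagonal of Z (any gauge).  Optionally also returns the
    moments E[v_i^2] under the Bingham density (the gradient of log C).
    """
    z = np.clip(np.asarray(z, dtype=float).reshape(4), CONCENTRATION_FLOOR, None)
    prev = None
    for order in (32, 64, 128, 192, 256):
        c, mom, zmax = _quadrature(z, order)
        if prev is not None and abs(c - prev) <= rtol * abs(c):
            logc = float(np.log(c) + zmax)
            return (logc, mom) if return_moments else logc
        prev = c
    raise QuadratureError(
        f"Bingham normalizer did not converge to rtol={rtol} "
        f"(last rel change {abs(c - prev) / abs(c):.2e})")


def scatter_moments(z, rtol: float = 1e-9) -> np.ndarray:
    """E[v_i^2] under Bingham(diag z) in the diagonal frame (sums to 1)."""
    _, mom = log_normalizer(z, rtol=rtol, return_moments=True)
    return mom


def fit_concentrations(scatter_eigenvalues: np.ndarray,
                       tol: float = 1e-8) -> np.ndarray:
    """Maximum-likelihood concentrations from scatter-matrix eigenvalues.

    ``scatter_eigenvalues`` are the eigenvalues of E[q q^T] in ascending
    order (nonnegative, summing to 1).  Returns z (ascending, gauge
    z_4 = 0) such that the Bingham moments match the eigenvalues.
    """
    lam = np.asarray(scatter_eigenvalues, dtype=float).reshape(4)
    if np.any(lam < 0) or abs(lam.sum() - 1.0) > 1e-6:
        raise DegenerateFitError("scatter eigenvalues must be >=0, sum to 1")
    if np.any(lam[:3] < 1e-12):
        raise DegenerateFitError(
            "rank-deficient quaternion scatter; rotational distribution "
            "degenerate along an axis")
    lam = lam / lam.sum()

    # moment-matching start: lambda_i ~ -1/(2 z_i) relative to the mode axis
    z0 = np.clip(0.5 / lam[3] - 0.5 / lam[:3], CONCENTRATION_FLOOR + 1.0, 0.0)

    def resid(z3):
        z = np.concatenate([z3, [0.0]])
        return scatter_moments(z, rtol=1e-10)[:3] - lam[:3]

    sol = least_squares(resid, z0, bounds=(CONCENTRATION_FLOOR, 0.0),
                        xtol=tol, ftol=tol, gtol=tol)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise DegenerateFitError(
            f"Bingham concentration fit failed (residual {np.max(np.abs(sol.fun)):.2e})")
    return np.concatenate([sol.x, [0.0]])


def _acg_envelope(a: np.ndarray):
    """ACG envelope parameters for target exp(-v^T diag(a) v), a >= 0.

    Solves sum_i 1/(b + 2 a_i) = 1 for b in (0, 4]; the envelope covariance
    is Omega^{-1} with Omega = I + 2 diag(a)/b.
    """
    def g(b):
        return np.sum(1.0 / (b + 2.0 * a)) - 1.0
    b = brentq(g, 1e-12, 4.0, xtol=1e-12)
    omega = 1.0 + 2.0 * a / b
    return b, omega


def sample_bingham(z, n: int, rng: np.random.Generator,
                   min_acceptance: float = 1e-3) -> np.ndarray:
    """Draw n unit quaternions from Bingham(diag z) in the diagonal frame.

    Rejection sampling with an angular-central-Gaussian envelope.  The
    returned samples are NOT canonicalized (the density is antipodally
    symmetric); callers map to the hemisphere as needed.
    """
    z = np.clip(np.asarray(z, dtype=float).reshape(4), CONCENTRATION_FLOOR, None)
    a = np.max(z) - z  # target exp(-v^T A v), A = diag(a) >= 0, min a = 0
    d = 4.0
    b, omega = _acg_envelope(a)
    log_m = -(d - b) / 2.0 + (d / 2.0) * np.log(d / b)

    out = np.empty((n, 4))
    got = 0
    attempts = 0
    scale = 1.0 / np.sqrt(omega)
    while got < n:
        m = max(2 * (n - got), 256)
        y = rng.standard_normal((m, 4)) * scale
        norms = np.linalg.norm(y, axis=1)
        v = y / norms[:, None]
        quad_a = (v**2) @ a
        quad_o = (v**2) @ omega
        log_accept = -quad_a + (d / 2.0) * np.log(quad_o) - log_m
        keep = np.log(rng.random(m)) < log_accept
        k = int(keep.sum())
        take = min(k, n - got)
        out[got:got + take] = v[keep][:take]
        got += take
        attempts += m
        if attempts > 4 * n and got / attempts < min_acceptance:
            raise ConcentrationOverflowError(
                f"Bingham rejection acceptance rate {got / attempts:.2e} "
                "below threshold; concentrations too extreme")
    return out


def uniform_s3_log_volume() -> float:
    """log of the total rotational volume under the S^3 surface measure."""
    return float(np.log(S3_VOLUME))
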