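"""Multistate Bennett acceptance ratio (MBAR) estimation.

Self-contained MBAR solver for K thermodynamic states with samples pooled
from each.  The solver minimizes the convex MBAR objective

    phi(f) = (1/N) sum_n log sum_k N_k exp(f_k - u_kn) - sum_k (N_k/N) f_k

whose stationary point satisfies the MBAR self-consistent equations.  A
scalar Bennett-acceptance-ratio (BAR) root-finder is provided separately as
an algorithmically independent route for the two-state case.

Infinite reduced potentials are allowed (hard-wall conditional states: a
sample simply has zero weight in that state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp, expit

from .errors import EstimatorError, ParameterError

__all__ = ["MBARResult", "solve_mbar", "bar_delta_f", "overlap_matrix"]


@dataclass
class MBARResult:
    """Dimensionless free energies and diagnostics from MBAR."""

    f: np.ndarray            # per-state reduced free energies, f[0] = 0
    delta_f: float           # f[-1] - f[0]
    d_delta_f: float         # asymptotic standard error of delta_f
    overlap: float           # 1 - second eigenvalue of the overlap matrix
    n_effective: np.ndarray  # Kish effective sample size per state
    weights: np.ndarray      # N x K normalized MBAR weights


def _validate(u_kn: np.ndarray, n_k: np.ndarray):
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(n_k, dtype=int)
    if u_kn.ndim != 2:
        raise ParameterError("u_kn must be K x N")
    K, N = u_kn.shape
    if len(n_k) != K or n_k.sum() != N:
        raise ParameterError("n_k must sum to the number of pooled samples")
    if np.any(n_k <= 0):
        raise ParameterError("every state must contribute samples")
    if np.any(np.isnan(u_kn)):
        raise ParameterError("NaN in reduced potentials")
    return u_kn, n_k


def solve_mbar(u_kn: np.ndarray, n_k: np.ndarray,
               tol: float = 1e-12) -> MBARResult:
    """Solve the MBAR equations for K states.

    ``u_kn[k, n]`` is the reduced potential of pooled sample n evaluated in
    state k; ``n_k`` gives how many samples came from each state (samples
    ordered by origin is not required).  +inf entries are permitted.
    """
    u_kn, n_k = _validate(u_kn, n_k)
    K, N = u_kn.shape
    log_nk = np.log(n_k)

    # Stabilize: subtract the per-sample minimum finite potential.
    shift = np.min(np.where(np.isfinite(u_kn), u_kn, np.inf), axis=0)
    if not np.all(np.isfinite(shift)):
        raise EstimatorError("a pooled sample has infinite potential in all states")
    u = u_kn - shift[None, :]

    def objective(theta):
        f = np.concatenate([[0.0], theta])
        a = f[:, None] + log_nk[:, None] - u  # K x N
        ln_den = logsumexp(a, axis=0)
        phi = ln_den.mean() - float(n_k @ f) / N
        w = np.exp(a - ln_den[None, :])       # K x N, columns sum to 1
        grad = (w.sum(axis=1) - n_k)[1:] / N
        return phi, grad

    theta0 = np.zeros(K - 1)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"ftol": tol, "gtol": 1e-10, "maxiter": 2000})
    phi, grad = objective(res.x)
    if np.max(np.abs(grad)) > 1e-7:
        raise EstimatorError(
            f"MBAR did not converge (gradient norm {np.max(np.abs(grad)):.2e})")

    f = np.concatenate([[0.0], res.x])
    # self-consistency polish
    for _ in range(200):
        a = f[:, None] + log_nk[:, None] - u
        ln_den = logsumexp(a, axis=0)
        f_new = -logsumexp(-u - ln_den[None, :], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new

    a = f[:, None] + log_nk[:, None] - u
    ln_den = logsumexp(a, axis=0)
    # W[n, k] = exp(f_k - u_kn) / sum_j N_j exp(f_j - u_jn); sum_n W = 1
    logW = (-u + f[:, None]) - ln_den[None, :]
    W = np.exp(logW).T  # N x K

    O = overlap_matrix(W, n_k)
    eig = np.sort(np.linalg.eigvals(O).real)
    overlap = float(np.clip(1.0 - eig[-2], 0.0, 1.0)) if K >= 2 else 1.0

    n_eff = 1.0 / np.maximum((W**2).sum(axis=0), 1e-300)

    d_delta_f = _bar_asymptotic_se(u_kn, n_k, f) if K == 2 else float("nan")
    return MBARResult(f=f, delta_f=float(f[-1] - f[0]), d_delta_f=d_delta_f,
                      overlap=overlap, n_effective=n_eff, weights=W)


def overlap_matrix(W: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """MBAR overlap matrix O_ij = sum_n W_ni W_nj N_j (rows sum to 1)."""
    return (W.T @ W) * np.asarray(n_k, float)[None, :]


def _bar_asymptotic_se(u_kn: np.ndarray, n_k: np.ndarray,
                       f: np.ndarray) -> float:
    """Asymptotic standard error of delta_f for two states.

    Maximum-likelihood (Bennett) variance: with a_n the MBAR weight-fraction
    logistic terms, var(delta_f) = [sum_n a_n(1-a_n)]^-1 - 1/n_0 - 1/n_1.
    """
    n0, n1 = int(n_k[0]), int(n_k[1])
    w = u_kn[1] - u_kn[0]          # forward reduced work, may be +-inf
    df = f[1] - f[0]
    x = df - w + np.log(n1) - np.log(n0)
    a = expit(x)
    fisher = float(np.sum(a * (1.0 - a)))
    if fisher <= 0.0:
        return float("inf")
    var = 1.0 / fisher - 1.0 / n0 - 1.0 / n1
    return float(np.sqrt(max(var, 0.0)))


def bar_delta_f(w_forward: np.ndarray, w_reverse: np.ndarray,
                tol: float = 1e-12) -> float:
    """Bennett acceptance ratio by scalar root finding (independent route).

    ``w_forward``: reduced work u_1 - u_0 evaluated on samples from state 0;
    ``w_reverse``: reduced work u_0 - u_1 evaluated on samples from state 1.
    Returns delta_f = f_1 - f_0.  +inf forward work (hard-wall rejection) is
    allowed.
    """
    wf = np.asarray(w_forward, dtype=float)
    wr = np.asarray(w_reverse, dtype=float)
    n0, n1 = len(wf), len(wr)
    if n0 == 0 or n1 == 0:
        raise ParameterError("need samples from both states")
    m = np.log(n1 / n0)

    def g(df):
        # pooled 2-state self-consistency split by sample origin:
        # sum_F sigma(df - wf + m) = sum_R sigma(-m - wr - df)
        return np.sum(expit(df - wf + m)) - np.sum(expit(-m - wr - df))

    lo = np.min(wf[np.isfinite(wf)]) - 50.0
    hi = np.max(-wr[np.isfinite(wr)]) + 50.0
    if g(lo) > 0 or g(hi) < 0:
        lo, hi = -1e3, 1e3
    try:
        return float(brentq(g, lo, hi, xtol=tol))
    except ValueError as exc:
        raise EstimatorError(f"BAR root bracketing failed: {exc}") from exc
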