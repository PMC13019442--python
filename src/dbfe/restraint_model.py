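"""Translation-rotation restraint on the rigid-body coordinate zeta.

The restraint potential is a Gaussian over translations times a Bingham
over rotation quaternions:

    U_zeta(t, q) = kB T [ 1/2 (t - mu)^T Sigma^-1 (t - mu) - q^T M Z M^T q ]

with the gauge max(Z) = 0 so the energy minimum is 0 at (mu, principal
axis).  Because U_zeta carries an explicit kB T prefactor, its reduced form
beta U_zeta is temperature independent.

Fitting uses the largest mean-shift mode of the complex-trajectory zeta
samples; the release free energy dG(0->r) of imposing the restraint on a
noninteracting ligand at standard concentration is analytic:

    dG(0->r) = -kB T [ ln(Z_t / V0) + ln(Z_q / Omega) ]

with Z_t = (2 pi)^{3/2} |Sigma|^{1/2}, Z_q the Bingham normalizer over S^3,
V0 = 1660 A^3 and Omega = 2 pi^2.  Both the restraint and the unrestrained
reference use the full double cover of SO(3), so the factor of two cancels
identically.  Single-atom (or collinear) ligands carry no resolvable
rotation; the restraint is then translational only and the rotational
factor is absent from both the density and the release term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import MeanShift, estimate_bandwidth

from . import bingham
from .constants import KB, S3_VOLUME, V_STANDARD
from .errors import (ClusteringError, DegenerateFitError, ParameterError)
from .rigid_geometry import RigidTransform, canonical_quaternion

__all__ = [
    "RestraintParameters", "select_largest_mode", "fit_restraint",
    "restraint_energy", "reduced_restraint_energy", "sample_restraint",
    "restraint_log_partition", "delta_g_release",
]

#: Lower clamp on translation covariance eigenvalues (A^2); rigid poses in
#: short trajectories can collapse Sigma.
COVARIANCE_FLOOR = 1e-4


@dataclass
class RestraintParameters:
    """Parameters (mu, Sigma, M, Z) of the zeta restraint."""

    mu: np.ndarray
    sigma: np.ndarray
    M: np.ndarray
    Z: np.ndarray
    reference_frame_index: int = 0
    pocket_atoms: np.ndarray = field(default_factory=lambda: np.array([], int))
    rotational: bool = True

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float).reshape(3)
        self.sigma = np.asarray(self.sigma, float).reshape(3, 3)
        self.M = np.asarray(self.M, float).reshape(4, 4)
        self.Z = np.asarray(self.Z, float).reshape(4, 4)
        self.pocket_atoms = np.asarray(self.pocket_atoms, int)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ParameterError("sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.sigma) <= 0):
            raise ParameterError("sigma must be positive definite")
        if not np.allclose(self.M @ self.M.T, np.eye(4), atol=1e-9):
            raise ParameterError("M must be orthogonal")
        if not np.allclose(self.Z, np.diag(np.diag(self.Z)), atol=1e-12):
            raise ParameterError("Z must be diagonal")
        if abs(np.max(np.diag(self.Z))) > 1e-9:
            raise ParameterError("gauge violation: max(Z) must be 0")

    @property
    def z_diag(self) -> np.ndarray:
        return np.diag(self.Z)

    def to_json(self, path=None) -> str:
        doc = {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "M": self.M.tolist(),
            "Z_diag": self.z_diag.tolist(),
            "reference_frame_index": int(self.reference_frame_index),
            "pocket_atoms": self.pocket_atoms.tolist(),
            "rotational": bool(self.rotational),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RestraintParameters":
        if isinstance(source, Path) or (
                isinstance(source, str) and "\n" not in source
                and Path(source).exists()):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(mu=doc["mu"], sigma=doc["sigma"], M=doc["M"],
                   Z=np.diag(doc["Z_diag"]),
                   reference_frame_index=doc["reference_frame_index"],
                   pocket_atoms=doc["pocket_atoms"],
                   rotational=doc["rotational"])


def _embed(zetas, rotational: bool) -> np.ndarray:
    vecs = []
    for z in zetas:
        vecs.append(z.as_vector() if rotational else z.t)
    return np.asarray(vecs, float)


def _default_bandwidth(X: np.ndarray) -> float:
    """Pairwise-distance-quantile bandwidth for mean-shift clustering.

    A KDE-style (Scott) bandwidth shrinks with n and fragments a single
    broad mode into micro-clusters at large sample counts, which would fit
    the restraint from a sliver of the data; the mean-shift convention of a
    fixed quantile of pairwise distances tracks the mode scale instead.
    """
    n = len(X)
    sub = X[np.linspace(0, n - 1, min(n, 500)).astype(int)]
    bw = float(estimate_bandwidth(sub, quantile=0.3))
    if bw <= 0.0:
        bw = float(np.sqrt(np.mean(np.var(X, axis=0))))
    return max(bw, 1e-6)


def select_largest_mode(zetas, bandwidth: float | None = None,
                        rotational: bool = True,
                        max_cluster_samples: int = 1500):
    """Most populated mean-shift mode of the zeta samples.

    Clusters in the 7-dimensional embedding [t, canonical q] (3-dimensional
    when the ligand carries no resolvable rotation).  Mean-shift iterations
    run on at most ``max_cluster_samples`` evenly spaced samples (the
    algorithm is quadratic in n); every sample is then assigned to its
    nearest discovered mode, so membership covers the full data set.
    Returns the member indices of the largest cluster and its center.
    """
    zetas = list(zetas)
    if len(zetas) < 10:
        raise ParameterError("need at least 10 zeta samples")
    X = _embed(zetas, rotational)
    if bandwidth is None:
        bandwidth = _default_bandwidth(X)
    n = len(X)
    sel = (np.linspace(0, n - 1, max_cluster_samples).astype(int)
           if n > max_cluster_samples else np.arange(n))
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False)
    sub_labels = ms.fit_predict(X[sel])
    centers = ms.cluster_centers_
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    labels = np.argmin(d, axis=1)
    counts = np.bincount(labels, minlength=len(centers))
    if counts.max() <= 1:
        raise ClusteringError(
            "all mean-shift clusters are singletons; try a larger bandwidth")
    winner = int(np.argmax(counts))
    members = np.nonzero(labels == winner)[0]
    return members, centers[winner]


def fit_restraint(zetas, mode_members, reference_frame_index: int = 0,
                  pocket_atoms=(), rotational: bool = True
                  ) -> RestraintParameters:
    """Fit (mu, Sigma, M, Z) from the mode members of the zeta samples.

    mu/Sigma are the sample mean/covariance of member translations (Sigma
    eigenvalues floored); M and Z come from the eigendecomposition of the
    antipodally symmetric quaternion scatter E[q q^T] with the maximum-
    likelihood concentration inversion, gauge-fixed to max(Z) = 0.
    """
    zetas = list(zetas)
    members = np.asarray(mode_members, int)
    if len(members) < 10:
        raise ParameterError("need at least 10 mode members")
    T = np.array([zetas[i].t for i in members])
    mu = T.mean(axis=0)
    cov = np.cov(T.T, bias=False) if len(members) > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, COVARIANCE_FLOOR)
    sigma = V @ np.diag(w) @ V.T

    if rotational:
        Q = np.array([zetas[i].q for i in members])
        scatter = (Q[:, :, None] * Q[:, None, :]).mean(axis=0)
        lam, M = np.linalg.eigh(scatter)  # ascending; mode axis last
        if np.any(lam < -1e-9):
            raise DegenerateFitError("quaternion scatter not PSD")
        lam = np.clip(lam, 0.0, None)
        lam = lam / lam.sum()
        z = bingham.fit_concentrations(lam)
        Z = np.diag(z)
    else:
        M = np.eye(4)
        Z = np.zeros((4, 4))

    return RestraintParameters(mu=mu, sigma=sigma, M=M, Z=Z,
                               reference_frame_index=reference_frame_index,
                               pocket_atoms=np.asarray(pocket_atoms, int),
                               rotational=rotational)


def reduced_restraint_energy(zeta: RigidTransform,
                             params: RestraintParameters) -> float:
    """beta * U_zeta, temperature independent by construction."""
    d = zeta.t - params.mu
    val = 0.5 * float(d @ np.linalg.solve(params.sigma, d))
    if params.rotational:
        q = zeta.q
        val -= float(q @ params.M @ params.Z @ params.M.T @ q)
    return val


def restraint_energy(zeta: RigidTransform, params: RestraintParameters,
                     temperature: float) -> float:
    """U_zeta in kcal/mol; invariant under q -> -q."""
    return KB * temperature * reduced_restraint_energy(zeta, params)


def sample_restraint_arrays(params: RestraintParameters, n: int,
                            seed: int) -> tuple:
    """Vectorized restraint draws: translations (n, 3), quaternions (n, 4).

    Quaternions are canonicalized to the nonnegative-scalar hemisphere.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    T = rng.multivariate_normal(params.mu, params.sigma, size=n,
                                method="cholesky")
    if params.rotational:
        V = bingham.sample_bingham(params.z_diag, n, rng)
        Q = V @ params.M.T
        Q[Q[:, 0] < 0] *= -1.0
    else:
        Q = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    return T, Q


def sample_restraint(params: RestraintParameters, n: int,
                     seed: int) -> list:
    """Draw n zeta samples from the restraint density, reproducibly.

    Translations are exact multivariate normal draws; quaternions come from
    Bingham rejection sampling with an angular-central-Gaussian envelope
    and are returned canonicalized.
    """
    T, Q = sample_restraint_arrays(params, n, seed)
    return [RigidTransform(t=T[i], q=canonical_quaternion(Q[i]))
            for i in range(n)]


def _log_translation_partition(sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ParameterError("sigma must be positive definite")
    return 1.5 * np.log(2.0 * np.pi) + 0.5 * logdet


def restraint_log_partition(params: RestraintParameters) -> float:
    """ln of Int exp(-U_zeta / kB T) dt dS(q).

    Translation factor in closed form; rotational factor is the Bingham
    normalizer over S^3 (computed to relative tolerance 1e-6 or better).
    Invariant under any orthogonal change of M and under the additive gauge
    of Z only through the stated gauge max(Z) = 0.
    """
    val = _log_translation_partition(params.sigma)
    if params.rotational:
        val += bingham.log_normalizer(params.z_diag, rtol=1e-9)
    return float(val)


def delta_g_release(params: RestraintParameters, temperature: float) -> float:
    """dG(0->r): imposing the restraint on a noninteracting ligand (kcal/mol).

    Relative to standard-state volume V0 = 1660 A^3 and the uniform
    rotational density on S^3 (volume 2 pi^2).
    """
    val = _log_translation_partition(params.sigma) - np.log(V_STANDARD)
    if params.rotational:
        val += bingham.log_normalizer(params.z_diag, rtol=1e-9) - np.log(S3_VOLUME)
    return float(-KB * temperature * val)
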