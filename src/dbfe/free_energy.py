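"""Reduced potentials, the MBAR leg, total assembly, poses and metrics.

Thermodynamic cycle bookkeeping (all reduced potentials dimensionless,
beta = 1 / kB T):

    state rc (restrained, decoupled, clash-free):
        u_rc(x) = beta [U_P(x_P) + U_L(x_L) + U_zeta(zeta(x))],
        +inf when any receptor/ligand atom pair violates its clash cutoff;
    state 1 (coupled complex, no restraint):
        u_1(x)  = beta U_PL(x).

The MBAR leg dG(rc->1) = -kB T ln(Z_1 / Z_rc) is estimated from samples of
both states pooled; combined with the analytic release leg dG(0->r) and the
filter leg dG(r->rc) = -kB T ln(alpha), the cycle telescopes to

    dG_binding = -kB T ln( Z_PL / (Z_P Z_L V0 Omega) )

— the standard-state binding free energy.  The restraint appears once in
the release leg and once in the decoupled ensemble with opposite sign, so
its particular parameters cancel exactly; only the phase-space overlap of
the MBAR leg depends on how well it matches the bound ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import logsumexp
from scipy.stats import pearsonr, spearmanr

from .constants import KB
from .errors import (AssemblyError, EnergyEvaluationError, ParameterError)
from .mbar import solve_mbar
from .restraint_model import RestraintParameters, reduced_restraint_energy
from .rigid_geometry import RigidTransform
from .trajectory_io import Topology

__all__ = [
    "EnergyBackend", "ReducedPotentialMatrix", "DBFEResult",
    "evaluate_reduced_potentials", "mbar_delta_g", "assemble_total",
    "combine_poses", "mmgbsa_baseline", "bootstrap_metrics",
    "DecoupledSample",
]

OVERLAP_WARN_THRESHOLD = 0.01


@runtime_checkable
class EnergyBackend(Protocol):
    """Potential-energy evaluator contract (kcal/mol, implicit solvent).

    Must be deterministic for fixed coordinates and translation/rotation
    invariant for isolated molecules; must accept receptor-only,
    ligand-only, and complex topologies.
    """

    def evaluate(self, topology: Topology, coordinates: np.ndarray) -> float:
        ...


def _evaluate_many(backend, topology, coords: np.ndarray) -> np.ndarray:
    """Batch-evaluate a backend, using its vectorized path when offered."""
    coords = np.asarray(coords, float)
    if hasattr(backend, "evaluate_many"):
        out = np.asarray(backend.evaluate_many(topology, coords), float)
    else:
        out = np.empty(len(coords))
        for i, c in enumerate(coords):
            try:
                out[i] = backend.evaluate(topology, c)
            except Exception as exc:
                raise EnergyEvaluationError(
                    f"backend failed on frame {i}: {exc}") from exc
    if np.any(np.isnan(out)):
        bad = int(np.nonzero(np.isnan(out))[0][0])
        raise EnergyEvaluationError(f"backend returned NaN on frame {bad}")
    return out


@dataclass
class DecoupledSample:
    """One composed clash-free sample of the restrained decoupled state."""

    receptor_coords: np.ndarray
    ligand_coords: np.ndarray
    zeta: RigidTransform


@dataclass
class ReducedPotentialMatrix:
    """2 x N dimensionless energies for states (rc, coupled) over pooled samples."""

    u: np.ndarray
    origin: np.ndarray  # per-sample label: "complex_traj" | "filtered_decoupled"

    def __post_init__(self):
        self.u = np.asarray(self.u, float)
        self.origin = np.asarray(self.origin)
        if self.u.shape[0] != 2 or self.u.shape[1] != len(self.origin):
            raise ParameterError("u must be 2 x N with matching origin labels")
        if np.any(np.isnan(self.u)):
            raise ParameterError("NaN in reduced potentials")

    @property
    def n_k(self) -> np.ndarray:
        return np.array([int(np.sum(self.origin == "filtered_decoupled")),
                         int(np.sum(self.origin == "complex_traj"))])


@dataclass
class DBFEResult:
    """The three legs, total dG, uncertainty and diagnostics."""

    dg_release: float
    dg_filter: float
    dg_mbar: float
    dg_total: float
    se_total: float
    se_filter: float = 0.0
    se_mbar: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dg_release": self.dg_release, "dg_filter": self.dg_filter,
            "dg_mbar": self.dg_mbar, "dg_total": self.dg_total,
            "se_total": self.se_total, "se_filter": self.se_filter,
            "se_mbar": self.se_mbar, "diagnostics": self.diagnostics,
        }


def evaluate_reduced_potentials(complex_samples, decoupled_samples,
                                backend, restraint: RestraintParameters,
                                temperature: float,
                                zeta_extractor=None,
                                complex_zetas=None,
                                n_s: int = 5000,
                                seed: int = 0,
                                cutoffs=None) -> ReducedPotentialMatrix:
    """Reduced potentials of both end states on both sample sets.

    ``complex_samples`` is a TrajectoryEnsemble of the complex trajectory;
    ``decoupled_samples`` a list of DecoupledSample.  Each set is first
    subsampled to at most ``n_s`` (reproducibly under ``seed``).  Complex
    zetas are either supplied per frame (``complex_zetas``) or computed via
    ``zeta_extractor(frame_coords) -> RigidTransform``.  If ``cutoffs`` is
    given, complex frames violating a clash cutoff get u_rc = +inf (the
    conditional state has no support there).
    """
    from .clash_filter import pose_clashes  # local import avoids a cycle

    beta = 1.0 / (KB * temperature)
    rng = np.random.default_rng(seed)
    cpx_top = complex_samples.topology
    rec_idx = cpx_top.receptor_atoms()
    lig_idx = cpx_top.ligand_atoms()
    rec_top = _subset_topology(cpx_top, rec_idx, "receptor")
    lig_top = _subset_topology(cpx_top, lig_idx, "ligand")

    n_cpx = len(complex_samples)
    cpx_sel = np.sort(rng.choice(n_cpx, size=min(n_s, n_cpx), replace=False))
    n_dec = len(decoupled_samples)
    if n_dec == 0:
        raise ParameterError("no decoupled samples")
    dec_sel = np.sort(rng.choice(n_dec, size=min(n_s, n_dec), replace=False))

    rows_rc, rows_1, origin = [], [], []

    # --- decoupled clash-free samples -----------------------------------
    dec = [decoupled_samples[i] for i in dec_sel]
    rec_coords = np.stack([d.receptor_coords for d in dec])
    lig_coords = np.stack([d.ligand_coords for d in dec])
    u_p = _evaluate_many(backend, rec_top, rec_coords)
    u_l = _evaluate_many(backend, lig_top, lig_coords)
    u_z = np.array([reduced_restraint_energy(d.zeta, restraint) for d in dec])
    u_rc_dec = beta * (u_p + u_l) + u_z
    cpx_coords = np.concatenate([rec_coords, lig_coords], axis=1)
    u_1_dec = beta * _evaluate_many(backend, cpx_top, cpx_coords)
    rows_rc.append(u_rc_dec)
    rows_1.append(u_1_dec)
    origin.extend(["filtered_decoupled"] * len(dec))

    # --- complex-trajectory samples --------------------------------------
    frames = [complex_samples.frames[i] for i in cpx_sel]
    coords = np.stack([f.coordinates for f in frames])
    if complex_zetas is not None:
        zetas = [complex_zetas[i] for i in cpx_sel]
    elif zeta_extractor is not None:
        zetas = [zeta_extractor(c) for c in coords]
    else:
        raise ParameterError("need complex_zetas or zeta_extractor")
    u_p = _evaluate_many(backend, rec_top, coords[:, rec_idx])
    u_l = _evaluate_many(backend, lig_top, coords[:, lig_idx])
    u_z = np.array([reduced_restraint_energy(z, restraint) for z in zetas])
    u_rc_cpx = beta * (u_p + u_l) + u_z
    if cutoffs is not None:
        for i in range(len(frames)):
            if pose_clashes(coords[i, rec_idx], coords[i, lig_idx], cutoffs):
                u_rc_cpx[i] = np.inf
    u_1_cpx = beta * _evaluate_many(backend, cpx_top, coords)
    rows_rc.append(u_rc_cpx)
    rows_1.append(u_1_cpx)
    origin.extend(["complex_traj"] * len(frames))

    u = np.vstack([np.concatenate(rows_rc), np.concatenate(rows_1)])
    return ReducedPotentialMatrix(u=u, origin=np.array(origin))


def _subset_topology(top: Topology, idx: np.ndarray, role: str) -> Topology:
    idx = np.asarray(idx, int)
    pos = {int(a): k for k, a in enumerate(idx)}
    bonds = [(pos[i], pos[j]) for i, j in top.bonds
             if int(i) in pos and int(j) in pos]
    return Topology([top.atom_names[i] for i in idx],
                    [top.elements[i] for i in idx],
                    top.lj_sigma[idx], top.lj_epsilon[idx], bonds, role)


def mbar_delta_g(u: ReducedPotentialMatrix, temperature: float):
    """Solve the two-state MBAR equations for dG(rc->1).

    Returns (dg kcal/mol, asymptotic se kcal/mol, overlap in [0,1]).  An
    overlap below 0.01 indicates the clash-free decoupled ensemble barely
    touches the bound ensemble; callers should surface the attached
    warning rather than trust the number.
    """
    n_k = u.n_k
    if np.any(n_k == 0):
        raise ParameterError("both origins must be represented")
    # order pooled columns as (decoupled first, complex second) to match n_k
    order = np.concatenate([np.nonzero(u.origin == "filtered_decoupled")[0],
                            np.nonzero(u.origin == "complex_traj")[0]])
    res = solve_mbar(u.u[:, order], n_k)
    kT = KB * temperature
    return float(kT * res.delta_f), float(kT * res.d_delta_f), float(res.overlap)


def assemble_total(dg_release: float, dg_filter: float, dg_mbar: float,
                   se_release: float = 0.0, se_filter: float = 0.0,
                   se_mbar: float = 0.0, diagnostics: dict | None = None
                   ) -> DBFEResult:
    """Sum the three legs; uncertainties combine in quadrature."""
    legs = np.array([dg_release, dg_filter, dg_mbar], float)
    if not np.all(np.isfinite(legs)):
        raise AssemblyError(f"non-finite leg in {legs}")
    ses = np.array([se_release, se_filter, se_mbar], float)
    if not np.all(np.isfinite(ses)):
        raise AssemblyError(f"non-finite standard error in {ses}")
    return DBFEResult(
        dg_release=float(dg_release), dg_filter=float(dg_filter),
        dg_mbar=float(dg_mbar), dg_total=float(legs.sum()),
        se_total=float(np.sqrt(np.sum(ses**2))),
        se_filter=float(se_filter), se_mbar=float(se_mbar),
        diagnostics=diagnostics or {})


def combine_poses(dgs, temperature: float) -> float:
    """Boltzmann combination -kB T ln sum_i exp(-dG_i / kB T) across poses."""
    dgs = np.asarray(list(dgs), float)
    if dgs.size == 0:
        raise ParameterError("need at least one pose")
    kT = KB * temperature
    return float(-kT * logsumexp(-dgs / kT))


def mmgbsa_baseline(complex_samples, backend) -> float:
    """Single-trajectory MM/GBSA interaction energy (kcal/mol).

    Mean over complex frames of U_PL - U_P - U_L with the components
    extracted from each complex frame; no conformational-entropy
    correction.
    """
    top = complex_samples.topology
    rec_idx, lig_idx = top.receptor_atoms(), top.ligand_atoms()
    coords = complex_samples.coordinates()
    u_pl = _evaluate_many(backend, top, coords)
    u_p = _evaluate_many(backend, _subset_topology(top, rec_idx, "receptor"),
                         coords[:, rec_idx])
    u_l = _evaluate_many(backend, _subset_topology(top, lig_idx, "ligand"),
                         coords[:, lig_idx])
    return float(np.mean(u_pl - u_p - u_l))


def bootstrap_metrics(predicted, experimental, n_resamples: int = 1000,
                      seed: int = 0) -> dict:
    """RMSE / Pearson r / Spearman rho with percentile bootstrap 95% CIs.

    Paired resampling; constant predictions make the correlations
    undefined, which is reported as None rather than raising.
    """
    pred = np.asarray(predicted, float)
    expt = np.asarray(experimental, float)
    if pred.shape != expt.shape or pred.ndim != 1:
        raise ParameterError("predicted/experimental must be equal-length 1-D")
    n = len(pred)
    if n < 3:
        raise ParameterError("need at least 3 points")
    rng = np.random.default_rng(seed)

    def stats(p, e):
        rmse = float(np.sqrt(np.mean((p - e) ** 2)))
        if np.std(p) == 0 or np.std(e) == 0:
            return rmse, None, None
        return (rmse, float(pearsonr(p, e).statistic),
                float(spearmanr(p, e).statistic))

    point = stats(pred, expt)
    boots = {k: [] for k in ("rmse", "pearson_r", "spearman_rho")}
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        r, pr, sr = stats(pred[idx], expt[idx])
        boots["rmse"].append(r)
        boots["pearson_r"].append(pr)
        boots["spearman_rho"].append(sr)

    out = {}
    for key, val in zip(("rmse", "pearson_r", "spearman_rho"), point):
        draws = [b for b in boots[key] if b is not None]
        ci = (None, None)
        if val is not None and draws:
            ci = tuple(float(v) for v in np.percentile(draws, [2.5, 97.5]))
        out[key] = {"value": val, "ci95": ci}
    return out
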