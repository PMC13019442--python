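"""Steric-clash filtering of combinatorial receptor/ligand frame pairs.

Per-pair clash cutoffs c_ij are the distances at which the Lennard-Jones
energy between receptor atom i and ligand atom j (Lorentz-Berthelot
combination) equals an energy threshold (2 kcal/mol by default) on the
repulsive branch d < 2^{1/6} sigma_ij.  A composed (receptor frame, ligand
pose) pair passes the filter iff every interatomic distance satisfies
d_ij >= c_ij; the clash-free fraction alpha of the combinatorial ensemble
gives the conditional-restriction free energy

    dG(r->rc) = -kB T ln(alpha).

Candidate pairs are found with a KD-tree over receptor atoms queried at the
maximum cutoff radius, then checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import KB
from .errors import NoOverlapError, ParameterError

__all__ = [
    "CutoffMatrix", "FilterResult", "compute_cutoff_matrix",
    "lj_cutoff_distance", "plan_pose_budget", "filter_frame_pairs",
    "delta_g_filter",
]


@dataclass
class CutoffMatrix:
    """P x L clash cutoff distances (A); 0 marks LJ-exempt pairs."""

    cutoffs: np.ndarray
    energy_threshold: float

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, float)
        if np.any(self.cutoffs < 0):
            raise ParameterError("negative cutoff")

    @property
    def max_cutoff(self) -> float:
        return float(self.cutoffs.max()) if self.cutoffs.size else 0.0


@dataclass
class FilterResult:
    """Surviving (receptor frame, ligand pose) pairs and the fraction alpha."""

    passing_pairs: list
    n_tested: int
    n_receptor_frames: int
    n_ligand_confs: int
    n_zeta: int

    @property
    def alpha(self) -> float:
        return len(self.passing_pairs) / self.n_tested

    def to_json(self, path=None) -> str:
        doc = {
            "alpha": self.alpha,
            "n_tested": self.n_tested,
            "n_passing": len(self.passing_pairs),
            "n_receptor_frames": self.n_receptor_frames,
            "n_ligand_confs": self.n_ligand_confs,
            "n_zeta": self.n_zeta,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def lj_cutoff_distance(sigma: np.ndarray, epsilon: np.ndarray,
                       energy_threshold: float) -> np.ndarray:
    """Distance where 4 eps [(s/d)^12 - (s/d)^6] = threshold, repulsive branch.

    Closed form: with y = (sigma/d)^6, y = (1 + sqrt(1 + E/eps)) / 2 and
    d = sigma y^{-1/6}; y >= 1 guarantees d <= 2^{1/6} sigma.  Pairs with
    eps = 0 have no finite root and are exempt (cutoff 0).
    """
    if energy_threshold <= 0:
        raise ParameterError("energy threshold must be positive")
    sigma = np.asarray(sigma, float)
    epsilon = np.asarray(epsilon, float)
    out = np.zeros(np.broadcast_shapes(sigma.shape, epsilon.shape))
    mask = epsilon > 0
    y = 0.5 * (1.0 + np.sqrt(1.0 + energy_threshold / epsilon[mask]))
    out[mask] = np.broadcast_to(sigma, out.shape)[mask] * y ** (-1.0 / 6.0)
    return out


def compute_cutoff_matrix(receptor_topology, ligand_topology,
                          energy_threshold: float = 2.0) -> CutoffMatrix:
    """Per-pair clash cutoffs from Lorentz-Berthelot combined LJ parameters."""
    sp = receptor_topology.lj_sigma[:, None]
    sl = ligand_topology.lj_sigma[None, :]
    ep = receptor_topology.lj_epsilon[:, None]
    el = ligand_topology.lj_epsilon[None, :]
    sigma_ij = 0.5 * (sp + sl)
    eps_ij = np.sqrt(ep * el)
    cut = lj_cutoff_distance(sigma_ij, eps_ij, energy_threshold)
    return CutoffMatrix(cutoffs=cut, energy_threshold=float(energy_threshold))


def plan_pose_budget(n_receptor: int, n_ligand: int,
                     n_target: int = 10**9) -> int:
    """N_zeta = max(1, floor(n_target / (N_P N_L)))."""
    if n_receptor < 1 or n_ligand < 1 or n_target < 1:
        raise ParameterError("counts must be >= 1")
    return max(1, n_target // (n_receptor * n_ligand))


def pose_clashes(receptor_coords: np.ndarray, pose: np.ndarray,
                 cutoffs: CutoffMatrix, tree: cKDTree | None = None) -> bool:
    """True iff any receptor/ligand atom pair violates its cutoff."""
    if tree is None:
        tree = cKDTree(receptor_coords)
    r = cutoffs.max_cutoff
    if r == 0.0:
        return False
    for j, atom in enumerate(np.asarray(pose, float)):
        cand = tree.query_ball_point(atom, r)
        if not cand:
            continue
        d = np.linalg.norm(receptor_coords[cand] - atom, axis=1)
        if np.any(d < cutoffs.cutoffs[cand, j]):
            return True
    return False


def filter_frame_pairs(receptor_frames, pose_generator, cutoffs: CutoffMatrix,
                       batch_size: int = 4096) -> FilterResult:
    """Stream combinatorial poses against receptor frames through the filter.

    ``receptor_frames``: iterable of (frame_index, receptor P x 3 coords).
    ``pose_generator(frame_index)``: yields batches ``(labels, poses)``
    with ``poses`` of shape (B, L, 3) already expressed in that frame's own
    coordinate system (B capped by ``batch_size`` keeps memory bounded).
    A KD-tree is built once per receptor frame; every ligand atom is
    queried at the maximum cutoff radius and only the candidate pairs are
    checked exactly against d_ij >= c_ij.  Deterministic given its inputs.
    """
    passing = []
    n_tested = 0
    n_frames = 0
    r = cutoffs.max_cutoff
    cut = cutoffs.cutoffs
    for frame_index, rec in receptor_frames:
        n_frames += 1
        rec = np.asarray(rec, float)
        tree = cKDTree(rec)
        for labels, poses in pose_generator(frame_index):
            poses = np.asarray(poses, float)
            if poses.ndim == 2:
                poses = poses[None]
            b, n_lig = poses.shape[0], poses.shape[1]
            n_tested += b
            if r == 0.0:
                passing.extend((frame_index, lab) for lab in labels)
                continue
            flat = poses.reshape(-1, 3)
            groups = tree.query_ball_point(flat, r)
            ok = np.ones(b, dtype=bool)
            for idx in range(len(flat)):
                cand = groups[idx]
                if not cand:
                    continue
                p, j = divmod(idx, n_lig)
                if not ok[p]:
                    continue
                d = np.linalg.norm(rec[cand] - flat[idx], axis=1)
                if np.any(d < cut[cand, j]):
                    ok[p] = False
            passing.extend((frame_index, labels[p])
                           for p in np.nonzero(ok)[0])
    if n_tested == 0:
        raise ParameterError("empty pose list")
    return FilterResult(passing_pairs=passing, n_tested=n_tested,
                        n_receptor_frames=n_frames, n_ligand_confs=0, n_zeta=0)


def pose_clashes_many(receptor_coords: np.ndarray, poses: np.ndarray,
                      cutoffs: CutoffMatrix) -> np.ndarray:
    """Vectorized clash verdicts for a pose batch against one frame."""
    tree = cKDTree(np.asarray(receptor_coords, float))
    verdicts = np.zeros(len(poses), dtype=bool)
    for i, pose in enumerate(np.asarray(poses, float)):
        verdicts[i] = pose_clashes(receptor_coords, pose, cutoffs, tree)
    return verdicts


def delta_g_filter(result_or_alpha, temperature: float,
                   n_tested: int | None = None):
    """dG(r->rc) = -kB T ln(alpha) and its binomial standard error.

    The error is the delta-method standard error on the log scale,
    kB T sqrt((1 - alpha) / (alpha n)).  alpha = 0 means no combinatorial
    sample fit the pocket (binding site closed); that is a structured
    failure, not a number.
    """
    if isinstance(result_or_alpha, FilterResult):
        alpha = result_or_alpha.alpha
        n = result_or_alpha.n_tested
    else:
        alpha = float(result_or_alpha)
        n = n_tested
    if n is None or n < 1:
        raise ParameterError("n_tested must be >= 1")
    if alpha == 0.0:
        raise NoOverlapError(
            "no pose passed the clash filter (alpha = 0); the receptor "
            "ensemble has no room for the ligand")
    dg = -KB * temperature * np.log(alpha)
    se = KB * temperature * np.sqrt((1.0 - alpha) / (alpha * n))
    return float(dg), float(se)
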