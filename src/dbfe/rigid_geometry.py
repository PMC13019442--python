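"""Rigid-body geometry: superposition, quaternions, symmetry, zeta extraction.

The rigid-body coordinate zeta = (t, q) relates the ligand in a complex frame
to the ligand of a fixed reference frame *after* the pocket C-alpha atoms of
the current frame have been superposed onto the reference pocket.  The
rotation q acts about the reference-ligand centroid, so translation and
rotation are decoupled:

    pose(x_ref) = R(q) (x_ref - c_ref) + c_ref + t

Quaternions are scalar-first, unit norm, and canonicalized to the hemisphere
with nonnegative scalar part (q and -q encode the same rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ParameterError

__all__ = [
    "RigidTransform",
    "SymmetryGroup",
    "kabsch_superpose",
    "enumerate_symmetry_permutations",
    "extract_zeta",
    "apply_transform",
    "canonical_quaternion",
    "quaternion_to_matrix",
    "matrix_to_quaternion",
]

#: Max automorphisms enumerated before truncation.
SYMMETRY_CAP = 10_000


def canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Map q to the canonical hemisphere representative of {q, -q}.

    Nonnegative scalar part; exact ties broken by the first nonzero
    component being positive.
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ParameterError("zero quaternion")
    q = q / n
    if q[0] < 0.0:
        return -q
    if q[0] == 0.0:
        for c in q[1:]:
            if c != 0.0:
                return q if c > 0.0 else -q
    return q


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion."""
    w, x, y, z = q
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Canonical scalar-first quaternion of a proper rotation matrix."""
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return canonical_quaternion(np.array([w, x, y, z]))


@dataclass(frozen=True)
class RigidTransform:
    """Translation + rotation quaternion (scalar-first, canonical)."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float).reshape(3)
        q = canonical_quaternion(np.asarray(self.q, dtype=float).reshape(4))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ParameterError("quaternion not unit norm")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.zeros(3), np.array([1.0, 0.0, 0.0, 0.0]))

    def rotation_matrix(self) -> np.ndarray:
        return quaternion_to_matrix(self.q)

    def as_vector(self) -> np.ndarray:
        """7-vector embedding [t, q] used by mode clustering."""
        return np.concatenate([self.t, self.q])

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.t, 0.0, atol=tol)
            and np.allclose(self.q, [1.0, 0.0, 0.0, 0.0], atol=tol)
        )


@dataclass
class SymmetryGroup:
    """Element-preserving atom-index automorphisms of a molecular graph."""

    permutations: list = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self):
        if not self.permutations:
            raise ParameterError("symmetry group must contain the identity")

    def __len__(self):
        return len(self.permutations)

    @classmethod
    def identity(cls, n_atoms: int) -> "SymmetryGroup":
        return cls([np.arange(n_atoms)])


def _check_noncollinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateGeometryError(
            "point set is collinear/degenerate; superposition rotation "
            "is not identifiable"
        )


def _fit_rotation(mobile_c: np.ndarray, target_c: np.ndarray,
                  weights: np.ndarray) -> np.ndarray:
    """Weighted Kabsch rotation (proper, via SVD determinant correction)."""
    H = (mobile_c * weights[:, None]).T @ target_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation + translation minimizing the weighted RMSD,
    in the convention ``mapped = R (x - c_mob) + c_mob + t`` (rotation about
    the mobile centroid), together with the minimized RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ParameterError("mobile/target must be matching Nx3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    c_mob = weights @ mobile
    c_tgt = weights @ target
    mob_c = mobile - c_mob
    tgt_c = target - c_tgt
    _check_noncollinear(mobile)

    R = _fit_rotation(mob_c, tgt_c, weights)
    mapped = mob_c @ R.T + c_tgt
    rmsd = float(np.sqrt(np.sum(weights * np.sum((mapped - target) ** 2, axis=1))))
    zeta = RigidTransform(t=c_tgt - c_mob, q=matrix_to_quaternion(R))
    return zeta, rmsd


def enumerate_symmetry_permutations(graph: nx.Graph,
                                    cap: int = SYMMETRY_CAP) -> SymmetryGroup:
    """All element-preserving automorphisms of a connected molecular graph.

    Nodes are atom indices 0..N-1 and must carry an ``element`` attribute.
    Enumeration stops at ``cap`` permutations; the result is then flagged
    truncated.
    """
    if graph.number_of_nodes() == 0:
        raise ParameterError("empty graph")
    if not nx.is_connected(graph):
        raise ParameterError("molecular graph must be connected")
    n = graph.number_of_nodes()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        graph, graph,
        node_match=lambda a, b: a.get("element") == b.get("element"),
    )
    perms = []
    truncated = False
    for mapping in matcher.isomorphisms_iter():
        perms.append(np.array([mapping[i] for i in range(n)], dtype=int))
        if len(perms) >= cap:
            truncated = True
            break
    perms.sort(key=lambda p: tuple(p))
    # identity always exists; ensure it survived any truncation
    ident = np.arange(n)
    if not any(np.array_equal(p, ident) for p in perms):
        perms.insert(0, ident)
    return SymmetryGroup(permutations=perms, truncated=truncated)


def _align_pocket(frame_coords: np.ndarray, reference_coords: np.ndarray,
                  pocket_atoms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Superpose a frame's pocket C-alphas onto the reference pocket.

    Returns (R, s) such that aligned = (x - c) @ R.T + c + s for the frame's
    full coordinate set, where c is the frame pocket centroid.
    """
    mob = frame_coords[pocket_atoms]
    tgt = reference_coords[pocket_atoms]
    zeta, _ = kabsch_superpose(mob, tgt)
    return zeta


def align_frame_to_reference(frame_coords: np.ndarray,
                             reference_coords: np.ndarray,
                             pocket_atoms) -> tuple[np.ndarray, RigidTransform]:
    """Pocket-superpose ``frame_coords`` onto the reference frame.

    Returns the fully transformed coordinates and the alignment transform
    (rotation about the frame pocket centroid).
    """
    pocket_atoms = np.asarray(pocket_atoms, dtype=int)
    align = _align_pocket(frame_coords, reference_coords, pocket_atoms)
    c = frame_coords[pocket_atoms].mean(axis=0)
    R = align.rotation_matrix()
    aligned = (frame_coords - c) @ R.T + c + align.t
    return aligned, align


def invert_alignment(coords: np.ndarray, alignment: RigidTransform,
                     pocket_centroid: np.ndarray) -> np.ndarray:
    """Map reference-frame coordinates back into a frame's own system.

    Exact inverse of :func:`align_frame_to_reference` for the given frame.
    """
    R = alignment.rotation_matrix()
    return (coords - pocket_centroid - alignment.t) @ R + pocket_centroid


def _min_rmsd_fit(reference: np.ndarray, current: np.ndarray,
                  symmetry: SymmetryGroup
                  ) -> tuple[RigidTransform, float, np.ndarray]:
    """Symmetry-aware rigid fit carrying ``reference`` onto ``current``.

    Rotation acts about the reference centroid.  Ties in RMSD break toward
    the lexicographically lowest permutation (the list is pre-sorted).
    Falls back to a pure translation for <3 or collinear atoms (rotation
    unresolvable; q = identity).
    """
    n = reference.shape[0]
    c_ref = reference.mean(axis=0)
    c_cur = current.mean(axis=0)

    rotatable = n >= 3
    if rotatable:
        try:
            _check_noncollinear(reference)
        except DegenerateGeometryError:
            rotatable = False

    best = None
    for perm in symmetry.permutations:
        ref_p = reference[perm]
        if rotatable:
            zeta, rmsd = kabsch_superpose(ref_p, current)
        else:
            t = c_cur - c_ref
            mapped = ref_p + t
            rmsd = float(np.sqrt(np.mean(np.sum((mapped - current) ** 2, axis=1))))
            zeta = RigidTransform(t=t, q=np.array([1.0, 0.0, 0.0, 0.0]))
        if best is None or rmsd < best[1] - 1e-12:
            best = (zeta, rmsd, perm)
    return best


def extract_zeta(complex_frame, reference_frame, pocket_atoms, ligand_atoms,
                 symmetry: SymmetryGroup | None = None) -> RigidTransform:
    """Rigid-body transform of the ligand relative to the reference frame.

    Steps: (1) superpose the current frame's pocket C-alphas onto the
    reference frame's; (2) over all symmetry permutations, find the minimal
    RMSD rigid transform carrying the reference ligand onto the aligned
    current ligand.  Accepts Frame objects or raw Nx3 arrays.
    """
    cur = np.asarray(getattr(complex_frame, "coordinates", complex_frame), float)
    ref = np.asarray(getattr(reference_frame, "coordinates", reference_frame), float)
    ligand_atoms = np.asarray(ligand_atoms, dtype=int)
    if symmetry is None:
        symmetry = SymmetryGroup.identity(len(ligand_atoms))

    aligned, _ = align_frame_to_reference(cur, ref, pocket_atoms)
    zeta, _, _ = _min_rmsd_fit(ref[ligand_atoms], aligned[ligand_atoms], symmetry)
    return zeta


def apply_transform(zeta: RigidTransform, reference_ligand: np.ndarray,
                    receptor_frame_alignment: RigidTransform | None = None,
                    pocket_centroid: np.ndarray | None = None) -> np.ndarray:
    """Place the reference-pose ligand according to zeta.

    Rotates the reference ligand about its centroid by q, translates by t,
    then (optionally) maps the result into the receptor frame's own
    coordinate system by inverting that frame's pocket alignment.  Exact
    inverse of :func:`extract_zeta` on noise-free data.
    """
    ref = np.asarray(reference_ligand, dtype=float)
    c_ref = ref.mean(axis=0)
    R = zeta.rotation_matrix()
    pose = (ref - c_ref) @ R.T + c_ref + zeta.t
    if receptor_frame_alignment is not None:
        if pocket_centroid is None:
            raise ParameterError(
                "pocket_centroid required to invert a frame alignment")
        pose = invert_alignment(pose, receptor_frame_alignment,
                                np.asarray(pocket_centroid, float))
    return pose


def align_conformer_to_reference(conformer: np.ndarray,
                                 reference_ligand: np.ndarray,
                                 symmetry: SymmetryGroup | None = None
                                 ) -> np.ndarray:
    """Superpose a ligand-only conformer onto the reference ligand pose.

    Removes the conformer's arbitrary rigid-body placement (symmetry-aware,
    minimal RMSD) so that sampled restraint transforms can be applied to it.
    Returns the conformer expressed in the reference-pose frame, with atoms
    re-labelled by the best-fit permutation.
    """
    conf = np.asarray(conformer, dtype=float)
    if symmetry is None:
        symmetry = SymmetryGroup.identity(conf.shape[0])
    zeta, _, perm = _min_rmsd_fit(conf, np.asarray(reference_ligand, float),
                                  symmetry)
    c = conf[perm].mean(axis=0)
    R = zeta.rotation_matrix()
    return (conf[perm] - c) @ R.T + c + zeta.t
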