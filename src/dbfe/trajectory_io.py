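"""Topology/trajectory I/O and reduction of correlated MD data.

Units: angstrom, kcal/mol.  Topologies come from PDB (receptor/complex,
CONECT honored, read through mdtraj) or SDF/MOL2 (ligand, read through
RDKit); Lennard-Jones parameters ride in a JSON sidecar
``{atom_index: {"sigma": A, "epsilon": kcal/mol}}``.

Trajectories use either a binary MD format via the mdtraj adapter
(DCD/XTC) or the plain-text fixture format documented below, so the test
fixtures need no MD libraries:

    # dbfe-traj 1
    <natoms>
    frame <index>
    x y z            (natoms lines, angstrom)
    frame <index>
    ...
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import (EmptyTrajectoryError, FormatError, InsufficientDataError,
                     ParameterError, ParameterizationError, TopologyError)

__all__ = [
    "Topology", "Frame", "TrajectoryEnsemble",
    "read_topology", "read_trajectory", "write_fixture_trajectory",
    "decorrelate_frames", "subsample_frames", "statistical_inefficiency",
]

FIXTURE_MAGIC = "# dbfe-traj 1"


@dataclass
class Topology:
    """Atom identities, LJ parameters and bond graph for one molecule role."""

    atom_names: list
    elements: list
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    bonds: list
    role: str
    receptor_atom_count: int | None = None

    def __post_init__(self):
        n = len(self.atom_names)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        if self.role not in ("receptor", "ligand", "complex"):
            raise ParameterError(f"unknown role {self.role!r}")
        if len(self.elements) != n or len(self.lj_sigma) != n or len(self.lj_epsilon) != n:
            raise TopologyError("per-atom field lengths disagree")
        if np.any(self.lj_sigma < 0) or np.any(self.lj_epsilon < 0):
            raise ParameterizationError("negative LJ parameter")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i},{j}) out of range")
        if self.role == "complex":
            if self.receptor_atom_count is None or not (
                    0 < self.receptor_atom_count < n):
                raise TopologyError(
                    "complex topology needs 0 < receptor_atom_count < n_atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def molecular_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        g.add_edges_from(self.bonds)
        return g

    def receptor_atoms(self) -> np.ndarray:
        if self.role != "complex":
            raise TopologyError("receptor_atoms only defined for complexes")
        return np.arange(self.receptor_atom_count)

    def ligand_atoms(self) -> np.ndarray:
        if self.role != "complex":
            raise TopologyError("ligand_atoms only defined for complexes")
        return np.arange(self.receptor_atom_count, self.n_atoms)


@dataclass
class Frame:
    coordinates: np.ndarray
    index: int

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatError("frame coordinates must be N x 3")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("non-finite coordinate in frame")


@dataclass
class TrajectoryEnsemble:
    topology: Topology
    frames: list
    source_runs: list = field(default_factory=lambda: ["run0"])

    def __post_init__(self):
        if len(self.frames) == 0:
            raise EmptyTrajectoryError("ensemble has no frames")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise TopologyError(
                    f"frame has {f.coordinates.shape[0]} atoms, topology {n}")

    def __len__(self):
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """All frames stacked, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    @classmethod
    def from_coordinates(cls, topology: Topology, coords: np.ndarray,
                         source_runs=None) -> "TrajectoryEnsemble":
        frames = [Frame(c, i) for i, c in enumerate(np.asarray(coords, float))]
        return cls(topology, frames, source_runs or ["run0"])


def _load_lj_sidecar(lj_params, n_atoms: int):
    """LJ parameters from a JSON path/dict keyed by atom index."""
    if lj_params is None:
        raise ParameterizationError("no LJ parameters supplied")
    if isinstance(lj_params, (str, Path)):
        lj_params = json.loads(Path(lj_params).read_text())
    sigma = np.full(n_atoms, np.nan)
    eps = np.full(n_atoms, np.nan)
    for key, entry in lj_params.items():
        i = int(key)
        sigma[i] = float(entry["sigma"])
        eps[i] = float(entry["epsilon"])
    missing = np.nonzero(~np.isfinite(sigma) | ~np.isfinite(eps))[0]
    if missing.size:
        raise ParameterizationError(
            f"missing LJ parameters for atom index {missing[0]}")
    return sigma, eps


def _read_pdb(path: Path, role: str, lj_params, receptor_atom_count):
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover
        raise FormatError("mdtraj required to read PDB topologies") from exc
    try:
        traj = mdtraj.load(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable PDB {path}: {exc}") from exc
    top = traj.topology
    names = [a.name for a in top.atoms]
    elements = [a.element.symbol if a.element is not None else "X"
                for a in top.atoms]
    bonds = [(a.index, b.index) for a, b in top.bonds]
    sigma, eps = _load_lj_sidecar(lj_params, len(names))
    return Topology(names, elements, sigma, eps, bonds, role,
                    receptor_atom_count)


def _read_ligand_rdkit(path: Path, lj_params):
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise FormatError("rdkit required to read SDF/MOL2 ligands") from exc
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    else:
        raise FormatError(f"unsupported ligand format {suffix}")
    if mol is None:
        raise FormatError(f"unreadable ligand file {path}")
    frags = Chem.GetMolFrags(mol)
    if len(frags) != 1:
        raise FormatError(
            f"ligand must be a single connected molecule, found {len(frags)} fragments")
    names = [f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in mol.GetAtoms()]
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    sigma, eps = _load_lj_sidecar(lj_params, len(names))
    return Topology(names, elements, sigma, eps, bonds, "ligand", None)


def read_topology(path, role: str, lj_params=None,
                  receptor_atom_count: int | None = None) -> Topology:
    """Read a validated topology from PDB (receptor/complex) or SDF/MOL2.

    ``lj_params`` is a JSON sidecar path or dict assigning sigma (A) and
    epsilon (kcal/mol) per atom index; missing atoms raise a
    parameterization error naming the first offender.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if role in ("receptor", "complex"):
        return _read_pdb(path, role, lj_params, receptor_atom_count)
    if role == "ligand":
        if path.suffix.lower() == ".pdb":
            return _read_pdb(path, role, lj_params, None)
        return _read_ligand_rdkit(path, lj_params)
    raise ParameterError(f"unknown role {role!r}")


def _read_fixture_trajectory(path: Path) -> list:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != FIXTURE_MAGIC:
        raise FormatError(f"{path} is not a dbfe fixture trajectory")
    try:
        natoms = int(lines[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"bad atom count header in {path}") from exc
    frames = []
    i = 2
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("frame"):
            raise FormatError(f"expected 'frame' record at line {i + 1} of {path}")
        idx = int(line.split()[1])
        block = lines[i + 1:i + 1 + natoms]
        if len(block) < natoms:
            raise FormatError(f"truncated frame {idx} in {path}")
        coords = np.array([[float(v) for v in row.split()] for row in block])
        frames.append(Frame(coords, idx))
        i += 1 + natoms
    return frames


def read_trajectory(paths, topology: Topology,
                    mdtraj_top=None) -> TrajectoryEnsemble:
    """Read one or more trajectory files sharing a topology.

    Multiple files are concatenated in order with per-file run provenance.
    Plain-text fixture files are parsed directly; DCD/XTC/PDB go through
    mdtraj (coordinates converted nm -> A).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_frames = []
    runs = []
    for run_id, p in enumerate(paths):
        p = Path(p)
        if not p.exists():
            raise FormatError(f"no such file: {p}")
        if p.suffix in (".traj", ".txt"):
            frames = _read_fixture_trajectory(p)
        else:
            try:
                import mdtraj
                traj = (mdtraj.load(str(p)) if p.suffix == ".pdb"
                        else mdtraj.load(str(p), top=str(mdtraj_top)))
            except Exception as exc:
                raise FormatError(f"unreadable trajectory {p}: {exc}") from exc
            frames = [Frame(xyz * 10.0, i) for i, xyz in enumerate(traj.xyz)]
        if not frames:
            raise EmptyTrajectoryError(f"no frames in {p}")
        for f in frames:
            if f.coordinates.shape[0] != topology.n_atoms:
                raise TopologyError(
                    f"{p}: frame has {f.coordinates.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}")
        all_frames.extend(frames)
        runs.append(f"{p.name}#{run_id}")
    return TrajectoryEnsemble(topology, all_frames, runs)


def write_fixture_trajectory(path, coords: np.ndarray) -> None:
    """Write frames (n_frames x n_atoms x 3, angstrom) in the fixture format."""
    coords = np.asarray(coords, dtype=float)
    lines = [FIXTURE_MAGIC, str(coords.shape[1])]
    for i, frame in enumerate(coords):
        lines.append(f"frame {i}")
        lines.extend(" ".join(f"{v:.8f}" for v in row) for row in frame)
    Path(path).write_text("\n".join(lines) + "\n")


def statistical_inefficiency(series: np.ndarray) -> float:
    """Statistical inefficiency g = 1 + 2 sum (1 - t/N) C(t).

    The normalized autocorrelation is computed by FFT and the sum truncated
    at the first negative value (standard fast heuristic).  A constant
    series has undefined autocorrelation and is treated as g = 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 1e-15 * max(1.0, np.mean(np.abs(series)) ** 2):
        return 1.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    g = 1.0
    for t in range(1, n):
        if acf[t] <= 0.0:
            break
        g += 2.0 * (1.0 - t / n) * acf[t]
    return max(g, 1.0)


def _equilibration_split(observable: np.ndarray, min_burn_in: int):
    """Burn-in index and inefficiency maximizing effective sample count.

    Candidate burn-in points lie on a geometric grid past ``min_burn_in``;
    the pair (t0, g) maximizing (N - t0)/g is returned.
    """
    n = len(observable)
    candidates = [min_burn_in]
    t = max(min_burn_in, 1)
    while t < n - 2:
        t = int(np.ceil(t * 1.5)) if t > 0 else 1
        if t >= n - 2:
            break
        if t > min_burn_in:
            candidates.append(t)
    best = None
    for t0 in candidates:
        tail = observable[t0:]
        if len(tail) < 2:
            continue
        g = statistical_inefficiency(tail)
        neff = len(tail) / g
        if best is None or neff > best[0]:
            best = (neff, t0, g)
    if best is None:
        raise InsufficientDataError("fewer than 2 frames after burn-in")
    return best[1], best[2]


def decorrelate_frames(ensemble: TrajectoryEnsemble, observable: np.ndarray,
                       min_burn_in: int = 0) -> TrajectoryEnsemble:
    """Drop equilibration and thin to effectively independent frames.

    Applied independently per source run (runs are assumed to partition the
    frame list in order, equally when sizes are unknown).  The burn-in for
    each run is at least ``min_burn_in`` frames; thinning uses stride
    ceil(g) from the statistical inefficiency of the post-burn-in
    observable.
    """
    observable = np.asarray(observable, dtype=float)
    if len(observable) != len(ensemble):
        raise ParameterError("observable length must equal frame count")
    n_runs = max(len(ensemble.source_runs), 1)
    bounds = np.linspace(0, len(ensemble), n_runs + 1).astype(int)
    kept = []
    for r in range(n_runs):
        lo, hi = bounds[r], bounds[r + 1]
        if hi - lo == 0:
            continue
        t0, g = _equilibration_split(observable[lo:hi], min_burn_in)
        # float stride g: keeps ~n/g frames instead of over-thinning to
        # n/ceil(g) when g is barely above 1
        n_avail = hi - lo - t0
        k = np.arange(int(np.floor(n_avail / g)) + 1)
        idx = lo + t0 + np.unique(np.floor(k * g).astype(int))
        kept.extend(idx[idx < hi].tolist())
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 frames after decorrelation")
    frames = [ensemble.frames[i] for i in kept]
    return TrajectoryEnsemble(ensemble.topology, frames, list(ensemble.source_runs))


def subsample_frames(ensemble: TrajectoryEnsemble, n: int,
                     seed: int) -> TrajectoryEnsemble:
    """Uniform without-replacement subsample of at most n frames.

    Identity when the ensemble is already small enough; reproducible under
    ``seed``; selected frames keep their original order.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if len(ensemble) <= n:
        return ensemble
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(ensemble), size=n, replace=False))
    frames = [ensemble.frames[i] for i in idx]
    return TrajectoryEnsemble(ensemble.topology, frames, list(ensemble.source_runs))
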