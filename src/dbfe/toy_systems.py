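"""Self-contained toy host-guest systems with exactly computable dG.

Each toy is a small "receptor" cage plus a guest bound by a confining site
potential, designed so that every pipeline stage (decorrelation, zeta
extraction, restraint fitting, clash filtering, MBAR) has nontrivial work
while the binding free energy is independently computable by low-
dimensional quadrature:

    dG = -kB T ln[ (1/V0) Int dt <exp(-beta U_int(t, q))>_{q uniform on S^3} ]

with V0 = 1660 A^3 and the rotational average over the full quaternion
double cover (absent for single-atom guests).  Receptor internal modes are
harmonic and decouple from the site coordinate, so they cancel between
Z_PL and Z_P exactly.

Preset systems:

``pure_harmonic``   soft tethered cage, single-atom guest, harmonic site,
                    no LJ (clash filter trivially passes).
``harmonic_lj``     rigid cage with LJ spheres, single-atom LJ guest in a
                    harmonic site; the filter and MBAR both matter.
``double_well``     rigid cage, single-atom guest in a tilted double well
                    along the pocket x axis.
``rigid_rotor``     rigid cage, rigid 3-atom guest with a harmonic site
                    plus an orientation coupling kappa (1 - u.z); exercises
                    the Bingham restraint end to end.

Boltzmann sampling is exact (independent draws) wherever closed forms
exist; the LJ-coupled complex uses Metropolis Monte Carlo with automatic
step tuning and decorrelation thinning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import bingham
from .constants import KB, V_STANDARD, DEFAULT_TEMPERATURE
from .errors import ParameterError, QuadratureError, SamplerError
from .trajectory_io import (Topology, TrajectoryEnsemble,
                            write_fixture_trajectory)

__all__ = [
    "ToySystemSpec", "make_harmonic_host_guest", "preset",
    "direct_boltzmann_sample", "exact_delta_g_quadrature",
    "generate_fixture_trajectories", "ToyBackend", "PRESETS",
]

PRESETS = ("pure_harmonic", "harmonic_lj", "double_well", "rigid_rotor")


@dataclass
class ToySystemSpec:
    """A toy host-guest system (templates, potential, conditions)."""

    name: str
    receptor_template: np.ndarray
    ligand_template: np.ndarray
    receptor_stiffness: float | None   # kcal/mol/A^2; None = rigid cage
    site_stiffness: float              # kcal/mol/A^2 (harmonic site / k_perp)
    well_depth: float                  # kcal/mol, subtracted from U_int
    site_kind: str = "harmonic"        # or "double_well"
    double_well_a: float = 0.0         # kcal/mol/A^4
    double_well_b: float = 0.0         # A (half well separation)
    double_well_tilt: float = 0.0      # kcal/mol/A
    orient_stiffness: float = 0.0      # kcal/mol, kappa (1 - u.z) coupling
    lj_sigma_receptor: np.ndarray | None = None
    lj_epsilon_receptor: np.ndarray | None = None
    lj_sigma_ligand: np.ndarray | None = None
    lj_epsilon_ligand: np.ndarray | None = None
    ligand_elements: list = field(default_factory=list)
    ligand_bonds: list = field(default_factory=list)
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        self.receptor_template = np.asarray(self.receptor_template, float)
        self.ligand_template = np.asarray(self.ligand_template, float)
        self.ligand_template = (self.ligand_template
                                - self.ligand_template.mean(axis=0))
        nR, nL = len(self.receptor_template), len(self.ligand_template)
        if self.lj_sigma_receptor is None:
            self.lj_sigma_receptor = np.zeros(nR)
            self.lj_epsilon_receptor = np.zeros(nR)
        if self.lj_sigma_ligand is None:
            self.lj_sigma_ligand = np.zeros(nL)
            self.lj_epsilon_ligand = np.zeros(nL)
        self.lj_sigma_receptor = np.asarray(self.lj_sigma_receptor, float)
        self.lj_epsilon_receptor = np.asarray(self.lj_epsilon_receptor, float)
        self.lj_sigma_ligand = np.asarray(self.lj_sigma_ligand, float)
        self.lj_epsilon_ligand = np.asarray(self.lj_epsilon_ligand, float)
        if not self.ligand_elements:
            self.ligand_elements = ["C", "N", "O", "S"][:nL] + ["C"] * max(0, nL - 4)
        if self.has_lj and self.receptor_stiffness is not None:
            raise ParameterError(
                "LJ-coupled toys require a rigid receptor cage")
        if self.has_lj and nL > 1:
            raise ParameterError(
                "LJ-coupled toys support single-atom guests only")
        if self.site_kind not in ("harmonic", "double_well"):
            raise ParameterError(f"unknown site kind {self.site_kind}")

    # -- structure ---------------------------------------------------------
    @property
    def n_receptor_atoms(self) -> int:
        return len(self.receptor_template)

    @property
    def n_ligand_atoms(self) -> int:
        return len(self.ligand_template)

    @property
    def has_lj(self) -> bool:
        return bool(np.any(self.lj_epsilon_receptor > 0)
                    and np.any(self.lj_epsilon_ligand > 0))

    @property
    def rotational(self) -> bool:
        """Whether the guest carries a resolvable rigid-body rotation."""
        if self.n_ligand_atoms < 3:
            return False
        c = self.ligand_template - self.ligand_template.mean(axis=0)
        return np.linalg.matrix_rank(c, tol=1e-8) >= 2

    @property
    def site_center(self) -> np.ndarray:
        return self.receptor_template.mean(axis=0)

    def pocket_atoms(self) -> np.ndarray:
        return np.arange(self.n_receptor_atoms)

    def receptor_topology(self) -> Topology:
        n = self.n_receptor_atoms
        return Topology([f"C{i+1}" for i in range(n)], ["C"] * n,
                        self.lj_sigma_receptor, self.lj_epsilon_receptor,
                        [], "receptor")

    def ligand_topology(self) -> Topology:
        n = self.n_ligand_atoms
        bonds = self.ligand_bonds or [(i, i + 1) for i in range(n - 1)]
        if n == 1:
            bonds = []
        return Topology([f"{e}{i+1}" for i, e in enumerate(self.ligand_elements)],
                        list(self.ligand_elements),
                        self.lj_sigma_ligand, self.lj_epsilon_ligand,
                        bonds, "ligand")

    def complex_topology(self) -> Topology:
        rt, lt = self.receptor_topology(), self.ligand_topology()
        bonds = list(rt.bonds) + [(i + rt.n_atoms, j + rt.n_atoms)
                                  for i, j in lt.bonds]
        return Topology(rt.atom_names + lt.atom_names,
                        rt.elements + lt.elements,
                        np.concatenate([rt.lj_sigma, lt.lj_sigma]),
                        np.concatenate([rt.lj_epsilon, lt.lj_epsilon]),
                        bonds, "complex", receptor_atom_count=rt.n_atoms)

    # -- energies (kcal/mol), batched over leading axes --------------------
    def receptor_energy(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        if self.receptor_stiffness is None:
            return np.zeros(coords.shape[:-2])
        d2 = np.sum((coords - self.receptor_template) ** 2, axis=(-2, -1))
        return 0.5 * self.receptor_stiffness * d2

    def ligand_energy(self, coords: np.ndarray) -> np.ndarray:
        # guests are rigid bodies: no internal energy
        coords = np.asarray(coords, float)
        return np.zeros(coords.shape[:-2])

    def _site_energy(self, dt: np.ndarray) -> np.ndarray:
        """Site potential of the guest-centroid displacement from the pocket."""
        if self.site_kind == "harmonic":
            return 0.5 * self.site_stiffness * np.sum(dt**2, axis=-1)
        x, y, z = dt[..., 0], dt[..., 1], dt[..., 2]
        return (self.double_well_a * (x**2 - self.double_well_b**2) ** 2
                + self.double_well_tilt * x
                + 0.5 * self.site_stiffness * (y**2 + z**2))

    def _orient_energy(self, lig: np.ndarray) -> np.ndarray:
        if self.orient_stiffness == 0.0 or self.n_ligand_atoms < 2:
            return np.zeros(lig.shape[:-2])
        axis = lig[..., 0, :] - np.mean(lig, axis=-2)
        axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
        return self.orient_stiffness * (1.0 - axis[..., 2])

    def _lj_energy(self, rec: np.ndarray, lig: np.ndarray) -> np.ndarray:
        if not self.has_lj:
            return np.zeros(np.broadcast_shapes(rec.shape[:-2], lig.shape[:-2]))
        sig = 0.5 * (self.lj_sigma_receptor[:, None] + self.lj_sigma_ligand[None, :])
        eps = np.sqrt(self.lj_epsilon_receptor[:, None]
                      * self.lj_epsilon_ligand[None, :])
        diff = rec[..., :, None, :] - lig[..., None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        s6 = (sig**2 / d2) ** 3
        return np.sum(4.0 * eps * (s6**2 - s6), axis=(-2, -1))

    def interaction_energy(self, rec: np.ndarray, lig: np.ndarray) -> np.ndarray:
        rec = np.asarray(rec, float)
        lig = np.asarray(lig, float)
        pocket = np.mean(rec, axis=-2)
        centroid = np.mean(lig, axis=-2)
        u = self._site_energy(centroid - pocket)
        u = u + self._orient_energy(lig)
        u = u + self._lj_energy(rec, lig)
        return u - self.well_depth

    def complex_energy(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        nR = self.n_receptor_atoms
        rec, lig = coords[..., :nR, :], coords[..., nR:, :]
        return (self.receptor_energy(rec) + self.ligand_energy(lig)
                + self.interaction_energy(rec, lig))


def make_harmonic_host_guest(n_receptor_atoms: int = 8,
                             n_ligand_atoms: int = 1,
                             stiffness: float = 1.0,
                             well_depth: float = 5.0,
                             seed: int = 0,
                             receptor_stiffness: float | None = 10.0,
                             **extra) -> ToySystemSpec:
    """Generic harmonic host-guest builder (deterministic under seed).

    Receptor atoms sit on a sphere of radius 4 A around the origin (jittered
    reproducibly); the guest is a compact rigid cluster bound to the pocket
    centroid by a harmonic site of the given stiffness.
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ParameterError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_receptor_atoms, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    receptor = 4.0 * v + 0.3 * rng.standard_normal((n_receptor_atoms, 3))
    if n_ligand_atoms == 1:
        ligand = np.zeros((1, 3))
    else:
        ligand = rng.standard_normal((n_ligand_atoms, 3))
        ligand -= ligand.mean(axis=0)
        ligand *= 0.8 / max(np.linalg.norm(ligand, axis=1).max(), 1e-9)
    return ToySystemSpec(name="harmonic_host_guest",
                         receptor_template=receptor, ligand_template=ligand,
                         receptor_stiffness=receptor_stiffness,
                         site_stiffness=stiffness, well_depth=well_depth,
                         seed=seed, **extra)


def preset(name: str, seed: int = 0,
           temperature: float = DEFAULT_TEMPERATURE) -> ToySystemSpec:
    """One of the standard toy systems (see module docstring)."""
    if name == "pure_harmonic":
        spec = make_harmonic_host_guest(n_receptor_atoms=6, n_ligand_atoms=1,
                                        stiffness=2.0, well_depth=5.0,
                                        seed=seed, receptor_stiffness=10.0,
                                        temperature=temperature)
        spec.name = name
        return spec
    if name == "harmonic_lj":
        # cage tight enough that the restraint ensemble genuinely reaches
        # the clash region (vertex distance 3.8 A vs cutoff ~2.8 A)
        cube = np.array([[sx, sy, sz] for sx in (-2.2, 2.2)
                         for sy in (-2.2, 2.2) for sz in (-2.2, 2.2)])
        return ToySystemSpec(
            name=name, receptor_template=cube,
            ligand_template=np.zeros((1, 3)),
            receptor_stiffness=None, site_stiffness=0.5, well_depth=5.0,
            lj_sigma_receptor=np.full(8, 3.2), lj_epsilon_receptor=np.full(8, 0.15),
            lj_sigma_ligand=np.array([3.2]), lj_epsilon_ligand=np.array([0.15]),
            temperature=temperature, seed=seed)
    if name == "double_well":
        tetra = 3.5 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                               float) / np.sqrt(3)
        return ToySystemSpec(
            name=name, receptor_template=tetra,
            ligand_template=np.zeros((1, 3)),
            receptor_stiffness=None, site_stiffness=1.5, well_depth=5.0,
            site_kind="double_well", double_well_a=2.0, double_well_b=1.1,
            double_well_tilt=0.5, temperature=temperature, seed=seed)
    if name == "rigid_rotor":
        tetra = 3.5 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                               float) / np.sqrt(3)
        # asymmetric rigid triangle (distinct elements -> trivial symmetry)
        tri = np.array([[0.9, 0.0, 0.0], [-0.5, 0.6, 0.0], [-0.4, -0.6, 0.1]])
        return ToySystemSpec(
            name=name, receptor_template=tetra, ligand_template=tri,
            receptor_stiffness=None, site_stiffness=1.5, well_depth=5.0,
            orient_stiffness=2.0, ligand_elements=["C", "N", "O"],
            temperature=temperature, seed=seed)
    raise ParameterError(f"unknown preset {name!r}; choose from {PRESETS}")


# ---------------------------------------------------------------------------
# Boltzmann sampling
# ---------------------------------------------------------------------------

def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()


def _sample_receptor(spec: ToySystemSpec, n: int, rng) -> np.ndarray:
    if spec.receptor_stiffness is None:
        return np.tile(spec.receptor_template, (n, 1, 1))
    sd = np.sqrt(KB * spec.temperature / spec.receptor_stiffness)
    jitter = rng.standard_normal((n, spec.n_receptor_atoms, 3)) * sd
    return spec.receptor_template[None] + jitter


def _sample_ligand(spec: ToySystemSpec, n: int, rng) -> np.ndarray:
    if spec.n_ligand_atoms == 1:
        return np.zeros((n, 1, 3))
    R = _random_rotations(n, rng)
    return np.einsum("nij,aj->nai", R, spec.ligand_template)


def _sample_site_displacement(spec: ToySystemSpec, n: int, rng) -> np.ndarray:
    beta = 1.0 / (KB * spec.temperature)
    if spec.site_kind == "harmonic":
        sd = np.sqrt(KB * spec.temperature / spec.site_stiffness)
        return rng.standard_normal((n, 3)) * sd
    # tilted double well along x: exact inverse-CDF on a dense grid
    a, b, tilt = spec.double_well_a, spec.double_well_b, spec.double_well_tilt
    span = b + 4.0 / np.sqrt(beta * max(a * b**2, 1e-6))
    xg = np.linspace(-span, span, 20001)
    dens = np.exp(-beta * (a * (xg**2 - b**2) ** 2 + tilt * xg))
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    x = np.interp(rng.random(n), cdf, xg)
    sd = np.sqrt(KB * spec.temperature / spec.site_stiffness)
    yz = rng.standard_normal((n, 2)) * sd
    return np.column_stack([x, yz])


def _sample_orientations(spec: ToySystemSpec, n: int, rng) -> np.ndarray:
    """Rotation matrices from the orientation-coupled Boltzmann density."""
    if spec.orient_stiffness == 0.0 or spec.n_ligand_atoms < 2:
        return _random_rotations(n, rng)
    bk = spec.orient_stiffness / (KB * spec.temperature)
    # axis polar angle: p(c) ~ exp(bk c) on c in [-1, 1]
    u01 = rng.random(n)
    c = 1.0 + np.log1p(-u01 * (1.0 - np.exp(-2.0 * bk))) / bk
    phi = rng.random(n) * 2 * np.pi
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    target = np.column_stack([s * np.cos(phi), s * np.sin(phi), c])
    # body axis of the template (first atom from centroid, normalized)
    e0 = spec.ligand_template[0] - spec.ligand_template.mean(axis=0)
    e0 = e0 / np.linalg.norm(e0)
    spin = rng.random(n) * 2 * np.pi
    R_spin = Rotation.from_rotvec(np.outer(spin, e0)).as_matrix()
    R_align = np.stack([_rotation_between(e0, tv) for tv in target])
    return np.einsum("nij,njk->nik", R_align, R_spin)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector a onto unit vector b."""
    v = np.cross(a, b)
    cth = float(np.dot(a, b))
    if cth > 1.0 - 1e-12:
        return np.eye(3)
    if cth < -1.0 + 1e-12:
        # pick any perpendicular axis
        perp = np.eye(3)[np.argmin(np.abs(a))]
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / np.linalg.norm(v)
    angle = np.arccos(np.clip(cth, -1, 1))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _mc_sample_complex(spec: ToySystemSpec, n: int, rng) -> np.ndarray:
    """Metropolis sampling of the guest in a rigid cage (LJ toys)."""
    rec = spec.receptor_template
    beta = 1.0 / (KB * spec.temperature)

    def energy(t):
        lig = spec.ligand_template + t
        return float(spec.interaction_energy(rec, lig))

    t = spec.site_center.copy()
    e = energy(t)
    step = 0.5
    acc_hist = []
    # tuning + burn-in
    for i in range(2000):
        prop = t + rng.standard_normal(3) * step
        ep = energy(prop)
        if np.log(rng.random()) < -beta * (ep - e):
            t, e = prop, ep
            acc_hist.append(1)
        else:
            acc_hist.append(0)
        if (i + 1) % 200 == 0:
            rate = np.mean(acc_hist[-200:])
            step *= 1.3 if rate > 0.5 else (0.7 if rate < 0.3 else 1.0)
    rate = np.mean(acc_hist[-1000:])
    if rate < 0.05 or rate > 0.98:
        raise SamplerError(f"Metropolis acceptance rate {rate:.2f} pathological")

    thin = 10
    out = np.empty((n, 3))
    for k in range(n):
        for _ in range(thin):
            prop = t + rng.standard_normal(3) * step
            ep = energy(prop)
            if np.log(rng.random()) < -beta * (ep - e):
                t, e = prop, ep
        out[k] = t
    return out


def direct_boltzmann_sample(spec: ToySystemSpec, which: str, n: int,
                            seed: int) -> TrajectoryEnsemble:
    """Boltzmann samples of the receptor, ligand, or complex subsystem.

    Exact independent draws wherever the marginal is Gaussian or separable
    (all presets except the LJ-coupled complex, which uses tuned Metropolis
    Monte Carlo with thinning).  Output plugs straight into trajectory_io.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if which == "receptor":
        coords = _sample_receptor(spec, n, rng)
        return TrajectoryEnsemble.from_coordinates(spec.receptor_topology(), coords)
    if which == "ligand":
        coords = _sample_ligand(spec, n, rng)
        return TrajectoryEnsemble.from_coordinates(spec.ligand_topology(), coords)
    if which != "complex":
        raise ParameterError(f"unknown subsystem {which!r}")

    rec = _sample_receptor(spec, n, rng)
    if spec.has_lj:
        t = _mc_sample_complex(spec, n, rng)
        lig = spec.ligand_template[None] + t[:, None, :]
    else:
        dt = _sample_site_displacement(spec, n, rng)
        R = _sample_orientations(spec, n, rng)
        body = np.einsum("nij,aj->nai", R, spec.ligand_template)
        pocket = rec.mean(axis=1)
        lig = body + (pocket + dt)[:, None, :]
    coords = np.concatenate([rec, lig], axis=1)
    return TrajectoryEnsemble.from_coordinates(spec.complex_topology(), coords)


# ---------------------------------------------------------------------------
# Exact reference free energy
# ---------------------------------------------------------------------------

def _translation_integral(spec: ToySystemSpec, order: int) -> float:
    """ln Int dt exp(-beta U(t)) with the guest in template orientation."""
    beta = 1.0 / (KB * spec.temperature)
    if spec.site_kind == "harmonic":
        span = 6.0 * np.sqrt(KB * spec.temperature / spec.site_stiffness)
    else:
        span = spec.double_well_b + 6.0 * np.sqrt(
            KB * spec.temperature / spec.site_stiffness)
    x, w = np.polynomial.legendre.leggauss(order)
    g = span * x
    gw = span * w
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    dt = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    W = (gw[:, None, None] * gw[None, :, None] * gw[None, None, :]).reshape(-1)
    u = np.empty(len(dt))
    for lo in range(0, len(dt), 200_000):  # bounded memory for LJ broadcasts
        sl = slice(lo, lo + 200_000)
        ub = spec._site_energy(dt[sl])
        if spec.has_lj:
            lig = (spec.ligand_template[None]
                   + (spec.site_center + dt[sl])[:, None, :])
            ub = ub + spec._lj_energy(spec.receptor_template, lig)
        u[sl] = ub
    umin = u.min()
    val = float(W @ np.exp(-beta * (u - umin)))
    return np.log(val) - beta * umin


def _orientation_integral(spec: ToySystemSpec, order: int) -> float:
    """ln <exp(-beta U_orient)> over the uniform S^3 double cover."""
    if spec.orient_stiffness == 0.0 or spec.n_ligand_atoms < 2:
        return 0.0
    beta = 1.0 / (KB * spec.temperature)
    V, W = bingham._s3_grid(order)
    R = Rotation.from_quat(V[:, [1, 2, 3, 0]]).as_matrix()
    lig = np.einsum("nij,aj->nai", R, spec.ligand_template)
    u = spec._orient_energy(lig)
    val = float(W @ np.exp(-beta * u)) / float(W.sum())
    return float(np.log(val))


def exact_delta_g_quadrature(spec: ToySystemSpec, rtol: float = 1e-6) -> float:
    """Reference binding free energy by deterministic nested quadrature.

    Valid for every preset: receptor internal modes marginalize in closed
    form, and the coupled degrees of freedom are the guest translation
    (plus its rigid-body orientation when an orientation coupling is
    present).  Raises if the requested tolerance is not reached.
    """
    if spec.has_lj and spec.n_ligand_atoms > 1:
        raise QuadratureError(
            "more than 6 coupled degrees of freedom; use a Monte Carlo oracle")
    beta = 1.0 / (KB * spec.temperature)
    prev = None
    for order in (48, 96, 160, 240):
        val = (_translation_integral(spec, order)
               + _orientation_integral(spec, min(order, 96)))
        if prev is not None and abs(val - prev) <= rtol * max(abs(val), 1.0):
            ln_ratio = val - np.log(V_STANDARD) + beta * spec.well_depth
            return float(-KB * spec.temperature * ln_ratio)
        prev = val
    raise QuadratureError(f"quadrature did not reach rtol={rtol}")


# ---------------------------------------------------------------------------
# Energy backend + fixtures
# ---------------------------------------------------------------------------

class ToyBackend:
    """EnergyBackend over a toy potential (see free_energy.EnergyBackend)."""

    def __init__(self, spec: ToySystemSpec):
        self.spec = spec

    def evaluate(self, topology: Topology, coordinates: np.ndarray) -> float:
        return float(self.evaluate_many(topology, np.asarray(coordinates)[None])[0])

    def evaluate_many(self, topology: Topology, coordinates: np.ndarray
                      ) -> np.ndarray:
        coords = np.asarray(coordinates, float)
        if topology.role == "receptor":
            return self.spec.receptor_energy(coords)
        if topology.role == "ligand":
            return self.spec.ligand_energy(coords)
        return self.spec.complex_energy(coords)


def _write_toy_pdb(path: Path, topology: Topology, coords: np.ndarray) -> None:
    lines = []
    for i, (name, el) in enumerate(zip(topology.atom_names, topology.elements)):
        x, y, z = coords[i]
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s} TOY A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}")
    for i, j in topology.bonds:
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_toy_sdf(path: Path, topology: Topology, coords: np.ndarray) -> None:
    n, nb = topology.n_atoms, len(topology.bonds)
    lines = ["toy_guest", "  dbfe-toy        3D", "",
             f"{n:3d}{nb:3d}  0  0  0  0  0  0  0  0999 V2000"]
    for i in range(n):
        x, y, z = coords[i]
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {topology.elements[i]:<3s}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in topology.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}  1  0")
    lines += ["M  END", "$$$$"]
    path.write_text("\n".join(lines) + "\n")


def _lj_sidecar(topology: Topology) -> dict:
    return {str(i): {"sigma": float(topology.lj_sigma[i]),
                     "epsilon": float(topology.lj_epsilon[i])}
            for i in range(topology.n_atoms)}


def generate_fixture_trajectories(spec: ToySystemSpec, out_dir,
                                  n_frames: int = 100) -> dict:
    """Write fixture topologies/trajectories/sidecars plus a manifest.

    Regenerating with the manifest's seeds reproduces the files byte for
    byte.  The manifest records the exact reference dG for the system.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"name": spec.name, "seed": int(spec.seed),
                "temperature": spec.temperature, "n_frames": n_frames,
                "files": {}, "exact_delta_g": exact_delta_g_quadrature(spec)}
    rec_top, lig_top = spec.receptor_topology(), spec.ligand_topology()
    cpx_top = spec.complex_topology()
    _write_toy_pdb(out / "receptor.pdb", rec_top, spec.receptor_template)
    _write_toy_sdf(out / "ligand.sdf", lig_top, spec.ligand_template)
    _write_toy_pdb(out / "complex.pdb", cpx_top,
                   np.vstack([spec.receptor_template,
                              spec.ligand_template + spec.site_center]))
    for role, top in (("receptor", rec_top), ("ligand", lig_top),
                      ("complex", cpx_top)):
        seed = spec.seed * 3 + {"receptor": 0, "ligand": 1, "complex": 2}[role]
        ens = direct_boltzmann_sample(spec, role, n_frames, seed)
        write_fixture_trajectory(out / f"{role}.traj", ens.coordinates())
        (out / f"{role}_lj.json").write_text(
            json.dumps(_lj_sidecar(top), indent=2, sort_keys=True))
        manifest["files"][role] = {"trajectory": f"{role}.traj",
                                   "lj": f"{role}_lj.json", "seed": seed}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
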