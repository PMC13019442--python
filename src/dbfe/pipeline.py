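"""End-to-end DBFE orchestration: config, the three legs, reports.

The pipeline wires the modules together:

    decorrelate -> zeta extraction -> mode selection -> restraint fit
    -> dG(0->r) -> combinatorial pose generation -> clash filter
    -> dG(r->rc) -> reduced potentials -> MBAR -> dG(rc->1) -> total.

All randomness flows from ``RunConfig.seed`` through named substreams, so
identical configs produce byte-identical reports (timing aside).
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clash_filter import (compute_cutoff_matrix, delta_g_filter,
                           filter_frame_pairs, plan_pose_budget)
from .constants import DEFAULT_TEMPERATURE
from .errors import NoOverlapError, ParameterError
from .free_energy import (DBFEResult, DecoupledSample, assemble_total,
                          combine_poses, evaluate_reduced_potentials,
                          mbar_delta_g, OVERLAP_WARN_THRESHOLD)
from .restraint_model import (RestraintParameters, delta_g_release,
                              fit_restraint, sample_restraint_arrays,
                              select_largest_mode)
from .rigid_geometry import (RigidTransform, SymmetryGroup,
                             align_conformer_to_reference,
                             align_frame_to_reference, apply_transform,
                             enumerate_symmetry_permutations, extract_zeta)
from .toy_systems import PRESETS, ToyBackend, direct_boltzmann_sample, preset
from .trajectory_io import decorrelate_frames, subsample_frames

__all__ = ["RunConfig", "run_dbfe", "run_multipose"]


@dataclass
class RunConfig:
    """Everything a DBFE run needs; defaults follow the method's protocol.

    Either ``toy_preset`` names a built-in toy system, or the four path
    fields plus an injected energy backend describe a real system.
    """

    toy_preset: str | None = None
    receptor_trajectory: str | None = None
    ligand_trajectory: str | None = None
    complex_trajectory: str | None = None
    pocket_atoms: list | None = None

    temperature: float = DEFAULT_TEMPERATURE
    energy_threshold: float = 2.0        # kcal/mol LJ clash cutoff energy
    n_target: int = 10**9                # desired total frame pairs
    n_s: int = 5000                      # MBAR subsample cap per state
    min_burn_in: int = 50                # frames (0.1 ns at 2 ps spacing)
    seed: int = 0

    # ensemble sizes (toy mode) and filter-stage caps
    n_frames: int = 10000
    n_receptor_filter: int = 200
    n_ligand_filter: int = 50
    max_kept_samples: int = 20000
    mode_bandwidth: float | None = None
    restraint_sigma_scale: float = 1.0
    reference_frame_index: int = 0

    def validate(self):
        if self.toy_preset is None and not (
                self.receptor_trajectory and self.ligand_trajectory
                and self.complex_trajectory):
            raise ParameterError(
                "config needs either toy_preset or the three trajectories")
        if self.toy_preset is not None and self.toy_preset not in PRESETS:
            raise ParameterError(f"unknown toy preset {self.toy_preset!r}")
        if self.energy_threshold <= 0:
            raise ParameterError("energy_threshold must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc).validate()


def _derived_seed(base: int, tag: str) -> int:
    # zlib.crc32 is stable across processes (unlike str hash)
    return int(np.random.SeedSequence([base, zlib.crc32(tag.encode())])
               .generate_state(1)[0] % 2**31)


def _toy_ensembles(config: RunConfig):
    spec = preset(config.toy_preset, seed=_derived_seed(config.seed, "system"),
                  temperature=config.temperature)
    backend = ToyBackend(spec)
    ens = {}
    for role in ("receptor", "ligand", "complex"):
        ens[role] = direct_boltzmann_sample(
            spec, role, config.n_frames, _derived_seed(config.seed, role))
    pocket = (np.asarray(config.pocket_atoms, int)
              if config.pocket_atoms is not None else spec.pocket_atoms())
    return spec, backend, ens, pocket


def _decorrelated(ensemble, backend, config: RunConfig):
    obs = backend.evaluate_many(ensemble.topology, ensemble.coordinates())
    obs = np.asarray(obs, float)
    if np.allclose(obs, obs[0] if len(obs) else 0.0):
        # flat-energy subsystem (rigid cage / noninteracting guest): fall
        # back to the first principal component of the coordinates
        X = ensemble.coordinates().reshape(len(ensemble), -1)
        Xc = X - X.mean(axis=0)
        if np.allclose(Xc, 0.0):
            return ensemble
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        obs = Xc @ vt[0]
    return decorrelate_frames(ensemble, obs, min_burn_in=min(
        config.min_burn_in, max(len(ensemble) // 10, 0)))


def run_dbfe(config: RunConfig, backend=None, report_path=None) -> DBFEResult:
    """Execute the full three-leg DBFE pipeline and return the result.

    Raises NoOverlapError when no combinatorial sample passes the clash
    filter (the binding-site-closed failure mode).  A JSON report is
    written to ``report_path`` when given; the report is deterministic for
    a fixed config except for its ``timing`` block.
    """
    config.validate()
    t_start = time.time()
    log = {}

    if config.toy_preset is not None:
        spec, backend, ens, pocket = _toy_ensembles(config)
    else:
        if backend is None:
            raise ParameterError("real-system runs require an energy backend")
        raise ParameterError(
            "file-based runs: load ensembles with trajectory_io and call "
            "run_dbfe_from_ensembles")
    return _run(config, backend, ens, pocket, log, t_start, report_path)


def run_dbfe_from_ensembles(config: RunConfig, backend, receptor, ligand,
                            complex_, pocket_atoms,
                            report_path=None) -> DBFEResult:
    """DBFE on pre-loaded TrajectoryEnsembles (file-based or custom toys)."""
    ens = {"receptor": receptor, "ligand": ligand, "complex": complex_}
    return _run(config, backend, ens, np.asarray(pocket_atoms, int), {},
                time.time(), report_path)


def _run(config, backend, ens, pocket, log, t_start, report_path):
    # 1. decorrelate every ensemble
    dec = {role: _decorrelated(e, backend, config) for role, e in ens.items()}
    log["n_frames_decorrelated"] = {r: len(e) for r, e in dec.items()}

    cpx = dec["complex"]
    cpx_top = cpx.topology
    lig_idx = cpx_top.ligand_atoms()
    ref_coords = cpx.frames[min(config.reference_frame_index,
                                len(cpx) - 1)].coordinates

    # 2. ligand symmetry and rotational resolvability
    lig_top = dec["ligand"].topology
    graph = lig_top.molecular_graph()
    if lig_top.n_atoms > 1 and graph.number_of_edges() > 0:
        symmetry = enumerate_symmetry_permutations(graph)
    else:
        symmetry = SymmetryGroup.identity(lig_top.n_atoms)
    ref_lig = ref_coords[lig_idx]
    rotational = (lig_top.n_atoms >= 3
                  and np.linalg.matrix_rank(ref_lig - ref_lig.mean(axis=0),
                                            tol=1e-8) >= 2)

    # 3. zeta per complex frame
    zetas = [extract_zeta(f.coordinates, ref_coords, pocket, lig_idx, symmetry)
             for f in cpx.frames]

    # 4. largest mode + restraint fit + release leg
    members, _ = select_largest_mode(zetas, bandwidth=config.mode_bandwidth,
                                     rotational=rotational)
    restraint = fit_restraint(zetas, members,
                              reference_frame_index=config.reference_frame_index,
                              pocket_atoms=pocket, rotational=rotational)
    if config.restraint_sigma_scale != 1.0:
        restraint = RestraintParameters(
            mu=restraint.mu,
            sigma=restraint.sigma * config.restraint_sigma_scale,
            M=restraint.M, Z=restraint.Z,
            reference_frame_index=restraint.reference_frame_index,
            pocket_atoms=restraint.pocket_atoms,
            rotational=restraint.rotational)
    dg_rel = delta_g_release(restraint, config.temperature)
    log["mode_members"] = int(len(members))

    # 5. combinatorial pose generation + clash filter
    rec_sub = subsample_frames(dec["receptor"], config.n_receptor_filter,
                               _derived_seed(config.seed, "rec-filter"))
    lig_sub = subsample_frames(dec["ligand"], config.n_ligand_filter,
                               _derived_seed(config.seed, "lig-filter"))
    confs = [align_conformer_to_reference(f.coordinates, ref_lig, symmetry)
             for f in lig_sub.frames]
    n_p, n_l = len(rec_sub), len(confs)
    n_zeta = plan_pose_budget(n_p, n_l, config.n_target)
    cutoffs = compute_cutoff_matrix(rec_sub.topology, lig_top,
                                    config.energy_threshold)

    kept: list = []
    n_seen_passing = 0
    rng_res = np.random.default_rng(_derived_seed(config.seed, "reservoir"))
    rec_frames = []
    alignments = {}
    for i, f in enumerate(rec_sub.frames):
        coords = f.coordinates
        _, align = align_frame_to_reference(coords, ref_coords, pocket)
        c_pocket = coords[pocket].mean(axis=0)
        alignments[i] = (align, c_pocket, coords)
        rec_frames.append((i, coords))

    def _compose_batch(T, Q, conf, align, c_pocket):
        """Vectorized apply_transform for a zeta batch on one conformer."""
        c_ref = conf.mean(axis=0)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_quat(Q[:, [1, 2, 3, 0]]).as_matrix()
        poses = (np.einsum("nij,aj->nai", R, conf - c_ref)
                 + c_ref + T[:, None, :])
        Ra = align.rotation_matrix()
        return (poses - c_pocket - align.t) @ Ra + c_pocket

    def pose_gen(frame_index):
        align, c_pocket, _ = alignments[frame_index]
        seed = _derived_seed(config.seed, f"zeta-{frame_index}")
        T, Q = sample_restraint_arrays(restraint, n_l * n_zeta, seed)
        for ci in range(n_l):
            sl = slice(ci * n_zeta, (ci + 1) * n_zeta)
            poses = _compose_batch(T[sl], Q[sl], confs[ci], align, c_pocket)
            labels = [(ci, k) for k in range(ci * n_zeta, (ci + 1) * n_zeta)]
            yield labels, poses

    result = filter_frame_pairs(rec_frames, pose_gen, cutoffs)
    result.n_ligand_confs = n_l
    result.n_zeta = n_zeta
    log.update(n_receptor_frames=n_p, n_ligand_confs=n_l, n_zeta=n_zeta,
               n_tested=result.n_tested, alpha=result.alpha)

    if not result.passing_pairs:
        raise NoOverlapError(
            "no combinatorial sample passed the clash filter (alpha = 0); "
            "the receptor ensemble leaves no room for the ligand")
    dg_fil, se_fil = delta_g_filter(result, config.temperature)

    # reservoir-subsample the passing pairs, then recompose coordinates
    n_keep = min(len(result.passing_pairs), config.max_kept_samples)
    keep_idx = (np.arange(len(result.passing_pairs)) if n_keep == len(result.passing_pairs)
                else np.sort(rng_res.choice(len(result.passing_pairs), n_keep,
                                            replace=False)))
    zeta_cache = {}
    for j in keep_idx:
        frame_index, (ci, k) = result.passing_pairs[j]
        align, c_pocket, coords = alignments[frame_index]
        if frame_index not in zeta_cache:
            zeta_cache[frame_index] = sample_restraint_arrays(
                restraint, n_l * n_zeta,
                _derived_seed(config.seed, f"zeta-{frame_index}"))
        T, Q = zeta_cache[frame_index]
        z = RigidTransform(t=T[k], q=Q[k])
        pose = apply_transform(z, confs[ci], align, c_pocket)
        kept.append(DecoupledSample(receptor_coords=coords,
                                    ligand_coords=pose, zeta=z))

    # 6. MBAR leg
    u = evaluate_reduced_potentials(
        cpx, kept, backend, restraint, config.temperature,
        complex_zetas=zetas, n_s=config.n_s,
        seed=_derived_seed(config.seed, "mbar"), cutoffs=cutoffs)
    dg_mbar, se_mbar, overlap = mbar_delta_g(u, config.temperature)
    log["overlap"] = overlap
    if overlap < OVERLAP_WARN_THRESHOLD:
        log["warnings"] = log.get("warnings", []) + [
            f"phase-space overlap {overlap:.3g} below "
            f"{OVERLAP_WARN_THRESHOLD}; MBAR leg may be unreliable"]

    res = assemble_total(dg_rel, dg_fil, dg_mbar,
                         se_filter=se_fil, se_mbar=se_mbar,
                         diagnostics={**log})
    if report_path is not None:
        write_report(res, config, report_path,
                     runtime_seconds=time.time() - t_start)
    return res


def write_report(result: DBFEResult, config: RunConfig, path,
                 runtime_seconds: float | None = None) -> dict:
    """Serialize a run report; deterministic except the ``timing`` block."""
    doc = {
        "dbfe_version": __version__,
        "config": asdict(config),
        "result": result.to_dict(),
        "timing": {"runtime_seconds": runtime_seconds},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def run_multipose(configs, report_path=None) -> dict:
    """Run several pose configs and Boltzmann-combine the survivors.

    Poses that fail structurally (alpha = 0) are excluded from the
    combination and reported with the failure reason, mirroring how closed
    binding sites are excluded rather than imputed.
    """
    configs = list(configs)
    if not configs:
        raise ParameterError("need at least one pose config")
    per_pose = []
    dgs = []
    temperature = configs[0].temperature
    for i, cfg in enumerate(configs):
        try:
            res = run_dbfe(cfg)
            per_pose.append({"pose": i, "status": "ok",
                             "result": res.to_dict()})
            dgs.append(res.dg_total)
        except NoOverlapError as exc:
            per_pose.append({"pose": i, "status": "excluded",
                             "reason": str(exc)})
    if not dgs:
        raise NoOverlapError("every pose failed the clash filter")
    combined = combine_poses(dgs, temperature)
    doc = {"poses": per_pose, "combined_dg": combined,
           "n_included": len(dgs), "temperature": temperature}
    if report_path is not None:
        Path(report_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc
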