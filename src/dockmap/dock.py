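"""Exhaustive rigid-body docking: rotation sweep, FFT translation scan,
restraint-aware retention and local refinement of retained poses."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation as _SciRot
from scipy.stats import qmc

from . import energy as _energy
from .gridcore import (COEFF_SETS, CorrelationEngine, EnergyWeights, GridSet,
                       Rotation, build_ligand_grids, build_receptor_grids,
                       load_contact_matrix, rotate)
from .restraints import RestraintSet, satisfied
from .structio import ParamStructure


class DockingError(RuntimeError):
    pass


@dataclass
class Pose:
    """A rigid placement of the ligand: rotate about `center`, then shift."""

    rotation: Rotation
    center: np.ndarray
    shift: np.ndarray
    energy: float
    components: dict = field(default_factory=dict)
    tvox: tuple | None = None
    rank: int = 0
    energy_cont: float | None = None
    refined: bool = False
    warn: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.rotation.apply(coords, self.center) + self.shift


@dataclass
class PoseList:
    poses: list
    n_candidates: int = 0
    params: "DockParams | None" = None

    def __len__(self):
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i):
        return self.poses[i]


@dataclass
class DockParams:
    n_rotations: int = 500
    retained_total: int = 1000
    per_rotation_keep: int = 1
    weights: EnergyWeights = field(default_factory=lambda: COEFF_SETS["balanced"])
    spacing: float = 1.0
    margin: float | None = None  # None -> ligand diameter + 2 Å
    seed: int = 0

    def __post_init__(self):
        if self.retained_total < 1 or self.per_rotation_keep < 1:
            raise ValueError("retention counts must be >= 1")


def rotation_set(n: int, seed: int = 0) -> list:
    """Deterministic quasi-uniform rotations; identity always first.

    Shoemake's map applied to a scrambled Halton sequence: uniform points
    in the cube map to uniformly distributed unit quaternions.
    """
    if n < 1:
        raise ValueError("need at least one rotation")
    rots = [Rotation.identity()]
    if n == 1:
        return rots
    u = qmc.Halton(d=3, scramble=True, seed=seed).random(n - 1)
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    q = np.stack([np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
                  np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
                  np.sqrt(u1) * np.sin(2 * np.pi * u3),
                  np.sqrt(u1) * np.cos(2 * np.pi * u3)], axis=1)
    rots.extend(Rotation.from_quaternion(qi) for qi in q)
    return rots


def _restraint_feasible_mask(rec: ParamStructure, lig: ParamStructure,
                             rot_coords: np.ndarray, base_shift: np.ndarray,
                             h: float, out_dims: tuple,
                             rs: RestraintSet) -> np.ndarray:
    """Boolean feasibility over the translation lattice for one rotation."""
    mask = np.ones(out_dims, dtype=bool)
    ax = [np.arange(out_dims[k]) * h for k in range(3)]
    for g in rs.groups:
        count = np.zeros(out_dims, dtype=np.int16)
        for r in g.restraints:
            p = rec.coords[r.rec_sel.resolve(rec.structure)]
            a = rot_coords[r.lig_sel.resolve(lig.structure)] + base_shift
            dx = p[0] - a[0] - ax[0]
            dy = p[1] - a[1] - ax[1]
            dz = p[2] - a[2] - ax[2]
            d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                  + dz[None, None, :] ** 2)
            count += ((d2 >= r.dmin ** 2) & (d2 <= r.dmax ** 2)).astype(np.int16)
        mask &= count >= g.required
    return mask


def dock_rigid(rec: ParamStructure, lig: ParamStructure,
               params: DockParams | None = None,
               restraints: RestraintSet | None = None,
               rotations: list | None = None) -> PoseList:
    """Sweep rotations, score all translations by FFT, keep the best poses.

    For each rotation the best `per_rotation_keep` feasible translations
    are collected; the pooled candidates are sorted by energy and the
    lowest `retained_total` are returned with contiguous ranks.
    """
    params = params or DockParams()
    lig_coords = lig.coords
    center = lig_coords.mean(axis=0)
    diam = 2.0 * float(np.max(np.linalg.norm(lig_coords - center, axis=1)))
    margin = params.margin if params.margin is not None else diam + 2.0
    rec_grids = build_receptor_grids(rec, params.spacing, margin)
    engine = CorrelationEngine(rec_grids, params.weights)
    if rotations is None:
        rotations = rotation_set(params.n_rotations, params.seed)

    candidates = []
    n_cand = 0
    for rot in rotations:
        lig_rot = rotate(lig, rot, center)
        lig_grids = build_ligand_grids(lig_rot, params.spacing)
        sf = engine.score(lig_grids, rot)
        vals = sf.values
        base_shift = rec_grids.origin - lig_grids.origin
        if restraints is not None:
            feas = _restraint_feasible_mask(rec, lig, lig_rot.coords,
                                            base_shift, params.spacing,
                                            vals.shape, restraints)
            if not feas.any():
                continue
            vals = np.where(feas, vals, np.inf)
        flat = vals.ravel()
        k = min(params.per_rotation_keep, flat.size)
        idx = np.argpartition(flat, k - 1)[:k]
        idx = idx[np.isfinite(flat[idx])]
        for i in sorted(idx, key=lambda j: flat[j]):
            tvox = np.unravel_index(i, vals.shape)
            shift = base_shift + np.array(tvox, dtype=float) * params.spacing
            comps = {c: float(sf.components[c][tvox]) for c in sf.components}
            candidates.append(Pose(rotation=rot, center=center.copy(),
                                   shift=shift, energy=float(flat[i]),
                                   components=comps, tvox=tuple(int(t) for t in tvox)))
            n_cand += 1

    if not candidates:
        raise DockingError("no feasible pose (restraints eliminated all "
                           "translations for every rotation)")
    candidates.sort(key=lambda p: p.energy)
    kept = candidates[:params.retained_total]
    for r, p in enumerate(kept, start=1):
        p.rank = r
    return PoseList(poses=kept, n_candidates=n_cand, params=params)


def rescore(rec: ParamStructure, lig: ParamStructure, pose: Pose,
            params: DockParams | None = None) -> float:
    """Recompute a pose's grid score by direct summation (invariant check)."""
    params = params or DockParams()
    lig_coords = lig.coords
    center = lig_coords.mean(axis=0)
    diam = 2.0 * float(np.max(np.linalg.norm(lig_coords - center, axis=1)))
    margin = params.margin if params.margin is not None else diam + 2.0
    rec_grids = build_receptor_grids(rec, params.spacing, margin)
    lig_rot = rotate(lig, pose.rotation, center)
    lig_grids = build_ligand_grids(lig_rot, params.spacing)
    eps = load_contact_matrix()
    w = params.weights
    t = pose.tvox
    ld = lig_grids.dims

    def corr_at(ra, la):
        block = ra[t[0]:t[0] + ld[0], t[1]:t[1] + ld[1], t[2]:t[2] + ld[2]]
        return float(np.sum(block * la))

    from .gridcore import ATYPES, PAIR_CHANNELS
    total = (w.w_rep * corr_at(rec_grids.channels["core"], lig_grids.channels["core"])
             - w.w_attr * corr_at(rec_grids.channels["surface"],
                                  lig_grids.channels["surface"])
             + w.w_elec * corr_at(rec_grids.channels["charge"],
                                  lig_grids.channels["charge"]))
    pair = 0.0
    for i in range(len(ATYPES)):
        for j in range(len(ATYPES)):
            ra = rec_grids.channels[PAIR_CHANNELS[i]]
            la = lig_grids.channels[PAIR_CHANNELS[j]]
            if eps[i, j] == 0.0 or not la.any() or not ra.any():
                continue
            pair += eps[i, j] * corr_at(ra, la)
    return total + w.w_pair * pair


def _fit_rigid(ref: np.ndarray, moved: np.ndarray, center: np.ndarray):
    """Rotation+shift such that moved ≈ R(ref - center) + center + shift."""
    rc, mc = ref.mean(axis=0), moved.mean(axis=0)
    A, B = moved - mc, ref - rc
    if len(ref) < 3 or float(np.max(np.linalg.norm(B, axis=1))) < 1e-9:
        rot = Rotation.identity()  # pure translation is exact here
    else:
        sci, _ = _SciRot.align_vectors(A, B)
        rot = Rotation.from_quaternion(sci.as_quat())
    shift = mc - rot.apply(rc[None], center)[0]
    return rot, shift


def refine_pose(rec: ParamStructure, lig: ParamStructure, pose: Pose,
                max_iter: int = 60) -> Pose:
    """Rigid local minimization of the continuous clash+attraction energy.

    Never worsens the continuous energy; caps displacement at 3 Å RMSD.
    On divergence the input pose is returned with `warn` set.
    """
    coords0 = pose.apply(lig.coords)
    new, e_min, e0, div = _energy.minimize_rigid(
        rec, coords0[None], lig.radius, lig.charge, mob_types=lig.atype,
        max_iter=max_iter)
    if div[0] or e_min[0] > e0[0]:
        out = replace(pose, energy_cont=float(e0[0]), warn=True)
        return out
    rot, shift = _fit_rigid(lig.coords, new[0], pose.center)
    return Pose(rotation=rot, center=pose.center.copy(), shift=shift,
                energy=pose.energy, components=dict(pose.components),
                tvox=pose.tvox, rank=pose.rank,
                energy_cont=float(e_min[0]), refined=True)
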