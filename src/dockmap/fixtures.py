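"""Deterministic synthetic test systems with built-in ground truth.

Two generators: a planted-pose receptor/ligand pair whose unique
shape-complementarity optimum is recorded, and a single receptor with a
designed surface cavity.  Constructors self-validate their guarantees.
Pseudo-atoms use real residue/atom names (ALA CB) so parameter lookup
works unmodified downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dock import Pose
from .gridcore import Rotation
from .structio import Atom, ParamStructure, Structure, assign_params

_LATTICE = 2.9  # pseudo-atom lattice constant, Å


class FixtureError(ValueError):
    pass


@dataclass
class ToyComplex:
    receptor: ParamStructure
    ligand: ParamStructure          # stored displaced from the planted pose
    planted_transform: Pose         # maps stored ligand onto the planted pose
    planted_coords: np.ndarray
    seed: int


@dataclass
class ToyPocket:
    receptor: ParamStructure
    cavity_center: np.ndarray
    cavity_radius: float
    lining_residues: list
    seed: int


def _lattice_points(rng: np.random.Generator, radius: float,
                    jitter: float) -> np.ndarray:
    k = int(np.ceil(radius / _LATTICE)) + 1
    ax = np.arange(-k, k + 1) * _LATTICE
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def _pseudo_structure(coords: np.ndarray, chain: str, label: str) -> ParamStructure:
    atoms = [Atom(serial=i + 1, name="CB", element="C", res_name="ALA",
                  chain=chain, res_seq=i + 1, icode="",
                  xyz=np.asarray(c, dtype=float))
             for i, c in enumerate(coords)]
    return assign_params(Structure(atoms, id=label))


#: partner atom type maximizing the packaged contact-matrix attraction
_PARTNER = {"N_don": "O_acc", "O_acc": "N_don",
            "C_arom": "C_arom", "C_aliph": "C_aliph"}


def _quadrant_type(p: np.ndarray, origin: np.ndarray) -> str:
    y, z = p[1] - origin[1], p[2] - origin[2]
    if y > 0:
        return "N_don" if z > 0 else "O_acc"
    return "C_arom" if z > 0 else "C_aliph"


def make_toy_complex(seed: int, n_rec: int = 300, n_lig: int = 60) -> ToyComplex:
    """Receptor with a concave patch + ligand built as the patch complement.

    The ligand is an asymmetric two-lobe blob with three non-coplanar knob
    arms; the receptor pocket is carved as the dilation of the planted
    ligand, so the plant has zero core overlap and full shell contact.
    Quadrant-wise polar atom typing (matched complementarily on the pocket
    lining) makes the planted orientation the unique optimum.  The stored
    ligand is displaced from the plant by a recorded translation.
    """
    if n_rec < 20 or n_lig < 10:
        raise FixtureError("fixture too small: need n_rec >= 20, n_lig >= 10")
    rng = np.random.default_rng(seed)
    r_rec = _LATTICE * (3.0 * n_rec * 1.35 / (4.0 * np.pi)) ** (1.0 / 3.0)
    pocket = np.array([r_rec - 1.0, 0.0, 0.0])

    # two-lobe blob on a fine jittered lattice
    k = 4
    ax = np.arange(-k, k + 1) * 1.8
    cand = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"),
                    axis=-1).reshape(-1, 3) + pocket
    cand = cand + rng.uniform(-0.15, 0.15, size=cand.shape)
    second_lobe = pocket + np.array([-1.0, 3.5, 0.8])
    in_blob = ((np.linalg.norm(cand - pocket, axis=1) <= 4.2)
               | (np.linalg.norm(cand - second_lobe, axis=1) <= 3.2))
    blob = cand[in_blob]
    # three knob arms break the remaining rotational ambiguity
    dirs = np.array([[-0.2, -1.0, 0.3], [-0.3, 0.4, -1.0], [-1.0, 0.5, 0.6]])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    knobs = np.array([pocket + d * t + rng.uniform(-0.1, 0.1, 3)
                      for d in dirs for t in (5.4, 7.2)])
    lig_pts = np.vstack([blob, knobs])
    if len(lig_pts) < 10:
        raise FixtureError("ligand construction produced too few atoms")
    if len(lig_pts) > n_lig:
        order = np.argsort(np.linalg.norm(lig_pts - pocket, axis=1))
        keep = np.unique(np.concatenate(
            [order[:max(n_lig - len(knobs), 1)],
             np.arange(len(lig_pts))[-len(knobs):]]))
        lig_pts = lig_pts[np.sort(keep)]

    # receptor: jittered ball minus the dilated ligand
    ball = _lattice_points(rng, r_rec, jitter=0.3)
    dmin = np.min(np.linalg.norm(
        ball[:, None, :] - lig_pts[None, :, :], axis=-1), axis=1)
    rec_pts = ball[dmin > 3.6]
    if len(rec_pts) < 20:
        raise FixtureError("receptor construction produced too few atoms")

    receptor = _pseudo_structure(rec_pts, "A", f"toy-receptor-{seed}")
    offset = np.array([r_rec + 30.0, 0.0, 0.0])
    stored = lig_pts + offset
    ligand = _pseudo_structure(stored, "B", f"toy-ligand-{seed}")
    # complementary polar typing: ligand by pocket-frame quadrant, pocket
    # lining by the partner type of its nearest ligand atom
    for i, p in enumerate(lig_pts):
        ligand.atype[i] = _quadrant_type(p, pocket)
    d_rl = np.linalg.norm(rec_pts[:, None, :] - lig_pts[None, :, :], axis=-1)
    for i in range(len(rec_pts)):
        j = int(np.argmin(d_rl[i]))
        if d_rl[i, j] <= 6.0:
            receptor.atype[i] = _PARTNER[ligand.atype[j]]

    plant = Pose(rotation=Rotation.identity(), center=stored.mean(axis=0),
                 shift=-offset, energy=0.0)
    # self-validation of the construction guarantees
    back = plant.apply(stored)
    if not np.allclose(back, lig_pts, atol=1e-9):
        raise FixtureError("planted transform does not reproduce the plant")
    gap = np.min(np.linalg.norm(
        lig_pts[:, None, :] - rec_pts[None, :, :], axis=-1))
    if gap < 3.2:
        raise FixtureError(f"core overlap at planted pose (min dist {gap:.2f})")
    return ToyComplex(receptor=receptor, ligand=ligand,
                      planted_transform=plant, planted_coords=lig_pts,
                      seed=seed)


def make_toy_pocket(seed: int, radius: float = 11.0,
                    cavity_radius: float = 5.0) -> ToyPocket:
    """Roughly spherical pseudo-protein with one carved surface cavity."""
    rng = np.random.default_rng(seed)
    pts = _lattice_points(rng, radius, jitter=0.3)
    center = np.array([radius - 2.5, 0.0, 0.0])
    keep = np.linalg.norm(pts - center, axis=1) > cavity_radius
    rec_pts = pts[keep]
    receptor = _pseudo_structure(rec_pts, "A", f"toy-pocket-{seed}")
    d = np.linalg.norm(rec_pts - center, axis=1)
    lining = [receptor.structure.atoms[i].res_seq
              for i in np.where(d <= cavity_radius + 3.0)[0]]
    if np.min(d) <= cavity_radius:
        raise FixtureError("cavity is not empty")
    if len(lining) < 5:
        raise FixtureError("cavity has too few lining residues")
    return ToyPocket(receptor=receptor, cavity_center=center,
                     cavity_radius=cavity_radius, lining_residues=lining,
                     seed=seed)
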