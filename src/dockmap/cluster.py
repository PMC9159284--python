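"""Greedy RMSD pose clustering and model-comparison metrics.

Ligand RMSD is computed in the fixed receptor frame (no superposition);
iRMSD superposes the backbone of reference-defined interface residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _SciRot

from .structio import ParamStructure, Structure

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class ClusterParams:
    radius: float = 9.0
    max_clusters: int = 10
    atom_mask: str = "heavy"  # "heavy" or "ca"

    def __post_init__(self):
        if self.radius <= 0 or self.max_clusters < 1:
            raise ValueError("invalid clustering parameters")


@dataclass
class PoseCluster:
    members: list          # indices into the input pose list
    representative: int    # member with the most neighbours (cluster center)
    population: int
    rank: int
    center_energy: float


def _mask_indices(lig: ParamStructure, atom_mask: str) -> np.ndarray:
    if atom_mask == "heavy":
        idx = np.arange(len(lig))
    elif atom_mask == "ca":
        idx = np.array([i for i, a in enumerate(lig.structure.atoms)
                        if a.name == "CA"], dtype=int)
    else:
        raise ValueError(f"unknown atom mask {atom_mask!r}")
    if idx.size == 0:
        raise ValueError("atom mask selects no atoms")
    return idx


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between matched coordinate sets, no superposition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("coordinate sets must match and be non-empty")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ligand_rmsd(pose_a, pose_b, lig: ParamStructure,
                atom_mask: str = "heavy") -> float:
    """RMSD between two placements of the same ligand, receptor frame fixed."""
    idx = _mask_indices(lig, atom_mask)
    coords = lig.coords[idx]
    return rmsd_fixed(pose_a.apply(coords), pose_b.apply(coords))


def pairwise_rmsd_matrix(poses, lig: ParamStructure,
                         atom_mask: str = "heavy") -> np.ndarray:
    """All-pairs fixed-frame ligand RMSD via the Gram-matrix identity."""
    idx = _mask_indices(lig, atom_mask)
    coords = lig.coords[idx]
    n_at = len(idx)
    X = np.stack([p.apply(coords).ravel() for p in poses])  # (P, 3*n)
    sq = np.sum(X * X, axis=1) / n_at
    gram = (X @ X.T) / n_at
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def greedy_cluster(poses, lig: ParamStructure,
                   params: ClusterParams | None = None) -> list:
    """Repeatedly seed on the pose with most neighbours within `radius`.

    Ties break towards lower energy, then lower input index, making the
    result independent of input permutation.  Clusters are ranked by
    population (ties: lower center energy).
    """
    params = params or ClusterParams()
    if isinstance(poses, (list, tuple)):
        pose_list = list(poses)
    else:
        pose_list = list(poses.poses)
    if not pose_list:
        raise ValueError("no poses to cluster")
    dmat = pairwise_rmsd_matrix(pose_list, lig, params.atom_mask)
    within = dmat <= params.radius
    alive = np.ones(len(pose_list), dtype=bool)
    energies = np.array([p.energy for p in pose_list])
    clusters = []
    while alive.any() and len(clusters) < params.max_clusters:
        counts = np.where(alive, (within & alive[None, :]).sum(axis=1), -1)
        best = np.lexsort((np.arange(len(pose_list)), energies, -counts))[0]
        members = np.where(alive & within[best])[0]
        clusters.append(PoseCluster(members=members.tolist(),
                                    representative=int(best),
                                    population=int(members.size),
                                    rank=0,
                                    center_energy=float(energies[best])))
        alive[members] = False
    clusters.sort(key=lambda c: (-c.population, c.center_energy))
    for r, c in enumerate(clusters, start=1):
        c.rank = r
    return clusters


def _interface_residue_ids(s: Structure, chains_a, chains_b,
                           cutoff: float) -> set:
    ia = [i for i, a in enumerate(s.atoms) if a.chain in chains_a]
    ib = [i for i, a in enumerate(s.atoms) if a.chain in chains_b]
    if not ia or not ib:
        raise ValueError("one of the chain sets matched no atoms")
    coords = s.coords
    ta, tb = cKDTree(coords[ia]), cKDTree(coords[ib])
    pairs = ta.query_ball_tree(tb, cutoff)
    out = set()
    for k, hits in enumerate(pairs):
        if hits:
            out.add(s.atoms[ia[k]].residue_id())
            for j in hits:
                out.add(s.atoms[ib[j]].residue_id())
    return out


def irmsd(model: Structure, reference: Structure, chains_a, chains_b,
          cutoff: float = 10.0) -> float:
    """Interface backbone RMSD after least-squares superposition.

    Interface residues are defined on the reference: any residue with a
    heavy atom within `cutoff` of the partner chain set.
    """
    iface = _interface_residue_ids(reference, set(chains_a), set(chains_b),
                                   cutoff)
    if not iface:
        raise ValueError("empty interface at this cutoff")
    ref_bb = {}
    for a in reference.atoms:
        if a.residue_id() in iface and a.name in BACKBONE:
            ref_bb[(a.chain, a.res_seq, a.icode, a.name)] = a.xyz
    mod_bb = {}
    for a in model.atoms:
        key = (a.chain, a.res_seq, a.icode, a.name)
        if key in ref_bb:
            mod_bb[key] = a.xyz
    keys = sorted(mod_bb)
    if len(keys) < 3:
        raise ValueError("fewer than 3 matched interface backbone atoms")
    P = np.array([mod_bb[k] for k in keys])
    Q = np.array([ref_bb[k] for k in keys])
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    rot, _ = _SciRot.align_vectors(Qc, Pc)
    return rmsd_fixed(rot.apply(Pc), Qc)
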