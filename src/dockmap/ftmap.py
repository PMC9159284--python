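"""Whole-surface solvent mapping.

Each of 16 small organic probe types is swept over the entire receptor
surface with the FFT engine, the best grid poses are minimized off-grid,
per-probe pose clusters are ranked by average minimized energy, and
clusters of different probe types that co-locate are merged into
consensus sites (hotspots).  Hotspot populations drive druggability
classification; nearby hotspots merge into predicted binding sites.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import energy as _energy
from .dock import rotation_set
from .gridcore import (CorrelationEngine, EnergyWeights, Rotation,
                       build_ligand_grids, build_receptor_grids)
from .structio import Atom, ParamStructure, Structure

#: probe-library checksum guard (geometry + parameters)
_PROBE_FILE = "probes.json"


@dataclass(frozen=True)
class Probe:
    name: str
    code: str
    template: ParamStructure
    checksum: str

    @property
    def diameter(self) -> float:
        c = self.template.coords
        cen = c.mean(axis=0)
        return 2.0 * float(np.max(np.linalg.norm(c - cen, axis=1)))


@dataclass
class ProbePose:
    probe: str
    rotation: Rotation
    coords: np.ndarray       # minimized heavy-atom coordinates
    center: np.ndarray       # centroid of coords
    energy_grid: float
    energy_min: float


@dataclass
class ProbeCluster:
    probe: str
    members: list            # ProbePose
    center: np.ndarray       # mean probe-center position
    avg_energy: float
    rank: int = 0

    @property
    def population(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSite:
    members: list            # ProbeCluster across probe types
    center: np.ndarray
    population: int
    strength_class: str
    mean_energy: float
    rank: int = 0

    @classmethod
    def from_population(cls, population: int, center=(0.0, 0.0, 0.0), *,
                        strong_threshold: int = 16,
                        intermediate_threshold: int = 10,
                        mean_energy: float = 0.0) -> "ConsensusSite":
        """Synthetic record for classifier input when only counts are known."""
        return cls(members=[], center=np.asarray(center, float),
                   population=int(population),
                   strength_class=_strength(population, strong_threshold,
                                            intermediate_threshold),
                   mean_energy=mean_energy)


@dataclass
class BindingSite:
    hotspots: list           # member ConsensusSites
    total_population: int
    center: np.ndarray
    residues: list           # contacting residue ids (chain, res_seq, icode)
    rank: int = 0


@dataclass
class MapParams:
    poses_retained_per_probe: int = 2000
    probe_rotations: int = 60
    probe_cluster_radius: float = 3.0
    clusters_kept_per_probe: int = 6
    consensus_radius: float = 4.0
    strong_threshold: int = 16
    intermediate_threshold: int = 10
    site_merge_cutoff: float = 8.0
    contact_cutoff: float = 4.0
    spacing: float = 0.8
    minimize_iter: int = 30
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    seed: int = 0

    def __post_init__(self):
        if min(self.probe_cluster_radius, self.consensus_radius,
               self.site_merge_cutoff) <= 0:
            raise ValueError("radii must be positive")
        if self.strong_threshold < 1:
            raise ValueError("strong_threshold must be >= 1")


def _strength(population: int, strong: int, intermediate: int) -> str:
    if population >= strong:
        return "strong"
    if population > intermediate:
        return "intermediate"
    return "weak"


def probe_library() -> list:
    """The 16 packaged organic probe molecules, in stable order."""
    text = resources.files("dockmap.data").joinpath(_PROBE_FILE).read_text()
    data = json.loads(text)
    probes = []
    for entry in data["probes"]:
        atoms = []
        radii, charges, atypes = [], [], []
        for i, a in enumerate(entry["atoms"]):
            atoms.append(Atom(serial=i + 1, name=a["name"], element=a["element"],
                              res_name=entry["code"], chain="X", res_seq=1,
                              icode="", xyz=np.array(a["xyz"], dtype=float),
                              is_hetero=True))
            radii.append(a["radius"])
            charges.append(a["charge"])
            atypes.append(a["atype"])
        ps = ParamStructure(Structure(atoms, id=entry["name"]),
                            np.array(radii), np.array(charges), atypes)
        digest = hashlib.sha256(
            json.dumps(entry, sort_keys=True).encode()).hexdigest()[:16]
        probes.append(Probe(name=entry["name"], code=entry["code"],
                            template=ps, checksum=digest))
    return probes


def map_probe(rec: ParamStructure, probe: Probe,
              params: MapParams | None = None,
              engine: CorrelationEngine | None = None,
              rotations: list | None = None) -> list:
    """FFT sweep of one probe type over the whole surface + minimization.

    Returns up to `poses_retained_per_probe` ProbePoses sorted by
    minimized energy.
    """
    params = params or MapParams()
    template = probe.template
    t_coords = template.coords
    center = t_coords.mean(axis=0)
    if engine is None:
        margin = probe.diameter + 2.0
        grids = build_receptor_grids(rec, params.spacing, margin)
        engine = CorrelationEngine(grids, params.weights)
    rec_grids = engine.rec
    if any(ld > rd for ld, rd in
           zip(build_ligand_grids(template, params.spacing).dims, rec_grids.dims)):
        raise ValueError("probe grid exceeds receptor grid")
    if rotations is None:
        rotations = rotation_set(params.probe_rotations, params.seed)

    K = params.poses_retained_per_probe
    per_rot = max(1, int(np.ceil(2.0 * K / len(rotations))))
    cand = []  # (energy, rot_index, tvox, shift)
    for ri, rot in enumerate(rotations):
        rot_coords = rot.apply(t_coords, center)
        lig = ParamStructure(template.structure.with_coords(rot_coords),
                             template.radius, template.charge, template.atype)
        lig_grids = build_ligand_grids(lig, params.spacing)
        sf = engine.score(lig_grids, rot)
        flat = sf.values.ravel()
        k = min(per_rot, flat.size)
        idx = np.argpartition(flat, k - 1)[:k]
        base = rec_grids.origin - lig_grids.origin
        for i in idx:
            tvox = np.unravel_index(int(i), sf.values.shape)
            shift = base + np.array(tvox, dtype=float) * params.spacing
            cand.append((float(flat[i]), ri, rot_coords, shift))
    cand.sort(key=lambda c: c[0])
    cand = cand[:K]
    if not cand:
        return []

    batch = np.stack([c[2] + c[3] for c in cand])
    mincoords, e_min, _, _ = _energy.minimize_rigid(
        rec, batch, template.radius, template.charge,
        mob_types=template.atype, max_iter=params.minimize_iter)
    poses = []
    for (e_grid, ri, _, _), mc, em in zip(cand, mincoords, e_min):
        poses.append(ProbePose(probe=probe.name, rotation=rotations[ri],
                               coords=mc, center=mc.mean(axis=0),
                               energy_grid=e_grid, energy_min=float(em)))
    poses.sort(key=lambda p: p.energy_min)
    return poses


def cluster_probe_poses(poses: list, params: MapParams | None = None) -> list:
    """Greedy probe-center clustering; ranked ascending by average energy."""
    params = params or MapParams()
    if not poses:
        return []
    centers = np.stack([p.center for p in poses])
    energies = np.array([p.energy_min for p in poses])
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    within = d <= params.probe_cluster_radius
    alive = np.ones(len(poses), dtype=bool)
    clusters = []
    while alive.any():
        counts = np.where(alive, (within & alive[None, :]).sum(axis=1), -1)
        seed = np.lexsort((np.arange(len(poses)), energies, -counts))[0]
        members = np.where(alive & within[seed])[0]
        sub = [poses[i] for i in members]
        clusters.append(ProbeCluster(
            probe=poses[seed].probe, members=sub,
            center=np.mean([p.center for p in sub], axis=0),
            avg_energy=float(np.mean([p.energy_min for p in sub]))))
        alive[members] = False
    clusters.sort(key=lambda c: c.avg_energy)
    clusters = clusters[:params.clusters_kept_per_probe]
    for r, c in enumerate(clusters, start=1):
        c.rank = r
    return clusters


def consensus_sites(all_clusters: list, params: MapParams | None = None) -> list:
    """Greedy cross-probe merge of cluster centers into hotspots.

    Every input cluster is assigned to exactly one site; sites are
    ranked by population (ties: lower mean average-energy).
    """
    params = params or MapParams()
    if not all_clusters:
        return []
    centers = np.stack([c.center for c in all_clusters])
    energies = np.array([c.avg_energy for c in all_clusters])
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    within = d <= params.consensus_radius
    alive = np.ones(len(all_clusters), dtype=bool)
    sites = []
    while alive.any():
        counts = np.where(alive, (within & alive[None, :]).sum(axis=1), -1)
        seed = np.lexsort((np.arange(len(all_clusters)), energies, -counts))[0]
        members_idx = np.where(alive & within[seed])[0]
        members = [all_clusters[i] for i in members_idx]
        weights = np.array([max(c.population, 1) for c in members], dtype=float)
        cen = np.average(np.stack([c.center for c in members]), axis=0,
                         weights=weights)
        pop = len(members)
        sites.append(ConsensusSite(
            members=members, center=cen, population=pop,
            strength_class=_strength(pop, params.strong_threshold,
                                     params.intermediate_threshold),
            mean_energy=float(np.mean([c.avg_energy for c in members]))))
        alive[members_idx] = False
    sites.sort(key=lambda s: (-s.population, s.mean_energy))
    for r, s in enumerate(sites, start=1):
        s.rank = r
    return sites


@dataclass
class DruggabilityReport:
    sites: list              # retained ConsensusSites (ranked)
    strongest_population: int
    druggable: bool

    def rows(self):
        return [(s.rank, s.population, s.strength_class) for s in self.sites]


def druggability_report(sites: list, interface_filter=None, *,
                        rec: ParamStructure | None = None,
                        params: MapParams | None = None,
                        contact_cutoff: float = 5.0) -> DruggabilityReport:
    """Classify druggability from hotspot populations.

    With an `interface_filter` (residue-id set) only sites whose center
    lies within `contact_cutoff` of an atom of those residues are kept.
    Verdict: druggable iff the strongest retained site has population at
    or above the strong threshold.
    """
    params = params or MapParams()
    retained = list(sites)
    if interface_filter is not None:
        if rec is None:
            raise ValueError("interface filtering requires the receptor")
        keep_ids = set(interface_filter)
        sel = [i for i, a in enumerate(rec.structure.atoms)
               if a.residue_id() in keep_ids
               or (a.chain, a.res_seq) in keep_ids]
        if not sel:
            raise ValueError("interface filter matched no residues")
        coords = rec.coords[sel]
        retained = [s for s in retained
                    if np.min(np.linalg.norm(coords - s.center, axis=1))
                    <= contact_cutoff]
    strongest = max((s.population for s in retained), default=0)
    return DruggabilityReport(
        sites=retained, strongest_population=strongest,
        druggable=strongest >= params.strong_threshold)


def predict_sites(sites: list, rec: ParamStructure,
                  params: MapParams | None = None) -> list:
    """Single-linkage merge of nearby hotspots into binding sites."""
    params = params or MapParams()
    if not sites:
        return []
    n = len(sites)
    centers = np.stack([s.center for s in sites])
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    adj = d <= params.site_merge_cutoff
    comp = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = cid
        while stack:
            k = stack.pop()
            for j in np.where(adj[k] & (comp < 0))[0]:
                comp[j] = cid
                stack.append(j)
        cid += 1
    rec_coords = rec.coords
    out = []
    for c in range(cid):
        members = [sites[i] for i in range(n) if comp[i] == c]
        pop = sum(s.population for s in members)
        pose_pts = [p.coords for s in members for cl in s.members
                    for p in cl.members]
        residues = []
        if pose_pts:
            pts = np.concatenate(pose_pts, axis=0)
            seen = set()
            for i, a in enumerate(rec.structure.atoms):
                rid = a.residue_id()
                if rid in seen:
                    continue
                if np.min(np.linalg.norm(pts - rec_coords[i], axis=1)) \
                        <= params.contact_cutoff:
                    seen.add(rid)
            residues = sorted(seen)
        wts = np.array([max(s.population, 1) for s in members], dtype=float)
        cen = np.average(np.stack([s.center for s in members]), axis=0,
                         weights=wts)
        out.append(BindingSite(hotspots=members, total_population=pop,
                               center=cen, residues=residues))
    out.sort(key=lambda b: -b.total_population)
    for r, b in enumerate(out, start=1):
        b.rank = r
    return out


@dataclass
class MapResult:
    probe_clusters: dict     # probe name -> list[ProbeCluster]
    sites: list              # ConsensusSites
    report: DruggabilityReport
    binding_sites: list


def map_structure(rec: ParamStructure, params: MapParams | None = None,
                  probes: list | None = None,
                  interface_filter=None) -> MapResult:
    """Full mapping protocol for one structure (all 16 probes)."""
    params = params or MapParams()
    if probes is None:
        probes = probe_library()
    max_diam = max(p.diameter for p in probes)
    grids = build_receptor_grids(rec, params.spacing, max_diam + 2.0)
    engine = CorrelationEngine(grids, params.weights)
    rotations = rotation_set(params.probe_rotations, params.seed)
    per_probe = {}
    all_clusters = []
    for probe in probes:
        poses = map_probe(rec, probe, params, engine=engine,
                          rotations=rotations)
        clusters = cluster_probe_poses(poses, params)
        per_probe[probe.name] = clusters
        all_clusters.extend(clusters)
    sites = consensus_sites(all_clusters, params)
    report = druggability_report(sites, interface_filter, rec=rec,
                                 params=params)
    bsites = predict_sites(sites, rec, params)
    return MapResult(probe_clusters=per_probe, sites=sites, report=report,
                     binding_sites=bsites)


def map_by_domains(rec: ParamStructure, domains: list,
                   params: MapParams | None = None,
                   probes: list | None = None):
    """Map the whole structure and each residue-range domain separately.

    `domains` is a list of (chain, first_res, last_res) inclusive ranges;
    ranges must be non-empty and pairwise disjoint.  Returns
    (results, merged_rows) where results maps label -> MapResult and each
    merged row is (label, site rank, population, strength, center).
    """
    params = params or MapParams()
    seen = []
    for chain, lo, hi in domains:
        if lo > hi:
            raise ValueError(f"empty domain range {chain}:{lo}-{hi}")
        for c2, l2, h2 in seen:
            if chain == c2 and not (hi < l2 or lo > h2):
                raise ValueError(
                    f"overlapping domain ranges {chain}:{lo}-{hi} and "
                    f"{c2}:{l2}-{h2}")
        seen.append((chain, lo, hi))
    results = {"whole": map_structure(rec, params, probes)}
    for chain, lo, hi in domains:
        sub = rec.subset([i for i, a in enumerate(rec.structure.atoms)
                          if a.chain == chain and lo <= a.res_seq <= hi])
        if len(sub) == 0:
            raise ValueError(f"domain {chain}:{lo}-{hi} selects no atoms")
        results[f"{chain}:{lo}-{hi}"] = map_structure(sub, params, probes)
    merged = []
    for label, res in results.items():
        for s in res.sites:
            merged.append((label, s.rank, s.population, s.strength_class,
                           tuple(np.round(s.center, 3))))
    return results, merged
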