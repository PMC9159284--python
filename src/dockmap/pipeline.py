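"""End-to-end docking and mapping workflows with manifest output.

Each pipeline composes the stage modules, logs per-stage counts and
timings, and (optionally) writes models/reports plus a JSON run
manifest to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import ClusterParams, PoseCluster, greedy_cluster
from .dock import DockParams, PoseList, dock_rigid, refine_pose
from .ftmap import MapParams, MapResult, map_structure
from .gridcore import EnergyWeights
from .restraints import RestraintSet, serialize_restraints
from .structio import ParamStructure, Structure, write_pdb

log = logging.getLogger(__name__)


def _params_dict(obj):
    if is_dataclass(obj):
        out = {}
        for k, v in asdict(obj).items():
            out[k] = _params_dict(v)
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _params_dict(v) for k, v in obj.items()}
    return obj


@dataclass
class RunManifest:
    tool_version: str
    input_checksums: dict
    parameters: dict
    seed: int
    outputs: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def write(self, path: Path):
        path.write_text(json.dumps(
            {"tool_version": self.tool_version,
             "input_checksums": self.input_checksums,
             "parameters": self.parameters,
             "seed": self.seed,
             "outputs": self.outputs,
             "timings": self.timings}, indent=1))


def _checksum_structure(ps: ParamStructure) -> str:
    return hashlib.sha256(write_pdb(ps.structure).encode()).hexdigest()[:16]


@dataclass
class DockingResult:
    poses: PoseList
    clusters: list
    models: list             # refined representative Pose per cluster, ranked
    manifest: RunManifest


def _merge_complex(rec: ParamStructure, lig: ParamStructure,
                   lig_coords: np.ndarray) -> Structure:
    moved = lig.structure.with_coords(lig_coords)
    return Structure(rec.structure.atoms + moved.atoms, id="complex")


def run_docking_pipeline(rec: ParamStructure, lig: ParamStructure,
                         params: DockParams | None = None,
                         cluster_params: ClusterParams | None = None,
                         restraints: RestraintSet | None = None,
                         refine_candidates: int = 10,
                         outdir=None) -> DockingResult:
    """dock → (restraint filter) → retain → cluster → refine → ≤10 models.

    Per cluster, the `refine_candidates` lowest-grid-energy members are
    energy-minimized and the refined pose with the lowest continuous
    energy becomes the cluster's output model; clusters stay ranked by
    population.
    """
    params = params or DockParams()
    cluster_params = cluster_params or ClusterParams()
    timings = {}

    t0 = time.perf_counter()
    try:
        poses = dock_rigid(rec, lig, params, restraints)
    except Exception as e:
        raise RuntimeError(f"stage dock_rigid failed: {e}") from e
    timings["dock"] = time.perf_counter() - t0
    log.info("dock: %d candidates -> %d retained", poses.n_candidates,
             len(poses))

    t0 = time.perf_counter()
    try:
        clusters = greedy_cluster(poses.poses, lig, cluster_params)
    except Exception as e:
        raise RuntimeError(f"stage greedy_cluster failed: {e}") from e
    timings["cluster"] = time.perf_counter() - t0
    log.info("cluster: %d clusters", len(clusters))

    t0 = time.perf_counter()
    models = []
    for c in clusters[:cluster_params.max_clusters]:
        members = sorted(c.members, key=lambda i: poses[i].energy)
        best = None
        for i in members[:max(refine_candidates, 1)]:
            try:
                refined = refine_pose(rec, lig, poses[i])
            except Exception as e:
                raise RuntimeError(f"stage refine_pose failed: {e}") from e
            if best is None or refined.energy_cont < best.energy_cont:
                best = refined
        best.rank = c.rank
        models.append(best)
    timings["refine"] = time.perf_counter() - t0

    manifest = RunManifest(
        tool_version=__version__,
        input_checksums={"receptor": _checksum_structure(rec),
                         "ligand": _checksum_structure(lig),
                         "restraints": (hashlib.sha256(
                             serialize_restraints(restraints).encode()
                         ).hexdigest()[:16] if restraints else None)},
        parameters={"dock": _params_dict(params),
                    "cluster": _params_dict(cluster_params)},
        seed=params.seed, timings=timings)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = ["rank\tpopulation\tcenter_energy\trepresentative"]
        for c in clusters:
            rows.append(f"{c.rank}\t{c.population}\t{c.center_energy:.6f}"
                        f"\t{c.representative}")
        (outdir / "clusters.tsv").write_text("\n".join(rows) + "\n")
        manifest.outputs.append("clusters.tsv")
        prows = ["rank\tenergy\tcore\tsurface\tcharge\tpair\tqx\tqy\tqz\tqw"
                 "\ttx\tty\ttz"]
        for p in poses:
            prows.append(
                f"{p.rank}\t{p.energy:.6f}\t{p.components.get('core', 0):.6f}"
                f"\t{p.components.get('surface', 0):.6f}"
                f"\t{p.components.get('charge', 0):.6f}"
                f"\t{p.components.get('pair', 0):.6f}"
                f"\t{p.rotation.q[0]:.9f}\t{p.rotation.q[1]:.9f}"
                f"\t{p.rotation.q[2]:.9f}\t{p.rotation.q[3]:.9f}"
                f"\t{p.shift[0]:.4f}\t{p.shift[1]:.4f}\t{p.shift[2]:.4f}")
        (outdir / "poses.tsv").write_text("\n".join(prows) + "\n")
        manifest.outputs.append("poses.tsv")
        for m in models:
            name = f"model.{m.rank:02d}.pdb"
            combo = _merge_complex(rec, lig, m.apply(lig.coords))
            (outdir / name).write_text(write_pdb(combo))
            manifest.outputs.append(name)
        manifest.write(outdir / "manifest.json")

    return DockingResult(poses=poses, clusters=clusters, models=models,
                         manifest=manifest)


@dataclass
class MappingResult:
    result: MapResult
    manifest: RunManifest


def _hotspot_rows(res: MapResult) -> str:
    rows = ["rank\tpopulation\tclass\tcx\tcy\tcz\tmean_energy"]
    for s in res.sites:
        rows.append(f"{s.rank}\t{s.population}\t{s.strength_class}"
                    f"\t{s.center[0]:.3f}\t{s.center[1]:.3f}"
                    f"\t{s.center[2]:.3f}\t{s.mean_energy:.6f}")
    return "\n".join(rows) + "\n"


def _site_rows(res: MapResult) -> str:
    rows = ["rank\ttotal_population\tcx\tcy\tcz\tn_residues\tresidues"]
    for b in res.binding_sites:
        rid = ",".join(f"{c}{n}" for c, n, _ in b.residues)
        rows.append(f"{b.rank}\t{b.total_population}\t{b.center[0]:.3f}"
                    f"\t{b.center[1]:.3f}\t{b.center[2]:.3f}"
                    f"\t{len(b.residues)}\t{rid}")
    return "\n".join(rows) + "\n"


def run_mapping_pipeline(prot: ParamStructure,
                         params: MapParams | None = None,
                         interface_filter=None,
                         outdir=None) -> MappingResult:
    """16-probe mapping → consensus sites → druggability → binding sites."""
    params = params or MapParams()
    t0 = time.perf_counter()
    try:
        res = map_structure(prot, params, interface_filter=interface_filter)
    except Exception as e:
        raise RuntimeError(f"stage map_structure failed: {e}") from e
    timings = {"map": time.perf_counter() - t0}
    for probe_name, clusters in res.probe_clusters.items():
        log.info("probe %-24s %d clusters", probe_name, len(clusters))

    manifest = RunManifest(
        tool_version=__version__,
        input_checksums={"protein": _checksum_structure(prot)},
        parameters={"map": _params_dict(params)},
        seed=params.seed, timings=timings)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "hotspots.tsv").write_text(_hotspot_rows(res))
        (outdir / "sites.tsv").write_text(_site_rows(res))
        manifest.outputs += ["hotspots.tsv", "sites.tsv"]
        probe_rows = ["probe\tcluster_rank\tpopulation\tavg_energy"
                      "\tcx\tcy\tcz"]
        for name, clusters in res.probe_clusters.items():
            for c in clusters:
                probe_rows.append(
                    f"{name}\t{c.rank}\t{c.population}\t{c.avg_energy:.6f}"
                    f"\t{c.center[0]:.3f}\t{c.center[1]:.3f}\t{c.center[2]:.3f}")
        (outdir / "probe_clusters.tsv").write_text("\n".join(probe_rows) + "\n")
        manifest.outputs.append("probe_clusters.tsv")
        verdict = "druggable" if res.report.druggable else "not_druggable"
        (outdir / "druggability.tsv").write_text(
            "strongest_population\tverdict\n"
            f"{res.report.strongest_population}\t{verdict}\n")
        manifest.outputs.append("druggability.tsv")
        manifest.write(outdir / "manifest.json")

    return MappingResult(result=res, manifest=manifest)
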