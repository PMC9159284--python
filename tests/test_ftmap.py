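import numpy as np
import pytest

from dockmap.ftmap import (ConsensusSite, MapParams, ProbeCluster, ProbePose,
                           cluster_probe_poses, consensus_sites,
                           druggability_report, map_by_domains, map_probe,
                           predict_sites, probe_library)
from dockmap.gridcore import Rotation

PAPER_NAMES = [
    "ethanol", "2-propanol", "isobutanol", "acetone", "acetaldehyde",
    "dimethyl ether", "cyclohexane", "ethane", "acetonitrile", "urea",
    "methylamine", "phenol", "benzaldehyde", "benzene", "acetamide",
    "N,N-dimethylformamide",
]


class TestProbeLibrary:
    def test_sixteen_probes_with_printed_names(self, probes):
        assert len(probes) == 16
        assert [p.name for p in probes] == PAPER_NAMES

    def test_templates_neutral(self, probes):
        for p in probes:
            assert abs(float(np.sum(p.template.charge))) <= 1e-6 * len(p.template)

    def test_templates_connected_with_sane_bonds(self, probes):
        for p in probes:
            c = p.template.coords
            n = len(c)
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            bonded = (d > 0) & (d <= 1.8)
            if n > 1:
                # no two heavy atoms closer than a short bond
                off = d[np.triu_indices(n, 1)]
                assert np.min(off) >= 0.9, p.name
                # connectivity by BFS over the bond graph
                seen = {0}
                stack = [0]
                while stack:
                    k = stack.pop()
                    for j in np.where(bonded[k])[0]:
                        if j not in seen:
                            seen.add(j)
                            stack.append(j)
                assert len(seen) == n, p.name

    def test_checksums_stable(self, probes):
        again = probe_library()
        assert [p.checksum for p in probes] == [p.checksum for p in again]

    def test_templates_centered(self, probes):
        for p in probes:
            np.testing.assert_allclose(p.template.coords.mean(axis=0),
                                       0.0, atol=1e-3)


def _probe_pose(center, energy, probe="ethanol"):
    center = np.asarray(center, float)
    coords = center[None, :] + np.array([[0.0, 0, 0], [1.4, 0, 0],
                                         [-1.4, 0, 0]])
    return ProbePose(probe=probe, rotation=Rotation.identity(),
                     coords=coords, center=center,
                     energy_grid=energy, energy_min=energy)


class TestClusterProbePoses:
    def test_single_pose(self):
        cl = cluster_probe_poses([_probe_pose([0, 0, 0], -4.0)])
        assert len(cl) == 1
        assert cl[0].population == 1
        assert cl[0].avg_energy == pytest.approx(-4.0)

    def test_zero_radius_limit(self):
        poses = [_probe_pose([i * 2.0, 0, 0], -1.0) for i in range(5)]
        cl = cluster_probe_poses(
            poses, MapParams(probe_cluster_radius=1e-9,
                             clusters_kept_per_probe=100))
        assert len(cl) == 5

    def test_empty_input(self):
        assert cluster_probe_poses([]) == []

    def test_two_lobes_ranked_by_average_energy(self):
        lobe_a = [_probe_pose([0, 0, 0], e) for e in (-1.0, -2.0, -3.0)]
        lobe_b = [_probe_pose([20, 0, 0], e) for e in (-8.0, -6.0)]
        cl = cluster_probe_poses(lobe_a + lobe_b)
        assert len(cl) == 2
        assert cl[0].avg_energy == pytest.approx(-7.0)   # lobe B mean
        assert cl[1].avg_energy == pytest.approx(-2.0)   # lobe A mean
        assert cl[0].rank == 1 and cl[1].rank == 2

    def test_keeps_at_most_configured_clusters(self):
        poses = [_probe_pose([i * 10.0, 0, 0], -float(i)) for i in range(9)]
        cl = cluster_probe_poses(poses, MapParams(clusters_kept_per_probe=6))
        assert len(cl) == 6


def _cluster(center, energy=-1.0, probe="ethanol", n_members=1):
    members = [_probe_pose(center, energy, probe) for _ in range(n_members)]
    return ProbeCluster(probe=probe, members=members,
                        center=np.asarray(center, float), avg_energy=energy)


class TestConsensusSites:
    def test_two_loci(self):
        a = [_cluster([0, 0, 0], -1.0 - i * 0.1) for i in range(5)]
        b = [_cluster([20, 0, 0], -2.0 - i * 0.1) for i in range(3)]
        sites = consensus_sites(a + b)
        assert [s.population for s in sites] == [5, 3]
        assert [s.rank for s in sites] == [1, 2]

    def test_empty(self):
        assert consensus_sites([]) == []

    def test_population_equals_member_count_and_conserved(self):
        rng = np.random.default_rng(0)
        clusters = [_cluster(rng.uniform(0, 40, 3)) for _ in range(30)]
        sites = consensus_sites(clusters)
        assert all(s.population == len(s.members) for s in sites)
        assert sum(s.population for s in sites) == 30

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            clusters = [_cluster(rng.uniform(0, 30, 3))
                        for _ in range(int(rng.integers(5, 25)))]
            counts = [len(consensus_sites(
                clusters, MapParams(consensus_radius=r)))
                for r in (1.0, 2.0, 4.0, 8.0, 16.0)]
            assert counts == sorted(counts, reverse=True)

    def test_strength_classes(self):
        for pop, cls in ((16, "strong"), (15, "intermediate"),
                         (11, "intermediate"), (10, "weak"), (3, "weak")):
            s = ConsensusSite.from_population(pop)
            assert s.strength_class == cls, pop


class TestDruggability:
    def test_il2_style_populations(self):
        sites = [ConsensusSite.from_population(p) for p in (18, 12, 5, 3)]
        rep = druggability_report(sites)
        assert rep.strongest_population == 18
        assert rep.druggable

    def test_zipa_style_populations(self):
        sites = [ConsensusSite.from_population(p) for p in (8, 3, 2)]
        rep = druggability_report(sites)
        assert rep.strongest_population == 8
        assert not rep.druggable

    def test_boundary_16_inclusive(self):
        rep = druggability_report([ConsensusSite.from_population(16)])
        assert rep.druggable

    def test_interface_filter_restricts_sites(self, pocket):
        near = ConsensusSite.from_population(
            18, center=pocket.cavity_center)
        far = ConsensusSite.from_population(
            20, center=pocket.cavity_center + np.array([200.0, 0, 0]))
        rep = druggability_report(
            [far, near],
            interface_filter={("A", r) for r in pocket.lining_residues},
            rec=pocket.receptor, contact_cutoff=8.0)
        assert rep.strongest_population == 18


class TestPredictSites:
    def test_nearby_hotspots_merge(self, pocket):
        a = consensus_sites([_cluster([0, 0, 0])])[0]
        b = consensus_sites([_cluster([3, 0, 0])])[0]
        sites = predict_sites([a, b], pocket.receptor)
        assert len(sites) == 1
        assert sites[0].total_population == 2

    def test_distant_hotspots_stay_separate(self, pocket):
        a = consensus_sites([_cluster([0, 0, 0])])[0]
        b = consensus_sites([_cluster([30, 0, 0])])[0]
        sites = predict_sites([a, b], pocket.receptor)
        assert len(sites) == 2

    def test_pocket_site_residues_line_cavity(self, pocket, pocket_map):
        bs = pocket_map.binding_sites[0]
        assert bs.residues
        lining = set(pocket.lining_residues)
        res_in = [r for _, r, _ in bs.residues]
        frac = np.mean([r in lining for r in res_in])
        assert frac >= 0.8


class TestMapProbe:
    def test_pocket_poses_concentrate_in_cavity(self, pocket, probes,
                                                small_map_params):
        poses = map_probe(pocket.receptor, probes[0], small_map_params)
        d = [np.linalg.norm(p.center - pocket.cavity_center)
             for p in poses[:50]]
        assert np.mean(np.array(d) < pocket.cavity_radius) >= 0.8

    def test_output_bounded_by_k(self, pocket, probes):
        params = MapParams(seed=1, probe_rotations=6,
                           poses_retained_per_probe=40, minimize_iter=5)
        poses = map_probe(pocket.receptor, probes[7], params)
        assert 0 < len(poses) <= 40

    def test_minimizer_never_worsens(self, pocket, probes):
        params = MapParams(seed=1, probe_rotations=6,
                           poses_retained_per_probe=40, minimize_iter=10)
        poses = map_probe(pocket.receptor, probes[0], params)
        # energy_min is post-minimization continuous energy; spot-check a
        # few poses against their pre-minimization continuous energy
        from dockmap.energy import interaction_energy
        t = probes[0].template
        for p in poses[:5]:
            assert p.energy_min <= interaction_energy(
                pocket.receptor, p.coords, t.radius, t.charge,
                mob_types=t.atype) + 1e-9

    def test_deterministic(self, pocket, probes):
        params = MapParams(seed=4, probe_rotations=6,
                           poses_retained_per_probe=30, minimize_iter=8)
        a = map_probe(pocket.receptor, probes[3], params)
        b = map_probe(pocket.receptor, probes[3], params)
        assert [p.energy_min for p in a] == [p.energy_min for p in b]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.coords, pb.coords)


class TestMapByDomains:
    def test_overlapping_ranges_rejected(self, pocket):
        with pytest.raises(ValueError, match="overlap"):
            map_by_domains(pocket.receptor,
                           [("A", 1, 50), ("A", 40, 90)])

    def test_empty_range_rejected(self, pocket):
        with pytest.raises(ValueError, match="empty"):
            map_by_domains(pocket.receptor, [("A", 50, 10)])

    def test_full_range_matches_whole(self, pocket, probes):
        params = MapParams(seed=2, probe_rotations=6,
                           poses_retained_per_probe=60, minimize_iter=5)
        n = max(a.res_seq for a in pocket.receptor.structure.atoms)
        results, merged = map_by_domains(pocket.receptor, [("A", 1, n)],
                                        params, probes=probes[:2])
        whole = results["whole"].sites
        dom = results[f"A:1-{n}"].sites
        assert [s.population for s in whole] == [s.population for s in dom]
        for sw, sd in zip(whole, dom):
            np.testing.assert_allclose(sw.center, sd.center, atol=1e-9)
        labels = {row[0] for row in merged}
        assert labels == {"whole", f"A:1-{n}"}
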