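import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockmap.gridcore import (ATYPES, PAIR_CHANNELS, EnergyWeights, GridSet,
                              Rotation, brute_force_correlate,
                              build_ligand_grids, build_receptor_grids,
                              fft_correlate, load_contact_matrix, rotate)
from dockmap.structio import Atom, ParamStructure, Structure


def _one_atom_ps(xyz=(5.0, 5.0, 5.0), radius=1.9):
    a = Atom(serial=1, name="CB", element="C", res_name="ALA", chain="A",
             res_seq=1, icode="", xyz=np.array(xyz, dtype=float))
    return ParamStructure(Structure([a]), np.array([radius]),
                          np.array([0.0]), ["C_aliph"])


def _random_gridset(rng, dims, n_pair=2):
    channels = {"core": np.abs(rng.normal(size=dims)),
                "surface": rng.normal(size=dims),
                "charge": rng.normal(size=dims)}
    for i, name in enumerate(PAIR_CHANNELS):
        channels[name] = (rng.normal(size=dims) if i < n_pair
                          else np.zeros(dims))
    return GridSet(origin=np.zeros(3), spacing=1.0, dims=dims,
                   channels=channels)


class TestRotation:
    def test_identity(self):
        c = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(
            Rotation.identity().apply(c, np.zeros(3)), c, atol=1e-12)

    def test_90_about_z(self):
        r = Rotation.from_axis_angle([0, 0, 1], np.pi / 2)
        got = r.apply(np.array([[1.0, 0.0, 0.0]]), np.zeros(3))
        np.testing.assert_allclose(got, [[0.0, 1.0, 0.0]], atol=1e-9)

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError):
            Rotation((0.0, 0.0, 0.0, 1.1))

    def test_sign_canonicalized(self):
        q = np.array([0.1, 0.2, 0.3, -0.5])
        q /= np.linalg.norm(q)
        assert Rotation.from_quaternion(q) == Rotation.from_quaternion(-q)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1, 1), min_size=8, max_size=8))
    def test_composition_group_property(self, vals):
        q1 = np.array(vals[:4])
        q2 = np.array(vals[4:])
        if np.linalg.norm(q1) < 1e-3 or np.linalg.norm(q2) < 1e-3:
            return
        r1 = Rotation.from_quaternion(q1)
        r2 = Rotation.from_quaternion(q2)
        coords = np.array([[1.0, -2.0, 0.5], [0.3, 0.1, -1.2]])
        c = np.array([0.2, -0.1, 0.4])
        seq = r2.apply(r1.apply(coords, c), c)
        combo = r2.compose(r1).apply(coords, c)
        np.testing.assert_allclose(seq, combo, atol=1e-9)

    def test_rotate_preserves_parameters(self):
        ps = _one_atom_ps()
        out = rotate(ps, Rotation.from_axis_angle([1, 0, 0], 1.0),
                     np.zeros(3))
        np.testing.assert_array_equal(out.radius, ps.radius)
        assert out.atype == ps.atype


class TestBuildGrids:
    def test_single_atom_core_voxels(self):
        # r=1.9, delta=0.5, h=1.0 -> core at voxel centers within 1.4 A
        ps = _one_atom_ps()
        gs = build_receptor_grids(ps, h=1.0, margin=3.0)
        nz = set(zip(*np.nonzero(gs.channels["core"])))
        expected = set()
        for idx in np.ndindex(gs.dims):
            center = gs.origin + (np.array(idx) + 0.5) * gs.spacing
            if np.linalg.norm(center - ps.coords[0]) <= 1.4:
                expected.add(idx)
        assert nz == expected

    def test_empty_structure_raises(self):
        empty = ParamStructure(Structure([]), np.empty(0), np.empty(0), [])
        with pytest.raises(ValueError):
            build_receptor_grids(empty)

    def test_bad_spacing_raises(self):
        with pytest.raises(ValueError):
            build_receptor_grids(_one_atom_ps(), h=0.0)

    def test_translation_by_h_shifts_every_channel(self):
        ps = _one_atom_ps(xyz=(5.2, 5.1, 4.9))
        origin = np.zeros(3)
        dims = (14, 14, 14)
        a = build_receptor_grids(ps, h=1.0, origin=origin, dims=dims)
        moved = ps.with_coords(ps.coords + np.array([1.0, 0.0, 0.0]))
        b = build_receptor_grids(moved, h=1.0, origin=origin, dims=dims)
        for name in a.channels:
            np.testing.assert_allclose(b.channels[name][1:, :, :],
                                       a.channels[name][:-1, :, :],
                                       atol=1e-9, err_msg=name)


class TestCorrelation:
    def test_zero_ligand_zero_field(self):
        rng = np.random.default_rng(0)
        rec = _random_gridset(rng, (8, 8, 8))
        lig = GridSet(origin=np.zeros(3), spacing=1.0, dims=(4, 4, 4),
                      channels={n: np.zeros((4, 4, 4))
                                for n in rec.channels})
        sf = fft_correlate(rec, lig, EnergyWeights())
        np.testing.assert_allclose(sf.values, 0.0, atol=1e-9)

    def test_delta_surface_correlation(self):
        dims_r, dims_l = (6, 6, 6), (3, 3, 3)
        zero_r = {n: np.zeros(dims_r) for n in
                  ("core", "surface", "charge") + PAIR_CHANNELS}
        zero_l = {n: np.zeros(dims_l) for n in zero_r}
        zero_r["surface"] = np.zeros(dims_r)
        zero_r["surface"][4, 2, 3] = 1.0
        zero_l["surface"] = np.zeros(dims_l)
        zero_l["surface"][1, 0, 2] = 1.0
        rec = GridSet(np.zeros(3), 1.0, dims_r, zero_r)
        lig = GridSet(np.zeros(3), 1.0, dims_l, zero_l)
        w = EnergyWeights(w_attr=1.3)
        sf = fft_correlate(rec, lig, w)
        expect = np.zeros(sf.values.shape)
        expect[3, 2, 1] = -w.w_attr
        np.testing.assert_allclose(sf.values, expect, atol=1e-9)

    def test_spacing_mismatch_raises(self):
        rng = np.random.default_rng(1)
        rec = _random_gridset(rng, (8, 8, 8))
        lig = _random_gridset(rng, (4, 4, 4))
        lig.spacing = 0.5
        with pytest.raises(ValueError, match="spacing"):
            fft_correlate(rec, lig, EnergyWeights())

    def test_ligand_larger_than_receptor_raises(self):
        rng = np.random.default_rng(2)
        rec = _random_gridset(rng, (4, 4, 4))
        lig = _random_gridset(rng, (8, 8, 8))
        with pytest.raises(ValueError, match="larger"):
            fft_correlate(rec, lig, EnergyWeights())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fft_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rec = _random_gridset(rng, (12, 10, 11), n_pair=3)
        lig = _random_gridset(rng, (5, 6, 4), n_pair=3)
        w = EnergyWeights(w_attr=0.9, w_rep=1.1, w_elec=0.5, w_pair=0.8)
        a = fft_correlate(rec, lig, w)
        b = brute_force_correlate(rec, lig, w)
        scale = np.max(np.abs(b.values)) or 1.0
        np.testing.assert_allclose(a.values, b.values, atol=1e-8 * scale)

    def test_weight_linearity(self):
        rng = np.random.default_rng(3)
        rec = _random_gridset(rng, (9, 9, 9))
        lig = _random_gridset(rng, (4, 4, 4))
        base = fft_correlate(rec, lig, EnergyWeights(w_elec=0.6))
        double = fft_correlate(rec, lig, EnergyWeights(w_elec=1.2))
        diff = double.values - base.values
        np.testing.assert_allclose(diff, 0.6 * base.components["charge"],
                                   atol=1e-9 * max(1.0, np.max(np.abs(diff))))

    def test_score_decomposition_identity(self):
        rng = np.random.default_rng(4)
        rec = _random_gridset(rng, (10, 10, 10))
        lig = _random_gridset(rng, (4, 4, 4))
        sf = fft_correlate(rec, lig, EnergyWeights())
        np.testing.assert_allclose(
            sf.values, sf.recombine(),
            atol=1e-9 * max(1.0, float(np.max(np.abs(sf.values)))))

    def test_translational_covariance(self):
        ps = _one_atom_ps(xyz=(7.3, 7.1, 6.8))
        lig = _one_atom_ps(xyz=(1.1, 1.2, 1.0))
        origin, dims = np.zeros(3), (16, 16, 16)
        rec_a = build_receptor_grids(ps, 1.0, origin=origin, dims=dims)
        moved = ps.with_coords(ps.coords + np.array([1.0, 0.0, 0.0]))
        rec_b = build_receptor_grids(moved, 1.0, origin=origin, dims=dims)
        lg = build_ligand_grids(lig, 1.0)
        w = EnergyWeights()
        sa = fft_correlate(rec_a, lg, w)
        sb = fft_correlate(rec_b, lg, w)
        ta = np.unravel_index(np.argmin(sa.values), sa.values.shape)
        tb = np.unravel_index(np.argmin(sb.values), sb.values.shape)
        assert tb[0] - ta[0] == 1 and tb[1:] == ta[1:]
        assert sa.values[ta] == pytest.approx(sb.values[tb], abs=1e-9)


def test_contact_matrix_symmetric_and_complementary():
    m = load_contact_matrix()
    assert m.shape == (len(ATYPES), len(ATYPES))
    np.testing.assert_array_equal(m, m.T)
    i, j = ATYPES.index("N_don"), ATYPES.index("O_acc")
    assert m[i, j] < 0  # donor-acceptor attraction
    assert m[i, i] > 0 and m[j, j] > 0  # like-polar repulsion
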