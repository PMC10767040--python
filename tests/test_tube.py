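"""Tube model construction: radialization, symmetry expansion, contacts, I/O."""

import math

import numpy as np
import pytest

from helimorph.lattice import VP39_LATTICE, helix_from_wrapping
from helimorph.synthetic import make_pseudo_unit
from helimorph.tube import (
    AsymmetricUnit,
    AtomRecord,
    SubunitPlacement,
    TubeModel,
    build_tube,
    lattice_points_in_window,
    neighbor_pairs,
    radialize,
    read_unit,
    write_model,
    _rot_z,
    _rot_x,
)

L = VP39_LATTICE


def _toy_unit(offsets):
    return AsymmetricUnit([AtomRecord("C", np.asarray(p, float)) for p in offsets])


class TestRadialize:
    def test_moves_com_to_radius_on_x(self):
        unit = _toy_unit([[0, 0, 0], [2, 0, 0], [0, 2, 2]])
        out = radialize(unit, 223.3)
        assert out.center_of_mass == pytest.approx([223.3, 0, 0], abs=1e-9)
        assert out.radial_reference == pytest.approx([1, 0, 0])

    def test_idempotent(self):
        unit = _toy_unit([[1, 2, 3], [4, 5, 6], [-1, 0, 2]])
        once = radialize(unit, 100.0)
        twice = radialize(once, 100.0)
        assert np.allclose(once.positions, twice.positions, atol=1e-12)

    def test_nonpositive_radius_rejected(self):
        unit = _toy_unit([[0, 0, 0]])
        with pytest.raises(ValueError):
            radialize(unit, 0.0)

    def test_reorients_radial_reference(self):
        unit = _toy_unit([[0, 0, 0], [0, 3, 0], [1, 1, 1]])
        unit.radial_reference = np.array([0.0, 1.0, 0.0])
        out = radialize(unit, 50.0)
        assert out.radial_reference == pytest.approx([1, 0, 0])
        # rigid: pairwise distances preserved
        d_in = np.linalg.norm(unit.positions[0] - unit.positions[1])
        d_out = np.linalg.norm(out.positions[0] - out.positions[1])
        assert d_out == pytest.approx(d_in, abs=1e-12)


class TestLatticePointsInWindow:
    def test_c14_ring_has_14_sites_per_rise(self):
        sites = lattice_points_in_window(L, (14, 14), -1e-6, 43.86 - 1e-6)
        assert len(sites) == 14
        assert {round(s.z, 6) for s in sites} == {0.0}
        azimuths = sorted(s.azimuth_deg for s in sites)
        steps = np.diff(azimuths)
        assert np.allclose(steps, 360.0 / 14, atol=1e-6)

    def test_seamlessness_no_duplicate_positions(self):
        for idx in [(14, 14), (6, 13), (13, 14)]:
            sites = lattice_points_in_window(L, idx, -60.0, 60.0)
            keys = {(round(s.azimuth_deg % 360.0, 4), round(s.z, 4)) for s in sites}
            assert len(keys) == len(sites)

    def test_congruent_points_collapse(self):
        """(u1, u2) and (u1+n1, u2+n2) map to the same tube position."""
        idx = (6, 13)
        sym = helix_from_wrapping(L, idx)
        sites = lattice_points_in_window(L, idx, -30.0, 30.0)
        by_coords = {(s.u1, s.u2) for s in sites}
        for s in sites:
            assert (s.u1 + 6, s.u2 + 13) not in by_coords
        # the congruent point has identical azimuth (mod 360) and z
        s0 = sites[0]
        arc = (s0.u1 + 6) * sym.x1 + (s0.u2 + 13) * sym.x2
        z = (s0.u1 + 6) * sym.y1 + (s0.u2 + 13) * sym.y2
        assert (360.0 * arc / sym.circumference) % 360.0 == pytest.approx(
            s0.azimuth_deg % 360.0, abs=1e-6)
        assert z == pytest.approx(s0.z, abs=1e-9)

    def test_site_density_matches_cell_area(self):
        for idx in [(14, 14), (6, 13)]:
            sym = helix_from_wrapping(L, idx)
            sites = lattice_points_in_window(L, idx, -400.0, 400.0)
            expected = 800.0 * sym.circumference / abs(L.det)
            assert len(sites) == pytest.approx(expected, rel=0.05)

    def test_spin_relative_to_reference(self):
        sites = lattice_points_in_window(L, (6, 13), 0.0, 50.0)
        assert all(s.spin_deg == pytest.approx(15.49, abs=0.01) for s in sites)


class TestBuildTube:
    def test_com_radii_on_cylinder(self, pseudo_unit):
        tube = build_tube(pseudo_unit, L, (14, 14), -100.0, 100.0)
        radii = np.linalg.norm(tube.com_positions()[:, :2], axis=1)
        assert np.allclose(radii, 1403.08 / (2 * math.pi), atol=1e-8)

    def test_same_frame_spin_is_zero(self, pseudo_unit):
        tube = build_tube(pseudo_unit, L, (14, 14), 0.0, 44.0, reference_idx=(14, 14))
        runit = radialize(pseudo_unit, tube.symmetry.radius)
        # the placement at azimuth 0, z 0 must be the radialized unit itself
        p0 = min(tube.placements,
                 key=lambda p: np.linalg.norm(p.rotation - np.eye(3)))
        assert np.allclose(p0.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(p0.translation, 0.0, atol=1e-9)

    def test_rigid_body_property(self, pseudo_unit):
        """Intra-subunit pairwise distances identical across placements."""
        tube = build_tube(pseudo_unit, L, (6, 13), -80.0, 80.0)
        pos = tube.atom_positions().reshape(len(tube.placements), -1, 3)
        d_ref = np.linalg.norm(pos[0][:, None] - pos[0][None], axis=-1)
        for k in range(1, len(tube.placements)):
            d = np.linalg.norm(pos[k][:, None] - pos[k][None], axis=-1)
            assert np.allclose(d, d_ref, atol=1e-6)

    def test_cn_equivalence_oracle(self, pseudo_unit):
        """For n1 = n2 = k the tube equals ring-rotation x one-start screw.

        Independent construction: generate placements directly from the
        C14 rotation and the (rise, twist) operator, then match atom sets.
        """
        k = 14
        tube = build_tube(pseudo_unit, L, (k, k), -1e-6, 3 * 43.86 - 1e-6)
        sym = tube.symmetry
        runit = radialize(pseudo_unit, sym.radius)
        expected = []
        for m in range(3):  # three rings
            for j in range(k):
                ang = j * 360.0 / k + m * sym.one_start_twist
                R = _rot_z(ang)
                t = np.array([0.0, 0.0, m * sym.one_start_rise])
                expected.append(runit.positions @ R.T + t)
        expected = np.concatenate(expected)
        got = tube.atom_positions()
        assert got.shape == expected.shape
        # order-independent comparison
        from scipy.spatial import cKDTree
        d, _ = cKDTree(expected).query(got)
        assert d.max() < 1e-6

    def test_local_packing_invariance(self, pseudo_unit):
        """Sorted k-nearest COM distances match the C14 tube within 3 %."""
        def knn(idx, k=4):
            tube = build_tube(pseudo_unit, L, idx, -150.0, 150.0)
            com = tube.com_positions()
            d = np.linalg.norm(com[:, None] - com[None], axis=-1)
            d.sort(axis=1)
            central = np.argmin(np.abs(com[:, 2]))  # avoid window edges
            return d[central, 1:k + 1]

        ref = knn((14, 14))
        for idx in [(13, 13), (15, 15), (13, 14), (6, 13)]:
            assert np.allclose(knn(idx), ref, rtol=0.03)

    def test_inter_unit_contacts_guard_spin_convention(self, pseudo_unit):
        """Nearest inter-subunit atomic distances are nearly wrapping-independent.

        This is sensitive to the spin sign convention: mis-spinning the
        subunits changes the atomic contacts between neighbors by > 100 %
        for the strongly tilted (6, 13) wrapping, while the correct spin
        leaves only the small curvature-induced deviation.
        """
        def min_contacts(idx):
            tube = build_tube(pseudo_unit, L, idx, -120.0, 120.0)
            contacts = neighbor_pairs(tube, 60.0)
            com = tube.com_positions()
            central = np.argmin(np.abs(com[:, 2]))
            ds = sorted(c.distance for c in contacts
                        if central in (c.i, c.j))
            return np.array(ds[:3])

        ref = min_contacts((14, 14))
        assert np.allclose(min_contacts((13, 14)), ref, rtol=0.05)
        # smaller radius -> more curvature -> larger, but still bounded, drift
        assert np.allclose(min_contacts((6, 13)), ref, rtol=0.20)

    def test_empty_window_warns(self, pseudo_unit):
        with pytest.warns(UserWarning):
            tube = build_tube(pseudo_unit, L, (14, 14), 1.0, 2.0)
        assert len(tube.placements) == 0

    def test_lattice_recovery_from_surface_coordinates(self, pseudo_unit):
        """Basis vectors recovered from (arc, z) of generated subunits.

        Neighboring sites differing by one lattice step must be separated
        by the independently re-derived projections of a and b.
        """
        idx = (6, 13)
        sites = lattice_points_in_window(L, idx, -100.0, 100.0)
        sym = helix_from_wrapping(L, idx)
        r = sym.circumference / (2 * math.pi)
        by_uv = {(s.u1, s.u2): s for s in sites}
        # independent derivation of the rotated basis with plain numpy
        w = 6 * np.array(L.a) + 13 * np.array(L.b)
        w_hat = w / np.linalg.norm(w)
        ax_hat = np.array([-w_hat[1], w_hat[0]])
        a_rot = np.array([np.array(L.a) @ w_hat, np.array(L.a) @ ax_hat])
        b_rot = np.array([np.array(L.b) @ w_hat, np.array(L.b) @ ax_hat])
        checked = 0
        for (u1, u2), s in by_uv.items():
            for dv, basis in [((1, 0), a_rot), ((0, 1), b_rot)]:
                nb = by_uv.get((u1 + dv[0], u2 + dv[1]))
                if nb is None:
                    continue
                darc = (nb.azimuth_deg - s.azimuth_deg) * math.pi / 180.0 * r
                darc = (darc + sym.circumference / 2) % sym.circumference - sym.circumference / 2
                dz = nb.z - s.z
                assert np.allclose([darc, dz], basis, atol=1e-3)
                checked += 1
        assert checked > 10


class TestNeighborPairs:
    def test_brute_force_oracle(self):
        """Contacts match direct all-pairs computation on a toy tube."""
        rng = np.random.Generator(np.random.PCG64(5))
        unit = _toy_unit(rng.normal(0, 5, (6, 3)))
        sym = helix_from_wrapping(L, (14, 14))
        placements = [
            SubunitPlacement(_rot_z(a), np.array([0.0, 0.0, z]), (i, 0))
            for i, (a, z) in enumerate([(0, 0), (25.7, 0), (0, 43.9)])
        ]
        tube = TubeModel(radialize(unit, sym.radius), placements, sym, L)
        cutoff = 120.0
        got = {(c.i, c.j): c for c in neighbor_pairs(tube, cutoff)}
        pos = tube.atom_positions().reshape(3, -1, 3)
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(pos[i][:, None] - pos[j][None], axis=-1)
                if d.min() <= cutoff:
                    assert (i, j) in got
                    assert got[(i, j)].distance == pytest.approx(d.min(), rel=1e-12)
                    ai, aj = np.unravel_index(np.argmin(d), d.shape)
                    assert (got[(i, j)].atom_i, got[(i, j)].atom_j) == (ai, aj)
                else:
                    assert (i, j) not in got

    def test_cutoff_below_closest_approach_empty(self, pseudo_unit):
        tube = build_tube(pseudo_unit, L, (14, 14), -50.0, 50.0)
        assert neighbor_pairs(tube, 1e-3) == []


class TestModelIO:
    def test_mmcif_round_trip(self, tmp_path, pseudo_unit):
        tube = build_tube(pseudo_unit, L, (14, 14), -1e-6, 40.0)
        path = tmp_path / "ring.cif"
        write_model(tube, path)
        back = read_unit(path)
        assert len(back.atoms) == len(tube.placements) * len(pseudo_unit.atoms)
        assert len({a.chain for a in back.atoms}) == len(tube.placements)
        got = np.sort(back.positions, axis=0)
        want = np.sort(tube.atom_positions(), axis=0)
        assert np.allclose(got, want, atol=1e-3)

    def test_pdb_round_trip_precision(self, tmp_path):
        unit = _toy_unit([[1.2345, -2.3456, 3.4567], [0, 0, 0], [9.1, 8.2, 7.3]])
        sym = helix_from_wrapping(L, (14, 14))
        tube = TubeModel(unit, [SubunitPlacement(np.eye(3), np.zeros(3), (0, 0))], sym, L)
        path = tmp_path / "unit.pdb"
        write_model(tube, path)
        back = read_unit(path)
        assert len(back.atoms) == 3
        assert np.allclose(np.sort(back.positions, axis=0),
                           np.sort(unit.positions, axis=0), atol=1e-3)

    def test_pdb_chain_overflow_error(self, pseudo_unit, tmp_path):
        tube = build_tube(pseudo_unit, L, (14, 14), -250.0, 250.0)
        assert len(tube.placements) > 62
        with pytest.raises(ValueError, match="chain"):
            write_model(tube, tmp_path / "big.pdb")
        # mmCIF accepts arbitrarily many chains
        write_model(tube, tmp_path / "big.cif")

    def test_missing_element_inferred(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 20.00\n"
            "ATOM      2  N   ALA A   1       2.000   3.000   4.000  1.00 20.00\n"
            "END\n"
        )
        p = tmp_path / "noel.pdb"
        p.write_text(pdb)
        unit = read_unit(p)
        assert [a.element for a in unit.atoms] == ["C", "N"]

    def test_unparsable_file_raises(self, tmp_path):
        p = tmp_path / "junk.cif"
        p.write_text("this is not a model\n")
        with pytest.raises(ValueError):
            read_unit(p)
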