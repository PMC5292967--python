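"""Helix axes, inter-helix angles, piston/twist, and contact chemistry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from uvnma.geometry import (
    ContactThresholds, IllDefinedAxisError, MembraneFrame, detect_contacts,
    fit_helix_axis, helix_axial_rotation, interhelix_angle, piston_displacement,
)
from uvnma.structures import Atom, AtomSelection, Structure
from uvnma.synthetic import ComplexSpec, HelixSpec, make_helix, make_u_v_pair

Z_FRAME = MembraneFrame(normal=np.array([0.0, 0.0, 1.0]), center=np.zeros(3))


def helix_structure(n=20, direction=(0, 0, 1), origin=(0, 0, 0), chain="A"):
    return Structure(list(make_helix(
        HelixSpec(n, origin, direction, chain_id=chain)).atoms))


class TestHelixAxis:
    def test_axis_along_z_recovered(self):
        ax = fit_helix_axis(helix_structure(), "A", (1, 20))
        assert np.allclose(ax.direction, [0, 0, 1], atol=1e-4)

    def test_fit_rms_equals_radius(self):
        ax = fit_helix_axis(helix_structure(), "A", (1, 20))
        assert ax.fit_rms == pytest.approx(2.3, rel=0.05)

    def test_too_few_residues(self):
        with pytest.raises(IllDefinedAxisError):
            fit_helix_axis(helix_structure(4), "A", (1, 4))

    def test_no_dominant_direction(self):
        # cube corners: exactly isotropic covariance, no principal axis
        corners = [(x, y, z) for x in (0, 6.0) for y in (0, 6.0) for z in (0, 6.0)]
        blob = Structure([Atom(i + 1, "CA", "C", i + 1, "", "ALA", "A",
                               np.array(c)) for i, c in enumerate(corners)])
        with pytest.raises(IllDefinedAxisError):
            fit_helix_axis(blob, "A", (1, 8))

    def test_n_to_c_orientation(self):
        up = fit_helix_axis(helix_structure(direction=(0, 0, 1)), "A", (1, 20))
        dn = fit_helix_axis(helix_structure(direction=(0, 0, -1)), "A", (1, 20))
        assert up.direction[2] > 0.99
        assert dn.direction[2] < -0.99


class TestInterhelixAngle:
    def test_parallel_is_zero(self):
        a = fit_helix_axis(helix_structure(), "A", (1, 20))
        b = fit_helix_axis(helix_structure(origin=(10, 0, 0)), "A", (1, 20))
        assert interhelix_angle(a, b) == pytest.approx(0.0, abs=1e-4)

    def test_antiparallel_modes(self):
        a = fit_helix_axis(helix_structure(), "A", (1, 20))
        b = fit_helix_axis(helix_structure(direction=(0, 0, -1),
                                           origin=(10, 0, 0)), "A", (1, 20))
        assert interhelix_angle(a, b, directed=True) == pytest.approx(180.0, abs=1e-4)
        assert interhelix_angle(a, b, directed=False) == pytest.approx(0.0, abs=1e-4)

    def test_planted_11_degree_tilt(self):
        d = Rotation.from_euler("x", 11.0, degrees=True).apply([0, 0, 1.0])
        a = fit_helix_axis(helix_structure(), "A", (1, 20))
        b = fit_helix_axis(helix_structure(direction=tuple(d), origin=(10, 0, 0)),
                           "A", (1, 20))
        assert interhelix_angle(a, b) == pytest.approx(11.0, abs=1e-4)

    def test_symmetry(self):
        d = Rotation.from_euler("y", 23.0, degrees=True).apply([0, 0, 1.0])
        a = fit_helix_axis(helix_structure(), "A", (1, 20))
        b = fit_helix_axis(helix_structure(direction=tuple(d)), "A", (1, 20))
        assert interhelix_angle(a, b) == pytest.approx(interhelix_angle(b, a))


class TestPiston:
    def test_identical_structures_zero(self):
        h = helix_structure()
        assert piston_displacement(h, h, "A", (1, 20), Z_FRAME) == 0.0

    def test_planted_translation_recovered(self):
        h = helix_structure()
        shifted = h.with_coords(h.coords + np.array([0, 0, 0.5]))
        for end in ("cytoplasmic", "extracellular", "whole"):
            assert piston_displacement(h, shifted, "A", (1, 20), Z_FRAME,
                                       end=end) == pytest.approx(0.5, abs=1e-6)

    def test_rotation_about_normal_gives_zero(self):
        h = helix_structure()
        R = Rotation.from_euler("z", 25.0, degrees=True).as_matrix()
        rotated = h.with_coords(h.coords @ R.T)
        assert piston_displacement(h, rotated, "A", (1, 20), Z_FRAME,
                                   end="whole") == pytest.approx(0.0, abs=1e-6)

    def test_empty_range_rejected(self):
        h = helix_structure()
        with pytest.raises(ValueError):
            piston_displacement(h, h, "A", (900, 920), Z_FRAME)


class TestAxialRotation:
    def test_identical_is_zero(self):
        h = helix_structure()
        assert helix_axial_rotation(h, h, "A", (1, 20)) == pytest.approx(0.0, abs=1e-9)

    def test_planted_19_degrees(self):
        h = helix_structure()
        R = Rotation.from_euler("z", 19.0, degrees=True).as_matrix()
        twisted = h.with_coords(h.coords @ R.T)
        assert helix_axial_rotation(h, twisted, "A", (1, 20)) == pytest.approx(
            19.0, abs=1e-3)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(0.0, 40.0), st.floats(0.0, 2.0))
    def test_screw_motion_decoupling(self, theta, d):
        """Planted screw (twist θ + axial shift d) is recovered component-wise."""
        h = helix_structure()
        R = Rotation.from_euler("z", theta, degrees=True).as_matrix()
        screwed = h.with_coords(h.coords @ R.T + np.array([0, 0, d]))
        assert helix_axial_rotation(h, screwed, "A", (1, 20)) == pytest.approx(
            theta, abs=1e-3)
        assert piston_displacement(h, screwed, "A", (1, 20), Z_FRAME,
                                   end="whole") == pytest.approx(d, abs=1e-3)

    def test_sign_convention_right_handed(self):
        h = helix_structure()
        R = Rotation.from_euler("z", -12.0, degrees=True).as_matrix()
        assert helix_axial_rotation(h, h.with_coords(h.coords @ R.T),
                                    "A", (1, 20)) == pytest.approx(-12.0, abs=1e-3)


def _atom(serial, name, resname, resnum, pos, chain="A"):
    return Atom(serial, name, name[0], resnum, "", resname, chain,
                np.asarray(pos, dtype=float))


def salt_bridge_fixture(distance):
    """Lys NZ (with CE antecedent) facing Asp OD1 at the given distance."""
    a = Structure([_atom(1, "CE", "LYS", 1, (-1.5, 0, 0)),
                   _atom(2, "NZ", "LYS", 1, (0, 0, 0))])
    b = Structure([_atom(1, "OD1", "ASP", 5, (distance, 0, 0), chain="B"),
                   _atom(2, "CG", "ASP", 5, (distance + 1.3, 0, 0), chain="B")])
    return a, b


class TestContacts:
    def test_salt_bridge_at_3p8(self):
        recs = detect_contacts(*salt_bridge_fixture(3.8))
        kinds = {r.kind for r in recs}
        assert "salt_bridge" in kinds
        sb = [r for r in recs if r.kind == "salt_bridge"][0]
        assert sb.distance == pytest.approx(3.8)

    def test_same_pair_at_4p5_is_contact_only(self):
        recs = detect_contacts(*salt_bridge_fixture(4.5))
        assert {r.kind for r in recs} <= {"contact"}
        assert any(r.kind == "contact" for r in recs)

    def test_close_pair_is_clash(self):
        recs = detect_contacts(*salt_bridge_fixture(2.0))
        assert any(r.kind == "clash" for r in recs)
        assert not any(r.kind == "salt_bridge" for r in recs)

    def test_hydrogen_bond_with_angle_check(self):
        # Ser OG donor (CB antecedent) to backbone O acceptor at 2.9 Å,
        # antecedent angle ~109° → hydrogen bond
        don = Structure([_atom(1, "CB", "SER", 1, (-1.43, 0, 0)),
                         _atom(2, "OG", "SER", 1, (0, 0, 0))])
        acc = Structure([_atom(1, "O", "GLY", 9, (0.97, 2.73, 0), chain="B")])
        recs = detect_contacts(don, acc)
        assert any(r.kind == "hydrogen_bond" for r in recs)

    def test_hydrogen_bond_rejected_behind_donor(self):
        # acceptor on the same side as the antecedent (angle ~0°): no H-bond
        don = Structure([_atom(1, "CB", "SER", 1, (-1.43, 0, 0)),
                         _atom(2, "OG", "SER", 1, (0, 0, 0))])
        acc = Structure([_atom(1, "O", "GLY", 9, (-3.0, 0, 0), chain="B")])
        recs = detect_contacts(don, acc)
        assert not any(r.kind == "hydrogen_bond" for r in recs)

    def test_ca_only_warns_and_restricts_kinds(self):
        a = Structure([_atom(1, "CA", "ALA", 1, (0, 0, 0))])
        b = Structure([_atom(1, "CA", "ALA", 2, (2.0, 0, 0), chain="B")])
        with pytest.warns(UserWarning):
            recs = detect_contacts(a, b)
        assert {r.kind for r in recs} <= {"clash", "contact"}

    def test_symmetric_and_rigid_motion_invariant(self):
        a, b = salt_bridge_fixture(3.8)
        fwd = detect_contacts(a, b)
        rev = detect_contacts(b, a)
        assert sorted(r.kind for r in fwd) == sorted(r.kind for r in rev)
        R = Rotation.from_euler("xyz", [30, 40, 50], degrees=True).as_matrix()
        t = np.array([5.0, -2.0, 7.0])
        a2 = a.with_coords(a.coords @ R.T + t)
        b2 = b.with_coords(b.coords @ R.T + t)
        moved = detect_contacts(a2, b2)
        assert sorted(r.kind for r in moved) == sorted(r.kind for r in fwd)

    def test_thresholds_configurable(self):
        a, b = salt_bridge_fixture(4.2)
        default = detect_contacts(a, b)
        assert not any(r.kind == "salt_bridge" for r in default)
        wide = detect_contacts(a, b, thresholds=ContactThresholds(salt_bridge=4.4))
        assert any(r.kind == "salt_bridge" for r in wide)


def test_complex_piston_and_twist_recovery(layout):
    """End-to-end on the 2:2 complex: piston and twist decouple exactly."""
    u, v, t = make_u_v_pair(ComplexSpec(receptor_rotation_deg=0.0,
                                        piston_A=0.5, tm2_twist_deg=19.0))
    frame = layout.membrane_frame()
    assert piston_displacement(u, v, "C", layout.tm2_range, frame,
                               end="whole") == pytest.approx(0.5, abs=1e-3)
    assert helix_axial_rotation(u, v, "C", layout.tm2_range) == pytest.approx(
        19.0, abs=1e-3)
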