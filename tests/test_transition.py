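"""Mode overlaps, best-k reconstruction, and mode-character classification."""

import numpy as np
import pytest

from uvnma.enm import BlockDefinition, ENModel, rtb_modes
from uvnma.geometry import MembraneFrame
from uvnma.structures import AtomSelection
from uvnma.synthetic import ComplexSpec, make_u_v_pair
from uvnma.transition import (
    best_k_fit, classify_mode, displace_along_modes, mode_overlap,
    transition_vector,
)

FRAME = MembraneFrame(normal=np.array([0.0, 0.0, 1.0]), center=np.zeros(3))


@pytest.fixture(scope="module")
def complex_modes(layout_module=None):
    from uvnma.synthetic import ComplexLayout
    layout = ComplexLayout()
    u, v, truth = make_u_v_pair(ComplexSpec())
    ca = u.select(AtomSelection.ca())
    model = ENModel(ca.coords, cutoff=10.0)
    modes = rtb_modes(model, BlockDefinition.from_segments(layout.helix_segments(u)))
    return layout, u, v, ca, modes


class TestTransitionVector:
    def test_self_transition_is_zero(self, complex_modes):
        layout, u, _, _, _ = complex_modes
        d, r0, _ = transition_vector(u, u)
        assert np.allclose(d, 0.0)
        assert r0 == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed_by_frame_fit(self, complex_modes):
        _, u, _, _, _ = complex_modes
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("z", 40.0, degrees=True).as_matrix()
        moved = u.with_coords(u.coords @ R.T + np.array([5.0, 6.0, 7.0]))
        _, r0, _ = transition_vector(u, moved)
        assert r0 == pytest.approx(0.0, abs=1e-9)

    def test_planted_rmsd_magnitude(self, complex_modes):
        layout, u, v, _, _ = complex_modes
        d, r0, keys = transition_vector(u, v, frame_selection=layout.frame_selection())
        n = len(keys)
        assert r0 == pytest.approx(np.linalg.norm(d) / np.sqrt(n), abs=1e-12)
        assert r0 > 1.0  # 8.5° rotation moves the receptors by Å-scale amounts


class TestOverlap:
    def test_zero_displacement_rejected(self, complex_modes):
        *_, modes = complex_modes
        with pytest.raises(ValueError):
            mode_overlap(np.zeros(modes.vectors.shape[0]), modes)

    def test_single_mode_displacement(self, complex_modes):
        *_, modes = complex_modes
        d = modes.nonzero_modes()[1][:, 0] * 2.7
        per, cum = mode_overlap(d, modes)
        assert per[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(per[1:], 0.0, atol=1e-9)

    def test_equal_mixture_of_two_modes(self, complex_modes):
        *_, modes = complex_modes
        V = modes.nonzero_modes()[1]
        d = (V[:, 0] + V[:, 1]) / np.sqrt(2)
        per, cum = mode_overlap(d, modes)
        assert per[0] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert per[1] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert cum[1] == pytest.approx(1.0, abs=1e-9)

    def test_span_of_first_ten_modes(self, complex_modes):
        *_, modes = complex_modes
        rng = np.random.default_rng(0)
        d = modes.nonzero_modes()[1][:, :10] @ rng.normal(0, 1, 10)
        _, cum = mode_overlap(d, modes)
        assert cum[9] == pytest.approx(1.0, abs=1e-9)

    def test_cumulative_monotone_bounded(self, complex_modes):
        layout, u, v, _, modes = complex_modes
        d, _, _ = transition_vector(u, v, frame_selection=layout.frame_selection())
        _, cum = mode_overlap(d, modes)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] <= 1.0 + 1e-9


class TestBestKFit:
    def test_full_basis_zero_residual_in_span(self, complex_modes):
        *_, modes = complex_modes
        n_nz = modes.n_modes - modes.n_zero_modes
        rng = np.random.default_rng(5)
        d = modes.nonzero_modes()[1] @ rng.normal(0, 1, n_nz)
        _, resid = best_k_fit(d, modes, n_nz)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_full_basis_on_planted_rotation(self, complex_modes):
        """A finite 8.5° rigid rotation lies in the per-helix RTB span up
        to its quadratic curvature term, of relative size ~tan(θ/2).
        The whole-complex frame fit makes the displacement orthogonal to
        the rigid-body (zero) modes, so only that curvature remains."""
        _, u, v, _, modes = complex_modes
        d, r0, _ = transition_vector(u, v)   # default: whole-complex frame
        n_nz = modes.n_modes - modes.n_zero_modes
        _, resid = best_k_fit(d, modes, n_nz)
        assert resid < 1.5 * np.tan(np.radians(8.5 / 2)) * r0

    def test_k_zero_returns_initial(self, complex_modes):
        layout, u, v, _, modes = complex_modes
        d, r0, _ = transition_vector(u, v, frame_selection=layout.frame_selection())
        _, resid = best_k_fit(d, modes, 0)
        assert resid == pytest.approx(r0, abs=1e-12)

    def test_pythagorean_decomposition(self, complex_modes):
        layout, u, v, _, modes = complex_modes
        d, r0, keys = transition_vector(u, v, frame_selection=layout.frame_selection())
        n = len(keys)
        for k in (1, 5, 10, 30):
            coeffs, resid = best_k_fit(d, modes, k)
            explained = np.linalg.norm(coeffs) / np.sqrt(n)
            assert r0 ** 2 == pytest.approx(explained ** 2 + resid ** 2, abs=1e-6)

    def test_constructed_72_28_split(self, complex_modes):
        *_, modes = complex_modes
        V = modes.nonzero_modes()[1]
        rng = np.random.default_rng(1)
        inplane = V[:, :3] @ rng.normal(0, 1, 3)
        inplane /= np.linalg.norm(inplane)
        ortho = V[:, 20]
        d = 0.96 * inplane + 0.28 * ortho
        _, resid = best_k_fit(d, modes, 3)
        n = V.shape[0] // 3
        r0 = np.linalg.norm(d) / np.sqrt(n)
        assert resid / r0 == pytest.approx(0.28, abs=1e-6)

    def test_k_too_large_rejected(self, complex_modes):
        *_, modes = complex_modes
        with pytest.raises(ValueError):
            best_k_fit(np.ones(modes.vectors.shape[0]), modes, modes.n_modes + 1)


class TestClassifyMode:
    def test_pure_translation(self, complex_modes):
        layout, u, _, ca, _ = complex_modes
        groups = layout.group_indices(u)
        field = np.zeros((len(ca), 3))
        field[groups["receptor_A"]] = [0.0, 0.0, 1.0]
        chars = classify_mode(field.ravel(), ca.coords, groups, FRAME)
        rec_a = next(c for c in chars if c.group == "receptor_A")
        assert rec_a.translation_fraction == pytest.approx(1.0, abs=1e-9)
        assert rec_a.rotation_fraction == pytest.approx(0.0, abs=1e-9)
        assert rec_a.piston_component > 0

    def test_pure_infinitesimal_rotation(self, complex_modes):
        layout, u, _, ca, _ = complex_modes
        groups = layout.group_indices(u)
        idx = groups["receptor_A"]
        c = ca.coords[idx].mean(axis=0)
        omega = np.array([0.3, -0.2, 0.5])
        field = np.zeros((len(ca), 3))
        field[idx] = np.cross(omega, ca.coords[idx] - c)
        chars = classify_mode(field.ravel(), ca.coords, groups, FRAME)
        rec_a = next(c2 for c2 in chars if c2.group == "receptor_A")
        assert rec_a.rotation_fraction == pytest.approx(1.0, abs=1e-6)
        assert rec_a.translation_fraction == pytest.approx(0.0, abs=1e-6)

    def test_planted_screw_field_fractions(self, complex_modes):
        layout, u, _, ca, _ = complex_modes
        groups = layout.group_indices(u)
        idx = groups["transducers"]
        c = ca.coords[idx].mean(axis=0)
        omega = np.array([0.0, 0.0, 0.1])
        t = np.array([0.0, 0.0, 0.4])
        rot_part = np.cross(omega, ca.coords[idx] - c)
        field = np.zeros((len(ca), 3))
        field[idx] = t + rot_part
        chars = classify_mode(field.ravel(), ca.coords, groups, FRAME)
        g = next(c2 for c2 in chars if c2.group == "transducers")
        total = len(idx) * t @ t + np.sum(rot_part ** 2)
        assert g.translation_fraction == pytest.approx(len(idx) * (t @ t) / total, abs=1e-3)
        assert g.rotation_fraction == pytest.approx(np.sum(rot_part ** 2) / total, abs=1e-3)
        assert g.deformation_fraction == pytest.approx(0.0, abs=1e-9)

    def test_small_group_rejected(self, complex_modes):
        _, u, _, ca, _ = complex_modes
        with pytest.raises(ValueError):
            classify_mode(np.zeros(3 * len(ca)), ca.coords,
                          {"tiny": np.array([0, 1])}, FRAME)


class TestDisplaceAlongModes:
    def test_zero_amplitude_is_identity(self, complex_modes):
        _, u, _, _, modes = complex_modes
        out = displace_along_modes(u, modes, np.zeros(5), amplitude=0.0)
        assert np.array_equal(out.coords, u.coords)

    def test_best_fit_model_rmsd_equals_residual(self, complex_modes):
        layout, u, v, ca, modes = complex_modes
        d, r0, _ = transition_vector(u, v, frame_selection=layout.frame_selection())
        coeffs, resid = best_k_fit(d, modes, 10)
        vlike = displace_along_modes(u, modes, coeffs)
        vlike_ca = vlike.select(AtomSelection.ca()).coords
        target = ca.coords + d.reshape(-1, 3)
        achieved = np.sqrt(np.mean(np.sum((vlike_ca - target) ** 2, axis=1)))
        assert achieved == pytest.approx(resid, abs=1e-9)

    def test_mode_trajectory_animation(self, complex_modes, tmp_path):
        from uvnma.structures import read_pdb, write_multi_model_pdb
        from uvnma.transition import mode_trajectory
        _, u, _, ca, modes = complex_modes
        coeffs = np.array([1.0, 0.5])
        frames = mode_trajectory(u, modes, coeffs, n_frames=5)
        assert len(frames) == 5
        assert np.array_equal(frames[0].coords, u.coords)
        # linear interpolation: midpoint frame displaces by half
        half = (frames[2].select(AtomSelection.ca()).coords - ca.coords)
        full = (frames[4].select(AtomSelection.ca()).coords - ca.coords)
        assert np.allclose(full, 2 * half, atol=1e-12)
        p = tmp_path / "traj.pdb"
        write_multi_model_pdb(frames, p)
        text = p.read_text()
        assert text.count("MODEL") >= 5
        first = read_pdb(p)      # first model only
        assert np.abs(first.coords - u.coords).max() < 1e-3

    def test_projection_round_trip(self, complex_modes):
        _, u, _, ca, modes = complex_modes
        coeffs = np.linspace(0.5, -0.4, 8)
        moved = displace_along_modes(u, modes, coeffs)
        d2 = (moved.select(AtomSelection.ca()).coords - ca.coords).ravel()
        recovered = modes.nonzero_modes()[1][:, :8].T @ d2
        assert np.allclose(recovered, coeffs, atol=1e-9)
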