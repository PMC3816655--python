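import numpy as np
import pytest

from diabind import (
    DielectricMap,
    EnsembleFrames,
    effective_dielectric,
    ensemble_interaction_profile,
    entropy_descriptor,
    extract_features,
    asa_property,
    scaled_ele_profile,
    shrake_rupley_asa,
)
from diabind.ensemble import dihedral_angles
from diabind.exceptions import (
    ConfigurationError,
    CoverageError,
    ParameterError,
    ShapeError,
)


def lonlat_asa_oracle(center_a, r_a, center_b, r_b, n_theta=600, n_phi=1200):
    """Independent fine-grid integration of sphere A's area outside sphere B.

    Latitude-longitude quadrature with exact per-cell solid-angle weights;
    deliberately unrelated to the golden-spiral sampling under test.
    """
    theta_edges = np.linspace(0, np.pi, n_theta + 1)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False) + np.pi / n_phi
    theta = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    # solid angle of each band cell
    band = 2 * np.pi * (np.cos(theta_edges[:-1]) - np.cos(theta_edges[1:])) / n_phi
    area = 0.0
    for t, w in zip(theta, band):
        pts = center_a + r_a * np.column_stack((
            np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi),
            np.full(n_phi, np.cos(t)),
        ))
        outside = ((pts - center_b) ** 2).sum(axis=1) > r_b ** 2
        area += w * outside.sum()
    return r_a ** 2 * area


class TestShrakeRupley:
    def test_isolated_sphere_analytic(self):
        areas = shrake_rupley_asa(np.zeros((1, 3)), np.array([1.5]),
                                  probe=1.4, n_points=960)
        exact = 4 * np.pi * 2.9 ** 2
        assert areas[0] == pytest.approx(exact, rel=0.01)

    def test_buried_atom_is_zero(self):
        # central atom caged by six large overlapping spheres
        cage = 3.0 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                               [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        coords = np.vstack([[0, 0, 0], cage])
        radii = np.array([1.0] + [4.0] * 6)
        areas = shrake_rupley_asa(coords, radii, probe=1.4, n_points=960)
        assert areas[0] == 0.0

    def test_two_spheres_vs_integration_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.2, 0, 0]])
        radii = np.array([1.5, 1.8])
        probe = 1.4
        areas = shrake_rupley_asa(coords, radii, probe=probe, n_points=960)
        for i, j in ((0, 1), (1, 0)):
            oracle = lonlat_asa_oracle(coords[i], radii[i] + probe,
                                       coords[j], radii[j] + probe)
            assert areas[i] == pytest.approx(oracle, rel=0.02)

    def test_never_exceeds_isolated_sphere(self, toy):
        _, system, frames, _ = toy
        areas = shrake_rupley_asa(frames.frames[3], system.radius, 1.4, 240)
        caps = 4 * np.pi * (system.radius + 1.4) ** 2
        assert np.all(areas <= caps + 1e-9)

    def test_degenerate_coordinates_warn(self):
        coords = np.zeros((2, 3))
        with pytest.warns(RuntimeWarning):
            shrake_rupley_asa(coords, np.array([1.0, 1.0]), 1.4, 60)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            shrake_rupley_asa(np.zeros((1, 3)), np.array([1.0]), 1.4, n_points=10)
        with pytest.raises(ParameterError):
            shrake_rupley_asa(np.zeros((1, 3)), np.array([-1.0]), 1.4, 96)


class TestAsaProperty:
    def test_single_atom_equals_sphere(self, two_residue_system):
        sys_ = two_residue_system
        one = np.array([[0.0, 0, 0]])

        class Mini:  # minimal stand-in with the used attributes
            radius = np.array([1.6])
            solvation_param = np.array([1.0])

        area = asa_property(one, Mini(), probe=1.4, n_points=960)
        assert area == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.01)

    def test_unit_solvation_matches_unweighted(self, two_residue_system):
        sys_ = two_residue_system
        sys_.solvation_param = np.ones(sys_.n_atoms)
        a = asa_property(sys_.coordinates, sys_, weighted=False, n_points=240)
        b = asa_property(sys_.coordinates, sys_, weighted=True, n_points=240)
        assert a == pytest.approx(b, rel=1e-12)

    def test_weighted_is_dot_product(self, two_residue_system):
        sys_ = two_residue_system
        areas = shrake_rupley_asa(sys_.coordinates, sys_.radius, 1.4, 240)
        expected = float(np.dot(sys_.solvation_param, areas))
        got = asa_property(sys_.coordinates, sys_, weighted=True, n_points=240)
        assert got == pytest.approx(expected, rel=1e-12)


class TestInteractionProfile:
    def test_single_frame_zero_fluctuation(self, toy):
        _, system, frames, _ = toy
        single = EnsembleFrames(system=system, frames=frames.frames[:1])
        prof = ensemble_interaction_profile(single, form="8-4")
        assert np.all(prof.fluct_vdw == 0) and np.all(prof.fluct_ele == 0)

    def test_duplicated_frames_invariant(self, toy):
        _, system, frames, _ = toy
        one = EnsembleFrames(system=system, frames=frames.frames[:1])
        five = EnsembleFrames(system=system,
                              frames=np.repeat(frames.frames[:1], 5, axis=0))
        p1 = ensemble_interaction_profile(one, form="12-6")
        p5 = ensemble_interaction_profile(five, form="12-6")
        np.testing.assert_allclose(p1.mean_vdw, p5.mean_vdw)
        np.testing.assert_allclose(p5.fluct_vdw, 0.0, atol=1e-12)

    def test_hand_set_two_frame_statistics(self):
        # two frames of a single pair at distances giving energies E and E'
        vals = np.array([2.0, 4.0])
        assert vals.mean() == 3.0 and vals.std() == 1.0  # population SD


class TestEntropyDescriptor:
    def test_rigid_ensemble_all_zero(self, rigid_toy):
        _, system, frames, _ = rigid_toy
        for tag in ("ASA", "DIH", "VDW", "ELE"):
            d = entropy_descriptor(frames, tag, n_points=96)
            assert d.value == pytest.approx(0.0, abs=1e-10)

    def test_dihedral_wraparound(self):
        # alternating +179/-179 degrees must give ~1 degree of spread
        from scipy.stats import circstd
        ang = np.deg2rad(np.array([179.0, -179.0] * 10))
        sd = circstd(ang, high=np.pi, low=-np.pi)
        assert sd == pytest.approx(np.deg2rad(1.0), rel=0.05)

    def test_dihedral_angles_reference_values(self):
        # planar cis = 0, trans = pi
        cis = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        trans = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
        assert dihedral_angles(cis, [(0, 1, 2, 3)])[0] == pytest.approx(0.0)
        assert abs(dihedral_angles(trans, [(0, 1, 2, 3)])[0]) == pytest.approx(np.pi)

    def test_total_energy_fluctuation_hand_value(self, toy):
        _, system, frames, _ = toy
        d = entropy_descriptor(frames, "VDW", form="12-6")
        from diabind import residue_ligand_energies
        totals = np.array([
            residue_ligand_energies(system, f, form="12-6")[0].sum()
            for f in frames.frames
        ])
        assert d.value == pytest.approx(totals.std(), rel=1e-12)

    def test_frame_reorder_invariance(self, toy):
        _, system, frames, _ = toy
        rev = EnsembleFrames(system=system, frames=frames.frames[::-1].copy())
        for tag in ("DIH", "VDW", "ELE"):
            a = entropy_descriptor(frames, tag)
            b = entropy_descriptor(rev, tag)
            assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_dih_requires_dihedrals(self, toy):
        _, system, frames, _ = toy
        system.rotatable_dihedrals = []
        with pytest.raises(ConfigurationError):
            entropy_descriptor(frames, "DIH")


class TestEffectiveDielectric:
    def test_unscreened_limit(self):
        f = np.random.default_rng(0).normal(size=(20, 3))
        dmap = effective_dielectric(f, f, x=0.6)
        np.testing.assert_allclose(dmap.eps_eff, 1.0)

    def test_ratio_limit_large_forces(self):
        rng = np.random.default_rng(1)
        f_real = rng.normal(size=(30, 3))
        f_real *= 1e6 / np.linalg.norm(f_real, axis=1, keepdims=True)
        f_vac = 2.0 * f_real
        dmap = effective_dielectric(f_real, f_vac, x=1e-6, mode=19)
        np.testing.assert_allclose(dmap.eps_eff, 2.0, rtol=1e-4)

    def test_zero_real_force_bounded(self):
        f_vac = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        f_real = np.array([[0.0, 0, 0], [0, 2.0, 0]])
        x = 0.6
        dmap = effective_dielectric(f_real, f_vac, x=x)
        fbar = np.linalg.norm(f_vac, axis=1).mean()
        bound = (3.0 + x * fbar) / (x * fbar)
        assert np.isfinite(dmap.eps_eff).all()
        assert dmap.eps_eff[0] == pytest.approx(bound)

    @pytest.mark.parametrize("mode", [18, 19])
    @pytest.mark.parametrize("x", [0.1, 0.6, 2.0])
    def test_bounds_for_all_x(self, mode, x):
        rng = np.random.default_rng(5)
        f_real = rng.normal(size=(40, 3)) * rng.uniform(0, 10, (40, 1))
        f_vac = rng.normal(size=(40, 3)) * rng.uniform(0, 10, (40, 1))
        dmap = effective_dielectric(f_real, f_vac, x=x, mode=mode)
        assert np.all(dmap.eps_eff >= 1.0)
        assert np.all(np.isfinite(dmap.eps_eff))

    def test_mode18_projection(self):
        # orthogonal vacuum force projects to zero -> eps_eff clips to 1
        f_real = np.array([[1.0, 0, 0]] * 2)
        f_vac = np.array([[0.0, 5.0, 0], [3.0, 0, 0]])
        dmap = effective_dielectric(f_real, f_vac, x=1e-9, mode=18)
        assert dmap.eps_eff[0] == pytest.approx(1.0)
        assert dmap.eps_eff[1] == pytest.approx(3.0, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            effective_dielectric(np.zeros((3, 3)), np.zeros((4, 3)), 0.6)


class TestScaledProfile:
    def test_unit_map_bit_identical(self, toy):
        _, system, frames, _ = toy
        n_prot = system.protein_atom_ids.size
        unit = DielectricMap(eps_eff=np.ones(n_prot), x=0.6)
        plain = ensemble_interaction_profile(frames, form="12-6")
        scaled = scaled_ele_profile(frames, unit, form="12-6")
        assert np.array_equal(scaled.mean_ele_scaled, plain.mean_ele)

    def test_uniform_map_halves(self, toy):
        _, system, frames, _ = toy
        n_prot = system.protein_atom_ids.size
        two = DielectricMap(eps_eff=np.full(n_prot, 2.0), x=0.6)
        plain = ensemble_interaction_profile(frames, form="12-6")
        scaled = scaled_ele_profile(frames, two, form="12-6")
        np.testing.assert_allclose(scaled.mean_ele_scaled, plain.mean_ele / 2,
                                   rtol=1e-12)

    def test_mixed_map_matches_pairwise_oracle(self, two_residue_system):
        from diabind import coulomb_pair_energy, residue_ligand_energies
        sys_ = two_residue_system
        eps_map = np.array([1.5, 2.0, 4.0])  # per protein atom (ids 2,3,4)
        _, e_scaled = residue_ligand_energies(sys_, eps_map=eps_map)
        expected = np.zeros(2)
        for pi, (i, e) in enumerate(zip([2, 3, 4], eps_map)):
            for j in (0, 1):
                r = np.linalg.norm(sys_.coordinates[i] - sys_.coordinates[j])
                expected[sys_.residue_index[i] - 1] += coulomb_pair_energy(
                    sys_.charge[i], sys_.charge[j], r, eps_scale=e
                )
        np.testing.assert_allclose(e_scaled, expected, rtol=1e-9)

    def test_coverage_error(self, toy):
        _, system, frames, _ = toy
        short = DielectricMap(eps_eff=np.ones(3), x=0.6)
        with pytest.raises(CoverageError):
            scaled_ele_profile(frames, short)


class TestExtractFeatures:
    def test_feature_sums_match_profile(self, toy):
        _, system, frames, forces = toy
        dmap = effective_dielectric(*forces, x=0.6)
        feats = extract_features(frames, vdw_form="8-4", dmap=dmap, n_points=96)
        prof = ensemble_interaction_profile(frames, form="8-4",
                                            eps_map=dmap.eps_eff)
        assert feats.sum_vdw == pytest.approx(prof.mean_vdw.sum(), rel=1e-12)
        assert feats.sum_ele == pytest.approx(prof.mean_ele.sum(), rel=1e-12)
        assert feats.sum_ele_scaled == pytest.approx(
            prof.mean_ele_scaled.sum(), rel=1e-12
        )
        assert feats.sum_fluct_vdw == pytest.approx(prof.fluct_vdw.sum(), rel=1e-12)
        assert set(feats.entropy) == {"ASA", "DIH", "VDW", "ELE"}
        assert all(v >= 0 for v in feats.entropy.values())
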