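import numpy as np
import pytest

from vertemech import (MaterialParams, apply_rigid_plate_load, assign_materials,
                       build_model, hex_element_stiffness, solve,
                       stiffness_from_solution)
from vertemech.bvtv_map import (LABEL_BONE, LABEL_CEMENT, LABEL_VOID,
                                BVTVVolume, RegionLabelVolume)
from vertemech.voxfem import _constraint_transform


def make_block_model(shape, E=1.0, nu=0.0, spacing=1.0, modulus=None,
                     labels=None, load_N=1000.0):
    """Bare rectangular block meshed for verification problems."""
    bvtv = BVTVVolume(data=np.ones(shape), spacing=(spacing,) * 3)
    if labels is None:
        labels = np.full(shape, LABEL_BONE, np.uint8)
    lab = RegionLabelVolume(data=labels, spacing=(spacing,) * 3)
    params = MaterialParams(k=E, exponent=1, nu=nu)
    model = build_model(assign_materials(bvtv, lab, params), load_N=load_N,
                        require_cement=False)
    if modulus is not None:
        model = model.with_modulus(modulus)
    return model


def centre_loaded(model):
    xy = model.node_coords[model.plate_nodes, :2]
    return apply_rigid_plate_load(model, 0.5 * (xy.min(axis=0) + xy.max(axis=0)))


class TestHexElement:
    def test_symmetry_and_rigid_body_modes(self):
        K = hex_element_stiffness(1.3, 0.3, (1.0, 1.2, 0.8))
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-9 * w.max()) == 6
        assert np.all(w > -1e-9 * w.max())

    def test_linear_in_modulus(self):
        K1 = hex_element_stiffness(1.0, 0.25, (1, 1, 1))
        K3 = hex_element_stiffness(3.0, 0.25, (1, 1, 1))
        np.testing.assert_allclose(K3, 3 * K1, rtol=1e-12, atol=1e-14)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hex_element_stiffness(1.0, 0.5, (1, 1, 1))
        with pytest.raises(ValueError):
            hex_element_stiffness(-1.0, 0.3, (1, 1, 1))

    def test_single_unit_cube_axial_stiffness(self):
        # one element between frictionless platens at nu=0: S = E*A/L
        model = centre_loaded(make_block_model((2, 2, 2), E=2.0))
        # 2x2x2 elements of 1 mm: A = 4 mm^2, L = 2 mm -> S = 4 kN/mm
        sol = solve(model)
        res = stiffness_from_solution(model, sol)
        assert res.stiffness_kN_per_mm == pytest.approx(2.0 * 4 / 2, rel=1e-8)


class TestBuildModel:
    def test_uniform_block_counts(self):
        model = make_block_model((3, 4, 5))
        assert model.n_elements == 60
        assert model.n_nodes == 4 * 5 * 6

    def test_floating_voxel_dropped(self):
        labels = np.zeros((6, 3, 3), np.uint8)
        labels[0:3] = LABEL_BONE
        labels[5, 1, 1] = LABEL_BONE  # isolated
        bvtv = BVTVVolume(data=np.ones((6, 3, 3)), spacing=(1,) * 3)
        lab = RegionLabelVolume(data=labels, spacing=(1,) * 3)
        model = build_model(assign_materials(bvtv, lab, MaterialParams(k=1.0)),
                            require_cement=False)
        assert model.n_elements == 27
        assert model.n_dropped == 1

    def test_cement_required_by_default(self):
        bvtv = BVTVVolume(data=np.ones((2, 2, 2)), spacing=(1,) * 3)
        lab = RegionLabelVolume(data=np.full((2, 2, 2), LABEL_BONE, np.uint8),
                                spacing=(1,) * 3)
        with pytest.raises(ValueError, match="cement"):
            build_model(assign_materials(bvtv, lab, MaterialParams(k=1.0)))


class TestRigidPlate:
    def test_load_point_outside_footprint_rejected(self):
        model = make_block_model((2, 2, 2))
        with pytest.raises(ValueError):
            apply_rigid_plate_load(model, (5.0, 0.5))

    def test_central_load_on_symmetric_model_no_rotation(self):
        model = centre_loaded(make_block_model((4, 4, 6), nu=0.3))
        sol = solve(model)
        assert np.max(np.abs(sol.plate_rotation)) < 1e-10

    def test_offcentre_load_equilibrium(self):
        model = make_block_model((4, 4, 6), nu=0.3)
        model = apply_rigid_plate_load(model, (1.3, 2.2))
        sol = solve(model, tol=1e-12)
        K = model.assemble()
        R = K @ sol.displacement.ravel()
        reactions_z = R.reshape(-1, 3)[model.fixed_nodes, 2].sum()
        assert reactions_z == pytest.approx(model.load_N / 1000.0, rel=1e-8)

    def test_two_column_rig_matches_two_spring_closed_form(self):
        # two slender columns on a near-rigid base, rigid plate on top:
        # spring rates s_i = E_i A / L at the column centrelines
        shape = (2, 8, 8)
        labels = np.zeros(shape, np.uint8)
        labels[:, :, 0] = LABEL_CEMENT          # stiff base slab
        labels[:, 1, 1:] = LABEL_BONE           # column 1 at y = 1.5 mm
        labels[:, 6, 1:] = LABEL_BONE           # column 2 at y = 6.5 mm
        bvtv = BVTVVolume(data=np.ones(shape), spacing=(1,) * 3)
        lab = RegionLabelVolume(data=labels, spacing=(1,) * 3)
        E1, E2, L = 1.0, 3.0, 7.0
        params = MaterialParams(k=1.0, exponent=1, nu=0.0, E_cement=50000.0)
        model = build_model(assign_materials(bvtv, lab, params))
        mod = model.element_modulus.copy()
        mod[(model.element_label == LABEL_BONE)
            & (model.element_cells[:, 1] == 1)] = E1
        mod[(model.element_label == LABEL_BONE)
            & (model.element_cells[:, 1] == 6)] = E2
        model = model.with_modulus(mod)
        y0 = 3.1
        model = apply_rigid_plate_load(model, (1.0, y0))
        sol = solve(model, tol=1e-10)
        S_fe = stiffness_from_solution(model, sol).stiffness_kN_per_mm

        s = np.array([E1 * 2.0 / L, E2 * 2.0 / L])   # kN/mm, A = 2 mm^2 each
        dy = np.array([1.5 - y0, 6.5 - y0])
        M = np.array([[s.sum(), (s * dy).sum()],
                      [(s * dy).sum(), (s * dy ** 2).sum()]])
        F = model.load_N / 1000.0
        w, theta = np.linalg.solve(M, [F, 0.0])
        assert S_fe == pytest.approx(F / w, rel=0.02)
        # oracle counts downward displacement positive; FE z points up
        assert sol.plate_rotation[0] == pytest.approx(-theta, rel=0.05)


class TestSolve:
    def test_uniform_block_displacement_linear_in_z(self):
        model = centre_loaded(make_block_model((4, 4, 8), E=1.0))
        sol = solve(model)
        z = model.node_coords[:, 2]
        uz = sol.displacement[:, 2]
        coef = np.polyfit(z, uz, 1)
        np.testing.assert_allclose(uz, np.polyval(coef, z), atol=1e-10)

    def test_energy_identity(self):
        model = make_block_model((3, 4, 5), nu=0.3)
        model = apply_rigid_plate_load(model, (1.1, 2.6))
        sol = solve(model, tol=1e-12)
        K = model.assemble()
        u = sol.displacement.ravel()
        strain_energy = 0.5 * u @ (K @ u)
        external_work = 0.5 * (model.load_N / 1000.0) * abs(sol.plate_translation[2])
        assert strain_energy == pytest.approx(external_work, rel=1e-8)

    def test_cg_matches_dense_direct_solve(self):
        rng = np.random.default_rng(8)
        shape = (5, 5, 5)  # 125 elements
        modulus = rng.uniform(0.05, 2.0, 125)
        model = make_block_model(shape, nu=0.3)
        model = model.with_modulus(modulus)
        model = apply_rigid_plate_load(model, (1.7, 3.1))
        sol = solve(model, tol=1e-12)
        K = model.assemble()
        T, _ = _constraint_transform(model)
        Kr = (T.T @ K @ T).toarray()
        F = np.zeros(Kr.shape[0])
        F[-4] = -model.load_N / 1000.0
        u_dense = (T @ np.linalg.solve(Kr, F)).reshape(-1, 3)
        scale = np.abs(u_dense).max()
        np.testing.assert_allclose(sol.displacement, u_dense, atol=1e-6 * scale)

    def test_solve_is_deterministic(self):
        model = centre_loaded(make_block_model((3, 3, 4), nu=0.3))
        u1 = solve(model).displacement
        u2 = solve(model).displacement
        assert np.array_equal(u1, u2)

    def test_stiffness_monotone_in_element_modulus(self):
        model = centre_loaded(make_block_model((3, 3, 4), nu=0.3))
        S0 = stiffness_from_solution(model, solve(model)).stiffness_kN_per_mm
        for e in [0, 17, 35]:
            mod = model.element_modulus.copy()
            mod[e] *= 1.5
            S = stiffness_from_solution(
                model, solve(model.with_modulus(mod))).stiffness_kN_per_mm
            assert S >= S0 - 1e-12

    def test_homogeneity_in_all_moduli(self):
        model = centre_loaded(make_block_model((3, 3, 4), nu=0.3))
        S1 = stiffness_from_solution(model, solve(model)).stiffness_kN_per_mm
        S2 = stiffness_from_solution(
            model, solve(model.with_modulus(2.5 * model.element_modulus))
        ).stiffness_kN_per_mm
        assert S2 == pytest.approx(2.5 * S1, rel=1e-9)


class TestStiffnessResult:
    def test_uniform_column_recovers_modulus(self):
        # E = 1 GPa, A = 100 mm^2, L = 20 mm -> S = 5 kN/mm, E_app = 1 GPa
        model = centre_loaded(make_block_model((4, 4, 8), E=1.0, spacing=2.5))
        res = stiffness_from_solution(model, solve(model), height_mm=20.0,
                                      area_mm2=100.0)
        assert res.stiffness_kN_per_mm == pytest.approx(5.0, rel=1e-8)
        assert res.apparent_modulus_MPa == pytest.approx(1000.0, rel=1e-8)

    def test_two_layer_series_harmonic_mean(self):
        shape = (4, 4, 8)
        model = make_block_model(shape, E=1.0)
        mod = model.element_modulus.copy()
        mod[model.element_cells[:, 2] >= 4] = 2.0
        model = centre_loaded(model.with_modulus(mod))
        res = stiffness_from_solution(model, solve(model, tol=1e-12))
        A, L1, L2 = 16.0, 4.0, 4.0
        S_expected = 1.0 / (L1 / (1.0 * A) + L2 / (2.0 * A))
        assert res.stiffness_kN_per_mm == pytest.approx(S_expected, rel=1e-8)

    def test_apparent_modulus_arithmetic(self):
        model = centre_loaded(make_block_model((4, 4, 8)))
        sol = solve(model)
        res = stiffness_from_solution(model, sol, height_mm=20.0, area_mm2=400.0)
        S = res.stiffness_kN_per_mm
        assert res.apparent_modulus_MPa == pytest.approx(S * 20 / 400 * 1000)

    def test_stiffness_concave_increasing_in_k(self, human_phantom):
        from vertemech.calibrate import CalibrationProblem, SpecimenModel
        _, _, truth = human_phantom
        m = SpecimenModel(id="h", bvtv=truth.bvtv_coarse,
                          labels=truth.labels_coarse, measured_stiffness=1.0,
                          height_mm=truth.height_mm, area_mm2=truth.area_mm2)
        prob = CalibrationProblem([m], MaterialParams(k=1.0, exponent=1))
        ks = np.array([0.2, 0.5, 0.8])
        S = np.array([prob.predictions(k)[0] for k in ks])
        assert np.all(np.diff(S) > 0)
        assert S[1] >= 0.5 * (S[0] + S[2])  # concave on an arithmetic grid
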