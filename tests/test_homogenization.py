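"""Fabric-elasticity relations: the volume-fraction functions, stiffness
assembly (with an independent term-by-term oracle), engineering constants,
tensor rotation, directional modulus and the constants audit."""

import numpy as np
import pytest

import bonefab as bf
from bonefab.homogenization import (
    compliance_voigt_to_tensor,
    modulus_surface,
    stiffness_tensor_to_voigt,
    stiffness_voigt_to_tensor,
)

# cohort-mean fabric in axis order (x', y', z'): normalized eigenvalues of
# A = M^(-1/2) from the mean M eigenvalues (0.326, 0.617, 0.731)
_A = np.array([0.326, 0.617, 0.731]) ** -0.5
MEAN_LAM = (_A / _A.sum())[::-1].copy()


def _assemble_oracle(lam, bv_tv, k, et):
    """Independent, literally-indexed transcription of the orthotropic
    constants: c_iiii, c_iijj, c_ijij built element by element."""
    l1, l2, l3 = lam
    ii = l1 * l2 + l1 * l3 + l2 * l3
    k1, k2, k3, k4, k5, k6, k7, k8, k9 = k
    c = np.zeros((6, 6))
    lam = [l1, l2, l3]
    for i in range(3):
        li = lam[i]
        c[i, i] = et * (
            k1 + 2 * k6 + (k2 + 2 * k7) * ii + 2 * (k3 + 2 * k8) * li
            + (2 * k4 + k5 + 4 * k9) * li * li
        )
    pairs = {(0, 1): 5, (0, 2): 4, (1, 2): 3}
    for (i, j), v in pairs.items():
        li, lj = lam[i], lam[j]
        c[i, j] = c[j, i] = et * (
            k1 + k2 * ii + k3 * (li + lj) + k4 * (li * li + lj * lj) + k5 * li * lj
        )
        c[v, v] = et * (k6 + k7 * ii + k8 * (li + lj) + k9 * (li * li + lj * lj))
    return c


class TestKFunctions:
    def test_limits_at_zero_and_one(self, printed):
        np.testing.assert_allclose(bf.k_functions(0.0, printed), printed.k_a)
        np.testing.assert_allclose(bf.k_functions(1.0, printed), printed.k_a + printed.k_b)

    def test_worked_value_at_cohort_mean_density(self, printed):
        k = bf.k_functions(0.133, printed)
        assert k[0] == pytest.approx(-6.523e-3 + 6.238e-1 * 0.133**1.6, rel=1e-12)
        assert k[0] == pytest.approx(1.82e-2, abs=5e-4)

    def test_domain_check(self, printed):
        with pytest.raises(ValueError):
            bf.k_functions(-0.1, printed)

    def test_constants_json_round_trip(self, tmp_path, calibrated):
        path = tmp_path / "c.json"
        calibrated.to_json(path)
        back = bf.KabelConstants.from_json(path)
        np.testing.assert_array_equal(back.k_a, calibrated.k_a)
        np.testing.assert_array_equal(back.k_b, calibrated.k_b)
        assert back.p == calibrated.p

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            bf.KabelConstants(k_a=np.ones(8), k_b=np.ones(9))
        with pytest.raises(ValueError):
            bf.KabelConstants(k_a=np.ones(9), k_b=np.ones(9), p=-1)


class TestAssembleStiffness:
    def test_matches_term_by_term_oracle(self, calibrated):
        lam = np.array([0.25, 0.33, 0.42])
        e = bf.assemble_stiffness(lam, 0.15, calibrated, order_by_stiffness=False)
        k = bf.k_functions(0.15, calibrated)
        oracle = _assemble_oracle(lam, 0.15, k, calibrated.tissue_modulus_gpa)
        np.testing.assert_allclose(e.c_voigt, oracle, rtol=1e-12, atol=1e-12)

    def test_isotropic_fabric_gives_cubic_symmetry(self, calibrated):
        e = bf.assemble_stiffness((1 / 3, 1 / 3, 1 / 3), 0.133, calibrated)
        c = e.c_voigt
        assert c[0, 0] == pytest.approx(c[1, 1]) == pytest.approx(c[2, 2])
        assert c[0, 1] == pytest.approx(c[0, 2]) == pytest.approx(c[1, 2])
        assert c[3, 3] == pytest.approx(c[4, 4]) == pytest.approx(c[5, 5])

    def test_lambda_permutation_permutes_axes(self, calibrated):
        lam = np.array([0.25, 0.33, 0.42])
        a = bf.assemble_stiffness(lam, 0.15, calibrated, order_by_stiffness=False)
        b = bf.assemble_stiffness(lam[[1, 0, 2]], 0.15, calibrated, order_by_stiffness=False)
        # swapping lambda_1 and lambda_2 swaps axes 1 and 2 of the stiffness
        assert b.c_voigt[0, 0] == pytest.approx(a.c_voigt[1, 1])
        assert b.c_voigt[1, 1] == pytest.approx(a.c_voigt[0, 0])
        assert b.c_voigt[2, 2] == pytest.approx(a.c_voigt[2, 2])
        assert b.c_voigt[3, 3] == pytest.approx(a.c_voigt[4, 4])
        assert b.c_voigt[4, 4] == pytest.approx(a.c_voigt[3, 3])
        assert b.c_voigt[5, 5] == pytest.approx(a.c_voigt[5, 5])

    def test_symmetry_and_validation(self, calibrated):
        e = bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated)
        np.testing.assert_allclose(e.c_voigt, e.c_voigt.T, atol=1e-12)
        with pytest.raises(ValueError, match="sum"):
            bf.assemble_stiffness((0.5, 0.4, 0.4), 0.133, calibrated)

    def test_non_positive_definite_is_flagged_not_raised(self, printed):
        e = bf.assemble_stiffness(MEAN_LAM, 0.133, printed)
        assert not e.valid
        assert e.warnings and e.warnings[0]["kind"] == "non_positive_definite_stiffness"
        with pytest.raises(ValueError, match="positive definite"):
            bf.engineering_constants(e)

    def test_axes_ordered_by_stiffness(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        assert e.E[0] <= e.E[1] <= e.E[2]  # z' is the stiffest axis


class TestEngineeringConstants:
    def test_isotropic_closed_form_recovery(self):
        e0, nu0 = 15.0, 0.3
        lame = e0 * nu0 / ((1 + nu0) * (1 - 2 * nu0))
        mu = e0 / (2 * (1 + nu0))
        c = np.zeros((6, 6))
        c[:3, :3] = lame
        c[np.diag_indices(3)] = lame + 2 * mu
        c[3, 3] = c[4, 4] = c[5, 5] = mu
        e = bf.OrthotropicElasticity(
            c_voigt=c, tissue_modulus_gpa=15.0, lam=np.full(3, 1 / 3), bv_tv=1.0,
            valid=True, eigen_spectrum=np.linalg.eigvalsh(c),
        )
        bf.engineering_constants(e)
        np.testing.assert_allclose(e.E, e0, rtol=1e-12)
        np.testing.assert_allclose(e.G, mu, rtol=1e-12)
        for v in e.nu.values():
            assert v == pytest.approx(nu0, rel=1e-12)

    def test_poisson_reciprocity(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.15, calibrated))
        ex, ey, ez = e.E
        assert e.nu["yx"] / ey == pytest.approx(e.nu["xy"] / ex, rel=1e-10)
        assert e.nu["zx"] / ez == pytest.approx(e.nu["xz"] / ex, rel=1e-10)
        assert e.nu["zy"] / ez == pytest.approx(e.nu["yz"] / ey, rel=1e-10)

    def test_diagonal_stiffness_has_zero_poisson(self):
        c = np.diag([10.0, 12.0, 14.0, 4.0, 5.0, 6.0])
        e = bf.OrthotropicElasticity(
            c_voigt=c, tissue_modulus_gpa=15.0, lam=np.full(3, 1 / 3), bv_tv=0.5,
            valid=True, eigen_spectrum=np.diag(c),
        )
        bf.engineering_constants(e)
        np.testing.assert_allclose(e.E, [10, 12, 14])
        np.testing.assert_allclose(e.G, [4, 5, 6])
        assert all(v == 0 for v in e.nu.values())

    def test_compliance_reassembly_round_trip(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        s = np.zeros((6, 6))
        ex, ey, ez = e.E
        s[0, 0], s[1, 1], s[2, 2] = 1 / ex, 1 / ey, 1 / ez
        s[3, 3], s[4, 4], s[5, 5] = 1 / e.G[0], 1 / e.G[1], 1 / e.G[2]
        s[0, 1] = s[1, 0] = -e.nu["xy"] / ex
        s[0, 2] = s[2, 0] = -e.nu["xz"] / ex
        s[1, 2] = s[2, 1] = -e.nu["yz"] / ey
        np.testing.assert_allclose(s, e.s_voigt, rtol=1e-10, atol=1e-14)


class TestDirectionalModulus:
    def test_principal_axes_reduce_to_axial_moduli(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        for i, axis in enumerate(np.eye(3)):
            assert bf.directional_modulus(e, axis) == pytest.approx(e.E[i], rel=1e-12)

    def test_isotropic_material_is_direction_independent(self):
        e0, nu0 = 15.0, 0.3
        lame = e0 * nu0 / ((1 + nu0) * (1 - 2 * nu0))
        mu = e0 / (2 * (1 + nu0))
        c = np.zeros((6, 6))
        c[:3, :3] = lame
        c[np.diag_indices(3)] = lame + 2 * mu
        c[3, 3] = c[4, 4] = c[5, 5] = mu
        e = bf.OrthotropicElasticity(
            c_voigt=c, tissue_modulus_gpa=15.0, lam=np.full(3, 1 / 3), bv_tv=1.0,
            valid=True, eigen_spectrum=np.linalg.eigvalsh(c),
        )
        dirs, vals = modulus_surface(e, n_points=1000)
        np.testing.assert_allclose(vals, e0, rtol=1e-10)

    def test_maximum_found_near_stiffest_axis(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        dirs, vals = modulus_surface(e, n_points=10000)
        best = dirs[np.argmax(vals)]
        # directions live in the fabric frame (x', y', z'); z' (index 2) is
        # the stiffest axis by construction
        angle = np.degrees(np.arccos(abs(best[2])))
        assert angle < 3.0

    def test_zero_vector_rejected(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        with pytest.raises(ValueError):
            bf.directional_modulus(e, (0, 0, 0))


class TestRotation:
    def test_identity_is_noop(self, calibrated):
        e = bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated)
        np.testing.assert_allclose(bf.rotate_stiffness(e.c_voigt, np.eye(3)), e.c_voigt, atol=1e-12)

    def test_quarter_turn_permutes_entries(self, calibrated):
        e = bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated)
        r = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # about axis 3
        c_rot = bf.rotate_stiffness(e.c_voigt, r)
        assert c_rot[0, 0] == pytest.approx(e.c_voigt[1, 1], rel=1e-12)
        assert c_rot[1, 1] == pytest.approx(e.c_voigt[0, 0], rel=1e-12)
        assert c_rot[3, 3] == pytest.approx(e.c_voigt[4, 4], rel=1e-12)

    def test_random_rotation_round_trip(self, calibrated, rng):
        e = bf.assemble_stiffness(MEAN_LAM, 0.15, calibrated)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        back = bf.rotate_stiffness(bf.rotate_stiffness(e.c_voigt, q), q.T)
        np.testing.assert_allclose(back, e.c_voigt, atol=1e-10)

    def test_frame_indifference_of_directional_modulus(self, calibrated, rng):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        c_rot = bf.rotate_stiffness(e.c_voigt, q)
        e_rot = bf.OrthotropicElasticity(
            c_voigt=c_rot, tissue_modulus_gpa=15.0, lam=e.lam, bv_tv=e.bv_tv,
            valid=True, eigen_spectrum=np.linalg.eigvalsh(c_rot),
        )
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        assert bf.directional_modulus(e_rot, q @ n) == pytest.approx(
            bf.directional_modulus(e, n), rel=1e-10
        )

    def test_voigt_tensor_conversions_invert(self, calibrated):
        e = bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated)
        np.testing.assert_allclose(
            stiffness_tensor_to_voigt(stiffness_voigt_to_tensor(e.c_voigt)), e.c_voigt
        )
        s4 = compliance_voigt_to_tensor(np.linalg.inv(e.c_voigt))
        # minor symmetries of the compliance tensor
        np.testing.assert_allclose(s4, np.swapaxes(s4, 0, 1), atol=1e-15)
        np.testing.assert_allclose(s4, np.swapaxes(s4, 2, 3), atol=1e-15)

    def test_non_orthonormal_matrix_rejected(self, calibrated):
        e = bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated)
        with pytest.raises(ValueError, match="orthonormal"):
            bf.rotate_stiffness(e.c_voigt, np.ones((3, 3)))


class TestAuditAndCalibration:
    def test_audit_reports_printed_profile_invalid_everywhere(self, printed):
        rep = bf.audit_positive_definiteness(printed)
        assert rep["n_total"] > 50
        assert rep["valid_fraction"] == 0.0
        assert rep["example_offenders"]

    def test_audit_reports_calibrated_profile_mostly_valid(self, calibrated):
        rep = bf.audit_positive_definiteness(calibrated)
        assert 0.0 <= rep["valid_fraction"] <= 1.0
        assert rep["valid_fraction"] > 0.7
        # valid everywhere on the observed density range at the mean fabric
        for bv in np.linspace(0.082, 0.194, 10):
            assert bf.assemble_stiffness(MEAN_LAM, bv, calibrated).valid

    def test_calibrated_profile_reproduces_cohort_mean_constants(self, calibrated):
        e = bf.engineering_constants(bf.assemble_stiffness(MEAN_LAM, 0.133, calibrated))
        et = calibrated.tissue_modulus_gpa
        np.testing.assert_allclose(e.E / et, [13.6e-3, 15.76e-3, 47.60e-3], rtol=0.02)
        np.testing.assert_allclose(e.G / et, [9.80e-3, 8.70e-3, 5.46e-3], rtol=0.05)
        assert e.nu["xy"] == pytest.approx(0.300, abs=0.01)

    def test_calibration_solver_round_trip(self, printed):
        cal = bf.calibrate_kb_from_mean_constants(
            e_over_et=(13.6e-3, 15.76e-3, 47.60e-3),
            g_over_et=(9.80e-3, 8.70e-3, 5.46e-3),
            nu=(0.109, 0.098, 0.300),
            lam=MEAN_LAM,
            bv_tv=0.133,
            base=printed,
        )
        np.testing.assert_array_equal(cal.k_a, printed.k_a)
        e = bf.engineering_constants(
            bf.assemble_stiffness(MEAN_LAM, 0.133, cal, order_by_stiffness=False)
        )
        np.testing.assert_allclose(e.E / 15.0, [13.6e-3, 15.76e-3, 47.60e-3], rtol=0.02)
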