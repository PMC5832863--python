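"""Alignment-tensor construction, SVD fitting, back-calculation, R-factor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solnmr import (AlignmentTensor, BondVectorSet, RdcRecord, back_calculate,
                    extract_vectors, random_unit_vectors, rdc_rfactor,
                    simulate_rdc, svd_fit, tensor_from_da_rhombicity)


def _vecset(n, seed=0, start_id=1):
    return BondVectorSet(np.arange(start_id, start_id + n),
                         random_unit_vectors(n, seed=seed))


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * k @ k


class TestTensorConstruction:
    def test_principal_values(self):
        t = tensor_from_da_rhombicity(7.3, 0.35)
        assert t.da == pytest.approx(7.3, rel=1e-12)
        assert t.rhombicity == pytest.approx(0.35, rel=1e-12)
        assert np.trace(t.saupe) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_preserves_da_and_rhombicity(self):
        t = tensor_from_da_rhombicity(7.3, 0.35, euler_deg=(31.0, 57.0, -12.0))
        assert t.da == pytest.approx(7.3, rel=1e-10)
        assert t.rhombicity == pytest.approx(0.35, rel=1e-10)

    def test_invalid_rhombicity_rejected(self):
        with pytest.raises(ValueError):
            tensor_from_da_rhombicity(7.3, 0.8)

    def test_non_traceless_rejected(self):
        with pytest.raises(ValueError, match="traceless"):
            AlignmentTensor(np.eye(3))


class TestExtractVectors:
    def test_axis_aligned_pair(self):
        model = {1: {"N": np.zeros(3), "H": np.array([0.0, 0.0, 1.02])}}
        # pad with two more residues so geometry is non-trivial
        model[2] = {"N": np.array([3.0, 0, 0]), "H": np.array([3.0, 1.02, 0])}
        vs = extract_vectors(model)
        assert np.allclose(vs.vectors[0], [0, 0, 1])
        assert np.allclose(vs.vectors[1], [0, 1, 0])

    def test_missing_proton_skipped(self):
        model = {1: {"N": np.zeros(3), "H": np.array([0, 0, 1.02])},
                 2: {"N": np.array([3.0, 0, 0])}}  # no H (e.g. proline)
        vs = extract_vectors(model)
        assert list(vs.residue_ids) == [1]

    def test_count_matches_complete_residues(self, small_ensemble):
        vs = extract_vectors(small_ensemble)
        assert len(vs) == len(small_ensemble.residue_ids)

    def test_vectors_rotate_with_structure(self):
        rng = np.random.default_rng(3)
        model = {i: {"N": rng.normal(size=3), "H": rng.normal(size=3)}
                 for i in range(1, 6)}
        rot = _rotation([1, 2, 3], 1.1)
        rotated = {i: {a: rot @ xyz for a, xyz in atoms.items()}
                   for i, atoms in model.items()}
        v0 = extract_vectors(model).vectors
        v1 = extract_vectors(rotated).vectors
        assert np.allclose(v1, v0 @ rot.T, atol=1e-12)

    def test_coincident_atoms_rejected(self):
        model = {1: {"N": np.zeros(3), "H": np.zeros(3)}}
        with pytest.raises(ValueError, match="coincident"):
            extract_vectors(model)


class TestSvdFit:
    def test_zero_couplings_give_zero_tensor(self):
        vs = _vecset(10)
        recs = [RdcRecord(int(r), 0.0) for r in vs.residue_ids]
        t = svd_fit(vs, recs)
        assert t.da == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.saupe, 0.0, atol=1e-12)

    def test_five_couplings_exact_recovery(self):
        truth = tensor_from_da_rhombicity(5.0, 0.2, euler_deg=(10, 40, 70))
        vs = _vecset(5, seed=4)
        recs = simulate_rdc(truth, vs)
        fitted = svd_fit(vs, recs)
        assert np.allclose(fitted.saupe, truth.saupe, atol=1e-9)
        assert all(r.d_calc == pytest.approx(r.d_obs, abs=1e-9) for r in recs)

    def test_paper_tensor_recovery_79_vectors(self):
        """79 seeded random NH vectors, noise-free couplings from
        Da = 7.3 Hz, R = 0.35: the SVD refit returns both exactly."""
        truth = tensor_from_da_rhombicity(7.3, 0.35, euler_deg=(25, 65, -40))
        vs = _vecset(79, seed=20)
        recs = simulate_rdc(truth, vs)
        fitted = svd_fit(vs, recs)
        assert fitted.da == pytest.approx(7.3, abs=1e-6)
        assert fitted.rhombicity == pytest.approx(0.35, abs=1e-6)

    def test_rotational_invariance_of_fit(self):
        truth = tensor_from_da_rhombicity(7.3, 0.35, euler_deg=(25, 65, -40))
        vs = _vecset(30, seed=8)
        recs = simulate_rdc(truth, vs)
        d_obs = [r.d_obs for r in recs]
        rot = _rotation([0.3, -1.0, 0.7], 2.0)
        vs_rot = BondVectorSet(vs.residue_ids, vs.vectors @ rot.T)
        # observed couplings move with the frame: refit from rotated vectors
        # and identically rotated tensor predictions
        recs_rot = [RdcRecord(int(r), d) for r, d in zip(vs.residue_ids, d_obs)]
        t_rot = svd_fit(vs_rot, [RdcRecord(int(r), d) for r, d in zip(
            vs.residue_ids, back_calculate(
                AlignmentTensor(rot @ truth.saupe @ rot.T), vs_rot))])
        assert t_rot.da == pytest.approx(truth.da, rel=1e-9)
        assert t_rot.rhombicity == pytest.approx(truth.rhombicity, rel=1e-8)

    def test_least_squares_optimality(self):
        """The fitted tensor's residual beats random perturbations of it."""
        truth = tensor_from_da_rhombicity(6.0, 0.3, euler_deg=(5, 30, 55))
        vs = _vecset(40, seed=13)
        recs = simulate_rdc(truth, vs, noise_sd=1.0, seed=14)
        fitted = svd_fit(vs, recs)
        d_obs = np.array([r.d_obs for r in recs])
        best = np.sum((d_obs - back_calculate(fitted, vs)) ** 2)
        rng = np.random.default_rng(15)
        for _ in range(25):
            p = rng.normal(0, 0.05, (3, 3))
            p = p + p.T
            p -= np.eye(3) * np.trace(p) / 3
            other = AlignmentTensor(fitted.saupe + p)
            assert np.sum((d_obs - back_calculate(other, vs)) ** 2) >= best

    def test_too_few_records_rejected(self):
        vs = _vecset(4)
        recs = [RdcRecord(int(r), 1.0) for r in vs.residue_ids]
        with pytest.raises(ValueError, match=">= 5"):
            svd_fit(vs, recs)

    def test_degenerate_geometry_rejected(self):
        v = np.tile([0.0, 0.0, 1.0], (6, 1))  # all vectors parallel
        vs = BondVectorSet(np.arange(1, 7), v)
        recs = [RdcRecord(int(r), 1.0) for r in vs.residue_ids]
        with pytest.raises(ValueError, match="rank"):
            svd_fit(vs, recs)

    def test_bootstrap_errors_positive_under_noise(self):
        truth = tensor_from_da_rhombicity(7.3, 0.35, euler_deg=(25, 65, -40))
        vs = _vecset(40, seed=21)
        recs = simulate_rdc(truth, vs, noise_sd=0.5, seed=22)
        _, err = svd_fit(vs, recs, bootstrap=100, seed=23)
        assert err["da_sd"] > 0
        assert err["rhombicity_sd"] > 0


class TestBackCalculate:
    def test_vector_along_z_gives_2da(self):
        t = tensor_from_da_rhombicity(7.3, 0.0)
        vs = BondVectorSet([1], [[0.0, 0.0, 1.0]])
        assert back_calculate(t, vs)[0] == pytest.approx(14.6, rel=1e-12)

    def test_vector_in_xy_plane_axial_tensor(self):
        t = tensor_from_da_rhombicity(7.3, 0.0)
        vs = BondVectorSet([1], [[1.0, 0.0, 0.0]])
        assert back_calculate(t, vs)[0] == pytest.approx(-7.3, rel=1e-12)

    @given(theta=st.floats(0.0, math.pi), phi=st.floats(0.0, 2 * math.pi),
           da=st.floats(-10, 10), rh=st.floats(0.0, 2.0 / 3.0))
    @settings(max_examples=60, deadline=None)
    def test_principal_frame_formula_equals_quadratic_form(self, theta, phi,
                                                           da, rh):
        t = tensor_from_da_rhombicity(da, rh)
        v = np.array([math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi), math.cos(theta)])
        d_quad = v @ t.saupe @ v
        d_pf = da * ((3 * math.cos(theta) ** 2 - 1)
                     + 1.5 * rh * math.sin(theta) ** 2 * math.cos(2 * phi))
        assert d_quad == pytest.approx(d_pf, abs=1e-10)


class TestRFactor:
    def test_perfect_fit_is_zero(self):
        recs = [RdcRecord(i, 3.0, d_calc=3.0) for i in range(1, 8)]
        assert rdc_rfactor(recs) == 0.0

    def test_null_prediction_is_70_71_percent(self):
        recs = [RdcRecord(i, d, d_calc=0.0)
                for i, d in enumerate([3.0, -5.0, 8.0, 1.0, -2.0], 1)]
        assert rdc_rfactor(recs) == pytest.approx(100 / math.sqrt(2), rel=1e-12)

    def test_noise_free_round_trip_below_1e6_percent(self):
        truth = tensor_from_da_rhombicity(7.3, 0.35, euler_deg=(25, 65, -40))
        vs = _vecset(79, seed=20)
        recs = simulate_rdc(truth, vs)
        svd_fit(vs, recs)
        assert rdc_rfactor(recs) < 1e-6

    def test_monotone_in_noise(self):
        truth = tensor_from_da_rhombicity(7.3, 0.35, euler_deg=(25, 65, -40))
        vs = _vecset(60, seed=30)
        rf = []
        for sigma in (0.1, 0.5, 1.5, 4.0):
            recs = simulate_rdc(truth, vs, noise_sd=sigma, seed=31)
            svd_fit(vs, recs)
            rf.append(rdc_rfactor(recs))
        assert all(a < b for a, b in zip(rf, rf[1:]))

    def test_all_zero_observed_rejected(self):
        recs = [RdcRecord(i, 0.0, d_calc=0.0) for i in range(1, 8)]
        with pytest.raises(ValueError, match="zero"):
            rdc_rfactor(recs)
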