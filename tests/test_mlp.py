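"""MLP field evaluation, sums, logP back-calculation and its calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hostguest.mlp import (
    CalibrationError,
    DistanceWeight,
    LogPCalibration,
    MLPField,
    calibrate_logp,
    logp_mlp,
    mlp_at_points,
    mlp_sums,
    read_field_csv,
    write_field_csv,
    write_field_pdb,
)
from hostguest.structures import Atom, FragmentSystem, Molecule

from conftest import random_molecule


def brute_force_mlp(points, mol, constants, weight_fn):
    """Cutoff-free double loop — the reference for the vectorised path."""
    out = np.zeros(len(points))
    for k, p in enumerate(points):
        for f, pos in zip(constants, mol.coordinates):
            out[k] += f * weight_fn(np.linalg.norm(p - pos))
    return out


def make_fs(values: dict[str, float]) -> FragmentSystem:
    return FragmentSystem("test", values)


class TestDistanceWeight:
    def test_exponential_at_zero_and_two(self):
        w = DistanceWeight("exponential", cutoff=np.inf)
        assert w(0.0) == pytest.approx(1.0)
        assert w(2.0) == pytest.approx(math.exp(-1.0))

    def test_hyperbolic(self):
        w = DistanceWeight("hyperbolic", cutoff=np.inf)
        assert w(np.array([0.0, 1.0, 3.0])) == pytest.approx([1.0, 0.5, 0.25])

    def test_cutoff_zeroes_far_contributions(self):
        w = DistanceWeight("exponential", cutoff=5.0)
        assert w(5.1) == 0.0 and w(4.9) > 0.0

    def test_bad_form(self):
        with pytest.raises(ValueError):
            DistanceWeight("gaussian")


class TestMlpAtPoints:
    def test_self_point_equals_constant(self):
        mol = Molecule("m", [Atom("C", np.zeros(3), 1.7, "A")])
        fld = mlp_at_points(np.zeros((1, 3)), mol, make_fs({"A": 1.0}))
        assert fld.values[0] == pytest.approx(1.0)

    def test_symmetric_opposite_constants_cancel(self):
        mol = Molecule("m", [Atom("C", np.array([-2.0, 0, 0]), 1.7, "A"),
                             Atom("C", np.array([+2.0, 0, 0]), 1.7, "B")])
        fld = mlp_at_points(np.zeros((1, 3)), mol, make_fs({"A": 1.0, "B": -1.0}))
        assert fld.values[0] == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_exponential(self):
        mol = Molecule("m", [Atom("C", np.array([2.0, 0, 0]), 1.7, "A")])
        fld = mlp_at_points(np.zeros((1, 3)), mol, make_fs({"A": 0.5}))
        assert fld.values[0] == pytest.approx(0.5 * math.exp(-1.0), rel=1e-12)
        assert fld.values[0] == pytest.approx(0.18394, abs=5e-6)

    def test_empty_points_rejected(self, sevoflurane, fragment_system):
        with pytest.raises(ValueError):
            mlp_at_points(np.empty((0, 3)), sevoflurane, fragment_system)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence_vs_brute_force(self, seed):
        """Finite cutoff beyond every distance reproduces the double loop."""
        rng = np.random.default_rng(seed)
        mol = random_molecule(rng, rng.integers(2, 12))
        pts = rng.normal(scale=6.0, size=(7, 3))
        from hostguest.structures import assign_constants, default_fragment_system
        fs = default_fragment_system()
        f = assign_constants(mol, fs)
        for form in ("exponential", "hyperbolic"):
            w = DistanceWeight(form, cutoff=1e6)
            fld = mlp_at_points(pts, mol, fs, w)
            ref = brute_force_mlp(pts, mol, f, lambda d: float(w(d)))
            np.testing.assert_allclose(fld.values, ref, atol=1e-9)

    def test_linearity_in_constants(self, sevoflurane, fragment_system):
        pts = np.array([[0.0, 0, 0], [3.0, 1, -2]])
        doubled = FragmentSystem("x2", {k: 2 * v for k, v in
                                        fragment_system.constants.items()})
        v1 = mlp_at_points(pts, sevoflurane, fragment_system).values
        v2 = mlp_at_points(pts, sevoflurane, doubled).values
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)

    def test_rigid_motion_invariance(self, sevoflurane, fragment_system):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        t = np.array([-3.0, 9.0, 1.0])
        pts = np.random.default_rng(5).normal(scale=5.0, size=(20, 3))
        v = mlp_at_points(pts, sevoflurane, fragment_system).values
        v_moved = mlp_at_points(pts @ R.T + t, sevoflurane.transformed(R, t),
                                fragment_system).values
        np.testing.assert_allclose(v_moved, v, atol=1e-9)


class TestSumsAndLogP:
    def test_sums_split_signs(self):
        fld = MLPField(np.zeros((3, 3)), [1.0, -2.0, 3.0])
        assert mlp_sums(fld) == (4.0, -2.0)

    def test_all_zero(self):
        assert mlp_sums(MLPField(np.zeros((2, 3)), [0.0, 0.0])) == (0.0, 0.0)

    def test_sums_partition_total(self):
        v = np.random.default_rng(3).normal(size=1000)
        s_plus, s_minus = mlp_sums(MLPField(np.zeros((1000, 3)), v))
        assert s_plus + s_minus == pytest.approx(float(v.sum()), abs=1e-12)

    @pytest.mark.parametrize("sums,calib,expected", [
        ((2.0, -3.0), (1.0, 1.0, 0.0), -1.0),
        ((0.0, 0.0), (0.7, -1.3, 2.5), 2.5),
        ((5.0, -2.0), (0.2, 0.3, -0.1), 0.3),
    ])
    def test_logp_linear_combination(self, sums, calib, expected):
        n_plus = 3
        values = [sums[0] / n_plus] * n_plus + [sums[1]]
        values = [v for v in values if v != 0] or [0.0]
        fld = MLPField(np.zeros((len(values), 3)), values)
        result = logp_mlp(fld, LogPCalibration(*calib))
        assert result == pytest.approx(expected, abs=1e-12)

    def test_default_calibration_warns(self):
        fld = MLPField(np.zeros((1, 3)), [1.0])
        with pytest.warns(UserWarning, match="uncalibrated"):
            logp_mlp(fld)


class TestCalibration:
    @staticmethod
    def synthetic_training(n, w_plus, w_minus, intercept, seed=0):
        rng = np.random.default_rng(seed)
        training = []
        for _ in range(n):
            v = rng.normal(size=12)
            fld = MLPField(np.zeros((12, 3)), v)
            s_plus, s_minus = mlp_sums(fld)
            training.append((fld, w_plus * s_plus + w_minus * s_minus + intercept))
        return training

    def test_exact_recovery_on_noiseless_data(self):
        calib, rss = calibrate_logp(self.synthetic_training(10, 0.4, 0.6, 1.2))
        assert calib.w_plus == pytest.approx(0.4, abs=1e-9)
        assert calib.w_minus == pytest.approx(0.6, abs=1e-9)
        assert calib.intercept_C == pytest.approx(1.2, abs=1e-9)
        assert rss == pytest.approx(0.0, abs=1e-15)

    def test_too_few_records(self):
        with pytest.raises(CalibrationError):
            calibrate_logp(self.synthetic_training(2, 1, 1, 0))

    def test_rank_deficiency_when_one_sign_absent(self):
        training = []
        for i in range(5):
            fld = MLPField(np.zeros((2, 3)), [float(i + 1), 0.5])  # Σ⁻ = 0 always
            training.append((fld, float(i)))
        with pytest.raises(CalibrationError):
            calibrate_logp(training)


class TestFieldIO:
    def test_csv_roundtrip(self, tmp_path):
        fld = MLPField(np.random.default_rng(1).normal(size=(5, 3)),
                       np.random.default_rng(2).normal(size=5), source="t")
        p = tmp_path / "field.csv"
        write_field_csv(fld, p)
        back = read_field_csv(p)
        np.testing.assert_allclose(back.points, fld.points, rtol=1e-12)
        np.testing.assert_allclose(back.values, fld.values, rtol=1e-12)

    def test_pdb_point_cloud_has_bfactor_column(self, tmp_path):
        fld = MLPField([[1.0, 2.0, 3.0]], [0.25])
        p = tmp_path / "field.pdb"
        write_field_pdb(fld, p)
        line = p.read_text().splitlines()[0]
        assert line.startswith("HETATM")
        assert float(line[60:66]) == pytest.approx(0.25)
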