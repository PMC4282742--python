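import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares

import footkin as fk
from footkin.joint_kinematics import COMPONENTS, JOINTS

from .conftest import transform_series


def brute_force_jcs(rrel: np.ndarray) -> np.ndarray:
    """Numerical inversion of the forward JCS composition (independent oracle)."""
    def resid(p):
        return (fk.jcs_compose(*p) - rrel).ravel()

    sol = least_squares(resid, x0=np.zeros(3), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return sol.x


class TestJcsKernel:
    def test_identity(self):
        assert np.allclose(fk.jcs_decompose(np.eye(3), np.eye(3)), (0, 0, 0), atol=1e-12)

    def test_pure_rotation_about_proximal_z(self):
        rd = fk.jcs_compose(30.0, 0.0, 0.0)
        dopl, eveinv, abdadd = fk.jcs_decompose(np.eye(3), rd)
        assert abs(dopl - 30.0) < 1e-9
        assert abs(eveinv) < 1e-9 and abs(abdadd) < 1e-9

    def test_single_axis_components(self):
        for comp, expected in [((0.0, 20.0, 0.0), 1), ((0.0, 0.0, 15.0), 2)]:
            rd = fk.jcs_compose(*comp)
            out = fk.jcs_decompose(np.eye(3), rd)
            assert np.allclose(out, comp, atol=1e-9), (comp, out)

    @given(seed=st.integers(0, 5000))
    def test_compose_decompose_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-89.0, 89.0, 3)
        out = fk.jcs_decompose(np.eye(3), fk.jcs_compose(*angles))
        assert np.abs(np.asarray(out) - angles).max() < 1e-9

    def test_matches_brute_force_inversion(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            angles = rng.uniform(-45.0, 45.0, 3)
            rrel = fk.jcs_compose(*angles)
            ours = np.asarray(fk.jcs_decompose(np.eye(3), rrel))
            oracle = brute_force_jcs(rrel)
            assert np.abs(ours - oracle).max() < 1e-6

    def test_gimbal_warning(self):
        rd = fk.jcs_compose(10.0, 5.0, 90.0)
        with pytest.warns(RuntimeWarning):
            fk.jcs_decompose(np.eye(3), rd)


class TestJointSeries:
    def test_static_trial_constant_and_matches_calibration(self, static_series, calib):
        joints = fk.compute_joint_series(static_series)
        assert [j.joint for j in joints] == list(JOINTS)
        for js in joints:
            for comp in COMPONENTS:
                vals = js.component(comp)
                assert np.nanstd(vals) < 1e-9
                key = f"{js.joint}_{comp}"
                if key in calib.static_angles and key != "Sha-Cal_eveinv":
                    assert abs(vals[0] - calib.static_angles[key]) < 1e-9

    def test_prescribed_curves_recovered(self, template):
        curves = {"Sha-Cal": {"dopl": [(15.0, 1, 0.0)]}}
        spec = fk.SimSpec(n_cycles=2, curves=curves, seed=2)
        series, truth = fk.generate_trial(template, spec)
        joints = {j.joint: j for j in fk.compute_joint_series(series)}
        sc = joints["Sha-Cal"]
        gt = truth.joint_angles["Sha-Cal"]
        rec = np.column_stack([sc.dopl, sc.eveinv, sc.abdadd])
        assert np.sqrt(np.nanmean((rec - gt) ** 2)) < 0.1
        # the prescribed 15-deg sinusoid appears as deviation from static
        dev = sc.dopl - np.nanmean(gt[:, 0])
        assert abs((dev.max() - dev.min()) / 2 - 15.0) < 0.2

    def test_invariant_to_global_rigid_motion(self, walking):
        series, _ = walking
        rng = np.random.default_rng(5)
        from .conftest import random_rotation

        moved = transform_series(series, random_rotation(rng, 60.0), rng.uniform(-2000, 2000, 3))
        a = fk.compute_joint_series(series)
        b = fk.compute_joint_series(moved)
        for ja, jb in zip(a, b):
            for comp in COMPONENTS:
                assert np.nanmax(np.abs(ja.component(comp) - jb.component(comp))) < 1e-9


class TestPlanarAngles:
    def _flat_foot_series(self, extra=None):
        markers = {
            "CA": [0.0, 50.0, 0.0], "FMH": [160.0, 50.0, -30.0], "VMH": [160.0, 50.0, 30.0],
            "FMB": [100.0, 50.0, -30.0], "SMB": [100.0, 50.0, 0.0], "SMH": [165.0, 50.0, 0.0],
            "VMB": [95.0, 50.0, 30.0], "PM": [190.0, 50.0, -32.0],
        }
        if extra:
            markers.update(extra)
        labels = list(markers)
        data = np.array([[markers[k] for k in labels]], dtype=float)
        return fk.MarkerFrameSeries(labels=labels, data=data, rate=100.0)

    def test_vector_parallel_to_ground_gives_zero_pitch(self):
        s = self._flat_foot_series()
        out = {p.name: p.values for p in fk.compute_planar_angles(s)}
        assert abs(out["F2G"][0]) < 1e-9
        assert abs(out["S2G"][0]) < 1e-9

    def test_parallel_rays_give_zero_transverse_angle(self):
        s = self._flat_foot_series()
        out = {p.name: p.values for p in fk.compute_planar_angles(s)}
        # 1st ray (60,0,0) vs 2nd ray (65,0,0): parallel in the ground plane
        assert abs(out["S2F"][0]) < 1e-9

    def test_constructed_ten_degree_pitch(self):
        fmh = np.array([160.0, 50.0, -30.0])
        fmb = fmh - 80.0 * np.array([np.cos(np.radians(10)), np.sin(np.radians(10)), 0.0])
        s = self._flat_foot_series({"FMB": fmb.tolist()})
        out = {p.name: p.values for p in fk.compute_planar_angles(s)}
        assert abs(out["F2G"][0] - 10.0) < 1e-6

    def test_medial_deviation_sign(self):
        # rotate the 1st ray 5 deg toward medial (-Z) in the ground plane
        fmh = [100.0 + 60 * np.cos(np.radians(5)), 50.0, -30.0 - 60 * np.sin(np.radians(5))]
        s = self._flat_foot_series({"FMH": [160.0, 50.0, -30.0]})
        s2 = self._flat_foot_series({"FMH": fmh, "VMH": [160.0, 50.0, 30.0]})
        out = {p.name: p.values for p in fk.compute_planar_angles(s2)}
        assert out["S2F"][0] > 4.0  # medial deviation positive

    def test_ground_referenced_invariance(self, walking, calib):
        """Vertical-axis rotation + horizontal translation leave planar angles."""
        series, _ = walking
        th = np.radians(73.0)
        r = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]])
        moved = transform_series(series, r, [500.0, 0.0, -300.0])
        a = {p.name: p.values for p in fk.compute_planar_angles(series, calib)}
        b = {p.name: p.values for p in fk.compute_planar_angles(moved, calib)}
        for name in ("F2G", "S2G", "V2G", "S2F", "S2V", "MLA"):
            assert np.nanmax(np.abs(a[name] - b[name])) < 1e-9, name


class TestMla:
    def _mla_series(self, st_y, cap_y=0.0):
        """Foot heading +X; CA directly above the heel so CAp = origin."""
        markers = {
            "CA": [0.0, 60.0, 0.0], "PT": [40.0, 30.0, 20.0], "ST": [60.0, st_y, -25.0],
            "FMH": [120.0, 0.0, -30.0], "VMH": [120.0, 0.0, 30.0],
        }
        labels = list(markers)
        data = np.array([[markers[k] for k in labels]] * 2, dtype=float)
        series = fk.MarkerFrameSeries(labels=labels, data=data, rate=100.0, trial_kind="static")
        _, cap_local = fk.define_cap_point(series)
        calib = fk.StaticCalibration(side="right", hindfoot_frontal_offset=0.0,
                                     cap_local=cap_local)
        return series, calib

    def test_collinear_gives_180(self):
        # CAp=(0,0), FMH drops to y=0 at x=120; ST on the chord at (60, 0)
        series, calib = self._mla_series(st_y=0.0)
        mla = fk.compute_mla(series, calib)
        assert abs(mla.values[0] - 180.0) < 1e-9

    def test_worked_triangle(self):
        """CAp=(-60,0), ST=(0,30), FMH=(60,0) in sagittal coordinates -> 126.87 deg."""
        markers = {
            "CA": [0.0, 50.0, 0.0], "PT": [30.0, 25.0, 20.0], "ST": [60.0, 30.0, 0.0],
            "FMH": [120.0, 0.0, -30.0], "VMH": [120.0, 0.0, 30.0],
        }
        labels = list(markers)
        data = np.array([[markers[k] for k in labels]], dtype=float)
        series = fk.MarkerFrameSeries(labels=labels, data=data, rate=100.0, trial_kind="static")
        _, cap_local = fk.define_cap_point(series)
        calib = fk.StaticCalibration(side="right", hindfoot_frontal_offset=0.0,
                                     cap_local=cap_local)
        mla = fk.compute_mla(series, calib)
        expected = np.degrees(np.arccos(-0.6))  # 126.8699 deg
        assert abs(mla.values[0] - expected) < 1e-6

    def test_dropped_st_gives_reflex_angle(self):
        # chord from CAp to FMH sits at y = 0 at the ST station, so +/-30 mm
        # puts ST symmetrically above (arched) and below (dropped) the chord
        s_lo, c_lo = self._mla_series(st_y=-30.0)
        s_hi, c_hi = self._mla_series(st_y=30.0)
        mla_lo = fk.compute_mla(s_lo, c_lo).values[0]
        mla_hi = fk.compute_mla(s_hi, c_hi).values[0]
        assert abs((mla_lo - 180.0) + (mla_hi - 180.0)) < 1e-9  # mirror symmetry
        assert mla_lo > 180.0 > mla_hi

    @pytest.mark.parametrize("n_heights", [50])
    def test_monotone_decreasing_in_arch_height(self, n_heights):
        heights = np.linspace(1.0, 55.0, n_heights)
        values = [fk.make_template(arch_height_mm=h).static_mla() for h in heights]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_mirrored_left_side_identical(self, template):
        spec = fk.SimSpec(n_cycles=2, seed=9)
        right, _ = fk.generate_trial(template, spec, side="right")
        left, _ = fk.generate_trial(template, spec, side="left")
        a = fk.compute_joint_series(right)
        b = fk.compute_joint_series(left)
        for ja, jb in zip(a, b):
            for comp in COMPONENTS:
                assert np.nanmax(np.abs(ja.component(comp) - jb.component(comp))) < 1e-9
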