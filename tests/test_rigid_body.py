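import numpy as np
import pytest
from scipy.optimize import minimize

from osteokin import ConfigError, DegenerateFitError, FormatError, UnusableBodyError
from osteokin import rigid_body as rb
from osteokin._geometry import apply_hom, hom, rot_axis, rot_z

RNG = np.random.default_rng(20240917)

TETRA = np.array([
    [0.0, 0.0, 0.0],
    [2.0, 0.0, 0.0],
    [0.0, 2.0, 0.0],
    [0.0, 0.0, 2.0],
])


def _random_transform(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return hom(rot_axis(axis, rng.uniform(-np.pi, np.pi)), rng.uniform(-5, 5, 3))


# ---------------------------------------------------------------------------
# points CSV


class TestPointsCSV:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a_X,a_Y,a_Z\n1,2,3\n4,5,6\n")
        mset = rb.read_points_csv(p, fps=150.0)
        assert mset.coords.shape == (2, 1, 3)
        assert mset.fps == 150.0
        np.testing.assert_array_equal(mset.get("a"), [[1, 2, 3], [4, 5, 6]])

    def test_nan_marks_untracked(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a_X,a_Y,a_Z\n1,2,3\n,,\n1,2,3\nNaN,NaN,NaN\n")
        mset = rb.read_points_csv(p)
        np.testing.assert_array_equal(mset.present("a"), [True, False, True, False])

    def test_round_trip_500_frames(self, tmp_path, clean_strike):
        mset, _ = clean_strike
        path = tmp_path / "points.csv"
        rb.write_points_csv(mset, path)
        back = rb.read_points_csv(path, fps=mset.fps)
        assert back.markers == mset.markers
        assert np.nanmax(np.abs(back.coords - mset.coords)) < 1e-9

    def test_non_triple_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a_X,a_Y,b_Z\n1,2,3\n")
        with pytest.raises(FormatError, match="b_Z"):
            rb.read_points_csv(p)

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a_X,a_Y\n1,2\n")
        with pytest.raises(FormatError):
            rb.read_points_csv(p)


class TestTransformsCSV:
    def test_round_trip(self, clean_poses, tmp_path):
        series = clean_poses["lower_jaw"]
        path = tmp_path / "jaw.csv"
        rb.write_transforms_csv(series, path)
        back = rb.read_transforms_csv(path, fps=series.fps)
        assert back.body == "lower_jaw"
        np.testing.assert_allclose(back.transforms, series.transforms, atol=1e-9)

    def test_row_vector_dialect_puts_translation_in_fourth_row(self, tmp_path):
        T = hom(rot_z(0.3), [1.0, 2.0, 3.0])
        series = rb.PoseSeries("b", T[None], np.zeros(1), np.ones(1, bool), 500.0)
        path = tmp_path / "b.csv"
        rb.write_transforms_csv(series, path)
        row = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(row.reshape(4, 4)[3, :3], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# rigid transform estimation


class TestEstimateRigidTransform:
    def test_identity_on_equal_sets(self):
        T, resid = rb.estimate_rigid_transform(TETRA, TETRA)
        np.testing.assert_allclose(T, np.eye(4), atol=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generator_transform(self):
        # 90 deg about z plus (1, 2, 3) translation
        T_true = hom(rot_z(np.pi / 2), [1.0, 2.0, 3.0])
        T, resid = rb.estimate_rigid_transform(TETRA, apply_hom(T_true, TETRA))
        np.testing.assert_allclose(T, T_true, atol=1e-10)
        assert resid < 1e-10

    def test_monte_carlo_rotation_error(self):
        # 4 markers spanning ~3 cm, sigma = 0.01 cm: median error < 0.5 deg
        ref = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [1.0, 1.0, 2.5]], dtype=float
        )
        rng = np.random.default_rng(11)
        errors = []
        for _ in range(1000):
            T_true = _random_transform(rng)
            obs = apply_hom(T_true, ref) + rng.normal(0, 0.01, ref.shape)
            T, _ = rb.estimate_rigid_transform(ref, obs)
            dR = T[:3, :3] @ T_true[:3, :3].T
            errors.append(np.degrees(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1))))
        assert np.median(errors) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            rb.estimate_rigid_transform(TETRA[:2], TETRA[:2])

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateFitError):
            rb.estimate_rigid_transform(line, line)

    def test_never_returns_reflection(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ref = rng.normal(size=(4, 3))
            obs = rng.normal(size=(4, 3))  # pure noise: worst case
            try:
                T, _ = rb.estimate_rigid_transform(ref, obs)
            except DegenerateFitError:
                continue
            assert np.linalg.det(T[:3, :3]) > 0

    def test_matches_brute_force_minimizer(self):
        # independent oracle: direct minimization over axis-angle + translation
        rng = np.random.default_rng(3)

        def cost(params, ref, obs):
            rotvec, t = params[:3], params[3:]
            angle = np.linalg.norm(rotvec)
            R = np.eye(3) if angle < 1e-12 else rot_axis(rotvec / angle, angle)
            return np.sum((ref @ R.T + t - obs) ** 2)

        for _ in range(10):
            ref = rng.normal(size=(4, 3)) * 2
            if rb._is_collinear(ref):
                continue
            T_true = _random_transform(rng)
            obs = apply_hom(T_true, ref) + rng.normal(0, 0.05, ref.shape)
            T, _ = rb.estimate_rigid_transform(ref, obs)
            best = None
            for _ in range(8):
                x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.uniform(-5, 5, 3)])
                res = minimize(cost, x0, args=(ref, obs), method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-14})
                if best is None or res.fun < best.fun:
                    best = res
            assert cost(best.x, ref, obs) >= 0
            kabsch_cost = np.sum((apply_hom(T, ref) - obs) ** 2)
            assert kabsch_cost <= best.fun + 1e-4

    def test_weights_pull_fit_toward_heavy_point(self):
        obs = TETRA.copy()
        obs[0] += [0.5, 0.0, 0.0]
        w_hi = np.array([100.0, 1.0, 1.0, 1.0])
        T_hi, _ = rb.estimate_rigid_transform(TETRA, obs, w_hi)
        T_lo, _ = rb.estimate_rigid_transform(TETRA, obs, np.ones(4))
        err_hi = np.linalg.norm(apply_hom(T_hi, TETRA[0]) - obs[0])
        err_lo = np.linalg.norm(apply_hom(T_lo, TETRA[0]) - obs[0])
        assert err_hi < err_lo


# ---------------------------------------------------------------------------
# animate_body / fit_body_plane


def _four_marker_body():
    ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], dtype=float)
    return rb.RigidBodyDefinition("blk", ["m1", "m2", "m3", "m4"], ref)


def _make_set(coords, names, fps=500.0):
    return rb.MarkerTrajectorySet(fps=fps, markers=names, coords=coords)


class TestAnimateBody:
    def test_noiseless_synthetic_matches_ground_truth(self, clean_strike, clean_poses):
        _, gt = clean_strike
        series = clean_poses["lower_jaw"]
        np.testing.assert_allclose(
            series.transforms, gt.poses["lower_jaw"], atol=1e-7
        )
        assert series.valid.all()

    def test_redundant_marker_survives_gap(self):
        defn = _four_marker_body()
        rng = np.random.default_rng(0)
        F = 30
        coords = np.tile(defn.reference, (F, 1, 1)) + rng.normal(0, 1e-3, (F, 4, 3))
        coords[5:15, 0, :] = np.nan  # one marker missing for 10 frames
        series = rb.animate_body(defn, _make_set(coords, defn.marker_names))
        assert series.valid.all()

    def test_two_visible_markers_flag_frame_invalid(self):
        defn = _four_marker_body()
        coords = np.tile(defn.reference, (10, 1, 1))
        coords[4, 0, :] = np.nan
        coords[4, 1, :] = np.nan
        series = rb.animate_body(defn, _make_set(coords, defn.marker_names))
        assert not series.valid[4]
        assert series.valid[[f for f in range(10) if f != 4]].all()

    def test_never_three_markers_rejected(self):
        defn = _four_marker_body()
        coords = np.full((10, 4, 3), np.nan)
        coords[:, 0, :] = defn.reference[0]
        with pytest.raises(UnusableBodyError):
            rb.animate_body(defn, _make_set(coords, defn.marker_names))

    def test_rotation_blocks_orthonormal(self, clean_poses):
        for series in clean_poses.values():
            for f in np.nonzero(series.valid)[0]:
                R = series.transforms[f, :3, :3]
                assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
                assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_virtual_constraint_points_used(self):
        # 2 real markers + 1 virtual point: still a valid 3-point fit
        ref = np.array([[0, 0, 0], [3, 0, 0]], dtype=float)
        defn = rb.RigidBodyDefinition(
            "vb", ["m1", "m2"], ref,
            virtual_points=[("vp", np.array([0.0, 3.0, 0.0]), 1.0)],
        )
        T_true = hom(rot_z(0.4), [0.5, -0.2, 1.0])
        pts = np.vstack([ref, [[0.0, 3.0, 0.0]]])
        world = apply_hom(T_true, pts)
        coords = np.tile(world, (5, 1, 1))
        series = rb.animate_body(defn, _make_set(coords, ["m1", "m2", "vp"]))
        np.testing.assert_allclose(series.transforms[0], T_true, atol=1e-10)


class TestFitBodyPlane:
    def test_static_plane_gives_identity_relative_motion(self, clean_strike):
        mset, _ = clean_strike
        names = [m for m in mset.markers if m.startswith("bp_")]
        series = rb.fit_body_plane(mset, names)
        assert series.valid.all()
        assert np.nanmax(series.residual) < 1e-9

    def test_too_few_markers_rejected(self, clean_strike):
        mset, _ = clean_strike
        with pytest.raises(DegenerateFitError):
            rb.fit_body_plane(mset, ["bp_v1", "bp_v2"])

    def test_deforming_markers_raise_residual(self):
        rng = np.random.default_rng(2)
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 1]], dtype=float)
        coords = np.tile(base, (20, 1, 1))
        coords[10:] += rng.normal(0, 0.3, coords[10:].shape)  # deformation
        series = rb.fit_body_plane(_make_set(coords, list("abcd")), list("abcd"))
        assert series.residual[15] > series.residual[5]


# ---------------------------------------------------------------------------
# filtering / smoothing


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        x = np.full(300, 5.0)
        np.testing.assert_allclose(rb.lowpass_filter(x, 35.0, 500.0), x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(2000) / 500.0
        x = np.sin(2 * np.pi * 5.0 * t)
        y = rb.lowpass_filter(x, 35.0, 500.0)
        core = slice(200, -200)
        amp = (y[core].max() - y[core].min()) / 2
        assert amp == pytest.approx(1.0, rel=0.01)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (len(x[core]) - 1)
        assert lag == 0

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(2000) / 500.0
        x = np.sin(2 * np.pi * 100.0 * t)
        y = rb.lowpass_filter(x, 35.0, 500.0)
        assert np.abs(y[200:-200]).max() < 0.2

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            rb.lowpass_filter(np.zeros(300), 260.0, 500.0)

    def test_zero_phase_symmetric_impulse_response(self):
        x = np.zeros(801)
        x[400] = 1.0
        y = rb.lowpass_filter(x, 35.0, 500.0)
        np.testing.assert_allclose(y, y[::-1], atol=1e-9)

    def test_filters_vector_series_along_time(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(400, 2, 3))
        y = rb.lowpass_filter(x, 35.0, 500.0)
        assert y.shape == x.shape
        np.testing.assert_allclose(
            y[:, 1, 2], rb.lowpass_filter(x[:, 1, 2], 35.0, 500.0)
        )


class TestSmoothTrajectoryPoly:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(100, dtype=float)
        x = 0.3 * t**2 - 2 * t + 7
        y = rb.smooth_trajectory_poly(x, 11, 2)
        np.testing.assert_allclose(y, x, atol=1e-8)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(1).normal(size=50)
        np.testing.assert_array_equal(rb.smooth_trajectory_poly(x, 1, 0), x)

    def test_noise_on_line_reduced(self):
        rng = np.random.default_rng(4)
        t = np.arange(500, dtype=float)
        true = 0.01 * t
        noisy = true + rng.normal(0, 0.05, t.shape)
        smoothed = rb.smooth_trajectory_poly(noisy, 11, 1)
        rms = lambda e: np.sqrt(np.mean(e**2))
        assert rms(smoothed - true) <= rms(noisy - true) / 2

    def test_order_ge_window_rejected(self):
        with pytest.raises(ConfigError):
            rb.smooth_trajectory_poly(np.zeros(10), 5, 5)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            rb.smooth_trajectory_poly(np.zeros(10), 4, 1)


# ---------------------------------------------------------------------------
# precision


class TestMarkerPrecision:
    def test_noiseless_static_all_zero(self, rig):
        from osteokin import synthetic_rig as sr

        mset = sr.simulate_frozen(rig, n_frames=50, noise_sigma=0.0)
        bodies = {"neurocranium": [f"neuro_{i}" for i in range(1, 6)]}
        report = rb.marker_precision(mset, bodies)
        assert report.mean == pytest.approx(0.0, abs=1e-12)
        assert report.max == pytest.approx(0.0, abs=1e-12)

    def test_distance_std_approaches_sigma_sqrt2(self):
        # two markers far apart: distance std -> sigma * sqrt(2)
        rng = np.random.default_rng(8)
        F, sigma = 10_000, 0.02
        base = np.array([[0, 0, 0], [5, 0, 0]], dtype=float)
        coords = np.tile(base, (F, 1, 1)) + rng.normal(0, sigma, (F, 2, 3))
        report = rb.marker_precision(_make_set(coords, ["a", "b"]), {"bone": ["a", "b"]})
        assert report.mean == pytest.approx(sigma * np.sqrt(2), rel=0.05)

    def test_grand_mean_is_mean_of_body_means(self):
        rng = np.random.default_rng(9)
        base = np.array(
            [[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 0, 0]], dtype=float
        )
        coords = np.tile(base, (5000, 1, 1))
        coords[:, :2] += rng.normal(0, 0.01, (5000, 2, 3))
        coords[:, 2:] += rng.normal(0, 0.05, (5000, 2, 3))
        report = rb.marker_precision(
            _make_set(coords, list("abcd")), {"b1": ["a", "b"], "b2": ["c", "d"]}
        )
        assert report.mean == pytest.approx(
            np.mean([report.body_mean["b1"], report.body_mean["b2"]])
        )
        assert report.body_mean["b2"] > report.body_mean["b1"]

    def test_single_marker_body_skipped_with_warning(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = np.arange(10) * 0.1
        with pytest.warns(UserWarning, match="fewer than 2"):
            report = rb.marker_precision(
                _make_set(coords, ["a", "b"]), {"solo": ["a"], "pair": ["a", "b"]}
            )
        assert "solo" not in report.body_mean


class TestJCSPrecision:
    def test_noiseless_frozen_all_zero(self, rig, body_defs, jcs_set):
        from osteokin import synthetic_rig as sr

        mset = sr.simulate_frozen(rig, n_frames=40, noise_sigma=0.0)
        poses = {b: rb.animate_body(d, mset) for b, d in body_defs.items()}
        j = jcs_set["lower_jaw"]
        stds = rb.jcs_precision(j, poses[j.proximal_body], poses[j.distal_body])
        assert all(v == pytest.approx(0.0, abs=1e-7) for v in stds.values())

    def test_noisy_frozen_positive_and_monotone_in_noise(self, rig, body_defs, jcs_set):
        from osteokin import synthetic_rig as sr

        j = jcs_set["lower_jaw"]
        results = []
        for sigma in (0.029, 0.058):
            mset = sr.simulate_frozen(rig, n_frames=160, noise_sigma=sigma, seed=12)
            poses = {b: rb.animate_body(d, mset) for b, d in body_defs.items()}
            stds = rb.jcs_precision(j, poses[j.proximal_body], poses[j.distal_body])
            assert all(np.isfinite(v) and v > 0 for v in stds.values())
            results.append(stds)
        for ch in results[0]:
            assert results[1][ch] > results[0][ch]
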