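"""Calibration fitting, windowing, receiver selection and multilateration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from conftest import grid_search_position
from pairtrack.localization import (
    CalibrationModel,
    LocalizationConfig,
    _ellipse_from_replicates,
    _solve_replicates,
    assess_accuracy,
    fit_calibration,
    localize_all,
    multilaterate,
    rss_to_distance,
    select_receivers,
    window_rss,
)
from pairtrack.synthetic import (
    MovementParams,
    ObservationModel,
    make_grid,
    simulate_calibration,
    simulate_detections,
    simulate_independent,
)

B0, B1 = -1.27009, -0.03302


def _exact_rss(d: np.ndarray) -> np.ndarray:
    return (np.log10(np.asarray(d, dtype=float)) - B0) / B1


class TestFitCalibration:
    def test_line_through_two_exact_points(self):
        d = np.array([1.0, 10.0])
        calib = pd.DataFrame({"distance_m": d, "rss": _exact_rss(d)})
        model = fit_calibration(calib)
        assert model.b0 == pytest.approx(B0, rel=1e-9)
        assert model.b1 == pytest.approx(B1, rel=1e-9)
        assert model.resid_sd == 0.0
        assert model.d_max == 10.0

    def test_one_distance_rejected(self):
        calib = pd.DataFrame({"distance_m": [10.0] * 5, "rss": [-60, -61, -62, -63, -64.0]})
        with pytest.raises(ValueError):
            fit_calibration(calib)

    def test_constant_rss_singular(self):
        calib = pd.DataFrame({"distance_m": [1.0, 10.0], "rss": [-50.0, -50.0]})
        with pytest.raises(ValueError):
            fit_calibration(calib)

    def test_noisy_fit_reports_residual_spread(self):
        calib = simulate_calibration(obs=ObservationModel(rss_noise_sd=5.0), seed=3)
        model = fit_calibration(calib)
        assert model.resid_sd > 0
        assert model.d_max == 150.0


class TestRssToDistance:
    def test_moderate_signal(self):
        # hand evaluation: 10^(-1.27009 + 3.302) = 107.62 m
        model = CalibrationModel(B0, B1, 0.0, 150.0)
        d_hat, d_se = rss_to_distance(-100.0, model)
        assert d_hat == pytest.approx(107.624, abs=0.01)
        assert d_se == 0.0

    def test_weak_signal_truncated_to_ceiling(self):
        model = CalibrationModel(B0, B1, 0.05, 150.0)
        d_hat, d_se = rss_to_distance(-130.0, model)
        assert d_hat == 150.0
        # s.e. from the delta method on the untruncated prediction
        untrunc = 10 ** (B0 + B1 * -130.0)
        assert untrunc == pytest.approx(1053, rel=0.01)
        assert d_se == pytest.approx(untrunc * np.log(10) * 0.05)

    def test_distance_monotone_and_bounded(self):
        model = CalibrationModel(B0, B1, 0.03, 150.0)
        rss = np.linspace(-140, -20, 200)
        d_hat, _ = rss_to_distance(rss, model)
        assert np.all(np.diff(d_hat) <= 0)  # weaker signal -> farther (until ceiling)
        assert np.all(d_hat <= 150.0)

    def test_nonfinite_rss_rejected(self):
        model = CalibrationModel(B0, B1)
        with pytest.raises(ValueError):
            rss_to_distance(np.nan, model)


class TestWindowRss:
    CONFIG = LocalizationConfig(window=15.0, lag=-5.0)

    def test_mean_within_window(self):
        det = pd.DataFrame(
            {"tag_id": "t", "receiver_id": "R0", "t": [0.0, 1.0, 2.0], "rss": [-60.0, -70.0, -80.0]}
        )
        out = window_rss(det, self.CONFIG)
        assert len(out) == 1
        assert out.loc[0, "mean_rss"] == -70.0
        assert out.loc[0, "n_detections"] == 3

    def test_window_boundary_shifted_five_seconds_early(self):
        # interval k covers [15k-5, 15k+10): t=4 -> 0, t=12 -> 1
        det = pd.DataFrame(
            {"tag_id": "t", "receiver_id": "R0", "t": [4.0, 12.0], "rss": [-60.0, -60.0]}
        )
        out = window_rss(det, self.CONFIG)
        assert sorted(out["interval_index"]) == [0, 1]

    def test_single_detection(self):
        det = pd.DataFrame({"tag_id": "t", "receiver_id": "R0", "t": [3.0], "rss": [-55.0]})
        out = window_rss(det, self.CONFIG)
        assert out.loc[0, "n_detections"] == 1
        assert out.loc[0, "mean_rss"] == -55.0

    def test_empty_input_empty_output(self):
        out = window_rss(pd.DataFrame(columns=["tag_id", "receiver_id", "t", "rss"]), self.CONFIG)
        assert out.empty


class TestSelectReceivers:
    RECEIVERS = pd.DataFrame(
        {"receiver_id": ["A", "B", "C"], "x": [0.0, 150.0, 250.0], "y": [0.0, 0.0, 0.0]}
    )

    def _rows(self, rss):
        return pd.DataFrame(
            {"tag_id": "t", "interval_index": 0, "receiver_id": ["A", "B", "C"],
             "mean_rss": rss, "n_detections": 1}
        )

    def test_retains_receivers_within_radius_of_strongest(self):
        config = LocalizationConfig(retain_radius=200.0)
        kept = select_receivers(self._rows([-50.0, -60.0, -70.0]), self.RECEIVERS, config)
        assert sorted(kept["receiver_id"]) == ["A", "B"]

    def test_all_kept_when_compact(self):
        config = LocalizationConfig(retain_radius=300.0)
        kept = select_receivers(self._rows([-50.0, -60.0, -70.0]), self.RECEIVERS, config)
        assert len(kept) == 3

    def test_tie_broken_by_receiver_id(self):
        config = LocalizationConfig(retain_radius=120.0)
        kept = select_receivers(self._rows([-50.0, -50.0, -70.0]), self.RECEIVERS, config)
        # anchor is A (lexicographic), so C at 250 m is dropped
        assert sorted(kept["receiver_id"]) == ["A"]

    def test_unknown_receiver_rejected(self):
        rows = self._rows([-50.0, -60.0, -70.0]).assign(receiver_id=["A", "B", "ZZ"])
        with pytest.raises(ValueError):
            select_receivers(rows, self.RECEIVERS, LocalizationConfig())


def _estimates(coords, d_hat, d_se=0.0):
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame(
        {
            "receiver_id": [f"R{i}" for i in range(len(coords))],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "d_hat": d_hat,
            "d_se": np.broadcast_to(d_se, len(coords)).astype(float),
        }
    )


class TestMultilaterate:
    COORDS = [(0.0, 0.0), (100.0, 0.0), (0.0, 100.0)]
    TRUE = np.array([30.0, 40.0])
    DISTS = [50.0, np.sqrt(70**2 + 40**2), np.sqrt(30**2 + 60**2)]

    def test_exact_distances_recover_position(self):
        config = LocalizationConfig(n_reps=10, seed=0)
        loc = multilaterate(_estimates(self.COORDS, self.DISTS), config, np.random.default_rng(0))
        assert np.hypot(loc.x - 30, loc.y - 40) < 0.1
        assert loc.ell_a == pytest.approx(0.0, abs=1e-6)
        assert loc.ell_b == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        config = LocalizationConfig(n_reps=5, seed=0)
        loc = multilaterate(_estimates(self.COORDS, self.DISTS), config, np.random.default_rng(0))
        oracle = grid_search_position(np.asarray(self.COORDS), np.asarray(self.DISTS))
        assert np.hypot(loc.x - oracle[0], loc.y - oracle[1]) < 0.1

    def test_two_receivers_insufficient(self):
        config = LocalizationConfig()
        est = _estimates(self.COORDS[:2], self.DISTS[:2])
        assert multilaterate(est, config, np.random.default_rng(0)) is None

    def test_solver_agrees_with_scipy_on_noisy_scenes(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            coords = rng.uniform(0, 300, size=(5, 2))
            truth = rng.uniform(50, 250, size=2)
            dists = np.hypot(*(coords - truth).T) + rng.normal(0, 5, size=5)
            dists = np.maximum(dists, 0.1)
            p0 = coords.mean(axis=0)
            ours = _solve_replicates(coords, dists[None, :], p0)[0]

            def resid(p):
                return np.hypot(*(coords - p).T) - dists

            ref = least_squares(resid, p0).x
            assert np.hypot(*(ours - ref)) < 0.01

    def test_ellipse_axes_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(1)
        cov = np.array([[400.0, 120.0], [120.0, 90.0]])
        pts = rng.multivariate_normal([10, -5], cov, size=2000)
        a, b, theta = _ellipse_from_replicates(pts)
        vals = np.linalg.eigvalsh(np.cov(pts.T))
        assert a == pytest.approx(2 * np.sqrt(vals[1]))
        assert b == pytest.approx(2 * np.sqrt(vals[0]))
        assert a >= b >= 0
        assert 0 <= theta < np.pi


class TestLocalizeAll:
    def _static_scene(self, n_receivers_subset=None):
        receivers = make_grid(450, 400, 150, layout="triangular")
        if n_receivers_subset is not None:
            receivers = receivers.head(n_receivers_subset)
        # near-static tag inside the hull; calibration out to 500 m so no
        # retained receiver is distance-truncated
        track = pd.DataFrame(
            {"tag_id": "tag", "t": np.arange(0, 300, 5.0), "x": 200.0, "y": 180.0}
        )
        obs = ObservationModel(rss_noise_sd=0.0, detection_radius=500.0)
        det = simulate_detections(track, receivers, obs, seed=0)
        calib = simulate_calibration([1, 2, 5, 10, 25, 50, 100, 200, 350, 500], obs, 4, seed=0)
        model = fit_calibration(calib)
        return det, receivers, model, track

    def test_noiseless_scene_recovers_positions(self):
        det, receivers, model, track = self._static_scene()
        locs = localize_all(det, receivers, model, LocalizationConfig(n_reps=10, seed=1))
        assert len(locs) > 0
        acc = assess_accuracy(locs, track.rename(columns={}))
        assert acc["median"] < 1.0

    def test_empty_detections_empty_output(self):
        receivers = make_grid(300, 300, 150, "square")
        model = CalibrationModel(B0, B1)
        det = pd.DataFrame(columns=["tag_id", "receiver_id", "t", "rss"])
        assert localize_all(det, receivers, model, LocalizationConfig()).empty

    def test_two_receivers_never_localize(self):
        det, receivers, model, _ = self._static_scene(n_receivers_subset=2)
        locs = localize_all(det, receivers, model, LocalizationConfig(seed=1))
        assert locs.empty

    def test_more_receivers_not_worse(self):
        # same noisy distance field solved with 3 vs 6 receivers, paired seeds
        rng_truth = np.random.default_rng(5)
        truth = np.array([130.0, 110.0])
        coords6 = np.array(
            [(0, 0), (260, 0), (0, 260), (260, 260), (130, -20), (-20, 130)], dtype=float
        )
        true_d = np.hypot(*(coords6 - truth).T)
        errs = {3: [], 6: []}
        for rep in range(60):
            noisy = np.maximum(true_d + rng_truth.normal(0, 15, size=6), 0.1)
            for k in (3, 6):
                config = LocalizationConfig(n_reps=25, seed=0)
                loc = multilaterate(
                    _estimates(coords6[:k], noisy[:k], d_se=10.0),
                    config,
                    np.random.default_rng(1000 + rep),
                )
                errs[k].append(np.hypot(loc.x - truth[0], loc.y - truth[1]))
        assert np.median(errs[6]) <= np.median(errs[3])


class TestAssessAccuracy:
    def test_perfect_estimates_zero_error(self):
        locs = pd.DataFrame(
            {"tag_id": "t", "t_mid": [10.0, 20.0], "x": [1.0, 2.0], "y": [3.0, 4.0]}
        )
        truth = pd.DataFrame({"tag_id": "t", "t": [10.0, 20.0], "x": [1.0, 2.0], "y": [3.0, 4.0]})
        acc = assess_accuracy(locs, truth)
        assert acc["median"] == 0.0
        assert acc["n"] == 2

    def test_noisy_scene_error_positive_finite(self):
        receivers = make_grid(1224, 1224, 150, "triangular")
        p = MovementParams(center_x=612, center_y=612, sigma_pos=120, tau=120)
        (tr,) = simulate_independent([p], 600, 5, seed=6)
        det = simulate_detections(tr, receivers, ObservationModel(rss_noise_sd=5.0), seed=7)
        model = fit_calibration(simulate_calibration(obs=ObservationModel(rss_noise_sd=0.0), seed=0))
        locs = localize_all(det, receivers, model, LocalizationConfig(n_reps=25, seed=8))
        acc = assess_accuracy(locs, tr)
        assert 0 < acc["median"] < np.inf
        assert acc["q90"] >= acc["median"]

    def test_no_matches_rejected(self):
        locs = pd.DataFrame({"tag_id": "a", "t_mid": [0.0], "x": [0.0], "y": [0.0]})
        truth = pd.DataFrame({"tag_id": "b", "t": [0.0], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError):
            assess_accuracy(locs, truth)
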