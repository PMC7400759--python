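"""Gaussian line-profile diameter estimation: oracles, gates, aggregation."""

import math

import numpy as np
import pytest

from fundusavr.errors import MeasurementRejectedError, SeedOffVesselError
from fundusavr.phantom import (FramePhantomSpec, VesselPhantom,
                               generate_fundus_frame)
from fundusavr.vessels import (FWHM_PER_SIGMA, AVRecord, VesselMeasurement,
                               VesselPoint, VesselSeed, classify_pair,
                               compute_av_series, measure_diameter_at,
                               measure_vessel, summarize_epoch,
                               trace_centerline)


def _tophat_frame(width_px=9, background=0.55, depth=0.25):
    """A frame with a vertical rectangular (top-hat) dark band."""
    img = np.full((256, 256), background)
    c = 128
    half = width_px / 2.0
    xs = np.arange(256)
    img[:, np.abs(xs - c) <= half - 0.5] = background - depth
    return img


def _bruteforce_gaussian_fwhm(ts, vals):
    """Independent oracle: scan sigma/mu on a fine grid, solve the linear
    (offset, amplitude) subproblem exactly, return the FWHM of the best fit."""
    best = (np.inf, None)
    for sigma in np.arange(0.8, 12.0, 0.02):
        for mu in np.arange(-2.0, 2.0, 0.1):
            basis = np.exp(-((ts - mu) ** 2) / (2 * sigma ** 2))
            A = np.vstack([np.ones_like(ts), -basis]).T
            coef, res, *_ = np.linalg.lstsq(A, vals, rcond=None)
            sse = float(res[0]) if len(res) else float(
                np.sum((A @ coef - vals) ** 2))
            if sse < best[0]:
                best = (sse, FWHM_PER_SIGMA * sigma)
    return best[1]


class TestMeasureDiameterAt:
    def test_closed_form_fwhm_identity(self, straight_vessel):
        _, img, _ = straight_vessel(fwhm_px=8.0)
        pt = measure_diameter_at(img, (325.0, 250.0),
                                 math.degrees(math.atan2(200, 350)))
        assert pt.ok
        amplitude, sigma, offset, rmse = pt.fit
        assert pt.diameter_px == pytest.approx(FWHM_PER_SIGMA * sigma, abs=0.0)
        assert pt.diameter_px == pytest.approx(8.0, abs=0.25)
        # the closed form itself: sigma = 3 px corresponds to FWHM 7.0645
        assert FWHM_PER_SIGMA * 3.0 == pytest.approx(7.0645, abs=5e-4)

    def test_flat_profile_rejected_for_low_contrast(self):
        img = np.full((256, 256), 0.5)
        pt = measure_diameter_at(img, (128.0, 128.0), 0.0)
        assert not pt.ok and pt.reason == "low_contrast"

    def test_profile_leaving_frame_rejected(self, straight_vessel):
        _, img, _ = straight_vessel()
        pt = measure_diameter_at(img, (2.0, 2.0), 0.0)
        assert not pt.ok and pt.reason == "out_of_bounds"

    def test_tophat_width_agrees_with_bruteforce_oracle(self):
        img = _tophat_frame(width_px=9)
        pt = measure_diameter_at(img, (128.0, 128.0), 90.0)
        assert pt.ok
        th = math.radians(90.0 + 90.0)
        ts = np.linspace(-12, 12, 25)
        vals = img[128, (128 + ts * math.cos(th)).round().astype(int)]
        oracle = _bruteforce_gaussian_fwhm(ts, vals)
        assert pt.diameter_px == pytest.approx(oracle, rel=0.03)
        assert pt.diameter_px == pytest.approx(9.0, rel=0.15)


class TestTraceCenterline:
    def test_straight_vessel_gives_51_points_on_centerline(self, straight_vessel):
        spec, img, _ = straight_vessel(fwhm_px=8.0)
        pts = trace_centerline(img, VesselSeed((325.0, 250.0), "unknown"))
        assert len(pts) == 51
        (x1, y1), (x2, y2) = spec.vessels[0].centerline
        for (px, py), _tangent in pts:
            # distance to the infinite line through the true centerline
            num = abs((y2 - y1) * px - (x2 - x1) * py + x2 * y1 - y2 * x1)
            assert num / math.hypot(x2 - x1, y2 - y1) < 1.0

    def test_seed_far_from_any_vessel_raises(self, straight_vessel):
        _, img, _ = straight_vessel()
        with pytest.raises(SeedOffVesselError):
            trace_centerline(img, VesselSeed((325.0, 150.0), "unknown"))

    def test_truncated_vessel_stops_at_the_tip(self):
        # vessel starts 10 steps (20 px) behind the seed: 25 forward points,
        # 10 backward on the vessel plus at most a short overshoot at the cap
        spec = FramePhantomSpec(vessels=(VesselPhantom(
            centerline=((300.0, 250.0), (560.0, 250.0)), fwhm_px=8.0,
            contrast=0.25, vclass="venule"),))
        img, _ = generate_fundus_frame(spec, seed=0)
        pts = trace_centerline(img, VesselSeed((320.0, 250.0), "unknown"))
        assert len(pts) == 37  # 25 + 10 + seed + one cap overshoot step
        assert pts[0][0][0] > 290.0  # stopped near the x=300 tip


class TestMeasureVessel:
    def test_noiseless_summary_matches_truth(self, straight_vessel):
        _, img, _ = straight_vessel(fwhm_px=8.0)
        m = measure_vessel(img, VesselSeed((325.0, 250.0), "unknown"))
        assert m.summary_diameter_px == pytest.approx(8.0, abs=0.2)
        assert m.n_ok >= 13
        for p in m.points:
            if p.ok:
                assert p.diameter_px == FWHM_PER_SIGMA * p.fit[1]

    def test_noisy_summary_within_5_percent(self, straight_vessel):
        errs = []
        for seed in range(20):
            _, img, _ = straight_vessel(fwhm_px=8.0, noise_sd=0.02, seed=seed)
            m = measure_vessel(img, VesselSeed((325.0, 250.0), "unknown"))
            errs.append(abs(m.summary_diameter_px - 8.0) / 8.0)
        assert float(np.mean(errs)) < 0.05

    def test_crossing_vessel_points_gated_summary_unbiased(self):
        main = VesselPhantom(centerline=((150.0, 150.0), (500.0, 350.0)),
                             fwhm_px=8.0, contrast=0.25, vclass="venule")
        crosser = VesselPhantom(centerline=((150.0, 350.0), (500.0, 150.0)),
                                fwhm_px=6.0, contrast=0.18, vclass="arteriole")
        img, _ = generate_fundus_frame(FramePhantomSpec(vessels=(main, crosser)), 0)
        m = measure_vessel(img, VesselSeed((290.0, 230.0), "unknown"))
        assert m.rejection_counts.get("high_rmse", 0) >= 1
        assert abs(m.summary_diameter_px - 8.0) / 8.0 < 0.05

    def test_too_few_valid_points_rejected_with_counts(self):
        # a very short vessel stub: trace succeeds near the seed but almost
        # every profile fails, so the whole measurement must be rejected
        spec = FramePhantomSpec(vessels=(VesselPhantom(
            centerline=((310.0, 250.0), (330.0, 250.0)), fwhm_px=6.0,
            contrast=0.25, vclass="venule"),))
        img, _ = generate_fundus_frame(spec, seed=0)
        with pytest.raises(MeasurementRejectedError) as exc:
            measure_vessel(img, VesselSeed((320.0, 250.0), "unknown"),
                           min_ok=30)
        assert sum(exc.value.rejection_counts.values()) >= 0

    def test_monotone_degradation_with_noise(self, straight_vessel):
        levels = [0.0, 0.01, 0.02, 0.04, 0.06]
        xs, ys = [], []
        for lvl in levels:
            for seed in range(8):
                _, img, _ = straight_vessel(fwhm_px=8.0, noise_sd=lvl, seed=seed)
                try:
                    m = measure_vessel(img, VesselSeed((325.0, 250.0), "unknown"))
                    err = abs(m.summary_diameter_px - 8.0)
                except MeasurementRejectedError:
                    err = 8.0  # outright rejection is maximal degradation
                xs.append(lvl)
                ys.append(err)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(xs, ys)
        assert rho >= 0.0


class TestClassifyPair:
    @staticmethod
    def _meas(diam, amp, claimed="unknown"):
        pts = [VesselPoint(position=(0, 0), tangent_deg=0.0, diameter_px=diam,
                           fit=(amp, diam / FWHM_PER_SIGMA, 0.5, 0.001))]
        return VesselMeasurement(vclass=claimed,
                                 seed=VesselSeed((0, 0), claimed),
                                 points=pts, summary_diameter_px=diam, n_ok=1)

    def test_darker_and_wider_is_the_venule(self):
        art, ven = classify_pair(self._meas(10.0, 0.30), self._meas(7.0, 0.20))
        assert ven.summary_diameter_px == 10.0
        assert art.summary_diameter_px == 7.0
        assert ven.vclass == "venule" and art.vclass == "arteriole"

    def test_equal_diameters_darker_wins_venule(self):
        art, ven = classify_pair(self._meas(8.0, 0.20), self._meas(8.0, 0.30))
        assert ven.median_amplitude == 0.30

    def test_consistent_claims_are_honored(self):
        # claims contradict the ranking: the wider/darker vessel is claimed
        # arteriole -- claims win, with a logged notice
        m1 = self._meas(10.0, 0.30, claimed="arteriole")
        m2 = self._meas(7.0, 0.20, claimed="venule")
        art, ven = classify_pair(m1, m2)
        assert art.summary_diameter_px == 10.0 and ven.summary_diameter_px == 7.0


class TestAVSeries:
    def test_constant_video_gives_constant_ratio(self, clean_spec, seed_positions):
        img, _ = generate_fundus_frame(clean_spec, seed=0)
        frames = [(i, img) for i in range(16)]
        pair = (VesselSeed(seed_positions["arteriole"], "arteriole"),
                VesselSeed(seed_positions["venule"], "venule"))
        records = compute_av_series(frames, pair, fps=16)
        assert len(records) == 1
        assert records[0].av_ratio == pytest.approx(0.70, abs=0.02)
        assert records[0].n_frames_used == 16

    def test_equal_vessels_give_unit_ratio(self):
        twins = tuple(VesselPhantom(centerline=cl, fwhm_px=8.0, contrast=0.25,
                                    vclass="venule")
                      for cl in (((150.0, 180.0), (500.0, 180.0)),
                                 ((150.0, 330.0), (500.0, 330.0))))
        img, _ = generate_fundus_frame(FramePhantomSpec(vessels=twins), 0)
        pair = (VesselSeed((325.0, 180.0), "unknown"),
                VesselSeed((325.0, 330.0), "unknown"))
        records = compute_av_series([(0, img)], pair, fps=16)
        assert records[0].av_ratio == pytest.approx(1.0, abs=0.02)

    def test_missing_frames_reduce_n_frames_used(self, clean_spec, seed_positions):
        img, _ = generate_fundus_frame(clean_spec, seed=0)
        # second 0: only 12 of 16 frames survived screening upstream
        frames = [(i, img) for i in range(16) if i not in (3, 7, 11, 15)]
        pair = (VesselSeed(seed_positions["arteriole"], "arteriole"),
                VesselSeed(seed_positions["venule"], "venule"))
        records = compute_av_series(frames, pair, fps=16)
        assert records[0].n_frames_used == 12

    def test_av_ratio_is_scale_invariant(self, clean_spec, seed_positions):
        from skimage.transform import rescale
        img, _ = generate_fundus_frame(clean_spec, seed=0)
        pair = (VesselSeed(seed_positions["arteriole"], "arteriole"),
                VesselSeed(seed_positions["venule"], "venule"))
        r1 = compute_av_series([(0, img)], pair, fps=16)[0].av_ratio
        big = rescale(img, 2.0, anti_aliasing=True)
        pair2 = (VesselSeed(tuple(2 * c for c in seed_positions["arteriole"]),
                            "arteriole"),
                 VesselSeed(tuple(2 * c for c in seed_positions["venule"]),
                            "venule"))
        r2 = compute_av_series([(0, big)], pair2, fps=16,
                               profile_halfwidth_px=24.0)[0].av_ratio
        assert r2 == pytest.approx(r1, rel=0.02)


class TestSummarizeEpoch:
    def _rec(self, sec, ratio):
        return AVRecord(second_index=sec, arteriole_px=7.0, venule_px=10.0,
                        av_ratio=ratio, n_frames_used=16)

    def test_median_av_and_mean_icp(self):
        row = summarize_epoch([self._rec(0, 0.7), self._rec(1, 0.8),
                               self._rec(2, 0.9)], [14.0, 16.0])
        assert row["median_av"] == pytest.approx(0.8)
        assert row["mean_icp_mmHg"] == pytest.approx(15.0)

    def test_single_record_and_even_count_median(self):
        assert summarize_epoch([self._rec(0, 0.73)], [12.0])["median_av"] == 0.73
        row = summarize_epoch([self._rec(0, 0.7), self._rec(1, 0.9)], [10.0])
        assert row["median_av"] == pytest.approx(0.8)
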