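"""2D Gaussian model, R^2 and fitting, against closed forms, brute-force
summation and planted simulations."""

import dataclasses
import math

import numpy as np
import pytest

import cosiquant as cq
from cosiquant.gaussfit import (
    canonical_orientation,
    extract_roi,
    fit_gaussian2d,
    gaussian2d_model,
    r_squared,
)


class TestModel:
    def test_peak_value_is_offset_plus_amplitude(self):
        v = gaussian2d_model(3.0, 4.0, x0=3.0, y0=4.0, sigma_major=2.0,
                             sigma_minor=1.0, theta=0.3, amplitude=50.0, offset=7.0)
        assert v == pytest.approx(57.0)

    def test_isotropic_case_is_rotation_invariant(self):
        vals = [
            gaussian2d_model(5.0, 2.0, 1.0, 1.0, 2.0, 2.0, th, 10.0, 0.0)
            for th in (0.0, 0.4, 1.1, 3.0)
        ]
        assert np.ptp(vals) < 1e-12

    def test_value_one_sigma_along_major_axis(self):
        # at (x0 + s1*cos(t), y0 + s1*sin(t)) the quadratic form equals 1/2
        x0, y0, s1, s2, th, a, off = 1.5, -2.0, 2.5, 1.0, 0.7, 40.0, 3.0
        v = gaussian2d_model(x0 + s1 * math.cos(th), y0 + s1 * math.sin(th),
                             x0, y0, s1, s2, th, a, off)
        assert v == pytest.approx(off + a * math.exp(-0.5), rel=1e-12)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(cq.DomainError):
            gaussian2d_model(0, 0, 0, 0, -1.0, 1.0, 0.0, 1.0, 0.0)


class TestRSquared:
    def test_perfect_model(self):
        d = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert r_squared(d, d) == pytest.approx(1.0)

    def test_mean_model_scores_zero(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(d, np.full(4, d.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SS_res = 1, SS_tot = 5 -> R^2 = 0.8
        assert r_squared(np.array([1.0, 2, 3, 4]),
                         np.array([1.0, 2, 3, 5])) == pytest.approx(0.8)

    def test_zero_variance_data_is_not_computable(self):
        assert math.isnan(r_squared(np.full(9, 2.0), np.zeros(9)))


def test_canonical_orientation_properties():
    s1, s2, th = canonical_orientation(1.0, 3.0, 0.2)
    assert s1 >= s2 and 0 <= th < math.pi
    assert (s1, s2) == (3.0, 1.0)
    # theta and theta + pi describe the same ellipse
    assert canonical_orientation(3.0, 1.0, 0.2 + math.pi)[2] == pytest.approx(0.2)


def _render_spot(ny, nx, **params):
    yy, xx = np.mgrid[0:ny, 0:nx]
    return gaussian2d_model(xx, yy, **params)


class TestFitRecovery:
    def test_noiseless_spot_recovered_exactly(self):
        truth = dict(x0=7.3, y0=7.8, sigma_major=2.0, sigma_minor=2.0,
                     theta=0.4, amplitude=100.0, offset=10.0)
        roi = _render_spot(15, 15, **truth)
        fit = fit_gaussian2d(roi, init_sigma_px=3.0)
        assert fit.converged and fit.r2 >= 0.999999
        assert fit.x0_px == pytest.approx(truth["x0"], abs=1e-3)
        assert fit.y0_px == pytest.approx(truth["y0"], abs=1e-3)
        assert fit.amplitude == pytest.approx(truth["amplitude"], rel=1e-3)
        assert fit.offset == pytest.approx(truth["offset"], rel=1e-3)
        assert fit.integrated_intensity == pytest.approx(
            2 * math.pi * 100.0 * 4.0, rel=1e-3
        )

    def test_integrated_intensity_identity_and_brute_force(self):
        # identity 2*pi*A*s1*s2 holds exactly; numeric summation of the
        # offset-subtracted model over a wide grid agrees within 0.5%
        truth = dict(x0=24.0, y0=25.0, sigma_major=2.6, sigma_minor=1.4,
                     theta=0.9, amplitude=80.0, offset=5.0)
        roi = _render_spot(49, 49, **truth)
        fit = fit_gaussian2d(roi, init_sigma_px=2.0)
        assert fit.integrated_intensity == pytest.approx(
            2 * math.pi * fit.amplitude * fit.sigma_major_px * fit.sigma_minor_px
        )
        brute = float((roi - truth["offset"]).sum())
        assert fit.integrated_intensity == pytest.approx(brute, rel=5e-3)

    def test_poisson_noise_center_and_intensity_tolerances(self):
        # peak SNR ~ 10; tolerances: center 0.2 px, integrated intensity 5%
        truth = dict(x0=7.0, y0=7.0, sigma_major=2.0, sigma_minor=2.0,
                     theta=0.0, amplitude=100.0, offset=10.0)
        clean = _render_spot(15, 15, **truth)
        expected = 2 * math.pi * 100.0 * 4.0
        for seed in range(5):
            noisy = np.random.default_rng(seed).poisson(clean).astype(float)
            fit = fit_gaussian2d(noisy, init_sigma_px=2.0)
            assert fit.converged
            assert math.hypot(fit.x0_px - 7.0, fit.y0_px - 7.0) < 0.2
            assert fit.integrated_intensity == pytest.approx(expected, rel=0.05)

    def test_pure_noise_roi_is_never_accepted(self, config, rng):
        roi = rng.poisson(50.0, size=(15, 15)).astype(float)
        fit = fit_gaussian2d(roi, init_sigma_px=3.0, role="poi")
        assert (not fit.converged) or fit.r2 < min(config.r2_thresholds.values())

    def test_random_noiseless_spots_parameter_recovery(self, rng):
        # 200 random noiseless spots: median center error < 0.01 px and all
        # R^2 > 0.999; parameters recovered to 1e-3 relative.
        errors = []
        for _ in range(200):
            truth = dict(
                x0=7.0 + rng.uniform(-1.5, 1.5), y0=7.0 + rng.uniform(-1.5, 1.5),
                sigma_major=rng.uniform(1.8, 3.5), sigma_minor=None,
                theta=rng.uniform(0, math.pi), amplitude=rng.uniform(50, 400),
                offset=rng.uniform(0, 40),
            )
            truth["sigma_minor"] = truth["sigma_major"] * rng.uniform(0.55, 0.85)
            roi = _render_spot(15, 15, **truth)
            fit = fit_gaussian2d(roi, init_sigma_px=2.5)
            assert fit.converged and fit.r2 > 0.999
            assert fit.amplitude == pytest.approx(truth["amplitude"], rel=1e-3)
            assert fit.sigma_major_px == pytest.approx(truth["sigma_major"], rel=1e-3)
            assert fit.sigma_minor_px == pytest.approx(truth["sigma_minor"], rel=1e-3)
            dth = abs(fit.theta_rad - truth["theta"]) % math.pi
            assert min(dth, math.pi - dth) < 1e-2
            errors.append(math.hypot(fit.x0_px - truth["x0"], fit.y0_px - truth["y0"]))
        assert np.median(errors) < 0.01


class TestRoiAndChannels:
    def test_extract_roi_bounds(self):
        img = np.arange(100.0).reshape(10, 10)
        roi = extract_roi(img, x_px=5, y_px=5, half=2)
        assert roi.shape == (5, 5) and roi[2, 2] == img[5, 5]
        with pytest.raises(cq.DomainError):
            extract_roi(img, x_px=1, y_px=5, half=2)

    def test_fit_all_channels_one_record_per_candidate(self, config, small_spec):
        f, truth = cq.simulate_field(small_spec)
        det = cq.find_candidates(f, config)
        records = cq.fit_all_channels(f, det, config)
        assert len(records) == len(det.candidates)
        assert all(set(r.fits) == set(cq.SYNAPSE_ROLES) for r in records)

    def test_marker_only_spot_fails_poi_filtering(self, config):
        rng = np.random.default_rng(3)
        yy, xx = np.mgrid[0:64, 0:64]
        spot = 300.0 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 1.6**2))
        marker = rng.poisson(spot + 20).astype(float)
        az = rng.poisson(spot + 20).astype(float)
        poi = rng.poisson(np.full((64, 64), 20.0)).astype(float)  # flat noise
        f = cq.ImageField((marker, az, poi), cq.SYNAPSE_ROLES, 160)
        det = cq.find_candidates(f, config)
        assert len(det.candidates) == 1
        rec = cq.filter_records(cq.fit_all_channels(f, det, config), config)[0]
        assert rec.accepted is False
        assert "poi" in rec.reject_reason
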