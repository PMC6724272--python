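"""Sigmoid model fitting, the two-step procedure and derived quantities."""

from __future__ import annotations

import numpy as np
import pytest

import roothairsizer as rhs
from roothairsizer.fit import RootHairSigmoidModel, sigmoid, sigmoid_slope


def _profile_from_arrays(d, L):
    pts = [rhs.ProfilePoint(float(dd), float(ll), "left") for dd, ll in zip(d, L)]
    return rhs.RHProfile(points=pts, w_um=8.0, interval_k=10, scan_range_um=(0, d[-1]))


TRUE = dict(L_noise=10.0, L_max=600.0, d50=2500.0, delta=500.0)


def _exact_data(n=100, lo=0.0, hi=6000.0, **over):
    p = {**TRUE, **over}
    d = np.linspace(lo, hi, n)
    return d, sigmoid(d, p["L_noise"], p["L_max"], p["d50"], p["delta"])


class TestFitSigmoid:
    def test_exact_data_recovered_to_four_digits(self):
        d, L = _exact_data()
        res = RootHairSigmoidModel(d, L).fit()
        p = res.params
        assert p.L_noise == pytest.approx(TRUE["L_noise"], rel=1e-4)
        assert p.L_max == pytest.approx(TRUE["L_max"], rel=1e-4)
        assert p.d50 == pytest.approx(TRUE["d50"], rel=1e-4)
        assert p.delta == pytest.approx(TRUE["delta"], rel=1e-4)
        assert p.r2 >= 0.9999

    def test_model_at_d50_is_the_midpoint(self):
        d, L = _exact_data()
        p = RootHairSigmoidModel(d, L).fit().params
        assert p.predict(p.d50) == pytest.approx((p.L_noise + p.L_max) / 2, rel=1e-12)

    def test_constant_lengths_are_degenerate(self):
        d = np.linspace(0, 100, 20)
        with pytest.raises(ValueError, match="degenerate"):
            RootHairSigmoidModel(d, np.full_like(d, 5.0)).fit()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            RootHairSigmoidModel(np.arange(5.0), np.arange(5.0))

    def test_shift_equivariance(self):
        d, L = _exact_data()
        p0 = RootHairSigmoidModel(d, L).fit().params
        shift = 777.0
        p1 = RootHairSigmoidModel(d + shift, L).fit().params
        assert p1.d50 - p0.d50 == pytest.approx(shift, abs=1e-3)
        for name in ("L_noise", "L_max", "delta"):
            assert getattr(p1, name) == pytest.approx(getattr(p0, name), rel=1e-6)

    def test_exclude_flags_drop_annotated_points(self):
        d, L = _exact_data()
        pts = [rhs.ProfilePoint(float(dd), float(ll), "left") for dd, ll in zip(d, L)]
        for p in pts[:30]:
            p.flags["artefact"] = 1
            p.L_um = 0.0  # corrupt the flagged points
        prof = rhs.RHProfile(points=pts, w_um=8, interval_k=10, scan_range_um=(0, 6000))
        p_fit = rhs.fit_sigmoid(prof, (0, 6000), exclude_flags={"artefact"})
        assert p_fit.L_max == pytest.approx(TRUE["L_max"], rel=1e-3)


class TestTwoStepFit:
    def test_exact_data_second_fit_centred_on_first_d50(self):
        d, L = _exact_data()
        res = RootHairSigmoidModel(d, L).fit_two_step()
        p1, p2 = res.first.params, res.final.params
        centre = 0.5 * (res.requested_range_um[0] + res.requested_range_um[1])
        assert centre == pytest.approx(p1.d50, abs=1e-9)
        for name in ("L_noise", "L_max", "d50", "delta"):
            assert getattr(p2, name) == pytest.approx(getattr(p1, name), rel=1e-4)

    def test_requested_range_is_d50_plus_minus_5_delta(self, rng):
        d = np.linspace(0, 6000, 200)
        L = sigmoid(d, **TRUE) + rng.normal(0, 0.05 * TRUE["L_max"], d.size)
        L = np.clip(L, 0, None)
        res = RootHairSigmoidModel(d, L).fit_two_step()
        p1 = res.first.params
        assert res.requested_range_um[0] == p1.d50 - 5 * p1.delta
        assert res.requested_range_um[1] == p1.d50 + 5 * p1.delta

    def test_second_window_with_too_few_points_fails_in_step_two(self):
        # wide point spacing with a sharp transition: the +/- 5 delta window
        # of the first fit holds almost no data
        d = np.arange(0.0, 1600.0, 100.0)
        L = sigmoid(d, 0.0, 100.0, 750.0, 5.0)
        with pytest.raises(ValueError, match="second fit"):
            RootHairSigmoidModel(d, L).fit_two_step()

    def test_functional_wrapper_returns_results_object(self):
        d, L = _exact_data()
        res = rhs.two_step_fit(_profile_from_arrays(d, L), (0, 6000))
        assert isinstance(res, rhs.TwoStepFitResults)
        assert res.params.L_max == pytest.approx(TRUE["L_max"], rel=1e-4)


class TestTangentGeometry:
    def test_tangent_meets_asymptotes_at_two_delta_each_side(self, rng):
        # exact for every parameter set: slope at d50 is (L_max-L_noise)/(4 delta)
        for _ in range(100):
            L_noise = rng.uniform(0, 50)
            L_max = L_noise + rng.uniform(10, 1000)
            d50 = rng.uniform(100, 5000)
            delta = rng.uniform(10, 1000)
            f0 = sigmoid(d50, L_noise, L_max, d50, delta)
            slope = sigmoid_slope(d50, L_noise, L_max, d50, delta)
            d_lo = d50 + (L_noise - f0) / slope
            d_hi = d50 + (L_max - f0) / slope
            assert abs((d50 - d_lo) / delta - 2.0) < 1e-10
            assert abs((d_hi - d50) / delta - 2.0) < 1e-10
            assert abs((d_hi - d_lo) / delta - 4.0) < 1e-10


class TestNoisyRecovery:
    def test_median_parameter_errors_over_20_seeds(self):
        errs = {"L_max": [], "d50": [], "delta": []}
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = np.linspace(0, 6000, 200)
            L = sigmoid(d, **TRUE) + rng.normal(0, 0.1 * TRUE["L_max"], d.size)
            L = np.clip(L, 0, None)
            res = RootHairSigmoidModel(d, L).fit_two_step()
            p = res.final.params
            for name in errs:
                errs[name].append(abs(getattr(p, name) / TRUE[name] - 1))
            r2s.append(p.r2)
        assert np.median(errs["L_max"]) < 0.05
        assert np.median(errs["d50"]) < 0.05
        assert np.median(errs["delta"]) < 0.20
        assert min(r2s) >= 0.9

    def test_standard_errors_scale_with_noise(self):
        d = np.linspace(0, 6000, 200)
        rng = np.random.default_rng(1)
        res_small = RootHairSigmoidModel(
            d, sigmoid(d, **TRUE) + rng.normal(0, 5, d.size)
        ).fit()
        res_big = RootHairSigmoidModel(
            d, sigmoid(d, **TRUE) + rng.normal(0, 50, d.size)
        ).fit()
        assert np.all(res_big.bse[1:] > res_small.bse[1:])


class TestDerivedParams:
    def test_growth_rate_worked_example(self):
        p = rhs.SigmoidParams(0.0, 600.0, 2500.0, 500.0, 1.0, (0, 6000), 100)
        der = rhs.derive_parameters(p, root_growth_rate_um_h=300.0)
        assert der.rh_growth_rate_um_h == pytest.approx(90.0)
        assert der.growth_region_um == pytest.approx(2000.0)
        assert der.initiation_um == pytest.approx(1500.0)
        assert der.arrest_um == pytest.approx(3500.0)
        assert der.div_elong_zone_um == der.initiation_um

    def test_rate_absent_without_root_rate(self):
        p = rhs.SigmoidParams(5.0, 400.0, 2000.0, 300.0, 0.95, (0, 5000), 80)
        der = rhs.derive_parameters(p)
        assert der.rh_growth_rate_um_h is None
        assert der.arrest_um - der.initiation_um == pytest.approx(der.growth_region_um)

    def test_hand_computed_rates_for_random_parameters(self, rng):
        for _ in range(20):
            L_noise = rng.uniform(0, 50)
            L_max = L_noise + rng.uniform(10, 900)
            delta = rng.uniform(50, 900)
            rate = rng.uniform(50, 400)
            p = rhs.SigmoidParams(L_noise, L_max, rng.uniform(500, 4000), delta,
                                  0.99, (0, 6000), 100)
            der = rhs.derive_parameters(p, rate)
            expected = (L_max - L_noise) / (4 * delta) * rate
            assert abs(der.rh_growth_rate_um_h / expected - 1) < 1e-12


class TestResultsAPI:
    def test_summary_contains_estimates_and_r2(self):
        d, L = _exact_data()
        res = RootHairSigmoidModel(d, L).fit()
        text = res.summary()
        assert "r2" in text and "L_max" in text and "delta" in text

    def test_from_profile_restricts_sides(self):
        d = np.linspace(0, 6000, 60)
        L = sigmoid(d, **TRUE)
        pts = [rhs.ProfilePoint(float(dd), float(ll), "left") for dd, ll in zip(d, L)]
        pts += [rhs.ProfilePoint(float(dd), 0.0, "right") for dd in d]
        prof = rhs.RHProfile(points=pts, w_um=8, interval_k=10, scan_range_um=(0, 6000))
        model = RootHairSigmoidModel.from_profile(prof, sides=("left",))
        assert model.fit().params.L_max == pytest.approx(TRUE["L_max"], rel=1e-4)
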