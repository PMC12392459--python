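import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fastgrowth import (DecisionPolicy, MixtureSpec, StageWorkSet, WorkSet,
                        anderson_darling, convolution_jarzynski,
                        gaussian_estimate, gen_mixture_works, gen_normal_works,
                        gen_stage_works, jarzynski, select_estimator,
                        stage_independence)
from fastgrowth.constants import beta, rt

from .conftest import scipy_ad_oracle

work_lists = st.lists(st.floats(-30, 30), min_size=1, max_size=40)


class TestJarzynski:
    def test_constant_works(self):
        assert jarzynski(WorkSet([2.5] * 3, 300)).dG == pytest.approx(2.5)

    def test_two_value_closed_form(self):
        # oracle: direct evaluation of -RT ln((1 + e^{-beta*1.372})/2)
        b, RT = beta(300), rt(300)
        expected = -RT * math.log((1 + math.exp(-b * 1.372)) / 2)
        assert expected == pytest.approx(0.356, abs=5e-4)
        assert jarzynski(WorkSet([0.0, 1.372], 300)).dG == pytest.approx(expected)

    @given(work_lists, st.floats(-20, 20))
    @settings(max_examples=100, deadline=None)
    def test_shift_covariance(self, works, c):
        base = jarzynski(WorkSet(works, 300)).dG
        shifted = jarzynski(WorkSet([w + c for w in works], 300)).dG
        assert shifted == pytest.approx(base + c, abs=1e-9)

    @given(work_lists)
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_mean_work(self, works):
        ws = WorkSet(works, 300)
        assert jarzynski(ws).dG <= ws.values.mean() + 1e-9

    def test_extreme_values_stable(self):
        # naive exponentiation would overflow; the log-sum-exp path must not
        est = jarzynski(WorkSet([-900.0, -850.0], 300))
        assert np.isfinite(est.dG)
        # the lower work dominates the exponential average: -900 + RT ln 2
        assert est.dG == pytest.approx(-900.0 + rt(300) * math.log(2), abs=1e-9)


class TestGaussianEstimate:
    def test_constant_works(self):
        assert gaussian_estimate(WorkSet([1.2, 1.2], 300)).dG == pytest.approx(1.2)

    def test_hand_example(self):
        # mean 0, unbiased variance 1 at 300 K: dG = -beta/2
        est = gaussian_estimate(WorkSet([-1.0, 0.0, 1.0], 300))
        assert est.dG == pytest.approx(-1.6774 / 2, abs=5e-4)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            gaussian_estimate(WorkSet([1.0], 300))

    def test_large_sample_consistency(self):
        # law of large numbers: estimate -> mu - beta sigma^2/2
        mu, sigma, n = 3.0, 1.5, 100_000
        rng = np.random.default_rng(5)
        ws = WorkSet(mu + sigma * rng.standard_normal(n), 300)
        target = mu - beta(300) * sigma ** 2 / 2
        se = sigma / math.sqrt(n) + beta(300) * sigma ** 2 / math.sqrt(2 * n)
        assert gaussian_estimate(ws).dG == pytest.approx(target, abs=3 * se)


class TestAndersonDarling:
    def test_normal_quantiles_accepted(self):
        q = (np.arange(1, 51) - 0.5) / 50
        from scipy.stats import norm
        ws = WorkSet(norm.ppf(q), 300)
        a = anderson_darling(ws)
        assert a < 0.34
        assert a == pytest.approx(scipy_ad_oracle(ws.values), rel=1e-6)

    def test_exponential_rejected(self):
        rng = np.random.default_rng(42)
        ws = WorkSet(rng.exponential(1.0, 200), 300)
        a = anderson_darling(ws)
        assert a > 0.754
        assert a == pytest.approx(scipy_ad_oracle(ws.values), rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(2.0, 3.0, size=117)
        assert anderson_darling(WorkSet(x, 300)) == pytest.approx(
            scipy_ad_oracle(x), rel=1e-6)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=64)
        a0 = anderson_darling(WorkSet(x, 300))
        a1 = anderson_darling(WorkSet(3.7 * x - 11.0, 300))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            anderson_darling(WorkSet([1.0] * 20, 300))

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="N >= 8"):
            anderson_darling(WorkSet([0.1, 0.2, 0.3], 300))


class TestConvolution:
    def test_single_pair(self):
        st_ = StageWorkSet(WorkSet([2.0], 300), WorkSet([3.0], 300))
        assert convolution_jarzynski(st_).dG == pytest.approx(5.0)

    def test_brute_force_four_pairs(self):
        b, RT = beta(300), rt(300)
        lj = [0.0, 1.372]
        qq = [0.0, 1.372]
        sums = [x + y for x in lj for y in qq]
        expected = -RT * math.log(np.mean(np.exp(-b * np.array(sums))))
        assert expected == pytest.approx(0.713, abs=5e-4)
        st_ = StageWorkSet(WorkSet(lj, 300), WorkSet(qq, 300))
        assert convolution_jarzynski(st_).dG == pytest.approx(expected, abs=1e-12)

    @given(work_lists, work_lists)
    @settings(max_examples=200, deadline=None)
    def test_factorizes_into_stage_sum(self, lj, qq):
        st_ = StageWorkSet(WorkSet(lj, 300), WorkSet(qq, 300))
        total = jarzynski(st_.lj).dG + jarzynski(st_.qq).dG
        assert abs(convolution_jarzynski(st_).dG - total) <= 1e-10

    def test_mixed_temperatures_rejected(self):
        with pytest.raises(ValueError):
            StageWorkSet(WorkSet([1.0], 300), WorkSet([1.0], 350))


class TestSelectEstimator:
    def test_normal_totals_use_gaussian(self):
        spec = MixtureSpec((1.0,), (1.0,), (0.5,), 300)
        stage = gen_stage_works(spec, spec, 0.0, 200, seed=0)
        est = select_estimator(stage)
        assert est.method == "gaussian"
        assert est.ad_statistic < 0.34

    def test_separated_mixture_uses_convolution(self):
        spec = MixtureSpec((0.6, 0.4), (0.0, 3.0), (0.3, 0.3), 300)
        stage = gen_stage_works(spec, spec, 0.0, 200, seed=13)
        est = select_estimator(stage)
        assert est.method == "convolution"
        assert est.ad_statistic > 0.754

    def test_non_normal_single_ensemble_demands_stages(self):
        spec = MixtureSpec((0.6, 0.4), (0.0, 3.0), (0.3, 0.3), 300)
        works = gen_mixture_works(spec, 200, seed=13)
        with pytest.raises(ValueError, match="stage-resolved"):
            select_estimator(works)

    def test_zero_variance_short_circuit(self):
        est = select_estimator(WorkSet([4.2] * 200, 300))
        assert est.method == "gaussian"
        assert est.dG == pytest.approx(4.2)
        assert est.ad_statistic is None

    def test_pure_function(self):
        works = gen_normal_works(-5, 2, 200, seed=7)
        a = select_estimator(works, DecisionPolicy())
        b = select_estimator(works, DecisionPolicy())
        assert (a.method, a.dG, a.ad_statistic) == (b.method, b.dG, b.ad_statistic)

    def test_policy_thresholds_respected(self):
        # with an absurdly high normal threshold everything is gaussian
        spec = MixtureSpec((0.6, 0.4), (0.0, 3.0), (0.3, 0.3), 300)
        works = gen_mixture_works(spec, 200, seed=13)
        est = select_estimator(works, DecisionPolicy(ad_normal_threshold=100.0,
                                                     ad_upper_threshold=100.0))
        assert est.method == "gaussian"


class TestStageIndependence:
    def test_identical_stages(self):
        ws = WorkSet([1.0, 2.0, 4.0, 3.0], 300)
        assert stage_independence(StageWorkSet(ws, ws)) == (1.0, 1.0)

    def test_anticorrelated_stages(self):
        ws = WorkSet([1.0, 2.0, 4.0, 3.0], 300)
        neg = WorkSet(-ws.values, 300)
        rho, tau = stage_independence(StageWorkSet(ws, neg))
        assert rho == pytest.approx(-1.0)
        assert tau == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(99)
        st_ = StageWorkSet(WorkSet(rng.standard_normal(200), 300),
                           WorkSet(rng.standard_normal(200), 300))
        rho, tau = stage_independence(st_)
        assert abs(rho) < 0.2
        assert abs(tau) < 0.2

    def test_unequal_lengths_rejected(self):
        st_ = StageWorkSet(WorkSet([1.0, 2.0, 3.0], 300), WorkSet([1.0, 2.0], 300))
        with pytest.raises(ValueError, match="paired"):
            stage_independence(st_)
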