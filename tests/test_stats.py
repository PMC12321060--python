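import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sstats

from fatiguenet.stats import (
    PairedSample,
    bonferroni,
    d_to_r,
    normality_gate,
    paired_test,
    r_to_d,
    spearman,
)


class TestNormalityGate:
    def test_normal_samples_pass_gate(self):
        """Type-I control: n=48 Gaussian differences pass in ≥90% of draws
        (the nominal rate is 95%; 200 replicates keep the MC error small)."""
        rng = np.random.default_rng(0)
        hits = sum(
            normality_gate(rng.standard_normal(48)).is_normal
            for _ in range(200))
        assert hits >= 180

    def test_skewed_samples_fail_gate(self):
        """Power: n=48 exponential differences fail in ≥90% of draws."""
        rng = np.random.default_rng(1)
        hits = sum(
            not normality_gate(rng.exponential(size=48)).is_normal
            for _ in range(200))
        assert hits >= 180

    def test_tiny_sample_not_evaluated(self):
        res = normality_gate(np.array([1.0, 2.0]))
        assert not res.evaluated and res.is_normal is None
        assert math.isnan(res.p)

    def test_ks_variant_runs(self):
        rng = np.random.default_rng(2)
        res = normality_gate(rng.standard_normal(48), method="ks")
        assert res.evaluated and 0 <= res.p <= 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            normality_gate(np.zeros(10), method="anderson")


class TestPairedTest:
    def test_constant_shift_detected(self):
        """A constant positive shift with tiny noise is detected with the
        matching effect-size sign, whichever branch the gate picks."""
        rng = np.random.default_rng(3)
        pre = rng.standard_normal(30)
        sample = PairedSample(pre=pre, post=pre + 2.0 + 0.05 * rng.standard_normal(30))
        res = paired_test(sample)
        assert res.p < 0.001
        assert res.r > 0
        if res.test == "paired_t":
            assert res.d > 0

    def test_null_p_values_roughly_uniform(self):
        """Within-subject permutation null: p should not concentrate low."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            pre = rng.standard_normal(24)
            shift = np.abs(rng.standard_normal(24))
            sign = np.where(rng.random(24) < 0.5, 1.0, -1.0)
            sample = PairedSample(pre=pre, post=pre + sign * shift)
            ps.append(paired_test(sample).p)
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.10
        assert abs(np.mean(ps) - 0.5) < 0.06

    def test_cohens_d_is_mean_over_sd_of_differences(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(1.0, 1.0, 30)
        res = paired_test(PairedSample(pre=np.zeros(30), post=diffs))
        assert res.test == "paired_t"
        assert res.d == pytest.approx(diffs.mean() / diffs.std(ddof=1))

    def test_branch_choice_is_pure_function_of_gate(self):
        rng = np.random.default_rng(6)
        pre = rng.standard_normal(25)
        post = pre + rng.standard_normal(25)
        sample = PairedSample(pre=pre, post=post)
        gate_pass = normality_gate(sample.differences)
        res_auto = paired_test(sample, gate_pass)
        assert res_auto.test == ("paired_t" if gate_pass.is_normal else "wilcoxon")
        # forcing the gate flips the branch
        from fatiguenet.stats import NormalityResult

        forced = NormalityResult(p=0.001, is_normal=False, evaluated=True,
                                 method="shapiro")
        assert paired_test(sample, forced).test == "wilcoxon"

    def test_wilcoxon_z_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(7)
        diffs = rng.standard_normal(40) + 0.3
        sample = PairedSample(pre=np.zeros(40), post=diffs)
        from fatiguenet.stats import NormalityResult

        gate = NormalityResult(p=0.0, is_normal=False, evaluated=True,
                               method="shapiro")
        res = paired_test(sample, gate)
        ref = sstats.wilcoxon(diffs, correction=True, method="approx")
        assert abs(res.statistic) == pytest.approx(abs(ref.zstatistic), abs=1e-9)
        assert res.r == pytest.approx(res.statistic / math.sqrt(40))

    def test_wilcoxon_literal_r_convention(self):
        rng = np.random.default_rng(8)
        diffs = rng.standard_normal(25) + 0.5
        sample = PairedSample(pre=np.zeros(25), post=diffs)
        from fatiguenet.stats import NormalityResult

        gate = NormalityResult(p=0.0, is_normal=False, evaluated=True,
                               method="shapiro")
        a = paired_test(sample, gate, wilcoxon_r="z_over_sqrt_n")
        b = paired_test(sample, gate, wilcoxon_r="z_over_n")
        assert b.r == pytest.approx(a.r / math.sqrt(25))

    def test_degenerate_all_zero_differences_rejected(self):
        sample = PairedSample(pre=np.ones(10), post=np.ones(10))
        with pytest.raises(ValueError):
            paired_test(sample)

    def test_mismatched_or_missing_pairs_rejected(self):
        with pytest.raises(ValueError):
            PairedSample(pre=np.ones(3), post=np.ones(4))
        with pytest.raises(ValueError):
            PairedSample(pre=np.array([1.0, np.nan]), post=np.ones(2))


class TestEffectSizeConversion:
    @pytest.mark.parametrize(
        "d,expected",
        [(4.23, 0.90), (0.81, 0.38), (1.10, 0.48), (0.0, 0.0),
         (2.0, round(1 / math.sqrt(2), 2))],
    )
    def test_d_to_r_reference_values(self, d, expected):
        assert round(d_to_r(d), 2) == expected

    @given(st.floats(-10.0, 10.0))
    def test_round_trip(self, d):
        assert r_to_d(d_to_r(d)) == pytest.approx(d, abs=1e-9)

    @given(st.floats(-50.0, 50.0))
    def test_monotone_odd_bounded(self, d):
        r = d_to_r(d)
        assert -1 < r < 1
        assert d_to_r(-d) == pytest.approx(-r)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            d_to_r(float("nan"))


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [(3, 0.0167), (5, 0.01), (1, 0.05)])
    def test_adjusted_thresholds(self, m, expected):
        assert round(bonferroni(0.05, m), 4) == expected

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_null_quantile(self):
        """Independent n=48 vectors: |rho| ≤ 0.4 in ≥95% of replicates."""
        rng = np.random.default_rng(9)
        hits = sum(
            abs(spearman(rng.standard_normal(48), rng.standard_normal(48))[0]) <= 0.4
            for _ in range(100))
        assert hits >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))
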