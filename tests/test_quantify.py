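"""Splice/allele fractions, AEI testing, and model inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oct1splice.classify import CountTable
from oct1splice.quantify import (Z95, aei_test, allele_fraction,
                                 forward_allele_fraction,
                                 forward_alt_fraction, nmd_from_ratio,
                                 nmd_invert, pyro_apply, pyro_calibrate,
                                 solve_decay_for_alt_frac, splice_fraction,
                                 wilson_ci)


def table(correct_a=0, correct_g=0, alt_a=0, alt_g=0, uncls=0):
    counts = {("correct", "A"): correct_a, ("correct", "G"): correct_g,
              ("alternative", "A"): alt_a, ("alternative", "G"): alt_g,
              ("unclassified", "unclassified"): uncls}
    return CountTable("s", {k: v for k, v in counts.items() if v})


class TestSpliceFraction:
    def test_minigene_style_fraction(self):
        sq = splice_fraction(table(correct_a=62, alt_a=38))
        assert sq.f_correct == pytest.approx(0.62)
        assert sq.ci95[0] < 0.62 < sq.ci95[1]
        assert sq.n_classified == 100

    def test_boundary_all_alternative(self):
        sq = splice_fraction(table(alt_a=100))
        assert sq.f_correct == 0.0
        assert sq.ci95[1] < 0.05

    def test_wilson_matches_score_test_inversion(self):
        # oracle: the Wilson interval is the set of p not rejected by the
        # normal score test; recover it by dense grid inversion
        n, x = 100, 50
        lo, hi = wilson_ci(x, n)
        grid = np.linspace(0.0, 1.0, 2_000_001)
        phat = x / n
        keep = np.abs(phat - grid) <= Z95 * np.sqrt(
            grid * (1 - grid) / n) + 1e-12
        assert lo == pytest.approx(grid[keep].min(), abs=1e-6)
        assert hi == pytest.approx(grid[keep].max(), abs=1e-6)

    def test_zero_classified_reads_error(self):
        with pytest.raises(ValueError):
            splice_fraction(table(uncls=10))

    def test_unclassified_excluded_from_denominator(self):
        sq = splice_fraction(table(correct_a=50, alt_a=50, uncls=100))
        assert sq.f_correct == 0.5
        assert sq.unclassified_frac == 0.5

    def test_wilson_coverage_is_nominal(self):
        # empirical 95% CI coverage within [93%, 97%] at n=500, p=0.38
        rng = np.random.default_rng(7)
        n, p, reps = 500, 0.38, 2000
        x = rng.binomial(n, p, size=reps)
        lo, hi = wilson_ci(x, n)
        cover = ((lo <= p) & (p <= hi)).mean()
        assert 0.93 <= cover <= 0.97


class TestAlleleFraction:
    def test_rna_imbalance_fraction(self):
        af = allele_fraction(table(correct_a=42, correct_g=58))
        assert af.f_A == pytest.approx(0.42)

    def test_correct_only_stratum(self):
        af = allele_fraction(table(correct_a=3, correct_g=1, alt_a=2),
                             stratum="correct_only")
        assert af.f_A == pytest.approx(0.75)
        assert (af.n_A, af.n_G) == (3, 1)

    def test_no_allele_calls_error(self):
        with pytest.raises(ValueError):
            allele_fraction(table(uncls=5))


class TestAEITest:
    def test_hand_computed_t_statistic(self):
        pairs = [(0.5, 0.4), (0.5, 0.5), (0.5, 0.45)]
        res = aei_test(pairs)
        # diffs 0.1, 0, 0.05: mean 0.05, sd 0.05 -> t = sqrt(3)
        assert res.t_stat == pytest.approx(np.sqrt(3))
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(np.sqrt(3), df=2))

    def test_zero_variance_flagged_not_nan(self):
        res = aei_test([(0.50, 0.42)] * 9)
        assert res.zero_variance
        assert res.p_value == 0.0
        assert res.diff > 0

    def test_null_p_values_uniform(self):
        # simulated DNA == RNA: KS test against U(0,1) not rejected
        rng = np.random.default_rng(13)
        reps, n = 5000, 9
        diffs = rng.normal(0.0, 0.01, size=(reps, n))
        t = diffs.mean(1) / (diffs.std(1, ddof=1) / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
        _, ks_p = stats.kstest(p, "uniform")
        assert ks_p > 0.01
        # and our implementation reproduces those p-values
        res = aei_test(list(zip(diffs[0], np.zeros(n))))
        assert res.p_value == pytest.approx(p[0])

    def test_study_scale_imbalance_is_detected(self):
        # 9 samples with DNA ~50% and RNA ~42% at study depth: the paired
        # test should essentially always reject
        rng = np.random.default_rng(17)
        depth, reject = 74_326, 0
        reps = 200
        for _ in range(reps):
            dna = rng.binomial(depth, 0.50, 9) / depth
            rna = rng.binomial(depth, 0.42, 9) / depth
            if aei_test(list(zip(dna, rna))).p_value < 0.05:
                reject += 1
        assert reject / reps >= 0.99


class TestNMDInversion:
    def test_liver_observations_invert_to_published_estimates(self):
        est = nmd_invert(0.42, 0.0036)
        assert est.md == pytest.approx(0.27586, abs=1e-4)
        assert est.m == pytest.approx(0.28207, abs=1e-4)
        assert est.d == pytest.approx(0.9780, abs=1e-3)
        # forward oracle closes the loop
        assert forward_allele_fraction(est.m, est.d) == pytest.approx(
            0.42, abs=1e-9)
        assert forward_alt_fraction(est.m, est.d) == pytest.approx(
            0.0036, abs=1e-9)

    def test_balanced_input_flags_no_imbalance(self):
        est = nmd_invert(0.5, 0.0)
        assert est.md == 0.0 and est.m == 0.0
        assert "no detectable imbalance" in est.flags

    def test_roundtrip_on_unit_square(self):
        rng = np.random.default_rng(23)
        m = rng.uniform(1e-6, 1 - 1e-6, 1000)
        d = rng.uniform(1e-6, 1 - 1e-6, 1000)
        f = forward_allele_fraction(m, d)
        alt = forward_alt_fraction(m, d)
        for fi, ai, mi, di in zip(f, alt, m, d):
            est = nmd_invert(float(fi), float(ai))
            assert est.m == pytest.approx(mi, abs=1e-9)
            assert est.d == pytest.approx(di, abs=1e-9)

    def test_monotone_in_decay_product(self):
        md = np.linspace(0.0, 0.99, 50)
        f = (1 - md) / (2 - md)
        assert (np.diff(f) < 0).all()
        inverted = [nmd_invert(float(fi), 0.0).md for fi in f[1:]]
        assert (np.diff(inverted) > 0).all()

    def test_ratio_estimator(self):
        est = nmd_from_ratio(0.713)
        assert est.m == pytest.approx(0.287)
        assert nmd_from_ratio(1.0).m == 0.0
        assert nmd_from_ratio(0.5).m == 0.5
        with_md = nmd_from_ratio(0.713, md=0.27586)
        assert with_md.d == pytest.approx(0.9612, abs=1e-3)

    def test_out_of_range_inputs_rejected(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                nmd_invert(bad, 0.0)

    def test_solve_decay_reproduces_target_alt_fraction(self):
        for gt, target in (("dup/dup", 0.0058), ("WT/dup", 0.0036)):
            d = solve_decay_for_alt_frac(0.287, target, gt)
            assert forward_alt_fraction(0.287, d, gt) == pytest.approx(
                target, abs=1e-12)


class TestPyroCalibration:
    def test_identity_series(self):
        cal = pyro_calibrate([0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        assert cal == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_constructed_line_recovered(self):
        fracs = [0.0, 0.25, 0.5, 0.75, 1.0]
        signals = [0.9 * f + 0.05 for f in fracs]
        slope, intercept = pyro_calibrate(fracs, signals)
        assert (slope, intercept) == pytest.approx((0.9, 0.05))
        assert pyro_apply((slope, intercept), 0.5) == pytest.approx(0.5)

    def test_inversion_clamps_to_unit_interval(self):
        assert pyro_apply((0.9, 0.05), 1.5) == 1.0
        assert pyro_apply((0.9, 0.05), -0.5) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pyro_calibrate([0.5], [0.4])
        with pytest.raises(ValueError):
            pyro_calibrate([0.5, 0.5], [0.4, 0.6])
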