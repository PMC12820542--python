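"""Egger regression, funnel data, and Duval–Tweedie trim-and-fill."""

import math
import random

import numpy as np
import pytest

from metaweight import (
    CorpusSpec,
    EffectPoint,
    egger_test,
    effects_from_records,
    funnel_data,
    generate_corpus,
    pool_random,
    trim_and_fill,
)
from metaweight.errors import (
    ConfigurationError,
    InsufficientDataError,
    SingularDesignError,
)


def _eff(z, se, i=0):
    n = max(4, round(1 / se**2 + 3))
    return EffectPoint(f"s{i}", z, se, n, True)


def _effects(pairs):
    return [_eff(z, se, i) for i, (z, se) in enumerate(pairs)]


class TestEgger:
    def test_constant_effect_lies_on_line_through_origin(self):
        # z_i = c  =>  SND = c * precision: slope c, intercept 0, no residual
        c = 0.37
        effs = _effects([(c, se) for se in (0.05, 0.08, 0.1, 0.2)])
        res = egger_test(effs)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.slope == pytest.approx(c, abs=1e-12)

    def test_effect_proportional_to_se_gives_pure_intercept(self):
        c = 1.4
        effs = _effects([(c * se, se) for se in (0.05, 0.08, 0.1, 0.2)])
        res = egger_test(effs)
        assert res.intercept == pytest.approx(c, abs=1e-10)
        assert res.slope == pytest.approx(0.0, abs=1e-10)

    def test_three_point_closed_form_normal_equations(self):
        pairs = [(0.21, 0.05), (0.45, 0.11), (0.10, 0.24)]
        x = [1 / se for _, se in pairs]
        y = [z / se for z, se in pairs]
        k = len(x)
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        sxy = sum(a * b for a, b in zip(x, y))
        slope = (k * sxy - sx * sy) / (k * sxx - sx**2)
        intercept = (sy - slope * sx) / k
        res = egger_test(_effects(pairs))
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.df == 1

    def test_fixture_matches_independent_least_squares(self, pe_bi_effects):
        x = np.array([1 / e.se_z for e in pe_bi_effects])
        y = np.array([e.z / e.se_z for e in pe_bi_effects])
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / (len(x) - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        res = egger_test(pe_bi_effects)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        assert res.slope == pytest.approx(beta[1], abs=1e-8)
        assert res.intercept_se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-8)
        assert res.slope_se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-8)

    def test_identical_precisions_are_singular(self):
        with pytest.raises(SingularDesignError):
            egger_test(_effects([(0.1, 0.1), (0.2, 0.1), (0.3, 0.1)]))

    def test_requires_three_effects(self):
        with pytest.raises(InsufficientDataError):
            egger_test(_effects([(0.1, 0.1), (0.2, 0.2)]))

    def test_null_calibration_under_symmetric_funnel(self):
        """With effects = mu + se*noise (symmetric, mean zero) the intercept
        test at alpha=.10 should flag at roughly its nominal rate. The pass
        proportion is asserted above the nominal 90% minus two binomial
        standard errors at 100 replicates."""
        rng = np.random.default_rng(20240915)
        passes = 0
        reps = 100
        for _ in range(reps):
            se = rng.uniform(0.04, 0.25, size=40)
            z = 0.3 + se * rng.standard_normal(40)
            effs = _effects(list(zip(z, se)))
            passes += egger_test(effs).p_intercept >= 0.10
        assert passes / reps >= 0.90 - 2 * math.sqrt(0.9 * 0.1 / reps)


class TestFunnel:
    def test_point_conservation_and_largest_se_point(self, pe_bi_effects):
        pooled = pool_random(pe_bi_effects)
        fd = funnel_data(pe_bi_effects, pooled)
        assert len(fd.points) == 77
        z_max, se_max = max(fd.points, key=lambda p: p[1])
        assert (z_max, round(se_max, 3)) == (0.202, 0.125)

    def test_contour_half_width_shrinks_to_zero_with_se(self, pe_bi_effects):
        pooled = pool_random(pe_bi_effects)
        fd = funnel_data(pe_bi_effects, pooled, levels=(0.95,))
        assert fd.half_width(0.95, 0.0) == 0.0
        assert fd.half_width(0.95, 0.1) == pytest.approx(1.959964 * 0.1, abs=1e-5)

    def test_unknown_level_is_configuration_error(self, pe_bi_effects):
        fd = funnel_data(pe_bi_effects, pool_random(pe_bi_effects))
        with pytest.raises(ConfigurationError):
            fd.half_width(0.5, 0.1)


class TestTrimAndFill:
    def _symmetric(self):
        # mirror pairs about 0.4 with matched SEs: a perfectly even funnel
        offsets = [0.02, 0.05, 0.11, 0.2, 0.3]
        ses = [0.05, 0.07, 0.09, 0.12, 0.2]
        pairs = [(0.4 + d, se) for d, se in zip(offsets, ses)]
        pairs += [(0.4 - d, se) for d, se in zip(offsets, ses)]
        return _effects(pairs)

    def test_symmetric_set_imputes_nothing(self):
        for estimator in ("L0", "R0"):
            res = trim_and_fill(self._symmetric(), estimator=estimator)
            assert res.k0 == 0
            assert res.imputed == ()
            unadjusted = pool_random(self._symmetric())
            assert res.adjusted.r == pytest.approx(unadjusted.r, abs=1e-12)

    def test_recovers_planted_right_flank_excess(self):
        """Symmetric core plus m extra right-flank studies: L0 recovers k0
        within +-1 of m, matching a single-iteration rank oracle."""
        m = 4
        effs = self._symmetric() + _effects(
            [(1.3, 0.16), (1.45, 0.18), (1.6, 0.2), (1.75, 0.22)]
        )
        res = trim_and_fill(effs, side="right", estimator="L0")
        assert abs(res.k0 - m) <= 1

        # independent single-iteration L0 oracle
        z = np.array([e.z for e in effs])
        se = np.array([e.se_z for e in effs])
        w = 1 / se**2
        center = np.sum(w * z) / np.sum(w)
        d = z - center
        order = np.argsort(np.abs(d))
        ranks = np.empty(len(z))
        ranks[order] = np.arange(1, len(z) + 1)
        t_n = ranks[d > 0].sum()
        k = len(z)
        l0_first = max(0, round((4 * t_n - k * (k + 1)) / (2 * k - 1)))
        assert abs(res.k0 - l0_first) <= 2  # iteration refines the estimate

    def test_imputed_points_mirror_donors(self):
        effs = self._symmetric() + _effects(
            [(1.3, 0.16), (1.45, 0.18), (1.6, 0.2)]
        )
        res = trim_and_fill(effs, side="right", estimator="L0")
        assert res.k0 > 0
        donors = sorted(e.z for e in effs)[-res.k0 :]
        sums = sorted(
            imp.z + donor for imp, donor in zip(
                sorted(res.imputed, key=lambda e: -e.z), donors
            )
        )
        # each imputed z is 2*center - donor z: all pair sums equal 2*center
        assert max(sums) - min(sums) < 1e-9
        donor_ses = sorted(e.se_z for e in effs if e.z in donors)
        assert sorted(e.se_z for e in res.imputed) == pytest.approx(donor_ses)

    def test_invariant_to_input_order(self):
        effs = self._symmetric() + _effects([(1.3, 0.16), (1.5, 0.2)])
        shuffled = list(effs)
        random.Random(5).shuffle(shuffled)
        a = trim_and_fill(effs, side="right")
        b = trim_and_fill(shuffled, side="right")
        assert a.k0 == b.k0
        assert a.adjusted.r == pytest.approx(b.adjusted.r, abs=1e-12)

    def test_adjustment_pulls_estimate_toward_null(self):
        effs = self._symmetric() + _effects(
            [(1.3, 0.16), (1.45, 0.18), (1.6, 0.2), (1.75, 0.22)]
        )
        res = trim_and_fill(effs, side="right")
        assert res.adjusted.r < pool_random(effs).r

    def test_bias_detection_rate_under_selective_publication(self):
        """bias_prob=0.8 suppression of nonsignificant studies is flagged
        (Egger p<.10 or k0>0) in at least 60% of 20 seeded corpora."""
        flagged = 0
        for seed in range(20):
            spec = CorpusSpec(
                true_r=0.2,
                tau=0.15,
                n_studies=60,
                n_range=(40, 400),
                bias_prob=0.8,
                seed=seed,
            )
            effs = effects_from_records(generate_corpus(spec))
            egger_hit = egger_test(effs).p_intercept < 0.10
            tf_hit = trim_and_fill(effs).k0 > 0
            flagged += egger_hit or tf_hit
        assert flagged / 20 >= 0.60
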