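"""Length-weight power law, isometry, sex covariate, composition trends."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavegrowth import allometry
from cavegrowth.io_model import (
    CompositionRecord,
    IndividualRecord,
    Sex,
    ValidationError,
)
from cavegrowth.simulate import CohortSimConfig, simulate_cohort


def _fish(L, W, sex=Sex.FEMALE, fid=None):
    return IndividualRecord(
        fish_id=fid or f"L{L}", sex_class=sex, total_length=L, body_weight=W
    )


class TestFitLWR:
    def test_zero_noise_fixture_recovers_published_power_law(self, zero_noise_cohort):
        fit = allometry.fit_lwr(zero_noise_cohort)
        assert fit.a == pytest.approx(0.0046, rel=1e-10)
        assert fit.b == pytest.approx(3.03, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_too_few_records(self):
        with pytest.raises(ValidationError):
            allometry.fit_lwr([_fish(5, 1), _fish(6, 2)])

    def test_zero_length_variance(self):
        with pytest.raises(ValidationError):
            allometry.fit_lwr([_fish(5, 1, fid="a"), _fish(5, 2, fid="b"),
                               _fish(5, 3, fid="c")])

    def test_exponent_unbiased_over_replicates(self):
        bs = []
        for seed in range(200):
            c = simulate_cohort(CohortSimConfig(seed=seed))
            bs.append(allometry.fit_lwr(c).b)
        mc_se = np.std(bs) / math.sqrt(len(bs))
        assert abs(np.mean(bs) - 3.03) < 3 * mc_se

    @given(c=st.floats(min_value=0.2, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_scale_covariance_of_exponent(self, c, zero_noise_cohort):
        sub = zero_noise_cohort[:20]
        base = allometry.fit_lwr(sub)
        scaled = [
            _fish(c * r.total_length, (c**base.b) * r.body_weight, fid=r.fish_id)
            for r in sub
        ]
        assert allometry.fit_lwr(scaled).b == pytest.approx(base.b, rel=1e-9)


class TestIsometry:
    def test_exact_isometry_gives_t_zero_p_one(self):
        fit = allometry.PowerLawFit(a=0.005, b=3.0, se_b=0.1, se_log10_a=0.1,
                                    r_squared=0.9, n=50)
        res = allometry.test_isometry(fit)
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_t_table_case(self):
        # b = 3.2, se = 0.1, n = 102: t = 2.0 at df = 100 -> P ~ 0.048
        fit = allometry.PowerLawFit(a=0.005, b=3.2, se_b=0.1, se_log10_a=0.1,
                                    r_squared=0.9, n=102)
        res = allometry.test_isometry(fit)
        assert res.t_statistic == pytest.approx(2.0)
        assert res.df == 100
        assert res.p_value == pytest.approx(0.0482, abs=5e-4)

    def test_zero_noise_isometric_data(self):
        # exactly cubic data: the fitted exponent is 3 to floating tolerance,
        # so the isometry departure b - 3 vanishes (the t ratio itself is
        # 0/0-degenerate at zero residual variance and not asserted)
        rng = np.random.default_rng(0)
        L = rng.uniform(4, 14, 30)
        fish = [_fish(l, 0.0046 * l**3.0, fid=str(i)) for i, l in enumerate(L)]
        fit = allometry.fit_lwr(fish)
        assert fit.b == pytest.approx(3.0, abs=1e-9)
        assert fit.se_b < 1e-9

    def test_p_decreases_with_departure_from_isometry(self):
        ps = []
        for b in (3.0, 3.1, 3.2, 3.4):
            fit = allometry.PowerLawFit(a=0.005, b=b, se_b=0.1, se_log10_a=0.1,
                                        r_squared=0.9, n=50)
            ps.append(allometry.test_isometry(fit).p_value)
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_degenerate_se_rejected(self):
        fit = allometry.PowerLawFit(a=0.005, b=3.0, se_b=0.0, se_log10_a=0.1,
                                    r_squared=1.0, n=50)
        with pytest.raises(ValidationError):
            allometry.test_isometry(fit)


class TestSexEffect:
    def _two_groups(self, b_f, b_m, n=30, sd=0.02, seed=0):
        rng = np.random.default_rng(seed)
        fish = []
        for sex, b in ((Sex.FEMALE, b_f), (Sex.MALE, b_m)):
            L = rng.uniform(5, 14, n)
            W = 0.0046 * L**b * np.exp(rng.normal(0, sd, n))
            fish += [
                _fish(l, w, sex=sex, fid=f"{sex.value}{i}")
                for i, (l, w) in enumerate(zip(L, W))
            ]
        return fish

    def test_mirror_image_groups_have_zero_contrasts(self):
        rng = np.random.default_rng(1)
        L = rng.uniform(5, 14, 20)
        W = 0.0046 * L**3.03 * np.exp(rng.normal(0, 0.05, 20))
        fish = [_fish(l, w, Sex.FEMALE, f"f{i}") for i, (l, w) in enumerate(zip(L, W))]
        fish += [_fish(l, w, Sex.MALE, f"m{i}") for i, (l, w) in enumerate(zip(L, W))]
        slope_t, int_t = allometry.test_sex_effect(fish)
        assert abs(slope_t.t_statistic) < 1e-8
        assert abs(int_t.t_statistic) < 1e-8
        assert slope_t.slope_1 == pytest.approx(slope_t.slope_2, abs=1e-10)

    def test_juveniles_are_excluded(self):
        fish = self._two_groups(3.0, 3.0)
        fish.append(_fish(2.0, 5.0, Sex.JUVENILE, "j1"))  # absurd point
        slope_with_juv, _ = allometry.test_sex_effect(fish)
        fish_no_juv = [f for f in fish if f.sex_class != Sex.JUVENILE]
        slope_without, _ = allometry.test_sex_effect(fish_no_juv)
        assert slope_with_juv.t_statistic == pytest.approx(slope_without.t_statistic)

    def test_type_one_error_rate_when_sexes_share_one_curve(self):
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            fish = self._two_groups(3.03, 3.03, sd=0.1, seed=seed)
            slope_t, _ = allometry.test_sex_effect(fish)
            rejections += slope_t.p_value < 0.05
        assert 0.015 <= rejections / n_reps <= 0.10

    def test_power_when_exponents_differ(self):
        detected = 0
        n_reps = 50
        for seed in range(n_reps):
            fish = self._two_groups(3.0, 3.5, n=30, sd=0.05, seed=seed)
            slope_t, _ = allometry.test_sex_effect(fish)
            detected += slope_t.p_value < 0.05
        assert detected / n_reps > 0.9

    def test_too_few_per_group(self):
        fish = [_fish(5, 1, Sex.FEMALE, "a"), _fish(6, 2, Sex.MALE, "b")]
        with pytest.raises(ValidationError):
            allometry.test_sex_effect(fish)


def _comp(L, value, analyte="lipid", pid=None):
    values = {"protein": 100.0, "lipid": 50.0, "glycogen": 5.0, "ash": 30.0}
    values[analyte] = value
    return CompositionRecord(pool_id=pid or f"p{L}", total_length=L, **values)


class TestTrends:
    def test_exact_line_recovered(self):
        recs = [_comp(L, 20 + 11.3 * L) for L in (4.0, 6.0, 8.5, 11.0, 14.0)]
        fit = allometry.fit_trend(recs, "lipid")
        assert fit.slope == pytest.approx(11.3, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_analyte(self):
        recs = [_comp(L, 80.0) for L in (4.0, 6.0, 8.5, 11.0)]
        fit = allometry.fit_trend(recs, "lipid")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_normal_equation_oracle(self):
        """OLS output equals the closed-form solution on random data."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            x = rng.uniform(3, 15, n)
            y = rng.normal(50 + 4 * x, 10)
            fit = allometry.linear_fit_xy(x, y)
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            intercept = y.mean() - slope * x.mean()
            resid = y - intercept - slope * x
            s2 = resid @ resid / (n - 2)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10)
            assert fit.se_slope == pytest.approx(math.sqrt(s2 / sxx), rel=1e-10)

    def test_unknown_analyte(self):
        with pytest.raises(ValidationError):
            allometry.fit_trend([_comp(5, 50)], "water")


class TestSlopeComparison:
    def _fit(self, slope, se, n):
        return allometry.LinearFit(
            slope=slope, intercept=0.0, se_slope=se, se_intercept=1.0,
            r_squared=0.5, n=n, p_slope=0.1, residual_sd=1.0,
        )

    def test_identical_fits(self):
        f = self._fit(11.3, 1.0, 30)
        res = allometry.compare_trend_slopes(f, f)
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_arithmetic_case(self):
        # slopes 11.3 vs 0, SE 1 each: t = -11.3/sqrt(2) = -7.990, df = 56
        res = allometry.compare_trend_slopes(self._fit(11.3, 1.0, 30), self._fit(0.0, 1.0, 30))
        assert res.t_statistic == pytest.approx(-7.9903, abs=1e-3)
        assert res.df == 56
        assert res.p_value < 1e-9

    def test_type_one_rate_same_generating_line(self):
        rejections = 0
        n_reps = 300
        rng = np.random.default_rng(77)
        for _ in range(n_reps):
            x1, x2 = rng.uniform(4, 14, (2, 30))
            y1 = 20 + 5 * x1 + rng.normal(0, 10, 30)
            y2 = 20 + 5 * x2 + rng.normal(0, 10, 30)
            res = allometry.compare_trend_slopes(
                allometry.linear_fit_xy(x1, y1), allometry.linear_fit_xy(x2, y2)
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_paired_mode_runs_and_detects_difference(self):
        rng = np.random.default_rng(3)
        L = rng.uniform(4, 14, 30)
        recs = []
        for i, l in enumerate(L):
            recs.append(
                CompositionRecord(
                    pool_id=f"p{i}", total_length=l,
                    protein=140 - 2 * l + rng.normal(0, 3),
                    lipid=-13 + 11.3 * l + rng.normal(0, 3),
                    glycogen=5.0, ash=30.0,
                )
            )
        res = allometry.compare_trend_slopes_paired(recs, "protein", "lipid")
        assert res.p_value < 1e-6
        assert res.slope_2 == pytest.approx(13.3, abs=1.0)

    def test_undefined_se_rejected(self):
        with pytest.raises(ValidationError):
            allometry.compare_trend_slopes(self._fit(1, 0.0, 30), self._fit(2, 1, 30))
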