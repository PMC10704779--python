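"""Interspecific K-L_inf allometry, PGLS with Pagel's lambda, group tests."""

import math

import numpy as np
import pytest
from scipy import linalg

from cavegrowth import interspecific, io_model
from cavegrowth.interspecific import (
    auximetric_table,
    compare_groups,
    fit_loglog_allometry,
    fit_pgls,
    normalize_name,
)
from cavegrowth.io_model import SpeciesGrowthRecord, ValidationError
from cavegrowth.simulate import (
    SpeciesSimConfig,
    simulate_species_set,
    simulate_tree,
)


def _sp(name, L, K):
    return SpeciesGrowthRecord(species=name, L_inf=L, K=K)


class TestOLSAllometry:
    def test_six_species_reproduce_published_regression(self, six_species):
        fit = fit_loglog_allometry(six_species)
        assert round(fit.slope, 2) == -1.64
        assert round(fit.intercept, 2) == 1.09
        assert round(fit.r_squared, 2) == 0.91
        assert round(fit.p_slope, 3) == 0.003

    def test_collinear_species_have_r2_one(self):
        sp = [_sp(f"s{i}", 10.0 * 2**i, 0.4 / 4**i) for i in range(3)]
        assert fit_loglog_allometry(sp).r_squared == pytest.approx(1.0)

    def test_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sp = simulate_species_set(
                SpeciesSimConfig(n_species=12, residual_sd=0.1, seed=int(rng.integers(1e6)))
            )
            fit = fit_loglog_allometry(sp)
            x = np.log10([s.L_inf for s in sp])
            y = np.log10([s.K for s in sp])
            X = np.column_stack([np.ones(len(sp)), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
            assert fit.slope == pytest.approx(beta[1], rel=1e-10)


class TestPGLS:
    def _matched(self, n, seed, residual_sd=0.08, bm=False):
        tree = simulate_tree(n, seed=seed)
        sp = simulate_species_set(
            SpeciesSimConfig(
                n_species=n, residual_sd=residual_sd, evolve_on_tree=bm, seed=seed
            ),
            tree=tree if bm else None,
        )
        if not bm:
            # give the i.i.d. species the tree's taxon names
            for s, name in zip(sp, tree.taxa):
                s.species = name
        return sp, tree

    def test_lambda_zero_equals_ols_exactly(self):
        sp, tree = self._matched(10, seed=1)
        ols = fit_loglog_allometry(sp)
        pg = fit_pgls(sp, tree, lam=0.0)
        assert pg.slope == pytest.approx(ols.slope, rel=1e-10)
        assert pg.intercept == pytest.approx(ols.intercept, rel=1e-10)

    def test_star_tree_equals_ols_for_any_lambda(self, star_tree_factory):
        sp = simulate_species_set(SpeciesSimConfig(n_species=8, seed=2))
        tree = star_tree_factory([s.species for s in sp])
        ols = fit_loglog_allometry(sp)
        for lam in (0.0, 0.5, 1.0, "ML"):
            pg = fit_pgls(sp, tree, lam=lam)
            assert pg.slope == pytest.approx(ols.slope, rel=1e-10)
            assert pg.intercept == pytest.approx(ols.intercept, rel=1e-10)

    def test_brute_force_gls_oracle(self):
        """GLS via explicit matrix inversion on random 10-taxon problems."""
        for seed in (3, 4, 5):
            sp, tree = self._matched(10, seed=seed, bm=True)
            lam = 0.63
            pg = fit_pgls(sp, tree, lam=lam)
            order = [s.species for s in sp]
            V = interspecific.pgls_covariance(tree, order, lam)
            X = np.column_stack([np.ones(10), np.log10([s.L_inf for s in sp])])
            y = np.log10([s.K for s in sp])
            Vinv = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            assert pg.intercept == pytest.approx(beta[0], rel=1e-9)
            assert pg.slope == pytest.approx(beta[1], rel=1e-9)

    def test_profile_likelihood_dominates_grid(self):
        sp, tree = self._matched(25, seed=6, bm=True)
        ml = fit_pgls(sp, tree, lam="ML")
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            fixed = fit_pgls(sp, tree, lam=lam)
            assert ml.log_likelihood >= fixed.log_likelihood - 1e-8

    def test_against_frozen_r_gls_corpagel_oracle(self):
        """Fixed-lambda fits match nlme::gls + ape::corPagel (ML) values.

        Oracle values computed once in R 4.3 on the identical fixture
        (12-taxon Yule tree seed 11, Brownian species set seed 11).
        """
        tree = simulate_tree(12, seed=11)
        sp = simulate_species_set(
            SpeciesSimConfig(
                n_species=12, residual_sd=0.08, evolve_on_tree=True, seed=11
            ),
            tree=tree,
        )
        expected = {
            0.0: (-1.741417, 1.216337, 19.4911, 0.097560),
            0.7: (-1.748031, 1.219839, 20.9335, 0.067986),
            1.0: (-1.745302, 1.215028, 21.8274, 0.049240),
        }
        for lam, (slope, intercept, loglik, se_slope) in expected.items():
            pg = fit_pgls(sp, tree, lam=lam)
            assert pg.slope == pytest.approx(slope, abs=2e-5)
            assert pg.intercept == pytest.approx(intercept, abs=2e-5)
            assert pg.log_likelihood == pytest.approx(loglik, abs=2e-3)
            assert pg.se_slope == pytest.approx(se_slope, abs=2e-5)

    def test_bm_simulation_recovers_slope_and_lambda(self):
        slopes, lams = [], []
        for seed in range(20):
            sp, tree = self._matched(60, seed=100 + seed, residual_sd=0.1, bm=True)
            pg = fit_pgls(sp, tree)
            slopes.append(pg.slope)
            lams.append(pg.lambda_hat)
        mc_se = np.std(slopes) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) - (-1.64)) < 4 * mc_se + 1e-3
        assert np.median(lams) > 0.8

    def test_name_normalization_and_unmatched_error(self):
        sp, tree = self._matched(6, seed=7)
        sp[0].species = sp[0].species.upper().replace("", "")
        fit_pgls(sp, tree, lam=0.5)  # case-insensitive match works
        sp[0].species = "Missing species"
        with pytest.raises(ValidationError, match="Missing species"):
            fit_pgls(sp, tree, lam=0.5)
        assert normalize_name("Triplophysa rosa") == normalize_name("triplophysa_ROSA")

    def test_lambda_hat_within_unit_interval(self):
        sp, tree = self._matched(15, seed=8, bm=True)
        pg = fit_pgls(sp, tree)
        assert 0.0 <= pg.lambda_hat <= 1.0


class TestGroupComparison:
    def test_identical_groups(self):
        a = [_sp(f"a{i}", 10 + i, 0.1 + 0.01 * i) for i in range(4)]
        b = [_sp(f"b{i}", 10 + i, 0.1 + 0.01 * i) for i in range(4)]
        labels = {s.species: ("A" if s.species.startswith("a") else "B") for s in a + b}
        res = compare_groups(a + b, labels, parameter="phi_prime")
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            vals = rng.normal(1.5, 0.2, 20)
            sp = [_sp(f"s{i}", 10.0, 10 ** (v - 2) ) for i, v in enumerate(vals)]
            labels = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
            res = compare_groups(sp, labels, parameter="K", log_transform=True)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_power_with_three_sd_shift(self):
        rng = np.random.default_rng(10)
        detected = 0
        n_reps = 100
        for _ in range(n_reps):
            a = rng.normal(1.5, 0.1, 6)
            b = rng.normal(1.8, 0.1, 20)  # 3 SD shift
            sp = [_sp(f"a{i}", 10.0, 1.0) for i in range(6)]
            sp += [_sp(f"b{i}", 10.0, 1.0) for i in range(20)]
            for s, v in zip(sp, np.concatenate([a, b])):
                s.phi_prime = float(v)
            labels = {s.species: s.species[0] for s in sp}
            res = compare_groups(sp, labels, parameter="phi_prime")
            detected += res.p_value < 0.01
        assert detected / n_reps > 0.95

    def test_group_with_one_member_rejected(self):
        sp = [_sp("a1", 10, 0.1), _sp("b1", 12, 0.1), _sp("b2", 14, 0.1)]
        with pytest.raises(ValidationError):
            compare_groups(sp, {"a1": "A", "b1": "B", "b2": "B"})


class TestAuximetric:
    def test_single_species_hand_logs(self):
        points, iso = auximetric_table({"g": [_sp("x", 10.0, 0.1)]})
        row = points.iloc[0]
        assert row["log10_L_inf"] == pytest.approx(1.0)
        assert row["log10_K"] == pytest.approx(-1.0)
        assert row["phi_prime"] == pytest.approx(1.0)
        assert iso.iloc[0]["slope"] == -2.0
        assert iso.iloc[0]["intercept"] == pytest.approx(1.0)

    def test_six_species_phi_column_matches_printed(self, six_species):
        points, _ = auximetric_table({"Triplophysa": six_species})
        printed = [1.52, 1.40, 1.68, 1.56, 1.49, 1.51]
        np.testing.assert_allclose(points["phi_prime"], printed, atol=1e-12)

    def test_iso_line_conserves_phi_prime(self):
        from cavegrowth.growth import growth_performance

        phi0 = growth_performance(10.0, 0.1)
        # walk along the slope -2 line through (1, -1)
        for dlog in (-0.5, 0.25, 0.5):
            L = 10.0 ** (1.0 + dlog)
            K = 10.0 ** (-1.0 - 2.0 * dlog)
            assert growth_performance(L, K) == pytest.approx(phi0, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            auximetric_table({"empty": []})
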