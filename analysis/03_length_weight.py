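"""Length-weight allometry and the isometry question.

Fits W = a L^b in log10 space, tests the exponent against 3 (isometric
growth), and checks whether females and males need separate curves
(ANCOVA-style slope and intercept contrasts, juveniles excluded).
"""

from _common import RESULTS_DIR, load_tables
from cavegrowth import allometry, io_model


def main():
    cohort, _, _ = load_tables()
    fit = allometry.fit_lwr(cohort)
    iso = allometry.test_isometry(fit)
    slope_t, int_t = allometry.test_sex_effect(cohort)
    manifest = io_model.write_results(
        {
            "lwr_fit": fit,
            "isometry_test": iso,
            "sex_slope_test": slope_t,
            "sex_intercept_test": int_t,
        },
        RESULTS_DIR / "length_weight",
    )
    print(f"{fit.equation()}   (R^2 = {fit.r_squared:.3f}, n = {fit.n})")
    print(
        f"isometry: t = {iso.t_statistic:.3f}, P = {iso.p_value:.3f} -> "
        + ("allometric" if iso.p_value < 0.05 else "consistent with isometric growth")
    )
    print(
        f"sex effect: slope t = {slope_t.t_statistic:.3f} (P = {slope_t.p_value:.3f}), "
        f"intercept t = {int_t.t_statistic:.3f} (P = {int_t.p_value:.3f}) -> "
        + (
            "separate curves warranted"
            if min(slope_t.p_value, int_t.p_value) < 0.05
            else "one curve for both sexes"
        )
    )
    print(f"wrote {len(manifest['files'])} tables -> results/length_weight/")


if __name__ == "__main__":
    main()
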