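"""Length-weight allometry and composition-versus-length trends.

The length-weight relationship (LWR) is the power law W = a L^b, fitted
by ordinary least squares on log10-transformed axes. The exponent b
measures allometry: b = 3 is isometric growth (weight scales with the
cube of length, shape-preserving), tested with a one-sample t-test on
the fitted exponent. Sex differences in the LWR are tested ANCOVA-style
with sex as a covariate: the slope contrast is the t-test on the
sex-by-log-length interaction, the intercept contrast the t-test on the
sex term in the common-slope model. Juveniles — an age class, not a sex
— are excluded from sex contrasts.

Proximate-composition trends (analyte in mg/g, or energy in kJ/g,
against total length in cm) are plain straight-line fits on
untransformed axes; pairs of trends are compared on their slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io_model import (
    CompositionRecord,
    IndividualRecord,
    LinearFit,
    Sex,
    ValidationError,
)

__all__ = [
    "PowerLawFit",
    "SlopeComparison",
    "linear_fit_xy",
    "fit_lwr",
    "test_isometry",
    "test_sex_effect",
    "fit_trend",
    "compare_trend_slopes",
    "compare_trend_slopes_paired",
    "ANALYTES",
]

ANALYTES = ("protein", "lipid", "glycogen", "ash", "energy")


@dataclass
class PowerLawFit:
    """W = a L^b fitted in log10 space; R² is the log-space R²."""

    a: float
    b: float
    se_b: float
    se_log10_a: float
    r_squared: float
    n: int
    log_base: int = 10

    def equation(self) -> str:
        return f"W = {self.a:.4g} L^{self.b:.3g}"

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "se_b": self.se_b,
            "se_log10_a": self.se_log10_a,
            "r_squared": self.r_squared,
            "n": self.n,
        }


@dataclass
class SlopeComparison:
    """A t-test result comparing two slopes (or means, or a slope to a constant)."""

    t_statistic: float
    df: float
    p_value: float
    slope_1: float
    slope_2: float
    method: str = ""

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "slope_1": self.slope_1,
            "slope_2": self.slope_2,
            "method": self.method,
        }


def linear_fit_xy(x: Sequence[float], y: Sequence[float], label: str = "") -> LinearFit:
    """OLS straight line y = intercept + slope*x with full inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need >= 3 points for a linear fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    if not math.isfinite(r2):  # constant response: TSS = 0
        r2 = 0.0
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        se_slope=float(model.bse[1]),
        se_intercept=float(model.bse[0]),
        r_squared=r2,
        n=int(x.size),
        p_slope=float(model.pvalues[1]),
        residual_sd=float(np.sqrt(model.mse_resid)),
        label=label,
    )


def fit_lwr(individuals: Sequence[IndividualRecord]) -> PowerLawFit:
    """Fit W = a L^b by OLS of log10 W on log10 L."""
    if len(individuals) < 3:
        raise ValidationError("need >= 3 fish to fit the LWR")
    L = np.array([r.total_length for r in individuals])
    W = np.array([r.body_weight for r in individuals])
    fit = linear_fit_xy(np.log10(L), np.log10(W), label="log10W~log10L")
    return PowerLawFit(
        a=float(10.0 ** fit.intercept),
        b=fit.slope,
        se_b=fit.se_slope,
        se_log10_a=fit.se_intercept,
        r_squared=fit.r_squared,
        n=fit.n,
    )


def test_isometry(fit: PowerLawFit, b0: float = 3.0) -> SlopeComparison:
    """One-sample t-test of the LWR exponent against b0 (default 3, isometry)."""
    if not (fit.se_b > 0) or not math.isfinite(fit.se_b):
        raise ValidationError("se_b is zero or undefined; isometry test degenerate")
    if fit.n < 4:
        raise ValidationError("need n >= 4")
    t = (fit.b - b0) / fit.se_b
    df = fit.n - 2
    return SlopeComparison(
        t_statistic=float(t),
        df=df,
        p_value=float(2.0 * stats.t.sf(abs(t), df)),
        slope_1=fit.b,
        slope_2=b0,
        method=f"one-sample t of exponent vs {b0}",
    )


def test_sex_effect(
    individuals: Sequence[IndividualRecord],
) -> tuple[SlopeComparison, SlopeComparison]:
    """Test female/male differences in the LWR; returns (slope, intercept) tests.

    The slope contrast is the t-test on the sex x log10(L) interaction in
    the full two-slopes model; the intercept contrast is the t-test on
    the sex indicator in the common-slope (additive) model — testing a
    level shift given no slope difference, the conventional ANCOVA order.
    """
    rows = [
        {
            "logL": math.log10(r.total_length),
            "logW": math.log10(r.body_weight),
            "sex": r.sex_class.value,
        }
        for r in individuals
        if r.sex_class in (Sex.FEMALE, Sex.MALE)
    ]
    df = pd.DataFrame(rows)
    counts = df["sex"].value_counts() if not df.empty else {}
    if df.empty or len(counts) < 2 or min(counts) < 3:
        raise ValidationError("need >= 3 females and >= 3 males")
    full = smf.ols("logW ~ logL * C(sex)", data=df).fit()
    additive = smf.ols("logW ~ logL + C(sex)", data=df).fit()
    inter = "logL:C(sex)[T.male]"
    group = "C(sex)[T.male]"
    slope_by_sex = {
        s: float(
            full.params["logL"]
            + (full.params[inter] if s == "male" else 0.0)
        )
        for s in ("female", "male")
    }
    slope_test = SlopeComparison(
        t_statistic=float(full.tvalues[inter]),
        df=float(full.df_resid),
        p_value=float(full.pvalues[inter]),
        slope_1=slope_by_sex["female"],
        slope_2=slope_by_sex["male"],
        method="t on sex x log10L interaction",
    )
    intercept_test = SlopeComparison(
        t_statistic=float(additive.tvalues[group]),
        df=float(additive.df_resid),
        p_value=float(additive.pvalues[group]),
        slope_1=float(additive.params["Intercept"]),
        slope_2=float(additive.params["Intercept"] + additive.params[group]),
        method="t on sex term, common-slope model",
    )
    return slope_test, intercept_test


def fit_trend(
    records: Sequence[CompositionRecord], analyte: str
) -> LinearFit:
    """OLS of an analyte (mg/g; kJ/g for energy) on total length (cm)."""
    if analyte not in ANALYTES:
        raise ValidationError(f"unknown analyte {analyte!r}; choose from {ANALYTES}")
    pairs = [
        (r.total_length, getattr(r, analyte))
        for r in records
        if getattr(r, analyte) is not None
    ]
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 records with {analyte} present")
    x, y = zip(*pairs)
    return linear_fit_xy(x, y, label=f"{analyte}~total_length")


def compare_trend_slopes(fit1: LinearFit, fit2: LinearFit) -> SlopeComparison:
    """Compare two independent regression slopes.

    t = (slope2 - slope1) / sqrt(se1^2 + se2^2), df = n1 + n2 - 4
    (two slopes and two intercepts estimated). Treats the fits as
    independent; for analytes measured on the same individuals see
    :func:`compare_trend_slopes_paired`.
    """
    for f in (fit1, fit2):
        if not (f.se_slope > 0) or not math.isfinite(f.se_slope):
            raise ValidationError("slope SE undefined; cannot compare")
    se = math.hypot(fit1.se_slope, fit2.se_slope)
    t = (fit2.slope - fit1.slope) / se
    df = fit1.n + fit2.n - 4
    return SlopeComparison(
        t_statistic=float(t),
        df=df,
        p_value=float(2.0 * stats.t.sf(abs(t), df)),
        slope_1=fit1.slope,
        slope_2=fit2.slope,
        method="independent-slopes t",
    )


def compare_trend_slopes_paired(
    records: Sequence[CompositionRecord], analyte_1: str, analyte_2: str
) -> SlopeComparison:
    """Paired slope comparison for analytes measured on the same samples.

    Regresses the within-sample difference (analyte2 - analyte1) on
    length; the slope t-test of that regression is the paired contrast,
    which respects the correlation between analytes within a sample.
    """
    for a in (analyte_1, analyte_2):
        if a not in ANALYTES:
            raise ValidationError(f"unknown analyte {a!r}")
    diffs = [
        (r.total_length, getattr(r, analyte_2) - getattr(r, analyte_1))
        for r in records
        if getattr(r, analyte_1) is not None and getattr(r, analyte_2) is not None
    ]
    if len(diffs) < 3:
        raise ValidationError("need >= 3 records with both analytes")
    x, y = zip(*diffs)
    fit = linear_fit_xy(x, y)
    t = fit.slope / fit.se_slope
    df = fit.n - 2
    return SlopeComparison(
        t_statistic=float(t),
        df=df,
        p_value=float(2.0 * stats.t.sf(abs(t), df)),
        slope_1=float("nan"),
        slope_2=fit.slope,
        method="paired difference-slope t",
    )
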