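"""Cross-species growth-parameter comparisons.

Across fish species, the von Bertalanffy parameters K and L_inf trade
off: slow-approaching species reach larger asymptotic sizes. On log10
axes the relationship is close to linear, and because species share
evolutionary history the residuals may be phylogenetically correlated.
Both views are provided:

* plain OLS of log10 K on log10 L_inf;
* phylogenetic generalized least squares (PGLS) under a Brownian-motion
  covariance with Pagel's lambda branch-length transformation, lambda
  estimated by maximum likelihood on [0, 1].

Pagel's lambda multiplies the off-diagonal (shared-branch) entries of
the Brownian covariance: lambda = 0 recovers OLS exactly, lambda = 1
keeps the full tree structure. The profile log-likelihood concentrates
out the regression coefficients and the scale sigma^2, leaving a
one-dimensional bounded optimization.

Group-level contrasts (e.g. one genus against a broad reference set)
are Welch two-sample t-tests on K, L_inf or phi', optionally on log10
scale. The auximetric table emits the (log10 L_inf, log10 K) scatter
with iso-phi' reference lines of slope -2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .allometry import SlopeComparison, linear_fit_xy
from .growth import growth_performance
from .io_model import LinearFit, Phylogeny, SpeciesGrowthRecord, ValidationError

__all__ = [
    "PGLSFit",
    "fit_loglog_allometry",
    "pgls_covariance",
    "fit_pgls",
    "compare_groups",
    "auximetric_table",
    "normalize_name",
]


def normalize_name(name: str) -> str:
    """Case-insensitive, space/underscore-equivalent species-name key."""
    return name.strip().lower().replace(" ", "_")


def fit_loglog_allometry(species: Sequence[SpeciesGrowthRecord]) -> LinearFit:
    """OLS of log10 K on log10 L_inf across species."""
    if len(species) < 3:
        raise ValidationError("need >= 3 species")
    x = np.log10([s.L_inf for s in species])
    y = np.log10([s.K for s in species])
    return linear_fit_xy(x, y, label="log10K~log10L_inf")


def pgls_covariance(
    tree: Phylogeny, taxa_order: Sequence[str], lam: float
) -> np.ndarray:
    """Brownian covariance with Pagel's lambda applied to the off-diagonal."""
    C = tree.shared_depth_matrix(taxa_order)
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


@dataclass
class PGLSFit:
    """PGLS estimates with the ML branch-length transformation.

    ``r_squared`` is computed on GLS-whitened data (1 - RSS/TSS after
    premultiplying by C(lambda)^(-1/2), TSS from the whitened
    intercept-only model) — definitions of a PGLS R² vary, so the
    convention is recorded here.
    """

    slope: float
    intercept: float
    lambda_hat: float
    log_likelihood: float
    r_squared: float
    n: int
    se_slope: float
    se_intercept: float
    p_slope: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "lambda_hat": self.lambda_hat,
            "log_likelihood": self.log_likelihood,
            "r_squared": self.r_squared,
            "n": self.n,
            "se_slope": self.se_slope,
            "se_intercept": self.se_intercept,
            "p_slope": self.p_slope,
        }


def _gls_profile(X: np.ndarray, y: np.ndarray, C: np.ndarray):
    """GLS coefficients and profile (ML) log-likelihood for fixed covariance C."""
    n = y.size
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ValidationError(f"covariance not positive definite: {exc}") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdet + n)
    return beta, rss, loglik, L, Xw, yw


def fit_pgls(
    species: Sequence[SpeciesGrowthRecord],
    tree: Phylogeny,
    lam: float | str = "ML",
    x_field: str = "L_inf",
    y_field: str = "K",
    log10_axes: bool = True,
) -> PGLSFit:
    """PGLS of (by default) log10 K on log10 L_inf over a phylogeny.

    ``lam`` is either ``"ML"`` (profile-likelihood estimate on [0, 1] by
    bounded scalar optimization, endpoints included) or a fixed value in
    [0, 1]. Species are matched to tree taxa case-insensitively with
    spaces and underscores interchangeable; unmatched names raise.
    """
    n = len(species)
    if n < 3 or (lam == "ML" and n < 4):
        raise ValidationError("need >= 3 species (>= 4 for ML lambda)")
    tree_keys = {normalize_name(t): t for t in tree.taxa}
    order = []
    missing = []
    for s in species:
        key = normalize_name(s.species)
        if key in tree_keys:
            order.append(tree_keys[key])
        else:
            missing.append(s.species)
    if missing:
        raise ValidationError(f"species not found in tree: {missing}")

    xv = np.array([getattr(s, x_field) for s in species], dtype=float)
    yv = np.array([getattr(s, y_field) for s in species], dtype=float)
    if log10_axes:
        xv, yv = np.log10(xv), np.log10(yv)
    X = np.column_stack([np.ones(n), xv])
    C_full = tree.shared_depth_matrix(order)

    def cov(l: float) -> np.ndarray:
        Cl = l * C_full
        np.fill_diagonal(Cl, np.diag(C_full))
        return Cl

    if lam == "ML":
        def neg_loglik(l: float) -> float:
            return -_gls_profile(X, yv, cov(l))[2]

        res = optimize.minimize_scalar(
            neg_loglik, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        # interior optimum can be beaten by an endpoint; check both
        candidates = [(neg_loglik(0.0), 0.0), (neg_loglik(1.0), 1.0),
                      (res.fun, float(res.x))]
        _, lam_hat = min(candidates)
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValidationError("lambda must lie in [0, 1]")

    beta, rss, loglik, L, Xw, yw = _gls_profile(X, yv, cov(lam_hat))
    df = n - 2
    s2 = rss / df
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    # whitened intercept-only model for the R² baseline
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float((ones_w @ yw) / (ones_w @ ones_w))
    tss = float(np.sum((yw - mu * ones_w) ** 2))
    t_slope = beta[1] / se[1]
    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        lambda_hat=float(lam_hat),
        log_likelihood=float(loglik),
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
        n=n,
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        p_slope=float(2.0 * stats.t.sf(abs(t_slope), df)),
    )


def compare_groups(
    species: Sequence[SpeciesGrowthRecord],
    group_labels: Mapping[str, str],
    parameter: str = "phi_prime",
    log_transform: bool = False,
    equal_var: bool = False,
) -> SlopeComparison:
    """Two-sample t-test (Welch by default) of a growth parameter between groups.

    ``group_labels`` maps species name to one of exactly two group
    labels; ``parameter`` is ``K``, ``L_inf`` or ``phi_prime``. The
    reported ``slope_1``/``slope_2`` fields carry the group means, in
    label-sorted order.
    """
    if parameter not in ("K", "L_inf", "phi_prime"):
        raise ValidationError(f"unknown parameter {parameter!r}")
    groups: dict[str, list[float]] = {}
    for s in species:
        if s.species not in group_labels:
            continue
        v = getattr(s, parameter)
        if v is None:
            v = growth_performance(s.L_inf, s.K)
        groups.setdefault(group_labels[s.species], []).append(
            math.log10(v) if log_transform else float(v)
        )
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {sorted(groups)}")
    (la, a), (lb, b) = sorted(groups.items())
    if min(len(a), len(b)) < 2:
        raise ValidationError("each group needs >= 2 species")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = (len(a) + len(b) - 2) if equal_var else float(res.df)
    return SlopeComparison(
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        slope_1=float(np.mean(a)),
        slope_2=float(np.mean(b)),
        method=f"{'pooled' if equal_var else 'Welch'} t on {parameter}"
        + (" (log10)" if log_transform else "")
        + f", groups {la}|{lb}",
    )


def auximetric_table(
    species_sets: Mapping[str, Sequence[SpeciesGrowthRecord]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready auximetric scatter plus iso-phi' reference lines.

    Returns ``(points, iso_lines)``: one point row per species with
    log10-transformed parameters and phi', and per group a slope -2 line
    through the group's mean phi' (log10 K = phi' - 2 log10 L_inf),
    along which growth performance is constant.
    """
    rows = []
    for group, records in species_sets.items():
        if not records:
            raise ValidationError(f"group {group!r} is empty")
        for s in records:
            phi = (
                s.phi_prime
                if s.phi_prime is not None
                else growth_performance(s.L_inf, s.K)
            )
            rows.append(
                {
                    "species": s.species,
                    "group": group,
                    "log10_L_inf": math.log10(s.L_inf),
                    "log10_K": math.log10(s.K),
                    "phi_prime": phi,
                }
            )
    points = pd.DataFrame(rows)
    iso = (
        points.groupby("group", sort=True)["phi_prime"]
        .mean()
        .rename("mean_phi_prime")
        .reset_index()
    )
    iso["slope"] = -2.0
    iso["intercept"] = iso["mean_phi_prime"]
    return points, iso
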