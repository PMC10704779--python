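"""Von Bertalanffy growth modelling.

The von Bertalanffy growth function (VBGF)

    L(t) = L_inf * (1 - exp(-K * (t - t0)))

describes asymptotic growth in length: ``L_inf`` (cm) is the asymptotic
length, ``K`` (1/yr) the rate at which it is approached, and ``t0`` (yr)
the theoretical age at zero length. Parameters are estimated by
unconstrained nonlinear least squares on (age, length) pairs; standard
errors come from the Jacobian-based covariance s^2 (J'J)^-1 at the
optimum, and per-parameter t statistics use df = n - 3.

Slow-growing, long-lived fish sampled over a narrow age window (e.g. a
mature-only subset) often leave (L_inf, K) nearly unidentifiable: the
optimizer wanders to enormous L_inf with tiny K and the standard errors
explode. Such fits are returned, flagged, never silently dropped —
reporting the failure is part of the analysis.

The growth performance index

    phi_prime = log10(K) + 2 * log10(L_inf)

collapses the negatively correlated (K, L_inf) pair into a single number
comparable across species; it is constant along slope -2 lines in
(log10 L_inf, log10 K) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .io_model import IndividualRecord, Sex, ValidationError

__all__ = [
    "VBGFParams",
    "GrowthFit",
    "vbgf_predict",
    "vbgf_jacobian",
    "default_start",
    "fit_vbgf",
    "fit_vbgf_partitions",
    "growth_performance",
    "DEFAULT_PARTITIONS",
]

_PARAM_NAMES = ("L_inf", "K", "t0")


@dataclass(frozen=True)
class VBGFParams:
    """VBGF parameter triple. ``K <= 0`` is tolerated mid-optimization but
    flagged in fit results; ``L_inf`` must be positive."""

    L_inf: float
    K: float
    t0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L_inf, self.K, self.t0], dtype=float)


@dataclass
class GrowthFit:
    """A fitted VBGF with per-parameter inference.

    ``se``, ``t_stat`` and ``p_value`` are keyed by parameter name;
    ``t_stat[k] = estimate_k / se_k`` and P-values are two-sided from
    Student's t with ``df = n - 3``. ``feasible`` is False when the
    partition had too few fish to attempt a fit; ``converged`` reflects
    optimizer status; ``k_nonpositive`` flags a fitted K <= 0.
    """

    params: VBGFParams | None
    se: dict[str, float] = field(default_factory=dict)
    t_stat: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    n: int = 0
    rss: float = float("nan")
    converged: bool = False
    feasible: bool = True
    singular: bool = False
    k_nonpositive: bool = False
    partition_label: str = ""
    message: str = ""

    def to_row(self) -> dict:
        row: dict = {"partition": self.partition_label, "n": self.n}
        for name in _PARAM_NAMES:
            row[name] = getattr(self.params, name) if self.params else float("nan")
            row[f"se_{name}"] = self.se.get(name, float("nan"))
            row[f"t_{name}"] = self.t_stat.get(name, float("nan"))
            row[f"p_{name}"] = self.p_value.get(name, float("nan"))
        row.update(
            rss=self.rss,
            converged=self.converged,
            feasible=self.feasible,
            singular=self.singular,
        )
        return row


def vbgf_predict(params: VBGFParams, age) -> np.ndarray | float:
    """Length at age under the VBGF; vectorized over ``age``."""
    age = np.asarray(age, dtype=float)
    out = params.L_inf * (1.0 - np.exp(-params.K * (age - params.t0)))
    return out if out.ndim else float(out)


def vbgf_jacobian(params: VBGFParams, age) -> np.ndarray:
    """Analytic Jacobian of the VBGF, columns (dL/dL_inf, dL/dK, dL/dt0)."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    e = np.exp(-params.K * (age - params.t0))
    return np.column_stack(
        [1.0 - e, params.L_inf * (age - params.t0) * e, -params.L_inf * params.K * e]
    )


def default_start(ages: Sequence[float], lengths: Sequence[float]) -> VBGFParams:
    """Data-driven starting values.

    L_inf starts at 1.1x the largest observed length; K from the slope of
    the linearization log(1 - L/L_inf0) against age (which is -K when
    L_inf0 is right); t0 at 0. Falls back to K = 0.1/yr when the
    linearization is uninformative.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    L0 = 1.1 * float(lengths.max())
    z = np.log(np.clip(1.0 - lengths / L0, 1e-12, None))
    if np.ptp(ages) > 0:
        slope = float(np.polyfit(ages, z, 1)[0])
        K0 = -slope if slope < 0 else 0.1
    else:
        K0 = 0.1
    return VBGFParams(L_inf=L0, K=K0, t0=0.0)


def fit_vbgf(
    ages: Sequence[float],
    lengths: Sequence[float],
    start: VBGFParams | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    label: str = "",
) -> GrowthFit:
    """Fit the VBGF to (age, length) pairs by nonlinear least squares.

    Unconstrained by default (pass ``bounds`` to box-constrain);
    residuals are unweighted. Non-convergence or a singular Jacobian is
    reported through flags, never raised.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if ages.shape != lengths.shape or ages.ndim != 1:
        raise ValueError("ages and lengths must be equal-length 1-D sequences")
    n = ages.size
    if n < 4:
        raise ValidationError(f"need >= 4 (age, length) pairs, got {n}")
    if np.ptp(ages) == 0:
        raise ValidationError("ages are all equal; VBGF is unidentifiable")
    if start is None:
        start = default_start(ages, lengths)

    def resid(theta: np.ndarray) -> np.ndarray:
        return vbgf_predict(VBGFParams(*theta), ages) - lengths

    def jac(theta: np.ndarray) -> np.ndarray:
        return vbgf_jacobian(VBGFParams(*theta), ages)

    kwargs: dict = dict(ftol=ftol, xtol=xtol, gtol=1e-12)
    if bounds is not None:
        kwargs["bounds"] = bounds
        kwargs["method"] = "trf"
    else:
        kwargs["method"] = "lm"
    res = optimize.least_squares(resid, start.as_array(), jac=jac, **kwargs)

    params = VBGFParams(*res.x)
    rss = float(2.0 * res.cost)
    fit = GrowthFit(
        params=params,
        n=n,
        rss=rss,
        converged=bool(res.success),
        k_nonpositive=params.K <= 0,
        partition_label=label,
        message=res.message,
    )
    df = n - 3
    J = vbgf_jacobian(params, ages)
    JtJ = J.T @ J
    # covariance via pinv would hide rank deficiency; detect it explicitly
    cond = np.linalg.cond(JtJ)
    if not np.isfinite(cond) or cond > 1e14 or df <= 0:
        fit.singular = True
        return fit
    cov = rss / df * np.linalg.inv(JtJ)
    se = np.sqrt(np.diag(cov))
    est = params.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = est / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    fit.se = dict(zip(_PARAM_NAMES, se.tolist()))
    fit.t_stat = dict(zip(_PARAM_NAMES, tvals.tolist()))
    fit.p_value = dict(zip(_PARAM_NAMES, pvals.tolist()))
    return fit


DEFAULT_PARTITIONS = (
    "total",
    "female",
    "male",
    "female&juvenile",
    "male&juvenile",
)


def _partition_members(
    individuals: Sequence[IndividualRecord], label: str
) -> list[IndividualRecord]:
    by_sex = {
        "total": None,
        "female": {Sex.FEMALE},
        "male": {Sex.MALE},
        "juvenile": {Sex.JUVENILE},
        "female&juvenile": {Sex.FEMALE, Sex.JUVENILE},
        "male&juvenile": {Sex.MALE, Sex.JUVENILE},
    }
    if label not in by_sex:
        raise ValidationError(f"unknown partition label {label!r}")
    keep = by_sex[label]
    return [r for r in individuals if keep is None or r.sex_class in keep]


def fit_vbgf_partitions(
    individuals: Sequence[IndividualRecord],
    partitions: Iterable[str] = DEFAULT_PARTITIONS,
    age_field: str = "age_otolith",
    **fit_kwargs,
) -> list[GrowthFit]:
    """Fit the VBGF separately to labelled subsets of the cohort.

    The default five-series design fits all fish, each sex alone, and
    each sex pooled with the juveniles (juveniles appear in both mixed
    partitions). A partition with fewer than four aged fish is returned
    as an infeasible flagged fit; the others proceed.
    """
    fits = []
    for label in partitions:
        members = [
            r for r in _partition_members(individuals, label)
            if getattr(r, age_field) is not None
        ]
        if len(members) < 4:
            fits.append(
                GrowthFit(
                    params=None,
                    n=len(members),
                    feasible=False,
                    partition_label=label,
                    message="fewer than 4 aged fish",
                )
            )
            continue
        ages = [getattr(r, age_field) for r in members]
        lengths = [r.total_length for r in members]
        fits.append(fit_vbgf(ages, lengths, label=label, **fit_kwargs))
    return fits


def growth_performance(L_inf: float, K: float) -> float:
    """Growth performance index phi' = log10(K) + 2 log10(L_inf)."""
    if not (L_inf > 0 and K > 0):
        raise ValidationError("growth_performance requires L_inf > 0 and K > 0")
    return float(np.log10(K) + 2.0 * np.log10(L_inf))
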