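"""Age-reading precision and between-structure agreement.

Ages are read repeatedly (three times in the standard protocol) from two
calcified structures per fish — lapillus otoliths and vertebrae. Two
standard precision indices summarise between-reading agreement:

* APE (average percent error, Beamish-Fournier): per fish,
  ``100 * mean_i |X_ij - mean_j| / mean_j``, averaged over fish.
* ACV (average coefficient of variation, Chang): per fish,
  ``100 * sd_j / mean_j`` with the sample SD (divisor R-1), averaged
  over fish.

Both are scale-free percentages; both are zero exactly when every fish's
reads agree. For R = 2 reads, ACV = sqrt(2) * APE identically.

The two structures are compared on their consensus ages by ordinary
least squares (vertebral age on otolith age); a slope-fixed-at-one mode
estimates only the mean offset, for protocols that assume the structures
count the same annuli.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_model import LinearFit, ReadingSet, Structure, ValidationError

__all__ = [
    "PrecisionSummary",
    "StructureComparison",
    "per_fish_ape",
    "per_fish_cv",
    "ape",
    "acv",
    "precision_summary",
    "consensus_age",
    "compare_structures",
]


@dataclass
class PrecisionSummary:
    structure: Structure
    n_fish: int
    ape_percent: float
    acv_percent: float
    per_fish_ape: list[float] = field(default_factory=list)
    per_fish_cv: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.value,
            "n_fish": self.n_fish,
            "ape_percent": self.ape_percent,
            "acv_percent": self.acv_percent,
        }


def _check(rs: ReadingSet) -> np.ndarray:
    x = np.asarray(rs.readings, dtype=float)
    if x.size < 2:
        raise ValidationError(f"{rs.fish_id}: need >= 2 readings")
    if x.mean() <= 0:
        raise ValidationError(f"{rs.fish_id}: mean reading must be > 0")
    return x


def per_fish_ape(rs: ReadingSet) -> float:
    x = _check(rs)
    m = x.mean()
    return float(100.0 * np.mean(np.abs(x - m)) / m)


def per_fish_cv(rs: ReadingSet, ddof: int = 1) -> float:
    x = _check(rs)
    return float(100.0 * x.std(ddof=ddof) / x.mean())


def ape(reading_sets: Sequence[ReadingSet]) -> float:
    """Average percent error: unweighted mean of per-fish APE."""
    if not reading_sets:
        raise ValidationError("no reading sets")
    return float(np.mean([per_fish_ape(rs) for rs in reading_sets]))


def acv(reading_sets: Sequence[ReadingSet], ddof: int = 1) -> float:
    """Average coefficient of variation: unweighted mean of per-fish CV.

    ``ddof=1`` (sample SD) is the convention of the precision
    literature; pass ``ddof=0`` for the population-SD variant.
    """
    if not reading_sets:
        raise ValidationError("no reading sets")
    return float(np.mean([per_fish_cv(rs, ddof=ddof) for rs in reading_sets]))


def precision_summary(reading_sets: Sequence[ReadingSet]) -> PrecisionSummary:
    structures = {rs.structure for rs in reading_sets}
    if len(structures) != 1:
        raise ValidationError("reading sets mix structures; summarise one at a time")
    return PrecisionSummary(
        structure=structures.pop(),
        n_fish=len(reading_sets),
        ape_percent=ape(reading_sets),
        acv_percent=acv(reading_sets),
        per_fish_ape=[per_fish_ape(rs) for rs in reading_sets],
        per_fish_cv=[per_fish_cv(rs) for rs in reading_sets],
    )


def consensus_age(rs: ReadingSet, rule: str = "median") -> tuple[float, bool]:
    """Collapse repeated reads to one age; returns (age, needs_reread).

    ``median`` (default) is deterministic and never flags. ``modal``
    returns the most frequent read when one exists; when all reads
    disagree (or tie), it falls back to the median as a provisional age
    and raises the re-read flag — in the wet-lab protocol such fish go
    back under the microscope for a consensus read.
    """
    x = list(rs.readings)
    if rule == "median":
        return float(statistics.median(x)), False
    if rule == "modal":
        counts = {v: x.count(v) for v in set(x)}
        top = max(counts.values())
        modes = [v for v, c in counts.items() if c == top]
        if top > 1 and len(modes) == 1:
            return float(modes[0]), False
        return float(statistics.median(x)), True
    raise ValidationError(f"unknown consensus rule {rule!r}")


@dataclass
class StructureComparison:
    """Agreement between otolith and vertebral ages on matched fish."""

    fit: LinearFit
    otolith: PrecisionSummary
    vertebra: PrecisionSummary
    n_matched: int


def compare_structures(
    otolith_sets: Sequence[ReadingSet],
    vertebra_sets: Sequence[ReadingSet],
    fix_slope: bool = False,
    consensus_rule: str = "median",
) -> StructureComparison:
    """Regress vertebral consensus age on otolith consensus age.

    Fish are matched by ``fish_id``; unmatched fish are excluded from
    the regression but the per-structure precision summaries cover the
    matched fish only, so the two summaries describe the same animals.
    With ``fix_slope`` the slope is held at exactly 1 and only the mean
    offset (intercept) is estimated.
    """
    ot = {rs.fish_id: rs for rs in otolith_sets}
    ve = {rs.fish_id: rs for rs in vertebra_sets}
    matched = sorted(set(ot) & set(ve))
    if len(matched) < 3:
        raise ValidationError(f"need >= 3 matched fish, got {len(matched)}")
    x = np.array([consensus_age(ot[f], consensus_rule)[0] for f in matched])
    y = np.array([consensus_age(ve[f], consensus_rule)[0] for f in matched])
    n = len(matched)
    if fix_slope:
        c = float(np.mean(y - x))
        resid = y - x - c
        dof = n - 1
        s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
        tss = float(np.sum((y - y.mean()) ** 2))
        fit = LinearFit(
            slope=1.0,
            intercept=c,
            se_slope=0.0,
            se_intercept=float(np.sqrt(s2 / n)),
            r_squared=1.0 - float(resid @ resid) / tss if tss > 0 else 1.0,
            n=n,
            p_slope=float("nan"),
            residual_sd=float(np.sqrt(s2)),
            label="vertebra~otolith (slope fixed at 1)",
        )
    else:
        from .allometry import linear_fit_xy

        fit = linear_fit_xy(x, y, label="vertebra~otolith")
    return StructureComparison(
        fit=fit,
        otolith=precision_summary([ot[f] for f in matched]),
        vertebra=precision_summary([ve[f] for f in matched]),
        n_matched=n,
    )
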