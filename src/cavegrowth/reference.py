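"""Published growth-parameter tables used as comparison inputs.

Two literature-compiled tables ship with the package:

* :data:`TRIPLOPHYSA_GROWTH` — von Bertalanffy parameters, growth
  performance index and habitat metadata for six *Triplophysa* loaches
  (the troglobitic cave species *T. rosa* and five epigean congeners),
  as printed in the source literature.
* :data:`TROSA_VBGF_TABLE` — the published five-partition VBGF fits for
  the *T. rosa* cohort (estimate ± SE, t, P per parameter), used to
  validate inference conventions (t = estimate/SE, two-sided P at
  df = n - 3) against an independently produced table.

Printed numbers are kept as strings alongside their float values so
rounding precision (the decimal ulp of each printed figure) is
recoverable; helper functions propagate that rounding into tolerances
for consistency checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_model import SpeciesGrowthRecord

__all__ = [
    "TRIPLOPHYSA_GROWTH",
    "TROSA_VBGF_TABLE",
    "VBGFTableCell",
    "VBGFTableRow",
    "triplophysa_species",
    "half_ulp",
    "phi_prime_rounding_tolerance",
    "ratio_rounding_tolerance",
]

# species, habitat, L_inf (cm), K (1/yr), t0 (yr), phi', temperature (C), altitude (m)
# — printed values as strings so each figure's precision is preserved.
TRIPLOPHYSA_GROWTH: tuple[dict, ...] = (
    dict(species="Triplophysa rosa", habitat="troglobitic", L_inf="23.4",
         K="0.060", t0="0.12", phi_prime="1.52", temperature=15, altitude=350),
    dict(species="Triplophysa anterodorsalis", habitat="epigean", L_inf="9.8",
         K="0.26", t0="-2.09", phi_prime="1.40", temperature=17, altitude=1600),
    dict(species="Triplophysa markehenensis", habitat="epigean", L_inf="17.3",
         K="0.16", t0="-0.53", phi_prime="1.68", temperature=4, altitude=3600),
    dict(species="Triplophysa stenura", habitat="epigean", L_inf="24.7",
         K="0.06", t0="0.17", phi_prime="1.56", temperature=3, altitude=4200),
    dict(species="Triplophysa orientalis", habitat="epigean", L_inf="15.2",
         K="0.13", t0="0.02", phi_prime="1.49", temperature=7, altitude=3500),
    dict(species="Triplophysa stewarti", habitat="epigean", L_inf="13.9",
         K="0.17", t0="2.10", phi_prime="1.51", temperature=4, altitude=4600),
)


def triplophysa_species() -> list[SpeciesGrowthRecord]:
    """The six-species comparison table as domain records."""
    return [
        SpeciesGrowthRecord(
            species=row["species"],
            L_inf=float(row["L_inf"]),
            K=float(row["K"]),
            t0=float(row["t0"]),
            phi_prime=float(row["phi_prime"]),
            habitat_type=row["habitat"],
            temperature=float(row["temperature"]),
            altitude=float(row["altitude"]),
            source="literature compilation",
        )
        for row in TRIPLOPHYSA_GROWTH
    ]


@dataclass(frozen=True)
class VBGFTableCell:
    """One parameter's printed estimate ± SE, t and P."""

    estimate: str
    se: str
    t: str
    p: str  # "<0.001" or a decimal string

    @property
    def p_is_bound(self) -> bool:
        return self.p.startswith("<")


@dataclass(frozen=True)
class VBGFTableRow:
    partition: str
    n: int
    L_inf: VBGFTableCell
    K: VBGFTableCell
    t0: VBGFTableCell

    @property
    def cells(self) -> dict[str, VBGFTableCell]:
        return {"L_inf": self.L_inf, "K": self.K, "t0": self.t0}


# Published five-partition VBGF fits for the T. rosa cohort (n = 102:
# 32 females, 33 males, 37 juveniles). The male L_inf cell is internally
# inconsistent in the source (271.7/433.9 = 0.626, printed t = 0.051;
# the printed t and P do agree with each other at df = n - 3), i.e. the
# printed estimate or SE carries a typo — flagged here so checks can
# treat that single cell accordingly.
TROSA_VBGF_TABLE: tuple[VBGFTableRow, ...] = (
    VBGFTableRow("total", 102,
                 VBGFTableCell("23.4", "6.5", "3.604", "<0.001"),
                 VBGFTableCell("0.060", "0.026", "2.313", "0.023"),
                 VBGFTableCell("0.12", "0.60", "0.196", "0.845")),
    VBGFTableRow("female", 32,
                 VBGFTableCell("102.17", "754.1", "0.135", "0.893"),
                 VBGFTableCell("0.008", "0.065", "0.122", "0.904"),
                 VBGFTableCell("-3.90", "5.54", "-0.704", "0.487")),
    VBGFTableRow("male", 33,
                 VBGFTableCell("271.7", "433.9", "0.051", "0.960"),
                 VBGFTableCell("0.003", "0.061", "0.050", "0.961"),
                 VBGFTableCell("-2.31", "3.19", "-0.725", "0.474")),
    VBGFTableRow("female&juvenile", 69,
                 VBGFTableCell("21.1", "4.99", "4.235", "<0.001"),
                 VBGFTableCell("0.077", "0.030", "2.533", "0.014"),
                 VBGFTableCell("0.60", "0.54", "1.096", "0.277")),
    VBGFTableRow("male&juvenile", 70,
                 VBGFTableCell("55.1", "86.9", "0.634", "0.528"),
                 VBGFTableCell("0.018", "0.033", "0.546", "0.587"),
                 VBGFTableCell("-1.16", "1.02", "-1.142", "0.258")),
)

# the one source cell where estimate/SE does not reproduce the printed t
INCONSISTENT_CELLS: frozenset[tuple[str, str]] = frozenset({("male", "L_inf")})


def half_ulp(printed: str) -> float:
    """Half a unit in the last printed decimal place of a number string."""
    printed = printed.lstrip("<>-+")
    if "." in printed:
        return 0.5 * 10.0 ** -(len(printed) - printed.index(".") - 1)
    return 0.5


def phi_prime_rounding_tolerance(L_inf: str, K: str, phi_prime: str) -> float:
    """Largest |recomputed - printed| phi' consistent with printed rounding.

    First-order propagation of half-ulp errors in the printed L_inf and
    K through phi' = log10 K + 2 log10 L_inf, plus the half-ulp of the
    printed phi' itself.
    """
    ln10 = math.log(10.0)
    return (
        half_ulp(K) / (float(K) * ln10)
        + 2.0 * half_ulp(L_inf) / (float(L_inf) * ln10)
        + half_ulp(phi_prime)
    )


def ratio_rounding_tolerance(estimate: str, se: str) -> float:
    """Largest |est/SE - printed t| consistent with rounding of est and SE."""
    e, s = abs(float(estimate)), float(se)
    return half_ulp(estimate) / s + e * half_ulp(se) / s**2
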