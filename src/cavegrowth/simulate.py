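"""Synthetic-data generators with the statistical structure the analysis assumes.

Every downstream stage — precision, allometry, growth, interspecific,
energy — can be exercised on data whose generating parameters are known,
so estimator behaviour (exactness at zero noise, bias, coverage,
identifiability failures) is testable without specimens.

The generators invert the analysis models:

* cohorts: age uniform on an observed range; true length from the VBGF;
  observed length with additive Gaussian error; weight from the power
  law with multiplicative lognormal error; sex assigned by a maturity
  age (younger fish are juveniles) and a female fraction among adults.
* age readings: replicated reads per structure = true age plus Gaussian
  reading error, optionally rounded to whole annuli.
* composition: each analyte linear in length plus Gaussian noise,
  truncated at zero (truncations counted, never silent).
* species sets: log10 L_inf uniform; log10 K linear in log10 L_inf with
  residuals either i.i.d. or Brownian-motion-correlated on a tree.
* trees: pure-birth (Yule) with unit birth rate.

Defaults mirror a real cave-loach cohort: 102 fish aged 3.3-15.8 yr,
VBGF (23.4 cm, 0.060/yr, 0.12 yr), weight 0.0046 L^3.03, maturity at
4.8 yr — see docs/methods.md for the provenance of every default.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_model import (
    CompositionRecord,
    IndividualRecord,
    Phylogeny,
    ReadingSet,
    Sex,
    SpeciesGrowthRecord,
    Structure,
    ValidationError,
)
from .growth import VBGFParams, growth_performance, vbgf_predict

__all__ = [
    "ConfigError",
    "CohortSimConfig",
    "ReadingSimConfig",
    "SpeciesSimConfig",
    "DEFAULT_COMPOSITION_TRENDS",
    "simulate_cohort",
    "simulate_readings",
    "simulate_composition",
    "simulate_species_set",
    "simulate_tree",
]


class ConfigError(ValueError):
    """A simulation configuration that cannot generate valid data."""


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generator settings; defaults emulate the studied cave loach."""

    n_fish: int = 102
    age_range: tuple[float, float] = (3.3, 15.8)
    vbgf_true: tuple[float, float, float] = (23.4, 0.060, 0.12)
    length_noise_sd: float = 0.5
    lwr_true: tuple[float, float] = (0.0046, 3.03)
    weight_lognoise_sd: float = 0.1  # SD of natural-log weight error
    maturity_age: float = 4.8
    sex_ratio: float = 0.5  # P(female | mature)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 4:
            raise ConfigError("n_fish must be >= 4")
        if self.length_noise_sd < 0 or self.weight_lognoise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        lo, hi = self.age_range
        t0 = self.vbgf_true[2]
        if not (t0 < lo <= hi):
            raise ConfigError("age_range must lie within (t0, inf)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must be in [0, 1]")


@dataclass(frozen=True)
class ReadingSimConfig:
    """Replicated-read generator; three reads per structure by default.

    Otolith and vertebral reading errors are independently configurable
    (otoliths are typically the more precise structure)."""

    n_reads: int = 3
    otolith_sd: float = 0.4
    vertebra_sd: float = 0.5
    rounding: str = "none"  # or "nearest_integer"
    min_read: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 2:
            raise ConfigError("n_reads must be >= 2")
        if self.otolith_sd < 0 or self.vertebra_sd < 0:
            raise ConfigError("reading SDs must be >= 0")
        if self.rounding not in ("none", "nearest_integer"):
            raise ConfigError(f"unknown rounding mode {self.rounding!r}")


@dataclass(frozen=True)
class SpeciesSimConfig:
    """Species-set generator for the interspecific K-L_inf allometry."""

    n_species: int = 20
    log10_Linf_range: tuple[float, float] = (0.95, 1.45)
    allometry_true: tuple[float, float] = (-1.64, 1.09)  # (slope, intercept)
    residual_sd: float = 0.05
    evolve_on_tree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")


def simulate_cohort(config: CohortSimConfig) -> list[IndividualRecord]:
    """Draw a cohort of individual fish from the generating models.

    The generated ``age_otolith`` is the (continuous) true age; reading
    error is layered on separately by :func:`simulate_readings`.
    Observed lengths are redrawn until positive (relevant only at
    extreme noise).
    """
    rng = np.random.default_rng(config.seed)
    params = VBGFParams(*config.vbgf_true)
    lo, hi = config.age_range
    if vbgf_predict(params, lo) <= 0:
        raise ConfigError("VBGF gives nonpositive length at the youngest age")
    ages = rng.uniform(lo, hi, config.n_fish)
    true_len = vbgf_predict(params, ages)
    obs_len = true_len + rng.normal(0.0, config.length_noise_sd, config.n_fish)
    bad = obs_len <= 0
    while bad.any():  # truncation to positive support by redraw
        obs_len[bad] = true_len[bad] + rng.normal(
            0.0, config.length_noise_sd, int(bad.sum())
        )
        bad = obs_len <= 0
    a, b = config.lwr_true
    weight = a * obs_len**b * np.exp(
        rng.normal(0.0, config.weight_lognoise_sd, config.n_fish)
    )
    mature = ages >= config.maturity_age
    female = rng.random(config.n_fish) < config.sex_ratio
    ndigits = len(str(config.n_fish))
    records = []
    for i in range(config.n_fish):
        sex = (
            Sex.JUVENILE
            if not mature[i]
            else (Sex.FEMALE if female[i] else Sex.MALE)
        )
        records.append(
            IndividualRecord(
                fish_id=f"f{i + 1:0{ndigits}d}",
                sex_class=sex,
                total_length=float(obs_len[i]),
                body_weight=float(weight[i]),
                age_otolith=float(ages[i]),
                collection_label="simulated",
            )
        )
    return records


def simulate_readings(
    individuals: Sequence[IndividualRecord], config: ReadingSimConfig
) -> dict[Structure, list[ReadingSet]]:
    """Replicated noisy age reads per fish for both structures.

    Uses each fish's ``age_otolith`` as the true age; each read is truth
    plus Gaussian error at the structure's SD, optionally rounded to the
    nearest whole annulus, floored at ``min_read``.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[Structure, list[ReadingSet]] = {}
    sds = {
        Structure.OTOLITH: config.otolith_sd,
        Structure.VERTEBRA: config.vertebra_sd,
    }
    for structure, sd in sds.items():
        sets = []
        for r in individuals:
            if r.age_otolith is None:
                raise ValidationError(f"{r.fish_id}: no true age to read")
            reads = r.age_otolith + rng.normal(0.0, sd, config.n_reads)
            if config.rounding == "nearest_integer":
                reads = np.round(reads)
            reads = np.maximum(reads, config.min_read)
            sets.append(
                ReadingSet(
                    fish_id=r.fish_id,
                    structure=structure,
                    readings=tuple(float(v) for v in reads),
                )
            )
        out[structure] = sets
    return out


# analyte -> (intercept mg/g, slope mg/g per cm, per-fish noise SD mg/g).
# The lipid trend rises steeply and detectably with length; protein, ash
# and glycogen drift gently downward but are noisy enough that their
# slopes are usually *not* significant at cohort scale — the pattern the
# composition stage is meant to reproduce. The implied energy slope is
# (23.6*(-2) + 39.5*11.3 + 17.2*(-0.05))/1000 ~ 0.40 kJ/g/cm.
DEFAULT_COMPOSITION_TRENDS: dict[str, tuple[float, float, float]] = {
    "protein": (140.0, -2.0, 45.0),
    "lipid": (-13.0, 11.3, 35.0),
    "glycogen": (6.0, -0.05, 2.0),
    "ash": (35.0, -0.5, 10.0),
}


def simulate_composition(
    individuals: Sequence[IndividualRecord],
    trends: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> list[CompositionRecord]:
    """Per-fish proximate composition, linear in length plus Gaussian noise.

    ``trends`` maps analyte to (intercept, slope, sd). A configuration
    whose expected analyte goes negative anywhere over the cohort's
    length range triggers a warning; realized negative draws are
    truncated at zero and the truncation count is reported via warning.
    Energy is left blank — it is computed downstream, never generated.
    """
    trends = dict(DEFAULT_COMPOSITION_TRENDS, **(trends or {}))
    rng = np.random.default_rng(seed)
    lengths = np.array([r.total_length for r in individuals])
    for analyte, (c0, c1, sd) in trends.items():
        if sd < 0:
            raise ConfigError(f"{analyte}: sd must be >= 0")
        expected = c0 + c1 * lengths
        if (expected < 0).any():
            warnings.warn(
                f"{analyte}: expected value negative for "
                f"{int((expected < 0).sum())} fish; draws will be truncated at 0",
                stacklevel=2,
            )
    records = []
    n_trunc = 0
    for r in individuals:
        values = {}
        for analyte in ("protein", "lipid", "glycogen", "ash"):
            c0, c1, sd = trends[analyte]
            v = c0 + c1 * r.total_length + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            if v < 0:
                n_trunc += 1
                v = 0.0
            values[analyte] = float(v)
        records.append(
            CompositionRecord(
                pool_id=r.fish_id, total_length=r.total_length, **values
            )
        )
    if n_trunc:
        warnings.warn(f"truncated {n_trunc} negative analyte draws to 0", stacklevel=2)
    return records


def simulate_species_set(
    config: SpeciesSimConfig, tree: Phylogeny | None = None
) -> list[SpeciesGrowthRecord]:
    """Species with a K-L_inf allometry and optional phylogenetic residuals.

    log10 L_inf is uniform on the configured range; log10 K = intercept
    + slope * log10 L_inf + residual. Residuals are i.i.d. Gaussian, or,
    with ``evolve_on_tree``, multivariate normal with the tree's
    Brownian covariance scaled so the *average* marginal SD equals
    ``residual_sd`` (tip variances differ on non-ultrametric trees).
    Species take the tree's taxon names when a tree is supplied.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    if config.evolve_on_tree:
        if tree is None:
            raise ConfigError("evolve_on_tree requires a tree")
        if len(tree) != n:
            raise ConfigError(
                f"tree has {len(tree)} taxa but n_species = {n}"
            )
        names = list(tree.taxa)
    else:
        names = [f"sp{i + 1:03d}" for i in range(n)]
    lo, hi = config.log10_Linf_range
    x = rng.uniform(lo, hi, n)
    slope, intercept = config.allometry_true
    if config.residual_sd == 0:
        resid = np.zeros(n)
    elif config.evolve_on_tree:
        C = tree.shared_depth_matrix(names)
        scale = config.residual_sd**2 / float(np.mean(np.diag(C)))
        resid = rng.multivariate_normal(np.zeros(n), scale * C, method="cholesky")
    else:
        resid = rng.normal(0.0, config.residual_sd, n)
    y = intercept + slope * x + resid
    records = []
    for i in range(n):
        L_inf = float(10.0**x[i])
        K = float(10.0 ** y[i])
        records.append(
            SpeciesGrowthRecord(
                species=names[i],
                L_inf=L_inf,
                K=K,
                t0=0.0,
                phi_prime=growth_performance(L_inf, K),
                habitat_type="simulated",
                source="simulate_species_set",
            )
        )
    return records


def simulate_tree(n_taxa: int, seed: int = 0, birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_taxa`` extant tips, deterministic per seed."""
    if n_taxa < 2:
        raise ConfigError("n_taxa must be >= 2")
    from dendropy.model import birthdeath

    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_taxa)])
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    # the process stops at the n-th speciation, leaving the newest tips with
    # zero-length terminal branches; run the clock one more exponential
    # waiting time so every terminal branch is positive (tree stays ultrametric)
    extra = rng.expovariate(n_taxa * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.is_rooted = True
    return Phylogeny(tree)
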