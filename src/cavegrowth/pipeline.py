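"""End-to-end pipeline: simulate or ingest, then run every analysis stage.

Stages run in dependency order — cohort (simulated or loaded), age
precision, length-weight allometry, partitioned VBGF fits, growth
performance / auximetric and interspecific comparisons, composition and
energy — and each stage's failure is recorded in the manifest without
aborting independent stages. A run is a pure function of its config
(including the seed): identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import ageing, allometry, energy, growth, interspecific, io_model, simulate
from .io_model import ValidationError
from .reference import triplophysa_species

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "simulate",
    "precision",
    "lwr",
    "growth",
    "interspecific",
    "composition",
)


@dataclass
class PipelineConfig:
    """One config drives the whole analysis.

    Either ``individuals_csv`` (plus optionally ``readings_csv`` and
    ``composition_csv``) points at real tables, or the ``simulate``
    stage generates everything from the cohort/reading configs. The
    species table for the interspecific stage defaults to the shipped
    six-loach literature compilation; a ``species_csv`` and
    ``tree_newick`` override it.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    maturity_age: float = 4.8
    alpha: float = 0.05
    individuals_csv: str | None = None
    readings_csv: str | None = None
    composition_csv: str | None = None
    species_csv: str | None = None
    tree_newick: str | None = None
    cohort: simulate.CohortSimConfig = field(default_factory=simulate.CohortSimConfig)
    readings: simulate.ReadingSimConfig = field(
        default_factory=simulate.ReadingSimConfig
    )
    energy_coefficients: energy.EnergyCoefficients = field(
        default_factory=energy.EnergyCoefficients
    )
    partitions: tuple[str, ...] = growth.DEFAULT_PARTITIONS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        seed = int(raw.get("seed", 0))
        for key in (
            "stages", "maturity_age", "alpha", "individuals_csv",
            "readings_csv", "composition_csv", "species_csv", "tree_newick",
            "partitions",
        ):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key in ("stages", "partitions") else raw[key]
        kwargs["seed"] = seed
        if "cohort" in raw:
            kwargs["cohort"] = simulate.CohortSimConfig(
                **{**raw["cohort"], "seed": raw["cohort"].get("seed", seed)}
            )
        else:
            kwargs["cohort"] = simulate.CohortSimConfig(seed=seed)
        if "readings" in raw:
            kwargs["readings"] = simulate.ReadingSimConfig(
                **{**raw["readings"], "seed": raw["readings"].get("seed", seed + 1)}
            )
        else:
            kwargs["readings"] = simulate.ReadingSimConfig(seed=seed + 1)
        if "energy_coefficients" in raw:
            kwargs["energy_coefficients"] = energy.EnergyCoefficients(
                **raw["energy_coefficients"]
            )
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.stages:
            raise ValidationError("no stages enabled")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        for attr in ("individuals_csv", "readings_csv", "composition_csv",
                     "species_csv", "tree_newick"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{attr}: path {p!r} does not exist")
        if "simulate" not in self.stages and self.individuals_csv is None:
            needs_cohort = {"precision", "lwr", "growth", "composition"}
            if needs_cohort & set(self.stages):
                raise ValidationError(
                    "cohort-dependent stages need either the simulate stage "
                    "or individuals_csv"
                )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> tuple[dict, dict]:
    """Execute the enabled stages; returns (bundle, manifest).

    The bundle maps result names to fit/summary objects (also written as
    CSVs under ``out_dir`` with a manifest); stage status, parameters
    and any error tracebacks are recorded in the manifest's ``stages``
    section.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    status: dict = {}
    data_files: list[str] = []
    individuals = None
    readings = None
    composition = None

    def run_stage(name, fn):
        try:
            fn()
            status[name] = {"status": "ok"}
        except Exception as exc:  # one stage failing must not kill the rest
            status[name] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(),
            }

    # --- data acquisition -------------------------------------------------
    def stage_data():
        nonlocal individuals, readings, composition
        if "simulate" in config.stages:
            individuals = simulate.simulate_cohort(config.cohort)
            readings = simulate.simulate_readings(individuals, config.readings)
            composition = simulate.simulate_composition(
                individuals, seed=config.readings.seed + 1
            )
            io_model.write_individuals(individuals, out / "cohort.csv")
            io_model.write_reading_sets(
                [rs for sets in readings.values() for rs in sets],
                out / "readings.csv",
            )
            io_model.write_composition(composition, out / "composition.csv")
            data_files.extend(["cohort.csv", "readings.csv", "composition.csv"])
        if config.individuals_csv:
            individuals = io_model.read_individuals(config.individuals_csv)
        if config.readings_csv:
            sets = io_model.read_reading_sets(config.readings_csv)
            readings = {
                s: [rs for rs in sets if rs.structure == s]
                for s in io_model.Structure
            }
        if config.composition_csv:
            composition = io_model.read_composition(config.composition_csv)

    run_stage("simulate", stage_data)
    if status["simulate"]["status"] == "error" and "simulate" in config.stages:
        # nothing downstream can run without data
        manifest = io_model.write_results(bundle, out)
        manifest["stages"] = status
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
        return bundle, manifest

    def stage_precision():
        if readings is None:
            raise ValidationError("no readings available")
        cmp = ageing.compare_structures(
            readings[io_model.Structure.OTOLITH],
            readings[io_model.Structure.VERTEBRA],
        )
        bundle["precision_summary"] = [cmp.otolith, cmp.vertebra]
        bundle["structure_agreement"] = cmp.fit

    def stage_lwr():
        fit = allometry.fit_lwr(individuals)
        bundle["lwr_fit"] = fit
        bundle["isometry_test"] = allometry.test_isometry(fit)
        try:
            slope_t, int_t = allometry.test_sex_effect(individuals)
            bundle["sex_slope_test"] = slope_t
            bundle["sex_intercept_test"] = int_t
        except ValidationError:
            pass  # too few sexed fish; LWR itself stands

    def stage_growth():
        fits = growth.fit_vbgf_partitions(
            individuals, partitions=config.partitions
        )
        bundle["vbgf_partitions"] = fits
        total = next(
            (f for f in fits if f.partition_label == "total" and f.params), None
        )
        if total is not None:
            bundle["growth_performance"] = {
                "phi_prime": growth.growth_performance(
                    total.params.L_inf, total.params.K
                ),
                "L_inf": total.params.L_inf,
                "K": total.params.K,
            }

    def stage_interspecific():
        species = (
            io_model.read_species_table(config.species_csv)
            if config.species_csv
            else triplophysa_species()
        )
        bundle["interspecific_ols"] = interspecific.fit_loglog_allometry(species)
        points, iso = interspecific.auximetric_table({"Triplophysa": species})
        bundle["auximetric_points"] = points
        bundle["auximetric_isolines"] = iso
        if config.tree_newick:
            tree = io_model.read_newick(config.tree_newick)
            bundle["interspecific_pgls"] = interspecific.fit_pgls(species, tree)

    def stage_composition():
        if composition is None:
            raise ValidationError("no composition data available")
        pooled = energy.pool_small_individuals(composition)
        annotated, _ = energy.annotate_energy(pooled, config.energy_coefficients)
        io_model.write_composition(annotated, out / "composition_pooled.csv")
        data_files.append("composition_pooled.csv")
        trends = {}
        for analyte in allometry.ANALYTES:
            trends[analyte] = allometry.fit_trend(annotated, analyte)
        bundle["composition_trends"] = list(trends.values())
        bundle["lipid_vs_protein_slopes"] = allometry.compare_trend_slopes(
            trends["lipid"], trends["protein"]
        )

    stage_fns = {
        "precision": stage_precision,
        "lwr": stage_lwr,
        "growth": stage_growth,
        "interspecific": stage_interspecific,
        "composition": stage_composition,
    }
    for name in config.stages:
        if name == "simulate":
            continue
        run_stage(name, stage_fns[name])

    manifest = io_model.write_results(
        {k: v for k, v in bundle.items() if not isinstance(v, dict)}, out
    )
    manifest["data_files"] = data_files
    manifest["stages"] = status
    manifest["seed"] = config.seed
    manifest["alpha"] = config.alpha
    if "growth_performance" in bundle:
        manifest["growth_performance"] = bundle["growth_performance"]
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return bundle, manifest


def _sig(p: float, alpha: float) -> str:
    return "significant" if p < alpha else "not significant"


def make_report(bundle: Mapping, alpha: float = 0.05) -> str:
    """Render a result bundle as a markdown summary, one section per stage."""
    lines = ["# Analysis report", ""]
    if "precision_summary" in bundle:
        lines += ["## Age-reading precision", ""]
        for s in bundle["precision_summary"]:
            lines.append(
                f"- {s.structure.value}: APE = {s.ape_percent:.2f}%, "
                f"ACV = {s.acv_percent:.2f}% (n = {s.n_fish})"
            )
        if "structure_agreement" in bundle:
            f = bundle["structure_agreement"]
            lines.append(
                f"- vertebra vs otolith age: slope {f.slope:.3f}, "
                f"intercept {f.intercept:.3f}, R^2 = {f.r_squared:.3f}"
            )
        lines.append("")
    if "lwr_fit" in bundle:
        f = bundle["lwr_fit"]
        lines += ["## Length-weight relationship", ""]
        lines.append(f"- {f.equation()} (R^2 = {f.r_squared:.3f}, n = {f.n})")
        if "isometry_test" in bundle:
            t = bundle["isometry_test"]
            lines.append(
                f"- isometry (b = 3): t = {t.t_statistic:.3f}, "
                f"P = {t.p_value:.3f} ({_sig(t.p_value, alpha)})"
            )
        lines.append("")
    if "vbgf_partitions" in bundle:
        lines += ["## Von Bertalanffy growth fits", ""]
        lines.append("| partition | n | L_inf | K | t0 | converged |")
        lines.append("|---|---|---|---|---|---|")
        for f in bundle["vbgf_partitions"]:
            if f.params is None:
                lines.append(f"| {f.partition_label} | {f.n} | - | - | - | infeasible |")
            else:
                lines.append(
                    f"| {f.partition_label} | {f.n} | "
                    f"{f.params.L_inf:.2f}±{f.se.get('L_inf', float('nan')):.2f} | "
                    f"{f.params.K:.3f}±{f.se.get('K', float('nan')):.3f} | "
                    f"{f.params.t0:.2f}±{f.se.get('t0', float('nan')):.2f} | "
                    f"{f.converged} |"
                )
        lines.append("")
    if "growth_performance" in bundle:
        g = bundle["growth_performance"]
        lines += [
            "## Growth performance",
            "",
            f"- phi' = {g['phi_prime']:.2f} "
            f"(L_inf = {g['L_inf']:.1f} cm, K = {g['K']:.3f}/yr)",
            "",
        ]
    if "interspecific_ols" in bundle:
        f = bundle["interspecific_ols"]
        lines += ["## Interspecific K-L_inf allometry", ""]
        lines.append(
            f"- OLS: log10 K = {f.slope:.2f} log10 L_inf + {f.intercept:.2f} "
            f"(R^2 = {f.r_squared:.2f}, P = {f.p_slope:.3f})"
        )
        if "interspecific_pgls" in bundle:
            p = bundle["interspecific_pgls"]
            lines.append(
                f"- PGLS (lambda = {p.lambda_hat:.2f}): log10 K = "
                f"{p.slope:.2f} log10 L_inf + {p.intercept:.2f} "
                f"(R^2 = {p.r_squared:.2f})"
            )
        lines.append("")
    if "composition_trends" in bundle:
        lines += ["## Composition and energy trends vs total length", ""]
        for f in bundle["composition_trends"]:
            lines.append(
                f"- {f.label}: slope {f.slope:.3f} (R^2 = {f.r_squared:.3f}, "
                f"P = {f.p_slope:.4f}, {_sig(f.p_slope, alpha)})"
            )
        lines.append("")
    return "\n".join(lines)
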