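"""Domain types and file I/O.

The analysis operates on three kinds of tabular input — individual fish
records, repeated age readings, and species-level growth parameters — plus
a newick phylogeny. All tables are plain CSV (comma-separated, UTF-8,
header row, ``.`` decimal separator); missing optional values are empty
cells. Column names are remappable so externally produced tables can be
ingested without editing.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "Sex",
    "Structure",
    "IndividualRecord",
    "ReadingSet",
    "SpeciesGrowthRecord",
    "CompositionRecord",
    "LinearFit",
    "Phylogeny",
    "read_individuals",
    "write_individuals",
    "read_species_table",
    "write_species_table",
    "read_composition",
    "write_composition",
    "read_reading_sets",
    "write_reading_sets",
    "read_newick",
    "write_results",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant; message lists offending rows."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    JUVENILE = "juvenile"


class Structure(str, enum.Enum):
    OTOLITH = "otolith"
    VERTEBRA = "vertebra"


@dataclass(frozen=True)
class IndividualRecord:
    """One fish: sex class, total length (cm), body weight (g), consensus ages.

    ``sex_class`` is determined from gonads for mature fish; individuals
    younger than the earliest observed maturity age are ``juvenile`` — a
    third age-defined class, not a sex. Ages are continuous years; the
    otolith age is the default input to growth modelling, the vertebral
    age is retained for the between-structure agreement analysis.
    """

    fish_id: str
    sex_class: Sex
    total_length: float
    body_weight: float
    age_otolith: float | None = None
    age_vertebra: float | None = None
    collection_label: str | None = None

    def __post_init__(self) -> None:
        if not self.total_length > 0:
            raise ValidationError(f"{self.fish_id}: total_length must be > 0")
        if not self.body_weight > 0:
            raise ValidationError(f"{self.fish_id}: body_weight must be > 0")
        for name in ("age_otolith", "age_vertebra"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{self.fish_id}: {name} must be > 0")


@dataclass(frozen=True)
class ReadingSet:
    """Replicated age counts for one fish on one bony structure."""

    fish_id: str
    structure: Structure
    readings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.readings) < 2:
            raise ValidationError(
                f"{self.fish_id}/{self.structure.value}: need >= 2 readings"
            )
        if any(not r > 0 for r in self.readings):
            raise ValidationError(
                f"{self.fish_id}/{self.structure.value}: readings must be > 0"
            )


@dataclass
class SpeciesGrowthRecord:
    """One species' von Bertalanffy parameters with habitat metadata.

    ``phi_prime`` is the growth performance index
    Φ′ = log10 K + 2 log10 L∞; when present it must agree with the stored
    parameters within rounding of the source from which it was copied.
    """

    species: str
    L_inf: float
    K: float
    t0: float = 0.0
    phi_prime: float | None = None
    habitat_type: str = ""
    temperature: float | None = None
    altitude: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.L_inf > 0:
            raise ValidationError(f"{self.species}: L_inf must be > 0")
        if not self.K > 0:
            raise ValidationError(f"{self.species}: K must be > 0")


@dataclass
class CompositionRecord:
    """Proximate composition (mg per g body mass) of one fish or one pool.

    Small fish of near-identical length are pooled upstream; ``pooled_n``
    records how many individuals the sample represents. ``energy`` (kJ/g)
    is derivable from the analytes and usually left blank on input.
    """

    pool_id: str
    total_length: float
    protein: float
    lipid: float
    glycogen: float
    ash: float
    energy: float | None = None
    pooled_n: int = 1

    def __post_init__(self) -> None:
        for name in ("protein", "lipid", "glycogen", "ash"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.pool_id}: {name} must be >= 0")
        if self.protein + self.lipid + self.glycogen + self.ash >= 1000:
            raise ValidationError(
                f"{self.pool_id}: analytes sum to >= 1000 mg/g"
            )
        if self.pooled_n < 1:
            raise ValidationError(f"{self.pool_id}: pooled_n must be >= 1")


@dataclass
class LinearFit:
    """A straight-line fit: slope, intercept, their SEs, R², n, P(slope)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    n: int
    p_slope: float
    residual_sd: float
    label: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy tree.

    Ultrametricity is *not* assumed; :meth:`is_ultrametric` reports it.
    The Brownian-motion trait covariance between two tips equals the
    depth of their most recent common ancestor (shared root-to-tip path
    length), computed here from pairwise patristic distances.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon names in tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")

    def __len__(self) -> int:
        return len(self.taxa)

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-tip path length per taxon."""
        self.tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self.tree.leaf_node_iter()
        }

    def shared_depth_matrix(self, taxa_order: Sequence[str] | None = None) -> np.ndarray:
        """Brownian covariance matrix C: C[i,j] = depth of MRCA(i, j).

        Computed as (d_i + d_j - patristic(i, j)) / 2, which equals the
        shared root-to-MRCA path length on any rooted tree.
        """
        order = list(taxa_order) if taxa_order is not None else self.taxa
        missing = set(order) - set(self.taxa)
        if missing:
            raise ValidationError(f"taxa not in tree: {sorted(missing)}")
        depths = self.leaf_depths()
        pdm = self.tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in self.tree.taxon_namespace}
        n = len(order)
        C = np.empty((n, n))
        for i, a in enumerate(order):
            C[i, i] = depths[a]
            for j in range(i + 1, n):
                b = order[j]
                d = pdm.patristic_distance(tax[a], tax[b])
                C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
        return C

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.leaf_depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# CSV readers / writers

_INDIVIDUAL_COLUMNS = (
    "fish_id",
    "sex_class",
    "total_length",
    "body_weight",
    "age_otolith",
    "age_vertebra",
    "collection_label",
)


def _remap(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_individuals(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[IndividualRecord]:
    """Read an individual-fish CSV into validated records.

    ``dialect`` maps canonical column names to the file's column names,
    e.g. ``{"total_length": "TL_cm"}``. Rows violating an invariant are
    reported together, indexed by row number, and nothing is returned.
    """
    df = _remap(pd.read_csv(path, float_precision="round_trip"), dialect)
    for col in ("fish_id", "sex_class", "total_length", "body_weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            sex = Sex(str(row["sex_class"]).strip().lower())
        except ValueError:
            problems.append(f"row {idx}: unknown sex_class {row['sex_class']!r}")
            continue
        try:
            records.append(
                IndividualRecord(
                    fish_id=str(row["fish_id"]),
                    sex_class=sex,
                    total_length=float(row["total_length"]),
                    body_weight=float(row["body_weight"]),
                    age_otolith=_opt_float(row.get("age_otolith")),
                    age_vertebra=_opt_float(row.get("age_vertebra")),
                    collection_label=(
                        str(row["collection_label"])
                        if "collection_label" in df.columns
                        and not pd.isna(row["collection_label"])
                        else None
                    ),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return records


def write_individuals(records: Iterable[IndividualRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["sex_class"] = r.sex_class.value
        rows.append(d)
    pd.DataFrame(rows, columns=_INDIVIDUAL_COLUMNS).to_csv(path, index=False)


def read_species_table(
    path: str | Path, phi_tol: float = 0.02
) -> list[SpeciesGrowthRecord]:
    """Read a species growth-parameter table (one row per species).

    ``phi_prime`` is recomputed from (L∞, K) when the column is absent or
    blank; when present it must agree with the recomputed value within
    ``phi_tol`` (rounding slack for values copied from printed tables).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("species", "L_inf", "K"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate species names: {dupes}")
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            phi = _opt_float(row.get("phi_prime"))
            rec = SpeciesGrowthRecord(
                species=str(row["species"]),
                L_inf=float(row["L_inf"]),
                K=float(row["K"]),
                t0=float(row.get("t0", 0.0) if not pd.isna(row.get("t0", 0.0)) else 0.0),
                phi_prime=phi,
                habitat_type=str(row.get("habitat_type", "") or ""),
                temperature=_opt_float(row.get("temperature")),
                altitude=_opt_float(row.get("altitude")),
                source=str(row.get("source", "") or ""),
            )
            recomputed = math.log10(rec.K) + 2 * math.log10(rec.L_inf)
            if rec.phi_prime is None:
                rec.phi_prime = recomputed
            elif abs(rec.phi_prime - recomputed) > phi_tol:
                problems.append(
                    f"row {idx} ({rec.species}): phi_prime {rec.phi_prime} "
                    f"inconsistent with parameters (recomputed {recomputed:.4f})"
                )
                continue
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return records


_SPECIES_COLUMNS = (
    "species",
    "habitat_type",
    "L_inf",
    "K",
    "t0",
    "phi_prime",
    "temperature",
    "altitude",
    "source",
)


def write_species_table(records: Iterable[SpeciesGrowthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=_SPECIES_COLUMNS
    ).to_csv(path, index=False)


_COMPOSITION_COLUMNS = (
    "pool_id",
    "total_length",
    "protein",
    "lipid",
    "glycogen",
    "ash",
    "energy",
    "pooled_n",
)


def read_composition(path: str | Path) -> list[CompositionRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("pool_id", "total_length", "protein", "lipid", "glycogen", "ash"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            records.append(
                CompositionRecord(
                    pool_id=str(row["pool_id"]),
                    total_length=float(row["total_length"]),
                    protein=float(row["protein"]),
                    lipid=float(row["lipid"]),
                    glycogen=float(row["glycogen"]),
                    ash=float(row["ash"]),
                    energy=_opt_float(row.get("energy")),
                    pooled_n=int(row.get("pooled_n", 1)),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return records


def write_composition(records: Iterable[CompositionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=_COMPOSITION_COLUMNS
    ).to_csv(path, index=False)


def read_reading_sets(path: str | Path) -> list[ReadingSet]:
    """Read a long-format readings CSV (fish_id, structure, read_index, value)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("fish_id", "structure", "read_index", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    sets = []
    for (fid, struct), grp in df.groupby(["fish_id", "structure"], sort=False):
        grp = grp.sort_values("read_index")
        sets.append(
            ReadingSet(
                fish_id=str(fid),
                structure=Structure(str(struct).strip().lower()),
                readings=tuple(float(v) for v in grp["value"]),
            )
        )
    return sets


def write_reading_sets(sets: Iterable[ReadingSet], path: str | Path) -> None:
    rows = [
        {
            "fish_id": s.fish_id,
            "structure": s.structure.value,
            "read_index": i,
            "value": v,
        }
        for s in sets
        for i, v in enumerate(s.readings)
    ]
    pd.DataFrame(rows, columns=["fish_id", "structure", "read_index", "value"]).to_csv(
        path, index=False
    )


def read_newick(path_or_string: str | Path) -> Phylogeny:
    """Read a single-tree newick file (or literal newick string)."""
    text = str(path_or_string)
    if not text.lstrip().startswith("("):
        text = Path(path_or_string).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable newick: {exc}") from exc
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Result bundles


def _result_to_frame(obj) -> pd.DataFrame:
    """Flatten a fit/result object (or list of them) to a one-or-more-row frame."""
    from . import growth  # late import to avoid a cycle

    if isinstance(obj, (list, tuple)):
        frames = [_result_to_frame(o) for o in obj]
        return pd.concat(frames, ignore_index=True)
    if isinstance(obj, growth.GrowthFit):
        return pd.DataFrame([obj.to_row()])
    if isinstance(obj, pd.DataFrame):
        return obj
    if hasattr(obj, "to_dict"):
        return pd.DataFrame([obj.to_dict()])
    if dataclasses.is_dataclass(obj):
        return pd.DataFrame([dataclasses.asdict(obj)])
    raise TypeError(f"cannot serialize result of type {type(obj)!r}")


def write_results(bundle: Mapping[str, object], out_dir: str | Path) -> dict:
    """Write every result in ``bundle`` as a CSV and return the manifest.

    The manifest (also written as ``manifest.json``) enumerates every file
    produced, keyed by bundle entry, in sorted order so repeated runs are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "n_results": 0}
    for name in sorted(bundle):
        frame = _result_to_frame(bundle[name])
        fname = f"{name}.csv"
        frame.to_csv(out / fname, index=False)
        manifest["files"][name] = fname
        manifest["n_results"] += 1
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
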