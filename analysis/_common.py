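"""Shared plumbing for the numbered analysis scripts.

One fixed master seed defines the synthetic study cohort every script
analyses, so the whole sequence is reproducible end to end. Scripts 02+
read the tables written by 01; if those are missing they regenerate them
from the identical configuration.
"""

from pathlib import Path

from cavegrowth import io_model
from cavegrowth.simulate import (
    CohortSimConfig,
    ReadingSimConfig,
    simulate_cohort,
    simulate_composition,
    simulate_readings,
)

MASTER_SEED = 20230
ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

COHORT_CONFIG = CohortSimConfig(seed=MASTER_SEED)
READING_CONFIG = ReadingSimConfig(seed=MASTER_SEED + 1)
COMPOSITION_SEED = MASTER_SEED + 2


def generate_tables():
    cohort = simulate_cohort(COHORT_CONFIG)
    readings = simulate_readings(cohort, READING_CONFIG)
    composition = simulate_composition(cohort, seed=COMPOSITION_SEED)
    return cohort, readings, composition


def write_tables():
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    cohort, readings, composition = generate_tables()
    io_model.write_individuals(cohort, DATA_DIR / "cohort.csv")
    io_model.write_reading_sets(
        [rs for sets in readings.values() for rs in sets],
        DATA_DIR / "readings.csv",
    )
    io_model.write_composition(composition, DATA_DIR / "composition.csv")
    return cohort, readings, composition


def load_tables():
    if not (DATA_DIR / "cohort.csv").exists():
        return write_tables()
    cohort = io_model.read_individuals(DATA_DIR / "cohort.csv")
    sets = io_model.read_reading_sets(DATA_DIR / "readings.csv")
    readings = {
        s: [rs for rs in sets if rs.structure == s] for s in io_model.Structure
    }
    composition = io_model.read_composition(DATA_DIR / "composition.csv")
    return cohort, readings, composition
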