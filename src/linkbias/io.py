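"""Delimited-text I/O for the synthetic-world tables.

All tables are comma-separated UTF-8 with a header row and RFC 4180 quoting
(pandas defaults); absent fields are written as empty strings. Schemas:

registry.csv        one row per person: person_id, name_1, name_2, sex,
                    birth_year, birth_month, birth_day, village, sub_village,
                    household_id, tcl_name_1, tcl_name_2, hh_member_name_1,
                    hh_member_name_2, residency_episodes ("start:end;..."),
                    hh_x, hh_y
encounters.csv      one row per clinic/survey record: encounter_id, source,
                    identifier fields (possibly blank), diagnosis_date,
                    age_at_encounter, prior_positive_flag, reported_resident,
                    gold_person_id (synthetic mode)
gold_links.csv      encounter_id, person_id
covariates.csv      person-level analysis attributes
person_outcomes.csv person_id, registration_day, death_day (blank = never)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic_data import Population, SyntheticWorld

_INT_COLS = {
    "registry": ["birth_year", "birth_month", "birth_day"],
    "encounters": ["birth_year", "birth_month", "birth_day", "diagnosis_date"],
    "person_outcomes": ["registration_day", "death_day"],
    "covariates": ["birth_year"],
    "gold_links": [],
}
_BOOL_COLS = {
    "encounters": ["prior_positive_flag", "reported_resident"],
    "covariates": ["paved_road"],
}


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype=object)
    for col in _INT_COLS.get(kind, []):
        if col in df.columns:
            df[col] = pd.array(
                [pd.NA if pd.isna(v) else int(float(v)) for v in df[col]], dtype="Int64"
            )
    for col in _BOOL_COLS.get(kind, []):
        if col in df.columns:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    for col in ("hh_x", "hh_y", "distance_km", "age_at_encounter"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    # blank identifier strings back to ""
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].fillna("")
    return df


WORLD_FILES = {
    "registry": "registry.csv",
    "encounters": "encounters.csv",
    "gold_links": "gold_links.csv",
    "covariates": "covariates.csv",
    "person_outcomes": "person_outcomes.csv",
}


def write_world(world: SyntheticWorld, outdir) -> dict:
    """Write every world table to ``outdir``; returns {table name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "registry": world.population.registry,
        "encounters": world.encounters,
        "gold_links": world.gold_links,
        "covariates": world.population.covariates,
        "person_outcomes": world.person_outcomes,
    }
    paths = {}
    for kind, fname in WORLD_FILES.items():
        path = outdir / fname
        write_table(tables[kind], path)
        paths[kind] = str(path)
    return paths


def read_world(indir) -> SyntheticWorld:
    """Re-load a world written by :func:`write_world`.

    The hidden truth table (latent third names) is not round-tripped; the
    returned population re-uses the registry in its place, which is all the
    linkage and analysis stages need.
    """
    indir = Path(indir)
    tables = {kind: read_table(indir / fname, kind) for kind, fname in WORLD_FILES.items()}
    population = Population(
        registry=tables["registry"], truth=tables["registry"], covariates=tables["covariates"]
    )
    return SyntheticWorld(
        population=population,
        encounters=tables["encounters"],
        gold_links=tables["gold_links"],
        person_outcomes=tables["person_outcomes"],
    )
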