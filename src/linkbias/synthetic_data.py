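"""Synthetic HDSS world: population registry, corrupted clinic/survey encounters,
gold-standard links, and a proportional-hazards time-to-care-registration outcome.

The generator emulates a rural-ward surveillance population: finite name pools
(so distinct people collide on names), households grouped under ten-cell
leaders, nested village/sub-village geography with household coordinates, and
encounter records whose identifiers are transcribed from the person's true
identity with configurable missingness and typographic error. Every encounter
carries a hidden ``gold_person_id`` so linkage error can be measured exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    EPOCH_YEAR,
    STUDY_END_DAY,
    STUDY_START_DAY,
    ConfigurationError,
    CorruptionConfig,
    OutcomeConfig,
    PopulationConfig,
)

# ---------------------------------------------------------------------------
# name pools — invented Swahili/Sukuma-flavoured names; finite by design so
# that full-name collisions occur at realistic rates in a few-thousand-person
# registry (false matches arise from shared names)

FIRST_NAMES = [
    "AMANI", "BARAKA", "CHAUSIKU", "DAUDI", "ESTHER", "FARAJA", "GRACE",
    "HALIMA", "IBRAHIM", "JUMA", "KULWA", "LUCIA", "MASHAKA", "NEEMA",
    "PENDO", "RAMADHANI", "SARA", "TUMAINI", "UPENDO", "VERONICA", "WILSON",
    "YOHANA", "ZAWADI", "ANNA", "BHOKE", "CHARLES", "DOTO", "ELIZABETH",
    "FATUMA", "GEORGE", "HAMISI", "ISSA", "JOHN", "LEAH", "MARIAM", "OMARI",
    "PAULO", "REHEMA", "SALOME", "THOMAS", "VUMILIA", "WEMA", "YUSUFU",
    "ZUHURA", "AGNES", "BUPE", "DINA", "EMMANUEL", "FURAHA", "GIDION",
    "IRENE", "JOSEPH", "KEZIA", "LAMECK", "MAGRETH", "NGASA", "PILI",
    "SHIDA", "TATU", "WANDE",
]

SURNAMES = [
    "MWITA", "MAKOYE", "SHIJA", "MASANJA", "KABULA", "NGWANDU", "MAGESA",
    "BUNDALA", "KISHOSHA", "MALIMI", "SALU", "MIHAYO", "NGOLLO", "KAPESA",
    "MASUNGA", "NDAKI", "MAZIKU", "LUGATA", "NGASSA", "MABULA", "NKWABI",
    "MAGANGA", "BUHOLO", "KADELYA", "MISANA", "NYANDA", "PASTORY", "SAYI",
    "SHILINDE", "WAMBURA", "LUHENDE", "MAKORERE", "NG'HOBOKO", "BUPAMBA",
    "CHACHA", "GHATI", "ITONGO", "JILALA", "KAHABI", "LUBINZA", "MACHIBYA",
    "NDELWA", "NYAMIZI", "PAMBA", "SANANE", "SOLOMON", "TEMBA", "WANZAGI",
    "ZENGO", "BUNUMA", "DOTTO", "GWAJIMA", "KASHINJE", "LIMBU", "MAYALA",
    "NGOKOLO", "SALULA", "SHABANI", "WELELO",
]

VILLAGES = {
    # village -> straight-line distance (km) of the village centre from the CTC
    "Igekemaja": 2.5,
    "Ihayabuyaga": 5.5,
    "Isangijo": 7.5,
    "Kanyama": 1.2,
    "Kisesa": 0.6,
    "Kitumba": 3.5,
    "Welamasonga": 9.0,
}
VILLAGE_WEIGHTS = {
    "Igekemaja": 0.10, "Ihayabuyaga": 0.09, "Isangijo": 0.10, "Kanyama": 0.15,
    "Kisesa": 0.30, "Kitumba": 0.14, "Welamasonga": 0.12,
}
SUB_VILLAGES_PER_VILLAGE = 3

RESIDENCY_HORIZON = 6000  # day index closing every open-ended episode

AGE_GROUPS = ("15-29", "30-39", "40-49", "50+")
DISTANCE_BANDS = ("<1", "1-1.9", "2-4.9", "5-11")
RURALITIES = ("rural", "peri_urban", "urban")

ALPHABET = string.ascii_uppercase


def age_group(age: float) -> str:
    if age < 15:
        return "<15"
    if age < 30:
        return "15-29"
    if age < 40:
        return "30-39"
    if age < 50:
        return "40-49"
    return "50+"


def distance_band(km: float) -> str:
    if km < 1:
        return "<1"
    if km < 2:
        return "1-1.9"
    if km < 5:
        return "2-4.9"
    return "5-11"


# -- residency episode (de)serialisation: "start:end;start:end", integer days


def format_episodes(episodes) -> str:
    return ";".join(f"{int(s)}:{int(e)}" for s, e in episodes)


def parse_episodes(text: str):
    if not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split(":")
        out.append((int(s), int(e)))
    return out


def resident_on(episodes_text: str, day: int) -> bool:
    return any(s <= day < e for s, e in parse_episodes(episodes_text))


@dataclass
class Population:
    """The generated registry plus the hidden truth it was derived from.

    ``registry`` is what the linkage engine sees (registry-side missingness
    applied); ``truth`` holds every person's complete identity, including the
    latent third name the surveillance system never records; ``covariates``
    holds the person-level analysis attributes.
    """

    registry: pd.DataFrame
    truth: pd.DataFrame
    covariates: pd.DataFrame


def _zipf_choice(rng: np.random.Generator, pool, size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, len(pool) + 1, dtype=float)
    w = ranks ** (-exponent)
    w /= w.sum()
    return np.asarray(pool, dtype=object)[rng.choice(len(pool), size=size, p=w)]


def generate_population(config: PopulationConfig, seed: int) -> Population:
    """Generate a registry of persons nested in households, TCL groups and villages.

    Deterministic for a given ``(config, seed)``. Raises
    :class:`~linkbias.config.ConfigurationError` on invalid sizes.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_people

    # -- households ------------------------------------------------------
    sizes = []
    while sum(sizes) < n:
        sizes.append(1 + rng.poisson(max(config.mean_household_size - 1.0, 0.0)))
    sizes[-1] -= sum(sizes) - n
    if sizes[-1] == 0:
        sizes.pop()
    n_households = len(sizes)

    village_names = list(VILLAGES)
    vweights = np.array([VILLAGE_WEIGHTS[v] for v in village_names])
    vweights = vweights / vweights.sum()
    hh_village_idx = rng.choice(len(village_names), size=n_households, p=vweights)

    # sub-village geography and attributes
    sub_names, sub_attrs = [], {}
    for v in village_names:
        base_d = VILLAGES[v]
        for j in range(SUB_VILLAGES_PER_VILLAGE):
            name = f"{v}-{chr(ord('A') + j)}"
            theta = rng.uniform(0, 2 * np.pi)
            d = max(0.05, base_d + rng.normal(0, 0.8))
            cx, cy = d * np.cos(theta), d * np.sin(theta)
            if d < 1.5:
                rurality = rng.choice(RURALITIES, p=[0.1, 0.2, 0.7])
            elif d < 4.0:
                rurality = rng.choice(RURALITIES, p=[0.3, 0.5, 0.2])
            else:
                rurality = rng.choice(RURALITIES, p=[0.8, 0.15, 0.05])
            paved = bool(rng.random() < {"urban": 0.85, "peri_urban": 0.55, "rural": 0.25}[rurality])
            sub_names.append(name)
            sub_attrs[name] = (v, cx, cy, rurality, paved)

    hh_sub = []
    for vi in hh_village_idx:
        v = village_names[vi]
        j = rng.integers(SUB_VILLAGES_PER_VILLAGE)
        hh_sub.append(f"{v}-{chr(ord('A') + j)}")
    hh_sub = np.asarray(hh_sub, dtype=object)

    hh_x = np.empty(n_households)
    hh_y = np.empty(n_households)
    for i, s in enumerate(hh_sub):
        _, cx, cy, _, _ = sub_attrs[s]
        hh_x[i] = cx + rng.normal(0, 0.3)
        hh_y[i] = cy + rng.normal(0, 0.3)

    # ten-cell-leader groups: consecutive households within a sub-village
    order = np.argsort(hh_sub, kind="stable")
    tcl_of_hh = np.empty(n_households, dtype=int)
    tcl_counter = 0
    pos = 0
    while pos < n_households:
        sub = hh_sub[order[pos]]
        end = pos
        while end < n_households and hh_sub[order[end]] == sub:
            end += 1
        for chunk_start in range(pos, end, config.households_per_tcl):
            for k in range(chunk_start, min(chunk_start + config.households_per_tcl, end)):
                tcl_of_hh[order[k]] = tcl_counter
            tcl_counter += 1
        pos = end
    tcl_first = _zipf_choice(rng, FIRST_NAMES, tcl_counter, config.name_zipf_exponent)
    tcl_second = _zipf_choice(rng, SURNAMES, tcl_counter, config.name_zipf_exponent)

    # -- persons ---------------------------------------------------------
    hh_of_person = np.repeat(np.arange(n_households), sizes)
    name_1 = _zipf_choice(rng, FIRST_NAMES, n, config.name_zipf_exponent)
    name_2 = _zipf_choice(rng, SURNAMES, n, config.name_zipf_exponent)
    name_3 = _zipf_choice(rng, SURNAMES, n, config.name_zipf_exponent)
    sex = np.where(rng.random(n) < 0.52, "F", "M").astype(object)
    # child-heavy age pyramid at the nominal reference year
    is_child = rng.random(n) < 0.35
    ages = np.where(is_child, rng.uniform(0, 15, n), rng.uniform(15, 80, n))
    ref_year = EPOCH_YEAR + (STUDY_START_DAY + STUDY_END_DAY) // (2 * 365)
    birth_year = (ref_year - ages).astype(int)
    birth_month = rng.integers(1, 13, n)
    birth_day = rng.integers(1, 29, n)

    # residency episodes
    episodes = []
    u = rng.random(n)
    for i in range(n):
        if u[i] < config.two_episode_rate:
            a = int(rng.integers(STUDY_START_DAY, STUDY_END_DAY - 200))
            b = int(rng.integers(a + 30, STUDY_END_DAY))
            episodes.append(format_episodes([(0, a), (b, RESIDENCY_HORIZON)]))
        elif u[i] < config.two_episode_rate + config.partial_residency_rate:
            if rng.random() < 0.5:
                a = int(rng.integers(STUDY_START_DAY, STUDY_END_DAY))
                episodes.append(format_episodes([(a, RESIDENCY_HORIZON)]))
            else:
                a = int(rng.integers(STUDY_START_DAY, STUDY_END_DAY))
                episodes.append(format_episodes([(0, a)]))
        else:
            episodes.append(format_episodes([(0, RESIDENCY_HORIZON)]))

    # household-member names: the next co-resident in the household (if any)
    hh_first = np.full(n, "", dtype=object)
    hh_second = np.full(n, "", dtype=object)
    start = 0
    for size in sizes:
        idx = np.arange(start, start + size)
        if size > 1:
            partner = np.roll(idx, -1)
            hh_first[idx] = name_1[partner]
            hh_second[idx] = name_2[partner]
        start += size

    person_id = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    household_id = np.array([f"H{h:05d}" for h in hh_of_person], dtype=object)
    sub_village = hh_sub[hh_of_person]
    village = np.array([sub_attrs[s][0] for s in sub_village], dtype=object)
    px = hh_x[hh_of_person]
    py = hh_y[hh_of_person]
    tcl_idx = tcl_of_hh[hh_of_person]

    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "name_1": name_1,
            "name_2": name_2,
            "name_3": name_3,
            "sex": sex,
            "birth_year": birth_year,
            "birth_month": birth_month,
            "birth_day": birth_day,
            "village": village,
            "sub_village": sub_village,
            "household_id": household_id,
            "tcl_name_1": tcl_first[tcl_idx],
            "tcl_name_2": tcl_second[tcl_idx],
            "hh_member_name_1": hh_first,
            "hh_member_name_2": hh_second,
            "residency_episodes": episodes,
            "hh_x": px,
            "hh_y": py,
        }
    )

    # registry view: the surveillance database never records the third name
    # and has small amounts of missingness of its own
    registry = truth.drop(columns=["name_3"]).copy()
    comp = config.registry_completeness
    miss = rng.random(n) >= comp.get("birth_year", 1.0)
    registry["birth_year"] = registry["birth_year"].astype("Int64")
    registry.loc[miss, "birth_year"] = pd.NA
    for col, key in (("birth_month", "birth_month"), ("birth_day", "birth_day")):
        registry[col] = registry[col].astype("Int64")
        registry.loc[rng.random(n) >= comp.get(key, 1.0), col] = pd.NA
    miss = rng.random(n) >= comp.get("tcl_name", 1.0)
    registry.loc[miss, ["tcl_name_1", "tcl_name_2"]] = ""
    miss = rng.random(n) >= comp.get("hh_member_name", 1.0)
    registry.loc[miss, ["hh_member_name_1", "hh_member_name_2"]] = ""

    dist = np.hypot(px, py)
    covariates = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": birth_year,
            "village": village,
            "sub_village": sub_village,
            "rurality": np.array([sub_attrs[s][3] for s in sub_village], dtype=object),
            "paved_road": np.array([sub_attrs[s][4] for s in sub_village]),
            "distance_km": dist,
            "distance_band": np.array([distance_band(d) for d in dist], dtype=object),
        }
    )
    return Population(registry=registry, truth=truth, covariates=covariates)


# ---------------------------------------------------------------------------
# encounter corruption


def _typo(name: str, rng: np.random.Generator) -> str:
    """One random substitution, transposition or deletion; guaranteed to change
    any name of length >= 2."""
    if len(name) < 2:
        # single character: substitution with a different letter
        c = ALPHABET[rng.integers(len(ALPHABET))]
        while c == name:
            c = ALPHABET[rng.integers(len(ALPHABET))]
        return c
    op = rng.integers(3)
    if op == 0:  # substitution
        i = int(rng.integers(len(name)))
        c = ALPHABET[rng.integers(len(ALPHABET))]
        while c == name[i]:
            c = ALPHABET[rng.integers(len(ALPHABET))]
        return name[:i] + c + name[i + 1:]
    if op == 1:  # adjacent transposition
        candidates = [i for i in range(len(name) - 1) if name[i] != name[i + 1]]
        if not candidates:
            return _typo(name, rng)  # e.g. "AA": fall back to substitution/deletion
        i = candidates[int(rng.integers(len(candidates)))]
        return name[:i] + name[i + 1] + name[i] + name[i + 2:]
    i = int(rng.integers(len(name)))  # deletion
    return name[:i] + name[i + 1:]


ENCOUNTER_ID_FIELDS = [
    "name_1", "name_2", "name_3", "sex", "birth_year", "birth_month", "birth_day",
    "village", "sub_village", "tcl_name_1", "tcl_name_2", "tcl_name_3",
    "hh_member_name_1", "hh_member_name_2", "hh_member_name_3",
]


def corrupt_encounter(person, source: str, corruption: CorruptionConfig,
                      rng: np.random.Generator) -> dict:
    """Transcribe a person's true identity onto an encounter record.

    ``person`` is a row of ``Population.truth`` (mapping-like). Fields are
    present with the source's completeness probabilities; present names may
    receive a typo; the first two personal names may be recorded in swapped
    order; birth year may be shifted. Returns a plain dict of identifier
    fields (no encounter id / dates — the caller adds those).
    """
    if source not in corruption.field_completeness:
        raise ConfigurationError(f"unknown encounter source {source!r}")
    comp = corruption.field_completeness[source]

    names = [person["name_1"], person["name_2"], person["name_3"]]
    if rng.random() < corruption.name_swap_rate:
        names[0], names[1] = names[1], names[0]

    def name_field(true_value: str, key: str, replace_rate: float, pool) -> str:
        if not true_value or rng.random() >= comp.get(key, 0.0):
            return ""
        if replace_rate and rng.random() < replace_rate:
            # alias / out-of-date name: a different value entirely
            alt = true_value
            while alt == true_value:
                alt = pool[int(rng.integers(len(pool)))]
            return alt
        if corruption.typo_rate and rng.random() < corruption.typo_rate:
            return _typo(true_value, rng)
        return true_value

    rep = corruption.name_replace_rate
    rec: dict = {}
    rec["name_1"] = name_field(names[0], "name_1", rep, FIRST_NAMES)
    rec["name_2"] = name_field(names[1], "name_2", rep, SURNAMES)
    rec["name_3"] = name_field(names[2], "name_3", rep, SURNAMES)
    trep = corruption.tcl_replace_rate
    rec["tcl_name_1"] = name_field(person["tcl_name_1"], "tcl_name_1", trep, FIRST_NAMES)
    rec["tcl_name_2"] = name_field(person["tcl_name_2"], "tcl_name_2", trep, SURNAMES)
    rec["tcl_name_3"] = ""
    hrep = corruption.hh_member_replace_rate
    rec["hh_member_name_1"] = name_field(person["hh_member_name_1"], "hh_member_name_1", hrep, FIRST_NAMES)
    rec["hh_member_name_2"] = name_field(person["hh_member_name_2"], "hh_member_name_2", hrep, SURNAMES)
    rec["hh_member_name_3"] = ""

    if rng.random() < comp.get("sex", 0.0):
        sex = person["sex"]
        if corruption.sex_error_rate and rng.random() < corruption.sex_error_rate:
            sex = "M" if sex == "F" else "F"
        rec["sex"] = sex
    else:
        rec["sex"] = ""
    if rng.random() < comp.get("birth_year", 0.0):
        by = int(person["birth_year"])
        if corruption.birth_year_error_rate and rng.random() < corruption.birth_year_error_rate:
            shift = 0
            while shift == 0:
                shift = int(round(rng.normal(0, corruption.birth_year_error_sd)))
            by += shift
        rec["birth_year"] = by
    else:
        rec["birth_year"] = pd.NA
    for col, hi in (("birth_month", 13), ("birth_day", 29)):
        if rng.random() < comp.get(col, 0.0):
            v = int(person[col])
            if (corruption.birth_month_day_error_rate
                    and rng.random() < corruption.birth_month_day_error_rate):
                alt = v
                while alt == v:
                    alt = int(rng.integers(1, hi))
                v = alt
            rec[col] = v
        else:
            rec[col] = pd.NA

    village, sub_village = person["village"], person["sub_village"]
    if corruption.geography_error_rate and rng.random() < corruption.geography_error_rate:
        # reported residence out of date: a different sub-village (its village implied)
        alt = sub_village
        while alt == sub_village:
            v = list(VILLAGES)[int(rng.integers(len(VILLAGES)))]
            alt = f"{v}-{chr(ord('A') + int(rng.integers(SUB_VILLAGES_PER_VILLAGE)))}"
        village, sub_village = alt.rsplit("-", 1)[0], alt
    rec["village"] = village if rng.random() < comp.get("village", 0.0) else ""
    rec["sub_village"] = sub_village if rng.random() < comp.get("sub_village", 0.0) else ""
    return rec


# ---------------------------------------------------------------------------
# cohort simulation

# modality-conditional covariate targets used to sample the diagnosed cohort
# (importance weights against the population's empirical distribution),
# calibrated once to the reference cohort's descriptive table
_MODALITY_TARGETS = {
    "sero_survey": {
        "sex": {"F": 173 / 263, "M": 90 / 263},
        "age_group": {"15-29": 62 / 263, "30-39": 96 / 263, "40-49": 59 / 263, "50+": 46 / 263},
        "rurality": {"rural": 140 / 263, "peri_urban": 54 / 263, "urban": 69 / 263},
        "paved_road": {True: 109 / 263, False: 154 / 263},
        "distance_band": {"<1": 53 / 263, "1-1.9": 58 / 263, "2-4.9": 60 / 263, "5-11": 92 / 263},
    },
    "clinic": {
        "sex": {"F": 98 / 142, "M": 44 / 142},
        "age_group": {"15-29": 51 / 142, "30-39": 53 / 142, "40-49": 22 / 142, "50+": 16 / 142},
        "rurality": {"rural": 55 / 142, "peri_urban": 39 / 142, "urban": 48 / 142},
        "paved_road": {True: 70 / 142, False: 72 / 142},
        "distance_band": {"<1": 37 / 142, "1-1.9": 45 / 142, "2-4.9": 29 / 142, "5-11": 31 / 142},
    },
}


@dataclass
class SyntheticWorld:
    """A complete synthetic study: population, encounters, gold links, outcomes."""

    population: Population
    encounters: pd.DataFrame
    gold_links: pd.DataFrame       # encounter_id -> person_id
    person_outcomes: pd.DataFrame  # person_id, registration_day, death_day


def _linear_predictor(cov_row, modality: str, diag_year: int, outcome: OutcomeConfig) -> float:
    lp = outcome.true_log_hr_modality if modality == "clinic" else 0.0
    ag = age_group(diag_year - cov_row["birth_year"])
    levels = {
        "sex": cov_row["sex"],
        "age_group": ag,
        "rurality": cov_row["rurality"],
        "paved_road": bool(cov_row["paved_road"]),
        "distance_band": cov_row["distance_band"],
    }
    for (cov, level), beta in outcome.covariate_log_hrs.items():
        if levels.get(cov) == level:
            lp += beta
    return lp


def _modality_weights(cov: pd.DataFrame, modality: str, diag_year: int) -> np.ndarray:
    """Importance weights making the sampled cohort's covariates approximate
    the modality-conditional targets."""
    targets = _MODALITY_TARGETS[modality]
    ag = (diag_year - cov["birth_year"]).map(age_group)
    w = np.ones(len(cov))
    for var, levels in targets.items():
        vals = ag if var == "age_group" else cov[var]
        pop_p = vals.value_counts(normalize=True)
        for level, target_p in levels.items():
            mask = (vals == level).to_numpy()
            denom = pop_p.get(level, np.nan)
            if denom and not np.isnan(denom):
                w[mask] *= target_p / denom
    return w


def simulate_cohort(population: Population, outcome: OutcomeConfig,
                    corruption: CorruptionConfig, seed: int) -> SyntheticWorld:
    """Sample a diagnosed cohort, generate encounters and registration outcomes.

    Every registry person receives a (possibly absent) first CTC-registration
    calendar day and death day: diagnosed persons via the exponential
    proportional-hazards model, undiagnosed persons via low-rate background
    clinic traffic. This is what lets a falsely linked encounter inherit the
    wrong person's outcome history downstream. Also emits deliberately
    ineligible encounters (under-15, repeat testers, reported non-residents)
    so eligibility filtering is exercisable.
    """
    outcome.validate()
    corruption.validate()
    if len(population.registry) == 0:
        raise ValueError("registry is empty")
    rng = np.random.default_rng(seed)
    cov = population.covariates
    truth = population.truth
    n = len(cov)
    diag_year_mid = EPOCH_YEAR + (STUDY_START_DAY + STUDY_END_DAY) // (2 * 365)

    adult = (diag_year_mid - cov["birth_year"] >= 15).to_numpy()
    resident = np.array(
        [resident_on(e, (STUDY_START_DAY + STUDY_END_DAY) // 2)
         for e in truth["residency_episodes"]]
    )
    eligible_idx = np.flatnonzero(adult & resident)
    n_clinic = int(round(outcome.cohort_size * (1 - outcome.sero_fraction)))
    n_sero = outcome.cohort_size - n_clinic
    if len(eligible_idx) < outcome.cohort_size:
        raise ValueError(
            f"registry has only {len(eligible_idx)} eligible adults for a cohort of {outcome.cohort_size}"
        )

    cov_elig = cov.iloc[eligible_idx]
    w_sero = _modality_weights(cov_elig, "sero_survey", diag_year_mid)
    sero_pick = rng.choice(len(eligible_idx), size=n_sero, replace=False, p=w_sero / w_sero.sum())
    remaining = np.setdiff1d(np.arange(len(eligible_idx)), sero_pick)
    w_clin = _modality_weights(cov_elig.iloc[remaining], "clinic", diag_year_mid)
    clin_pick = remaining[
        rng.choice(len(remaining), size=n_clinic, replace=False, p=w_clin / w_clin.sum())
    ]
    cohort_idx = eligible_idx[np.concatenate([sero_pick, clin_pick])]
    modality = np.array(["sero_survey"] * n_sero + ["clinic"] * n_clinic, dtype=object)

    diag_day = rng.integers(STUDY_START_DAY, STUDY_END_DAY + 1, size=outcome.cohort_size)

    # person-level outcome histories
    reg_day = np.full(n, np.nan)
    death_day = np.full(n, np.nan)
    # background clinic traffic for everyone (overwritten below for the cohort)
    bg = rng.random(n) < outcome.background_registration_prob
    reg_day[bg] = rng.integers(STUDY_START_DAY, STUDY_END_DAY + 1, size=int(bg.sum()))
    if outcome.death_rate > 0:
        t_death = rng.exponential(1.0 / outcome.death_rate, size=n)
        died = t_death < (STUDY_END_DAY - STUDY_START_DAY)
        death_day[died] = STUDY_START_DAY + np.floor(t_death[died]) + 1

    for k, idx in enumerate(cohort_idx):
        lp = _linear_predictor(cov.iloc[idx], modality[k],
                               EPOCH_YEAR + int(diag_day[k]) // 365, outcome)
        lam = outcome.baseline_hazard_rate * np.exp(lp)
        t = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        reg_day[idx] = diag_day[k] + np.floor(t) + 1 if np.isfinite(t) else np.nan
        if outcome.death_rate > 0:
            td = rng.exponential(1.0 / outcome.death_rate)
            death_day[idx] = diag_day[k] + np.floor(td) + 1
        else:
            death_day[idx] = np.nan

    # -- encounters ------------------------------------------------------
    rows = []
    gold = []
    counter = 0

    def add_encounter(person_idx: int, source: str, day: int, prior_positive: bool,
                      reported_resident: bool):
        nonlocal counter
        person = truth.iloc[person_idx]
        rec = corrupt_encounter(person, source, corruption, rng)
        eid = f"E{counter:05d}"
        counter += 1
        rec.update(
            encounter_id=eid,
            source=source,
            diagnosis_date=int(day),
            age_at_encounter=float(EPOCH_YEAR + day // 365 - person["birth_year"]),
            prior_positive_flag=bool(prior_positive),
            reported_resident=bool(reported_resident),
            gold_person_id=person["person_id"],
        )
        rows.append(rec)
        gold.append((eid, person["person_id"]))

    for k, idx in enumerate(cohort_idx):
        if modality[k] == "sero_survey":
            source = "sero_survey"
        else:
            source = "HTC" if rng.random() < outcome.htc_fraction else "ANC"
        add_encounter(idx, source, int(diag_day[k]), prior_positive=False, reported_resident=True)

    # deliberately ineligible extras, drawn outside the cohort
    pool = np.setdiff1d(np.arange(n), cohort_idx)
    children = pool[(diag_year_mid - cov["birth_year"].to_numpy()[pool]) < 15]
    n_u15 = int(round(outcome.under15_rate * outcome.cohort_size))
    for idx in rng.choice(children, size=min(n_u15, len(children)), replace=False):
        add_encounter(int(idx), "HTC", int(rng.integers(STUDY_START_DAY, STUDY_END_DAY + 1)),
                      prior_positive=False, reported_resident=True)
    adults_pool = pool[(diag_year_mid - cov["birth_year"].to_numpy()[pool]) >= 15]
    n_rep = int(round(outcome.repeat_tester_rate * outcome.cohort_size))
    rep = rng.choice(adults_pool, size=min(n_rep, len(adults_pool)), replace=False)
    for idx in rep:
        add_encounter(int(idx), "HTC", int(rng.integers(STUDY_START_DAY, STUDY_END_DAY + 1)),
                      prior_positive=True, reported_resident=True)
    rest = np.setdiff1d(adults_pool, rep)
    n_nr = int(round(outcome.nonresident_rate * outcome.cohort_size))
    for idx in rng.choice(rest, size=min(n_nr, len(rest)), replace=False):
        add_encounter(int(idx), "HTC", int(rng.integers(STUDY_START_DAY, STUDY_END_DAY + 1)),
                      prior_positive=False, reported_resident=False)

    encounters = pd.DataFrame(rows)
    for col in ("birth_year", "birth_month", "birth_day"):
        encounters[col] = encounters[col].astype("Int64")
    gold_links = pd.DataFrame(gold, columns=["encounter_id", "person_id"])
    person_outcomes = pd.DataFrame(
        {
            "person_id": cov["person_id"],
            "registration_day": pd.array(
                [int(d) if np.isfinite(d) else pd.NA for d in reg_day], dtype="Int64"
            ),
            "death_day": pd.array(
                [int(d) if np.isfinite(d) else pd.NA for d in death_day], dtype="Int64"
            ),
        }
    )
    return SyntheticWorld(population=population, encounters=encounters,
                          gold_links=gold_links, person_outcomes=person_outcomes)


def generate_world(population_config: PopulationConfig, outcome: OutcomeConfig,
                   corruption: CorruptionConfig, seed: int) -> SyntheticWorld:
    """Convenience: population + cohort in one call, both driven by ``seed``."""
    ss = np.random.SeedSequence(seed)
    pop_seed, cohort_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    population = generate_population(population_config, pop_seed)
    return simulate_cohort(population, outcome, corruption, cohort_seed)
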