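"""Generator tests: determinism, completeness calibration, corruption mechanics,
and validity of the simulated survival outcomes."""

import numpy as np
import pandas as pd
import pytest

from linkbias.config import (
    ConfigurationError,
    CorruptionConfig,
    OutcomeConfig,
    PopulationConfig,
)
from linkbias.outcome import assemble_analysis_dataset
from linkbias.synthetic_data import (
    corrupt_encounter,
    format_episodes,
    generate_population,
    generate_world,
    parse_episodes,
    resident_on,
    simulate_cohort,
)


class TestGeneratePopulation:
    def test_seed_determinism(self):
        cfg = PopulationConfig(n_people=1000)
        a = generate_population(cfg, seed=7)
        b = generate_population(cfg, seed=7)
        pd.testing.assert_frame_equal(a.registry, b.registry)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_different_seeds_differ(self):
        cfg = PopulationConfig(n_people=200)
        a = generate_population(cfg, seed=1)
        b = generate_population(cfg, seed=2)
        assert not a.registry["name_1"].equals(b.registry["name_1"])

    def test_zero_size_rejected(self):
        with pytest.raises(ConfigurationError, match="n_people"):
            generate_population(PopulationConfig(n_people=0), seed=1)

    def test_finite_pools_force_name_collisions(self):
        # oracle: direct tally of exact (first, second) name duplicates
        pop = generate_population(PopulationConfig(n_people=10_000), seed=5)
        full = pop.truth["name_1"] + " " + pop.truth["name_2"]
        assert full.duplicated().sum() > 0

    def test_person_ids_unique(self, tiny_population):
        assert tiny_population.registry["person_id"].is_unique

    def test_household_members_share_context(self, tiny_population):
        g = tiny_population.truth.groupby("household_id")
        for col in ("sub_village", "tcl_name_1", "tcl_name_2", "hh_x", "hh_y"):
            assert (g[col].nunique() == 1).all(), col

    def test_residency_episodes_disjoint(self, tiny_population):
        for text in tiny_population.truth["residency_episodes"]:
            eps = sorted(parse_episodes(text))
            assert all(s < e for s, e in eps)
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(eps, eps[1:]))


class TestEpisodes:
    def test_round_trip(self):
        eps = [(0, 1800), (2000, 6000)]
        assert parse_episodes(format_episodes(eps)) == eps
        assert parse_episodes("") == []

    def test_resident_on_half_open(self):
        text = format_episodes([(100, 200)])
        assert resident_on(text, 100)
        assert not resident_on(text, 200)


class TestCorruptEncounter:
    def _person(self, tiny_population, i=0):
        return tiny_population.truth.iloc[i]

    def test_identity_when_perfect(self, tiny_population):
        person = self._person(tiny_population)
        rec = corrupt_encounter(person, "HTC", CorruptionConfig.perfect(),
                                np.random.default_rng(0))
        for f in ("name_1", "name_2", "name_3", "sex", "village", "sub_village",
                  "tcl_name_1", "tcl_name_2", "hh_member_name_1", "hh_member_name_2"):
            assert rec[f] == person[f], f
        for f in ("birth_year", "birth_month", "birth_day"):
            assert rec[f] == person[f], f

    def test_forced_typo_always_changes_names(self, tiny_population):
        cor = CorruptionConfig.perfect()
        cor.typo_rate = 1.0
        rng = np.random.default_rng(1)
        for i in range(20):
            person = self._person(tiny_population, i)
            rec = corrupt_encounter(person, "sero_survey", cor, rng)
            assert rec["name_1"] != person["name_1"]
            assert rec["name_2"] != person["name_2"]

    def test_completeness_calibration_third_name(self, tiny_population):
        """Observed presence of the third name under the sero-survey profile
        stays within 3 binomial standard errors of the configured 13.3%."""
        cor = CorruptionConfig()
        rng = np.random.default_rng(42)
        person = self._person(tiny_population)
        n = 10_000
        present = sum(
            corrupt_encounter(person, "sero_survey", cor, rng)["name_3"] != ""
            for _ in range(n)
        )
        p = 0.133
        se = np.sqrt(p * (1 - p) / n)
        assert abs(present / n - p) < 3 * se

    @pytest.mark.parametrize("field,p", [("tcl_name_1", 0.915), ("hh_member_name_1", 0.113)])
    def test_completeness_calibration_clinic(self, tiny_population, field, p):
        cor = CorruptionConfig()
        rng = np.random.default_rng(7)
        person = self._person(tiny_population)
        n = 5_000
        present = sum(
            corrupt_encounter(person, "HTC", cor, rng)[field] != "" for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(present / n - p) < 3 * se

    def test_unknown_source_rejected(self, tiny_population):
        with pytest.raises(ConfigurationError, match="source"):
            corrupt_encounter(self._person(tiny_population), "pharmacy",
                              CorruptionConfig(), np.random.default_rng(0))


class TestSimulateCohort:
    def test_empty_registry_rejected(self, tiny_population):
        import dataclasses
        empty = dataclasses.replace(
            tiny_population,
            registry=tiny_population.registry.iloc[0:0],
            truth=tiny_population.truth.iloc[0:0],
            covariates=tiny_population.covariates.iloc[0:0],
        )
        with pytest.raises(ValueError):
            simulate_cohort(empty, OutcomeConfig(cohort_size=10), CorruptionConfig(), seed=0)

    def test_gold_links_are_a_function(self, small_world):
        assert small_world.gold_links["encounter_id"].is_unique
        assert set(small_world.gold_links["person_id"]) <= set(
            small_world.population.registry["person_id"]
        )
        assert len(small_world.gold_links) == len(small_world.encounters)

    def test_modality_split(self, small_world):
        # 160-cohort scaled 263:142 split = 104 sero; the deliberately
        # ineligible extras are all clinic-sourced
        sero = (small_world.encounters["source"] == "sero_survey").sum()
        assert sero == 104

    def test_survival_validity(self, small_world):
        """Times positive and capped at the administrative horizon; events binary."""
        gold = small_world.gold_links
        df = assemble_analysis_dataset(
            gold, small_world.encounters, small_world.population.covariates,
            small_world.person_outcomes, admin_days=90,
        )
        assert (df["time_days"] > 0).all()
        assert (df["time_days"] <= 90).all()
        assert set(df["event"]) <= {0, 1}

    def test_null_modality_effect_gives_matching_km_curves(self):
        """With a zero modality log-HR and no covariate effects the two
        registration curves agree (log-rank test far from rejection)."""
        from lifelines.statistics import logrank_test

        pop_cfg = PopulationConfig(n_people=3000)
        out = OutcomeConfig(cohort_size=800, true_log_hr_modality=0.0,
                            covariate_log_hrs={})
        world = generate_world(pop_cfg, out, CorruptionConfig.perfect(), seed=9)
        df = assemble_analysis_dataset(
            world.gold_links, world.encounters, world.population.covariates,
            world.person_outcomes, admin_days=90,
        )
        df = df.merge(world.encounters[["encounter_id", "source", "prior_positive_flag",
                                        "reported_resident", "age_at_encounter"]],
                      on="encounter_id")
        df = df[~df["prior_positive_flag"] & df["reported_resident"]
                & (df["age_at_encounter"] >= 15)]
        a = df[df["modality"] == "sero_survey"]
        b = df[df["modality"] == "clinic"]
        res = logrank_test(a["time_days"], b["time_days"], a["event"], b["event"])
        assert res.p_value > 0.01

    def test_world_seed_determinism(self):
        cfg_pop = PopulationConfig(n_people=400)
        out = OutcomeConfig(cohort_size=60)
        cor = CorruptionConfig()
        w1 = generate_world(cfg_pop, out, cor, seed=13)
        w2 = generate_world(cfg_pop, out, cor, seed=13)
        pd.testing.assert_frame_equal(w1.encounters, w2.encounters)
        pd.testing.assert_frame_equal(w1.person_outcomes, w2.person_outcomes)
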