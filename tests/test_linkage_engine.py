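"""Linkage-engine tests: the string comparator, Fellegi–Sunter weights, pair
scoring, best-candidate selection against a brute-force oracle, percentile
thresholds, and the data-integrity flags."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from linkbias.config import ALL_FIELDS, ConfigurationError, MatchParams
from linkbias.linkage_engine import (
    AGREE,
    DISAGREE,
    MISSING,
    build_linked_dataset,
    em_refine_params,
    estimate_u_probabilities,
    field_weight,
    jaro,
    jaro_winkler,
    link_best_candidates,
    name_field_agreement,
    nearest_rank_percentile,
    qc_flags,
    resolve_thresholds,
    score_pair,
)

names = st.text(alphabet="ABCDE", min_size=0, max_size=8)


class TestJaroWinkler:
    def test_martha_marhta(self):
        # hand computation: m=6 matches, t=1 transposition -> Jaro 0.9444;
        # common prefix "MAR" (3) with scale 0.1 -> 0.9444 + 0.3*0.0556 = 0.9611
        assert jaro("MARTHA", "MARHTA") == pytest.approx(17 / 18, abs=1e-12)
        assert jaro_winkler("MARTHA", "MARHTA") == pytest.approx(0.9611, abs=1e-4)

    def test_identity_and_disjoint(self):
        assert jaro_winkler("KISESA", "KISESA") == 1.0
        assert jaro_winkler("ABC", "XYZ") == 0.0
        assert jaro_winkler("", "ABC") == 0.0

    @given(a=names, b=names)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        s = jaro_winkler(a, b)
        assert s == jaro_winkler(b, a)
        assert 0.0 <= s <= 1.0
        if a and a == b:
            assert s == 1.0

    def test_prefix_boost_capped_at_four(self):
        # identical 5-char prefixes must not boost beyond the 4-char cap
        base = jaro("ABCDEF", "ABCDEX")
        assert jaro_winkler("ABCDEF", "ABCDEX") == pytest.approx(base + 4 * 0.1 * (1 - base))


class TestNameFieldAgreement:
    def test_permutation_invariance(self, default_params):
        out, sim = name_field_agreement(["JOHN", "DOE"], ["DOE", "JOHN"], default_params)
        assert (out, sim) == (AGREE, 1.0)

    def test_fuzzy_agreement(self, default_params):
        out, sim = name_field_agreement(["MARTHA"], ["MARHTA"], default_params)
        assert out == AGREE
        assert sim == pytest.approx(0.9611, abs=1e-4)

    def test_empty_is_missing(self, default_params):
        assert name_field_agreement([], ["DOE"], default_params)[0] == MISSING
        assert name_field_agreement(["", ""], ["DOE"], default_params)[0] == MISSING


class TestFieldWeight:
    def test_closed_forms(self):
        assert field_weight(AGREE, 0.9, 0.05) == pytest.approx(math.log2(18), abs=1e-10)
        assert field_weight(AGREE, 0.9, 0.05) == pytest.approx(4.1699, abs=1e-4)
        assert field_weight(DISAGREE, 0.9, 0.05) == pytest.approx(math.log2(0.1 / 0.95), abs=1e-10)
        assert field_weight(DISAGREE, 0.9, 0.05) == pytest.approx(-3.2479, abs=1e-4)
        assert field_weight(MISSING, 0.9, 0.05) == 0.0

    def test_no_information_limit(self):
        assert field_weight(AGREE, 0.3 + 1e-9, 0.3) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_m_u_rejected(self):
        with pytest.raises(ValueError):
            field_weight(AGREE, 0.05, 0.9)

    @given(u=st.floats(0.01, 0.5), gap=st.floats(0.01, 0.45))
    @settings(max_examples=100, deadline=None)
    def test_agreement_positive_disagreement_negative(self, u, gap):
        m = u + gap
        assert field_weight(AGREE, m, u) > 0 > field_weight(DISAGREE, m, u)


def _uniform_params(m=0.9, u=0.05):
    return MatchParams(m={f: m for f in ALL_FIELDS}, u={f: u for f in ALL_FIELDS})


class TestScorePair:
    def test_five_agreeing_fields(self):
        """Five comparable fields, all agreeing, m=0.9/u=0.05 per field ->
        5 * log2(18) = 20.849."""
        params = _uniform_params()
        enc = {"encounter_id": "E", "sex": "F", "birth_year": 1980, "birth_month": 2,
               "birth_day": 14, "village": "Kisesa"}
        per = {"person_id": "P", "sex": "F", "birth_year": 1980, "birth_month": 2,
               "birth_day": 14, "village": "Kisesa"}
        pair = score_pair(enc, per, params)
        assert pair.match_score == pytest.approx(5 * math.log2(18), abs=1e-9)
        assert pair.match_score == pytest.approx(20.849, abs=1e-3)

    def test_five_disagreeing_fields(self):
        params = _uniform_params()
        enc = {"sex": "F", "birth_year": 1980, "birth_month": 2, "birth_day": 14,
               "village": "Kisesa"}
        per = {"sex": "M", "birth_year": 1991, "birth_month": 3, "birth_day": 15,
               "village": "Kanyama"}
        pair = score_pair(enc, per, params)
        assert pair.match_score == pytest.approx(5 * math.log2(0.1 / 0.95), abs=1e-9)
        assert pair.match_score == pytest.approx(-16.239, abs=1e-3)

    def test_all_missing_scores_zero(self):
        pair = score_pair({}, {"person_id": "P"}, _uniform_params())
        assert pair.match_score == 0.0
        assert all(o == MISSING for o in pair.outcomes.values())

    def test_name_order_invariance(self, small_world, default_params):
        person = small_world.population.registry.iloc[0].to_dict()
        enc = {"name_1": "JUMA", "name_2": "MWITA", "name_3": "SHIJA",
               "sex": "M", "birth_year": 1980}
        perm = {"name_1": "SHIJA", "name_2": "JUMA", "name_3": "MWITA",
                "sex": "M", "birth_year": 1980}
        assert (score_pair(enc, person, default_params).match_score
                == score_pair(perm, person, default_params).match_score)


def _brute_force_best(encounters, registry, params):
    """Independent oracle: exhaustive scalar maximisation with the documented
    tie-break (fewest disagreements, then lowest person_id)."""
    picks = []
    reg_rows = registry.to_dict("records")
    for enc in encounters.to_dict("records"):
        scored = []
        for person in reg_rows:
            pair = score_pair(enc, person, params)
            n_dis = sum(o == DISAGREE for o in pair.outcomes.values())
            scored.append((pair.match_score, n_dis, person["person_id"]))
        best = max(s for s, _, _ in scored)
        contenders = [(d, pid) for s, d, pid in scored if abs(s - best) <= 1e-9]
        d_min = min(d for d, _ in contenders)
        pid = min(pid for d, pid in contenders if d == d_min)
        picks.append((enc["encounter_id"], pid, best))
    return picks


class TestLinkBestCandidates:
    def test_exact_match_dominance(self, perfect_world, default_params):
        best = link_best_candidates(perfect_world.encounters,
                                    perfect_world.population.registry, default_params)
        gold = perfect_world.gold_links.set_index("encounter_id")["person_id"]
        assert (best.set_index("encounter_id")["person_id"] == gold).all()

    def test_empty_registry_rejected(self, small_world, default_params):
        with pytest.raises(ValueError):
            link_best_candidates(small_world.encounters,
                                 small_world.population.registry.iloc[0:0], default_params)

    def test_tie_reported_and_broken_by_person_id(self, default_params):
        person = {
            "name_1": "JUMA", "name_2": "MWITA", "sex": "M", "birth_year": 1980,
            "birth_month": 1, "birth_day": 2, "village": "Kisesa",
            "sub_village": "Kisesa-A", "household_id": "H1",
            "tcl_name_1": "ISSA", "tcl_name_2": "SHIJA",
            "hh_member_name_1": "ANNA", "hh_member_name_2": "MWITA",
            "residency_episodes": "0:6000",
        }
        registry = pd.DataFrame([{**person, "person_id": "P2"}, {**person, "person_id": "P1"}])
        registry["birth_year"] = registry["birth_year"].astype("Int64")
        registry["birth_month"] = registry["birth_month"].astype("Int64")
        registry["birth_day"] = registry["birth_day"].astype("Int64")
        enc = pd.DataFrame([{**person, "encounter_id": "E0", "name_3": "", "tcl_name_3": "",
                             "hh_member_name_3": ""}])
        best = link_best_candidates(enc, registry, default_params)
        assert best.loc[0, "person_id"] == "P1"
        assert bool(best.loc[0, "tie"])

    def test_matches_brute_force_oracle(self, small_world, default_params):
        """Vectorised selection equals exhaustive scalar maximisation on a
        50-encounter x 500-person instance (25,000 scored pairs)."""
        enc = small_world.encounters.iloc[:50]
        reg = small_world.population.registry.iloc[:500]
        best = link_best_candidates(enc, reg, default_params)
        oracle = _brute_force_best(enc, reg, default_params)
        for (eid, pid, score), row in zip(oracle, best.to_dict("records")):
            assert row["encounter_id"] == eid
            assert row["person_id"] == pid
            assert row["match_score"] == pytest.approx(score, abs=1e-9)

    def test_blocking_matches_full_search_on_clean_data(self, perfect_world, default_params):
        best_full = link_best_candidates(perfect_world.encounters,
                                         perfect_world.population.registry, default_params)
        best_blocked = link_best_candidates(perfect_world.encounters,
                                            perfect_world.population.registry,
                                            default_params, blocking=True)
        assert (best_full["person_id"] == best_blocked["person_id"]).all()


class TestThresholds:
    def test_percentile_zero_is_minimum(self):
        ts = resolve_thresholds([-21, 13, 24, 35, 61], {"minimum": 0})
        assert ts.cutoffs["minimum"] == -21

    def test_nearest_rank(self):
        assert nearest_rank_percentile([10, 20, 30, 40], 25) == 10  # ceil(.25*4)=1st
        assert nearest_rank_percentile([10, 20, 30, 40], 75) == 30  # ceil(.75*4)=3rd
        assert nearest_rank_percentile([10, 20, 30, 40], 50) == 20
        assert nearest_rank_percentile([10, 20, 30, 40], 100) == 40

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_thresholds([], {"minimum": 0})

    def test_cutoffs_nondecreasing(self, small_report):
        cuts = [small_report.thresholds[k] for k in ("minimum", "low", "medium", "high")]
        assert cuts == sorted(cuts)

    @given(scores=st.lists(st.floats(-50, 100, allow_nan=False), min_size=1, max_size=30),
           p=st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_percentile_is_an_order_statistic(self, scores, p):
        v = nearest_rank_percentile(scores, p)
        assert v in scores
        assert v >= min(scores)


class TestBuildLinkedDataset:
    def test_vacuous_and_impossible_cutoffs(self, small_report):
        best = small_report.best_candidates
        assert len(build_linked_dataset(best, -np.inf)) == len(best)
        assert len(build_linked_dataset(best, best["match_score"].max() + 1)) == 0

    def test_median_cutoff_by_enumeration(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        best = pd.DataFrame({"encounter_id": [f"E{i}" for i in range(10)],
                             "person_id": "P0", "match_score": scores})
        cutoff = nearest_rank_percentile(scores, 50)
        kept = build_linked_dataset(best, cutoff)
        expected = [s for s in scores if s >= cutoff]
        assert sorted(kept["match_score"]) == expected

    def test_inclusive_comparison(self):
        best = pd.DataFrame({"encounter_id": ["E0"], "person_id": ["P0"],
                             "match_score": [5.0]})
        assert len(build_linked_dataset(best, 5.0)) == 1


class TestQCFlags:
    def _registry(self):
        base = {
            "name_1": "JUMA", "name_2": "MWITA", "sex": "M",
            "birth_month": 1, "birth_day": 2, "village": "Kisesa",
            "sub_village": "Kisesa-A",
            "tcl_name_1": "ISSA", "tcl_name_2": "SHIJA",
            "hh_member_name_1": "", "hh_member_name_2": "",
        }
        rows = [
            {**base, "person_id": "P1", "birth_year": 1960, "household_id": "H1",
             "residency_episodes": "0:1900"},
            {**base, "person_id": "P2", "birth_year": 1975, "household_id": "H2",
             "residency_episodes": "1850:2200", "sex": "F"},
            {**base, "person_id": "P3", "birth_year": 1961, "household_id": "H1",
             "residency_episodes": "3000:4000"},
        ]
        df = pd.DataFrame(rows)
        for c in ("birth_year", "birth_month", "birth_day"):
            df[c] = df[c].astype("Int64")
        return df

    def test_multi_match_rules(self):
        reg = self._registry()
        linked = pd.DataFrame({"encounter_id": ["E0", "E0"], "person_id": ["P1", "P2"]})
        rules = set(qc_flags(linked, reg)["rule"])
        assert rules == {"birth_year_gap_gt10", "sex_conflict", "overlapping_residency"}

    def test_same_household_and_no_overlap(self):
        reg = self._registry()
        linked = pd.DataFrame({"encounter_id": ["E0", "E0"], "person_id": ["P1", "P3"]})
        rules = set(qc_flags(linked, reg)["rule"])
        # episodes 0:1900 and 3000:4000 do not overlap; gap is 1 year
        assert rules == {"same_household_multimatch"}

    def test_clean_linkage_no_flags(self):
        reg = self._registry()
        linked = pd.DataFrame({"encounter_id": ["E0", "E1"], "person_id": ["P1", "P2"]})
        assert qc_flags(linked, reg).empty


class TestParameterEstimation:
    def test_u_estimate_below_m_and_in_range(self, small_world, default_params):
        params = estimate_u_probabilities(small_world.encounters,
                                          small_world.population.registry,
                                          default_params, n_pairs=1000, seed=0)
        for f in ALL_FIELDS:
            assert 0 < params.u[f] < params.m[f]

    def test_em_recovers_planted_m_u(self):
        """EM on patterns simulated from known m/u separates the two classes."""
        rng = np.random.default_rng(0)
        m_true, u_true, p = 0.9, 0.1, 0.2
        n = 4000
        is_match = rng.random(n) < p
        probs = np.where(is_match[:, None], m_true, u_true)
        a = (rng.random((n, len(ALL_FIELDS))) < probs).astype(float)
        a[rng.random(a.shape) < 0.1] = np.nan  # missing at random
        patterns = pd.DataFrame(a, columns=list(ALL_FIELDS))
        start = MatchParams(m={f: 0.8 for f in ALL_FIELDS}, u={f: 0.2 for f in ALL_FIELDS})
        refined = em_refine_params(patterns, start)
        for f in ALL_FIELDS:
            assert refined.m[f] == pytest.approx(m_true, abs=0.05)
            assert refined.u[f] == pytest.approx(u_true, abs=0.05)


class TestMatchParamsValidation:
    def test_m_not_above_u_rejected(self):
        bad = MatchParams()
        bad.u["name"] = 0.95
        with pytest.raises(ConfigurationError, match="name"):
            bad.validate()
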