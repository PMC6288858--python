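"""Fellegi–Sunter probabilistic linkage of encounter records to a person registry.

Each identifier field contributes a log-likelihood-ratio weight: ``log(m/u)``
when the field agrees, ``log((1-m)/(1-u))`` when it disagrees, nothing when it
is missing on either side (m = P(agree | true match), u = P(agree | non-match)).
Name fields (personal names, ten-cell-leader names, household-member names)
agree when the best Jaro–Winkler similarity over all cross pairs of listed
names reaches a threshold — name order is deliberately not trusted. The
registry record with the highest total score is selected for every encounter;
analytic datasets are then cut at percentiles of the score distribution among
gold-standard true matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .config import ALL_FIELDS, EXACT_FIELDS, NAME_FIELDS, MatchParams
from .synthetic_data import parse_episodes

AGREE, DISAGREE, MISSING = "agree", "disagree", "missing"

# encounter / registry columns backing each scored name field
_NAME_COLS = {
    "name": (["name_1", "name_2", "name_3"], ["name_1", "name_2"]),
    "tcl_name": (["tcl_name_1", "tcl_name_2", "tcl_name_3"], ["tcl_name_1", "tcl_name_2"]),
    "hh_member_name": (
        ["hh_member_name_1", "hh_member_name_2", "hh_member_name_3"],
        ["hh_member_name_1", "hh_member_name_2"],
    ),
}


# ---------------------------------------------------------------------------
# string comparison


def jaro(a: str, b: str) -> float:
    """Jaro similarity: matches within half the longer length, transposition-penalised."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    match_a = [False] * la
    match_b = [False] * lb
    m = 0
    for i in range(la):
        lo = i - window if i > window else 0
        hi = i + window + 1
        if hi > lb:
            hi = lb
        ca = a[i]
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    t = 0
    j = 0
    for i in range(la):
        if match_a[i]:
            while not match_b[j]:
                j += 1
            if a[i] != b[j]:
                t += 1
            j += 1
    t //= 2
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity with the Winkler boost for a shared prefix (up to 4 chars)."""
    sim = jaro(a, b)
    if sim == 0.0 or sim == 1.0:
        return sim
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return sim + prefix * prefix_scale * (1.0 - sim)


class _JWCache:
    """Memoised Jaro–Winkler keyed on the (unordered) string pair.

    Registry names come from finite pools, so across a full cross-product run
    the same comparisons recur thousands of times.
    """

    def __init__(self, prefix_scale: float, max_prefix: int):
        self.prefix_scale = prefix_scale
        self.max_prefix = max_prefix
        self._cache: dict = {}

    def __call__(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        sim = self._cache.get(key)
        if sim is None:
            sim = jaro_winkler(a, b, self.prefix_scale, self.max_prefix)
            self._cache[key] = sim
        return sim


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, str):
        return value == ""
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def name_field_agreement(names_a, names_b, params: MatchParams, jw=None):
    """Compare two name lists order-free.

    Returns ``(outcome, best_similarity)``: missing if either list is empty
    (after dropping blanks), else agree iff the maximum Jaro–Winkler
    similarity over all cross pairs reaches ``params.jw_agreement_threshold``.
    """
    names_a = [n for n in names_a if not _is_missing(n)]
    names_b = [n for n in names_b if not _is_missing(n)]
    if not names_a or not names_b:
        return MISSING, float("nan")
    if jw is None:
        jw = lambda a, b: jaro_winkler(a, b, params.winkler_prefix_scale, params.winkler_max_prefix)  # noqa: E731
    best = max(jw(a, b) for a in names_a for b in names_b)
    outcome = AGREE if best >= params.jw_agreement_threshold else DISAGREE
    return outcome, best


def field_weight(outcome: str, m: float, u: float, log_base: float = 2.0) -> float:
    """Fellegi–Sunter weight: positive evidence on agreement, negative on disagreement."""
    if not (0.0 < u < m < 1.0):
        raise ValueError(f"require 0 < u < m < 1, got m={m}, u={u}")
    log = math.log(log_base)
    if outcome == AGREE:
        return math.log(m / u) / log
    if outcome == DISAGREE:
        return math.log((1.0 - m) / (1.0 - u)) / log
    if outcome == MISSING:
        return 0.0
    raise ValueError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# pairwise scoring (scalar path — also the brute-force oracle's building block)


@dataclass
class CandidatePair:
    encounter_id: str
    person_id: str
    outcomes: dict = dc_field(default_factory=dict)  # field -> agree/disagree/missing
    match_score: float = 0.0


def compare_fields(encounter, person, params: MatchParams, jw=None) -> dict:
    """Per-field agreement outcomes between an encounter and a registry person.

    ``encounter``/``person`` are mapping-like rows. Name fields use order-free
    Jaro–Winkler agreement; the remaining identifiers use exact equality.
    """
    out = {}
    for f, (enc_cols, reg_cols) in _NAME_COLS.items():
        enc_names = [encounter.get(c, "") for c in enc_cols]
        reg_names = [person.get(c, "") for c in reg_cols]
        out[f], _ = name_field_agreement(enc_names, reg_names, params, jw=jw)
    for f in EXACT_FIELDS:
        a, b = encounter.get(f), person.get(f)
        if _is_missing(a) or _is_missing(b):
            out[f] = MISSING
        else:
            out[f] = AGREE if a == b else DISAGREE
    return out


def score_pair(encounter, person, params: MatchParams, jw=None) -> CandidatePair:
    """Score one (encounter, person) pair: sum of field weights over non-missing fields."""
    params.validate()
    if isinstance(encounter, pd.Series):
        encounter = encounter.to_dict()
    if isinstance(person, pd.Series):
        person = person.to_dict()
    outcomes = compare_fields(encounter, person, params, jw=jw)
    score = sum(
        field_weight(outcomes[f], params.m[f], params.u[f], params.log_base) for f in ALL_FIELDS
    )
    return CandidatePair(
        encounter_id=str(encounter.get("encounter_id", "")),
        person_id=str(person.get("person_id", "")),
        outcomes=outcomes,
        match_score=score,
    )


# ---------------------------------------------------------------------------
# u estimation and EM refinement


def estimate_u_probabilities(encounters: pd.DataFrame, registry: pd.DataFrame,
                             params: MatchParams, n_pairs: int = 2000,
                             seed: int = 0) -> MatchParams:
    """Estimate per-field u as the agreement rate among randomly paired records.

    Random (encounter, person) pairs are overwhelmingly non-matches in any
    realistically sized registry, so their agreement rate approximates
    P(agree | non-match). Estimates are clipped away from 0/1 and kept below
    the configured m.
    """
    rng = np.random.default_rng(seed)
    jw = _JWCache(params.winkler_prefix_scale, params.winkler_max_prefix)
    ei = rng.integers(len(encounters), size=n_pairs)
    pi = rng.integers(len(registry), size=n_pairs)
    agree = {f: 0 for f in ALL_FIELDS}
    seen = {f: 0 for f in ALL_FIELDS}
    enc_rows = encounters.iloc[ei].to_dict("records")
    reg_rows = registry.iloc[pi].to_dict("records")
    for e, p in zip(enc_rows, reg_rows):
        for f, o in compare_fields(e, p, params, jw=jw).items():
            if o != MISSING:
                seen[f] += 1
                agree[f] += o == AGREE
    u = dict(params.u)
    for f in ALL_FIELDS:
        if seen[f] > 0:
            est = agree[f] / seen[f]
            u[f] = float(np.clip(est, 1e-3, min(0.6, params.m[f] - 0.05)))
    out = MatchParams(m=dict(params.m), u=u,
                      jw_agreement_threshold=params.jw_agreement_threshold,
                      winkler_prefix_scale=params.winkler_prefix_scale,
                      winkler_max_prefix=params.winkler_max_prefix,
                      log_base=params.log_base)
    return out.validate()


def em_refine_params(patterns: pd.DataFrame, params: MatchParams,
                     prior_match: float = 0.1, max_iter: int = 50,
                     tol: float = 1e-6) -> MatchParams:
    """Optional EM pass over binary agreement patterns (NaN = missing).

    Two-class latent mixture: each pair is a match with probability ``p``;
    given the class, field agreements are independent Bernoulli(m_f) or
    Bernoulli(u_f). Missing fields are ignored in the likelihood. Returns
    refined parameters with m/u kept in their valid ordering.
    """
    a = patterns[list(ALL_FIELDS)].to_numpy(dtype=float)
    obs = ~np.isnan(a)
    m = np.array([params.m[f] for f in ALL_FIELDS])
    u = np.array([params.u[f] for f in ALL_FIELDS])
    p = prior_match
    for _ in range(max_iter):
        with np.errstate(invalid="ignore"):
            log_m = np.where(obs, np.where(a == 1, np.log(m), np.log(1 - m)), 0.0)
            log_u = np.where(obs, np.where(a == 1, np.log(u), np.log(1 - u)), 0.0)
        lm = log_m.sum(axis=1) + np.log(p)
        lu = log_u.sum(axis=1) + np.log(1 - p)
        g = 1.0 / (1.0 + np.exp(lu - lm))
        m_new = np.empty_like(m)
        u_new = np.empty_like(u)
        for j in range(len(ALL_FIELDS)):
            o = obs[:, j]
            wg, wng = g[o], 1.0 - g[o]
            m_new[j] = (wg * a[o, j]).sum() / max(wg.sum(), 1e-12)
            u_new[j] = (wng * a[o, j]).sum() / max(wng.sum(), 1e-12)
        p_new = g.mean()
        m_new = np.clip(m_new, 0.5, 1 - 1e-4)
        u_new = np.clip(u_new, 1e-4, 0.6)
        u_new = np.minimum(u_new, m_new - 1e-3)
        delta = max(np.abs(m_new - m).max(), np.abs(u_new - u).max(), abs(p_new - p))
        m, u, p = m_new, u_new, p_new
        if delta < tol:
            break
    out = MatchParams(m={f: float(m[j]) for j, f in enumerate(ALL_FIELDS)},
                      u={f: float(u[j]) for j, f in enumerate(ALL_FIELDS)},
                      jw_agreement_threshold=params.jw_agreement_threshold,
                      winkler_prefix_scale=params.winkler_prefix_scale,
                      winkler_max_prefix=params.winkler_max_prefix,
                      log_base=params.log_base)
    return out.validate()


# ---------------------------------------------------------------------------
# best-candidate linkage (vectorised over the registry)

_OUTCOME_COLS = [f"outcome_{f}" for f in ALL_FIELDS]


def link_best_candidates(encounters: pd.DataFrame, registry: pd.DataFrame,
                         params: MatchParams, blocking: bool = False) -> pd.DataFrame:
    """Select, for every encounter, the registry person with the highest match score.

    Ties on score are broken by fewest disagreeing fields, then lowest
    person_id, and reported in the ``tie`` column. With ``blocking=True``
    candidates are restricted to registry records agreeing on sex and village
    (encounters missing either field are compared against everyone).

    Returns a frame with one row per encounter: encounter_id, person_id,
    match_score, n_disagree, tie, and per-field outcome columns.
    """
    params.validate()
    if len(registry) == 0:
        raise ValueError("registry is empty")
    jw = _JWCache(params.winkler_prefix_scale, params.winkler_max_prefix)
    thr = params.jw_agreement_threshold

    w_agree = {f: field_weight(AGREE, params.m[f], params.u[f], params.log_base)
               for f in ALL_FIELDS}
    w_dis = {f: field_weight(DISAGREE, params.m[f], params.u[f], params.log_base)
             for f in ALL_FIELDS}

    # registry-side arrays
    reg_names = {}
    reg_name_missing = {}
    reg_unique = {}
    for f, (_, reg_cols) in _NAME_COLS.items():
        cols = [registry[c].fillna("").to_numpy(dtype=object) for c in reg_cols]
        reg_names[f] = cols
        reg_name_missing[f] = np.logical_and.reduce([c == "" for c in cols])
        uniq = set()
        for c in cols:
            uniq.update(x for x in c if x)
        reg_unique[f] = sorted(uniq)
    reg_exact = {}
    reg_exact_missing = {}
    for f in EXACT_FIELDS:
        col = registry[f]
        miss = col.isna().to_numpy()
        vals = col.astype(object).to_numpy()
        vals[miss] = ""
        reg_exact_missing[f] = miss | (vals == "")
        reg_exact[f] = vals
    person_ids = registry["person_id"].to_numpy(dtype=object)
    n_reg = len(registry)

    results = []
    enc_records = encounters.to_dict("records")
    for enc in enc_records:
        if blocking:
            cand = np.ones(n_reg, dtype=bool)
            if not _is_missing(enc.get("sex")):
                cand &= reg_exact_missing["sex"] | (reg_exact["sex"] == enc["sex"])
            if not _is_missing(enc.get("village")):
                cand &= reg_exact_missing["village"] | (reg_exact["village"] == enc["village"])
            cand_idx = np.flatnonzero(cand)
            if len(cand_idx) == 0:
                cand_idx = np.arange(n_reg)
        else:
            cand_idx = np.arange(n_reg)

        score = np.zeros(len(cand_idx))
        n_disagree = np.zeros(len(cand_idx), dtype=int)
        outcome_codes = {}  # field -> int array (1 agree, -1 disagree, 0 missing)

        for f, (enc_cols, _) in _NAME_COLS.items():
            enc_names = [enc.get(c) for c in enc_cols]
            enc_names = [x for x in enc_names if not _is_missing(x)]
            if not enc_names:
                outcome_codes[f] = np.zeros(len(cand_idx), dtype=int)
                continue
            agree_set = {
                rn for rn in reg_unique[f]
                if max(jw(a, rn) for a in enc_names) >= thr
            }
            cols = reg_names[f]
            agree = np.zeros(n_reg, dtype=bool)
            for c in cols:
                if agree_set:
                    agree |= np.isin(c, list(agree_set))
            agree = agree[cand_idx]
            missing = reg_name_missing[f][cand_idx]
            code = np.where(missing, 0, np.where(agree, 1, -1))
            outcome_codes[f] = code
            score += np.where(code == 1, w_agree[f], np.where(code == -1, w_dis[f], 0.0))
            n_disagree += code == -1

        for f in EXACT_FIELDS:
            v = enc.get(f)
            if _is_missing(v):
                outcome_codes[f] = np.zeros(len(cand_idx), dtype=int)
                continue
            missing = reg_exact_missing[f][cand_idx]
            agree = reg_exact[f][cand_idx] == v
            code = np.where(missing, 0, np.where(agree, 1, -1))
            outcome_codes[f] = code
            score += np.where(code == 1, w_agree[f], np.where(code == -1, w_dis[f], 0.0))
            n_disagree += code == -1

        best = score.max()
        top = np.flatnonzero(np.isclose(score, best, rtol=0, atol=1e-9))
        tie = len(top) > 1
        if tie:
            d = n_disagree[top]
            top = top[d == d.min()]
            pid_top = person_ids[cand_idx[top]]
            pick = top[np.argsort(pid_top, kind="stable")[0]]
        else:
            pick = top[0]

        row = {
            "encounter_id": enc["encounter_id"],
            "person_id": person_ids[cand_idx[pick]],
            "match_score": float(score[pick]),
            "n_disagree": int(n_disagree[pick]),
            "tie": bool(tie),
        }
        for f in ALL_FIELDS:
            code = outcome_codes[f][pick]
            row[f"outcome_{f}"] = AGREE if code == 1 else DISAGREE if code == -1 else MISSING
        results.append(row)

    return pd.DataFrame(results)


def score_true_pairs(encounters: pd.DataFrame, registry: pd.DataFrame,
                     gold_links: pd.DataFrame, params: MatchParams) -> pd.Series:
    """Match score of each (encounter, gold person) pair — the true-match score
    distribution that anchors the percentile thresholds."""
    reg = registry.set_index("person_id")
    gold = gold_links.set_index("encounter_id")["person_id"]
    jw = _JWCache(params.winkler_prefix_scale, params.winkler_max_prefix)
    scores = {}
    for enc in encounters.to_dict("records"):
        pid = gold.loc[enc["encounter_id"]]
        person = reg.loc[pid].to_dict()
        person["person_id"] = pid
        scores[enc["encounter_id"]] = score_pair(enc, person, params, jw=jw).match_score
    return pd.Series(scores, name="true_match_score")


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class ThresholdSet:
    """Named score cutoffs at percentiles of the true-match score distribution."""

    percentiles: dict  # label -> percentile
    cutoffs: dict      # label -> resolved score

    def items(self):
        return self.cutoffs.items()


def nearest_rank_percentile(scores, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic (p=0 -> minimum)."""
    s = np.sort(np.asarray(scores, dtype=float))
    if len(s) == 0:
        raise ValueError("empty score list")
    if p <= 0:
        return float(s[0])
    k = math.ceil(p / 100.0 * len(s))
    return float(s[min(k, len(s)) - 1])


def resolve_thresholds(true_match_scores, percentiles: dict) -> ThresholdSet:
    """Resolve labelled percentiles of the true-match score distribution into cutoffs."""
    scores = np.asarray(list(true_match_scores), dtype=float)
    if len(scores) == 0:
        raise ValueError("empty true-match score list")
    cutoffs = {label: nearest_rank_percentile(scores, p) for label, p in percentiles.items()}
    ordered = sorted(percentiles, key=percentiles.get)
    for lo, hi in zip(ordered, ordered[1:]):
        assert cutoffs[lo] <= cutoffs[hi], "cutoffs must be nondecreasing in percentile"
    return ThresholdSet(percentiles=dict(percentiles), cutoffs=cutoffs)


def build_linked_dataset(best_candidates: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Keep best-candidate pairs at or above the cutoff (inclusive comparison)."""
    return best_candidates[best_candidates["match_score"] >= cutoff].reset_index(drop=True)


# ---------------------------------------------------------------------------
# data-integrity flags


def qc_flags(linked: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Back-end integrity checks on encounters linked to multiple registry records.

    Flags: birth-year gap strictly greater than 10 years, conflicting sex,
    two linked records in the same household, and overlapping residency
    episodes between linked records.
    """
    reg = registry.set_index("person_id")
    flags = []
    for eid, grp in linked.groupby("encounter_id"):
        pids = sorted(set(grp["person_id"]))
        if len(pids) < 2:
            continue
        persons = reg.loc[pids]
        years = persons["birth_year"].dropna()
        if len(years) >= 2 and years.max() - years.min() > 10:
            flags.append((eid, "birth_year_gap_gt10",
                          f"birth years {int(years.min())}..{int(years.max())}"))
        if persons["sex"].nunique() > 1:
            flags.append((eid, "sex_conflict", "/".join(sorted(persons["sex"].unique()))))
        hh = persons["household_id"]
        if hh.duplicated().any():
            flags.append((eid, "same_household_multimatch", hh[hh.duplicated()].iloc[0]))
        episodes = [parse_episodes(t) for t in persons["residency_episodes"]]
        overlap = False
        for i in range(len(episodes)):
            for j in range(i + 1, len(episodes)):
                for s1, e1 in episodes[i]:
                    for s2, e2 in episodes[j]:
                        if s1 < e2 and s2 < e1:
                            overlap = True
        if overlap:
            flags.append((eid, "overlapping_residency", f"{len(pids)} linked records"))
    return pd.DataFrame(flags, columns=["encounter_id", "rule", "detail"])
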