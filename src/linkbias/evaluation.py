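"""Linkage-error quantification against gold-standard links.

Links are classified as true (linked to the gold person), false (linked to a
different person) or missed (gold encounter absent from the linked dataset).
Sensitivity = tp / n_gold, PPV = tp / (tp + fp), false-match rate = 1 - PPV.
Group characteristics are compared with standardised differences (anchors
0.2 / 0.5 / 0.8 for small / moderate / large imbalance) and contingency tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConfusionCounts:
    n_gold: int
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.n_gold, self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fn != self.n_gold:
            raise ValueError(f"tp + fn = {self.tp + self.fn} must equal n_gold = {self.n_gold}")


@dataclass
class LinkMetrics:
    sensitivity: float
    ppv: float
    false_match_rate: float


def classify_links(gold_links: pd.DataFrame, linked: pd.DataFrame) -> ConfusionCounts:
    """Count true / false / missed matches of a linked dataset vs the gold standard.

    ``gold_links`` and ``linked`` both carry (encounter_id, person_id); gold
    links must be a function of encounter_id.
    """
    gold = gold_links.set_index("encounter_id")["person_id"]
    if gold.index.has_duplicates:
        raise ValueError("gold links map an encounter to more than one person")
    unknown = set(linked["encounter_id"]) - set(gold.index)
    if unknown:
        raise ValueError(f"linked encounters absent from the gold universe: {sorted(unknown)[:5]}")
    merged = linked.merge(gold.rename("gold_person_id"), left_on="encounter_id", right_index=True)
    tp = int((merged["person_id"] == merged["gold_person_id"]).sum())
    fp = len(merged) - tp
    n_gold = len(gold)
    return ConfusionCounts(n_gold=n_gold, tp=tp, fp=fp, fn=n_gold - tp)


def link_metrics(counts: ConfusionCounts) -> LinkMetrics:
    """Sensitivity, PPV and false-match rate from confusion counts."""
    if counts.n_gold <= 0:
        raise ValueError("n_gold must be positive")
    sens = counts.tp / counts.n_gold
    linked_n = counts.tp + counts.fp
    if linked_n == 0:
        warnings.warn("no linked records: PPV undefined", stacklevel=2)
        return LinkMetrics(sensitivity=sens, ppv=float("nan"), false_match_rate=float("nan"))
    ppv = counts.tp / linked_n
    return LinkMetrics(sensitivity=sens, ppv=ppv, false_match_rate=1.0 - ppv)


# ---------------------------------------------------------------------------
# standardised differences


def standardized_difference_proportions(p_a: float, p_b: float) -> float:
    """Standardised difference of a binary variable from group proportions."""
    pooled = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0
    if pooled <= 0:
        return float("nan")
    return (p_a - p_b) / math.sqrt(pooled)


def standardized_difference_means(mean_a: float, sd_a: float,
                                  mean_b: float, sd_b: float) -> float:
    """Standardised difference of a continuous variable from group summaries."""
    pooled = (sd_a**2 + sd_b**2) / 2.0
    if pooled <= 0:
        return float("nan")
    return (mean_a - mean_b) / math.sqrt(pooled)


def imbalance_label(d: float) -> str:
    """Anchor-based label: '' / small / moderate / large at |d| = 0.2 / 0.5 / 0.8."""
    if not np.isfinite(d):
        return ""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    if a >= 0.2:
        return "small"
    return ""


def balance_table(true_set: pd.DataFrame, false_set: pd.DataFrame,
                  missed_set: pd.DataFrame, variables) -> pd.DataFrame:
    """Level-by-level comparison of true vs false and true vs missed matches.

    Categorical variables get one row per observed level with group
    proportions; the standardised difference of each level's indicator is
    reported with its anchor label. Empty groups yield absent columns.
    """
    groups = {"true": true_set, "false": false_set, "missed": missed_set}
    rows = []
    for var in variables:
        levels = sorted(
            set().union(*(set(g[var].dropna().unique()) for g in groups.values() if len(g))),
            key=str,
        )
        for level in levels:
            row = {"variable": var, "level": level}
            props = {}
            for gname, g in groups.items():
                if len(g) == 0:
                    props[gname] = float("nan")
                else:
                    props[gname] = float((g[var] == level).mean())
                row[f"prop_{gname}"] = props[gname]
            for other in ("false", "missed"):
                if np.isnan(props[other]) or np.isnan(props["true"]):
                    d = float("nan")
                else:
                    d = standardized_difference_proportions(props["true"], props[other])
                row[f"std_diff_true_vs_{other}"] = d
                row[f"imbalance_true_vs_{other}"] = imbalance_label(d)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency tests


def contingency_test(table) -> tuple:
    """Pearson chi-square (no continuity correction) for r x c tables; Fisher's
    exact test for 2 x 2 tables with any expected cell below 5.

    Returns ``(test_name, statistic, p_value)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D array of nonnegative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    if t.shape == (2, 2):
        row = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        expected = row @ col / t.sum()
        if (expected < 5).any():
            _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
            return ("fisher_exact", float("nan"), float(p))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return ("chi_square", float(chi2), float(p))
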