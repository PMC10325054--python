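"""Anemotaxic-turning behavior analysis.

Trials are scored by forced choice into three categories — turning
toward the airflow stimulus, turning away, or no reaction.  The module
tests (i) the direction bias among reactive trials (one-df chi-square
goodness of fit, no-reaction trials excluded), (ii) toward-rate
differences between weak (hand-flap) and strong (cardboard-flap)
stimuli (Fisher's exact test), (iii) unpaired group contrasts such as
wind- vs non-wind-whisker trimming (Mann-Whitney on per-animal toward
fractions), and (iv) paired treatment contrasts such as lidocaine vs
Ringer injections (signed-rank on per-animal toward fractions).  The
sampling unit for group tests is always the animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import RankTestResult, rank_sum_test, signed_rank_test

RESPONSES = ("toward", "away", "none")
REQUIRED_COLUMNS = (
    "animal_id",
    "trial_index",
    "stimulus_side",
    "stimulus_type",
    "treatment",
    "response",
)


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns {missing}")
    bad = set(table["response"]) - set(RESPONSES)
    if bad:
        raise ValueError(f"unknown response categories {sorted(bad)}")
    return table


@dataclass
class ContingencyResult:
    n_toward: int
    n_away: int
    statistic: float
    p: float


def turn_summary(table: pd.DataFrame, by: str = "animal_id") -> pd.DataFrame:
    """Per-animal (or per-group) response counts and toward fraction."""
    validate_trials(table)
    rows = []
    for key, sub in table.groupby(by):
        counts = sub["response"].value_counts()
        n = len(sub)
        rows.append(
            {
                by: key,
                "n_toward": int(counts.get("toward", 0)),
                "n_away": int(counts.get("away", 0)),
                "n_none": int(counts.get("none", 0)),
                "n_trials": n,
                "fraction_toward": counts.get("toward", 0) / n,
            }
        )
    return pd.DataFrame(rows)


def direction_bias_test(
    table: pd.DataFrame | None = None,
    stimulus_type: str | None = None,
    counts: tuple[int, int] | None = None,
    include_no_reaction: bool = False,
) -> ContingencyResult:
    """Chi-square goodness of fit of toward vs away counts against equal
    expected frequencies.

    Either pass a trial ``table`` (optionally filtered to one
    ``stimulus_type``) or the raw ``counts`` pair directly.  No-reaction
    trials are excluded by default (the test concerns reactive trials);
    ``include_no_reaction`` adds them as a third equiprobable cell.
    """
    if counts is not None:
        n_to, n_away = counts
        observed = [n_to, n_away]
    else:
        if table is None:
            raise ValueError("need a trial table or explicit counts")
        validate_trials(table)
        if stimulus_type is not None:
            table = table[table["stimulus_type"] == stimulus_type]
        vc = table["response"].value_counts()
        n_to = int(vc.get("toward", 0))
        n_away = int(vc.get("away", 0))
        observed = [n_to, n_away]
        if include_no_reaction:
            observed.append(int(vc.get("none", 0)))
    if sum(observed[:2]) < 1:
        raise ValueError("no reactive trials (toward + away = 0)")
    stat, p = sps.chisquare(observed)
    return ContingencyResult(
        n_toward=n_to, n_away=n_away, statistic=float(stat), p=float(p)
    )


@dataclass
class FisherResult:
    table: np.ndarray
    odds_ratio: float
    p: float


def stimulus_strength_comparison(
    table: pd.DataFrame, type_a: str = "hand", type_b: str = "cardboard"
) -> FisherResult:
    """Two-sided Fisher exact test comparing toward-rates between two
    stimulus types (2x2: toward vs not-toward x type)."""
    validate_trials(table)
    cells = np.zeros((2, 2), dtype=int)
    for j, st in enumerate((type_a, type_b)):
        sub = table[table["stimulus_type"] == st]
        if len(sub) == 0:
            raise ValueError(f"no trials of stimulus type {st!r}")
        toward = int((sub["response"] == "toward").sum())
        cells[0, j] = toward
        cells[1, j] = len(sub) - toward
    odds, p = sps.fisher_exact(cells, alternative="two-sided")
    return FisherResult(table=cells, odds_ratio=float(odds), p=float(p))


@dataclass
class GroupComparisonResult:
    fractions_a: np.ndarray
    fractions_b: np.ndarray
    test: RankTestResult


def group_turn_comparison(
    table: pd.DataFrame, group_a_treatment: str, group_b_treatment: str
) -> GroupComparisonResult:
    """Mann-Whitney comparison of per-animal toward fractions between two
    unpaired treatment groups (exact for small samples)."""
    validate_trials(table)
    fracs = {}
    for t in (group_a_treatment, group_b_treatment):
        sub = table[table["treatment"] == t]
        summ = turn_summary(sub) if len(sub) else pd.DataFrame()
        if len(summ) < 2:
            raise ValueError(f"treatment {t!r} has fewer than 2 animals")
        fracs[t] = summ["fraction_toward"].to_numpy()
    a, b = fracs[group_a_treatment], fracs[group_b_treatment]
    return GroupComparisonResult(
        fractions_a=a, fractions_b=b, test=rank_sum_test(a, b)
    )


@dataclass
class PairedComparisonResult:
    animals: list
    fractions_a: np.ndarray
    fractions_b: np.ndarray
    n_decreases: int
    test: RankTestResult


def paired_turn_comparison(
    table: pd.DataFrame,
    treatment_a: str = "lidocaine",
    treatment_b: str = "ringer",
) -> PairedComparisonResult:
    """Signed-rank comparison of per-animal toward fractions between two
    paired treatments; every animal must have a session under each.

    Also reports how many animals decreased from b to a (e.g. fewer
    toward-turns under lidocaine than Ringer).
    """
    validate_trials(table)
    sub = table[table["treatment"].isin([treatment_a, treatment_b])]
    per = {}
    for (animal, treatment), grp in sub.groupby(["animal_id", "treatment"]):
        per.setdefault(animal, {})[treatment] = (
            (grp["response"] == "toward").sum() / len(grp)
        )
    animals = sorted(per)
    for animal in animals:
        have = per[animal]
        if treatment_a not in have or treatment_b not in have:
            raise ValueError(f"animal {animal!r} lacks one of the paired treatments")
    fa = np.array([per[a][treatment_a] for a in animals])
    fb = np.array([per[a][treatment_b] for a in animals])
    diffs = fa - fb
    return PairedComparisonResult(
        animals=animals,
        fractions_a=fa,
        fractions_b=fb,
        n_decreases=int((diffs < 0).sum()),
        test=signed_rank_test(diffs),
    )
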