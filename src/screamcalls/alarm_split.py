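"""Exhaustive alarm/non-alarm categorization search over scream types.

The 6 non-neutral scream types can be partitioned into two categories of
2-4 types each; neutral vocalizations always form a third, fixed level.
There are exactly 25 such unordered partitions. Each is scored by a one-way
repeated-measures ANOVA on per-rater mean alarm ratings over the 3 levels
(neutral / one category / the other), and the partition with the largest F
maximally separates the scream types along the alarm dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .taxonomy import NEUTRAL, NONNEUTRAL_TYPES

__all__ = [
    "CategorySplit",
    "RatingTable",
    "SplitScore",
    "enumerate_splits",
    "split_anova",
    "best_split",
    "read_rating_table",
    "write_rating_table",
]


@dataclass(frozen=True)
class CategorySplit:
    """An unordered partition of the 6 scream types into two categories.

    ``alarm_types`` names the candidate alarm category; since the ANOVA is
    symmetric in the two categories, a split and its label-swapped twin are
    the same partition.
    """

    alarm_types: frozenset[str]
    nonalarm_types: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alarm_types", frozenset(self.alarm_types))
        object.__setattr__(self, "nonalarm_types", frozenset(self.nonalarm_types))
        all_types = set(NONNEUTRAL_TYPES)
        if self.alarm_types & self.nonalarm_types:
            raise ValueError("categories must be disjoint")
        if self.alarm_types | self.nonalarm_types != all_types:
            raise ValueError("categories must cover the 6 non-neutral scream types")
        for side in (self.alarm_types, self.nonalarm_types):
            if len(side) not in (2, 3, 4):
                raise ValueError("each category must contain 2-4 scream types")

    def swapped(self) -> "CategorySplit":
        return CategorySplit(self.nonalarm_types, self.alarm_types)

    def same_partition(self, other: "CategorySplit") -> bool:
        return {self.alarm_types, self.nonalarm_types} == {
            other.alarm_types,
            other.nonalarm_types,
        }

    def __str__(self) -> str:
        order = {t: i for i, t in enumerate(NONNEUTRAL_TYPES)}
        a = "+".join(sorted(self.alarm_types, key=order.get))
        b = "+".join(sorted(self.nonalarm_types, key=order.get))
        return f"{{{a}}} vs {{{b}}}"


@dataclass(frozen=True)
class RatingTable:
    """Per-rater per-scream alarm ratings in [0, 1] with a scream -> type map."""

    ratings: pd.DataFrame  # rows = raters, columns = scream ids
    scream_types: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.ratings.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("ratings must be finite")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("ratings must lie in [0, 1]")
        missing = [c for c in self.ratings.columns if c not in self.scream_types]
        if missing:
            raise ValueError(f"screams without a type mapping: {missing[:5]}")

    def columns_of_types(self, types: set[str] | frozenset[str]) -> list[str]:
        return [c for c in self.ratings.columns if self.scream_types[c] in types]


@dataclass(frozen=True)
class SplitScore:
    """A categorization candidate with its 3-level repeated-measures ANOVA.

    ``alarm_types`` is oriented: it names the category with the higher grand
    mean alarm rating, whatever orientation the input split had.
    """

    split: CategorySplit
    anova: stats.AnovaResult
    level_means: dict[str, float]

    @property
    def f_value(self) -> float:
        return self.anova.f_value

    def to_dict(self) -> dict:
        return {
            "alarm_types": sorted(self.split.alarm_types),
            "nonalarm_types": sorted(self.split.nonalarm_types),
            "f_value": self.anova.f_value,
            "df_num": self.anova.df_num,
            "df_den": self.anova.df_den,
            "p_value": self.anova.p_value,
            "eta_sq": self.anova.eta_sq,
            "epsilon": self.anova.epsilon,
            "mauchly_p": self.anova.mauchly_p,
            "corrected": self.anova.corrected,
            "level_means": self.level_means,
        }


def enumerate_splits() -> list[CategorySplit]:
    """All 25 admissible unordered partitions, in canonical order.

    Size-2-vs-4 partitions are listed by their 2-type side (15 of them),
    then 3-vs-3 partitions deduplicated by fixing the first scream type in
    the canonical order on the first side (10), for 25 in total.
    """
    types = NONNEUTRAL_TYPES
    splits: list[CategorySplit] = []
    for pair in combinations(types, 2):
        rest = frozenset(types) - set(pair)
        splits.append(CategorySplit(frozenset(pair), rest))
    for triple in combinations(types, 3):
        if types[0] in triple:
            rest = frozenset(types) - set(triple)
            splits.append(CategorySplit(frozenset(triple), rest))
    return splits


def split_anova(ratings: RatingTable, split: CategorySplit) -> SplitScore:
    """Score one partition: per-rater level means, then a 3-level rm-ANOVA.

    The returned score orients the split so that the higher-rated category
    is called alarm.
    """
    neutral_cols = ratings.columns_of_types({NEUTRAL})
    a_cols = ratings.columns_of_types(split.alarm_types)
    b_cols = ratings.columns_of_types(split.nonalarm_types)
    for name, cols in (("neutral", neutral_cols), ("alarm", a_cols), ("non-alarm", b_cols)):
        if not cols:
            raise ValueError(f"no screams for the {name} level")
    if len(ratings.ratings) < 2:
        raise ValueError("need at least 2 raters")
    levels = np.column_stack(
        [
            ratings.ratings[neutral_cols].mean(axis=1).to_numpy(),
            ratings.ratings[b_cols].mean(axis=1).to_numpy(),
            ratings.ratings[a_cols].mean(axis=1).to_numpy(),
        ]
    )
    anova = stats.rm_anova(levels)
    mean_a = float(levels[:, 2].mean())
    mean_b = float(levels[:, 1].mean())
    oriented = split if mean_a >= mean_b else split.swapped()
    return SplitScore(
        split=oriented,
        anova=anova,
        level_means={
            "neutral": float(levels[:, 0].mean()),
            "nonalarm": min(mean_a, mean_b),
            "alarm": max(mean_a, mean_b),
        },
    )


def best_split(ratings: RatingTable) -> list[SplitScore]:
    """Score all 25 partitions and return them sorted by F, largest first.

    Ties preserve the canonical enumeration order (the sort is stable).
    """
    scores = [split_anova(ratings, s) for s in enumerate_splits()]
    return sorted(scores, key=lambda s: -s.f_value)


def write_split_scores(path: str | Path, scores: list[SplitScore]) -> None:
    payload = [s.to_dict() for s in scores]
    if payload:
        payload[0]["best"] = True
    Path(path).write_text(json.dumps(payload, indent=2))


def write_rating_table(path: str | Path, table: RatingTable) -> None:
    """Delimited layout: one header row of scream ids, a second row of types."""
    df = table.ratings.copy()
    type_row = pd.DataFrame(
        [[table.scream_types[c] for c in df.columns]], columns=df.columns, index=["type"]
    )
    pd.concat([type_row, df]).to_csv(path, index_label="rater")


def read_rating_table(path: str | Path) -> RatingTable:
    df = pd.read_csv(path, index_col="rater")
    types = df.loc["type"].to_dict()
    ratings = df.drop(index="type").astype(float)
    return RatingTable(ratings=ratings, scream_types=types)
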