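"""Perceptual decision metrics from forced-choice trial logs.

Covers the behavioral analyses of scream recognition: confusion matrices
from 7-alternative forced-choice (7AFC) logs, the false-alarm rate in its
categorization sense (how often a category is the one chosen when a
stimulus is misclassified), one-vs-rest multi-class sensitivity
d' = Z(hit rate) - Z(false-alarm rate), RT/accuracy summaries at the
7-level and 3-level (neutral / non-alarm / alarm) groupings, and the
21-pair 2AFC discrimination analysis with paired t tests, Benjamini-
Hochberg correction, and the 4-way combination-category contrast
(neutral-vs-scream, within non-alarm, within alarm, alarm-vs-non-alarm).

RT means use correct trials only; accuracy denominators exclude missed
trials. Extreme hit or false-alarm rates are nudged off 0/1 by the 1/(2N)
rule before the inverse-normal transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .taxonomy import ALARM_TYPES, NEUTRAL, NONALARM_TYPES, SCREAM_TYPES

__all__ = [
    "TrialLog",
    "ConfusionMatrix",
    "ConfusionResult",
    "DPrimeResult",
    "PairResult",
    "ComboCategoryResult",
    "confusion_from_log",
    "false_alarm_rates",
    "dprime_table",
    "rt_accuracy_summary",
    "three_level_grouping",
    "afc2_pairwise",
    "afc2_combo_categories",
    "combo_category_of_pair",
    "read_trial_log",
    "write_trial_log",
]

MISSED = "MISSED"

COMBO_CATEGORIES = (
    "neutral_vs_scream",
    "nonalarm_vs_nonalarm",
    "alarm_vs_nonalarm",
    "alarm_vs_alarm",
)


@dataclass(frozen=True)
class TrialLog:
    """Per-trial forced-choice records.

    ``trials`` columns: participant, block, stimulus_id, true_type,
    response (a category or the MISSED sentinel), rt_ms (NaN when missed).
    """

    trials: pd.DataFrame
    task_kind: str  # "7AFC" or "2AFC"
    response_window_ms: float
    categories: tuple[str, ...] = field(default=SCREAM_TYPES)

    def __post_init__(self) -> None:
        required = {"participant", "block", "stimulus_id", "true_type", "response", "rt_ms"}
        missing_cols = required - set(self.trials.columns)
        if missing_cols:
            raise ValueError(f"trial log missing columns: {sorted(missing_cols)}")
        if self.task_kind not in ("7AFC", "2AFC"):
            raise ValueError("task_kind must be '7AFC' or '2AFC'")
        if self.response_window_ms <= 0:
            raise ValueError("response_window_ms must be positive")
        df = self.trials
        bad_types = set(df["true_type"]) - set(self.categories)
        if bad_types:
            raise ValueError(f"true types outside the category list: {sorted(bad_types)}")
        responded = df["response"] != MISSED
        rts = df.loc[responded, "rt_ms"].to_numpy(dtype=float)
        if len(rts) and (np.any(~np.isfinite(rts)) or np.any(rts <= 0) or np.any(
            rts > self.response_window_ms
        )):
            raise ValueError("responded trials must have rt in (0, response_window_ms]")
        if self.task_kind == "2AFC":
            per_block = df.groupby("block")["true_type"].nunique()
            if not (per_block == 2).all():
                raise ValueError("each 2AFC block must contain exactly 2 true types")

    @property
    def participants(self) -> list:
        return sorted(self.trials["participant"].unique())

    def bookkeeping(self) -> pd.DataFrame:
        """Per participant: missed + correct + incorrect = total trials."""
        df = self.trials
        out = df.assign(
            missed=df["response"] == MISSED,
            correct=(df["response"] == df["true_type"]) & (df["response"] != MISSED),
        )
        g = out.groupby("participant").agg(
            total=("response", "size"), missed=("missed", "sum"), correct=("correct", "sum")
        )
        g["incorrect"] = g["total"] - g["missed"] - g["correct"]
        return g


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of (true type, chosen type), missed trials excluded."""

    counts: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))
        k = len(self.categories)
        if counts.shape != (k, k) or np.any(counts < 0):
            raise ValueError("counts must be a nonnegative KxK matrix")

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.categories), columns=list(self.categories)
        )


@dataclass(frozen=True)
class ConfusionResult:
    pooled: ConfusionMatrix
    per_participant: dict


@dataclass(frozen=True)
class DPrimeResult:
    """Per-category hit rate, false-alarm rate, and sensitivity d'."""

    table: pd.DataFrame  # columns: hit_rate, false_alarm_rate, d_prime
    correction_method: str


@dataclass(frozen=True)
class PairResult:
    """One 2AFC scream pair: per-type means, normalized differences, tests."""

    pair: tuple[str, str]
    mean_rt_ms: dict[str, float]
    mean_accuracy: dict[str, float]
    norm_rt_diff: float
    norm_accuracy_diff: float
    rt_t: float
    rt_p: float
    rt_p_fdr: float
    acc_t: float
    acc_p: float
    acc_p_fdr: float

    def __post_init__(self) -> None:
        for raw, adj in ((self.rt_p, self.rt_p_fdr), (self.acc_p, self.acc_p_fdr)):
            for v in (raw, adj):
                if np.isfinite(v) and not (0 <= v <= 1):
                    raise ValueError("p-values must lie in [0, 1]")
            if np.isfinite(raw) and np.isfinite(adj) and adj < raw - 1e-12:
                raise ValueError("FDR-adjusted p must be >= raw p")


@dataclass(frozen=True)
class ComboCategoryResult:
    summary: pd.DataFrame  # per participant x combo category means
    rt_anova: stats.AnovaResult
    accuracy_anova: stats.AnovaResult
    class_sizes: dict[str, int]


def _confusion_counts(df: pd.DataFrame, categories: tuple[str, ...]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k), dtype=int)
    kept = df[df["response"] != MISSED]
    for true, resp in zip(kept["true_type"], kept["response"]):
        counts[idx[true], idx[resp]] += 1
    return counts


def confusion_from_log(log: TrialLog) -> ConfusionResult:
    """Pooled and per-participant confusion matrices from a 7AFC log."""
    if log.task_kind != "7AFC":
        raise ValueError("confusion matrices are defined for 7AFC logs")
    if len(log.trials) == 0:
        raise ValueError("empty trial log")
    pooled = ConfusionMatrix(_confusion_counts(log.trials, log.categories), log.categories)
    per = {
        p: ConfusionMatrix(_confusion_counts(g, log.categories), log.categories)
        for p, g in log.trials.groupby("participant")
    }
    return ConfusionResult(pooled=pooled, per_participant=per)


def false_alarm_rates(conf: ConfusionMatrix) -> pd.Series:
    """Probability of each category being the one chosen during misclassification.

    Off-diagonal choices of a category divided by all off-diagonal choices;
    the rates sum to 1. With zero misclassifications the rates are
    undefined and returned as NaN with a warning.
    """
    counts = conf.counts.astype(float)
    off = counts.copy()
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    if total == 0:
        warnings.warn("no misclassifications: false-alarm rates undefined", stacklevel=2)
        return pd.Series(np.nan, index=list(conf.categories), name="false_alarm_rate")
    return pd.Series(
        off.sum(axis=0) / total, index=list(conf.categories), name="false_alarm_rate"
    )


def _clamp_rate(rate: float, n: int) -> float:
    """1/(2N) correction for extreme rates before the inverse-normal transform."""
    if n <= 0:
        return 0.5
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    return float(np.clip(rate, lo, hi))


def dprime_table(conf: ConfusionMatrix, correction: str = "1/(2N)") -> DPrimeResult:
    """One-vs-rest sensitivity per category: d' = Z(hit) - Z(false alarm).

    Hit rate is the category's diagonal over its presentations; the
    false-alarm rate pools all other rows (choices of this category when
    any other type was presented, over all other presentations).
    """
    if correction != "1/(2N)":
        raise ValueError("only the 1/(2N) extreme-rate correction is implemented")
    counts = conf.counts.astype(float)
    row_sums = counts.sum(axis=1)
    total = counts.sum()
    rows = []
    for i, cat in enumerate(conf.categories):
        n_hit = int(row_sums[i])
        hit = _clamp_rate(counts[i, i] / row_sums[i] if row_sums[i] > 0 else 0.0, n_hit)
        n_fa = int(total - row_sums[i])
        fa_count = counts[:, i].sum() - counts[i, i]
        fa = _clamp_rate(fa_count / n_fa if n_fa > 0 else 0.0, n_fa)
        rows.append(
            {
                "category": cat,
                "hit_rate": hit,
                "false_alarm_rate": fa,
                "d_prime": stats.z_quantile(hit) - stats.z_quantile(fa),
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    return DPrimeResult(table=table, correction_method=correction)


def three_level_grouping() -> dict[str, str]:
    """Map each scream type to neutral / non-alarm / alarm."""
    grouping = {NEUTRAL: "neutral"}
    grouping.update({t: "nonalarm" for t in NONALARM_TYPES})
    grouping.update({t: "alarm" for t in ALARM_TYPES})
    return grouping


def rt_accuracy_summary(log: TrialLog, grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Per participant per level: mean RT over correct trials and accuracy.

    ``grouping`` maps each type to a level (identity by default, i.e. the
    7-level analysis); the 3-level analysis pools the member types' trials
    per participant. Accuracy excludes missed trials from the denominator;
    a participant x level cell with no correct trials gets RT = NaN.
    """
    levels = grouping or {t: t for t in log.categories}
    uncovered = set(log.trials["true_type"]) - set(levels)
    if uncovered:
        raise ValueError(f"grouping does not cover types: {sorted(uncovered)}")
    df = log.trials.assign(level=log.trials["true_type"].map(levels))
    df = df.assign(
        missed=df["response"] == MISSED,
        correct=(df["response"] == df["true_type"]) & (df["response"] != MISSED),
    )
    rows = []
    for (p, lev), g in df.groupby(["participant", "level"], sort=True):
        n_responded = int((~g["missed"]).sum())
        n_correct = int(g["correct"].sum())
        rt = g.loc[g["correct"], "rt_ms"].mean() if n_correct else np.nan
        rows.append(
            {
                "participant": p,
                "level": lev,
                "mean_rt_ms": float(rt) if np.isfinite(rt) else np.nan,
                "accuracy": n_correct / n_responded if n_responded else np.nan,
                "n_trials": len(g),
                "n_missed": int(g["missed"].sum()),
            }
        )
    return pd.DataFrame(rows)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    order = {t: i for i, t in enumerate(SCREAM_TYPES)}
    return (a, b) if order.get(a, 99) <= order.get(b, 99) else (b, a)


def afc2_pairwise(log: TrialLog) -> list[PairResult]:
    """Discrimination analysis for all 21 scream-type pairs of a 2AFC log.

    Per pair and participant: mean correct-trial RT and accuracy per type;
    paired t across participants between the two types; normalized
    differences (the mean difference divided by the per-participant mean of
    the two types, averaged over participants); Benjamini-Hochberg
    adjustment over the 21 tests, RT and accuracy families separately.
    """
    if log.task_kind != "2AFC":
        raise ValueError("pairwise discrimination requires a 2AFC log")
    df = log.trials.assign(
        missed=log.trials["response"] == MISSED,
        correct=(log.trials["response"] == log.trials["true_type"])
        & (log.trials["response"] != MISSED),
    )
    expected = {_pair_key(a, b) for a, b in combinations(log.categories, 2)}
    block_pairs: dict[tuple[str, str], list] = {}
    for block, g in df.groupby("block"):
        key = _pair_key(*sorted(g["true_type"].unique()))
        block_pairs.setdefault(key, []).append(block)
    missing = sorted(expected - set(block_pairs))
    if missing:
        raise ValueError(f"2AFC log is missing pair(s): {missing}")

    partials = []
    for pair in sorted(block_pairs, key=lambda k: (SCREAM_TYPES.index(k[0]), SCREAM_TYPES.index(k[1]))):
        sub = df[df["block"].isin(block_pairs[pair])]
        per = {}
        for t in pair:
            tt = sub[sub["true_type"] == t]
            g = tt.groupby("participant")
            rt = tt[tt["correct"]].groupby("participant")["rt_ms"].mean()
            acc = g["correct"].sum() / (g["missed"].size() - g["missed"].sum())
            per[t] = pd.DataFrame({"rt": rt, "acc": acc})
        joined = per[pair[0]].join(per[pair[1]], lsuffix="_a", rsuffix="_b", how="inner").dropna()
        if len(joined) < 2:
            raise ValueError(f"pair {pair}: fewer than 2 complete participants")

        def norm_diff(a: pd.Series, b: pd.Series) -> float:
            denom = (a + b) / 2.0
            return float(((a - b) / denom).mean())

        def safe_t(a: pd.Series, b: pd.Series) -> tuple[float, float]:
            try:
                t, _, p = stats.paired_t(a.to_numpy(), b.to_numpy())
            except ValueError:  # zero difference variance, e.g. identical means
                return np.nan, 1.0
            return t, p

        rt_t, rt_p = safe_t(joined["rt_a"], joined["rt_b"])
        acc_t, acc_p = safe_t(joined["acc_a"], joined["acc_b"])
        partials.append(
            dict(
                pair=pair,
                mean_rt_ms={pair[0]: float(joined["rt_a"].mean()), pair[1]: float(joined["rt_b"].mean())},
                mean_accuracy={pair[0]: float(joined["acc_a"].mean()), pair[1]: float(joined["acc_b"].mean())},
                norm_rt_diff=norm_diff(joined["rt_a"], joined["rt_b"]),
                norm_accuracy_diff=norm_diff(joined["acc_a"], joined["acc_b"]),
                rt_t=rt_t,
                rt_p=rt_p,
                acc_t=acc_t,
                acc_p=acc_p,
            )
        )

    rt_fdr = stats.fdr_adjust(np.array([p["rt_p"] for p in partials]))
    acc_fdr = stats.fdr_adjust(np.array([p["acc_p"] for p in partials]))
    return [
        PairResult(rt_p_fdr=float(rf), acc_p_fdr=float(af), **p)
        for p, rf, af in zip(partials, rt_fdr, acc_fdr)
    ]


def combo_category_of_pair(a: str, b: str) -> str:
    """Map a scream-type pair to one of the 4 combination categories."""
    pair = {a, b}
    if NEUTRAL in pair:
        return "neutral_vs_scream"
    n_alarm = len(pair & ALARM_TYPES)
    if n_alarm == 2:
        return "alarm_vs_alarm"
    if n_alarm == 1:
        return "alarm_vs_nonalarm"
    return "nonalarm_vs_nonalarm"


def afc2_combo_categories(log: TrialLog) -> ComboCategoryResult:
    """4-level contrast over the 21 pairs: neutral-vs-scream, within
    non-alarm, alarm-vs-non-alarm, within alarm.

    Trials are pooled per participant within each combination category, and
    RT and accuracy are each subjected to a 4-level repeated-measures
    ANOVA.
    """
    if log.task_kind != "2AFC":
        raise ValueError("combination categories require a 2AFC log")
    df = log.trials.assign(
        missed=log.trials["response"] == MISSED,
        correct=(log.trials["response"] == log.trials["true_type"])
        & (log.trials["response"] != MISSED),
    )
    pair_of_block = {}
    combo_of_block = {}
    for block, g in df.groupby("block"):
        types = sorted(g["true_type"].unique())
        pair_of_block[block] = _pair_key(*types)
        combo_of_block[block] = combo_category_of_pair(*types)
    df = df.assign(combo=df["block"].map(combo_of_block))

    class_sizes: dict[str, int] = {c: 0 for c in COMBO_CATEGORIES}
    for pair in set(pair_of_block.values()):
        class_sizes[combo_category_of_pair(*pair)] += 1

    rows = []
    for (p, combo), g in df.groupby(["participant", "combo"]):
        n_resp = int((~g["missed"]).sum())
        n_corr = int(g["correct"].sum())
        rows.append(
            {
                "participant": p,
                "combo": combo,
                "mean_rt_ms": float(g.loc[g["correct"], "rt_ms"].mean()) if n_corr else np.nan,
                "accuracy": n_corr / n_resp if n_resp else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    rt_wide = summary.pivot(index="participant", columns="combo", values="mean_rt_ms")
    acc_wide = summary.pivot(index="participant", columns="combo", values="accuracy")
    rt_wide = rt_wide[list(COMBO_CATEGORIES)].dropna()
    acc_wide = acc_wide[list(COMBO_CATEGORIES)].dropna()
    return ComboCategoryResult(
        summary=summary,
        rt_anova=stats.rm_anova(rt_wide.to_numpy()),
        accuracy_anova=stats.rm_anova(acc_wide.to_numpy()),
        class_sizes=class_sizes,
    )


def write_trial_log(path: str | Path, log: TrialLog) -> None:
    df = log.trials.copy()
    df["missed"] = (df["response"] == MISSED).astype(int)
    df.to_csv(path, index=False)


def read_trial_log(
    path: str | Path,
    task_kind: str,
    response_window_ms: float,
    categories: tuple[str, ...] = SCREAM_TYPES,
) -> TrialLog:
    df = pd.read_csv(path)
    if "missed" in df.columns:
        df = df.drop(columns=["missed"])
    return TrialLog(
        trials=df,
        task_kind=task_kind,
        response_window_ms=response_window_ms,
        categories=categories,
    )
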