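"""Trial classification for the preference decision-making task.

Subjects see short action descriptions (40 items, 3 repetitions), decide on
a four-point scale (strong no = -2 ... strong yes = +2), and afterwards rate
each item's anticipated short- and long-term consequences on a six-point
scale recoded to {-3..-1, +1..+3} (no neutral point). An item is
*divergent* when the two ratings have opposite signs. Each trial falls
into exactly one of eight regressor categories (or MISSED); the long-term
categories collapse to LONG and the short-term ones to SHORT for the
contrast of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ItemRating", "TrialResponse", "TrialClass", "ItemKind",
    "classify_item", "classify_trial", "collapse_label",
    "apply_task_exclusions", "behavioral_descriptives",
    "VALID_RATINGS", "VALID_DECISIONS",
]

VALID_RATINGS = (-3, -2, -1, 1, 2, 3)
VALID_DECISIONS = (-2, -1, 1, 2)


class ItemKind(str, Enum):
    DIVERGENT = "DIVERGENT"
    CONGRUENT_POS = "CONGRUENT_POS"
    CONGRUENT_NEG = "CONGRUENT_NEG"


class TrialClass(str, Enum):
    """The eight decision regressor categories plus MISSED.

    LT_A: declines activity with positive short-term / negative long-term.
    LT_B: accepts activity with negative short-term / positive long-term.
    ST_A: accepts activity with positive short-term / negative long-term.
    ST_B: declines activity with negative short-term / positive long-term.
    ALLPOS_ENACT / ALLPOS_NOENACT: accepts / declines all-positive items.
    ALLNEG_NOENACT / ALLNEG_ENACT: declines / accepts all-negative items.
    """

    LT_A = "LT_A"
    LT_B = "LT_B"
    ST_A = "ST_A"
    ST_B = "ST_B"
    ALLPOS_ENACT = "ALLPOS_ENACT"
    ALLNEG_NOENACT = "ALLNEG_NOENACT"
    ALLPOS_NOENACT = "ALLPOS_NOENACT"
    ALLNEG_ENACT = "ALLNEG_ENACT"
    MISSED = "MISSED"


LONG_SET = (TrialClass.LT_A, TrialClass.LT_B)
SHORT_SET = (TrialClass.ST_A, TrialClass.ST_B)


@dataclass(frozen=True)
class ItemRating:
    item_id: str
    short_term: int
    long_term: int

    def __post_init__(self) -> None:
        for name, v in (("short_term", self.short_term), ("long_term", self.long_term)):
            if v not in VALID_RATINGS:
                raise ValueError(
                    f"{name}={v} outside the six-point domain {VALID_RATINGS} "
                    f"for item {self.item_id!r}")


@dataclass(frozen=True)
class TrialResponse:
    trial_index: int
    item_id: str
    onset_s: float
    decision: int | None  # None encodes a missed response

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be nonnegative")
        if self.decision is not None and self.decision not in VALID_DECISIONS:
            raise ValueError(
                f"decision={self.decision} outside {VALID_DECISIONS} "
                f"for trial {self.trial_index}")


def classify_item(r: ItemRating) -> ItemKind:
    """Divergent iff the short- and long-term ratings have opposite signs."""
    if np.sign(r.short_term) != np.sign(r.long_term):
        return ItemKind.DIVERGENT
    return ItemKind.CONGRUENT_POS if r.short_term > 0 else ItemKind.CONGRUENT_NEG


def classify_trial(t: TrialResponse, r: ItemRating) -> TrialClass:
    """Map one trial onto its regressor category.

    Classification is per-trial: repetitions of an item may land in
    different categories when the decisions differ.
    """
    if t.decision is None:
        return TrialClass.MISSED
    accept = t.decision > 0
    s_pos, l_pos = r.short_term > 0, r.long_term > 0
    if s_pos and not l_pos:
        return TrialClass.ST_A if accept else TrialClass.LT_A
    if not s_pos and l_pos:
        return TrialClass.LT_B if accept else TrialClass.ST_B
    if s_pos and l_pos:
        return TrialClass.ALLPOS_ENACT if accept else TrialClass.ALLPOS_NOENACT
    return TrialClass.ALLNEG_ENACT if accept else TrialClass.ALLNEG_NOENACT


def collapse_label(c: TrialClass) -> str:
    """Collapse the eight categories to LONG / SHORT / OTHER / MISSED."""
    if c in LONG_SET:
        return "LONG"
    if c in SHORT_SET:
        return "SHORT"
    if c is TrialClass.MISSED:
        return "MISSED"
    return "OTHER"


def _longest_run(missed: np.ndarray) -> int:
    best = run = 0
    for m in missed:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def apply_task_exclusions(
    classes: list[TrialClass],
    max_missed_frac: float = 0.15,
    max_consecutive_missed: int = 9,
) -> tuple[bool, list[str]]:
    """Decide whether a subject's task data enter the analysis.

    A subject is excluded for (a) more than ``max_missed_frac`` of trials
    missed (strictly greater: 18 of 120 is retained, 19 excluded), (b) a
    run of more than ``max_consecutive_missed`` misses, or (c) floor /
    ceiling effects, operationalised as an empty collapsed LONG or SHORT
    set (the contrast would be undefined).

    Returns ``(included, reasons)``; reasons is empty iff included.
    """
    n = len(classes)
    if n == 0:
        return False, ["no_trials"]
    missed = np.array([c is TrialClass.MISSED for c in classes])
    reasons: list[str] = []
    if missed.sum() > max_missed_frac * n:
        reasons.append("missed_over_15pct")
    if _longest_run(missed) > max_consecutive_missed:
        reasons.append("missed_consecutive")
    labels = [collapse_label(c) for c in classes]
    if "LONG" not in labels:
        reasons.append("ceiling_no_long_trials")
    if "SHORT" not in labels:
        reasons.append("floor_no_short_trials")
    return (not reasons), reasons


def classify_subject(
    trials: list[TrialResponse], ratings: dict[str, ItemRating]
) -> list[TrialClass]:
    """Classify every trial of one subject against their item ratings."""
    return [classify_trial(t, ratings[t.item_id]) for t in trials]


def behavioral_descriptives(
    cohort: dict[str, list[TrialClass]],
    divergent_counts: dict[str, int] | None = None,
    p_scf: dict[str, float] | None = None,
    trait: dict[str, float] | None = None,
) -> dict:
    """Per-subject and mean counts of divergent / LONG / SHORT / missed trials.

    ``divergent_counts`` gives, per subject, the number of trials whose item
    is divergent (including missed ones); when absent it is approximated by
    the number of answered divergent-item trials (LONG + SHORT). When
    outcome (``p_scf``) or trait scores are supplied, adds Pearson
    correlations of the per-subject SHORT count with them; correlations on
    zero-variance inputs are reported as NaN and flagged.
    """
    rows = []
    for sid, classes in cohort.items():
        labels = [collapse_label(c) for c in classes]
        n_long = labels.count("LONG")
        n_short = labels.count("SHORT")
        if divergent_counts is not None:
            n_div = int(divergent_counts[sid])
        else:
            n_div = n_long + n_short
        rows.append({
            "subject_id": sid, "n_trials": len(classes),
            "n_divergent": n_div, "n_long": n_long, "n_short": n_short,
            "n_missed": labels.count("MISSED"),
        })
    table = pd.DataFrame(rows).set_index("subject_id")
    out: dict = {
        "per_subject": table,
        "mean": table.mean().to_dict(),
        "pct_divergent": 100.0 * table["n_divergent"].sum() / table["n_trials"].sum(),
    }
    for name, scores in (("p_scf", p_scf), ("trait", trait)):
        if scores is None:
            continue
        common = [s for s in table.index if s in scores and np.isfinite(scores[s])]
        x = table.loc[common, "n_short"].to_numpy(float)
        y = np.array([scores[s] for s in common], float)
        if len(common) < 3 or np.std(x) == 0 or np.std(y) == 0:
            out[f"r_short_{name}"] = float("nan")
            out[f"r_short_{name}_defined"] = False
        else:
            r, p = stats.pearsonr(x, y)
            out[f"r_short_{name}"] = float(r)
            out[f"r_short_{name}_p"] = float(p)
            out[f"r_short_{name}_defined"] = True
    return out
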