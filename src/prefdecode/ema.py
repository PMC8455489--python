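"""Ecological momentary assessment of real-life self-control.

Subjects carry a smartphone for a week and receive up to 56 random alarms
(8/day x 7 days). Each answered alarm asks whether a desire occurred in the
past hour; if so, its strength (1-6) and type (19 categories) and whether
it conflicted with a superordinate goal; if so, the conflict strength,
whether the desire was resisted, and whether it was enacted. A
*self-control failure* is an enacted conflict-laden desire, and each
subject's outcome is

    p_scf = n_failures / n_conflicts,

the relative amount of self-control failures in conflict situations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EmaRecord", "EmaSummary", "summarize_ema", "apply_ema_exclusions",
    "read_ema_tsv", "write_ema_tsv", "response_rate", "conflict_rate",
    "failure_rate",
]

EMA_COLUMNS = [
    "subject_id", "alarm_index", "answered", "desire", "desire_strength",
    "desire_type", "conflict", "conflict_strength", "resisted", "enacted",
]


@dataclass(frozen=True)
class EmaRecord:
    """One alarm's responses; conditional fields are ``None`` when not asked."""

    subject_id: str
    alarm_index: int
    answered: bool
    desire: bool | None = None
    desire_strength: int | None = None
    desire_type: int | None = None
    conflict: bool | None = None
    conflict_strength: int | None = None
    resisted: bool | None = None
    enacted: bool | None = None

    def validate(self, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if not self.answered:
            if self.desire is not None:
                raise ValueError(f"unanswered alarm with desire fields{where}")
            return
        if self.desire is None:
            raise ValueError(f"answered alarm without desire flag{where}")
        if not self.desire and self.conflict is not None:
            raise ValueError(f"conflict fields without desire{where}")
        if self.desire and self.conflict is None:
            raise ValueError(f"desire without conflict flag{where}")
        if self.conflict and (self.enacted is None or self.resisted is None):
            raise ValueError(f"conflict without enactment/resistance flags{where}")
        if not self.conflict and self.enacted is not None:
            raise ValueError(f"enactment field without conflict{where}")
        for name in ("desire_strength", "conflict_strength"):
            v = getattr(self, name)
            if v is not None and not 1 <= int(v) <= 6:
                raise ValueError(f"{name}={v} outside 1-6{where}")
        if self.desire_type is not None and not 1 <= int(self.desire_type) <= 19:
            raise ValueError(f"desire_type={self.desire_type} outside 1-19{where}")


@dataclass
class EmaSummary:
    """Per-subject EMA counts and the failure probability ``p_scf``."""

    subject_id: str
    n_answered: int
    n_desires: int
    n_conflicts: int
    n_failures: int
    p_scf: float = field(init=False)
    p_scf_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (self.n_failures <= self.n_conflicts <= self.n_desires
                <= self.n_answered):
            raise ValueError(
                f"count ordering violated for {self.subject_id}: "
                f"{self.n_failures} <= {self.n_conflicts} <= "
                f"{self.n_desires} <= {self.n_answered} expected")
        self.p_scf_defined = self.n_conflicts > 0
        self.p_scf = (self.n_failures / self.n_conflicts
                      if self.p_scf_defined else float("nan"))


def summarize_ema(records: list[EmaRecord]) -> EmaSummary:
    """Collapse one subject's alarm records to counts and ``p_scf``."""
    if not records:
        raise ValueError("no EMA records supplied")
    sids = {r.subject_id for r in records}
    if len(sids) != 1:
        raise ValueError(f"records mix subjects: {sorted(sids)}")
    for i, r in enumerate(records):
        r.validate(row=i)
    answered = [r for r in records if r.answered]
    desires = [r for r in answered if r.desire]
    conflicts = [r for r in desires if r.conflict]
    failures = [r for r in conflicts if r.enacted]
    return EmaSummary(
        subject_id=records[0].subject_id,
        n_answered=len(answered), n_desires=len(desires),
        n_conflicts=len(conflicts), n_failures=len(failures),
    )


def apply_ema_exclusions(
    summaries: list[EmaSummary],
    min_answered: int = 1,
) -> tuple[list[str], list[dict]]:
    """Exclude subjects with zero conflicts or incomplete EMA acquisition.

    "Incomplete" is operationalised as fewer than ``min_answered`` answered
    alarms (default 1). Returns ``(included_subject_ids, exclusion_log)``.
    """
    included, log = [], []
    for s in summaries:
        if s.n_answered < min_answered:
            log.append({"subject_id": s.subject_id, "reason": "incomplete_ema"})
        elif not s.p_scf_defined:
            log.append({"subject_id": s.subject_id, "reason": "zero_conflicts"})
        else:
            included.append(s.subject_id)
    return included, log


# descriptive rates used in group-level reporting; inputs may be means
def response_rate(n_answered: float, n_alarms: float) -> float:
    """Fraction of issued alarms answered."""
    return n_answered / n_alarms


def conflict_rate(n_conflicts: float, n_desires: float) -> float:
    """Fraction of desires that were conflict-laden."""
    return n_conflicts / n_desires


def failure_rate(n_failures: float, n_conflicts: float) -> float:
    """Fraction of conflict-laden desires that were enacted (p_scf)."""
    return n_failures / n_conflicts


def _to_cell(v) -> str:
    if v is None:
        return "n/a"
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    return str(int(v)) if isinstance(v, (int, np.integer)) else str(v)


def write_ema_tsv(records: list[EmaRecord], path: str | Path) -> None:
    """Write one-row-per-alarm TSV with missing values encoded as ``n/a``."""
    rows = [{c: _to_cell(getattr(r, c)) for c in EMA_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=EMA_COLUMNS).to_csv(path, sep="\t", index=False)


def _from_cell(v, as_bool: bool):
    if pd.isna(v):
        return None
    return bool(int(v)) if as_bool else int(v)


def read_ema_tsv(path: str | Path) -> list[EmaRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False,
                     dtype={"subject_id": str})
    bools = {"answered", "desire", "conflict", "resisted", "enacted"}
    records = []
    for _, row in df.iterrows():
        kw = {"subject_id": str(row["subject_id"]),
              "alarm_index": int(row["alarm_index"])}
        for c in EMA_COLUMNS[2:]:
            kw[c] = _from_cell(row[c], as_bool=c in bools)
        kw["answered"] = bool(kw["answered"])
        records.append(EmaRecord(**kw))
    return records
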