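"""Tally of literature-survey records on categorization practice.

A record is one publication: the journal it appeared in, whether its final
model categorized a predictor that could have stayed continuous, and (when
categorized) the stated rationale for the breakpoint.  The packaged fixture
``data/mini_review_synthetic.csv`` is a synthetic set of 72 records with the
marginal totals of a published audit of six ecology/evolution/behaviour
journals (22 of 72 categorizing, categorization more frequent in the
behaviour journals); the per-journal splits are invented.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import DataError

__all__ = ["ReviewRecord", "ReviewTally", "load_records", "tally"]

RATIONALES = ("statistical", "biological", "precedent", "arbitrary", "none")

_FIXTURE = "mini_review_synthetic.csv"


@dataclass(frozen=True)
class ReviewRecord:
    journal: str
    categorized: bool
    rationale: str | None = None

    def __post_init__(self) -> None:
        if self.rationale is not None and self.rationale not in RATIONALES:
            raise DataError(
                f"rationale '{self.rationale}' not in {RATIONALES}"
            )


@dataclass(frozen=True)
class ReviewTally:
    total: int
    categorized: int
    percentage: int  # rounded to the nearest integer
    by_journal: dict[str, int]
    by_rationale: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "total": self.total,
            "categorized": self.categorized,
            "percentage": self.percentage,
            "by_journal": self.by_journal,
            "by_rationale": self.by_rationale,
        }


def _parse_flag(value) -> bool:
    s = str(value).strip().lower()
    if s in ("yes", "y", "true", "1"):
        return True
    if s in ("no", "n", "false", "0"):
        return False
    raise DataError(f"cannot interpret categorized flag '{value}'")


def load_records(path=None) -> list[ReviewRecord]:
    """Read records from a ``journal,categorized,rationale`` CSV.

    With no path, loads the packaged synthetic fixture.
    """
    if path is None:
        with resources.files("splitcost.data").joinpath(_FIXTURE).open("r") as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    missing = {"journal", "categorized"} - set(frame.columns)
    if missing:
        raise DataError(f"review CSV lacks column(s) {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        rationale = row.get("rationale")
        if pd.isna(rationale) or rationale == "":
            rationale = None
        records.append(
            ReviewRecord(str(row["journal"]), _parse_flag(row["categorized"]), rationale)
        )
    return records


def tally(records: list[ReviewRecord]) -> ReviewTally:
    """Totals, percentage categorized (rounded to integer), per-journal counts."""
    if not records:
        raise DataError("cannot tally an empty record list")
    total = len(records)
    yes = sum(r.categorized for r in records)
    by_journal: dict[str, int] = {}
    by_rationale: dict[str, int] = {}
    for r in records:
        by_journal[r.journal] = by_journal.get(r.journal, 0) + r.categorized
        if r.categorized and r.rationale is not None:
            by_rationale[r.rationale] = by_rationale.get(r.rationale, 0) + 1
    return ReviewTally(
        total=total,
        categorized=yes,
        percentage=round(100.0 * yes / total),
        by_journal=by_journal,
        by_rationale=by_rationale,
    )
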