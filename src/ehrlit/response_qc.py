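"""Crowdsource quality-control filtering applied before any model fitting.

Two screens are applied per respondent, mirroring standard crowdsourcing
practice: (1) one test question is presented twice, and giving two
different answers excludes the respondent; (2) two simple catch questions
are included, and answering one or both incorrectly excludes the
respondent.  Exclusion is person-wise — an excluded respondent contributes
no responses downstream.  Platform-level screens (approval rate, location)
are upstream inclusion criteria and only carried as optional metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

__all__ = ["QCRecord", "QCReport", "apply_qc"]


@dataclass(frozen=True)
class QCRecord:
    """Quality-control side-channel answers for one respondent."""

    person_id: str
    repeat_pair: tuple[int, int]
    catch_answers: tuple[bool, bool]
    repeat_item: str | None = None
    verdict: str | None = None  # "retained" | "excluded" (set by apply_qc)
    reason: str | None = None  # "repeat_inconsistent" | "catch_failed" | "none"

    @property
    def repeat_consistent(self) -> bool:
        return self.repeat_pair[0] == self.repeat_pair[1]

    @property
    def catches_passed(self) -> bool:
        return all(self.catch_answers)


@dataclass
class QCReport:
    """Accounting of quality-control exclusions."""

    n_total: int
    n_excluded: int
    n_repeat_inconsistent: int
    n_catch_failed: int
    records: list[QCRecord]

    @property
    def removal_percent(self) -> float:
        return 100.0 * self.n_excluded / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_total - self.n_excluded,
            "by_reason": {
                "repeat_inconsistent": self.n_repeat_inconsistent,
                "catch_failed": self.n_catch_failed,
            },
            "removal_percent": self.removal_percent,
        }


def apply_qc(matrix, qc_records: Iterable[QCRecord]):
    """Filter a response matrix by the quality-control rules.

    A respondent is excluded if the repeated question got two different
    answers or at least one catch question was answered incorrectly (the
    repeat rule is reported when both apply).  Raises ``KeyError`` naming
    the first person in the matrix without a QC record.

    Returns ``(filtered_matrix, QCReport)``.  Idempotent: re-applying the
    filter with the surviving records removes no one further.
    """
    by_person = {r.person_id: r for r in qc_records}
    missing = [p for p in matrix.person_ids if p not in by_person]
    if missing:
        raise KeyError(f"missing QC record for person {missing[0]!r}")

    judged: list[QCRecord] = []
    keep: list[str] = []
    n_repeat = n_catch = 0
    for person in matrix.person_ids:
        rec = by_person[person]
        if not rec.repeat_consistent:
            rec = replace(rec, verdict="excluded", reason="repeat_inconsistent")
            n_repeat += 1
        elif not rec.catches_passed:
            rec = replace(rec, verdict="excluded", reason="catch_failed")
            n_catch += 1
        else:
            rec = replace(rec, verdict="retained", reason="none")
            keep.append(person)
        judged.append(rec)

    filtered = matrix.subset_persons(keep)
    report = QCReport(
        n_total=len(matrix.person_ids),
        n_excluded=n_repeat + n_catch,
        n_repeat_inconsistent=n_repeat,
        n_catch_failed=n_catch,
        records=judged,
    )
    return filtered, report
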