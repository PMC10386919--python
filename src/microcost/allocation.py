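"""Effort-based allocation of shared costs to delivery arms.

Staff worked across all three booster-delivery modes and on research
activities (trial conduct, intervention adaptation) that are not part of
service delivery.  Allocation therefore proceeds in two steps:

1. research-task hours are removed entirely — research is not a fourth
   arm, it is out of scope of the programme cost;
2. each shared cost pool (one per staff role: counselor time is split on
   the relative time spent on in-person sessions and live booster calls,
   all other pools on recorded effort) is divided across arms in
   proportion to the remaining hours.

Weights are exact rationals, so splitting a pool conserves its total to
full precision.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import IO, Iterable, Mapping, Sequence, Union

from .ledger import Arm, CostItem, DELIVERY_ARMS, LedgerError
from .money import Money, MoneyLike, as_money

__all__ = [
    "StaffRole",
    "Task",
    "EffortRecord",
    "AllocationWeights",
    "AllocationError",
    "UnallocatablePoolError",
    "effort_fractions",
    "allocate_pool",
    "counselor_time_cost",
    "read_effort_log",
    "write_effort_log",
    "EFFORT_FIELDS",
]


class StaffRole(str, Enum):
    COUNSELOR = "counselor"
    COORDINATOR = "coordinator"
    DATA_MANAGER = "data_manager"
    OVERSIGHT = "oversight"


class Task(str, Enum):
    IN_PERSON_SESSION = "in_person_session"
    LIVE_BOOSTER_CALL = "live_booster_call"
    SESSION_PREP = "session_prep"
    ADMIN = "admin"
    RESEARCH = "research"


#: Arms an effort record may carry (delivery arms, pooled, or research).
EFFORT_ARMS: tuple[str, ...] = tuple(a.value for a in Arm) + ("research",)

EFFORT_FIELDS: tuple[str, ...] = ("staff_role", "task", "arm", "hours", "period_start", "period_end")


class AllocationError(ValueError):
    """Invalid allocation input."""


class UnallocatablePoolError(AllocationError):
    """A cost pool has no intervention effort to allocate by."""


@dataclass(frozen=True)
class EffortRecord:
    """Hours one staff role spent on one task for one arm over a period.

    ``arm`` may be a delivery arm, ``"shared"`` for hours not attributable
    to a single mode, or ``"research"``; research-task hours must carry
    the research arm tag.
    """

    staff_role: StaffRole
    task: Task
    arm: str
    hours: Fraction
    period_start: str = ""
    period_end: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "staff_role", StaffRole(self.staff_role))
        object.__setattr__(self, "task", Task(self.task))
        arm = str(self.arm)
        if arm not in EFFORT_ARMS:
            raise AllocationError(f"unknown effort arm {arm!r}")
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "hours", as_money(self.hours))
        if self.hours < 0:
            raise AllocationError("hours must be non-negative")
        if self.task is Task.RESEARCH and arm != "research":
            raise AllocationError("research-task hours must be tagged arm='research'")


@dataclass(frozen=True)
class AllocationWeights:
    """Fraction of a shared cost pool attributed to each delivery arm.

    Fractions are exact rationals in [0, 1] summing to 1.
    """

    fractions: Mapping[Arm, Fraction]

    def __post_init__(self) -> None:
        fractions = {Arm(arm): as_money(w) for arm, w in self.fractions.items()}
        for arm, w in fractions.items():
            if arm not in DELIVERY_ARMS:
                raise AllocationError(f"weight keyed by non-delivery arm {arm.value!r}")
            if not 0 <= w <= 1:
                raise AllocationError(f"weight for {arm.value} outside [0, 1]: {w}")
        total = sum(fractions.values(), Fraction(0))
        if abs(total - 1) > Fraction(1, 10**9):
            raise AllocationError(f"weights sum to {total}, expected 1")
        object.__setattr__(self, "fractions", dict(fractions))

    def __getitem__(self, arm: Arm) -> Fraction:
        return self.fractions.get(Arm(arm), Fraction(0))


def _intervention_hours(records: Iterable[EffortRecord], pool: StaffRole) -> dict[Arm, Fraction]:
    """Per-arm non-research hours for one staff-role pool.

    Shared-arm hours cannot be attributed to a single mode and are left
    out of the weight basis (they ride along with whichever split the
    attributable hours imply).
    """
    hours: dict[Arm, Fraction] = {arm: Fraction(0) for arm in DELIVERY_ARMS}
    for rec in records:
        if rec.staff_role is not StaffRole(pool):
            continue
        if rec.task is Task.RESEARCH or rec.arm == "research":
            continue
        if rec.arm == Arm.SHARED.value:
            continue
        hours[Arm(rec.arm)] += rec.hours
    return hours


def effort_fractions(records: Sequence[EffortRecord], pool: StaffRole) -> AllocationWeights:
    """Normalize a pool's non-research hours into allocation weights.

    Research hours are dropped before normalization; an arm with zero
    effort gets weight 0.  Raises :class:`UnallocatablePoolError` when the
    pool has no intervention hours at all (research-only or empty).
    """
    pool = StaffRole(pool)
    if not any(r.staff_role is pool for r in records):
        raise UnallocatablePoolError(f"no effort records for pool {pool.value!r}")
    hours = _intervention_hours(records, pool)
    total = sum(hours.values(), Fraction(0))
    if total == 0:
        raise UnallocatablePoolError(
            f"pool {pool.value!r} has no intervention effort (research-only or all-zero hours)"
        )
    return AllocationWeights({arm: h / total for arm, h in hours.items()})


def allocate_pool(pool_items: Sequence[CostItem], weights: AllocationWeights) -> list[CostItem]:
    """Split shared items across arms in proportion to *weights*.

    Each ``arm='shared'`` item becomes one item per positive-weight arm,
    preserving category/phase/class/level; amounts are exact, so the
    split conserves the pool total to full precision.  Items already
    carrying a specific arm pass through unchanged (allocation is
    idempotent on an allocated ledger).
    """
    if not pool_items:
        raise AllocationError("empty cost pool")
    out: list[CostItem] = []
    for item in pool_items:
        if item.arm is not Arm.SHARED:
            out.append(item)
            continue
        for arm in DELIVERY_ARMS:
            w = weights[arm]
            if w == 0:
                continue
            out.append(item.with_amount(item.amount * w, arm=arm))
    return out


def counselor_time_cost(
    records: Sequence[EffortRecord], hourly_rate: MoneyLike, arm: Arm
) -> Money:
    """Cost of counselor time attributed to *arm*.

    Sums in-person session, live booster-call, preparation and admin
    hours logged against the arm (research hours excluded) and prices
    them at the loaded hourly rate.
    """
    rate = as_money(hourly_rate)
    if rate <= 0:
        raise AllocationError("hourly rate must be positive")
    arm = Arm(arm)
    hours = sum(
        (
            rec.hours
            for rec in records
            if rec.staff_role is StaffRole.COUNSELOR
            and rec.arm == arm.value
            and rec.task is not Task.RESEARCH
        ),
        Fraction(0),
    )
    return hours * rate


# --------------------------------------------------------------------------
# Effort-log file I/O


def read_effort_log(source: Union[str, os.PathLike, IO[str]]) -> list[EffortRecord]:
    """Read an effort-log CSV (header: staff_role,task,arm,hours,period_start,period_end)."""
    if hasattr(source, "read"):
        return _read_effort_stream(source)
    with open(os.fspath(source), "r", encoding="utf-8", newline="") as fh:
        return _read_effort_stream(fh)


def _read_effort_stream(stream: IO[str]) -> list[EffortRecord]:
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        raise AllocationError("empty effort log: missing header row")
    missing = [f for f in ("staff_role", "task", "arm", "hours") if f not in reader.fieldnames]
    if missing:
        raise AllocationError(f"effort log header missing fields: {', '.join(missing)}")
    records: list[EffortRecord] = []
    errors: list[str] = []
    for row_no, row in enumerate(reader, start=1):
        try:
            records.append(
                EffortRecord(
                    staff_role=StaffRole(row["staff_role"].strip()),
                    task=Task(row["task"].strip()),
                    arm=row["arm"].strip(),
                    hours=as_money(row["hours"].strip()),
                    period_start=(row.get("period_start") or "").strip(),
                    period_end=(row.get("period_end") or "").strip(),
                )
            )
        except (ValueError, AllocationError) as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise AllocationError("effort log validation failed — " + "; ".join(errors))
    return records


def write_effort_log(records: Iterable[EffortRecord], dest: Union[str, os.PathLike, IO[str]]) -> None:
    """Write an effort-log CSV that :func:`read_effort_log` round-trips."""
    if hasattr(dest, "write"):
        _write_effort_stream(records, dest)
    else:
        with open(os.fspath(dest), "w", encoding="utf-8", newline="") as fh:
            _write_effort_stream(records, fh)


def _write_effort_stream(records: Iterable[EffortRecord], fh: IO[str]) -> None:
    from .ledger import _amount_to_text

    writer = csv.writer(fh)
    writer.writerow(EFFORT_FIELDS)
    for rec in records:
        writer.writerow(
            [
                rec.staff_role.value,
                rec.task.value,
                rec.arm,
                _amount_to_text(rec.hours),
                rec.period_start,
                rec.period_end,
            ]
        )
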