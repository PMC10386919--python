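"""Per-arm cost aggregation: totals, composition and per-participant tables.

`summarize_arm` rolls a fully-allocated ledger up into the canonical
observed-cost table for one delivery arm: cells keyed by
(phase, level, category), phase/level subtotals, the arm total, and each
cell's percentage share of the total.  `per_participant` divides the
full-precision amounts by the recipient count and rounds half-up to
cents — the order of operations that reproduces published per-participant
tables exactly.  Percentage shares are computed once, at arm level, and
carried over to the per-participant table unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .ledger import Arm, Category, CostItem, DELIVERY_ARMS, Level, ParticipantFlow, Phase
from .money import Money, format_money, round_half_up

__all__ = [
    "CellKey",
    "ArmSummary",
    "PerParticipantSummary",
    "AggregationError",
    "SharedCostsError",
    "summarize_arm",
    "per_participant",
    "recipients",
    "summary_frame",
    "summary_to_dict",
    "ROW_ORDER",
]

#: (phase, level, category)
CellKey = tuple[Phase, Level, Category]

#: Canonical display order of table rows (phase, level, category).
ROW_ORDER: tuple[CellKey, ...] = (
    (Phase.START_UP, Level.INTERVENTION, Category.HARDWARE),
    (Phase.START_UP, Level.INTERVENTION, Category.SOFTWARE),
    (Phase.START_UP, Level.INTERVENTION, Category.TRAINING),
    (Phase.START_UP, Level.INTERVENTION, Category.OFFICE_EQUIPMENT),
    (Phase.IMPLEMENTATION, Level.INTERVENTION, Category.STAFF_SALARIES),
    (Phase.IMPLEMENTATION, Level.INTERVENTION, Category.CONNECTIVITY),
    (Phase.IMPLEMENTATION, Level.INTERVENTION, Category.OFFICE_CONSUMABLES),
    (Phase.IMPLEMENTATION, Level.COUNSELOR, Category.COUNSELOR_TIME),
    (Phase.IMPLEMENTATION, Level.COUNSELOR, Category.OFFICE_EQUIPMENT),
    (Phase.IMPLEMENTATION, Level.COUNSELOR, Category.OFFICE_CONSUMABLES),
    (Phase.IMPLEMENTATION, Level.PARTICIPANT, Category.PRINTED_MATERIAL),
    (Phase.IMPLEMENTATION, Level.PARTICIPANT, Category.PHONE_CREDIT_COUNSELOR),
    (Phase.IMPLEMENTATION, Level.PARTICIPANT, Category.PHONE_CREDIT_PARTICIPANT),
    (Phase.IMPLEMENTATION, Level.PARTICIPANT, Category.SMS_CHARGES),
)


class AggregationError(ValueError):
    """Invalid aggregation input."""


class SharedCostsError(AggregationError):
    """The ledger still contains unallocated shared costs."""


@dataclass(frozen=True)
class ArmSummary:
    """Stratified cost totals for one delivery arm.

    ``cells`` maps (phase, level, category) to the full-precision amount;
    ``shares`` holds each cell's percentage of the arm total (also full
    precision — round at presentation).  Subtotals are exact sums of
    their cells, and the sum of subtotals is the total.
    """

    arm: Arm
    total: Money
    cells: Mapping[CellKey, Money]
    shares: Mapping[CellKey, Fraction]
    subtotals: Mapping[tuple[Phase, Level], Money]
    phase_totals: Mapping[Phase, Money]

    def cell(self, phase: Phase, level: Level, category: Category) -> Money:
        return self.cells.get((Phase(phase), Level(level), Category(category)), Fraction(0))

    def share(self, phase: Phase, level: Level, category: Category) -> Fraction:
        """Percentage share of the arm total (0–100, full precision)."""
        return self.shares.get((Phase(phase), Level(level), Category(category)), Fraction(0))


@dataclass(frozen=True)
class PerParticipantSummary:
    """Arm costs divided by recipient count, rounded half-up to cents.

    Shares are carried over from the arm-level summary (the composition
    of a per-head table is the composition of the arm table).
    """

    arm: Arm
    n: int
    total: Decimal
    cells: Mapping[CellKey, Decimal]
    shares: Mapping[CellKey, Fraction]
    subtotals: Mapping[tuple[Phase, Level], Decimal]
    phase_totals: Mapping[Phase, Decimal]

    def cell(self, phase: Phase, level: Level, category: Category) -> Decimal:
        return self.cells.get((Phase(phase), Level(level), Category(category)), Decimal("0.00"))


def summarize_arm(ledger: Sequence[CostItem], arm: Arm) -> ArmSummary:
    """Aggregate a fully-allocated ledger into an :class:`ArmSummary`.

    Every ledger item tagged with *arm* lands in exactly one
    (phase, level, category) cell; items for other delivery arms are
    ignored.  Raises :class:`SharedCostsError` if any ``shared`` items
    remain — allocate them first (:mod:`microcost.allocation`).
    """
    arm = Arm(arm)
    if arm not in DELIVERY_ARMS:
        raise AggregationError(f"cannot summarize non-delivery arm {arm.value!r}")
    shared_rows = [i for i, item in enumerate(ledger, start=1) if item.arm is Arm.SHARED]
    if shared_rows:
        raise SharedCostsError(
            f"ledger contains {len(shared_rows)} unallocated shared item(s) "
            f"(rows {shared_rows}); run effort-based allocation first"
        )
    cells: dict[CellKey, Money] = {}
    for item in ledger:
        if item.arm is not arm:
            continue
        key = (item.phase, item.level, item.category)
        cells[key] = cells.get(key, Fraction(0)) + item.amount
    total = sum(cells.values(), Fraction(0))
    shares = {
        key: (amount / total * 100 if total > 0 else Fraction(0)) for key, amount in cells.items()
    }
    subtotals: dict[tuple[Phase, Level], Money] = {}
    phase_totals: dict[Phase, Money] = {}
    for (phase, level, _), amount in cells.items():
        subtotals[(phase, level)] = subtotals.get((phase, level), Fraction(0)) + amount
        phase_totals[phase] = phase_totals.get(phase, Fraction(0)) + amount
    return ArmSummary(
        arm=arm, total=total, cells=cells, shares=shares, subtotals=subtotals, phase_totals=phase_totals
    )


def per_participant(summary: ArmSummary, n: int) -> PerParticipantSummary:
    """Divide every full-precision amount by *n* and round half-up to cents."""
    if not isinstance(n, int) or isinstance(n, bool):
        raise AggregationError("recipient count must be an integer")
    if n < 1:
        raise AggregationError("per-participant cost undefined for n < 1")
    return PerParticipantSummary(
        arm=summary.arm,
        n=n,
        total=round_half_up(summary.total / n),
        cells={key: round_half_up(amount / n) for key, amount in summary.cells.items()},
        shares=dict(summary.shares),
        subtotals={key: round_half_up(amount / n) for key, amount in summary.subtotals.items()},
        phase_totals={key: round_half_up(amount / n) for key, amount in summary.phase_totals.items()},
    )


def recipients(flow: ParticipantFlow, arm: Arm) -> int:
    """Recipients of *arm*: randomized to it plus wait-list uptake of it."""
    return flow.recipients(arm)


# --------------------------------------------------------------------------
# Report rendering


def _fmt_pct(share: Fraction) -> str:
    return f"{round_half_up(share, 2)}%"


def summary_frame(
    summary: ArmSummary, pp: PerParticipantSummary | None = None, *, rounded: bool = True
) -> pd.DataFrame:
    """Render a summary (optionally with its per-participant column) as a DataFrame.

    Rows follow the canonical table order with phase/level subtotal rows
    interleaved and a final total row.  With ``rounded=False`` amounts are
    emitted as floats at full precision instead of cent-rounded strings.
    """
    rows: list[dict] = []

    def money_out(value) -> object:
        if rounded:
            return format_money(value)
        return float(value)

    seen_blocks: set[tuple[Phase, Level]] = set()
    for key in ROW_ORDER:
        phase, level, category = key
        block = (phase, level)
        if block not in seen_blocks:
            seen_blocks.add(block)
            sub = summary.subtotals.get(block, Fraction(0))
            sub_share = sub / summary.total * 100 if summary.total > 0 else Fraction(0)
            row = {
                "row": f"{phase.value}:{level.value} subtotal",
                "kind": "subtotal",
                "amount": money_out(sub),
                "share": _fmt_pct(sub_share),
            }
            if pp is not None:
                row["per_participant"] = money_out(pp.subtotals.get(block, Decimal("0.00")))
            rows.append(row)
        row = {
            "row": category.value,
            "kind": "item",
            "amount": money_out(summary.cells.get(key, Fraction(0))),
            "share": _fmt_pct(summary.shares.get(key, Fraction(0))),
        }
        if pp is not None:
            row["per_participant"] = money_out(pp.cells.get(key, Decimal("0.00")))
        rows.append(row)
    total_row = {
        "row": "total",
        "kind": "total",
        "amount": money_out(summary.total),
        "share": _fmt_pct(Fraction(100) if summary.total > 0 else Fraction(0)),
    }
    if pp is not None:
        total_row["per_participant"] = money_out(pp.total)
    rows.append(total_row)
    return pd.DataFrame(rows)


def summary_to_dict(
    summary: ArmSummary, pp: PerParticipantSummary | None = None, *, rounded: bool = True
) -> dict:
    """JSON-ready nested rendering of a summary (and per-participant table)."""

    def money_out(value) -> object:
        return str(round_half_up(value)) if rounded else float(value)

    out: dict = {"arm": summary.arm.value, "total": money_out(summary.total), "cells": []}
    for key in ROW_ORDER:
        if key not in summary.cells:
            continue
        phase, level, category = key
        cell = {
            "phase": phase.value,
            "level": level.value,
            "category": category.value,
            "amount": money_out(summary.cells[key]),
            "share_pct": float(round_half_up(summary.shares[key], 2)),
        }
        if pp is not None:
            cell["per_participant"] = money_out(pp.cells[key])
        out["cells"].append(cell)
    out["subtotals"] = {
        f"{phase.value}:{level.value}": money_out(amount)
        for (phase, level), amount in summary.subtotals.items()
    }
    if pp is not None:
        out["n"] = pp.n
        out["per_participant_total"] = money_out(pp.total)
    return out


def summary_to_json(summary: ArmSummary, pp: PerParticipantSummary | None = None, **kw) -> str:
    return json.dumps(summary_to_dict(summary, pp, **kw), indent=2)
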