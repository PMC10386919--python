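"""Seeded synthetic ledgers, effort logs and participant flows.

The trial's raw cost records and staff tracking logs are not published;
this module generates random but structurally valid stand-ins with known
ground truth, so every pipeline stage (allocation, aggregation,
scenarios) can be property-tested end to end: the generator records the
per-arm totals and allocation weights its output must reproduce, and a
correct pipeline recovers them exactly.

Amounts are drawn uniformly within per-category ranges and rounded to
cents at generation time, so cent-exact conservation assertions stay
meaningful.  Determinism under a fixed seed is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

from .aggregation import CellKey, ROW_ORDER
from .allocation import AllocationWeights, EffortRecord, StaffRole, Task
from .ledger import Arm, Category, CostItem, DELIVERY_ARMS, Level, ParticipantFlow, Phase
from .money import Money

__all__ = [
    "SyntheticSpec",
    "GeneratedLedger",
    "GeneratedEffort",
    "SyntheticError",
    "generate_ledger",
    "generate_effort_log",
    "generate_participant_flow",
]


class SyntheticError(ValueError):
    """Invalid synthetic-data specification."""


#: Tasks drawn for intervention effort, per arm.
_ARM_TASKS: dict[Arm, tuple[Task, ...]] = {
    Arm.LIVE: (Task.IN_PERSON_SESSION, Task.LIVE_BOOSTER_CALL, Task.SESSION_PREP, Task.ADMIN),
    Arm.SMS: (Task.IN_PERSON_SESSION, Task.SESSION_PREP, Task.ADMIN),
    Arm.IVR: (Task.IN_PERSON_SESSION, Task.SESSION_PREP, Task.ADMIN),
}

#: Shared-cost pools are intervention-level recurring categories.
_SHARED_ELIGIBLE: tuple[CellKey, ...] = tuple(
    key for key in ROW_ORDER if key[0] is Phase.IMPLEMENTATION and key[1] is Level.INTERVENTION
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    Defaults mirror the study conditions: all three delivery arms, the
    observed recipient counts (160 live / 40 SMS / 61 IVR), a moderate
    share of costs recorded as shared, and effort logs that include
    research activity to be excluded downstream.
    """

    seed: int
    arms: tuple[Arm, ...] = DELIVERY_ARMS
    amount_range: tuple[float, float] = (10.0, 5000.0)
    shared_fraction: float = 0.3
    effort_hours_range: tuple[float, float] = (5.0, 200.0)
    research_hours_range: tuple[float, float] = (0.0, 300.0)
    n_per_arm: Mapping[Arm, int] = field(
        default_factory=lambda: {Arm.LIVE: 160, Arm.SMS: 40, Arm.IVR: 61}
    )

    def __post_init__(self) -> None:
        arms = tuple(Arm(a) for a in self.arms)
        if not arms:
            raise SyntheticError("at least one delivery arm required")
        if any(a not in DELIVERY_ARMS for a in arms):
            raise SyntheticError("arms must be delivery arms (live/sms/ivr)")
        object.__setattr__(self, "arms", arms)
        for name, (lo, hi) in (
            ("amount_range", self.amount_range),
            ("effort_hours_range", self.effort_hours_range),
            ("research_hours_range", self.research_hours_range),
        ):
            if lo < 0 or hi < lo:
                raise SyntheticError(f"{name} must be non-negative and ordered")
        if not 0 <= self.shared_fraction <= 1:
            raise SyntheticError("shared_fraction must be in [0, 1]")
        n_per_arm = {Arm(a): int(n) for a, n in self.n_per_arm.items()}
        if any(n < 1 for n in n_per_arm.values()):
            raise SyntheticError("recipient counts must be >= 1")
        object.__setattr__(self, "n_per_arm", n_per_arm)


@dataclass(frozen=True)
class GeneratedLedger:
    """A synthetic ledger plus the ground truth it must reproduce."""

    items: tuple[CostItem, ...]
    weights: AllocationWeights  # the weights shared items were booked under
    truth_totals: Mapping[Arm, Money]
    truth_cells: Mapping[Arm, Mapping[CellKey, Money]]


@dataclass(frozen=True)
class GeneratedEffort:
    """A synthetic effort log plus its post-exclusion allocation weights."""

    records: tuple[EffortRecord, ...]
    truth_weights: Mapping[StaffRole, AllocationWeights]


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[stream])


def _draw_cents(rng: np.random.Generator, lo: float, hi: float) -> Fraction:
    cents_lo, cents_hi = round(lo * 100), round(hi * 100)
    return Fraction(int(rng.integers(cents_lo, cents_hi + 1)), 100)


def generate_effort_log(spec: SyntheticSpec) -> GeneratedEffort:
    """Generate a counselor + coordinator effort log with known weights.

    Research records are included (tagged ``arm='research'``); the
    recorded ground-truth weights are the normalization of the remaining
    hours, exactly what :func:`~microcost.allocation.effort_fractions`
    must recover.
    """
    rng = _child_rng(spec.seed, 0)
    lo, hi = spec.effort_hours_range
    rlo, rhi = spec.research_hours_range
    records: list[EffortRecord] = []
    truth: dict[StaffRole, AllocationWeights] = {}
    for role in (StaffRole.COUNSELOR, StaffRole.COORDINATOR):
        arm_hours: dict[Arm, Fraction] = {}
        for arm in spec.arms:
            tasks = _ARM_TASKS[arm] if role is StaffRole.COUNSELOR else (Task.ADMIN,)
            total = Fraction(0)
            for task in tasks:
                minutes = int(rng.integers(round(lo * 60), round(hi * 60) + 1))
                hours = Fraction(minutes, 60)
                total += hours
                records.append(
                    EffortRecord(staff_role=role, task=task, arm=arm.value, hours=hours)
                )
            arm_hours[arm] = total
        research_minutes = int(rng.integers(round(rlo * 60), round(rhi * 60) + 1))
        if research_minutes:
            records.append(
                EffortRecord(
                    staff_role=role,
                    task=Task.RESEARCH,
                    arm="research",
                    hours=Fraction(research_minutes, 60),
                )
            )
        pool_total = sum(arm_hours.values(), Fraction(0))
        if pool_total > 0:  # an all-research pool has no defined weights
            truth[role] = AllocationWeights(
                {arm: arm_hours.get(arm, Fraction(0)) / pool_total for arm in DELIVERY_ARMS}
            )
    return GeneratedEffort(records=tuple(records), truth_weights=truth)


def generate_ledger(spec: SyntheticSpec) -> GeneratedLedger:
    """Generate a ledger (arm-specific + shared items) with known totals.

    Shared items are emitted for intervention-level recurring categories
    with probability ``shared_fraction``; their ground-truth contribution
    to each arm is booked under the coordinator pool's effort weights
    (the weights a correct allocation of the matching effort log yields).
    With ``shared_fraction = 0`` the ledger is fully arm-specific and
    allocation is a no-op.
    """
    rng = _child_rng(spec.seed, 1)
    try:
        weights = generate_effort_log(spec).truth_weights[StaffRole.COORDINATOR]
    except KeyError:
        raise SyntheticError(
            "spec yields no intervention effort, so shared costs cannot be booked; "
            "widen effort_hours_range or set shared_fraction = 0"
        ) from None
    lo, hi = spec.amount_range
    items: list[CostItem] = []
    truth_cells: dict[Arm, dict[CellKey, Money]] = {arm: {} for arm in spec.arms}

    def book(arm: Arm, key: CellKey, amount: Money) -> None:
        truth_cells[arm][key] = truth_cells[arm].get(key, Fraction(0)) + amount

    for key in ROW_ORDER:
        phase, level, category = key
        for arm in spec.arms:
            amount = _draw_cents(rng, lo, hi)
            items.append(
                CostItem(
                    category=category,
                    phase=phase,
                    resource_class="capital" if phase is Phase.START_UP else "recurring",
                    level=level,
                    arm=arm,
                    amount=amount,
                )
            )
            book(arm, key, amount)
        if key in _SHARED_ELIGIBLE and rng.random() < spec.shared_fraction:
            amount = _draw_cents(rng, lo, hi)
            items.append(
                CostItem(
                    category=category,
                    phase=phase,
                    resource_class="recurring",
                    level=level,
                    arm=Arm.SHARED,
                    amount=amount,
                )
            )
            for arm in spec.arms:
                w = weights[arm]
                if w > 0:
                    book(arm, key, amount * w)

    truth_totals = {
        arm: sum(cells.values(), Fraction(0)) for arm, cells in truth_cells.items()
    }
    return GeneratedLedger(
        items=tuple(items), weights=weights, truth_totals=truth_totals, truth_cells=truth_cells
    )


def generate_participant_flow(spec: SyntheticSpec) -> ParticipantFlow:
    """A participant flow whose recipients match ``spec.n_per_arm``.

    Recipients are split between randomized and wait-list uptake at a
    seeded random point, preserving the additive recipients invariant.
    """
    rng = _child_rng(spec.seed, 0)
    randomized: dict[Arm, int] = {}
    waitlist: dict[Arm, int] = {}
    for arm in spec.arms:
        n = spec.n_per_arm.get(arm, 0)
        r = int(rng.integers(0, n + 1))
        randomized[arm] = r
        waitlist[arm] = n - r
    return ParticipantFlow(randomized=randomized, waitlist_uptake=waitlist)
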