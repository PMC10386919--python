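"""Effort-based allocation: weights, pool splitting, counselor time cost."""

from __future__ import annotations

import io
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microcost import (
    AllocationError,
    AllocationWeights,
    Arm,
    CostItem,
    EffortRecord,
    StaffRole,
    Task,
    UnallocatablePoolError,
    allocate_pool,
    counselor_time_cost,
    effort_fractions,
    read_effort_log,
    write_effort_log,
)


def rec(role="counselor", task="admin", arm="live", hours=1):
    return EffortRecord(staff_role=role, task=task, arm=arm, hours=Fraction(hours))


class TestEffortRecord:
    def test_research_task_requires_research_arm(self):
        with pytest.raises(AllocationError, match="research"):
            EffortRecord(staff_role="counselor", task="research", arm="live", hours=1)

    def test_negative_hours_rejected(self):
        with pytest.raises(AllocationError):
            rec(hours=-1)


class TestEffortFractions:
    def test_research_dropped_then_normalized(self):
        """Hours 30/5/8.3 with 100 research hours -> weights 30/43.3, 5/43.3, 8.3/43.3."""
        records = [
            rec(arm="live", hours=30),
            rec(arm="sms", hours=5),
            EffortRecord(staff_role="counselor", task="admin", arm="ivr", hours=Fraction(83, 10)),
            EffortRecord(staff_role="counselor", task="research", arm="research", hours=100),
        ]
        w = effort_fractions(records, StaffRole.COUNSELOR)
        total = Fraction(30) + 5 + Fraction(83, 10)
        assert w[Arm.LIVE] == Fraction(30) / total
        assert w[Arm.SMS] == Fraction(5) / total
        assert w[Arm.IVR] == Fraction(83, 10) / total
        assert sum(w.fractions.values()) == 1

    def test_single_arm_gets_weight_one(self):
        w = effort_fractions([rec(arm="live", hours=10)], StaffRole.COUNSELOR)
        assert w[Arm.LIVE] == 1
        assert w[Arm.SMS] == 0

    def test_equal_effort_is_symmetric(self):
        records = [rec(arm=a, hours=7) for a in ("live", "sms", "ivr")]
        w = effort_fractions(records, StaffRole.COUNSELOR)
        assert all(w[a] == Fraction(1, 3) for a in (Arm.LIVE, Arm.SMS, Arm.IVR))

    def test_research_only_pool_is_unallocatable(self):
        records = [EffortRecord(staff_role="counselor", task="research", arm="research", hours=10)]
        with pytest.raises(UnallocatablePoolError):
            effort_fractions(records, StaffRole.COUNSELOR)

    def test_all_zero_hours_is_unallocatable(self):
        with pytest.raises(UnallocatablePoolError):
            effort_fractions([rec(hours=0)], StaffRole.COUNSELOR)

    def test_pool_without_records_is_an_error(self):
        with pytest.raises(UnallocatablePoolError):
            effort_fractions([rec()], StaffRole.OVERSIGHT)

    @given(
        hours=st.lists(st.integers(min_value=0, max_value=10**6), min_size=3, max_size=3),
        factor=st.integers(min_value=1, max_value=1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, hours, factor):
        """Multiplying all hours by a constant leaves the weights unchanged."""
        if sum(hours) == 0:
            hours[0] = 1
        base = [rec(arm=a, hours=h) for a, h in zip(("live", "sms", "ivr"), hours)]
        scaled = [rec(arm=a, hours=h * factor) for a, h in zip(("live", "sms", "ivr"), hours)]
        assert (
            effort_fractions(base, StaffRole.COUNSELOR).fractions
            == effort_fractions(scaled, StaffRole.COUNSELOR).fractions
        )


def shared_item(amount, category="staff_salaries"):
    return CostItem(category, "implementation", "recurring", "intervention", "shared", amount)


class TestAllocatePool:
    def test_exact_split(self):
        w = AllocationWeights({Arm.LIVE: Fraction(1, 2), Arm.SMS: Fraction(1, 4), Arm.IVR: Fraction(1, 4)})
        out = allocate_pool([shared_item(100)], w)
        assert sorted((i.arm.value, i.amount) for i in out) == [
            ("ivr", 25),
            ("live", 50),
            ("sms", 25),
        ]

    def test_identity_weights_single_item(self):
        w = AllocationWeights({Arm.LIVE: 1})
        (out,) = allocate_pool([shared_item(100)], w)
        assert out.arm is Arm.LIVE and out.amount == 100

    def test_conservation_on_multi_item_pool(self):
        w = AllocationWeights({Arm.SMS: Fraction(2, 5), Arm.IVR: Fraction(3, 5)})
        out = allocate_pool([shared_item(10), shared_item(20)], w)
        assert len(out) == 4
        assert sum(i.amount for i in out) == 30

    def test_arm_specific_items_pass_through(self):
        """Allocating an already-allocated ledger is a no-op."""
        item = CostItem("connectivity", "implementation", "recurring", "intervention", "live", 42)
        w = AllocationWeights({Arm.LIVE: 1})
        assert allocate_pool([item], w) == [item]

    def test_empty_pool_rejected(self):
        with pytest.raises(AllocationError):
            allocate_pool([], AllocationWeights({Arm.LIVE: 1}))

    def test_strata_preserved(self):
        w = AllocationWeights({Arm.LIVE: Fraction(1, 3), Arm.SMS: Fraction(2, 3)})
        src = shared_item(99, category="connectivity")
        for out in allocate_pool([src], w):
            assert (out.category, out.phase, out.resource_class, out.level) == (
                src.category,
                src.phase,
                src.resource_class,
                src.level,
            )

    @given(
        amounts=st.lists(st.integers(min_value=0, max_value=10**8), min_size=1, max_size=10),
        hours=st.lists(st.integers(min_value=0, max_value=1000), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, amounts, hours):
        """Split amounts sum exactly to the pool total for any effort weights."""
        if sum(hours) == 0:
            hours[2] = 5
        records = [rec(arm=a, hours=h) for a, h in zip(("live", "sms", "ivr"), hours)]
        w = effort_fractions(records, StaffRole.COUNSELOR)
        pool = [shared_item(Fraction(a, 100)) for a in amounts]
        out = allocate_pool(pool, w)
        assert sum(i.amount for i in out) == sum(i.amount for i in pool)


class TestWeights:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(AllocationError, match="sum"):
            AllocationWeights({Arm.LIVE: Fraction(1, 2)})

    def test_weights_outside_unit_interval_rejected(self):
        with pytest.raises(AllocationError):
            AllocationWeights({Arm.LIVE: Fraction(3, 2), Arm.SMS: Fraction(-1, 2)})


class TestCounselorTimeCost:
    def test_hours_times_rate(self):
        assert counselor_time_cost([rec(task="live_booster_call", hours=10)], Fraction(25, 2), Arm.LIVE) == 125

    def test_zero_hours_is_zero(self):
        assert counselor_time_cost([], 20, Arm.LIVE) == 0

    def test_research_hours_excluded(self):
        records = [
            rec(task="live_booster_call", hours=4),
            EffortRecord(staff_role="counselor", task="research", arm="research", hours=1),
        ]
        assert counselor_time_cost(records, 20, Arm.LIVE) == 80

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(AllocationError):
            counselor_time_cost([rec()], 0, Arm.LIVE)


def test_effort_log_roundtrip():
    records = [
        rec(arm="live", hours=Fraction(5, 3)),
        EffortRecord(staff_role="oversight", task="research", arm="research", hours=Fraction(7, 2)),
    ]
    buf = io.StringIO()
    write_effort_log(records, buf)
    buf.seek(0)
    assert read_effort_log(buf) == records
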