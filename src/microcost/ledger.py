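"""Cost-ledger data model, validation, currency handling and I/O.

A ledger is a flat list of :class:`CostItem` lines, each stratified along
four axes that drive everything downstream:

``phase``
    whether the resource was consumed before (``start_up``) or during
    (``implementation``) programme operation;
``resource_class``
    capital (fixed, one-time) vs recurring (variable) — all start-up
    costs are capital by construction;
``level``
    whether the cost is driven by the programme as a whole
    (``intervention``), by the number of counselors (``counselor``), or
    by the number of enrolled participants (``participant``);
``arm``
    which booster-delivery mode the cost belongs to (``live`` counselor
    calls, ``sms``, ``ivr``), or ``shared`` for pooled costs awaiting
    effort-based allocation.

The module also ships the observed cost ledgers of a brief
alcohol-reduction intervention trial for persons with HIV in southwestern
Uganda (one in-person counselling programme, three booster-delivery
modes), as packaged per-arm CSV fixtures, together with the trial's
participant flow.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence, Union

from .money import Money, MoneyLike, as_money, parse_money

__all__ = [
    "Category",
    "Phase",
    "ResourceClass",
    "Level",
    "Arm",
    "Currency",
    "DELIVERY_ARMS",
    "CostItem",
    "ParticipantFlow",
    "ExchangeRate",
    "LedgerError",
    "LedgerValidationError",
    "convert_to_usd",
    "read_ledger",
    "write_ledger",
    "load_observed_fixture",
    "observed_participant_flow",
    "LEDGER_FIELDS",
]


class Category(str, Enum):
    """Controlled vocabulary of resource categories."""

    HARDWARE = "hardware"
    SOFTWARE = "software"
    TRAINING = "training"
    OFFICE_EQUIPMENT = "office_equipment"
    STAFF_SALARIES = "staff_salaries"
    CONNECTIVITY = "connectivity"
    OFFICE_CONSUMABLES = "office_consumables"
    COUNSELOR_TIME = "counselor_time"
    PRINTED_MATERIAL = "printed_material"
    PHONE_CREDIT_COUNSELOR = "phone_credit_counselor"
    PHONE_CREDIT_PARTICIPANT = "phone_credit_participant"
    SMS_CHARGES = "sms_charges"


class Phase(str, Enum):
    START_UP = "start_up"
    IMPLEMENTATION = "implementation"


class ResourceClass(str, Enum):
    CAPITAL = "capital"
    RECURRING = "recurring"


class Level(str, Enum):
    INTERVENTION = "intervention"
    COUNSELOR = "counselor"
    PARTICIPANT = "participant"


class Arm(str, Enum):
    LIVE = "live"
    SMS = "sms"
    IVR = "ivr"
    SHARED = "shared"


class Currency(str, Enum):
    USD = "USD"
    UGX = "UGX"


#: The three booster-delivery arms (excludes the ``shared`` pre-allocation tag).
DELIVERY_ARMS: tuple[Arm, ...] = (Arm.LIVE, Arm.SMS, Arm.IVR)

#: Header of the ledger CSV dialect, in column order.
LEDGER_FIELDS: tuple[str, ...] = (
    "category",
    "phase",
    "resource_class",
    "level",
    "arm",
    "amount",
    "currency",
    "note",
)


class LedgerError(ValueError):
    """Invalid ledger content."""


class LedgerValidationError(LedgerError):
    """One or more ledger rows failed validation.

    ``errors`` is a list of ``(row, message)`` pairs; ``row`` is the
    1-based data-row number (header excluded).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        detail = "; ".join(f"row {row}: {msg}" for row, msg in self.errors)
        super().__init__(f"ledger validation failed — {detail}")


@dataclass(frozen=True)
class CostItem:
    """One ledger line: a single resource expenditure.

    Invariants enforced at construction: the amount is non-negative, and
    start-up costs are capital (fixed) — consistent with how start-up
    blocks are reported in ingredient-based costing.
    """

    category: Category
    phase: Phase
    resource_class: ResourceClass
    level: Level
    arm: Arm
    amount: Money
    currency: Currency = Currency.USD
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "resource_class", ResourceClass(self.resource_class))
        object.__setattr__(self, "level", Level(self.level))
        object.__setattr__(self, "arm", Arm(self.arm))
        object.__setattr__(self, "currency", Currency(self.currency))
        object.__setattr__(self, "amount", as_money(self.amount))
        if self.amount < 0:
            raise LedgerError(f"negative amount: {self.amount}")
        if self.phase is Phase.START_UP and self.resource_class is not ResourceClass.CAPITAL:
            raise LedgerError("start-up costs must be capital (fixed)")

    def with_amount(self, amount: MoneyLike, *, arm: Arm | None = None, note: str | None = None) -> "CostItem":
        """Copy with a new amount (and optionally arm/note); used by allocation."""
        return replace(
            self,
            amount=as_money(amount),
            arm=self.arm if arm is None else arm,
            note=self.note if note is None else note,
        )


@dataclass(frozen=True)
class ParticipantFlow:
    """Participant counts feeding per-participant denominators.

    ``randomized`` holds, per delivery arm, the participants randomized to
    receive that booster mode (the technology arm split by the mode each
    participant chose); ``waitlist_uptake`` the wait-list controls who later
    took the intervention up in that mode.  Recipients of an arm are the sum
    of the two: randomized plus wait-list uptake.
    """

    randomized: Mapping[Arm, int]
    waitlist_uptake: Mapping[Arm, int]
    declined: int = 0
    lost: int = 0

    def __post_init__(self) -> None:
        for name, mapping in (("randomized", self.randomized), ("waitlist_uptake", self.waitlist_uptake)):
            for arm, count in mapping.items():
                if Arm(arm) not in DELIVERY_ARMS:
                    raise LedgerError(f"{name} keyed by non-delivery arm {arm!r}")
                if not isinstance(count, int) or count < 0:
                    raise LedgerError(f"{name}[{arm}] must be a non-negative integer")
        if self.declined < 0 or self.lost < 0:
            raise LedgerError("declined/lost counts must be non-negative")

    def recipients(self, arm: Arm) -> int:
        """Number of participants who received the intervention in *arm*."""
        arm = Arm(arm)
        if arm not in DELIVERY_ARMS:
            raise LedgerError(f"recipients undefined for arm {arm.value!r}")
        return self.randomized.get(arm, 0) + self.waitlist_uptake.get(arm, 0)


@dataclass(frozen=True)
class ExchangeRate:
    """UGX per USD conversion rate.

    The default is the study's standard rate of 3,690 Ugandan shillings
    per US dollar (September 2019).
    """

    ugx_per_usd: Money = Fraction(3690)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ugx_per_usd", as_money(self.ugx_per_usd))
        if self.ugx_per_usd <= 0:
            raise LedgerError("exchange rate must be positive")


def convert_to_usd(amount: MoneyLike, currency: Currency, rate: ExchangeRate | None = None) -> Money:
    """Convert *amount* to USD at *rate*, keeping full precision.

    USD amounts are returned unchanged; UGX amounts are divided by the
    UGX-per-USD rate.  No rounding happens here.
    """
    rate = rate if rate is not None else ExchangeRate()
    amount = as_money(amount)
    currency = Currency(currency)
    if currency is Currency.USD:
        return amount
    return amount / rate.ugx_per_usd


# --------------------------------------------------------------------------
# Ledger file I/O (CSV dialect; see LEDGER_FIELDS for the header)


def _open_source(source: Union[str, os.PathLike, IO[str]]):
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8", newline=""), True


def read_ledger(source: Union[str, os.PathLike, IO[str]]) -> list[CostItem]:
    """Read and validate a ledger CSV.

    Every row is either returned as a validated :class:`CostItem` (order
    preserved) or reported in a single :class:`LedgerValidationError`
    naming the offending 1-based data-row numbers and values.  Amounts may
    contain thousands separators, a ``$`` sign, or the ``p/q`` exact form.
    """
    stream, close = _open_source(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise LedgerError("empty ledger source: missing header row")
        missing = [f for f in LEDGER_FIELDS if f not in reader.fieldnames and f != "note"]
        if missing:
            raise LedgerError(f"ledger header missing fields: {', '.join(missing)}")
        items: list[CostItem] = []
        errors: list[tuple[int, str]] = []
        for row_no, row in enumerate(reader, start=1):
            try:
                items.append(
                    CostItem(
                        category=_parse_enum(Category, row["category"], "category"),
                        phase=_parse_enum(Phase, row["phase"], "phase"),
                        resource_class=_parse_enum(ResourceClass, row["resource_class"], "resource_class"),
                        level=_parse_enum(Level, row["level"], "level"),
                        arm=_parse_enum(Arm, row["arm"], "arm"),
                        amount=parse_money(row["amount"]),
                        currency=_parse_enum(Currency, row["currency"], "currency"),
                        note=(row.get("note") or "").strip(),
                    )
                )
            except (LedgerError, ValueError) as exc:
                errors.append((row_no, str(exc)))
        if errors:
            raise LedgerValidationError(errors)
        return items
    finally:
        if close:
            stream.close()


def _parse_enum(enum_cls, raw: str, field_name: str):
    value = (raw or "").strip()
    try:
        return enum_cls(value)
    except ValueError:
        raise LedgerError(f"unknown {field_name} value {value!r}") from None


def _amount_to_text(amount: Money) -> str:
    """Full-precision textual amount: exact decimal when terminating, else p/q."""
    d = amount.denominator
    while d % 2 == 0:
        d //= 2
    while d % 5 == 0:
        d //= 5
    if d == 1:  # terminating decimal
        from decimal import Decimal

        return str(Decimal(amount.numerator) / Decimal(amount.denominator))
    return f"{amount.numerator}/{amount.denominator}"


def write_ledger(items: Iterable[CostItem], dest: Union[str, os.PathLike, IO[str]]) -> None:
    """Write a ledger CSV that :func:`read_ledger` round-trips exactly."""
    if hasattr(dest, "write"):
        _write_ledger_stream(items, dest)
    else:
        with open(os.fspath(dest), "w", encoding="utf-8", newline="") as fh:
            _write_ledger_stream(items, fh)


def _write_ledger_stream(items: Iterable[CostItem], fh: IO[str]) -> None:
    writer = csv.writer(fh)
    writer.writerow(LEDGER_FIELDS)
    for item in items:
        writer.writerow(
            [
                item.category.value,
                item.phase.value,
                item.resource_class.value,
                item.level.value,
                item.arm.value,
                _amount_to_text(item.amount),
                item.currency.value,
                item.note,
            ]
        )


# --------------------------------------------------------------------------
# Packaged observed data


def load_observed_fixture(arm: Arm) -> list[CostItem]:
    """Load the packaged observed (post-allocation) ledger for one arm.

    The fixtures carry one line per reported cost cell of the trial's
    observed-cost table; their sums reproduce every subtotal and the arm
    total to the cent.  Five cells differ from the source report by one
    cent to reconcile line items with their printed subtotals and totals
    (flagged in each item's ``note``).
    """
    arm = Arm(arm)
    if arm not in DELIVERY_ARMS:
        raise LedgerError(f"no observed fixture for arm {arm.value!r}")
    ref = resources.files("microcost.data").joinpath(f"observed_{arm.value}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_ledger(fh)


def observed_participant_flow() -> ParticipantFlow:
    """The trial's participant flow.

    91 participants were randomized to live-call boosters and 91 to the
    technology arm (31 chose SMS, 60 IVR); of the 90 wait-list controls
    later offered the intervention, 69 chose live calls, 9 SMS and 1 IVR,
    6 declined and 5 were lost to follow-up.  One control participant
    inadvertently randomized twice is counted once.
    """
    return ParticipantFlow(
        randomized={Arm.LIVE: 91, Arm.SMS: 31, Arm.IVR: 60},
        waitlist_uptake={Arm.LIVE: 69, Arm.SMS: 9, Arm.IVR: 1},
        declined=6,
        lost=5,
    )
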