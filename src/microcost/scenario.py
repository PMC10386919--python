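"""Replication (scale-up) scenario models.

Re-prices an observed arm cost structure for an arbitrary enrolment size
under four canonical implementation models — the cross of two operators
(``ngo``: an international NGO/charity/private facility paying trial-like
salaries and bearing rent, utilities and "luxury" office items; ``moh``:
the Ministry of Health paying civil-service salaries with those items
excluded) and two staffing modes (``stand_alone``: dedicated counselors
hired in whole-FTE steps; ``integrated``: existing staff paid only for
the fraction of time used).

The cost model, per scenario with ``n`` participants:

* intervention-level recurring costs enter once, with the oversight
  salary line re-priced from the scenario salary table and any excluded
  categories removed;
* counselor costs are ``FTE × (annual salary + annual per-counselor
  overhead)``, with FTE = ``ceil(n / capacity)`` (stand-alone) or
  ``n / capacity`` (integrated);
* participant-level costs scale linearly at the observed per-head rate;
* start-up costs enter once when ``include_startup`` is set;
* optionally, connectivity (airtime/gateway charges of the automated
  arms) is scaled per participant at the observed per-head rate instead
  of entering as a fixed programme cost.

The scale-up parameters this model needs but the observed trial cannot
supply (salary scales, productive hours, counselor capacity) ship as
clearly-labelled placeholder defaults; see ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Union

import yaml

from .aggregation import ArmSummary
from .ledger import Arm, Category, Level, Phase
from .money import Money, MoneyLike, as_money

__all__ = [
    "Operator",
    "Integration",
    "CostTemplate",
    "ScenarioSpec",
    "ScenarioCost",
    "ScenarioError",
    "staffing_requirement",
    "apply_scenario",
    "scenario_grid",
    "replication_grid",
    "canonical_scenarios",
    "identity_spec",
    "derive_capacity",
    "scenario_from_config",
    "CANONICAL_SCENARIO_NAMES",
    "NGO_HOURLY_RATE",
    "MOH_HOURLY_RATE",
    "ANNUAL_PRODUCTIVE_HOURS",
]

Operator = str  # "ngo" | "moh"
Integration = str  # "stand_alone" | "integrated"

OPERATORS = ("ngo", "moh")
INTEGRATIONS = ("stand_alone", "integrated")
CANONICAL_SCENARIO_NAMES = ("ngo_standalone", "ngo_integrated", "moh_standalone", "moh_integrated")

#: Placeholder loaded hourly wage of a dedicated counselor at NGO scale (USD/h).
NGO_HOURLY_RATE = Fraction(15, 4)  # 3.75
#: Placeholder loaded hourly wage at Ministry-of-Health salary scale (USD/h).
MOH_HOURLY_RATE = Fraction(3, 2)  # 1.50
#: Productive hours per counselor FTE per year (48 weeks x ~37 h).
ANNUAL_PRODUCTIVE_HOURS = 1760
#: Placeholder MOH oversight salary as a fraction of the observed oversight cost.
MOH_OVERSIGHT_FACTOR = Fraction(1, 2)
#: Intervention-level categories excluded at MOH facilities (rent, utilities,
#: "luxury" items have no dedicated vocabulary term; recurring office
#: consumables are the closest proxy and the set is configurable).
MOH_EXCLUDED_CATEGORIES = frozenset({Category.OFFICE_CONSUMABLES})


class ScenarioError(ValueError):
    """Invalid scenario specification or application."""


@dataclass(frozen=True)
class CostTemplate:
    """An arm's observed cost structure, reduced to scenario ingredients.

    Built from an :class:`~microcost.aggregation.ArmSummary` plus the
    observed recipient count; participant-level categories are stored as
    per-head unit costs.
    """

    arm: Arm
    n_obs: int
    startup_by_category: Mapping[Category, Money]
    intervention_recurring: Mapping[Category, Money]
    counselor_time_total: Money
    counselor_overhead_total: Money
    participant_unit: Mapping[Category, Money]

    @classmethod
    def from_summary(cls, summary: ArmSummary, n_obs: int) -> "CostTemplate":
        if n_obs < 1:
            raise ScenarioError("observed recipient count must be >= 1")
        startup: dict[Category, Money] = {}
        intervention: dict[Category, Money] = {}
        counselor_time = Fraction(0)
        counselor_overhead = Fraction(0)
        participant_unit: dict[Category, Money] = {}
        for (phase, level, category), amount in summary.cells.items():
            if phase is Phase.START_UP:
                startup[category] = startup.get(category, Fraction(0)) + amount
            elif level is Level.INTERVENTION:
                intervention[category] = intervention.get(category, Fraction(0)) + amount
            elif level is Level.COUNSELOR:
                if category is Category.COUNSELOR_TIME:
                    counselor_time += amount
                else:
                    counselor_overhead += amount
            else:
                participant_unit[category] = (
                    participant_unit.get(category, Fraction(0)) + Fraction(amount, n_obs)
                )
        return cls(
            arm=summary.arm,
            n_obs=n_obs,
            startup_by_category=startup,
            intervention_recurring=intervention,
            counselor_time_total=counselor_time,
            counselor_overhead_total=counselor_overhead,
            participant_unit=participant_unit,
        )

    @property
    def startup_total(self) -> Money:
        return sum(self.startup_by_category.values(), Fraction(0))

    @property
    def participant_unit_total(self) -> Money:
        return sum(self.participant_unit.values(), Fraction(0))

    @property
    def connectivity_unit(self) -> Money:
        """Observed intervention-level connectivity cost per recipient."""
        return Fraction(
            self.intervention_recurring.get(Category.CONNECTIVITY, Fraction(0)), self.n_obs
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One replication model: operator, staffing mode, prices and size."""

    operator: Operator
    integration: Integration
    counselor_capacity: int
    salary_table: Mapping[str, Money]  # roles: "counselor", "oversight" (annual, USD)
    n_participants: int
    counselor_overhead_per_fte: Money | None = None  # None -> template's observed overhead
    excluded_categories: frozenset[Category] = frozenset()
    include_startup: bool = False
    connectivity_per_participant: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ScenarioError(f"unknown operator {self.operator!r}")
        if self.integration not in INTEGRATIONS:
            raise ScenarioError(f"unknown integration mode {self.integration!r}")
        if self.counselor_capacity < 1:
            raise ScenarioError("counselor capacity must be >= 1")
        if self.n_participants < 0:
            raise ScenarioError("participant count must be non-negative")
        table = {role: as_money(v) for role, v in self.salary_table.items()}
        for role, value in table.items():
            if value <= 0:
                raise ScenarioError(f"salary for role {role!r} must be positive")
        object.__setattr__(self, "salary_table", table)
        if self.counselor_overhead_per_fte is not None:
            overhead = as_money(self.counselor_overhead_per_fte)
            if overhead < 0:
                raise ScenarioError("counselor overhead must be non-negative")
            object.__setattr__(self, "counselor_overhead_per_fte", overhead)
        object.__setattr__(
            self, "excluded_categories", frozenset(Category(c) for c in self.excluded_categories)
        )

    def with_n(self, n: int) -> "ScenarioSpec":
        return dataclasses.replace(self, n_participants=n)


@dataclass(frozen=True)
class ScenarioCost:
    """Priced scenario: total, components and staffing requirement.

    ``breakdown`` nests start-up categories and implementation costs by
    level and category; its leaves sum to ``total`` exactly.
    ``counselors_required`` is a whole number for stand-alone staffing
    and a fraction of an FTE for integrated staffing.
    """

    total: Money
    n: int
    counselors_required: Union[int, Fraction]
    breakdown: Mapping[str, Mapping]

    @property
    def per_participant(self) -> Money:
        if self.n == 0:
            raise ScenarioError("per-participant cost undefined for an empty programme")
        return self.total / self.n


def staffing_requirement(n: int, capacity: int, integration: Integration) -> Union[int, Fraction]:
    """Counselor FTE needed to serve *n* participants per year.

    Stand-alone programmes hire whole counselors: one more whenever
    enrolment exceeds what the current staff can serve (``ceil(n /
    capacity)``).  Integrated programmes pay existing staff for the
    proportion of time used (``n / capacity``).
    """
    if n < 0:
        raise ScenarioError("participant count must be non-negative")
    if capacity < 1:
        raise ScenarioError("counselor capacity must be >= 1")
    if integration not in INTEGRATIONS:
        raise ScenarioError(f"unknown integration mode {integration!r}")
    if integration == "stand_alone":
        return math.ceil(Fraction(n, capacity))
    return Fraction(n, capacity)


def apply_scenario(template: CostTemplate, spec: ScenarioSpec) -> ScenarioCost:
    """Price *template* under *spec* for ``spec.n_participants``."""
    n = spec.n_participants
    fte = staffing_requirement(n, spec.counselor_capacity, spec.integration)

    try:
        counselor_salary = spec.salary_table["counselor"]
        oversight_salary = spec.salary_table["oversight"]
    except KeyError as exc:
        raise ScenarioError(f"salary table missing required role {exc.args[0]!r}") from None

    overhead = (
        spec.counselor_overhead_per_fte
        if spec.counselor_overhead_per_fte is not None
        else template.counselor_overhead_total
    )

    startup: dict[str, Money] = {}
    if spec.include_startup:
        startup = {cat.value: amt for cat, amt in template.startup_by_category.items()}

    intervention: dict[str, Money] = {}
    for category, amount in template.intervention_recurring.items():
        if category in spec.excluded_categories:
            continue
        if category is Category.STAFF_SALARIES:
            intervention[category.value] = oversight_salary
        elif category is Category.CONNECTIVITY and spec.connectivity_per_participant:
            continue  # moved to the participant level below
        else:
            intervention[category.value] = amount

    counselor: dict[str, Money] = {
        "salaries": fte * counselor_salary,
        "overhead": fte * overhead,
    }

    participant: dict[str, Money] = {
        cat.value: n * unit for cat, unit in template.participant_unit.items()
    }
    if spec.connectivity_per_participant and Category.CONNECTIVITY not in spec.excluded_categories:
        participant[Category.CONNECTIVITY.value] = n * template.connectivity_unit

    breakdown = {
        "start_up": startup,
        "implementation": {
            "intervention": intervention,
            "counselor": counselor,
            "participant": participant,
        },
    }
    total = (
        sum(startup.values(), Fraction(0))
        + sum(intervention.values(), Fraction(0))
        + sum(counselor.values(), Fraction(0))
        + sum(participant.values(), Fraction(0))
    )
    return ScenarioCost(total=total, n=n, counselors_required=fte, breakdown=breakdown)


# --------------------------------------------------------------------------
# Canonical scenarios and packaged defaults


def derive_capacity(
    template: CostTemplate,
    hourly_rate: MoneyLike = NGO_HOURLY_RATE,
    annual_hours: int = ANNUAL_PRODUCTIVE_HOURS,
) -> int:
    """Participants one counselor FTE can serve per year.

    Derived from the template's own effort accounting: per-participant
    counselor hours are the observed counselor-time cost divided by the
    loaded hourly rate and the observed recipient count; capacity is the
    annual productive hours divided by that, floored.
    """
    rate = as_money(hourly_rate)
    if rate <= 0:
        raise ScenarioError("hourly rate must be positive")
    if template.counselor_time_total <= 0:
        raise ScenarioError("template has no counselor time; capacity cannot be derived")
    per_participant_hours = template.counselor_time_total / rate / template.n_obs
    capacity = math.floor(annual_hours / per_participant_hours)
    if capacity < 1:
        raise ScenarioError("derived capacity below one participant per counselor-year")
    return capacity


def canonical_scenarios(
    template: CostTemplate,
    n: int,
    *,
    ngo_hourly_rate: MoneyLike = NGO_HOURLY_RATE,
    moh_hourly_rate: MoneyLike = MOH_HOURLY_RATE,
    annual_hours: int = ANNUAL_PRODUCTIVE_HOURS,
    moh_oversight_factor: Fraction = MOH_OVERSIGHT_FACTOR,
    moh_excluded: frozenset[Category] = MOH_EXCLUDED_CATEGORIES,
    include_startup: bool = False,
    connectivity_per_participant: bool = False,
) -> dict[str, ScenarioSpec]:
    """The four canonical replication scenarios for one arm template.

    NGO scenarios price oversight at the observed cost and counselors at
    the NGO hourly rate; MOH scenarios use the MOH salary scale and drop
    the excluded categories.  Capacity is derived from the template
    (:func:`derive_capacity`) and per-FTE overhead is the observed
    counselor-level non-time cost scaled to one FTE.
    """
    ngo_rate = as_money(ngo_hourly_rate)
    moh_rate = as_money(moh_hourly_rate)
    if moh_rate > ngo_rate:
        raise ScenarioError("MOH hourly rate must not exceed the NGO rate")
    capacity = derive_capacity(template, ngo_rate, annual_hours)
    oversight_obs = template.intervention_recurring.get(Category.STAFF_SALARIES, Fraction(0))
    if oversight_obs <= 0:
        raise ScenarioError("template has no oversight salary line")
    # Observed counselor FTE implied by the NGO wage; scales overhead to one FTE.
    observed_fte = template.counselor_time_total / (ngo_rate * annual_hours)
    overhead_per_fte = template.counselor_overhead_total / observed_fte
    ngo_salaries = {"counselor": ngo_rate * annual_hours, "oversight": oversight_obs}
    moh_salaries = {
        "counselor": moh_rate * annual_hours,
        "oversight": oversight_obs * moh_oversight_factor,
    }
    common = dict(
        counselor_capacity=capacity,
        n_participants=n,
        counselor_overhead_per_fte=overhead_per_fte,
        include_startup=include_startup,
        connectivity_per_participant=connectivity_per_participant,
    )
    return {
        "ngo_standalone": ScenarioSpec(
            operator="ngo", integration="stand_alone", salary_table=ngo_salaries,
            name="ngo_standalone", **common,
        ),
        "ngo_integrated": ScenarioSpec(
            operator="ngo", integration="integrated", salary_table=ngo_salaries,
            name="ngo_integrated", **common,
        ),
        "moh_standalone": ScenarioSpec(
            operator="moh", integration="stand_alone", salary_table=moh_salaries,
            excluded_categories=moh_excluded, name="moh_standalone", **common,
        ),
        "moh_integrated": ScenarioSpec(
            operator="moh", integration="integrated", salary_table=moh_salaries,
            excluded_categories=moh_excluded, name="moh_integrated", **common,
        ),
    }


def scenario_grid(
    template: CostTemplate, n: int, specs: Mapping[str, ScenarioSpec] | None = None, **kwargs
) -> dict[str, ScenarioCost]:
    """Price all four canonical scenarios (or caller-supplied *specs*) at *n*."""
    if n < 1:
        raise ScenarioError("scenario grid requires n >= 1")
    if specs is None:
        specs = canonical_scenarios(template, n, **kwargs)
    return {name: apply_scenario(template, spec.with_n(n)) for name, spec in specs.items()}


def replication_grid(
    templates: Mapping[Arm, CostTemplate], n: int = 1000, *, include_startup: bool = False
) -> dict[Arm, dict[str, ScenarioCost]]:
    """The packaged replication comparison: all arms x all four scenarios.

    For the automated arms (SMS, IVR) connectivity is scaled per
    participant — twice-weekly automated sessions drive airtime and
    gateway charges proportional to enrolment — while the live arm's
    modest connectivity stays a fixed programme cost.
    """
    out: dict[Arm, dict[str, ScenarioCost]] = {}
    for arm, template in templates.items():
        arm = Arm(arm)
        out[arm] = scenario_grid(
            template,
            n,
            include_startup=include_startup,
            connectivity_per_participant=arm in (Arm.SMS, Arm.IVR),
        )
    return out


def identity_spec(template: CostTemplate) -> ScenarioSpec:
    """A self-consistency scenario that reproduces the observed arm cost.

    Capacity equals the observed recipient count and the counselor annual
    cost equals the observed counselor-time total, i.e. the observed
    programme is 'one counselor-equivalent serving the observed load';
    with start-up included and no exclusions, applying this spec at the
    observed n returns the observed total exactly.
    """
    return ScenarioSpec(
        operator="ngo",
        integration="stand_alone",
        counselor_capacity=template.n_obs,
        salary_table={
            "counselor": template.counselor_time_total,
            "oversight": template.intervention_recurring.get(Category.STAFF_SALARIES, Fraction(0)),
        },
        n_participants=template.n_obs,
        counselor_overhead_per_fte=template.counselor_overhead_total,
        include_startup=True,
        name="identity",
    )


# --------------------------------------------------------------------------
# Config files


def scenario_from_config(source) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a YAML/JSON mapping or file path.

    Required keys: operator, integration, counselor_capacity,
    salary_table (counselor/oversight), n_participants; optional:
    counselor_overhead_per_fte, excluded_categories, include_startup,
    connectivity_per_participant, name.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ScenarioError("scenario config must be a mapping")
    required = {"operator", "integration", "counselor_capacity", "salary_table", "n_participants"}
    missing = required - data.keys()
    if missing:
        raise ScenarioError(f"scenario config missing keys: {sorted(missing)}")
    known = required | {
        "counselor_overhead_per_fte",
        "excluded_categories",
        "include_startup",
        "connectivity_per_participant",
        "name",
    }
    unknown = data.keys() - known
    if unknown:
        raise ScenarioError(f"scenario config has unknown keys: {sorted(unknown)}")
    if "excluded_categories" in data:
        data["excluded_categories"] = frozenset(Category(c) for c in data["excluded_categories"])
    data["salary_table"] = {role: as_money(v) for role, v in data["salary_table"].items()}
    if data.get("counselor_overhead_per_fte") is not None:
        data["counselor_overhead_per_fte"] = as_money(data["counselor_overhead_per_fte"])
    return ScenarioSpec(**data)
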