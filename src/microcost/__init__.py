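"""microcost: ingredient-based micro-costing of phone-delivered brief interventions.

Observed-cost aggregation (stratified ledgers -> per-arm and
per-participant tables), effort-based shared-cost allocation, four
replication scenario models (NGO/MOH x stand-alone/integrated) and
economy-of-scale curve analysis, with a seeded synthetic-data generator
for property testing.
"""

from .money import Money, as_money, format_money, parse_money, round_half_up
from .ledger import (
    Arm,
    Category,
    CostItem,
    Currency,
    DELIVERY_ARMS,
    ExchangeRate,
    LedgerError,
    LedgerValidationError,
    Level,
    ParticipantFlow,
    Phase,
    ResourceClass,
    convert_to_usd,
    load_observed_fixture,
    observed_participant_flow,
    read_ledger,
    write_ledger,
)
from .allocation import (
    AllocationError,
    AllocationWeights,
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
from .aggregation import (
    AggregationError,
    ArmSummary,
    PerParticipantSummary,
    SharedCostsError,
    per_participant,
    recipients,
    summarize_arm,
    summary_frame,
    summary_to_dict,
)
from .scenario import (
    CostTemplate,
    ScenarioCost,
    ScenarioError,
    ScenarioSpec,
    apply_scenario,
    canonical_scenarios,
    derive_capacity,
    identity_spec,
    replication_grid,
    scenario_from_config,
    scenario_grid,
    staffing_requirement,
)
from .scale_curve import (
    ScaleCurve,
    asymptotic_cost,
    cost_curve,
    curve_frame,
    default_grid,
    find_crossover,
    plot_curves,
)
from .synthetic import (
    GeneratedEffort,
    GeneratedLedger,
    SyntheticSpec,
    generate_effort_log,
    generate_ledger,
    generate_participant_flow,
)

__version__ = "0.1.0"


def observed_template(arm: Arm) -> CostTemplate:
    """Cost template for one arm from the packaged observed fixtures."""
    arm = Arm(arm)
    summary = summarize_arm(load_observed_fixture(arm), arm)
    n = observed_participant_flow().recipients(arm)
    return CostTemplate.from_summary(summary, n)


def observed_templates() -> dict[Arm, CostTemplate]:
    """Cost templates for all three arms from the packaged fixtures."""
    return {arm: observed_template(arm) for arm in DELIVERY_ARMS}
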