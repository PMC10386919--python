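"""Economy-of-scale analysis: per-participant cost vs enrolment size.

Sweeping a replication scenario over an enrolment grid produces the
arm's per-participant cost curve.  Integrated-staffing curves decline
monotonically (fixed costs amortize over more heads); stand-alone curves
are sawtoothed, jumping by one counselor's annual loaded cost each time
enrolment crosses a hiring threshold.  Every curve is bounded below by
its large-n asymptote: the participant-level unit cost plus the
counselor annual cost per unit of capacity (plus the per-head
connectivity rate when that is scaled).

One-time start-up costs, when included, are amortized over the
participants served (divided by n), which is what makes curves of arms
with cheap start-up cross below arms with expensive start-up as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .ledger import Arm, Category
from .money import Money
from .scenario import CostTemplate, ScenarioCost, ScenarioSpec, ScenarioError, apply_scenario

__all__ = [
    "ScaleCurve",
    "cost_curve",
    "find_crossover",
    "asymptotic_cost",
    "default_grid",
    "curve_frame",
    "plot_curves",
]


def default_grid(lo: int = 40, hi: int = 3200, step: int = 40) -> tuple[int, ...]:
    """Default enrolment grid: multiples of 40 from 40 to 3200."""
    return tuple(range(lo, hi + 1, step))


@dataclass(frozen=True)
class ScaleCurve:
    """Per-participant cost at each enrolment size for one arm x scenario."""

    arm: Arm
    scenario_name: str
    grid: tuple[int, ...]
    per_participant: tuple[Money, ...]
    asymptote: Money

    def __post_init__(self) -> None:
        if not self.grid:
            raise ScenarioError("scale curve requires a non-empty grid")
        if any(n < 1 for n in self.grid):
            raise ScenarioError("grid sizes must be >= 1")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ScenarioError("grid must be strictly increasing")
        if len(self.per_participant) != len(self.grid):
            raise ScenarioError("per-participant values must match the grid")


def cost_curve(
    template: CostTemplate, spec: ScenarioSpec, grid: Sequence[int] | None = None
) -> ScaleCurve:
    """Sweep *spec* over *grid*, returning per-participant cost at each size."""
    sizes = tuple(grid) if grid is not None else default_grid()
    values = tuple(apply_scenario(template, spec.with_n(n)).per_participant for n in sizes)
    return ScaleCurve(
        arm=template.arm,
        scenario_name=spec.name or f"{spec.operator}_{spec.integration}",
        grid=sizes,
        per_participant=values,
        asymptote=asymptotic_cost(template, spec),
    )


def asymptotic_cost(template: CostTemplate, spec: ScenarioSpec) -> Money:
    """Large-n limit of the per-participant cost.

    Fixed programme costs vanish per head as n grows; what remains is the
    participant-level unit cost plus one counselor-year's loaded cost per
    unit of capacity (ceil(n/c)/n -> 1/c), plus the per-head connectivity
    rate when connectivity is scaled per participant.
    """
    overhead = (
        spec.counselor_overhead_per_fte
        if spec.counselor_overhead_per_fte is not None
        else template.counselor_overhead_total
    )
    try:
        counselor_annual = spec.salary_table["counselor"] + overhead
    except KeyError:
        raise ScenarioError("salary table missing required role 'counselor'") from None
    unit = template.participant_unit_total
    if spec.connectivity_per_participant and Category.CONNECTIVITY not in spec.excluded_categories:
        unit += template.connectivity_unit
    return unit + Fraction(counselor_annual, spec.counselor_capacity)


def find_crossover(curve_a: ScaleCurve, curve_b: ScaleCurve) -> int | None:
    """Smallest grid size where the sign of (a - b) flips from its start.

    Exact ties count as a flip and resolve to that size; identical curves
    cross at the first grid point.  Returns ``None`` when one curve stays
    strictly on the same side of the other across the whole grid.
    """
    if curve_a.grid != curve_b.grid:
        raise ScenarioError("curves must share the same grid")
    diffs = [a - b for a, b in zip(curve_a.per_participant, curve_b.per_participant)]
    if diffs[0] == 0:
        return curve_a.grid[0]
    start_sign = 1 if diffs[0] > 0 else -1
    for n, d in zip(curve_a.grid[1:], diffs[1:]):
        sign = 0 if d == 0 else (1 if d > 0 else -1)
        if sign != start_sign:
            return n
    return None


# --------------------------------------------------------------------------
# Export and plotting


def curve_frame(curves: Sequence[ScaleCurve]) -> pd.DataFrame:
    """Long-format table (n, arm, scenario, per_participant) for export."""
    rows = [
        {
            "n": n,
            "arm": curve.arm.value,
            "scenario": curve.scenario_name,
            "per_participant": float(v),
        }
        for curve in curves
        for n, v in zip(curve.grid, curve.per_participant)
    ]
    return pd.DataFrame(rows)


def plot_curves(
    curves_by_scenario: Mapping[str, Sequence[ScaleCurve]], path: str, *, dpi: int = 150
) -> None:
    """Render one panel per scenario (curves per arm) to *path* (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(curves_by_scenario)
    ncols = 2
    nrows = (len(names) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(6 * ncols, 4 * nrows), squeeze=False)
    for ax, name in zip(axes.flat, names):
        for curve in curves_by_scenario[name]:
            ax.plot(curve.grid, [float(v) for v in curve.per_participant], label=curve.arm.value)
        ax.set_title(name)
        ax.set_xlabel("participants")
        ax.set_ylabel("cost per participant (USD)")
        ax.legend()
    for ax in axes.flat[len(names):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
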