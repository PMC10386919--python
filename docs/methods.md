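# Methods

## The costing model

`microcost` implements ingredient-based micro-costing of a brief
alcohol-reduction counselling intervention for persons with HIV, delivered
with booster sessions in one of three modes: live counselor phone calls,
two-way SMS dialogues, or interactive voice response (IVR). Every cost is a
ledger line stratified along four axes:

- **phase** — start-up (consumed before implementation; software
  development, training, initial equipment) vs implementation (consumed
  during operation). All start-up costs are treated as capital (fixed), an
  invariant the data model enforces.
- **resource class** — capital vs recurring, assessed over a one-year
  horizon; participant-level costs accrue over the three-month intervention
  window per participant.
- **level** — whether the cost is driven by the programme as a whole
  (*intervention-level*: oversight salaries, connectivity, office
  infrastructure), by the number of counselors (*counselor-level*:
  counselor time, per-counselor furniture and supplies), or by the number
  of participants (*participant-level*: printed workbooks, phone credit,
  SMS charges).
- **arm** — live / sms / ivr, or `shared` for pooled costs awaiting
  allocation.

Amounts are exact rationals (`fractions.Fraction`) internally; UGX amounts
convert to USD at 3,690 UGX/USD (the study's standard September-2019 rate)
at full precision. Half-up rounding to cents happens once, at presentation.
This order of operations is load-bearing: per-participant tables are
*full-precision arm amount ÷ n, then rounded*, which is the only order that
reproduces the published cells (e.g. 23,082.92/160 → 144.27;
1,980.00/160 = 12.375 → 12.38 only under half-up ties).

## Shared-cost allocation

Staff effort logs record hours by role, task and arm. Research activity
(trial conduct, intervention adaptation) is removed entirely before
anything else — it is out of scope of the programme cost, not a fourth
arm. Each shared pool is then split across arms proportionally to the
remaining hours of its staff role: counselor costs on the relative time
spent on in-person sessions and live booster calls, other pools on
recorded effort. Weights are exact rationals in [0, 1] summing to 1, so a
split conserves the pool total exactly; an arm with zero effort gets
weight 0, and a pool whose intervention effort is all zero raises an
unallocatable-pool error. The packaged observed ledgers are
post-allocation (the study published only allocated costs; raw effort
logs were not published, so effort-log fixtures here are synthetic only).

## Observed fixtures and their one-cent reconciliation

The packaged per-arm CSVs carry one line per published cost cell. The
published table is internally inconsistent at the cent level (line items
vs subtotals vs totals disagree by $0.01 in each arm, a typical artefact
of rounding independently computed cells). Five cells were adjusted by
one cent so that items, subtotals and grand totals are mutually
consistent and all grand totals match the published values exactly; each
adjusted line is flagged in its `note` field, and none of the adjusted
cells changes any published per-participant value or percentage share.
One published per-participant cell (SMS hardware, printed with four
decimals) does not equal its own division (61.48/40 = 1.537); the fixture
follows the overall-cost table and the cell is simply not asserted.

## Replication scenarios

Four canonical models re-price an arm's observed cost structure for an
arbitrary enrolment `n`: {NGO, MOH} × {stand-alone, integrated}.

- Intervention-level recurring costs enter once. The oversight salary
  line is re-priced from the scenario's salary table; MOH scenarios drop
  an exclusion set standing in for site rental, utilities and "luxury"
  items (default: intervention-level office consumables — the closest
  available vocabulary term; configurable, since the study describes the
  set only by example).
- Counselor costs are FTE × (annual salary + annual per-counselor
  overhead), with FTE = ⌈n/capacity⌉ for stand-alone staffing (whole
  counselors hired as enrolment exceeds capacity) and n/capacity for
  integrated staffing (existing staff paid for the fraction of time
  used). Integrated ≤ stand-alone follows by construction.
- Participant-level costs scale linearly at the observed per-head unit
  rate.
- Start-up costs enter once when `include_startup` is set (default off
  for the replication grid, on for scale curves — both behaviours are
  needed, see below).

### Parameters the observation cannot supply

The study publishes no salary scales, productive-hours assumption or
counselor capacity. The defaults are explicit placeholders chosen once at
realistic values for the setting, all overridable:

| parameter | default | rationale |
|---|---|---|
| NGO counselor loaded wage | $3.75/h ($6,600/FTE-year) | trial-like NGO salary level in Uganda |
| MOH counselor loaded wage | $1.50/h ($2,640/FTE-year) | civil-service scale, well below NGO |
| productive hours / FTE-year | 1,760 | 48 weeks × ~37 h |
| MOH oversight cost | 0.5 × observed | civil-service management scale |
| counselor capacity | derived | floor(annual hours ÷ per-participant counselor hours), with per-participant hours = observed counselor-time cost ÷ wage ÷ observed n — the least arbitrary default, from the data's own effort accounting (live arm: ≈15.3 h/participant → 115 participants/counselor-year) |

Per-FTE counselor overhead defaults to the observed counselor-level
non-time cost scaled to one FTE at the NGO wage. With MOH counselor wages
the live arm's per-participant cost at n = 1000 under the integrated
model comes out near $42 — in the vicinity of the $39 reported for a very
similar brief intervention in Vietnam, a sanity check on the placeholder
scale (not an asserted result).

### Connectivity: fixed or per-participant

Observed connectivity is classed intervention-level (fixed), but the
automated arms' airtime and gateway charges are usage-driven: twice-weekly
automated sessions scale with enrolment ($91.90/participant SMS,
$82.45/participant IVR over the intervention window, vs $2.49 for the
live arm). A `connectivity_per_participant` flag (default **off**)
re-books connectivity at the observed per-head rate. The packaged
replication grid (`replication_grid`) enables it for the SMS/IVR arms —
without it, holding automated-arm connectivity fixed makes SMS *cheaper*
than live calls at n = 1000, inverting the observed cost structure the
scenarios are meant to extrapolate. The crossover analysis below uses the
default-off configuration. Both modes are first-class; the flag surfaces
a genuine classification ambiguity rather than hiding it.

An `identity_spec` helper builds the self-consistency scenario (capacity
= observed n, counselor annual cost = observed counselor-level total,
oversight at observed cost, start-up included): applying it returns the
observed arm total exactly, which the tests assert.

## Economy-of-scale curves

`cost_curve` sweeps a scenario over an enrolment grid (default: multiples
of 40 from 40 to 3200; step 40 resolves the sawtooth at plausible
capacities) and reports total ÷ n at each size. Structural results, all
property-tested:

- integrated curves are monotone non-increasing;
- stand-alone curves are sawtoothed, and the total jumps by exactly one
  loaded counselor-year at each hiring threshold;
- every curve is bounded below by its asymptote — participant-level unit
  cost + counselor annual cost ÷ capacity (+ per-head connectivity when
  scaled) — and the integrated curve at n = 10⁶ agrees with it to well
  under 0.5%;
- with start-up amortized over participants (the implemented
  amortization basis; a per-time basis would need a programme-lifetime
  assumption the data does not support), the live-call curve — cheap to
  start but counselor-intensive — is crossed by the IVR curve inside the
  grid (at n = 280 under the NGO-integrated placeholders; the crossover
  *location* depends entirely on the placeholder salaries and capacity,
  so only its existence within the grid is asserted);
- SMS stays above IVR at the top of the grid because its participant-level
  unit cost (chiefly participant phone credit) is higher.

`find_crossover` reports at grid resolution, no interpolation; exact ties
resolve to the tied size, identical curves to the first grid point.

## Synthetic data

The generator stands in for the study's unpublished raw records. It
emits ledgers over the same (phase, level, category) structure with
amounts drawn uniformly per category and rounded to cents *at
generation*, so cent-exact conservation assertions stay meaningful, plus
effort logs (counselor and coordinator pools, research records included)
whose post-exclusion normalization is recorded as ground-truth weights.
Shared ledger items are booked against the coordinator pool's weights, so
a correct pipeline — allocate, then aggregate — recovers the recorded
per-arm totals exactly; the acceptance suite runs this recovery over 100
consecutive seeds. Defaults mirror the study conditions (all three arms,
recipients 160/40/61, a moderate shared fraction). Determinism under a
fixed seed is part of the public contract.

What the generator does *not* emulate: realistic Ugandan price
distributions, correlation between categories, seasonal effort patterns,
or recording error. Passing tests therefore demonstrate pipeline
correctness (conservation, exclusion, exact arithmetic), not robustness
to messy real-world ledgers.

## Numerical choices and degenerate inputs

- Exact rational money throughout; rounding half-up (ties away from
  zero) at 2 decimals for money and percentages, applied only at
  presentation. Non-terminating amounts round-trip through CSV as `p/q`.
- Zero-effort arms get weight 0; all-zero or research-only pools raise.
- n = 0 programmes are priceable (fixed costs only) but have no defined
  per-participant cost; requesting it raises.
- Percentage shares are computed at arm level on full-precision amounts
  and carried unchanged into per-participant tables.
- Category display order is fixed for bit-reproducible report output.

## Known limitations

- Scenario and curve *levels* (as opposed to orderings and shapes) are
  driven by placeholder salary/capacity parameters and should be
  re-parameterized before any real budgeting use.
- No uncertainty quantification: the underlying study reports point
  costs without variance, and none is invented here.
- No depreciation, inflation adjustment or discounting — the one-year
  horizon does not call for them and the source analysis used none.
- Cost-effectiveness is out of scope (the trial found no significant
  efficacy differences, so only costs are modelled).
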