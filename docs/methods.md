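# Methods notes

## Model and assumptions

The engine implements deterministic per-patient activity-based costing: an
intervention's cost is the sum of phase costs (pre-hospitalization work-up,
drugs, materials, personnel, operating room, hospital stay, follow-up,
productivity loss), each phase being a sum of driver lines valued at unit
costs. The model describes *average* patients — there is no patient-level
heterogeneity, no survival modelling, and no discounting; follow-up is a
single-year expected cost (the bundled datasets assume the same follow-up
horizon for all three treatments, which likely understates long-run costs of
ablative procedures that need surveillance imaging and of surgical arms that
need lifelong replacement therapy).

Retreatment is modelled multiplicatively: with a fraction r of patients
undergoing the procedure again, every phase except follow-up is scaled by
(1 + r). Follow-up is excluded because a repeat procedure re-enters the
pathway upstream of follow-up; datasets that need a follow-up adjustment
carry it explicitly as a flat residual. The thermal-ablation dataset uses
r = 0.15; the mid-point of the 5–25% recurrence range reported for ablative
procedures, and the value that reconciles the published uplifted aggregates
with their base tables.

Productivity loss follows the human-capital approach:
patient loss = (hospitalization + convalescence days) × hours lost per day ×
hourly wage, caregiver loss = caregiver share × patient loss. The bundled
hourly wage (€14.05) is an employment-category-weighted national average and
is treated as a scalar input; the published patient terms embed a weighting
not recoverable from the scalars, so they differ from the raw product by up
to ≈€0.15 (&lt;0.05%) and are carried as `printed_patient_loss`.

## Parameters that matter

| parameter | units | bundled values | notes |
| --- | --- | --- | --- |
| `retreatment_rate` r | fraction | 0 / 0 / 0.15 | uplift factor 1 + r |
| course frequencies | fraction | 0.93 / 0.035 / 0.035 | may sum to < 1 (residual fraction has no follow-up cost) |
| `stay_rate_per_day` | EUR/day | 674.00 | identical across all three datasets (cross-checked) |
| OR rate | EUR/min | ≈20.43 | implied by or_cost / or_minutes; agrees across the surgical datasets within €0.004/min |
| `hours_lost_per_day` | h | 5 | standard 40-h week assumption |
| `hourly_wage` | EUR/h | 14.05 | weighted national average |
| `caregiver_share` | fraction | 0.05 / 0.025 / 0.10 | survey-based |

## Numerical conventions

- Money is `decimal.Decimal`; rounding is half-up to whole cents.
- **Fidelity mode** rounds each phase at its boundary and honors printed
  aggregates at the *finest available level*: per-treatment-table phase
  totals, follow-up course totals, and printed productivity patient terms.
  Summary-table values are never inputs — they are reconciliation metadata.
  This rule was chosen over the alternative (honoring summary-table rows)
  because the published summary columns are cent-inconsistent in different
  directions across treatments; anchoring at the finest level reproduces the
  hemithyroidectomy (4,211.92) and ablation (1,560.06) totals and both
  opportunity-cost totals (4,027.17 / 1,519.42) exactly, and the total
  thyroidectomy total to within €0.01 (5,185.35 vs 5,185.36) — inside the
  €0.02 per-step drift the source tables themselves exhibit. No single rule
  can close all columns simultaneously.
- **Raw mode** recomputes everything from quantities and unit costs with no
  intermediate rounding (quantization only at display). It is the mode used
  by sensitivity analysis, where printed aggregates would mask parameter
  changes, and by the scale-invariance and linearity property tests, which
  hold exactly only without boundary rounding.
- `phase_overrides` are data, not printed metadata: they win in both modes
  and keep their stated precision (possibly sub-cent). The ablation
  materials base is pinned at 575.6348 = 661.98 / 1.15 to four decimals so
  the uplift reproduces the published 661.98 exactly; its device rows cannot
  be combined without an unstated laser/RF modality weighting and are kept
  as documentation.
- Drug category costs are summed *unrounded*; rounding displayed category
  values first is what produces the off-by-a-cent totals seen in the source
  (e.g. 11.50 instead of 11.49 for total thyroidectomy).
- Degenerate inputs: empty phases cost 0; a zero-day stay costs 0; a
  category with one line under `mean_of_alternatives` costs that line;
  tornado ties are broken by parameter path.

## Reconciliation and documented errata

`reconcile()` compares every printed aggregate with its recomputed value at
a tolerance of €0.02 per aggregation step. On the bundled datasets it
flags, by design, the source's internal inconsistencies, among them: the
thyroidectomy materials-table total (prints 13.00 less than its own
column), the ablation materials-table total (irreconcilable with its rows),
the hemithyroidectomy summary personnel cell (184.65 vs the staff-table
184.75) and follow-up subtotal (49.79 where the frequency-weighted mixture
is 122.38 — the value its own grand total requires), and several follow-up
course sums drifting a few euros from their printed totals. Printed values
are never altered; fidelity mode keeps the finest-level printed numbers
authoritative and the validator documents the rest.

## Sensitivity analysis

The source study is deterministic, so distributions are an explicit
extension, not a study claim: `fixed`, `uniform`, `triangular` and
`normal_truncated_at_zero` (rejection-sampled) are available, with ±20%
uniform bounds as the default when a spec gives no range. Draws are
independent across parameters; one master seed is spawned into per-spec
substreams in spec order, so appending a spec leaves earlier streams
unchanged. Evaluations run in raw mode on a working copy; the input dataset
is never mutated. For parameters entering the total linearly (prices, the
retreatment rate) the Monte Carlo mean converges to the analytic mean —
verified at n = 10,000 against the closed-form midpoint value within three
standard errors.

## Synthetic data and what passing tests show

`generate_dataset` samples bounded values on exact decimal grids (money to
cents, rates/fractions to 4 decimals) into the same structure as the bundled
datasets, and computes ground-truth totals for all three perspectives by an
independent straight-line accumulation (literal loops, no engine calls).
`generate_paperlike` fixes the bundled studies' exact shape (14 work-up
items, five staff roles, three courses at 0.93/0.035/0.035, r = 0.15) with
randomized values. Oracle-equivalence tests assert engine = truth to the
cent over 100 seeds.

What this does *not* show: synthetic datasets are internally consistent by
construction, so they exercise none of the printed-aggregate drift handling;
fidelity-mode behaviour on real transcriptions is covered only by the
bundled datasets themselves. Problem sizes throughout the suite (≤14 items
per phase, 100 seeds, 10,000 Monte Carlo draws) were chosen as comfortably
representative of desk-scale costing studies; the whole suite runs in
seconds.

## Known limitations

- No cost-utility (QALY) estimation, discounting, inflation adjustment or
  currency conversion.
- Per-unit drug prices are not recovered from national price lists; costs
  per procedure are taken as given.
- The uplift-scope choice (which aggregates receive 1 + r) follows what
  reconciles the published ablation figures; a study that uplifts follow-up
  as well would need a dataset-level residual or course adjustment.
- Parameter draws are uncorrelated; no value-of-information analysis.
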