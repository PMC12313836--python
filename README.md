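# abcost

Activity-based costing (ABC) of healthcare interventions, with bundled cost
datasets for the three treatments of benign symptomatic thyroid nodules:
**total thyroidectomy**, **hemithyroidectomy with isthmectomy**, and
ultrasound-guided **thermal ablation** (laser/radiofrequency, day-hospital).

It is written for health economists and HTA analysts who need a reproducible,
auditable costing engine: every cost driver (work-up items, drug lines,
consumables, staff, operating-room minutes, bed-days, follow-up courses,
productivity loss) lives in a declarative dataset file, and every aggregate
the engine reports can be traced back to those rows.

## The model

ABC assigns the full per-patient cost of an intervention by valuing each
consumed resource at its unit cost:

- **phase cost** — Σᵢ qᵢ·cᵢ over the driver lines of a phase (qᵢ mean
  quantity per patient, cᵢ unit cost), or a published per-patient weighted
  cost where the source prints one;
- **drug cost** — per-category aggregation (mean over alternative agents,
  sum over co-administered ones, or a pinned category cost), summed over
  categories before rounding;
- **facility cost** — operating-room minutes × per-minute rate and bed-days ×
  per-day rate;
- **expected follow-up cost** — a mixture over post-operative courses,
  Σₖ fₖ·Cₖ with course frequencies fₖ (e.g. 93% standard / 3.5% acute /
  3.5% chronic complications) summing to at most 1;
- **retreatment uplift** — every phase except follow-up scaled by (1 + r)
  for the fraction r of patients needing a repeat procedure (r = 0.15 for
  thermal ablation);
- **productivity loss** (human-capital approach) —
  (hospital + convalescence days) × hours lost/day × hourly wage, plus the
  same loss for the caregiver share of patients;
- **perspectives** — `nhs_direct` (direct payer costs), `societal` (adds
  productivity loss), `opportunity_cost_societal` (societal minus personnel,
  treating salaried staff time as an opportunity cost).

Money is exact decimal throughout, rounded half-up to cents only at component
boundaries. Because published tables carry one-cent rounding drift, the
engine has two modes: **fidelity** (printed fine-grained aggregates are
authoritative, summary tables are reproduced to the cent where internally
consistent) and **raw** (everything recomputed from quantities and prices —
the mode used for sensitivity analysis). A reconciliation validator reports
every printed-vs-recomputed difference and flags the source tables' known
errata rather than silently correcting them.

The `sensitivity` module adds one-way sweeps, tornado ranking, and seeded
Monte Carlo over any dataset parameter (e.g. the 5–25% recurrence band for
ablative procedures), and the `synthetic` module generates random datasets
with independently computed ground-truth totals used as the engine's oracle.

## Worked example

```bash
abcost compute -d thermal_ablation --audit
```

```
thermal_ablation (societal, fidelity mode)
--------------------------------------------
Pre-hospitalization                   369.25
Pharmacological therapy                 1.94
Materials                             661.98
Healthcare professionals               40.64
Hospital stay                         193.78
Subtotal for the procedure            898.34
Standard post-operative course         91.11
Subtotal for follow-up                108.70
Productivity loss                     183.77
Total intervention cost             1,560.06

retreatment uplift applied: x1.15
  prehospitalization       321.09 ->       369.25
  ...
```

Each row is a phase cost in EUR after the 15% retreatment uplift (the audit
trail shows pre- and post-uplift values); the total is the full societal cost
per treated patient. Comparing the three treatments:

```bash
abcost compare -d total_thyroidectomy -d hemithyroidectomy \
               -d thermal_ablation --baseline total_thyroidectomy
```

```
Comparison vs total_thyroidectomy (societal, fidelity mode)
-------------------------------------------------------------
total_thyroidectomy      5,185.35
hemithyroidectomy        4,211.92        973.43    18.8%
thermal_ablation         1,560.06      3,625.29    69.9%
```

Thermal ablation costs ~70% less than total thyroidectomy and ~63% less than
hemithyroidectomy per patient. The same computations are available from
Python (`bundled_dataset`, `intervention_total`, `compare`), and
`abcost validate -d <dataset>` prints the reconciliation report;
`abcost sensitivity` and `abcost synth` drive the uncertainty and
synthetic-data tools.

## Layout

```
src/abcost/cost_tables.py   dataset model, YAML/CSV dialects, bundled data
src/abcost/engine.py        costing operations, perspectives, breakdowns
src/abcost/sensitivity.py   sweeps, tornado, Monte Carlo
src/abcost/synthetic.py     random datasets + closed-form ground truth
src/abcost/reporting.py     console/CSV/JSON/Markdown rendering
src/abcost/cli.py           `abcost` command-line interface
docs/methods.md             modelling notes, conventions, limitations
```
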