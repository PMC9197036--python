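# pvcea — cost-effectiveness of peripheral venous catheter strategies

Short peripheral venous catheters (PVCs) frequently fail before the end of
treatment — dislodgement, phlebitis, diffusion (infiltration), local
infection, occlusion — forcing an unscheduled removal, a replacement
catheter, and the cost of treating the complication. A bundle of innovative
devices (closed integrated catheters, positive-displacement needleless
connectors, disinfecting caps, prefilled flush syringes) is more expensive
per insertion and per day of use than a standard open catheter with a
three-way stopcock, but fails less often. `pvcea` answers the
health-economic question: **is the bundle's extra material cost offset by
fewer and later catheter replacements?**

It is written for health economists and biostatisticians who want a tested,
reusable implementation of this analysis that runs on synthetic
individual-patient data calibrated to the published trial conditions (the
original hospital database is not public).

## The model

Patients move through a five-state continuous-time multi-state
(semi-Markov) model over a 14-day horizon:

* **S1** — first catheter in place, no event;
* **S2** — no catheter (routine removal: scheduled, useless, or suspected
  infection; events E1–E3);
* **S3** — second catheter in place after an unscheduled removal caused by
  one of the five studied complications (events E4–E8);
* **S4** discharge and **S5** death, both absorbing.

Occupancy and sojourn summaries are *observed* (prevalence-style counts on
a time grid), not derived from an estimated intensity matrix. Costs accrue
per catheter from an explicit unit-cost schedule (placement, removal,
daily use per started 24 h, complication treatment, second-catheter
placement and use) and scale to per-patient costs through the arm's mean
catheters-per-patient coefficient (1.5 standard / 1.3 bundled). Because
mean first-catheter exposure differs between arms (1.8269 vs 2.1226 days),
comparisons are catheter-time adjusted: the shorter-exposure arm's mean
cost is scaled by the sojourn ratio (1.1618), and every metric is also
reported per first-PVC-day (value ÷ mean S1 sojourn). Uncertainty comes
from a nonparametric percentile bootstrap (subjects resampled with
replacement within arm, cost and effectiveness jointly), which also yields
the cost-effectiveness plane and the dominance/ICER verdict.

## Worked example

```sh
pvcea all --reps 1000 --seed 0 --out results/
```

simulates one trial-calibrated cohort (495 standard- and 494 bundled-arm
subjects), analyses the base case and both scenario analyses, and prints:

```
Scenario: base   (seed 0, 1000 bootstrap replicates)
                                               SDs (reference)          BDs (assessed)
Mean cost/patient, adj. (95% CI)         142.31 (123.1; 165.0)    103.58 (97.0; 110.3)
Unscheduled removal n/N (%)           238/495 (48.08%)        164/494 (33.20%)
Cost/PVC-day (95% CI)                       79.00 (64.4; 96.7)      49.08 (43.9; 55.5)
Removals/PVC-day (95% CI)              0.2669 (0.2367; 0.3010) 0.1573 (0.1323; 0.1846)
Delta cost/patient (BDs-SDs)                                     -38.74 (-63.0; -19.7)
Delta effectiveness (SDs-BDs)         +14.88 patients / 100
Delta cost/PVC-day (BDs-SDs)                                     -29.92 (-51.7; -11.9)
Delta removals/PVC-day (BDs-SDs)                -0.1096 (-0.1543; -0.0690)
ICER / dominance                        BDs dominate SDs (less costly, more effective)
```

Reading it: in this simulated cohort 48.1% of standard-arm patients needed
an unscheduled first-catheter removal against 33.2% in the bundle arm; the
catheter-time-adjusted mean cost is €142.31 vs €103.58 per patient
(€79.00 vs €49.08 per first-catheter day), so the bundle saves money *and*
prevents removals — it dominates, and every one of the 1,000 bootstrap
replicates lands in the same (more effective, less costly) quadrant
(`results/ce_plane.csv`). The library API mirrors the CLI:
`generate_cohort`, `occupancy_table`, `trajectory_cost`,
`effectiveness_summary`, `analyse_scenario`, `render_report`.

The same run writes `report_base.json`, `report_s1.json` (2–14-day
subgroup: catheters > 24 h or complicated), `report_s2.json` (complication
costs excluded), `occupancy.csv` and the cohort CSVs.

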