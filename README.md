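# swaft — smartwatch activity-feedback trial toolkit

Stroke patients on rehabilitation wards are largely inactive outside formal
therapy. One candidate intervention is a wrist-worn smartwatch that scores a
patient's movement through the day and displays progress toward an adaptive
activity goal, nudging them to move a little more than they did yesterday.
`swaft` implements the full software side of such a trial for researchers
running (or simulating) wearable feedback studies on single-site wards:

* **Device logic** — the watch divides the monitored day (08:00–17:00) into
  four 2-h periods and one 1-h period. Raw tri-axial acceleration (g) is
  reduced to an **activity score** (AS) per epoch,

  $$\mathrm{AS} = \sum_i m_i\,\Delta t, \qquad
    m_i = \big|\,\lVert \mathbf{a}_i \rVert - 1\,\big| \;
    \text{if} \ge \delta \text{ else } 0,$$

  with dead-band δ = 0.05 g, alongside a movement-variance wear estimate
  (60 s sub-windows, threshold 10⁻⁴ g², worn when ≥ 25 % are active).
* **Feedback engine** — each day after baseline, the per-period goal is
  1.05 × the AS of the comparable epoch the preceding weekday (Friday feeds
  Monday). Progress shows on a four-level bar with thresholds at ⅓, ⅔ and
  the full goal; control mode shows a clock icon only, and day 1 never
  gives feedback.
* **Trial registry** — conjunctive eligibility screening (age 40–75, stroke
  onset < 4 months, first admission, …), concealed seeded 1:1 randomisation
  (simple or permuted-block), protocol-deviation bookkeeping.
* **Feasibility analytics** — recruitment/retention/completion rates,
  per-group wearing-adherence categories, baseline-exceedance rates (a day
  counts when its periods 1–4 total strictly exceeds the day-1 total),
  median/IQR activity summaries and per-period delta series.
* **Synthetic cohort simulator** — seeded generation of a whole trial
  (registry, epoch records, assessments, watch log) with configurable
  effect sizes, wear gaps, weekend recording and dropout, plus closed-loop
  raw-trace synthesis for any target AS.

## Worked example

```python
from swaft import FlowCounts, flow_rates, bar_state, set_goal

# recruitment and retention from a participant flow
print(flow_rates(FlowCounts(admitted=470, recruited=51, valid=50,
                            completed_discharge=39, completed_followup=24)))
# {'recruitment': 11, 'retention_discharge': 78,
#  'retention_followup': 48, 'followup_among_discharged': 62}

# tomorrow's goal after scoring 172 AS in a period today
print(set_goal(172))          # 180.6
print(bar_state(100, 300))    # 2  (one third of the goal reached)
```

Recruitment was 11 % of admissions; 78 % of valid patients completed the
discharge assessment, 48 % the 3-month follow-up (62 % of those discharged);
a patient scoring 172 AS gets a 180.6 goal, and 100 AS against a 300 goal
lights the second bar.

End to end from the shell:

```bash
swaft simulate --seed 5 --out data/
swaft report --epochs data/epochs.csv --registry data/registry.csv \
             --assessments data/assessments.csv --admitted 470 --out data/report/
```

which prints flow rates and the adherence, exceedance and activity-summary
tables, and writes them as CSV. `swaft score` converts raw trace CSVs to
epoch records, `swaft feedback` replays the goal/bar state machine, and
`swaft qc` audits a download folder for duplicate, mislabelled or
unconsolidated files.

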