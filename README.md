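# ewsbench

Early-warning-score comparison pipeline for emergency-department cohorts.

The package compares three track-and-trigger scores on the same patients in
a paired design:

- **TOKS** — a six-component regional early warning score (systolic BP,
  heart rate, temperature, respiratory rate, saturation, consciousness with
  an agitation point); maximum 18.
- **mTOKS** — TOKS plus 2 points for supplemental oxygen; maximum 20.
- **NEWS** — the Royal College of Physicians National Early Warning Score
  (2012), which also weights oxygen at 2 points; maximum 20.

Score systems are *data*, not code: each is a YAML file of ordered half-open
threshold bands per vital parameter plus a level-of-consciousness rule and
an oxygen modifier (`src/ewsbench/data/`). A validator checks that every
scale partitions the real line and that the computed maximum matches the
declared maximum, so transcription errors surface as data defects.

Modules:

| module | purpose |
| --- | --- |
| `ewsbench.scoring` | declarative score systems, GCS→AVPU conversion, scalar and vectorised scoring |
| `ewsbench.cohort` | eligibility filters, first-contact dedup, first complete vital set within 4 h, 7-day mortality, exclusion accounting |
| `ewsbench.discrimination` | ROC curves with tie handling, AUROC with DeLong variance/CI, paired chi-square comparison of correlated AUROCs |
| `ewsbench.simulate` | synthetic ED cohort generator (latent severity → vitals, oxygen, missingness, mortality) and deterministic test fixtures |
| `ewsbench.cli` / `ewsbench.report` | command-line entry points and paper-style report tables/figures |

## CLI

```bash
# generate a synthetic encounters table (one row per vital record)
ewsbench simulate --n 20000 --seed 42 --out scratch/encounters.csv

# score every complete row under the bundled systems
ewsbench score scratch/encounters.csv --out scratch/scored.csv

# eligibility + dedup + vitals window -> cohort.csv + exclusion_flow.json
ewsbench build-cohort scratch/encounters.csv --out scratch/cohort

# full analysis bundle: exclusion flow, characteristics table,
# score distribution with mortality, ROC overlay, paired DeLong tests
ewsbench compare scratch/encounters.csv --out scratch/report
```

Key flags: `--window-hours` (default 4), `--followup-days` (default 7),
`--alpha` (default 0.05), `--seed`. All randomness flows through
`numpy.random.default_rng(seed)`; seeded runs are byte-reproducible.

## Notes

- Band→point assignments for the one-sided extreme bands of the TOKS table
  are a transcription choice constrained by the published maximum of 18;
  they live in the YAML configs and can be revised without code changes.
- When consciousness is recorded as GCS (the triage pathway), the agitation
  flag is suppressed by default because GCS does not capture agitation;
  pass `honor_gcs_agitation=True` for sensitivity analyses.
- The paired AUROC test is the DeLong placement-based chi-square test. It
  is exact in its variance algebra (verified against the direct pairwise
  computation) but, like all DeLong-type tests, anti-conservative when the
  number of events is very small (≈8% type-I error at 10 events).
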