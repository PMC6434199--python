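# evigrade

Cumulative-evidence assessment of genetic association summaries.

Given one row per published association analysis (odds ratio, 95% CI,
sample counts, I², Egger's test p, minor-allele frequency, ...), the
package:

* recovers the log-OR standard error from the CI and computes the observed
  p-value, the statistical power to detect a target OR (default 1.5), and
  the **false-positive report probability** (FPRP) at a configurable prior
  (default 0.001), binned into strong / moderate / weak (<0.05 / 0.05–0.2 /
  >0.2) with a noteworthiness cutoff of 0.2;
* assigns **Venice criteria** grades — amount of evidence (test
  allele/genotype counts, with a MAF-based fallback calculation),
  replication (I² bins), protection from bias (Egger's test, effect
  magnitude, GWAS replication) — and the combined
  strong/moderate/weak/ungraded level;
* applies the FPRP-driven one-step upgrade/downgrade to the Venice level and
  tallies final evidence once per distinct variant via its primary analysis;
* provides summary-level meta-analysis statistics (fixed-effect pooling,
  Cochran's Q, I², Egger's regression) and a seeded **synthetic
  case-control meta-analysis generator** so the whole pipeline is testable
  without external data.

Two curated fixture tables ship inside the package (`evigrade.load_table1()`
with 69 meta-analysis rows covering 38 distinct significant variants, and
`evigrade.load_table2()` with 17 GWAS rows). Running the combiner on the
first with published grades and FPRP values yields the reference tally of
5 strong / 10 moderate / 18 weak / 5 ungraded variants.

## CLI

```sh
# FPRP columns (se, p_obs, power, fprp, category, noteworthy)
evigrade fprp input.tsv out.tsv --prior 0.001 --target-or 1.5 --cutoff 0.2

# Venice grading + FPRP adjustment + per-variant JSON tally
evigrade grade input.tsv out.tsv --summary-json tally.json \
    --use-published-grades --use-published-fprp

# Simulate association records from a JSON spec
echo '{"k_studies": 5, "n_cases_per_study": 1000, "n_controls_per_study": 1000,
      "control_maf": 0.3, "true_or": 1.5, "seed": 7}' > spec.json
evigrade simulate spec.json sim.tsv --n-associations 10

# Reproduction report for the packaged fixtures (per-row deltas)
evigrade verify --table table1 --out report.tsv
```

Input tables are TSV (or CSV via `--format csv`) with a header row; missing
values are `Na` or empty; a combined `or_ci` column like `1.49 (1.33-1.66)`
is accepted in place of separate `or_point`/`ci_low`/`ci_high` columns.

## Layout

| module | contents |
| --- | --- |
| `evigrade.records`  | record model, validation, TSV/CSV I/O, packaged fixtures |
| `evigrade.fprp`     | SE-from-CI, observed p, power, FPRP, categories |
| `evigrade.venice`   | element grades, MAF count calculation, combination rule |
| `evigrade.combine`  | FPRP adjustment, primary-analysis selection, tallies |
| `evigrade.meta`     | fixed-effect pooling, Q/I², Egger's regression |
| `evigrade.simulate` | seeded case-control meta-analysis generator |
| `evigrade.verify`   | fixture reproduction report with per-row deltas |
| `evigrade.cli`      | `evigrade` command-line entry point |

Note: the published power/FPRP columns were computed from unrounded inputs;
recomputing from the rounded printed CIs reproduces ~80% of cells within
±0.005 but leaves a documented set of rows with larger drift (see
`evigrade verify` and `tests/test_verify.py`), reported with deltas rather
than silently corrected.
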