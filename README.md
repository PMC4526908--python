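# activerx

Closed-loop personalized walking/running prescription from wearable
monitor data. The package ingests activity-monitor files (triaxial
acceleration plus instantaneous heart rate), applies beat-level filtering
and file-level quality control, extracts a daily resting heart rate, and
drives a 12-week progression whose target heart-rate zones
(heart-rate-reserve method) are re-personalized weekly and whose advancement
is gated on measured compliance. Doses are scored as training impulse
(TRIMP), and administrative monitoring (reminder/survey triggers, daily QC
logs) runs over a text-backed store. A synthetic-participant simulator
replaces the physical device and subjects, so the whole loop is testable
offline and bit-reproducibly.

## Layout

| module | contents |
| --- | --- |
| `activerx.am_format` | binary monitor-file (AMB) and prescription-record dialects, filename convention, fingerprints |
| `activerx.signal_qc` | trailing moving averages, aberrant-beat filtering, resting/activity file QC, daily resting HR, session phase segmentation, in-session zone-feedback events |
| `activerx.prescription` | 12-week progression table, Karvonen target zones, weekly effective resting HR, day scheduling, compliance gate, field-test override |
| `activerx.metrics` | TRIMP (sex-specific exponent), recommended/completed intensity ratios, weekly dose table, plug-in fitness estimate |
| `activerx.admin_monitor` | text-backed store, upload file management, streak triggers, milestone emails (as events), daily logs |
| `activerx.simulator` | synthetic physiology + compliance profiles, monitor-file generators, full closed-loop driver, `adherent`/`sporadic` presets |
| `activerx.cli` | `activerx` command-line interface |
| `activerx.config` | `RunConfig` with every tunable constant and its default |

Key defaults (all overridable): 10-beat moving-average filter with 25 %
relative deviation and [30, 220] bpm absolute bounds; resting files need
≥ 7.5 min and ≤ 20 % filtered beats; activity files need mean HR ≥ 80 bpm;
weekly advancement needs ≥ 70 % of recommended endurance minutes; missing
resting data for 3 days → reminder, no uploads for 7 days → survey;
TRIMP exponents 1.92 (M) / 1.67 (F); default resting HR 65 bpm when no
measurement exists.

## CLI

```sh
# synthetic 12-week run from a scenario file
cat > scenario.yaml <<EOF
preset: adherent        # or: physiology:/compliance: parameter mappings
weeks: 12
EOF
activerx simulate --scenario scenario.yaml --out out/ --seed 1

# per-participant store workflow
activerx init --store store/ --user u01 --hrmax 190 --hrrest 65 \
    --start-date 2025-01-06
activerx ingest u01_20250106_071500_R.amb --store store/ \
    --upload-date 2025-01-06
activerx prescribe --store store/ --date 2025-01-06 --out rx.bin
activerx monitor --store store/ --date 2025-01-08
activerx report --store store/
```

Exit codes: 0 success, 2 usage error, 3 data error.

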