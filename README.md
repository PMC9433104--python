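# timing

Single-cell dynamic profiling of CAR T cell–tumor interactions in
nanowell time-lapse (TIMING) assays: from per-frame object tracks to
conjugation kinetics, killing and serial-killing annotation, IFN-γ
secretion, directional-migration metrics, single-cell qPCR differential
expression, and clinical IHC H-score survival stratification.

The package is aimed at groups analyzing nanowell cytotoxicity screens —
thousands of sub-nanoliter wells, each confining one effector T cell with
1–5 tumor cells and antibody-coated capture beads, imaged every few
minutes for hours — and at readers who want a tested, ground-truthed
reference implementation of the analysis.

## The measurements

For each effector–target pair, with a *conjugation* defined as a stable
contact lasting strictly more than 5 minutes:

- `t_Seek` — time from assay start to the first conjugation;
- `t_Contact` — cumulative conjugation time between first contact and
  target death (apoptosis reported by annexin-V onset);
- `t_Death` — time from first contact to apoptosis onset,

so `t_Contact ≤ t_Death` always, with equality for continuous contact
until death.  Effectors are graded nonkiller / single killer / serial
killer (≥ 2 kills at E:T 1:2–5) and classified as multifunctional,
monofunctional (kill-only or IFN-γ-only) or nonfunctional.  Directional
migration — direction of movement maintained for at least one cell
diameter — is measured separately out of and in contact.  The clinical
module scores biopsies as

    H = %mild·1 + %moderate·2 + %intense·3        (0–300),

selects a cutoff by ROC analysis, and compares progression-free survival
across the strata with Kaplan-Meier estimates and a log-rank test.

Because real chips are not shippable, a first-class synthetic-data module
generates ground-truthed chips (persistent-random-walk effectors,
event-driven conjugation/kill/secretion dynamics), qPCR cohorts and
clinical cohorts; every detector in the pipeline is tested against that
ground truth.  See `docs/methods.md` for models, conventions and
limitations.

## Worked example

```sh
timing run-all --demo --out demo_run
```

runs a 120-well simulated chip plus the qPCR and clinical branches.  From
`demo_run/summary.json` and `demo_run/report.json` (seed 11):

- 88 wells of interest (one live effector, 1–5 targets, ≥ 1 bead), 78
  baseline (conjugating) effectors, 104 attributed kills;
- median cumulative contact: 192.5 min for IFN-γ-only monofunctional
  cells versus 45.0 min for multifunctional cells (Mann-Whitney
  p ≈ 8 × 10⁻⁷) — non-killing secretors stay attached, killers detach;
- median out-of-contact migration 1.21 µm/min (multifunctional) versus
  0.23 µm/min (nonfunctional), Kruskal-Wallis p ≈ 2 × 10⁻⁸ — migratory
  cells are the multifunctional ones;
- all six planted migration genes (CD2, CD58, CD244, CXCR3, IL18R1,
  LAG3) recovered at FDR q < 0.1;
- clinical stratification at H = 80: median PFS 44.2 vs 5.0 months,
  log-rank p ≈ 5 × 10⁻⁶.

The same stages are available as individual verbs (`timing simulate`,
`segment`, `track`, `kinetics`, `annotate`, `migration`, `qpcr`,
`clinical`, `report`) and as library calls (`timing.synthetic`,
`timing.kinetics.analyze_chip`, `timing.migration.migration_table`,
`timing.expression`, `timing.clinical`).

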