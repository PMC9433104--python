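# Methods

## What the package models

Nanowell time-lapse cytotoxicity profiling (TIMING) confines one effector
T cell with a small number of tumor cells and one or more cytokine-capture
beads in each well of a chip, imaged at a fixed interval (default 5 min)
over a fixed window (default 6 h).  From the resulting object tracks the
package measures:

- **Conjugation**: a stable effector–target contact lasting *strictly more*
  than 5 minutes.  Contact at a frame is declared when the centroid
  distance does not exceed the sum of the cells' disc-equivalent radii
  (`r = sqrt(area/π)`) plus a slack (default 2 µm).  Runs of contact frames
  bridging gaps of at most one frame form intervals; interval duration is
  the number of contact frames times the frame interval, so at 5-min
  sampling two contact frames (10 min) pass the strict filter and one frame
  (5 min) does not.
- **Kinetic parameters** per effector–target pair:
  `t_Seek` (assay start to first conjugation), `t_Contact` (cumulative
  conjugation between first contact and target death; total conjugation if
  the target survives) and `t_Death` (first contact to apoptosis onset).
  By construction `0 ≤ t_Contact ≤ t_Death` whenever a death exists.
- **Death calling**: apoptosis onset is the first frame of the earliest run
  of ≥ k (default 2) consecutive frames with annexin-V intensity above a
  threshold (default 50, between the simulated background ~3 and the
  reporter-on level ~150).  k = 2 rejects single-frame noise at 5-min
  sampling; the call is monotone in the threshold.
- **Kill attribution**: a target's death is credited to the effector iff
  some shared conjugation interval starts before the death and ends at most
  `max_latency` (default 120 min) before it — detachment precedes apoptosis
  in this assay, so the latency window is what links the two events.
- **Functional taxonomy** over effectors with at least one conjugation (the
  baseline population): multifunctional (≥ 2 kills regardless of IFN-γ, or
  exactly 1 kill plus secretion), monofunctional (kill-only or
  secretion-only), nonfunctional (conjugated, neither).  Killer grade is
  nonkiller / single killer / serial killer by attributed kill count.
- **Secretion calling**: a well is IFN-γ-positive when its per-well median
  bead intensity exceeds the mean + k·SD (default k = 3) of control wells
  (beads present, no effector); ≥ 10 controls are required.
- **Directional migration**: a run of consecutive steps each within an
  angular tolerance (default 45°) of the run's cumulative displacement
  direction, retained when the net displacement reaches one cell diameter
  (track median of `2·sqrt(area/π)`).  Frames are partitioned into
  in-contact and out-of-contact states by the conjugation intervals; runs
  never cross a state change.  The migration rate per state is the summed
  retained run displacement divided by the time in the state, where a
  track of *n* frames spans *n−1* step intervals.
- **Single-cell qPCR**: expression on a log2 scale is `Et = max(0, LOD − Ct)`
  with the limit of detection at 40 cycles (the common convention for
  Fluidigm-style panels); undetermined values map to zero.  QC removes
  cells expressing fewer than `min_genes` genes and flags genes detected in
  no-cell/no-RT controls.  Differential expression between migration groups
  uses a per-gene Mann-Whitney U test with Benjamini–Hochberg adjustment
  across the QC-surviving panel (significant at q < 0.1); the correlogram
  reports Pearson correlations of genes and the continuous migration
  metric, masked where the two-sided p ≥ 0.05.
- **Clinical H score**: `H = %mild·1 + %moderate·2 + %intense·3` over tumor
  cells (0–300).  An ROC sweep over midpoints between sorted unique scores
  picks a cutoff either by the Youden index or as the smallest cutoff with
  specificity ≥ a target (default 0.94); ties break toward the lower
  cutoff.  Progression-free survival is stratified at the cutoff
  (default 80) and compared with Kaplan-Meier curves and a 1-df log-rank
  test.  The KM median is the first time with S(t) ≤ 0.5, undefined if
  never reached.

## The statistics core

Mann-Whitney U uses midranks for ties and switches between an exact
enumeration of the null distribution (combined n ≤ 12, tie-free) and the
normal approximation with tie and continuity corrections.  Kruskal-Wallis
applies the standard tie correction with a chi-square reference
(k−1 df).  Correlation p-values use the t approximation.  BH q-values are
the step-up `min_{i≥k} m·p_(i)/i` with monotone enforcement.  These are
implemented in the package so the exact branch and tie conventions are
fully specified; scipy supplies only reference distributions and ranking,
and lifelines/scikit-learn serve as independent cross-checks in the test
suite, never as the implementation.

At very small n the log-rank chi-square reference is an approximation: on
n = 12 cohorts it deviates from an exact permutation p by up to ~0.05,
which the tests account for explicitly.

## The synthetic-data generator

Wells are independent; cells neither divide nor leave (nanowells confine
them).  Effectors move as persistent random walks — the heading is kept
with probability `directional_persistence` per step, otherwise redrawn
uniformly — with reflecting walls.  Targets jitter slowly; beads are
static.  When a (single) effector reaches a live target it conjugates for
a lognormal-distributed duration (minimum two frames), kills with the
profile's per-contact probability, and on a kill the annexin reporter
switches on a lognormal latency (clipped to 5–100 min) after detachment.
Captured IFN-γ on each bead is `(baseline + rate · cumulative conjugation
minutes) · lognormal noise` — lognormal because fluorescence is strictly
positive.  Default geometry: 65 µm wells, 9 µm effectors, 11 µm targets,
3 µm beads, which keeps the bead/cell area distributions disjoint for the
size-exclusion rule.

Four behavior profiles span the taxonomy: `migratory_killer` (fast,
persistent, kills without secreting), `serial_killer` (fastest, short
synapses, near-certain kills, secretes), `monofunctional_secretor` (slow,
very long synapses, never kills, secretes) and `nonmigratory_nonkiller`
(slow, erratic, neither).  Effector-count distributions include
effectorless wells so the secretion threshold has its control population.

Ground truth records every conjugation interval, kill and secretion flag.
A kill enters the ground truth only when the annexin onset lands at or
before the penultimate frame, i.e. when a two-frame death call is possible
inside the assay window — later onsets are unobservable truncation, not
kills.  True functional labels are derived from this event log by the same
taxonomy definitions.

The qPCR generator draws per-gene baseline Ct from U(24, 32) with
cell-level noise of 0.75 cycles (deliberately at the optimistic end for
abundant activation transcripts, so a 2-fold shift is reliably detectable
at n ≈ 45/group); effect genes have Ct reduced in proportion to each
cell's continuous migration metric, making them both group-shifted and
metric-correlated.  The clinical generator draws staining in 10%
increments (30% of patients fully negative), exponential PFS with the
hazard multiplied by `hazard_ratio` below the H-score cutoff, response
probability logistic in the H score, and uniform-fraction censoring.

### What the generator does not emulate

No optics (PSF, photobleaching, uneven illumination), no cell division or
death of effectors, no effector–effector interactions, no segmentation
artifacts beyond additive camera noise and rasterization, no batch or
chip-to-chip effects, and qPCR without the heavy zero-inflation of
low-abundance transcripts.  Passing tests therefore demonstrate that the
measurement and annotation logic is correct under the stated model, not
that the pipeline is robust to every failure mode of real microscopy or
chemistry data.

## Numerical and design choices

- Segmentation is per dye channel (effector and target membrane dyes are
  distinct channels), so a touching effector–target pair stays two
  objects; touching same-dye cells merge and are flagged when the area
  exceeds 1.8× the median cell area.  Thresholds default to Otsu with a
  flat-channel guard; blank tiles return an empty table with a warning.
- Tracking is greedy nearest-neighbor per well and object kind with a
  maximum step (default 20 µm ≈ 4 µm/min for one frame) and single-frame
  gap bridging; with one effector per well and near-stationary targets
  this is unambiguous by construction.
- The angular criterion for "direction maintained" (45° against the run's
  cumulative direction) is a declared convention — validated by ordering
  properties between phenotypes, not against any printed distribution.
- Degenerate inputs: zero-variance genes are masked/flagged rather than
  erroring; wells without beads yield flagged missing summaries; all-equal
  ROC scores raise.
- Problem sizes: simulation-scale checks use a 500-well chip (one seeded
  realization shared across tests), calibration loops use 20–25 seeds of
  the 92-cell qPCR design, and the permutation oracle uses 10⁴ shuffles —
  sizes at which the checked orderings are decisive while a full run of
  the suite stays in the minutes range.

## Known limitations

- Image-mode and track-mode analyses agree on selection and function
  classes but not bit-for-bit: at 1 µm/pixel a two-frame conjugation can
  fall below the strict filter after rasterization.
- Kill attribution assumes a single effector per well (as the well
  selection guarantees); overlapping conjugation histories from several
  effectors would need a different rule.
- The exact Mann-Whitney branch requires tie-free data; heavily tied small
  samples fall back to the corrected normal approximation.
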