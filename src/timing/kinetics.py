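"""Conjugation detection, kinetic parameters and functional annotation.

A conjugation is a stable effector-target contact lasting strictly more
than 5 minutes.  Contact at a frame is declared when the centroid
distance does not exceed the sum of the disc-equivalent radii plus a
slack; maximal runs of contact frames (bridging single-frame gaps) form
intervals whose duration is the number of contact frames times the frame
interval.

Per effector-target pair the kinetic parameters are
  t_Seek    — time from assay start to the first conjugation,
  t_Contact — cumulative conjugation time between first contact and
              target death (total conjugation time if no death),
  t_Death   — time from first contact to apoptosis onset.

Effectors are annotated by kill count (nonkiller / single killer /
serial killer) and by the functional taxonomy: multifunctional (serial
killing regardless of secretion, or exactly one kill plus IFN-gamma
secretion), monofunctional (kill-only or secretion-only), and
nonfunctional (conjugated but neither).  Only effectors with at least
one conjugation enter this baseline population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imaging as _imaging

__all__ = [
    "ConjugationInterval",
    "KineticRecord",
    "FunctionalLabel",
    "detect_conjugations",
    "compute_kinetics",
    "select_wells",
    "annotate_function",
    "call_secretion",
    "analyze_chip",
    "ChipAnalysis",
]


@dataclass
class ConjugationInterval:
    effector_id: str
    target_id: str
    start_min: float
    end_min: float  # end of the last contact frame (exclusive)
    duration_min: float  # contact frames x frame interval (gaps excluded)
    contact_times: list = field(default_factory=list)

    def __post_init__(self):
        if self.end_min <= self.start_min:
            raise ValueError("interval must have positive extent")


@dataclass
class KineticRecord:
    effector_id: str
    target_id: str
    t_seek: float
    t_contact: float
    t_death: float | None
    killed: bool
    valid: bool = True


@dataclass
class FunctionalLabel:
    killer_class: str  # nonkiller | single_killer | serial_killer
    secretion: bool
    function_class: str  # multifunctional | monofunctional_kill | monofunctional_ifng | nonfunctional
    conjugated: bool


def _radii_um(chain: pd.DataFrame) -> np.ndarray:
    return np.sqrt(chain["area_um2"].to_numpy(dtype=float) / math.pi)


def detect_conjugations(
    effector_chain: pd.DataFrame,
    target_chain: pd.DataFrame,
    slack_um: float = 2.0,
    min_duration_min: float = 5.0,
    gap_max: int = 1,
) -> list[ConjugationInterval]:
    """Find conjugation intervals between one effector and one target chain.

    Chains are per-object track tables with ``frame``, ``t_min``,
    ``x_um``, ``y_um``, ``area_um2`` columns sharing the same frame clock.
    Contact at a frame: centroid distance <= r_eff + r_tgt + slack with
    disc-equivalent radii.  Runs of contact frames with gaps <= ``gap_max``
    are merged; an interval is kept only if its duration (contact frames x
    frame interval) strictly exceeds ``min_duration_min``.
    """
    e = effector_chain.sort_values("frame")
    t = target_chain.sort_values("frame")
    merged = pd.merge(
        e[["frame", "t_min", "x_um", "y_um", "area_um2"]],
        t[["frame", "t_min", "x_um", "y_um", "area_um2"]],
        on="frame",
        suffixes=("_e", "_t"),
    )
    if len(merged) == 0:
        return []
    if not np.allclose(merged["t_min_e"], merged["t_min_t"]):
        raise ValueError("effector and target chains have mismatched frame clocks")
    times = merged["t_min_e"].to_numpy(dtype=float)
    frames = merged["frame"].to_numpy()
    if len(frames) > 1:
        dt = float(np.min(np.diff(np.sort(np.unique(times)))))
    else:
        dt = float("nan")
    dist = np.hypot(
        merged["x_um_e"] - merged["x_um_t"], merged["y_um_e"] - merged["y_um_t"]
    ).to_numpy()
    r_e = np.sqrt(merged["area_um2_e"].to_numpy(dtype=float) / math.pi)
    r_t = np.sqrt(merged["area_um2_t"].to_numpy(dtype=float) / math.pi)
    contact = dist <= r_e + r_t + slack_um

    eid = str(effector_chain["object_id"].iloc[0]) if "object_id" in effector_chain else ""
    tid = str(target_chain["object_id"].iloc[0]) if "object_id" in target_chain else ""

    intervals: list[ConjugationInterval] = []
    run: list[int] = []  # indices into merged
    for idx in np.nonzero(contact)[0]:
        if run and frames[idx] - frames[run[-1]] > gap_max + 1:
            intervals.append(_close_run(run, frames, times, dt, eid, tid))
            run = []
        run.append(int(idx))
    if run:
        intervals.append(_close_run(run, frames, times, dt, eid, tid))
    return [iv for iv in intervals if iv.duration_min > min_duration_min]


def _close_run(run, frames, times, dt, eid, tid) -> ConjugationInterval:
    ct = [float(times[i]) for i in run]
    duration = len(run) * dt if np.isfinite(dt) else 0.0
    return ConjugationInterval(
        effector_id=eid,
        target_id=tid,
        start_min=ct[0],
        end_min=ct[-1] + (dt if np.isfinite(dt) else 0.0),
        duration_min=duration,
        contact_times=ct,
    )


def compute_kinetics(
    intervals: list[ConjugationInterval],
    death_min: float | None,
    assay_start_min: float = 0.0,
    frame_interval_min: float = 5.0,
) -> KineticRecord | None:
    """Kinetic parameters for one effector-target pair.

    A record flagged invalid (death before first contact) is excluded from
    killer statistics by the caller.
    """
    if not intervals:
        return None
    ivs = sorted(intervals, key=lambda iv: iv.start_min)
    first = ivs[0].start_min
    t_seek = first - assay_start_min
    eid, tid = ivs[0].effector_id, ivs[0].target_id
    if death_min is None:
        total = sum(iv.duration_min for iv in ivs)
        return KineticRecord(eid, tid, t_seek, total, None, killed=False)
    if death_min < first:
        return KineticRecord(eid, tid, t_seek, 0.0, None, killed=False, valid=False)
    # clip cumulative conjugation to [first contact, death]
    t_contact = 0.0
    for iv in ivs:
        t_contact += frame_interval_min * sum(
            1 for ct in iv.contact_times if ct < death_min
        )
    t_death = death_min - first
    t_contact = min(t_contact, t_death) if t_death > 0 else t_contact
    return KineticRecord(eid, tid, t_seek, t_contact, t_death, killed=True)


def select_wells(
    tracks: pd.DataFrame,
    e_count: int = 1,
    t_min: int = 1,
    t_max: int = 5,
    bead_min: int = 1,
    annexin_threshold: float = 50.0,
) -> list[str]:
    """Wells of interest: e_count effectors, t_min..t_max targets, >= bead_min
    beads at frame 0, with the effector alive (annexin-negative) at frame 0."""
    f0 = tracks[tracks["frame"] == 0]
    selected = []
    for well_id, grp in f0.groupby("well_id", sort=True):
        n_e = int((grp["role"] == "effector").sum())
        n_t = int((grp["role"] == "target").sum())
        n_b = int((grp["role"] == "bead").sum())
        if n_e != e_count or not (t_min <= n_t <= t_max) or n_b < bead_min:
            continue
        eff = grp[grp["role"] == "effector"]
        if (eff["ch_annexin"] > annexin_threshold).any():
            continue
        selected.append(well_id)
    return selected


def annotate_function(
    n_kills: int,
    secretion: bool | None,
    conjugated: bool,
) -> FunctionalLabel | None:
    """Functional taxonomy for one effector.

    Returns None for effectors without any conjugation (excluded from the
    baseline population).  A missing secretion flag (end-point readout not
    matched) is an error.
    """
    if secretion is None:
        raise ValueError("secretion flag missing: end-point readout not matched")
    if not conjugated:
        return None
    killer_class = (
        "serial_killer" if n_kills >= 2 else "single_killer" if n_kills == 1 else "nonkiller"
    )
    if n_kills >= 2:
        fc = "multifunctional"
    elif n_kills == 1:
        fc = "multifunctional" if secretion else "monofunctional_kill"
    elif secretion:
        fc = "monofunctional_ifng"
    else:
        fc = "nonfunctional"
    return FunctionalLabel(killer_class, bool(secretion), fc, True)


def call_secretion(
    well_summary: pd.DataFrame,
    control_summary: pd.DataFrame,
    k: float = 3.0,
    min_controls: int = 10,
) -> pd.Series:
    """Per-well IFN-gamma secretion call from end-point bead intensities.

    ``well_summary`` / ``control_summary`` carry ``well_id`` and
    ``bead_intensity`` (control wells contain beads but no effector).  A
    well is positive iff its summary exceeds control mean + k * control SD.
    """
    ctrl = control_summary["bead_intensity"].dropna().to_numpy(dtype=float)
    if ctrl.size < min_controls:
        raise ValueError(
            f"need >= {min_controls} control wells for the secretion threshold "
            f"(got {ctrl.size})"
        )
    thr = ctrl.mean() + k * ctrl.std(ddof=1)
    out = well_summary.set_index("well_id")["bead_intensity"] > thr
    return out.rename("secretion")


# ---------------------------------------------------------------------------
# chip-level driver


@dataclass
class ChipAnalysis:
    """Tables produced by the kinetics/annotation stage of one chip."""

    selected_wells: list
    conjugations: pd.DataFrame  # one row per detected interval
    kinetics: pd.DataFrame  # one row per (effector, target) pair with >= 1 interval
    annotations: pd.DataFrame  # one row per baseline (conjugated) effector
    secretion: pd.Series  # per selected well
    deaths: pd.DataFrame  # per target with a called death


def analyze_chip(
    tracks: pd.DataFrame,
    bead_endpoint: pd.DataFrame,
    slack_um: float = 2.0,
    min_duration_min: float = 5.0,
    gap_max: int = 1,
    annexin_threshold: float = 50.0,
    death_run_k: int = 2,
    max_latency_min: float = 120.0,
    secretion_k: float = 3.0,
    e_count: int = 1,
    t_range: tuple = (1, 5),
    bead_min: int = 1,
) -> ChipAnalysis:
    """Full kinetics + annotation pass over a track table.

    Control wells for the secretion threshold are wells with beads and no
    effector.  Kill attribution: a called target death is credited to the
    effector iff some shared conjugation interval starts before the death
    and ends at most ``max_latency_min`` before it.
    """
    frame_interval = _frame_interval(tracks)
    selected = select_wells(
        tracks, e_count, t_range[0], t_range[1], bead_min, annexin_threshold
    )

    summary = _imaging.bead_endpoint_intensity(bead_endpoint)
    f0 = tracks[tracks["frame"] == 0]
    eff_counts = (
        f0[f0["role"] == "effector"].groupby("well_id")["object_id"].nunique()
    )
    control_wells = [
        w for w in summary["well_id"] if eff_counts.get(w, 0) == 0
    ]
    control_summary = summary[summary["well_id"].isin(control_wells)]
    secretion = call_secretion(
        summary[summary["well_id"].isin(selected)], control_summary, k=secretion_k
    )

    conj_rows, kin_rows, ann_rows, death_rows = [], [], [], []
    for well_id in selected:
        wtracks = tracks[tracks["well_id"] == well_id]
        eff_ids = wtracks.loc[wtracks["role"] == "effector", "object_id"].unique()
        tgt_ids = wtracks.loc[wtracks["role"] == "target", "object_id"].unique()
        eid = eff_ids[0]
        eff_chain = wtracks[wtracks["object_id"] == eid]

        n_kills = 0
        any_conj = False
        for tid in tgt_ids:
            tchain = wtracks[wtracks["object_id"] == tid].sort_values("frame")
            ivs = detect_conjugations(
                eff_chain, tchain, slack_um, min_duration_min, gap_max
            )
            death_frame = _imaging.call_death(
                tchain, threshold=annexin_threshold, k=death_run_k
            )
            death_min = (
                None if death_frame is None else float(death_frame) * frame_interval
            )
            if death_frame is not None:
                death_rows.append((well_id, tid, death_frame, death_min))
            for iv in ivs:
                conj_rows.append(
                    (
                        well_id,
                        eid,
                        tid,
                        iv.start_min,
                        iv.end_min,
                        iv.duration_min,
                    )
                )
            if not ivs:
                continue
            any_conj = True
            attributed = death_min is not None and any(
                iv.start_min < death_min
                and death_min - iv.end_min <= max_latency_min
                for iv in ivs
            )
            rec = compute_kinetics(
                ivs,
                death_min if attributed else None,
                assay_start_min=0.0,
                frame_interval_min=frame_interval,
            )
            if rec is None:
                continue
            if rec.killed and rec.valid:
                n_kills += 1
            kin_rows.append(
                (
                    well_id,
                    rec.effector_id,
                    rec.target_id,
                    rec.t_seek,
                    rec.t_contact,
                    rec.t_death,
                    rec.killed,
                    rec.valid,
                )
            )
        secr = bool(secretion.get(well_id, False))
        label = annotate_function(n_kills, secr, any_conj)
        if label is not None:
            ann_rows.append(
                (
                    well_id,
                    eid,
                    n_kills,
                    label.killer_class,
                    label.secretion,
                    label.function_class,
                )
            )

    return ChipAnalysis(
        selected_wells=selected,
        conjugations=pd.DataFrame(
            conj_rows,
            columns=["well_id", "effector_id", "target_id", "start_min", "end_min", "duration_min"],
        ),
        kinetics=pd.DataFrame(
            kin_rows,
            columns=[
                "well_id",
                "effector_id",
                "target_id",
                "t_seek",
                "t_contact",
                "t_death",
                "killed",
                "valid",
            ],
        ),
        annotations=pd.DataFrame(
            ann_rows,
            columns=[
                "well_id",
                "effector_id",
                "n_kills",
                "killer_class",
                "secretion",
                "function_class",
            ],
        ),
        secretion=secretion,
        deaths=pd.DataFrame(
            death_rows, columns=["well_id", "target_id", "death_frame", "death_min"]
        ),
    )


def _frame_interval(tracks: pd.DataFrame) -> float:
    t = np.sort(tracks["t_min"].unique())
    if t.size < 2:
        raise ValueError("track table has fewer than two frames")
    return float(np.min(np.diff(t)))
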