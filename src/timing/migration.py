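"""Directional-migration metrics per effector.

"Migration" here means directional movement: a run of consecutive steps
whose direction stays within an angular tolerance of the run's
cumulative displacement, retained only when the net displacement reaches
at least one cell diameter.  Frames are partitioned into in-contact
(inside a conjugation interval) and out-of-contact states; runs never
span a state change, and each state's migration rate is the summed run
displacement divided by the total time spent in the state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DirectionalRun",
    "MigrationRecord",
    "partition_frames",
    "directional_runs",
    "migration_rates",
    "aspect_ratio_profile",
    "migration_table",
]


@dataclass
class DirectionalRun:
    start_idx: int
    end_idx: int  # inclusive index of the last point in the run
    start_min: float
    end_min: float
    displacement_um: float


@dataclass
class MigrationRecord:
    effector_id: str
    out_of_contact_rate: float  # um/min of directional displacement
    in_contact_rate: float
    migratory_flag: bool
    cell_diameter_um: float
    runs: list = field(default_factory=list)


def partition_frames(times_min: np.ndarray, intervals) -> np.ndarray:
    """Label each frame in_contact iff it falls inside any conjugation
    interval [start_min, end_min) of the effector."""
    t = np.asarray(times_min, dtype=float)
    labels = np.zeros(t.size, dtype=bool)
    for iv in intervals:
        labels |= (t >= iv.start_min) & (t < iv.end_min)
    return np.where(labels, "in_contact", "out_of_contact")


def directional_runs(
    xy: np.ndarray,
    times_min: np.ndarray,
    cell_diameter_um: float,
    angle_tol_deg: float = 45.0,
) -> list[DirectionalRun]:
    """Maximal directionally persistent runs in a centroid series.

    A run grows while each new step stays within ``angle_tol_deg`` of the
    run's cumulative displacement direction (zero-length steps are always
    compatible); it is retained iff its net displacement is at least one
    cell diameter.  Series with fewer than 3 frames yield no runs.
    """
    xy = np.asarray(xy, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] != t.size:
        raise ValueError("xy must be (n, 2) matching times")
    n = xy.shape[0]
    if n < 3:
        return []
    cos_tol = math.cos(math.radians(angle_tol_deg))
    eps = 1e-9

    runs = []
    start = 0
    i = 0
    while i < n - 1:
        cum = xy[i] - xy[start]
        step = xy[i + 1] - xy[i]
        ok = True
        if i > start:
            nc, ns = np.hypot(*cum), np.hypot(*step)
            if ns > eps and nc > eps:
                ok = float(np.dot(cum, step)) / (nc * ns) >= cos_tol
        if ok:
            i += 1
            continue
        runs.append((start, i))
        start = i
    runs.append((start, n - 1))

    out = []
    for s, e in runs:
        if e <= s:
            continue
        disp = float(np.hypot(*(xy[e] - xy[s])))
        if disp >= cell_diameter_um:
            out.append(DirectionalRun(s, e, float(t[s]), float(t[e]), disp))
    return out


def migration_rates(
    chain: pd.DataFrame,
    intervals,
    angle_tol_deg: float = 45.0,
    migratory_threshold: float | None = None,
) -> MigrationRecord:
    """Per-state directional migration rates for one effector chain.

    Runs are computed within contiguous same-state segments so no run
    spans a contact-state change.  ``migratory_flag`` is True when any
    retained out-of-contact run exists (or, with ``migratory_threshold``,
    when the out-of-contact rate exceeds it).
    """
    chain = chain.sort_values("frame")
    t = chain["t_min"].to_numpy(dtype=float)
    xy = chain[["x_um", "y_um"]].to_numpy(dtype=float)
    diameter = 2.0 * math.sqrt(
        float(chain["area_um2"].median()) / math.pi
    )
    labels = partition_frames(t, intervals)

    state_time = {"in_contact": 0.0, "out_of_contact": 0.0}
    state_disp = {"in_contact": 0.0, "out_of_contact": 0.0}
    all_runs = {"in_contact": [], "out_of_contact": []}
    if t.size >= 2:
        # time in a state counts the steps starting in it, so a 13-frame
        # track spans 12 intervals (60 min at 5-min sampling)
        dt = float(np.min(np.diff(t)))
        for state in state_time:
            state_time[state] = dt * int((labels[:-1] == state).sum())
    # contiguous same-state segments
    seg_start = 0
    for i in range(1, t.size + 1):
        if i == t.size or labels[i] != labels[seg_start]:
            state = str(labels[seg_start])
            seg = slice(seg_start, i)
            runs = directional_runs(
                xy[seg], t[seg], diameter, angle_tol_deg
            )
            for r in runs:
                state_disp[state] += r.displacement_um
            all_runs[state].extend(runs)
            seg_start = i

    def rate(state):
        if state_time[state] <= 0:
            return float("nan")
        return state_disp[state] / state_time[state]

    out_rate = rate("out_of_contact")
    in_rate = rate("in_contact")
    if migratory_threshold is None:
        flag = len(all_runs["out_of_contact"]) > 0
    else:
        flag = (not math.isnan(out_rate)) and out_rate > migratory_threshold
    eid = str(chain["object_id"].iloc[0]) if "object_id" in chain else ""
    return MigrationRecord(
        effector_id=eid,
        out_of_contact_rate=out_rate,
        in_contact_rate=in_rate,
        migratory_flag=bool(flag),
        cell_diameter_um=diameter,
        runs=all_runs,
    )


def aspect_ratio_profile(chain: pd.DataFrame) -> np.ndarray:
    """Per-frame polarization (major/minor axis ratio) of an effector.

    Uses the ``aspect`` column (simulation or segmentation); degenerate
    values are clamped to 1."""
    if "aspect" not in chain.columns:
        raise ValueError("chain has no aspect column")
    a = chain.sort_values("frame")["aspect"].to_numpy(dtype=float)
    a = np.where(np.isfinite(a) & (a >= 1.0), a, 1.0)
    return a


def migration_table(
    tracks: pd.DataFrame,
    conjugations: pd.DataFrame,
    wells,
    angle_tol_deg: float = 45.0,
) -> pd.DataFrame:
    """Per-effector migration records across the selected wells."""
    from .kinetics import ConjugationInterval

    rows = []
    for well_id in wells:
        wtracks = tracks[tracks["well_id"] == well_id]
        eff_ids = wtracks.loc[wtracks["role"] == "effector", "object_id"].unique()
        if len(eff_ids) != 1:
            continue
        eid = eff_ids[0]
        chain = wtracks[wtracks["object_id"] == eid]
        wconj = conjugations[conjugations["well_id"] == well_id]
        intervals = [
            ConjugationInterval(
                effector_id=r.effector_id,
                target_id=r.target_id,
                start_min=r.start_min,
                end_min=r.end_min,
                duration_min=r.duration_min,
            )
            for r in wconj.itertuples(index=False)
        ]
        rec = migration_rates(chain, intervals, angle_tol_deg)
        rows.append(
            (
                well_id,
                eid,
                rec.out_of_contact_rate,
                rec.in_contact_rate,
                rec.migratory_flag,
                rec.cell_diameter_um,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "well_id",
            "effector_id",
            "out_of_contact_rate",
            "in_contact_rate",
            "migratory_flag",
            "cell_diameter_um",
        ],
    )
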