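"""Ground-truthed synthetic data for every stage of the analysis.

Emulates a nanowell time-lapse cytotoxicity assay: each well of a chip
confines one effector T cell with 1-5 tumor targets and one or more
cytokine-capture beads, imaged at a fixed interval (default 5 min) for a
fixed duration (default 6 h).  Effectors move as persistent random walks;
on reaching a target they conjugate for a sampled duration, may kill it
(apoptosis-reporter onset follows detachment after a sampled latency),
and IFN-gamma captured on the beads accrues with cumulative conjugation
time.  The generator records the full event log (conjugation intervals,
kill times, secretion) as ground truth, so every downstream detector can
be scored against what actually happened.

Also provides generators for the two tabular cohorts used downstream: a
single-cell qPCR Ct matrix whose effect genes covary with migration, and
a clinical cohort whose progression-free-survival hazard depends on an
IHC H-score threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical as _clinical
from . import expression as _expression

__all__ = [
    "AssayConfig",
    "BehaviorProfile",
    "SampledDuration",
    "ChipDataset",
    "GroundTruth",
    "default_behaviors",
    "simulate_chip",
    "simulate_qpcr_cohort",
    "simulate_clinical_cohort",
    "QPCR_PANEL",
    "MIGRATION_GENES",
]

TRACK_COLUMNS = [
    "well_id",
    "object_id",
    "role",
    "frame",
    "t_min",
    "x_um",
    "y_um",
    "area_um2",
    "aspect",
    "ch_eff",
    "ch_tgt",
    "ch_annexin",
]


@dataclass
class SampledDuration:
    """Lognormal duration (minutes) clipped to [minimum, maximum].

    ``median`` is the distribution median; ``sigma`` the log-scale spread.
    """

    median: float
    sigma: float = 0.35
    minimum: float = 10.0
    maximum: float = float("inf")

    def sample(self, rng: np.random.Generator) -> float:
        v = self.median * math.exp(self.sigma * rng.standard_normal())
        return float(min(max(v, self.minimum), self.maximum))


@dataclass
class AssayConfig:
    """Geometry and sampling of one chip run."""

    frame_interval_min: float = 5.0
    duration_h: float = 6.0
    wells: int = 100
    well_size_um: float = 65.0
    #: count distributions as {count: weight}; weights are normalized
    e_per_well: dict = field(default_factory=lambda: {0: 0.12, 1: 0.78, 2: 0.10})
    t_per_well: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.25, 3: 0.25, 4: 0.20, 5: 0.15}
    )
    beads_per_well: dict = field(default_factory=lambda: {1: 0.4, 2: 0.4, 3: 0.2})
    effector_radius_um: float = 4.5
    target_radius_um: float = 5.5
    bead_radius_um: float = 1.5
    bead_baseline_intensity: float = 100.0
    bead_noise_sigma: float = 0.03
    rng_seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(self.duration_h * 60.0 / self.frame_interval_min) + 1

    def validate(self) -> None:
        if self.frame_interval_min <= 0 or self.duration_h <= 0:
            raise ValueError("frame interval and duration must be positive")
        if self.wells <= 0:
            raise ValueError("chip must contain at least one well")
        big = 2 * max(self.effector_radius_um, self.target_radius_um)
        if big >= self.well_size_um:
            raise ValueError("cells larger than the well: impossible geometry")
        for dist in (self.e_per_well, self.t_per_well, self.beads_per_well):
            if not dist or any(w < 0 for w in dist.values()):
                raise ValueError("count distributions need non-negative weights")


@dataclass
class BehaviorProfile:
    """Parameters of one effector phenotype."""

    phenotype_label: str
    migration_speed_um_min: float
    directional_persistence: float
    kill_prob_per_contact: float
    contact_duration_min: SampledDuration
    death_latency_after_detach_min: SampledDuration
    secretion_rate_per_contact_min: float

    def validate(self) -> None:
        if self.migration_speed_um_min < 0 or self.secretion_rate_per_contact_min < 0:
            raise ValueError("rates must be non-negative")
        for p in (self.directional_persistence, self.kill_prob_per_contact):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def default_behaviors() -> dict[str, BehaviorProfile]:
    """The four canonical phenotypes spanning the functional taxonomy.

    migratory_killer: fast, persistent, kills without secreting (single
    kills are monofunctional-kill; serial kills multifunctional).
    serial_killer: fastest, short synapses, near-certain kills, secretes.
    monofunctional_secretor: slow, long synapses, never kills, secretes.
    nonmigratory_nonkiller: slow and erratic; occasional conjugation with
    neither kill nor secretion (nonfunctional baseline).
    """
    return {
        "migratory_killer": BehaviorProfile(
            "migratory_killer",
            migration_speed_um_min=2.5,
            directional_persistence=0.85,
            kill_prob_per_contact=0.85,
            contact_duration_min=SampledDuration(median=25.0, maximum=120.0),
            death_latency_after_detach_min=SampledDuration(
                median=20.0, minimum=5.0, maximum=100.0
            ),
            secretion_rate_per_contact_min=0.0,
        ),
        "serial_killer": BehaviorProfile(
            "serial_killer",
            migration_speed_um_min=3.0,
            directional_persistence=0.9,
            kill_prob_per_contact=0.95,
            contact_duration_min=SampledDuration(median=15.0, maximum=60.0),
            death_latency_after_detach_min=SampledDuration(
                median=15.0, minimum=5.0, maximum=100.0
            ),
            secretion_rate_per_contact_min=3.0,
        ),
        "monofunctional_secretor": BehaviorProfile(
            "monofunctional_secretor",
            migration_speed_um_min=1.3,
            directional_persistence=0.5,
            kill_prob_per_contact=0.0,
            contact_duration_min=SampledDuration(median=120.0, maximum=360.0),
            death_latency_after_detach_min=SampledDuration(median=20.0),
            secretion_rate_per_contact_min=3.0,
        ),
        "nonmigratory_nonkiller": BehaviorProfile(
            "nonmigratory_nonkiller",
            migration_speed_um_min=0.8,
            directional_persistence=0.2,
            kill_prob_per_contact=0.0,
            contact_duration_min=SampledDuration(median=25.0, maximum=120.0),
            death_latency_after_detach_min=SampledDuration(median=20.0),
            secretion_rate_per_contact_min=0.0,
        ),
    }


@dataclass
class ChipDataset:
    """Synthetic chip: per-frame track table + end-point bead readout."""

    config: AssayConfig
    tracks: pd.DataFrame
    bead_endpoint: pd.DataFrame  # well_id, bead_id, intensity
    wells: pd.DataFrame  # well_id, n_effectors, n_targets, n_beads


@dataclass
class GroundTruth:
    """Event log and derived true labels for a simulated chip."""

    conjugations: pd.DataFrame  # well_id, effector_id, target_id, frames
    kills: pd.DataFrame  # well_id, effector_id, target_id, conj_end_frame, death_frame
    labels: pd.DataFrame  # per-well phenotype + true functional labels


# ---------------------------------------------------------------------------
# chip simulation


def _sample_count(rng, dist: dict) -> int:
    keys = np.array(sorted(dist))
    w = np.array([dist[k] for k in keys], dtype=float)
    w = w / w.sum()
    return int(rng.choice(keys, p=w))


def _place_objects(rng, cfg: AssayConfig, n_eff, n_tgt, n_bead):
    """Non-overlapping initial positions; effector starts out of contact."""
    L = cfg.well_size_um
    radii = (
        [cfg.effector_radius_um] * n_eff
        + [cfg.target_radius_um] * n_tgt
        + [cfg.bead_radius_um] * n_bead
    )
    roles = ["effector"] * n_eff + ["target"] * n_tgt + ["bead"] * n_bead
    pos = []
    for i, r in enumerate(radii):
        ok = False
        for _ in range(4000):
            p = rng.uniform(r + 0.5, L - r - 0.5, size=2)
            ok = True
            for j, q in enumerate(pos):
                # 2 um clearance so initial frames rasterize as separate objects
                min_sep = r + radii[j] + 2.0
                # effectors start clearly out of contact with targets
                if {roles[i], roles[j]} == {"effector", "target"}:
                    min_sep = cfg.effector_radius_um + cfg.target_radius_um + 4.0
                if np.hypot(*(p - q)) < min_sep:
                    ok = False
                    break
            if ok:
                pos.append(p)
                break
        if not ok:
            raise ValueError("could not place objects without overlap")
    return np.array(pos), roles


def _reflect(p, lo, hi):
    x = p.copy()
    for k in range(2):
        if x[k] < lo[k]:
            x[k] = 2 * lo[k] - x[k]
        if x[k] > hi[k]:
            x[k] = 2 * hi[k] - x[k]
        x[k] = min(max(x[k], lo[k]), hi[k])
    return x


def _simulate_well(rng, cfg: AssayConfig, profile, n_eff, n_tgt, n_bead, well_id):
    """Event-driven per-well simulation. Returns (rows, events)."""
    dt = cfg.frame_interval_min
    nf = cfg.n_frames
    L = cfg.well_size_um
    re_, rt_, rb_ = cfg.effector_radius_um, cfg.target_radius_um, cfg.bead_radius_um
    pos, roles = _place_objects(rng, cfg, n_eff, n_tgt, n_bead)

    eff_idx = [i for i, r in enumerate(roles) if r == "effector"]
    tgt_idx = [i for i, r in enumerate(roles) if r == "target"]
    radii = {"effector": re_, "target": rt_, "bead": rb_}

    engage = n_eff == 1  # conjugation dynamics only for single-effector wells
    engage_dist = re_ + rt_ + 1.0
    pin_dist = 0.85 * (re_ + rt_)

    # effector state machines
    direction = {i: rng.uniform(0, 2 * math.pi) for i in eff_idx}
    state = {i: "free" for i in eff_idx}
    conj_target = {}
    conj_left = {}
    conj_kill = {}
    refractory = {i: 0 for i in eff_idx}
    death_frame = {j: None for j in tgt_idx}  # annexin onset frame
    current_frames: dict = {}

    conj_log = []  # dicts: effector obj, target obj, list of contact frames, kill
    rows = []

    def record(frame):
        t = frame * dt
        for i, role in enumerate(roles):
            r = radii[role]
            area = math.pi * r * r * (1.0 + 0.05 * rng.standard_normal())
            area = max(area, 1.0)
            aspect = 1.0
            ch_eff, ch_tgt, ch_ann = 4.0, 4.0, 3.0
            if role == "effector":
                ch_eff = 150.0 + 5 * rng.standard_normal()
                step = speed_step.get(i, 0.0)
                aspect = 1.0 + 1.2 * min(1.0, step / (2 * r))
            elif role == "target":
                ch_tgt = 150.0 + 5 * rng.standard_normal()
                if death_frame[i] is not None and frame >= death_frame[i]:
                    ch_ann = 150.0 + 5 * rng.standard_normal()
            rows.append(
                (
                    well_id,
                    f"{well_id}_o{i}",
                    role,
                    frame,
                    t,
                    pos[i, 0],
                    pos[i, 1],
                    area,
                    aspect,
                    ch_eff,
                    ch_tgt,
                    abs(ch_ann),
                )
            )

    speed_step = {}
    for frame in range(nf):
        if frame > 0:
            # targets: slow jitter; dead targets stop
            for j in tgt_idx:
                if death_frame[j] is not None and frame >= death_frame[j]:
                    continue
                if any(
                    state[i] == "conj" and conj_target.get(i) == j for i in eff_idx
                ):
                    continue  # conjugated target held by the synapse
                step = 0.15 * dt
                ang = rng.uniform(0, 2 * math.pi)
                pos[j] = _reflect(
                    pos[j] + step * np.array([math.cos(ang), math.sin(ang)]),
                    np.array([rt_, rt_]),
                    np.array([L - rt_, L - rt_]),
                )
            for i in eff_idx:
                if state[i] == "conj":
                    j = conj_target[i]
                    ang = direction[i]
                    pos[i] = _reflect(
                        pos[j]
                        + pin_dist * np.array([math.cos(ang), math.sin(ang)])
                        + 0.3 * rng.standard_normal(2),
                        np.array([re_, re_]),
                        np.array([L - re_, L - re_]),
                    )
                    speed_step[i] = 0.0
                    current_frames[i].append(frame)
                    conj_left[i] -= 1
                    if conj_left[i] <= 0:
                        # detach: log the interval, schedule death if killing
                        frames = current_frames.pop(i)
                        kill = conj_kill[i]
                        entry = {
                            "effector": i,
                            "target": j,
                            "frames": frames,
                            "kill": False,
                        }
                        if kill:
                            latency = profile.death_latency_after_detach_min.sample(rng)
                            df_ = frames[-1] + max(1, round(latency / dt))
                            death_frame[j] = df_
                            entry["kill"] = True
                            entry["death_frame"] = df_
                        conj_log.append(entry)
                        state[i] = "free"
                        del conj_target[i]
                        refractory[i] = 2
                        # step away radially, outside the detection slack
                        away = pos[i] - pos[j]
                        nrm = np.hypot(*away)
                        away = away / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
                        direction[i] = math.atan2(away[1], away[0])
                        pos[i] = _reflect(
                            pos[j] + (re_ + rt_ + 3.5) * away,
                            np.array([re_, re_]),
                            np.array([L - re_, L - re_]),
                        )
                    continue
                # free motion: persistent random walk
                if rng.uniform() > profile.directional_persistence:
                    direction[i] = rng.uniform(0, 2 * math.pi)
                step = profile.migration_speed_um_min * dt
                step *= max(0.2, 1.0 + 0.25 * rng.standard_normal())
                newp = pos[i] + step * np.array(
                    [math.cos(direction[i]), math.sin(direction[i])]
                )
                newp = _reflect(
                    newp, np.array([re_, re_]), np.array([L - re_, L - re_])
                )
                speed_step[i] = float(np.hypot(*(newp - pos[i])))
                pos[i] = newp
                if refractory[i] > 0:
                    refractory[i] -= 1
                elif engage:
                    # only targets with no kill already scheduled can be engaged
                    live = [j for j in tgt_idx if death_frame[j] is None]
                    near = [
                        j
                        for j in live
                        if np.hypot(*(pos[i] - pos[j])) <= engage_dist
                    ]
                    if near:
                        j = min(near, key=lambda j: np.hypot(*(pos[i] - pos[j])))
                        dur = profile.contact_duration_min.sample(rng)
                        n_contact = max(2, round(dur / dt))
                        state[i] = "conj"
                        conj_target[i] = j
                        conj_left[i] = n_contact - 1
                        conj_kill[i] = rng.uniform() < profile.kill_prob_per_contact
                        current_frames[i] = [frame]
                        ang = math.atan2(*(pos[i] - pos[j])[::-1])
                        direction[i] = ang
                        pos[i] = _reflect(
                            pos[j] + pin_dist * np.array([math.cos(ang), math.sin(ang)]),
                            np.array([re_, re_]),
                            np.array([L - re_, L - re_]),
                        )
                        speed_step[i] = 0.0
        record(frame)

    # close any conjugation still open at assay end (no kill can be observed)
    for i in list(current_frames):
        conj_log.append(
            {
                "effector": i,
                "target": conj_target[i],
                "frames": current_frames.pop(i),
                "kill": False,
            }
        )

    return rows, conj_log, death_frame


def _true_labels(profile, conj_log, death_frame, nf, dt, secretes):
    """Derive the true functional labels from the event log."""
    observable_kills = [
        e
        for e in conj_log
        if e["kill"] and e.get("death_frame", nf) <= nf - 2
    ]
    n_kills = len(observable_kills)
    conjugated = any(len(e["frames"]) >= 2 for e in conj_log)
    cum_min = dt * sum(len(e["frames"]) for e in conj_log)
    secretion = bool(secretes and cum_min > 0)
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
    if not conjugated:
        fc = None
    return n_kills, conjugated, cum_min, secretion, killer_class, fc


def simulate_chip(
    config: AssayConfig,
    behaviors=None,
    weights=None,
) -> tuple[ChipDataset, GroundTruth]:
    """Simulate a whole chip; returns the dataset and its ground truth.

    ``behaviors`` is a list of :class:`BehaviorProfile` and ``weights`` the
    matching mixture weights (must sum to 1).  Defaults to the four
    canonical phenotypes in equal-ish proportions.
    """
    config.validate()
    if behaviors is None:
        profs = default_behaviors()
        behaviors = [
            profs["migratory_killer"],
            profs["serial_killer"],
            profs["monofunctional_secretor"],
            profs["nonmigratory_nonkiller"],
        ]
        weights = [0.3, 0.2, 0.2, 0.3]
    if weights is None:
        weights = [1.0 / len(behaviors)] * len(behaviors)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    for b in behaviors:
        b.validate()

    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval_min
    nf = config.n_frames

    all_rows = []
    bead_rows = []
    well_rows = []
    conj_rows = []
    kill_rows = []
    label_rows = []

    for w in range(config.wells):
        well_id = f"W{w:04d}"
        n_eff = _sample_count(rng, config.e_per_well)
        n_tgt = _sample_count(rng, config.t_per_well)
        n_bead = _sample_count(rng, config.beads_per_well)
        profile = behaviors[int(rng.choice(len(behaviors), p=weights))]

        rows, conj_log, death_frame = _simulate_well(
            rng, config, profile, n_eff, n_tgt, n_bead, well_id
        )
        all_rows.extend(rows)
        well_rows.append((well_id, n_eff, n_tgt, n_bead))

        cum_min = dt * sum(len(e["frames"]) for e in conj_log)
        rate = profile.secretion_rate_per_contact_min if n_eff == 1 else 0.0
        for b in range(n_bead):
            level = config.bead_baseline_intensity + rate * cum_min
            noise = math.exp(config.bead_noise_sigma * rng.standard_normal())
            bead_rows.append((well_id, f"{well_id}_b{b}", level * noise))

        for e in conj_log:
            conj_rows.append(
                (
                    well_id,
                    f"{well_id}_o{e['effector']}",
                    f"{well_id}_o{e['target']}",
                    e["frames"][0],
                    e["frames"][-1],
                    len(e["frames"]),
                )
            )
            if e["kill"] and e["death_frame"] <= nf - 2:
                kill_rows.append(
                    (
                        well_id,
                        f"{well_id}_o{e['effector']}",
                        f"{well_id}_o{e['target']}",
                        e["frames"][-1],
                        e["death_frame"],
                    )
                )

        if n_eff == 1:
            nk, conj, cmin, secr, kc, fc = _true_labels(
                profile,
                conj_log,
                death_frame,
                nf,
                dt,
                profile.secretion_rate_per_contact_min > 0,
            )
            label_rows.append(
                (well_id, profile.phenotype_label, nk, conj, cmin, secr, kc, fc)
            )
        else:
            label_rows.append((well_id, None, 0, False, 0.0, False, None, None))

    tracks = pd.DataFrame(all_rows, columns=TRACK_COLUMNS)
    dataset = ChipDataset(
        config=config,
        tracks=tracks,
        bead_endpoint=pd.DataFrame(
            bead_rows, columns=["well_id", "bead_id", "intensity"]
        ),
        wells=pd.DataFrame(
            well_rows, columns=["well_id", "n_effectors", "n_targets", "n_beads"]
        ),
    )
    truth = GroundTruth(
        conjugations=pd.DataFrame(
            conj_rows,
            columns=[
                "well_id",
                "effector_id",
                "target_id",
                "start_frame",
                "end_frame",
                "n_frames",
            ],
        ),
        kills=pd.DataFrame(
            kill_rows,
            columns=["well_id", "effector_id", "target_id", "conj_end_frame", "death_frame"],
        ),
        labels=pd.DataFrame(
            label_rows,
            columns=[
                "well_id",
                "phenotype",
                "n_kills",
                "conjugated",
                "cum_conj_min",
                "secretion",
                "killer_class",
                "function_class",
            ],
        ),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# qPCR cohort

MIGRATION_GENES = ["CD2", "CD58", "CD244", "CXCR3", "IL18R1", "LAG3"]

QPCR_PANEL = MIGRATION_GENES + [
    "CAR",
    "FASLG",
    "GZMB",
    "PRF1",
] + [f"TG{i:03d}" for i in range(1, 86)]


def simulate_qpcr_cohort(
    n_migratory: int = 48,
    n_nonmigratory: int = 44,
    n_genes: int = 95,
    effect_genes=None,
    effect_size: float = 1.0,
    noise_sd: float = 0.75,
    lod_ct: float = 40.0,
    n_controls: int = 4,
    seed: int = 0,
):
    """Single-cell qPCR Ct matrix with migration-linked effect genes.

    Effect genes have their Ct reduced (expression raised) in proportion to
    each cell's continuous migration metric; migratory cells have the
    metric shifted up by 1 unit so the group contrast equals
    ``effect_size`` log2 units (Ct cycles).  Includes no-cell and no-RT
    control columns at the detection limit.  Returns
    (:class:`~timing.expression.ExpressionMatrix`, truth dict).
    """
    if not np.isfinite(effect_size):
        raise ValueError("effect_size must be finite")
    if n_genes > len(QPCR_PANEL):
        raise ValueError("panel supports up to %d genes" % len(QPCR_PANEL))
    genes = QPCR_PANEL[:n_genes]
    if effect_genes is None:
        effect_genes = [g for g in MIGRATION_GENES if g in genes]
    if not set(effect_genes) <= set(genes):
        raise ValueError("effect_genes must be a subset of the panel")

    rng = np.random.default_rng(seed)
    cells = [f"mig{i:03d}" for i in range(n_migratory)] + [
        f"non{i:03d}" for i in range(n_nonmigratory)
    ]
    labels = ["migratory"] * n_migratory + ["nonmigratory"] * n_nonmigratory
    metric = np.concatenate(
        [
            1.0 + 0.3 * rng.standard_normal(n_migratory),
            0.0 + 0.3 * rng.standard_normal(n_nonmigratory),
        ]
    )

    base = rng.uniform(24.0, 32.0, size=len(genes))
    ct = base[:, None] + noise_sd * rng.standard_normal((len(genes), len(cells)))
    for g in effect_genes:
        gi = genes.index(g)
        ct[gi] -= effect_size * metric
    ct = np.clip(ct, 5.0, lod_ct)

    ctrl_cols = [f"ctl_nocell{i}" for i in range(n_controls // 2)] + [
        f"ctl_noRT{i}" for i in range(n_controls - n_controls // 2)
    ]
    ct_df = pd.DataFrame(ct, index=genes, columns=cells)
    for c in ctrl_cols:
        ct_df[c] = lod_ct

    all_labels = pd.Series(
        labels + ["control"] * len(ctrl_cols), index=cells + ctrl_cols
    )
    expr = _expression.ct_to_expression(ct_df, lod_ct=lod_ct)
    metric_s = pd.Series(
        np.concatenate([metric, np.full(len(ctrl_cols), np.nan)]),
        index=cells + ctrl_cols,
    )
    matrix = _expression.ExpressionMatrix(
        values=expr, labels=all_labels, lod_ct=lod_ct, migration_metric=metric_s
    )
    truth = {"effect_genes": list(effect_genes), "effect_size": effect_size, "ct": ct_df}
    return matrix, truth


# ---------------------------------------------------------------------------
# clinical cohort


def simulate_clinical_cohort(
    n: int = 40,
    cutoff: float = 80.0,
    hazard_ratio: float = 4.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    median_pfs_high: float = 26.0,
    p_negative: float = 0.3,
) -> pd.DataFrame:
    """Cohort with H-score-dependent PFS hazard.

    Staining percentages come in 10% increments (a fraction ``p_negative``
    of patients stain nowhere, H = 0); PFS is exponential with the hazard
    multiplied by ``hazard_ratio`` for patients below the H-score
    ``cutoff``; response (CR/PD) is drawn with probability increasing in
    the H score.  ``censor_rate`` is the chance a patient is censored at a
    uniform fraction of their event time.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 patients")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= cutoff <= 300:
        raise ValueError("cutoff must lie in [0, 300]")
    rng = np.random.default_rng(seed)
    base_hazard = math.log(2.0) / median_pfs_high

    rows = []
    for i in range(n):
        if rng.uniform() < p_negative:
            mild = mod = intense = 0
        else:
            n_deciles = int(rng.integers(1, 11))
            cats = rng.integers(0, 3, size=n_deciles)
            mild = 10 * int((cats == 0).sum())
            mod = 10 * int((cats == 1).sum())
            intense = 10 * int((cats == 2).sum())
        h = _clinical.h_score(mild, mod, intense)
        lam = base_hazard * (hazard_ratio if h < cutoff else 1.0)
        t = rng.exponential(1.0 / lam)
        event = 1
        if rng.uniform() < censor_rate:
            t *= rng.uniform()
            event = 0
        p_cr = 1.0 / (1.0 + math.exp(-(h - cutoff) / 25.0))
        response = "CR" if rng.uniform() < p_cr else "PD"
        rows.append((f"P{i:03d}", mild, mod, intense, h, response, t, event))
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "pct_mild",
            "pct_moderate",
            "pct_intense",
            "h_score",
            "response",
            "pfs_months",
            "event",
        ],
    )
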