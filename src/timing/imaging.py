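"""Image stacks to object tables: segmentation, classification, tracking.

Per-well tiles carry four fluorescence channels (effector dye, target
dye, annexin-V apoptosis reporter, bead channel).  Objects are connected
components above a per-channel threshold (Otsu by default), holes
filled, small specks removed.  Beads are much smaller than cells, so a
size-exclusion rule on area separates the two roles; cells are classed
effector versus target by dye dominance.  Tracking is greedy
nearest-neighbor linking per well and class with bounded step length and
short gap bridging.  Apoptosis onset is the first frame of a sustained
run of annexin positivity.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "segment_frame",
    "segment_chip",
    "size_exclusion_classify",
    "link_tracks",
    "call_death",
    "bead_endpoint_intensity",
    "match_endpoint_to_timelapse",
]

CHANNELS = ("effector", "target", "annexin", "bead")

#: default area boundary between beads and cells (um^2); beads (~3 um
#: diameter, ~7 um^2) sit far below cells (~9-11 um diameter, >60 um^2)
BEAD_AREA_MAX_UM2 = 30.0


def _channel_mask(img: np.ndarray, threshold: float | None) -> np.ndarray:
    if threshold is None:
        if float(np.ptp(img)) < 10.0:  # blank / flat channel
            return np.zeros(img.shape, dtype=bool)
        threshold = threshold_otsu(img)
    return img > threshold


def segment_frame(
    tile: np.ndarray,
    pixel_size_um: float,
    thresholds: dict | None = None,
    min_area_um2: float = 3.0,
    bead_area_max_um2: float = BEAD_AREA_MAX_UM2,
    merged_factor: float = 1.8,
) -> pd.DataFrame:
    """Segment one (channels, H, W) well tile into labeled objects.

    Returns a DataFrame with centroid (um), area (um^2), per-channel mean
    intensities, ``role`` (cell/bead), ``cls`` (effector/target for
    cells), ``aspect`` (major/minor axis ratio) and a ``merged`` flag for
    cell objects whose area exceeds ``merged_factor`` times the median
    cell area (likely touching cells segmented as one).
    """
    if tile.ndim != 3 or tile.shape[0] < len(CHANNELS):
        raise ValueError("tile must be a (channels, H, W) array")
    thresholds = thresholds or {}
    ch = {name: tile[i].astype(float) for i, name in enumerate(CHANNELS)}
    min_area_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))

    # objects are detected per dye channel so that a touching effector and
    # target (distinct membrane dyes) stay separate objects
    rows = []
    for det_name in ("effector", "target", "bead"):
        mask = _channel_mask(ch[det_name], thresholds.get(det_name))
        if not mask.any():
            continue
        mask = ndi.binary_fill_holes(mask)
        labels = sk_label(mask)
        for prop in regionprops(labels):
            if prop.area < min_area_px:
                continue
            area_um2 = float(prop.area) * pixel_size_um**2
            yc, xc = prop.centroid
            sl = labels == prop.label
            means = {name: float(ch[name][sl].mean()) for name in CHANNELS}
            minor = prop.axis_minor_length
            aspect = float(prop.axis_major_length / minor) if minor > 0 else 1.0
            rows.append(
                {
                    "x_um": xc * pixel_size_um,
                    "y_um": yc * pixel_size_um,
                    "area_um2": area_um2,
                    "aspect": aspect,
                    "ch_eff": means["effector"],
                    "ch_tgt": means["target"],
                    "ch_annexin": means["annexin"],
                    "ch_bead": means["bead"],
                }
            )
    if not rows:
        warnings.warn("blank or saturated tile: no objects found", stacklevel=2)
        return _empty_objects()
    objects = pd.DataFrame(rows)
    objects = size_exclusion_classify(objects, bead_area_max_um2)
    cells = objects[objects["role"] == "cell"]
    if len(cells):
        med = float(cells["area_um2"].median())
        objects["merged"] = (objects["role"] == "cell") & (
            objects["area_um2"] > merged_factor * med
        )
    else:
        objects["merged"] = False
    return objects


def _empty_objects() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "x_um",
            "y_um",
            "area_um2",
            "aspect",
            "ch_eff",
            "ch_tgt",
            "ch_annexin",
            "ch_bead",
            "role",
            "cls",
            "merged",
        ]
    )


def size_exclusion_classify(
    objects: pd.DataFrame, bead_area_max_um2: float = BEAD_AREA_MAX_UM2
) -> pd.DataFrame:
    """Assign role by the size-exclusion rule (area <= max -> bead), and
    class cells as effector/target by dye dominance."""
    out = objects.copy()
    out["role"] = np.where(out["area_um2"] <= bead_area_max_um2, "bead", "cell")
    is_cell = out["role"] == "cell"
    out["cls"] = None
    out.loc[is_cell, "cls"] = np.where(
        out.loc[is_cell, "ch_eff"] >= out.loc[is_cell, "ch_tgt"],
        "effector",
        "target",
    )
    return out


def segment_chip(
    stack: np.ndarray,
    sidecar: dict,
    **segment_kwargs,
) -> pd.DataFrame:
    """Segment every well tile of a rendered chip across all frames.

    ``stack`` is (frames, channels, H, W); ``sidecar`` carries the layout
    written by the renderer (pixel size, tile size, well origins) and the
    frame interval.  Returns an unlinked detection table.
    """
    px = float(sidecar["pixel_size_um"])
    tile_px = int(sidecar["tile_px"])
    dt = float(sidecar["frame_interval_min"])
    rows = []
    for well_id, (r0, c0) in sidecar["well_origins"].items():
        for frame in range(stack.shape[0]):
            tile = stack[frame, :, r0 : r0 + tile_px, c0 : c0 + tile_px]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                objs = segment_frame(tile, px, **segment_kwargs)
            for _, o in objs.iterrows():
                rec = o.to_dict()
                rec.update(well_id=well_id, frame=frame, t_min=frame * dt)
                rows.append(rec)
    return pd.DataFrame(rows)


def link_tracks(
    detections: pd.DataFrame,
    max_step_um: float = 20.0,
    gap_max: int = 1,
) -> pd.DataFrame:
    """Greedy nearest-neighbor linking per well and object kind.

    Detections need ``well_id``, ``frame``, ``x_um``, ``y_um``, ``role``
    (and ``cls`` for cells).  Returns the table with ``object_id``
    assigned, ``role`` mapped to effector/target/bead, and a per-row
    ``gap`` count of bridged frames.
    """
    det = detections.copy()
    dup = det.duplicated(subset=["well_id", "frame", "x_um", "y_um"])
    if dup.any():
        raise ValueError("duplicate (frame, position) detections")
    kind = det["role"].astype(str).copy()
    if "cls" in det.columns:
        is_cell = det["role"] == "cell"
        kind[is_cell] = det.loc[is_cell, "cls"].astype(str)
    det["_kind"] = kind
    det["object_id"] = None
    det["gap"] = 0

    for (well_id, k), grp in det.groupby(["well_id", "_kind"], sort=True):
        active: list[dict] = []  # {'id', 'pos', 'frame'}
        counter = 0
        for frame in sorted(grp["frame"].unique()):
            rows = grp[grp["frame"] == frame]
            idxs = list(rows.index)
            pts = rows[["x_um", "y_um"]].to_numpy(dtype=float)
            # candidate (distance, track, detection) pairs
            cands = []
            for ti, tr in enumerate(active):
                span = frame - tr["frame"]
                if span > gap_max + 1:
                    continue
                for di in range(len(idxs)):
                    d = float(np.hypot(*(pts[di] - tr["pos"])))
                    if d <= max_step_um * span:
                        cands.append((d, ti, di))
            cands.sort(key=lambda c: c[0])
            used_t, used_d = set(), set()
            for d, ti, di in cands:
                if ti in used_t or di in used_d:
                    continue
                used_t.add(ti)
                used_d.add(di)
                tr = active[ti]
                det.loc[idxs[di], "object_id"] = tr["id"]
                det.loc[idxs[di], "gap"] = frame - tr["frame"] - 1
                tr["pos"] = pts[di]
                tr["frame"] = frame
            for di in range(len(idxs)):
                if di in used_d:
                    continue
                oid = f"{well_id}_{k}{counter}"
                counter += 1
                det.loc[idxs[di], "object_id"] = oid
                active.append({"id": oid, "pos": pts[di], "frame": frame})
            active = [t for t in active if frame - t["frame"] <= gap_max]

    det["role"] = det["_kind"].map(
        lambda k: k if k in ("effector", "target") else "bead"
    )
    return det.drop(columns=["_kind"])


def call_death(
    target_chain: pd.DataFrame,
    threshold: float = 50.0,
    k: int = 2,
) -> int | None:
    """Apoptosis onset: first frame of the earliest run of >= k consecutive
    frames with annexin mean intensity above ``threshold``; None if absent."""
    if len(target_chain) == 0:
        raise ValueError("empty target chain")
    chain = target_chain.sort_values("frame")
    frames = chain["frame"].to_numpy()
    hot = (chain["ch_annexin"].to_numpy(dtype=float) > threshold).astype(int)
    run = 0
    for i, h in enumerate(hot):
        if h and (run == 0 or frames[i] == frames[i - 1] + 1):
            run += 1
        elif h:
            run = 1
        else:
            run = 0
        if run >= k:
            return int(frames[i - k + 1])
    return None


def bead_endpoint_intensity(
    bead_table: pd.DataFrame,
    wells=None,
    value_col: str = "intensity",
) -> pd.DataFrame:
    """Per-well summary (median) of per-bead end-point intensities.

    ``bead_table`` has one row per bead (``well_id``, intensity column).
    Wells listed in ``wells`` but absent from the table get NaN and are
    flagged in the ``missing_beads`` column.
    """
    if value_col not in bead_table.columns:
        raise ValueError(f"bead table lacks column {value_col!r}")
    grouped = bead_table.groupby("well_id")[value_col]
    out = pd.DataFrame(
        {"bead_intensity": grouped.median(), "n_beads": grouped.size()}
    ).reset_index()
    if wells is not None:
        out = pd.DataFrame({"well_id": list(wells)}).merge(
            out, on="well_id", how="left"
        )
        out["n_beads"] = out["n_beads"].fillna(0).astype(int)
    out["missing_beads"] = out["n_beads"] == 0
    return out


def match_endpoint_to_timelapse(
    timelapse_wells: pd.DataFrame,
    endpoint_wells: pd.DataFrame,
    on: str = "well_id",
):
    """Inner-join time-lapse and end-point tables on well id.

    Returns (joined, unmatched_timelapse, unmatched_endpoint).  Duplicate
    keys on either side are an error.
    """
    for name, df in (("timelapse", timelapse_wells), ("endpoint", endpoint_wells)):
        if df[on].duplicated().any():
            raise ValueError(f"duplicate {on} in {name} table")
    joined = timelapse_wells.merge(endpoint_wells, on=on, how="inner")
    left_only = sorted(set(timelapse_wells[on]) - set(endpoint_wells[on]))
    right_only = sorted(set(endpoint_wells[on]) - set(timelapse_wells[on]))
    return joined, left_only, right_only
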