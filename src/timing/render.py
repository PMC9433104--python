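"""Render a simulated chip into a multi-channel image stack.

Objects are drawn as filled ellipses (axis-aligned, elongation from the
track's aspect ratio) into four channels — effector dye, target dye,
annexin (on from apoptosis onset), bead — laid out as one tile per well
on a dark background.  The sidecar dict records everything a reader
needs: channel order, pixel size, tile size, per-well tile origins and
the frame interval.  No optics are modeled beyond additive Gaussian
camera noise.
"""

from __future__ import annotations

import json
import math

import numpy as np
from skimage.draw import ellipse as sk_ellipse

from .imaging import CHANNELS
from .synthetic import ChipDataset

__all__ = ["render_frames", "save_stack"]

FOREGROUND = 150.0
BEAD_VALUE = 200.0
BACKGROUND = 3.0


def render_frames(
    chip: ChipDataset,
    pixel_size_um: float = 1.0,
    noise_sd: float = 1.0,
    wall_px: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Rasterize every well and frame; returns (stack, sidecar).

    ``stack`` has shape (frames, channels, H, W) in float32; channels are
    effector / target / annexin / bead.
    """
    cfg = chip.config
    tile_px = int(round(cfg.well_size_um / pixel_size_um))
    if tile_px <= 0:
        raise ValueError("degenerate well geometry")
    wells = list(chip.wells["well_id"])
    ncols = max(1, int(math.ceil(math.sqrt(len(wells)))))
    nrows = int(math.ceil(len(wells) / ncols))
    H = nrows * tile_px + (nrows + 1) * wall_px
    W = ncols * tile_px + (ncols + 1) * wall_px
    origins = {}
    for i, wid in enumerate(wells):
        r, c = divmod(i, ncols)
        origins[wid] = (
            wall_px + r * (tile_px + wall_px),
            wall_px + c * (tile_px + wall_px),
        )

    nf = cfg.n_frames
    rng = np.random.default_rng(seed)
    stack = np.full((nf, len(CHANNELS), H, W), BACKGROUND, dtype=np.float32)
    stack += rng.normal(0.0, noise_sd, size=stack.shape).astype(np.float32)

    chan_index = {name: i for i, name in enumerate(CHANNELS)}
    for row in chip.tracks.itertuples(index=False):
        r0, c0 = origins[row.well_id]
        frame = int(row.frame)
        r_eq = math.sqrt(max(row.area_um2, 1.0) / math.pi) / pixel_size_um
        aspect = max(float(row.aspect), 1.0)
        a = r_eq * math.sqrt(aspect)  # semi-axes preserving area
        b = r_eq / math.sqrt(aspect)
        cy = r0 + row.y_um / pixel_size_um
        cx = c0 + row.x_um / pixel_size_um
        rr, cc = sk_ellipse(cy, cx, a, b, shape=(H, W))
        if row.role == "effector":
            stack[frame, chan_index["effector"], rr, cc] = FOREGROUND
        elif row.role == "target":
            stack[frame, chan_index["target"], rr, cc] = FOREGROUND
            if row.ch_annexin > 50.0:
                stack[frame, chan_index["annexin"], rr, cc] = FOREGROUND
        else:  # bead
            stack[frame, chan_index["bead"], rr, cc] = BEAD_VALUE

    sidecar = {
        "channels": list(CHANNELS),
        "pixel_size_um": pixel_size_um,
        "tile_px": tile_px,
        "well_size_um": cfg.well_size_um,
        "frame_interval_min": cfg.frame_interval_min,
        "well_origins": origins,
    }
    return stack, sidecar


def save_stack(stack: np.ndarray, sidecar: dict, tiff_path, json_path) -> None:
    """Write the stack as multi-page TIFF plus the sidecar JSON."""
    import tifffile

    tifffile.imwrite(tiff_path, stack.astype(np.float32))
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
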