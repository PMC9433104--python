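"""Segmentation, classification, tracking and end-point extraction tests."""

import numpy as np
import pandas as pd
import pytest

from timing.imaging import (
    bead_endpoint_intensity,
    call_death,
    link_tracks,
    match_endpoint_to_timelapse,
    segment_chip,
    segment_frame,
    size_exclusion_classify,
)
from timing.render import render_frames


def blank_tile(size=64):
    rng = np.random.default_rng(0)
    return np.abs(3.0 + rng.normal(0, 1, size=(4, size, size))).astype(np.float32)


def draw_disc(tile, channel, cy, cx, r, value=150.0):
    yy, xx = np.ogrid[: tile.shape[1], : tile.shape[2]]
    tile[channel][(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value


class TestSegmentFrame:
    def test_blank_tile_empty_with_warning(self):
        with pytest.warns(UserWarning):
            objs = segment_frame(blank_tile(), pixel_size_um=1.0)
        assert len(objs) == 0

    def test_mixed_well_counts_and_classes(self):
        tile = blank_tile()
        draw_disc(tile, 0, 15, 15, 5)  # effector
        for cy, cx in [(40, 15), (15, 45), (45, 45)]:
            draw_disc(tile, 1, cy, cx, 6)  # targets
        draw_disc(tile, 3, 30, 30, 2, 200.0)  # beads
        draw_disc(tile, 3, 55, 10, 2, 200.0)
        objs = segment_frame(tile, pixel_size_um=1.0)
        assert len(objs) == 6
        assert (objs["cls"] == "effector").sum() == 1
        assert (objs["cls"] == "target").sum() == 3
        assert (objs["role"] == "bead").sum() == 2

    def test_touching_targets_get_merged_flag(self):
        tile = blank_tile()
        draw_disc(tile, 1, 30, 26, 6)
        draw_disc(tile, 1, 30, 36, 6)  # touching pair -> one big component
        draw_disc(tile, 1, 10, 50, 6)
        draw_disc(tile, 1, 50, 10, 6)
        objs = segment_frame(tile, pixel_size_um=1.0)
        cells = objs[objs["role"] == "cell"]
        assert len(cells) == 3
        assert cells["merged"].sum() == 1
        big = cells.loc[cells["merged"]].iloc[0]
        assert big["area_um2"] > 1.8 * cells["area_um2"].median()


class TestSizeExclusion:
    @pytest.mark.parametrize("area,expected", [(20.0, "bead"), (120.0, "cell")])
    def test_rule(self, area, expected):
        obj = pd.DataFrame({"area_um2": [area], "ch_eff": [10.0], "ch_tgt": [5.0]})
        assert size_exclusion_classify(obj, 40.0)["role"].iloc[0] == expected

    def test_role_accuracy_on_rendered_chip(self, small_chip):
        """Bead/cell separation is exact when the area distributions are
        disjoint (3 um beads vs 9-11 um cells)."""
        chip, _ = small_chip
        stack, sidecar = render_frames(chip, seed=1)
        det = segment_chip(stack[:1], sidecar)
        truth0 = chip.tracks[chip.tracks["frame"] == 0]
        true_beads = truth0.groupby("well_id").apply(
            lambda g: (g["role"] == "bead").sum(), include_groups=False
        )
        got_beads = det[det["role"] == "bead"].groupby("well_id").size()
        assert (got_beads.reindex(true_beads.index).fillna(0) == true_beads).all()


class TestRoundTrip:
    def test_rendered_chip_recovers_object_counts(self, small_chip):
        """Render -> segment recovers per-well object counts exactly at
        frame 0, where placement guarantees non-touching objects."""
        chip, _ = small_chip
        stack, sidecar = render_frames(chip, seed=2)
        det = segment_chip(stack[:1], sidecar)
        true0 = chip.tracks[chip.tracks["frame"] == 0].groupby("well_id").size()
        got0 = det.groupby("well_id").size()
        assert (got0.reindex(true0.index).fillna(0) == true0).all()

    def test_annexin_channel_follows_death(self, small_chip):
        chip, truth = small_chip
        if len(truth.kills) == 0:
            pytest.skip("no kills at this seed")
        row = truth.kills.iloc[0]
        chain = chip.tracks[chip.tracks["object_id"] == row.target_id]
        pre = chain[chain["frame"] < row.death_frame]["ch_annexin"]
        post = chain[chain["frame"] >= row.death_frame]["ch_annexin"]
        assert (pre < 50).all()
        assert (post > 50).all()


def make_detections(tracks):
    rows = []
    for t, pts in tracks.items():
        for x, y in pts:
            rows.append({"well_id": "W0", "frame": t, "x_um": x, "y_um": y, "role": "cell", "cls": "target"})
    return pd.DataFrame(rows)


class TestLinkTracks:
    def test_single_stationary_object(self):
        det = make_detections({t: [(10.0, 10.0 + 0.01 * t)] for t in range(10)})
        linked = link_tracks(det)
        assert linked["object_id"].nunique() == 1
        assert len(linked) == 10

    def test_gap_bridged_with_count(self):
        frames = {t: [(10.0, 10.0)] for t in range(10) if t != 4}
        linked = link_tracks(make_detections(frames), gap_max=1)
        assert linked["object_id"].nunique() == 1
        assert linked["gap"].sum() == 1

    def test_crossing_objects_keep_identity(self):
        """Two objects crossing with step << max_step stay distinct chains."""
        det = make_detections(
            {t: [(10.0 + 3 * t, 20.0), (40.0 - 3 * t, 24.0)] for t in range(11)}
        )
        linked = link_tracks(det, max_step_um=8.0)
        assert linked["object_id"].nunique() == 2
        # the chain starting left stays the +3 um/frame mover
        first = linked[(linked["frame"] == 0) & (linked["x_um"] == 10.0)][
            "object_id"
        ].iloc[0]
        chain = linked[linked["object_id"] == first].sort_values("frame")
        assert np.allclose(np.diff(chain["x_um"]), 3.0)

    def test_row_order_invariance(self):
        det = make_detections(
            {t: [(10.0 + t, 20.0), (40.0 - t, 50.0)] for t in range(8)}
        )
        l1 = link_tracks(det)
        l2 = link_tracks(det.sample(frac=1.0, random_state=1))
        key = ["frame", "x_um", "y_um"]
        m = l1.sort_values(key).reset_index(drop=True).merge(
            l2.sort_values(key).reset_index(drop=True), on=key, suffixes=("_a", "_b")
        )
        # identical partition into chains (ids may differ)
        pairs = m.groupby(["object_id_a", "object_id_b"]).size()
        assert len(pairs) == 2

    def test_duplicate_detections_rejected(self):
        det = make_detections({0: [(1.0, 1.0), (1.0, 1.0)]})
        with pytest.raises(ValueError):
            link_tracks(det)


class TestCallDeath:
    def chain(self, annexin):
        return pd.DataFrame(
            {"frame": range(len(annexin)), "ch_annexin": annexin}
        )

    def test_below_threshold_none(self):
        assert call_death(self.chain([3.0] * 20), threshold=50) is None

    def test_first_sustained_run(self):
        ann = [3.0] * 12 + [100.0, 100.0, 3.0, 100.0]
        assert call_death(self.chain(ann), threshold=50, k=2) == 12

    def test_single_frame_noise_rejected(self):
        ann = [3.0] * 5 + [100.0] + [3.0] * 10
        assert call_death(self.chain(ann), threshold=50, k=2) is None

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            call_death(self.chain([]))

    def test_monotone_in_threshold(self):
        """Raising the threshold never produces an earlier onset."""
        rng = np.random.default_rng(0)
        ann = np.concatenate([rng.uniform(0, 40, 20), rng.uniform(60, 160, 20)])
        chain = self.chain(list(ann))
        prev = -1
        for thr in [10, 30, 50, 100, 150]:
            d = call_death(chain, threshold=thr, k=2)
            if d is None:
                d = 10**9
            assert d >= prev
            prev = d

    def test_called_onset_close_to_truth_on_chip(self, chip500, analysis500):
        """|called - true onset| <= 1 frame for >= 95% of true kills."""
        chip, truth = chip500
        deaths = analysis500.deaths.set_index(["well_id", "target_id"])["death_frame"]
        hits, total = 0, 0
        for row in truth.kills.itertuples(index=False):
            if row.well_id not in analysis500.selected_wells:
                continue
            total += 1
            called = deaths.get((row.well_id, row.target_id))
            if called is not None and abs(called - row.death_frame) <= 1:
                hits += 1
        assert total > 50
        assert hits / total >= 0.95


class TestBeadEndpoint:
    def test_median_summary(self):
        table = pd.DataFrame(
            {"well_id": ["A"] * 3 + ["B"], "intensity": [80.0, 100.0, 120.0, 55.0]}
        )
        out = bead_endpoint_intensity(table)
        assert out.set_index("well_id").loc["A", "bead_intensity"] == 100.0

    def test_missing_well_flagged(self):
        table = pd.DataFrame({"well_id": ["A"], "intensity": [100.0]})
        out = bead_endpoint_intensity(table, wells=["A", "B"])
        assert bool(out.set_index("well_id").loc["B", "missing_beads"])

    def test_matches_brute_force(self, small_chip):
        chip, _ = small_chip
        out = bead_endpoint_intensity(chip.bead_endpoint).set_index("well_id")
        for wid, grp in chip.bead_endpoint.groupby("well_id"):
            assert out.loc[wid, "bead_intensity"] == pytest.approx(
                float(np.median(grp["intensity"]))
            )


class TestMatchEndpoint:
    def test_full_join(self):
        tl = pd.DataFrame({"well_id": ["A", "B"], "x": [1, 2]})
        ep = pd.DataFrame({"well_id": ["A", "B"], "y": [3, 4]})
        joined, lo, ro = match_endpoint_to_timelapse(tl, ep)
        assert len(joined) == 2 and lo == [] and ro == []

    def test_unmatched_reported(self):
        tl = pd.DataFrame({"well_id": list("ABCDE"), "x": range(5)})
        ep = pd.DataFrame({"well_id": list("AB"), "y": range(2)})
        joined, lo, ro = match_endpoint_to_timelapse(tl, ep)
        assert lo == ["C", "D", "E"] and ro == []

    def test_order_invariant(self):
        tl = pd.DataFrame({"well_id": list("ABC"), "x": [1, 2, 3]})
        ep = pd.DataFrame({"well_id": list("CAB"), "y": [9, 7, 8]})
        j1, _, _ = match_endpoint_to_timelapse(tl, ep)
        j2, _, _ = match_endpoint_to_timelapse(tl.iloc[::-1], ep)
        assert j1.sort_values("well_id").reset_index(drop=True).equals(
            j2.sort_values("well_id").reset_index(drop=True)
        )

    def test_duplicates_rejected(self):
        tl = pd.DataFrame({"well_id": ["A", "A"], "x": [1, 2]})
        ep = pd.DataFrame({"well_id": ["A"], "y": [3]})
        with pytest.raises(ValueError):
            match_endpoint_to_timelapse(tl, ep)
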