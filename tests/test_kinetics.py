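"""Conjugation detection, kinetic parameters and functional annotation."""

import math

import numpy as np
import pandas as pd
import pytest

from timing.kinetics import (
    ConjugationInterval,
    annotate_function,
    call_secretion,
    compute_kinetics,
    detect_conjugations,
    select_wells,
)

DT = 5.0
CELL_AREA = math.pi * 5.0**2  # radius 5 um


def chain(object_id, positions, areas=None, annexin=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "object_id": object_id,
            "frame": range(n),
            "t_min": [DT * i for i in range(n)],
            "x_um": [p[0] for p in positions],
            "y_um": [p[1] for p in positions],
            "area_um2": areas if areas is not None else [CELL_AREA] * n,
            "ch_annexin": annexin if annexin is not None else [3.0] * n,
        }
    )


def contact_series(contact_frames, n_frames=30, far=(50.0, 50.0), near=(8.0, 0.0)):
    """Effector positions: at `near` (touching the target at origin) during
    contact frames, at `far` otherwise."""
    return [near if i in contact_frames else far for i in range(n_frames)]


class TestDetectConjugations:
    def make(self, contact_frames, n_frames=30):
        eff = chain("E", contact_series(contact_frames, n_frames))
        tgt = chain("T", [(0.0, 0.0)] * n_frames)
        return detect_conjugations(eff, tgt, slack_um=2.0, min_duration_min=5.0)

    def test_single_frame_contact_excluded(self):
        # 1 frame at 5-min sampling = 5 min, not > 5 min
        assert self.make({10}) == []

    def test_six_frame_contact_duration(self):
        ivs = self.make(set(range(10, 16)))
        assert len(ivs) == 1
        assert ivs[0].duration_min == 30.0
        assert ivs[0].start_min == 50.0

    def test_strict_filter_on_mixed_durations(self):
        """Contacts of 5, 10 and 30 minutes yield exactly the two > 5-min
        conjugates."""
        frames = {3} | {8, 9} | set(range(14, 20))
        ivs = self.make(frames)
        assert sorted(iv.duration_min for iv in ivs) == [10.0, 30.0]

    def test_gap_of_one_frame_merged(self):
        ivs = self.make({5, 6, 8, 9})
        assert len(ivs) == 1
        assert ivs[0].duration_min == 20.0  # 4 contact frames, gap excluded

    def test_mismatched_clocks_rejected(self):
        eff = chain("E", contact_series(set(range(5))))
        tgt = chain("T", [(0.0, 0.0)] * 30)
        tgt["t_min"] = tgt["t_min"] + 1.0
        with pytest.raises(ValueError):
            detect_conjugations(eff, tgt)

    def test_agrees_with_brute_force_on_simulated_wells(self, chip500, analysis500):
        """Detected intervals equal a per-frame distance recomputation done
        independently of the detector."""
        chip, _ = chip500
        tracks = chip.tracks
        checked = 0
        for well_id in analysis500.selected_wells[:100]:
            w = tracks[tracks["well_id"] == well_id]
            eff_id = w.loc[w["role"] == "effector", "object_id"].iloc[0]
            eff = w[w["object_id"] == eff_id].sort_values("frame")
            for tgt_id in w.loc[w["role"] == "target", "object_id"].unique():
                tgt = w[w["object_id"] == tgt_id].sort_values("frame")
                got = detect_conjugations(eff, tgt)
                # oracle: vector distance threshold + run construction
                d = np.hypot(
                    eff["x_um"].to_numpy() - tgt["x_um"].to_numpy(),
                    eff["y_um"].to_numpy() - tgt["y_um"].to_numpy(),
                )
                rr = np.sqrt(eff["area_um2"].to_numpy() / math.pi) + np.sqrt(
                    tgt["area_um2"].to_numpy() / math.pi
                )
                contact = d <= rr + 2.0
                runs = []
                cur = []
                for i in np.nonzero(contact)[0]:
                    if cur and i - cur[-1] > 2:
                        runs.append(cur)
                        cur = []
                    cur.append(int(i))
                if cur:
                    runs.append(cur)
                oracle = [r for r in runs if len(r) * DT > 5.0]
                assert len(got) == len(oracle)
                for iv, r in zip(got, oracle):
                    assert iv.duration_min == pytest.approx(len(r) * DT)
                    assert iv.start_min == pytest.approx(r[0] * DT)
                checked += 1
        assert checked >= 100


def iv(start, frames):
    times = [start + DT * i for i in frames]
    return ConjugationInterval(
        "E", "T", times[0], times[-1] + DT, DT * len(frames), contact_times=times
    )


class TestComputeKinetics:
    def test_detach_before_death(self):
        # contact 50..95 (10 frames), detach at 100, death at 150
        record = compute_kinetics([iv(50.0, range(10))], death_min=150.0)
        assert record.t_contact == pytest.approx(50.0)
        assert record.t_death == pytest.approx(100.0)
        assert record.t_seek == pytest.approx(50.0)

    def test_continuous_contact_until_death(self):
        # contact 20..75 (12 frames, 60 min), death at 80
        record = compute_kinetics([iv(20.0, range(12))], death_min=80.0)
        assert record.t_contact == pytest.approx(60.0)
        assert record.t_death == pytest.approx(60.0)

    def test_death_before_first_contact_invalid(self):
        record = compute_kinetics([iv(100.0, range(4))], death_min=50.0)
        assert not record.valid

    def test_no_death_total_conjugation(self):
        record = compute_kinetics([iv(10.0, range(3)), iv(100.0, range(4))], None)
        assert record.t_contact == pytest.approx(35.0)
        assert record.t_death is None

    def test_contact_le_death_on_chip(self, analysis500):
        k = analysis500.kinetics
        killers = k[k["killed"] & k["valid"]]
        assert len(killers) >= 80
        assert (killers["t_contact"] <= killers["t_death"] + 1e-9).all()


class TestSelectWells:
    def tracks_for(self, counts):
        rows = []
        for wid, (ne, nt, nb) in counts.items():
            i = 0
            for role, n in (("effector", ne), ("target", nt), ("bead", nb)):
                for _ in range(n):
                    for frame in range(2):
                        rows.append(
                            {
                                "well_id": wid,
                                "object_id": f"{wid}_o{i}",
                                "role": role,
                                "frame": frame,
                                "t_min": DT * frame,
                                "ch_annexin": 3.0,
                            }
                        )
                    i += 1
        return pd.DataFrame(rows)

    def test_count_predicate(self):
        tracks = self.tracks_for(
            {"A": (1, 3, 1), "B": (2, 3, 1), "C": (1, 3, 0), "D": (1, 6, 1)}
        )
        assert select_wells(tracks) == ["A"]

    def test_matches_brute_force_on_chip(self, chip500, analysis500):
        chip, truth = chip500
        wells = chip.wells.set_index("well_id")
        expected = [
            w
            for w, r in wells.iterrows()
            if r["n_effectors"] == 1 and 1 <= r["n_targets"] <= 5 and r["n_beads"] >= 1
        ]
        assert analysis500.selected_wells == expected


class TestAnnotateFunction:
    @pytest.mark.parametrize(
        "kills,secretion,expected_killer,expected_fc",
        [
            (2, False, "serial_killer", "multifunctional"),
            (3, True, "serial_killer", "multifunctional"),
            (1, True, "single_killer", "multifunctional"),
            (1, False, "single_killer", "monofunctional_kill"),
            (0, True, "nonkiller", "monofunctional_ifng"),
            (0, False, "nonkiller", "nonfunctional"),
        ],
    )
    def test_taxonomy(self, kills, secretion, expected_killer, expected_fc):
        label = annotate_function(kills, secretion, conjugated=True)
        assert label.killer_class == expected_killer
        assert label.function_class == expected_fc

    def test_unconjugated_excluded(self):
        assert annotate_function(0, False, conjugated=False) is None

    def test_missing_secretion_rejected(self):
        with pytest.raises(ValueError):
            annotate_function(1, None, conjugated=True)

    def test_taxonomy_is_partition_on_chip(self, analysis500):
        ann = analysis500.annotations
        assert ann["well_id"].is_unique
        assert (
            ann["function_class"]
            .isin(
                [
                    "multifunctional",
                    "monofunctional_kill",
                    "monofunctional_ifng",
                    "nonfunctional",
                ]
            )
            .all()
        )

    def test_serial_kill_count_bounded_by_targets(self, chip500, analysis500):
        chip, _ = chip500
        wells = chip.wells.set_index("well_id")
        for row in analysis500.annotations.itertuples(index=False):
            assert row.n_kills <= wells.loc[row.well_id, "n_targets"]


class TestCallSecretion:
    def summary(self, wells, values):
        return pd.DataFrame({"well_id": wells, "bead_intensity": values})

    def test_equal_to_control_mean_negative(self):
        ctrl = self.summary(range(12), [100.0 + i % 3 for i in range(12)])
        obs = self.summary(["X"], [float(np.mean(ctrl["bead_intensity"]))])
        assert not call_secretion(obs, ctrl).iloc[0]

    def test_threshold_monotone_in_k(self):
        rng = np.random.default_rng(0)
        ctrl = self.summary(range(20), 100 + rng.normal(0, 5, 20))
        obs = self.summary(range(100, 130), 100 + rng.normal(10, 10, 30))
        prev = None
        for k in [1.0, 2.0, 3.0, 5.0]:
            pos = call_secretion(obs, ctrl, k=k)
            if prev is not None:
                # raising k never converts negative -> positive
                assert not (pos & ~prev).any()
            prev = pos

    def test_too_few_controls_rejected(self):
        ctrl = self.summary(range(3), [100.0] * 3)
        with pytest.raises(ValueError):
            call_secretion(self.summary(["X"], [200.0]), ctrl)

    def test_accuracy_on_simulated_chip(self, chip500, analysis500):
        """Secretor/non-secretor calls match ground truth >= 99% when the
        separation is many control SDs."""
        chip, truth = chip500
        gt = truth.labels.set_index("well_id")
        calls = analysis500.secretion
        common = [w for w in calls.index if gt.loc[w, "phenotype"] is not None]
        agree = np.mean([calls[w] == gt.loc[w, "secretion"] for w in common])
        assert agree >= 0.99
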