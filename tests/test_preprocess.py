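import numpy as np
import pandas as pd
import pytest

import visforage as vf
from visforage import preprocess
from visforage.synth import ConjunctionObject, Patch, PatchConfig


def _two_object_patch():
    objs = [
        ConjunctionObject(0, (100.0, 100.0), 0, "target", "red", "green"),
        ConjunctionObject(1, (140.0, 100.0), 0, "target", "red", "green"),
    ]
    return Patch(trial_id=0, objects=objs, grid_cells=[(0, 0), (1, 0)], config=PatchConfig())


class TestAssignTap:
    def test_tap_at_center(self, default_patch):
        obj = default_patch.objects[17]
        assert preprocess.assign_tap(obj.center_px, default_patch) == 17

    def test_tap_outside_all_radii(self):
        patch = _two_object_patch()
        assert preprocess.assign_tap((500.0, 500.0), patch) is None

    def test_equidistant_tie_breaks_to_lower_id(self):
        patch = _two_object_patch()  # centers 40 px apart; midpoint is 20 px from both
        assert preprocess.assign_tap((120.0, 100.0), patch) == 0

    def test_empty_patch_rejected(self):
        empty = Patch(trial_id=0, objects=[], grid_cells=[], config=PatchConfig())
        with pytest.raises(ValueError):
            preprocess.assign_tap((0.0, 0.0), empty)


class TestCanonicalAndClassify:
    def test_center_maps_to_origin(self):
        obj = ConjunctionObject(0, (640.0, 480.0), 0, "target", "red", "green")
        assert np.allclose(preprocess.to_canonical((640.0, 480.0), obj), [0.0, 0.0])

    def test_rotated_disc_centroid_round_trip(self):
        obj = ConjunctionObject(0, (640.0, 480.0), 90, "target", "red", "green")
        disc_c = vf.geometry.disc_centroid()
        screen = vf.geometry.canonical_to_screen(disc_c, obj.center_px, 90)
        assert np.allclose(preprocess.to_canonical(screen, obj), disc_c, atol=1e-9)

    @pytest.mark.parametrize(
        "xy,expected",
        [((0.0, 5.0), "disc"), ((10.0, -5.0), "rect"), ((3.0, 0.0), "rect")],
    )
    def test_classify_part(self, xy, expected):
        assert preprocess.classify_part(xy) == expected

    @pytest.mark.parametrize("orientation", [0, 90, 180, 270])
    def test_classification_rotation_invariant(self, orientation, rng):
        """A tap's part label does not depend on the object's orientation."""
        obj = ConjunctionObject(0, (300.0, 300.0), orientation, "target", "red", "green")
        for _ in range(50):
            canonical = rng.uniform(-23, 23, 2)
            screen = vf.geometry.canonical_to_screen(canonical, obj.center_px, orientation)
            assert preprocess.classify_part(preprocess.to_canonical(screen, obj)) == \
                preprocess.classify_part(canonical)


class TestCountSwitches:
    @pytest.mark.parametrize(
        "labels,k,m",
        [
            (["disc", "disc", "rect", "rect"], 1, 3),
            (["disc"] * 42, 0, 41),
            (["disc", "rect", "disc", "rect"], 3, 3),
        ],
    )
    def test_examples(self, labels, k, m):
        sc = preprocess.count_switches(labels)
        assert (sc.k_switch, sc.m_opportunities) == (k, m)

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            preprocess.count_switches([])

    def test_invariant_under_label_swap(self, rng):
        """Relabeling disc<->rect leaves the switch count unchanged."""
        labels = rng.choice(["disc", "rect"], 100)
        swapped = np.where(labels == "disc", "rect", "disc")
        assert preprocess.count_switches(labels).k_switch == \
            preprocess.count_switches(swapped).k_switch


class TestEndPeakFactor:
    def test_spike_over_unit_median(self):
        assert preprocess.end_peak_factor([1, 1, 1, 1, 10]) == pytest.approx(10.0)

    def test_constant_series(self):
        assert preprocess.end_peak_factor([3.3] * 8) == pytest.approx(1.0)

    def test_general_median(self):
        assert preprocess.end_peak_factor([2, 4, 6, 8, 40]) == pytest.approx(40 / 6)

    def test_median_excluding_last(self):
        assert preprocess.end_peak_factor([2, 4, 6, 8, 40], include_last_in_median=False) \
            == pytest.approx(8.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            preprocess.end_peak_factor([5.0])

    def test_participant_mean(self):
        assert preprocess.participant_mean([1.0, 2.0, 3.0]) == pytest.approx(2.0)


class TestCountsTables:
    def test_switch_totals_conserve_taps(self, small_labeled):
        """Sum of (m+1) over trials equals each participant's collected targets."""
        sw = preprocess.switch_counts_table(small_labeled)
        per_part = sw.groupby("participant_id")["m_opportunities"].apply(lambda s: (s + 1).sum())
        collected = small_labeled.loc[~small_labeled["is_error"]].groupby("participant_id").size()
        assert (per_part == collected).all()

    def test_blocks_partition_counts(self, small_labeled):
        """Block-wise red counts sum to the all-scope count."""
        blocks = preprocess.preference_counts_table(small_labeled, scope="block")
        allscope = preprocess.preference_counts_table(small_labeled, scope="all")
        merged = blocks.groupby("participant_id")[["k_red", "n"]].sum()
        for pid, row in allscope.set_index("participant_id").iterrows():
            assert merged.loc[pid, "k_red"] == row["k_red"]
            assert merged.loc[pid, "n"] == row["n"]

    def test_halves_partition_trials(self, small_labeled):
        halves = preprocess.preference_counts_table(small_labeled, scope="half", n_trials=4)
        assert set(halves["half"]) == {1, 2}
        total = preprocess.preference_counts_table(small_labeled, scope="all")
        assert halves["n"].sum() == total["n"].sum()

    def test_mapping_inversion_complements_k_red(self):
        """Swapping which color sits on which part mirrors the red count."""
        df = pd.DataFrame(
            dict(
                participant_id=0, trial_id=0, tap_index=range(6),
                is_error=False,
                part_label=["disc", "rect", "disc", "disc", "rect", "rect"],
                part_color=["red", "green", "red", "red", "green", "green"],
            )
        )
        inverted = df.assign(
            part_color=df["part_color"].map({"red": "green", "green": "red"})
        )
        k = preprocess.preference_counts_table(df, scope="all")["k_red"].iloc[0]
        k_inv = preprocess.preference_counts_table(inverted, scope="all")["k_red"].iloc[0]
        assert k + k_inv == 6

    def test_unassigned_taps_dropped_with_warning(self, default_patch):
        taplog = pd.DataFrame(
            dict(participant_id=[0], trial_id=[0], tap_index=[0], time_ms=[500.0],
                 x_px=[5.0], y_px=[5.0], object_id=[None], is_error=[False])
        )
        with pytest.warns(UserWarning, match="dropped 1"):
            labeled = preprocess.label_taps(taplog, {(0, 0): default_patch})
        assert labeled.empty

    def test_zero_noise_switch_proportion_matches_chain(self, small_experiment, small_labeled):
        """Without motor noise the empirical switch proportion equals the
        attention chain's realized switch fraction exactly."""
        _, truth = small_experiment
        sw = preprocess.switch_counts_table(small_labeled).set_index(
            ["participant_id", "trial_id"]
        )
        for (pid, trial), seq in truth["attention"].items():
            realized = int((seq[1:] != seq[:-1]).sum())
            assert sw.loc[(pid, trial), "k_switch"] == realized


class TestITTTable:
    def test_first_tap_latency_convention(self, small_labeled):
        itts = preprocess.itt_table(small_labeled)
        grp = itts.query("participant_id == 0 and trial_id == 0").sort_values("itt_index")
        taps = small_labeled.query(
            "participant_id == 0 and trial_id == 0 and ~is_error"
        ).sort_values("tap_index")
        assert len(grp) == len(taps)  # first latency included as first ITT
        assert grp["itt_ms"].iloc[0] == pytest.approx(taps["time_ms"].iloc[0])
        assert (grp["itt_ms"] > 0).all()

    def test_end_peak_table_matches_direct_computation(self, small_labeled):
        itts = preprocess.itt_table(small_labeled)
        ep = preprocess.end_peak_table(itts)
        one = itts.query("participant_id == 1 and trial_id == 2").sort_values("itt_index")
        direct = preprocess.end_peak_factor(one["itt_ms"].to_numpy())
        got = ep.query("participant_id == 1 and trial_id == 2")["end_peak_factor"].iloc[0]
        assert got == pytest.approx(direct)
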