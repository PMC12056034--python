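import numpy as np
import pytest
from scipy import stats

import visforage as vf
from visforage import geometry
from visforage.synth import simulate_taps_vectorized, tap_anchor


class TestGeneratePatch:
    def test_default_composition(self, default_patch):
        roles = default_patch.roles
        assert (roles == "target").sum() == 42
        assert (roles == "distractor").sum() == 42

    def test_distinct_cells_and_extent(self, default_patch):
        assert len(set(default_patch.grid_cells)) == 84
        cfg = default_patch.config
        centers = default_patch.centers
        x0 = (cfg.screen_px[0] - cfg.grid_extent_px[0]) / 2
        y0 = (cfg.screen_px[1] - cfg.grid_extent_px[1]) / 2
        assert (centers[:, 0] >= x0).all() and (centers[:, 0] <= x0 + cfg.grid_extent_px[0]).all()
        assert (centers[:, 1] >= y0).all() and (centers[:, 1] <= y0 + cfg.grid_extent_px[1]).all()

    def test_zero_jitter_snaps_to_grid_columns(self):
        cfg = vf.PatchConfig(jitter_px=0.0)
        patch = vf.generate_patch(cfg, seed=3)
        xs = np.unique(np.round(patch.centers[:, 0], 6))
        assert len(xs) == cfg.grid_cols

    def test_orientations_uniform(self):
        """Across ~10,000 objects each cardinal orientation occurs 1/4 of the
        time, within a 99% binomial interval."""
        counts = {o: 0 for o in geometry.CARDINAL_ORIENTATIONS}
        n_patches = 120  # 120 * 84 = 10,080 objects
        for s in range(n_patches):
            for obj in vf.generate_patch(vf.PatchConfig(), seed=1000 + s).objects:
                counts[obj.orientation_deg] += 1
        n = n_patches * 84
        lo, hi = stats.binom.interval(0.99, n, 0.25)
        for o, c in counts.items():
            assert lo <= c <= hi, f"orientation {o}: {c} outside [{lo}, {hi}]"

    def test_roles_and_colors_consistent(self, default_patch):
        for obj in default_patch.objects:
            if obj.role == "target":
                assert obj.rect_color == "green" and obj.disc_color == "red"
            else:
                assert obj.rect_color == "red" and obj.disc_color == "green"

    def test_overfull_grid_rejected(self):
        with pytest.raises(ValueError):
            vf.PatchConfig(grid_cols=5, grid_rows=5, n_targets=20, n_distractors=20)


class TestAttentionSequence:
    def test_degenerate_constant(self):
        params = vf.ForagerParams(p_switch_att=0.0, p_pref=1.0, preferred_part="rect")
        seq = vf.simulate_attention_sequence(params, 50, seed_or_rng=0)
        assert (seq == "rect").all()

    def test_forced_alternation(self):
        params = vf.ForagerParams(p_switch_att=1.0, p_pref=1.0, preferred_part="disc")
        seq = vf.simulate_attention_sequence(params, 10, seed_or_rng=0)
        assert list(seq) == ["disc", "rect"] * 5

    def test_switch_fraction_concentrates(self):
        """Empirical switch fraction at n=100,000 is inside the 99% binomial
        interval around the switching probability 0.41."""
        params = vf.ForagerParams(p_switch_att=0.41)
        seq = vf.simulate_attention_sequence(params, 100_000, seed_or_rng=5)
        k = int((seq[1:] != seq[:-1]).sum())
        lo, hi = stats.binom.interval(0.99, 99_999, 0.41)
        assert lo <= k <= hi

    def test_first_label_preference(self):
        params = vf.ForagerParams(p_pref=1.0, preferred_part="disc")
        firsts = {vf.simulate_attention_sequence(params, 3, seed_or_rng=s)[0] for s in range(20)}
        assert firsts == {"disc"}


class TestSimulateTap:
    def _obj(self, orientation=0):
        return vf.ConjunctionObject(0, (500.0, 300.0), orientation, "target", "red", "green")

    def test_noise_free_disc_anchor(self, rng):
        params = vf.ForagerParams(motor_sigma_px=0.0, com_weight=0.0)
        tap = vf.simulate_tap(self._obj(), "disc", params, rng)
        r = geometry.DEFAULT_RADIUS
        assert np.allclose(tap, [500.0, 300.0 + 4 * r / (3 * np.pi)])

    def test_full_com_pull_ignores_attended_part(self, rng):
        params = vf.ForagerParams(motor_sigma_px=0.0, com_weight=1.0)
        com_screen = geometry.canonical_to_screen(
            geometry.center_of_mass(), (500.0, 300.0), 90
        )
        for part in ("disc", "rect"):
            tap = vf.simulate_tap(self._obj(90), part, params, rng)
            assert np.allclose(tap, com_screen)

    def test_vectorized_matches_scalar_anchor(self, rng):
        params = vf.ForagerParams(motor_sigma_px=0.0, com_weight=0.4)
        centers = np.array([[100.0, 100.0], [200.0, 50.0]])
        orients = np.array([90, 270])
        parts = np.array(["disc", "rect"], dtype=object)
        taps = simulate_taps_vectorized(centers, orients, parts, params, rng)
        for i in range(2):
            expected = geometry.canonical_to_screen(
                tap_anchor(parts[i], params), centers[i], orients[i]
            )
            assert np.allclose(taps[i], expected)


class TestSimulateITTs:
    def test_no_end_peak(self, rng):
        params = vf.ForagerParams(endpeak_mult=1.0)
        itts = vf.simulate_itts(1000, params, rng)
        assert (itts > 0).all()
        # final value is an ordinary draw: not systematically extreme
        assert itts[-1] < itts.max() * 1.0 + 1e-9

    def test_deterministic_end_peak_limit(self, rng):
        params = vf.ForagerParams(itt_logsd=1e-12, endpeak_mult=10.0)
        itts = vf.simulate_itts(42, params, rng)
        assert vf.end_peak_factor(itts) == pytest.approx(10.0, rel=1e-6)

    def test_cruise_median_matches_lognormal(self, rng):
        """The count of draws below exp(logmean) is binomial(n, 1/2)."""
        params = vf.ForagerParams(itt_logmean=np.log(700.0), endpeak_mult=1.0)
        itts = vf.simulate_itts(10_000, params, rng)
        below = int((itts < 700.0).sum())
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= below <= hi

    def test_too_few_collections_rejected(self, rng):
        with pytest.raises(ValueError):
            vf.simulate_itts(1, vf.ForagerParams(), rng)


class TestSimulateExperiment:
    def test_trial_tap_counts(self, small_experiment):
        taplog, _ = small_experiment
        per_trial = taplog.loc[~taplog["is_error"]].groupby(
            ["participant_id", "trial_id"]
        ).size()
        assert (per_trial == 42).all()

    def test_no_error_taps_at_zero_error_rate(self, small_experiment):
        taplog, _ = small_experiment
        assert not taplog["is_error"].any()

    def test_round_trip_recovers_attention_sequence(self, small_experiment, small_labeled):
        """Zero motor noise, zero COM pull: classified part labels reproduce
        the generated attention sequence tap for tap."""
        _, truth = small_experiment
        for (pid, trial), seq in truth["attention"].items():
            got = (
                small_labeled.query("participant_id == @pid and trial_id == @trial")
                .sort_values("tap_index")["part_label"]
                .to_numpy()
            )
            assert (got == seq).all()

    def test_deterministic_replay(self, noiseless_params):
        a, _ = vf.simulate_experiment(2, 2, vf.PatchConfig(), [noiseless_params] * 2, seed=9)
        b, _ = vf.simulate_experiment(2, 2, vf.PatchConfig(), [noiseless_params] * 2, seed=9)
        assert a.equals(b)

    def test_error_taps_marked(self):
        params = vf.ForagerParams(error_rate=0.3, motor_sigma_px=0.0, com_weight=0.0)
        taplog, truth = vf.simulate_experiment(1, 2, vf.PatchConfig(), [params], seed=11)
        errors = taplog.loc[taplog["is_error"]]
        assert len(errors) > 0
        patch = truth["patches"][(0, 0)]
        roles = {o.object_id: o.role for o in patch.objects}
        trial0 = errors.query("trial_id == 0")
        assert all(roles[oid] == "distractor" for oid in trial0["object_id"])


def test_forager_params_validation():
    with pytest.raises(ValueError):
        vf.ForagerParams(p_switch_att=1.5)
    with pytest.raises(ValueError):
        vf.ForagerParams(endpeak_mult=0.5)
    with pytest.raises(ValueError):
        vf.ForagerParams(preferred_part="edge")
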