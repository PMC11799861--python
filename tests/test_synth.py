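"""Generator tests: schedules, SDT observer, sensor layout, and epochs."""

import numpy as np
import pandas as pd
import pytest

from cfserp.sdt import detection_counts, dprime
from cfserp.synth import (
    Condition,
    EffectSpec,
    ObserverParams,
    build_templates,
    default_times,
    inject_amplitude_spikes,
    make_calibration_schedule,
    make_layout,
    make_main_schedule,
    simulate_epochs,
    simulate_observer,
)
from conftest import two_condition_schedule


class TestCondition:
    def test_catch_invariant(self):
        Condition("none", "catch", True)
        Condition("fearful", "high", False)
        with pytest.raises(ValueError):
            Condition("none", "high", True)
        with pytest.raises(ValueError):
            Condition("fearful", "catch", True)


class TestSchedules:
    def test_calibration_design_counts(self):
        s = make_calibration_schedule(48, [0.05, 0.15, 0.25, 0.35], seed=0)
        assert s.n_trials == 240
        counts = s.table.groupby("contrast_level").size()
        assert (counts == 48).all() and len(counts) == 5
        assert (s.table.groupby("block").size() == 60).all()
        assert s.table.cfs.all()

    def test_calibration_minimal(self):
        s = make_calibration_schedule(1, [0.1], seed=0)
        assert s.n_trials == 2
        assert set(s.table.contrast_level) == {"c0.1", "catch"}

    def test_calibration_errors(self):
        with pytest.raises(ValueError):
            make_calibration_schedule(0, [0.1], seed=0)
        with pytest.raises(ValueError):
            make_calibration_schedule(5, [0.1, 0.1], seed=0)
        with pytest.raises(ValueError):
            make_calibration_schedule(5, [0.0, 0.1], seed=0)

    def test_main_design_counts(self):
        s = make_main_schedule(seed=0)
        assert s.n_trials == 840
        assert s.table.prompt.sum() == 280
        assert (s.table.groupby("block").size() == 120).all()
        counts = s.condition_counts()
        assert len(counts) == 14 and (counts == 60).all()

    def test_main_minimal_and_prompts(self):
        assert make_main_schedule(n_per_condition=1, n_blocks=1).n_trials == 14
        s = make_main_schedule(n_per_condition=2, n_blocks=1, prompt_fraction=0.0)
        assert s.table.prompt.sum() == 0

    def test_main_indivisible_blocks(self):
        with pytest.raises(ValueError):
            make_main_schedule(n_per_condition=1, n_blocks=4)

    def test_seed_determinism(self):
        a = make_main_schedule(seed=5)
        b = make_main_schedule(seed=5)
        c = make_main_schedule(seed=6)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert not a.table.expression.equals(c.table.expression)
        # same design counts regardless of order
        assert a.condition_counts().equals(c.condition_counts())

    def test_tsv_roundtrip(self, tmp_path):
        s = make_main_schedule(n_per_condition=3, n_blocks=1, seed=2)
        path = tmp_path / "sched.tsv"
        s.to_tsv(path)
        back = type(s).from_tsv(path)
        pd.testing.assert_frame_equal(s.table, back.table)
        assert back.contrasts == pytest.approx(s.contrasts)


class TestObserver:
    def test_chance_observer(self):
        """Zero sensitivity everywhere: estimated d' converges to 0."""
        s = make_calibration_schedule(10000, [0.1], seed=1)
        params = ObserverParams(
            detect_intercept_cfs=0.0, detect_slope_cfs=0.0, criterion=0.5
        )
        resp = simulate_observer(s, params, seed=2)
        d, _ = dprime(detection_counts(resp))
        assert abs(d) < 0.05

    def test_dprime_recovery(self):
        """Generating d' = 1.0 recovered within +-0.1 at 20 000 trials."""
        s = make_calibration_schedule(10000, [0.1], seed=3)
        params = ObserverParams(
            detect_intercept_cfs=1.0, detect_slope_cfs=0.0, criterion=0.5
        )
        resp = simulate_observer(s, params, seed=4)
        d, c = dprime(detection_counts(resp))
        assert 0.9 < d < 1.1

    def test_huge_sensitivity_saturates_hits_not_fas(self):
        s = make_calibration_schedule(300, [0.5], seed=5)
        strong = ObserverParams(detect_intercept_cfs=50.0, detect_slope_cfs=0.0)
        resp = simulate_observer(s, strong, seed=6)
        face = resp.contrast_level != "catch"
        assert (resp.loc[face, "detect_resp"] == 2).all()
        fa_rate = (resp.loc[~face, "detect_resp"] == 2).mean()
        assert 0.1 < fa_rate < 0.55  # criterion-driven, unchanged by d'

    def test_discrimination_only_on_prompts(self):
        s = make_main_schedule(n_per_condition=6, n_blocks=1, seed=7)
        resp = simulate_observer(s, ObserverParams(), seed=8)
        assert resp.loc[~resp.prompt, "discrim_resp"].isna().all()
        assert resp.loc[resp.prompt, "discrim_resp"].notna().all()

    def test_observer_determinism(self):
        s = make_main_schedule(n_per_condition=3, n_blocks=1, seed=9)
        r1 = simulate_observer(s, ObserverParams(), seed=10)
        r2 = simulate_observer(s, ObserverParams(), seed=10)
        pd.testing.assert_frame_equal(r1, r2)


class TestLayout:
    def test_adjacency_symmetric_irreflexive(self, layout64):
        adj = layout64.adjacency
        assert (adj == adj.T).all()
        assert not adj.diagonal().any()

    def test_two_distant_channels_no_edges(self):
        g = make_layout(2, neighbor_distance=1e-6)
        assert g.adjacency.sum() == 0

    def test_default_degree_range(self, layout64):
        deg = layout64.degree()
        assert deg.min() >= 2 and deg.max() <= 12

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_layout(1)
        with pytest.raises(ValueError):
            make_layout(8, neighbor_distance=0.0)


class TestEpochs:
    def test_zero_everything_gives_zero_data(self, layout16):
        sched = two_condition_schedule(2)
        eff = EffectSpec(
            contrast_gain={"low": 0, "medium": 0, "high": 0},
            subject_sd=0.0,
            trial_noise_sd=0.0,
        ).zeroed()
        ep = simulate_epochs(sched, eff, layout16, n_subjects=2, seed=0)
        assert np.all(ep.data == 0)

    def test_noise_free_waveform_is_summed_templates(self, layout16):
        """One fearful high-contrast trial equals gain + amplitude templates."""
        sched = two_condition_schedule(1)
        eff = EffectSpec(subject_sd=0.0, trial_noise_sd=0.0)
        ep = simulate_epochs(sched, eff, layout16, n_subjects=1, seed=0)
        tmpl = build_templates(eff, layout16, ep.times)
        early = np.outer(*tmpl["early"])
        late = np.outer(*tmpl["late"])
        gain = eff.contrast_gain["high"]
        expected_fearful = (
            gain * (early + late)
            + eff.expression_amplitude_early[("high", True)] * early
            + eff.expression_amplitude_late[("high", True)] * late
        )
        np.testing.assert_allclose(ep.data[0, 0], expected_fearful, atol=1e-4)
        np.testing.assert_allclose(ep.data[0, 1], gain * (early + late), atol=1e-4)

    def test_grand_average_difference_recovers_amplitude(self, layout16):
        """Law of large numbers: mean fearful-neutral diff -> set amplitude."""
        sched = two_condition_schedule(4000)
        eff = EffectSpec(
            expression_amplitude_early={("high", True): -1.0},
            expression_amplitude_late={("high", True): 0.0},
            subject_sd=0.0,
            trial_noise_sd=1.5,
        )
        ep = simulate_epochs(sched, eff, layout16, n_subjects=1, seed=11)
        tmpl = build_templates(eff, layout16, ep.times)
        ch = int(np.argmax(tmpl["early"][0]))
        tp = int(np.argmax(tmpl["early"][1]))
        fearful = ep.data[0, :4000, ch, tp].mean()
        neutral = ep.data[0, 4000:, ch, tp].mean()
        assert abs((fearful - neutral) - (-1.0)) < 0.1

    def test_catch_trials_carry_no_signal(self, layout16):
        sched = make_main_schedule(n_per_condition=2, n_blocks=1, seed=1)
        eff = EffectSpec(subject_sd=0.0, trial_noise_sd=0.0)
        ep = simulate_epochs(sched, eff, layout16, n_subjects=1, seed=0)
        catch = (sched.table.contrast_level == "catch").to_numpy()
        assert np.all(ep.data[0, catch] == 0)
        assert not np.all(ep.data[0, ~catch] == 0)

    def test_epoch_determinism_and_grid(self, layout16):
        sched = two_condition_schedule(3)
        eff = EffectSpec()
        a = simulate_epochs(sched, eff, layout16, n_subjects=2, seed=21)
        b = simulate_epochs(sched, eff, layout16, n_subjects=2, seed=21)
        assert np.array_equal(a.data, b.data)
        times = default_times()
        assert len(times) == 400
        assert times[0] == -200.0 and times[-1] == 598.0
        assert times[100] == 0.0  # stimulus onset sample

    def test_spike_injection_marks_trials(self, layout16):
        sched = two_condition_schedule(50)
        eff = EffectSpec(subject_sd=0.0, trial_noise_sd=1.0)
        ep = simulate_epochs(sched, eff, layout16, n_subjects=2, seed=3)
        spiked, mask = inject_amplitude_spikes(ep, rate=0.2, amplitude=500.0, seed=4)
        changed = np.abs(spiked.data - ep.data).max(axis=(2, 3)) > 100
        assert np.array_equal(changed, mask)
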