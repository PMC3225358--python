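"""Stimulus generators: Poisson statistics, targeting, template geometry."""

import numpy as np
import pytest

from chainsim.network_topology import build_pool
from chainsim.stimulus_generator import (StimulusEvent, StimulusProgram,
                                         TemplateProfileSpec, gen_feedback_train,
                                         gen_intention_burst, gen_poisson_train,
                                         gen_template_profiles,
                                         realize_event_trains)


def _bin20(profile_1ms):
    n = profile_1ms.size // 20
    return profile_1ms[:n * 20].reshape(n, 20).mean(axis=1)


class TestPoisson:
    def test_zero_rate_no_spikes(self):
        trains = gen_poisson_train(0.0, 1000.0, 10, seed=0)
        assert all(t.size == 0 for t in trains)

    def test_constant_rate_mean_count(self):
        trains = gen_poisson_train(100.0, 1000.0, 1000, seed=1)
        counts = np.array([t.size for t in trains])
        # mean 100, sem = 10/sqrt(1000); allow 4 sigma
        assert abs(counts.mean() - 100.0) < 4 * 10.0 / np.sqrt(1000)

    def test_reproducible_under_seed(self):
        a = gen_poisson_train(50.0, 500.0, 5, seed=42)
        b = gen_poisson_train(50.0, 500.0, 5, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_inhomogeneous_rate_follows_profile(self):
        t_grid = np.arange(0.0, 1000.0)
        rate = np.where((t_grid >= 250) & (t_grid < 750), 200.0, 0.0)
        trains = gen_poisson_train((t_grid, rate), 1000.0, 400, seed=3)
        all_t = np.concatenate(trains)
        inside = ((all_t >= 250) & (all_t < 750)).mean()
        assert inside > 0.98

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_poisson_train(-1.0, 100.0, 1, seed=0)


class TestEvents:
    def test_intention_burst_targets_fraction(self):
        pool, _, _ = build_pool(500, 0.25, 0.2, 1.0, 1.0, seed=0)
        ev = gen_intention_burst("p", fraction=0.20, peak_rate=400.0,
                                 width=150.0, seed=9)
        ids, trains = realize_event_trains(ev, pool)
        assert ids.size == 100  # 20% of 500
        assert len(trains) == 100

    def test_full_pool_targeting(self):
        pool, _, _ = build_pool(100, 0.25, 0.2, 1.0, 1.0, seed=0)
        ev = gen_intention_burst("p", fraction=1.0, peak_rate=100.0,
                                 width=100.0, seed=9)
        ids, _ = realize_event_trains(ev, pool)
        assert np.array_equal(np.sort(ids), pool.neuron_ids)

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError):
            gen_intention_burst("p", fraction=0.2, peak_rate=400.0, width=0.0, seed=0)

    def test_feedback_default_duration_and_kinds(self):
        ev = gen_feedback_train("sensory", "p", duration=300.0, seed=0)
        assert ev.duration == 300.0 and ev.channel == "sensory"
        ev = gen_feedback_train("corollary", "p", duration=300.0, seed=0)
        assert ev.channel == "motor"
        with pytest.raises(ValueError):
            gen_feedback_train("auditory?", "p", duration=300.0, seed=0)

    def test_bell_profile_peaks_at_center(self):
        ev = gen_intention_burst("p", fraction=0.2, peak_rate=400.0,
                                 width=150.0, seed=0)
        t = np.linspace(ev.onset, ev.onset + ev.duration, 301)
        r = ev.rate_at(t)
        assert r.max() == pytest.approx(400.0, rel=1e-3)
        assert abs(t[np.argmax(r)] - (ev.onset + ev.duration / 2)) < 2.0

    def test_program_round_trip(self):
        prog = StimulusProgram(events=[
            gen_feedback_train("sensory", "a", 300.0, seed=1, onset=50.0),
            gen_intention_burst("b", 0.2, 400.0, 150.0, seed=2),
        ])
        clone = StimulusProgram.from_dict(prog.to_dict())
        assert [e.target_pool for e in clone.events] == \
            [e.target_pool for e in prog.events]
        assert clone.events[0].onset <= clone.events[1].onset


class TestTemplates:
    def test_default_geometry_four_bursts_300ms_wide(self):
        t, profiles = gen_template_profiles(TemplateProfileSpec())
        assert profiles.shape[0] == 4
        for k in range(4):
            b = _bin20(profiles[k])
            width = (b >= 0.5 * b.max()).sum() * 20.0
            assert abs(width - 300.0) <= 20.0

    def test_successive_bursts_overlap_80ms(self):
        _, profiles = gen_template_profiles(TemplateProfileSpec())
        binned = [_bin20(p) for p in profiles]
        for a, b in zip(binned, binned[1:]):
            joint = ((a >= 0.5 * a.max()) & (b >= 0.5 * b.max())).sum() * 20.0
            assert abs(joint - 80.0) <= 20.0

    def test_baseline_subtraction_zeroes_interburst_rate(self):
        t, profiles = gen_template_profiles(TemplateProfileSpec(baseline=5.0))
        # far from its burst each profile is exactly zero
        assert profiles[0][t > 900].max() == 0.0
        assert profiles[-1][t < 300].max() == 0.0

    def test_peak_normalization(self):
        _, profiles = gen_template_profiles(TemplateProfileSpec(peak_rate=60.0))
        assert np.allclose(profiles.max(axis=1), 60.0)

    def test_deterministic(self):
        a = gen_template_profiles(TemplateProfileSpec())[1]
        b = gen_template_profiles(TemplateProfileSpec())[1]
        assert np.array_equal(a, b)

    def test_overlap_must_be_smaller_than_duration(self):
        with pytest.raises(ValueError):
            TemplateProfileSpec(burst_duration=300.0, overlap=300.0)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            StimulusEvent("p", 0.0, 0.0, 100.0, "constant", 10.0)
        with pytest.raises(ValueError):
            StimulusEvent("p", 0.5, 0.0, -5.0, "constant", 10.0)
        with pytest.raises(ValueError):
            StimulusEvent("p", 0.5, 0.0, 100.0, "wiggly", 10.0)


def test_program_yaml_round_trip(tmp_path):
    prog = StimulusProgram(events=[
        gen_feedback_train("sensory", "a", 300.0, seed=1, onset=50.0),
        gen_intention_burst("b", 0.2, 400.0, 150.0, seed=2),
    ])
    path = tmp_path / "program.yaml"
    prog.to_yaml(path)
    clone = StimulusProgram.from_yaml(path)
    assert clone.to_dict() == prog.to_dict()
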