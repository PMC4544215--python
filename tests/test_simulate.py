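"""Synthetic session generator: spacing constraints, uniform placement,
noise-free ERP recovery, reaction-time law, determinism."""

import itertools
import math

import numpy as np
import pytest

import rsvptriage as rt
from rsvptriage.simulate import (InfeasibleSequenceError, _sample_rare_slots,
                                 check_sequence_constraints,
                                 count_admissible_placements, erp_template,
                                 sample_reaction_times, spatial_pattern)


def _enumerate_admissible(n_slots, n_rare, gap):
    """Brute-force enumeration of admissible rare-position sets."""
    out = []
    for combo in itertools.combinations(range(n_slots), n_rare):
        ok = all(b - a >= gap + 1 for a, b in zip(combo, combo[1:]))
        ok = ok and (not combo or combo[-1] <= n_slots - 1 - gap)
        if ok:
            out.append(combo)
    return out


class TestSequence:
    def test_to_block_counts(self):
        # 2 Hz x 120 s with a 1:20 rare:frequent ratio -> 240 stimuli,
        # floor(240/21) = 11 targets per block
        cfg = rt.SimulationConfig(condition="TO")
        assert cfg.stimuli_per_block == 240
        counts = cfg.rare_counts_per_block()
        assert counts["target"] == 11
        assert counts["background"] == 229
        seq = rt.generate_sequence(cfg)
        assert seq.n_events == 6 * 240
        per_block = [
            (seq.classes[seq.block_ids == b] == "target").sum() for b in range(6)
        ]
        assert all(c == 11 for c in per_block)

    def test_tn_block_counts(self):
        cfg = rt.SimulationConfig(condition="TN")
        assert cfg.stimuli_per_block == 268
        counts = cfg.rare_counts_per_block()
        assert counts["target"] == 16
        assert counts["nontarget"] == 16

    @pytest.mark.parametrize("condition", ["TO", "TN"])
    def test_spacing_constraints_many_seeds(self, condition):
        # short blocks keep 1000 seeds cheap; constraints checked exhaustively
        for seed in range(1000):
            cfg = rt.SimulationConfig(condition=condition, n_blocks=1,
                                      block_duration_s=30.0, seed=seed)
            check_sequence_constraints(rt.generate_sequence(cfg), cfg)

    def test_infeasible_gap_raises(self):
        cfg = rt.SimulationConfig(condition="TO", n_blocks=1,
                                  block_duration_s=30.0, min_background_gap=50)
        with pytest.raises(InfeasibleSequenceError):
            rt.generate_sequence(cfg)

    def test_seed_determinism(self):
        cfg = rt.SimulationConfig(condition="TN", n_blocks=1, seed=42)
        a, b = rt.generate_sequence(cfg), rt.generate_sequence(cfg)
        assert np.array_equal(a.onsets_s, b.onsets_s)
        assert np.array_equal(a.classes, b.classes)

    def test_placement_count_matches_enumeration(self):
        for n_slots, n_rare, gap in [(10, 2, 2), (12, 3, 2), (8, 2, 1)]:
            expected = len(_enumerate_admissible(n_slots, n_rare, gap))
            assert count_admissible_placements(n_slots, n_rare, gap) == expected

    def test_placement_uniform_over_admissible(self, rng):
        # every admissible set should appear with equal frequency
        n_slots, n_rare, gap = 10, 2, 2
        admissible = _enumerate_admissible(n_slots, n_rare, gap)
        n_draws = 20000
        seen = {}
        for _ in range(n_draws):
            slots = tuple(_sample_rare_slots(rng, n_slots, n_rare, gap))
            assert slots in set(admissible)
            seen[slots] = seen.get(slots, 0) + 1
        assert len(seen) == len(admissible)
        expected = n_draws / len(admissible)
        # chi-square with |admissible|-1 dof; 5-sigma-ish guard band
        chi2 = sum((c - expected) ** 2 / expected for c in seen.values())
        dof = len(admissible) - 1
        assert chi2 < dof + 6 * math.sqrt(2 * dof)


class TestEEG:
    def test_noise_free_epoch_mean_equals_class_amplitude(self):
        # targets evoke a 13.66 uV mean amplitude (400-800 ms) at Pz when
        # noise and the other class amplitudes are zeroed
        cfg = rt.SimulationConfig(
            condition="TO", n_blocks=1, block_duration_s=30.0,
            noise_scale_uv=0.0, seed=3,
            erp_amplitudes_uv={"background": 0.0},
        )
        seq = rt.generate_sequence(cfg)
        eeg = rt.generate_eeg(seq, cfg)
        epochs = rt.epoch(eeg, seq, window_ms=(0.0, 1000.0), classes=("target",))
        amps = rt.mean_amplitude(rt.grand_average(epochs))
        assert amps["target"] == pytest.approx(13.66, abs=1e-9)

    def test_neighbor_overlap_does_not_leak_into_p3_window(self):
        # with background amplitude on, the 400-800 ms target window at Pz is
        # still exactly the target amplitude: the template fits between onsets
        cfg = rt.SimulationConfig(condition="TO", n_blocks=1,
                                  block_duration_s=30.0, noise_scale_uv=0.0,
                                  seed=3)
        seq = rt.generate_sequence(cfg)
        eeg = rt.generate_eeg(seq, cfg)
        epochs = rt.epoch(eeg, seq, window_ms=(0.0, 1000.0), classes=("target",))
        amps = rt.mean_amplitude(rt.grand_average(epochs))
        assert amps["target"] == pytest.approx(13.66, abs=1e-9)

    def test_zero_amplitudes_give_pure_noise(self):
        cfg = rt.SimulationConfig(
            condition="TO", n_blocks=1, block_duration_s=30.0, seed=5,
            erp_amplitudes_uv={"target": 0.0, "nontarget": 0.0,
                               "background": 0.0},
        )
        seq = rt.generate_sequence(cfg)
        eeg = rt.generate_eeg(seq, cfg)
        epochs = rt.epoch(eeg, seq, window_ms=(0.0, 1000.0))
        erps = rt.grand_average(epochs)
        amps = rt.mean_amplitude(erps)
        # class averages differ only by sampling error of the noise
        n_t = erps.n_trials["target"]
        sd = cfg.noise_scale_uv
        assert abs(amps["target"] - amps["background"]) < 6 * sd / np.sqrt(n_t)

    def test_evoked_average_linear_in_amplitude(self):
        base = dict(condition="TO", n_blocks=1, block_duration_s=30.0,
                    noise_scale_uv=0.0, seed=3)
        cfg1 = rt.SimulationConfig(**base)
        cfg2 = rt.SimulationConfig(
            **base, erp_amplitudes_uv={"target": 2 * 13.66, "background": -0.88}
        )
        seq = rt.generate_sequence(cfg1)
        e1 = rt.generate_eeg(seq, cfg1)
        e2 = rt.generate_eeg(seq, cfg2)
        assert np.allclose(e2.data, 2 * e1.data, atol=1e-9)

    def test_template_converges_to_class_average_as_noise_vanishes(self):
        devs = []
        for noise in (4.0, 1.0, 0.25):
            cfg = rt.SimulationConfig(condition="TO", n_blocks=1,
                                      block_duration_s=60.0, seed=11,
                                      noise_scale_uv=noise,
                                      erp_amplitudes_uv={"background": 0.0})
            seq = rt.generate_sequence(cfg)
            eeg = rt.generate_eeg(seq, cfg)
            epochs = rt.epoch(eeg, seq, window_ms=(0.0, 1000.0),
                              classes=("target",))
            avg = rt.grand_average(epochs).waveforms["target"]
            pz = eeg.pz_index()
            kernel = 13.66 * erp_template(cfg)
            tmpl = np.zeros(avg.shape[1])
            tmpl[: kernel.size] = kernel
            devs.append(np.abs(avg[pz] - tmpl).max())
        assert devs[0] > devs[-1]
        assert devs[-1] < 0.5  # close to the template at low noise

    def test_spatial_pattern_maximal_at_pz(self):
        cfg = rt.SimulationConfig(condition="TO")
        pattern, labels = spatial_pattern(cfg)
        assert labels.count("Pz") == 1
        assert pattern[labels.index("Pz")] == pytest.approx(1.0)
        assert pattern.argmax() == labels.index("Pz")

    def test_eeg_seed_determinism(self):
        cfg = rt.SimulationConfig(condition="TO", n_blocks=1,
                                  block_duration_s=20.0, seed=9)
        seq = rt.generate_sequence(cfg)
        assert np.array_equal(rt.generate_eeg(seq, cfg).data,
                              rt.generate_eeg(seq, cfg).data)

    def test_duration_covers_events_with_padding(self):
        cfg = rt.SimulationConfig(condition="TO", n_blocks=2,
                                  block_duration_s=20.0, seed=1)
        seq = rt.generate_sequence(cfg)
        eeg = rt.generate_eeg(seq, cfg)
        assert eeg.duration_s >= seq.onsets_s[-1] + 1.0
        assert np.all(np.isfinite(eeg.data))


class TestBehavior:
    def test_press_probability_zero_gives_no_presses(self):
        cfg = rt.SimulationConfig(
            condition="TO", n_blocks=1, block_duration_s=30.0, seed=2,
            behavior={"hit_probability": 0.0,
                      "background_press_probability": 0.0},
        )
        seq = rt.simulate_behavior(rt.generate_sequence(cfg), cfg)
        assert seq.presses_s.size == 0

    def test_rt_median_recovered(self, rng):
        # the log-normal RT law reproduces its configured median at large n
        rts = sample_reaction_times(rng, 514.67, 0.25, 100_000)
        se = 1.2533 * rts.std() / np.sqrt(rts.size)  # asymptotic median SE
        assert abs(np.median(rts) - 514.67) < 5 * se

    def test_invalid_rt_parameters_raise(self, rng):
        with pytest.raises(ValueError):
            sample_reaction_times(rng, -5.0, 0.25, 10)
        cfg = rt.SimulationConfig(condition="TO", n_blocks=1,
                                  block_duration_s=30.0,
                                  behavior={"rt_median_ms": -1.0})
        with pytest.raises(ValueError):
            rt.simulate_behavior(rt.generate_sequence(cfg), cfg)

    def test_presses_sorted_and_determined_by_seed(self):
        cfg = rt.SimulationConfig(condition="TN", n_blocks=1, seed=4)
        seq = rt.generate_sequence(cfg)
        a = rt.simulate_behavior(seq, cfg)
        b = rt.simulate_behavior(seq, cfg)
        assert np.array_equal(a.presses_s, b.presses_s)
        assert np.all(np.diff(a.presses_s) >= 0)

    def test_refilling_presses_rejected(self):
        cfg = rt.SimulationConfig(condition="TO", n_blocks=1,
                                  block_duration_s=30.0, seed=1)
        seq = rt.simulate_behavior(rt.generate_sequence(cfg), cfg)
        with pytest.raises(ValueError):
            rt.simulate_behavior(seq, cfg)


class TestContainer:
    def test_session_round_trip(self, tmp_path):
        cfg = rt.SimulationConfig(condition="TN", n_blocks=1,
                                  block_duration_s=30.0, seed=8)
        seq, eeg = rt.simulate_session(cfg)
        rt.simulate.save_session(tmp_path / "sess", seq, eeg, cfg)
        seq2, eeg2 = rt.simulate.load_session(tmp_path / "sess")
        assert np.allclose(seq2.onsets_s, seq.onsets_s)
        assert np.array_equal(seq2.classes, seq.classes)
        assert np.allclose(seq2.presses_s, seq.presses_s)
        assert np.array_equal(eeg2.data, eeg.data)
        assert eeg2.channel_labels == eeg.channel_labels
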