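"""Generator contracts: archetype libraries, Poisson statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

import costria
from costria import synthetic
from costria.evoked import compute_psth
from costria.synthetic import (
    ArchetypeKernel,
    ResponseSegment,
    build_archetype_library,
    reference_protocol,
    simulate_behavior,
    simulate_histology,
    simulate_spike_train,
    simulate_unit,
)


class TestArchetypeLibrary:
    def test_s1_has_four_kernels_dlst_six_with_flat(self):
        s1 = build_archetype_library("S1")
        dlst = build_archetype_library("DLSt")
        assert len(s1) == 4
        assert len(dlst) == 6
        flat = [k for k in dlst if not k.segments]
        assert len(flat) == 1
        offs = reference_protocol(1).pulse_offsets
        assert np.all(flat[0].sampled(offs) == 1.0)

    def test_unknown_region_rejected_with_valid_tags(self):
        with pytest.raises(ValueError, match="S1"):
            build_archetype_library("hippocampus")

    @pytest.mark.parametrize("region", ["S1", "DLSt"])
    def test_kernels_mutually_distinguishable(self, region):
        offs = reference_protocol(1).pulse_offsets
        curves = [k.sampled(offs) for k in build_archetype_library(region)]
        for i in range(len(curves)):
            for j in range(i + 1, len(curves)):
                a, b = curves[i], curves[j]
                if a.std() == 0 or b.std() == 0:
                    continue
                assert abs(np.corrcoef(a, b)[0, 1]) < 0.8

    @pytest.mark.parametrize("region", ["S1", "DLSt"])
    def test_gain_nonnegative_and_unity_outside_segments(self, region):
        offs = reference_protocol(1).pulse_offsets
        for k in build_archetype_library(region):
            g = k.sampled(offs)
            assert np.all(g >= 0)
            # before the first pulse's earliest segment the gain is 1
            assert g[0] == 1.0

    def test_nonpositive_pulse_scale_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            ArchetypeKernel("bad", (ResponseSegment(0.0, 0.1, 2.0),),
                            (1.0, 0.0, 1.0, 1.0, 1.0))


class TestSimulateUnit:
    def test_zero_rate_gives_empty_train(self, protocol):
        u = simulate_unit(build_archetype_library("S1")[0], 0.0, protocol, 100.0, seed=0)
        assert u.n_spikes == 0

    def test_negative_rate_and_duration_rejected(self, protocol):
        kern = build_archetype_library("S1")[0]
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_spike_train(kern, -1.0, protocol, 10.0, rng)
        with pytest.raises(ValueError):
            simulate_spike_train(kern, 1.0, protocol, -10.0, rng)

    def test_flat_kernel_rate_conservation(self, protocol):
        """gain == 1: empirical rate within 3 Poisson SDs of the nominal rate."""
        rate, duration = 5.0, 600.0
        flat = ArchetypeKernel("flat")
        rng = np.random.default_rng(7)
        spikes = simulate_spike_train(flat, rate, protocol, duration, rng)
        expected = rate * duration
        assert abs(spikes.size - expected) < 3 * np.sqrt(expected)

    def test_same_seed_reproduces_bit_identical_unit(self, protocol):
        kern = build_archetype_library("S1")[2]
        a = simulate_unit(kern, 5.0, protocol, 200.0, seed=42)
        b = simulate_unit(kern, 5.0, protocol, 200.0, seed=42)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.waveform, b.waveform)

    def test_pause_kernel_produces_psth_trough(self):
        """A gain-0.1 pause at 30-80 ms post pulse shows up as a PSTH trough,
        and the trial-averaged PSTH correlates > 0.9 with the gain curve."""
        protocol = reference_protocol(n_trains=250)
        duration = protocol.train_onsets[-1] + 5.0
        kern = ArchetypeKernel("pause", (ResponseSegment(0.030, 0.080, 0.1),))
        rng = np.random.default_rng(3)
        spikes = simulate_spike_train(kern, 20.0, protocol, duration, rng)
        counts, edges = compute_psth(spikes, protocol.train_onsets,
                                     window=(0.0, 1.5), binsize=0.01)
        rate = counts.mean(axis=0) / 0.01
        centers = (edges[:-1] + edges[1:]) / 2
        gain = kern.gain(centers, protocol.pulse_offsets)
        pause_bins = rate[(centers >= 0.03) & (centers < 0.08)]
        outside = rate[(centers >= 0.285) & (centers < 0.302)]
        assert pause_bins.mean() < 0.5 * max(outside.mean(), 1e-9) + 1.0
        assert np.corrcoef(rate, gain)[0, 1] > 0.9


class TestSimulateSession:
    def test_protocol_shape(self, small_s1_session):
        p = small_s1_session.protocol
        assert p.n_pulses == 5
        assert p.pulse_interval == pytest.approx(1 / 3.3)
        assert p.train_onsets.size == 50
        assert np.allclose(np.diff(p.train_onsets), 5.0)

    def test_label_counts_multinomially_consistent(self):
        w = 0.25
        cfg = costria.default_config(
            "S1", n_units=300, seed=5,
            archetype_weights={"sustained": w, "pause": w, "triphasic": w, "sharp": w},
        )
        s = costria.simulate_session(cfg)
        counts = pd.Series([u.truth_labels["archetype"] for u in s.units]).value_counts()
        # each count within 4 binomial SDs of n*w
        sd = np.sqrt(300 * w * (1 - w))
        assert set(counts.index) == {"sustained", "pause", "triphasic", "sharp"}
        assert all(abs(c - 300 * w) < 4 * sd for c in counts)

    def test_determinism_and_unit_stability_under_resizing(self):
        cfg = costria.default_config("S1", n_units=20, seed=9)
        a = costria.simulate_session(cfg)
        b = costria.simulate_session(cfg)
        for ua, ub in zip(a.units, b.units):
            assert np.array_equal(ua.spike_times, ub.spike_times)
        bigger = costria.simulate_session(costria.default_config("S1", n_units=25, seed=9))
        for ua, ub in zip(a.units, bigger.units[:20]):
            assert np.array_equal(ua.spike_times, ub.spike_times)

    def test_bad_mixture_weights_rejected(self):
        cfg = costria.default_config(
            "S1", n_units=10, seed=0,
            archetype_weights={"sustained": 0.5, "pause": 0.2,
                               "triphasic": 0.2, "sharp": 0.2},
        )
        with pytest.raises(ValueError, match="sum"):
            costria.simulate_session(cfg)

    def test_spikes_within_duration_and_sorted(self, small_s1_session):
        for u in small_s1_session.units:
            if u.n_spikes:
                assert u.spike_times[0] >= 0
                assert u.spike_times[-1] <= small_s1_session.duration
                assert np.all(np.diff(u.spike_times) >= 0)


class TestHistologyGenerator:
    def _means(self):
        return pd.DataFrame(
            {"group": ["control", "VPA"], "region": ["DLSt", "DLSt"],
             "marker": ["ChAT", "ChAT"], "density": [50.32, 21.69]}
        )

    def test_zero_noise_reproduces_means_exactly(self):
        table = simulate_histology(self._means(), noise_sd=0.0, n_animals=3, seed=0)
        dens = table["count"] / table["area_mm2"]
        assert np.allclose(
            dens[table["group"] == "control"], 50.32
        ) and np.allclose(dens[table["group"] == "VPA"], 21.69)

    def test_sem_scale_matches_configured_noise(self):
        """With noise_sd = printed SEM * sqrt(7) and n = 7 animals, the group
        SEM of the simulated densities lands within 50% of the printed SEM."""
        sem = 2.460
        means = self._means().iloc[[0]]
        reps = []
        for seed in range(30):
            t = simulate_histology(means, noise_sd=sem * np.sqrt(7), n_animals=7, seed=seed)
            per_animal = t.groupby("animal_id").apply(
                lambda g: (g["count"] / g["area_mm2"]).mean(), include_groups=False
            )
            reps.append(per_animal.std(ddof=1) / np.sqrt(7))
        assert abs(np.median(reps) - sem) < 0.5 * sem

    def test_negative_mean_and_single_animal_rejected(self):
        bad = self._means().assign(density=[-1.0, 10.0])
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_histology(bad, 1.0, 3, 0)
        with pytest.raises(ValueError, match="n_animals"):
            simulate_histology(self._means(), 1.0, 1, 0)


class TestBehaviorGenerator:
    def _config(self, sem=0.46):
        return pd.DataFrame(
            {"measure": ["contacts"], "group": ["control"],
             "mean": [10.67], "sem": [sem], "n": [18]}
        )

    def test_group_mean_within_two_sem(self):
        t = simulate_behavior(self._config(), seed=4)
        assert abs(t["value"].mean() - 10.67) < 2 * 0.46

    def test_zero_sem_collapses_onto_mean(self):
        t = simulate_behavior(self._config(sem=0.0), seed=4)
        assert np.allclose(t["value"], 10.67)

    def test_seeded_regeneration_identical(self):
        a = simulate_behavior(self._config(), seed=8)
        b = simulate_behavior(self._config(), seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            simulate_behavior(self._config(sem=-1.0), seed=0)


class TestConfigLoading:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "pop.yml"
        p.write_text("region: DLSt\ngroup: VPA\nn_units: 6\nseed: 3\n")
        cfg = synthetic.load_config(p)
        assert cfg.region == "DLSt" and cfg.group == "VPA"
        assert abs(sum(cfg.archetype_weights.values()) - 1.0) < 1e-9
        s = costria.simulate_session(cfg)
        assert len(s.units) == 6


class TestWaveforms:
    def test_templates_distinct_and_trough_normalized(self):
        w = {c: synthetic.waveform_template(c) for c in synthetic.WAVEFORM_CLASSES}
        for v in w.values():
            assert v.min() == pytest.approx(-1.0)
        assert np.corrcoef(w["msn"], w["fsi"])[0, 1] < 0.95

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown waveform"):
            synthetic.waveform_template("pyramidal")
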