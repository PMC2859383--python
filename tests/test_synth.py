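"""Synthetic-data generator: population structure, calibration, determinism."""
import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from gigglekit.audio import read_wav
from gigglekit.synth import (
    ConfigurationError,
    SynthesisConfig,
    make_population,
    population_frame,
    simulate_note_features,
    synthesize_bout,
    synthesize_note,
    truncated_normal,
    write_dataset,
    _draw_note_count,
)


class TestPopulation:
    def test_default_colony_structure(self, population, metadata):
        assert len(population) == 17
        ages = metadata["age"]
        assert ages.min() == 2 and ages.max() == 20
        assert metadata["dyad_id"].nunique() == 8
        # each housing group has exactly one dominant
        for _, grp in metadata.groupby("dyad_id"):
            assert (grp["dominance"] == "dominant").sum() == 1
            assert len(grp) in (2, 3)

    def test_note_count_bookkeeping(self, metadata):
        n = metadata["n_notes"]
        assert n.sum() == 695
        assert round(n.mean()) == 41
        assert n.min() == 20 and n.max() == 98

    def test_minimal_dyad(self):
        cfg = SynthesisConfig(seed=0)
        pop = make_population(
            cfg,
            colony=[
                ("x", "female", 5, "dominant", "control", 1, 20),
                ("y", "male", 5, "subordinate", "control", 1, 20),
            ],
        )
        assert {r.dominance for r in pop} == {"dominant", "subordinate"}

    def test_two_dominants_rejected(self):
        cfg = SynthesisConfig(seed=0)
        with pytest.raises(ConfigurationError):
            make_population(
                cfg,
                colony=[
                    ("x", "female", 5, "dominant", "control", 1, 20),
                    ("y", "male", 5, "dominant", "control", 1, 20),
                ],
            )

    def test_same_seed_identical(self, default_config):
        a = population_frame(make_population(default_config))
        b = population_frame(make_population(default_config))
        pd.testing.assert_frame_equal(a, b)
        # latent signatures identical too
        la = [r.target_f0_hz for r in make_population(default_config)]
        lb = [r.target_f0_hz for r in make_population(default_config)]
        assert la == lb

    def test_age_slope_enters_target_f0(self, default_config):
        """Two animals 18 years apart differ by ~18 x 14.7 Hz in expected
        target F0 (up to their individual offsets)."""
        rng = default_rng(0)
        diffs = []
        for seed in range(40):
            cfg = SynthesisConfig(seed=seed)
            pop = make_population(
                cfg,
                colony=[
                    ("young", "female", 2, "dominant", "control", 1, 20),
                    ("old", "male", 20, "subordinate", "control", 1, 20),
                ],
            )
            young = next(r for r in pop if r.animal_id == "young")
            old = next(r for r in pop if r.animal_id == "old")
            diffs.append(young.target_f0_hz - old.target_f0_hz)
        expected = 18 * 14.7
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - expected) < 2 * se + 1e-9


class TestDraws:
    def test_truncated_normal_preserves_mean(self):
        rng = default_rng(5)
        draws = truncated_normal(rng, 7.1, 4.1, 1.5, size=50_000)
        assert draws.min() >= 1.5
        assert abs(draws.mean() - 7.1) < 2 * draws.std() / np.sqrt(len(draws))

    def test_bout_note_count_calibration(self, default_config):
        rng = default_rng(11)
        counts = np.array(
            [_draw_note_count(default_config, rng) for _ in range(10_000)]
        )
        assert counts.min() >= 2
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 7.1) < 2 * se + 0.05  # rounding slack


class TestNote:
    def test_pure_tone_when_no_upper_harmonics(self, population):
        cfg = SynthesisConfig(seed=3, n_harmonics=0, noise_snr=80.0)
        pop = make_population(cfg)
        note = synthesize_note(pop[0], cfg, default_rng(2))
        # single spectral component: spectrum mean equals the peak frequency
        from gigglekit.features import welch_spectrum

        spec = welch_spectrum(note)
        peak = spec.frequencies[np.argmax(spec.power)]
        assert abs(spec.mean - peak) < 0.1 * peak

    def test_duration_bounds(self, population, default_config):
        rng = default_rng(4)
        for _ in range(20):
            note = synthesize_note(population[0], default_config, rng)
            assert 0.02 <= note.duration <= 0.2

    def test_samples_bounded(self, population, default_config):
        note = synthesize_note(population[1], default_config, default_rng(0))
        assert np.all(np.abs(note.samples) <= 1.0)
        assert np.all(np.isfinite(note.samples))


class TestBout:
    def test_minimum_two_notes(self, population, default_config):
        seen = []
        for s in range(60):
            _, segs = synthesize_bout(population[0], default_config, default_rng(s))
            seen.append(len(segs))
        assert min(seen) >= 2

    def test_segments_ordered_nonoverlapping(self, population, default_config):
        wave, segs = synthesize_bout(population[2], default_config, default_rng(9))
        for a, b in zip(segs, segs[1:]):
            assert a.end_s <= b.start_s
        assert segs[0].start_s >= 0
        assert segs[-1].end_s <= wave.duration + 1e-9

    def test_segment_contains_note_energy(self, population):
        """>= 90% of a note's energy lies inside its segment (noise-free
        config so the note energy is unambiguous)."""
        cfg = SynthesisConfig(seed=5, noise_snr=90.0)
        pop = make_population(cfg)
        wave, segs = synthesize_bout(pop[0], cfg, default_rng(3))
        total = np.sum(wave.samples**2)
        inside = sum(
            np.sum(wave.slice(s.start_s, s.end_s).samples ** 2) for s in segs
        )
        assert inside / total >= 0.9

    def test_typical_bout_under_one_second(self, population, default_config):
        """Bouts at the mean note count span < 1 s."""
        durs = []
        for s in range(40):
            wave, segs = synthesize_bout(population[3], default_config, default_rng(s))
            if 6 <= len(segs) <= 8:
                durs.append(wave.duration)
        assert durs and np.median(durs) < 1.0


class TestDataset:
    def test_written_dataset_roundtrip(self, audio_dataset):
        segs = audio_dataset["segments"]
        assert (segs.groupby("animal_id").size() >= 20).all()
        wav = read_wav(audio_dataset["root"] / segs["wav_path"].iloc[0])
        assert wav.sample_rate == 44100

    def test_wav_bitwise_roundtrip(self, tmp_path, population, default_config):
        from gigglekit.audio import write_wav

        wave, _ = synthesize_bout(population[0], default_config, default_rng(1))
        write_wav(tmp_path / "x.wav", wave)
        w1 = read_wav(tmp_path / "x.wav")
        write_wav(tmp_path / "y.wav", w1)
        w2 = read_wav(tmp_path / "y.wav")
        assert np.array_equal(w1.samples, w2.samples)

    def test_empty_population(self, tmp_path, default_config):
        meta, segs = write_dataset([], default_config, tmp_path)
        assert len(meta) == 0 and len(segs) == 0
        assert not list((tmp_path / "wav").glob("*.wav"))

    def test_dataset_deterministic(self, tmp_path, default_config):
        colony = [
            ("x", "female", 5, "dominant", "control", 1, 20),
            ("y", "male", 5, "subordinate", "control", 1, 20),
        ]
        pop = make_population(default_config, colony=colony)
        _, s1 = write_dataset(pop, default_config, tmp_path / "a")
        _, s2 = write_dataset(pop, default_config, tmp_path / "b")
        pd.testing.assert_frame_equal(s1, s2)
        f1 = sorted((tmp_path / "a" / "wav").glob("*.wav"))
        f2 = sorted((tmp_path / "b" / "wav").glob("*.wav"))
        assert [p.read_bytes() for p in f1] == [p.read_bytes() for p in f2]


class TestTwin:
    def test_feature_invariants(self, twin_features):
        f = twin_features
        assert (f["min_f"] <= f["mean_f"]).all()
        assert (f["mean_f"] <= f["max_f"]).all()
        assert (f["q1"] <= f["q2"]).all() and (f["q2"] <= f["q3"]).all()
        assert (f["dur"] > 0).all()
        assert f["ent"].between(0, 1).all()
        assert (f["sd_s"] >= 0).all()

    def test_null_dominance_configuration(self):
        """With the dominance delta at zero, subordinate and dominant
        CVMeanS distributions are statistically indistinguishable."""
        from scipy.stats import ttest_ind

        from gigglekit.features import individual_profile

        cfg = SynthesisConfig(seed=31, dominance_cv_means_delta=0.0)
        pop = make_population(cfg)
        subs, doms = [], []
        for rep in range(10):
            feats = simulate_note_features(
                pop, cfg, default_rng(500 + rep), notes_per_animal=40
            )
            prof = individual_profile(feats).merge(
                population_frame(pop), on="animal_id"
            )
            subs.extend(prof[prof.dominance == "subordinate"]["cv_mean_s"])
            doms.extend(prof[prof.dominance == "dominant"]["cv_mean_s"])
        _, p = ttest_ind(subs, doms)
        assert p > 0.01

    def test_injected_dominance_delta_recovered(self):
        """The generator's subordinate-minus-dominant CVMeanS difference
        recovers the configured delta within 2 SE over repeated draws
        (many notes per animal so estimator small-sample bias is minor)."""
        from gigglekit.features import individual_profile

        deltas = []
        for seed in range(16):
            cfg = SynthesisConfig(seed=seed)
            pop = make_population(cfg)
            feats = simulate_note_features(
                pop, cfg, default_rng(900 + seed), notes_per_animal=150
            )
            prof = individual_profile(feats).merge(
                population_frame(pop), on="animal_id"
            )
            deltas.append(
                prof[prof.dominance == "subordinate"]["cv_mean_s"].mean()
                - prof[prof.dominance == "dominant"]["cv_mean_s"].mean()
            )
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas) - 0.082) < 2 * se + 0.005
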