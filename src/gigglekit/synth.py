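"""Synthetic giggle-bout generator.

Giggle bouts are rapid successions of short (~70 ms) harmonic notes. The
generator produces WAV bouts plus metadata and note-segment tables for a
population of animals with known, configurable structure:

* a per-animal **individual signature**: fixed random offsets on fundamental
  frequency, spectral tilt and note duration, drawn once at population
  creation;
* an **age effect**: the animal's target fundamental decreases linearly with
  age (default -14.7 Hz/yr around the colony mean age);
* a **dominance effect**: the cross-note coefficient of variation of the
  spectrum mean frequency (CVMeanS) is higher for subordinate animals than
  for dominants of the same age, by a configurable delta (default +0.082).

Each note is a harmonic stack whose fundamental follows a rise-fall parabolic
contour, with a spectral envelope decaying at a per-note tilt (dB/octave),
a Hann amplitude envelope, and additive white noise at a configurable SNR.

A statistical twin of the acoustic model (:func:`simulate_note_features`)
draws the 13 per-note features directly, for Monte-Carlo studies where
synthesising and re-tracking audio would be needlessly slow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import optimize
from scipy.signal.windows import hann
from scipy.stats import norm, truncnorm

from .audio import Waveform, write_wav

__all__ = [
    "SynthesisConfig",
    "AnimalRecord",
    "NoteSegment",
    "DEFAULT_COLONY",
    "make_population",
    "population_frame",
    "synthesize_note",
    "synthesize_bout",
    "write_dataset",
    "simulate_note_features",
]


class ConfigurationError(ValueError):
    """Invalid population or synthesis configuration."""


@dataclass
class SynthesisConfig:
    """Parameters of the forward model.

    Frequency parameters are Hz, durations seconds, tilt dB/octave. The
    defaults reproduce the summary statistics of the captive-colony study
    population this generator emulates: notes of 69 +/- 18 ms, per-note mean
    fundamental 547 +/- 146 Hz, bouts of mean 7.1 (SD 4.1) notes, an age
    slope of -14.7 Hz/yr on the fundamental, and a subordinate-minus-dominant
    difference of +0.082 in the cross-note CV of the spectrum mean.
    """

    sample_rate: int = 44100
    population_mean_f0: float = 547.0
    population_sd_f0: float = 146.0
    age_slope_f0: float = -14.7
    note_duration_mean: float = 0.069
    note_duration_sd: float = 0.018
    notes_per_bout_mean: float = 7.1
    notes_per_bout_sd: float = 4.1
    dominance_cv_means_delta: float = 0.082
    n_harmonics: int = 7  # harmonics above the fundamental
    spectral_tilt: float = -6.0
    noise_snr: float = 25.0
    seed: int = 0
    # decomposition of the population F0 variance
    individual_f0_sd: float = 100.0
    note_f0_sd: float = 75.0
    # other per-animal signature components
    individual_tilt_sd: float = 1.5
    individual_duration_sd: float = 0.008
    # within-note contour: CV F ~ 0.298 * depth, so depth 0.52 -> CV F ~ 0.155
    contour_depth_mean: float = 0.52
    contour_depth_sd: float = 0.2
    # baseline cross-note CV of the spectrum mean for dominant animals;
    # dominant 0.31 and subordinate 0.31 + 0.082 average to ~0.35
    cv_means_base: float = 0.31
    # inter-note gaps (a 7-note bout spans < 1 s by default)
    gap_mean: float = 0.07
    gap_sd: float = 0.02
    min_note_duration: float = 0.02
    # optional true group effect on F0 (off by default; used in power studies)
    dominance_f0_shift: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sample_rate",
            "population_mean_f0",
            "population_sd_f0",
            "note_duration_mean",
            "note_duration_sd",
            "notes_per_bout_mean",
            "notes_per_bout_sd",
            "gap_mean",
            "min_note_duration",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_harmonics < 0:
            raise ConfigurationError("n_harmonics must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnimalRecord:
    """One animal: public metadata plus latent signature parameters.

    The latent fields (target_f0_hz, tilt_db, duration_mean_s,
    cv_means_target) are drawn once at population creation and define the
    animal's individual signature; they never appear in metadata.csv.
    """

    animal_id: str
    sex: str
    age: float
    dominance: str
    treatment: str
    dyad_id: int
    n_notes: int = 40
    target_f0_hz: float | None = None
    tilt_db: float | None = None
    duration_mean_s: float | None = None
    cv_means_target: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"bad sex {self.sex!r}")
        if self.dominance not in ("dominant", "subordinate"):
            raise ConfigurationError(f"bad dominance {self.dominance!r}")
        if not 0 < self.age:
            raise ConfigurationError("age must be positive")


@dataclass
class NoteSegment:
    """Location of one note inside a bout WAV."""

    bout_id: str
    note_index: int
    start_s: float
    end_s: float
    animal_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError("segment requires 0 <= start < end")


# Reference colony used as the default population: 17 animals housed in
# 7 dominant/subordinate dyads and one triad, ages 2-20 years, with the
# hormonal-treatment groups and per-animal analysed-note counts of the
# captive colony the generator's defaults emulate.
# tuple: (animal_id, sex, age, dominance, treatment, dyad_id, n_notes)
DEFAULT_COLONY: tuple[tuple, ...] = (
    ("rocco", "male", 20, "subordinate", "control", 1, 20),
    ("domino", "female", 13, "dominant", "anti_androgen", 1, 63),
    ("gremlin", "male", 14, "subordinate", "anti_androgen", 2, 98),
    ("kadogo", "female", 6, "dominant", "anti_estrogen", 2, 33),
    ("winnie", "male", 14, "subordinate", "anti_androgen", 3, 40),
    ("kombo", "female", 9, "dominant", "control", 3, 42),
    ("dusty", "male", 11, "dominant", "gonadectomized", 4, 35),
    ("denali", "male", 11, "subordinate", "control", 4, 27),
    ("buster", "male", 7, "subordinate", "anti_estrogen", 5, 52),
    ("bj", "female", 12, "dominant", "gonadectomized", 5, 33),
    ("nakuru", "female", 14, "subordinate", "anti_androgen", 6, 26),
    ("nairobi", "female", 14, "dominant", "anti_androgen", 6, 31),
    ("ursa", "female", 10, "subordinate", "control", 7, 53),
    ("cass", "female", 10, "dominant", "control", 7, 55),
    ("tembo", "male", 2, "subordinate", "anti_androgen", 8, 26),
    ("haji", "female", 2, "subordinate", "anti_androgen", 8, 21),
    ("jambo", "female", 2, "dominant", "anti_androgen", 8, 40),
)

# per-note realized mean F0 is kept inside the tracker's physical band
_F0_NOTE_FLOOR = 120.0
_F0_NOTE_CEIL = 960.0
# clip bounds for the per-note spectral-envelope multiplier
_ENV_CLIP = (0.55, 3.2)


# ---------------------------------------------------------------------------
# calibrated random draws


@lru_cache(maxsize=256)
def _truncnorm_loc(mean: float, sd: float, lower: float) -> float:
    """Location mu* such that a normal(mu*, sd) truncated at ``lower`` has
    the requested mean. Keeps configured means exact under truncation."""
    if mean - lower > 8 * sd:
        return mean  # truncation negligible

    def f(mu: float) -> float:
        a = (lower - mu) / sd
        return truncnorm.mean(a, np.inf, loc=mu, scale=sd) - mean

    lo, hi = lower - 10 * sd, mean + 2 * sd
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def truncated_normal(
    rng: Generator, mean: float, sd: float, lower: float, size=None
):
    """Mean-preserving truncated-normal draw (support [lower, inf))."""
    mu = _truncnorm_loc(float(mean), float(sd), float(lower))
    a = (lower - mu) / sd
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


@lru_cache(maxsize=2048)
def _env_sigma_for_cv(cv: float, lo: float = _ENV_CLIP[0], hi: float = _ENV_CLIP[1]) -> float:
    """Log-scale sigma such that the clipped lognormal multiplier
    clip(exp(N(-s^2/2, s)), lo, hi) has coefficient of variation ``cv``.

    Solved by Gauss-grid quadrature with the *actual* clip bounds of the
    animal (which depend on how much spectral-tilt headroom its envelope
    leaves), so the injected cross-note CV of the spectrum mean survives
    clipping by construction.
    """
    if cv <= 1e-4:
        return 1e-4
    z = np.linspace(-6.0, 6.0, 4001)
    w = norm.pdf(z)
    w /= w.sum()

    def cv_of(s: float) -> float:
        m = np.clip(np.exp(s * z - s * s / 2.0), lo, hi)
        mean = np.sum(w * m)
        var = np.sum(w * (m - mean) ** 2)
        return math.sqrt(var) / mean

    s_max = 1.6
    if cv_of(s_max) <= cv:
        return s_max
    return float(optimize.brentq(lambda s: cv_of(s) - cv, 1e-5, s_max, xtol=1e-8))


# ---------------------------------------------------------------------------
# harmonic envelope geometry


def _harmonic_powers(tilt_db: float, n_components: int) -> np.ndarray:
    k = np.arange(1, n_components + 1, dtype=float)
    return 10.0 ** (tilt_db * np.log2(k) / 10.0)


def _centroid_ratio(tilt_db: float, n_components: int) -> float:
    """Spectrum-mean-to-fundamental ratio of an ideal stack at this tilt."""
    k = np.arange(1, n_components + 1, dtype=float)
    w = _harmonic_powers(tilt_db, n_components)
    return float(np.sum(k * w) / np.sum(w))


@lru_cache(maxsize=16)
def _tilt_table(n_components: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(-40.0, 12.0 + 1e-9, 0.05)
    r = np.array([_centroid_ratio(ti, n_components) for ti in t])
    return t, r


def _tilt_for_ratio(ratio: float, n_components: int) -> float:
    """Invert the (monotone) tilt -> centroid-ratio map; clips to its range."""
    t, r = _tilt_table(n_components)
    return float(np.interp(ratio, r, t))


# ---------------------------------------------------------------------------
# population


def _validate_housing(records: Sequence[AnimalRecord]) -> None:
    by_dyad: dict[int, list[AnimalRecord]] = {}
    for rec in records:
        by_dyad.setdefault(rec.dyad_id, []).append(rec)
    for dyad_id, members in by_dyad.items():
        if len(members) not in (2, 3):
            raise ConfigurationError(
                f"dyad {dyad_id} has {len(members)} members (need 2, or 3 for a triad)"
            )
        n_dom = sum(m.dominance == "dominant" for m in members)
        if n_dom != 1:
            raise ConfigurationError(
                f"dyad {dyad_id} has {n_dom} dominants (need exactly 1)"
            )


def make_population(
    config: SynthesisConfig, colony: Iterable[tuple] | None = None
) -> list[AnimalRecord]:
    """Create the animal table and draw each animal's latent signature.

    ``colony`` rows are (animal_id, sex, age, dominance, treatment, dyad_id,
    n_notes); the default is the built-in 17-animal reference colony.
    Deterministic under a fixed config seed.
    """
    rows = tuple(colony) if colony is not None else DEFAULT_COLONY
    records = [AnimalRecord(*row) for row in rows]
    if not records:
        return []
    _validate_housing(records)
    for rec in records:
        if rec.n_notes < 20:
            raise ConfigurationError(
                f"{rec.animal_id}: n_notes must be >= 20 (got {rec.n_notes})"
            )
    mean_age = float(np.mean([r.age for r in records]))
    rng = default_rng(SeedSequence(entropy=config.seed, spawn_key=(0,)))
    for rec in records:
        f0_offset = rng.normal(0.0, config.individual_f0_sd)
        tilt_offset = rng.normal(0.0, config.individual_tilt_sd)
        dur_offset = rng.normal(0.0, config.individual_duration_sd)
        shift = config.dominance_f0_shift if rec.dominance == "subordinate" else 0.0
        rec.target_f0_hz = (
            config.population_mean_f0
            + config.age_slope_f0 * (rec.age - mean_age)
            + f0_offset
            + shift
        )
        rec.tilt_db = config.spectral_tilt + tilt_offset
        rec.duration_mean_s = max(
            config.note_duration_mean + dur_offset, config.min_note_duration + 0.005
        )
        rec.cv_means_target = config.cv_means_base + (
            config.dominance_cv_means_delta if rec.dominance == "subordinate" else 0.0
        )
    return records


def population_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Public metadata table (latent signature fields excluded)."""
    cols = ["animal_id", "sex", "age", "dominance", "treatment", "dyad_id", "n_notes"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


# ---------------------------------------------------------------------------
# note / bout synthesis


def _within_duration_sd(config: SynthesisConfig) -> float:
    v = config.note_duration_sd**2 - config.individual_duration_sd**2
    return math.sqrt(max(v, 1e-6))


def _draw_note_params(animal: AnimalRecord, config: SynthesisConfig, rng: Generator):
    """Per-note latent draws shared by the audio and statistical models."""
    if animal.target_f0_hz is None:
        raise ConfigurationError(
            "animal lacks latent signature fields; create it via make_population"
        )
    dur = float(
        truncated_normal(
            rng, animal.duration_mean_s, _within_duration_sd(config),
            config.min_note_duration,
        )
    )
    f0 = float(
        np.clip(
            animal.target_f0_hz + rng.normal(0.0, config.note_f0_sd),
            _F0_NOTE_FLOOR,
            _F0_NOTE_CEIL,
        )
    )
    depth = float(
        np.clip(rng.normal(config.contour_depth_mean, config.contour_depth_sd), 0.05, 0.9)
    )
    # keep the contour peak inside the tracker's 1 kHz search band
    depth = min(depth, max(0.05, 3.0 * (970.0 / f0 - 1.0)))
    cv_f = config.note_f0_sd / max(animal.target_f0_hz, 1.0)
    cv_env = math.sqrt(max(animal.cv_means_target**2 - cv_f**2, 1e-4))
    n_comp = config.n_harmonics + 1
    r_animal = _centroid_ratio(animal.tilt_db, n_comp)
    _, r_grid = _tilt_table(n_comp)
    # the multiplier can only be realised inside the invertible tilt range
    lo = max(_ENV_CLIP[0], 1.01 * float(r_grid[0]) / r_animal)
    hi = min(_ENV_CLIP[1], 0.99 * float(r_grid[-1]) / r_animal)
    s = _env_sigma_for_cv(round(cv_env, 4), round(lo, 3), round(hi, 3))
    env_mult = float(np.clip(np.exp(rng.normal(-s * s / 2.0, s)), lo, hi))
    tilt = _tilt_for_ratio(r_animal * env_mult, n_comp)
    return dur, f0, depth, tilt


@lru_cache(maxsize=256)
def _smear_bias(dur_ms: int, window_sd_s: float = 0.0032) -> float:
    """Relative bias of the short-time tracked mean F0 per unit contour depth.

    A Gaussian analysis window weights the instantaneous frequency by the
    (Hann) amplitude envelope, so frames near the note edges report
    frequencies pulled toward the louder interior. For the parabolic
    contour f = f0 (1 + c g(u)) the tracked mean is f0 (1 + c B), with B
    depending only on the note-duration / window-width geometry. B is
    computed here by quadrature and used to centre the synthesised contour
    on the *measured* mean. The envelope enters with an effective exponent
    of 1.6 -- between amplitude (1) and power (2) weighting -- which is how
    strongly the spectral ridge estimator favours the louder part of the
    window on this forward model.
    """
    dur = dur_ms / 1000.0
    n = 400
    t = np.linspace(0.0, dur, n)
    u = np.linspace(-1.0, 1.0, n)
    g = (1.0 - u * u) - 2.0 / 3.0
    env = np.sin(np.pi * np.arange(n) / (n - 1)) ** 3.2
    centers = np.linspace(0.0, dur, max(int(dur * 1000), 10))
    est = np.empty(len(centers))
    for i, tc in enumerate(centers):
        w = env * np.exp(-0.5 * ((t - tc) / window_sd_s) ** 2)
        est[i] = float(np.sum(w * g) / np.sum(w))
    return float(est.mean())


def synthesize_note(
    animal: AnimalRecord, config: SynthesisConfig, rng: Generator
) -> Waveform:
    """One giggle note: harmonic stack on a rise-fall parabolic F0 contour.

    The contour is f(u) = f_c * (1 + depth * ((1 - u^2) - 2/3)), u in
    [-1, 1], with the centre f_c chosen so that the *short-time tracked*
    mean F0 (which is amplitude-weighted by the Hann envelope; see
    :func:`_smear_bias`) equals the drawn per-note target. Noise is added
    at bout level so notes here are noise-free.
    """
    dur, f0, depth, tilt = _draw_note_params(animal, config, rng)
    fs = config.sample_rate
    n = max(int(round(dur * fs)), int(round(config.min_note_duration * fs)))
    u = np.linspace(-1.0, 1.0, n)
    f_center = f0 / (1.0 + depth * _smear_bias(int(round(dur * 1000))))
    contour = f_center * (1.0 + depth * ((1.0 - u * u) - 2.0 / 3.0))
    phase = 2.0 * np.pi * np.cumsum(contour) / fs
    n_comp = config.n_harmonics + 1
    amps = np.sqrt(_harmonic_powers(tilt, n_comp))
    amps /= math.sqrt(float(np.sum(amps**2)))
    k = np.arange(1, n_comp + 1, dtype=float)
    phases0 = rng.uniform(0.0, 2.0 * np.pi, n_comp)
    x = (amps[:, None] * np.sin(k[:, None] * phase[None, :] + phases0[:, None])).sum(0)
    x *= hann(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.5 / peak
    return Waveform(x, fs)


def _draw_note_count(config: SynthesisConfig, rng: Generator) -> int:
    raw = truncated_normal(
        rng, config.notes_per_bout_mean, config.notes_per_bout_sd, 1.5
    )
    return max(2, int(round(float(raw))))


def synthesize_bout(
    animal: AnimalRecord,
    config: SynthesisConfig,
    rng: Generator,
    bout_id: str = "bout",
) -> tuple[Waveform, list[NoteSegment]]:
    """A bout: >= 2 notes separated by short gaps, plus white noise at the
    configured SNR (SNR referenced to the RMS of the note samples)."""
    n_notes = _draw_note_count(config, rng)
    fs = config.sample_rate
    pad = int(round(0.02 * fs))
    pieces: list[np.ndarray] = [np.zeros(pad)]
    segments: list[NoteSegment] = []
    cursor = pad
    note_energy = 0.0
    note_samples = 0
    for i in range(n_notes):
        note = synthesize_note(animal, config, rng)
        start = cursor / fs
        pieces.append(note.samples)
        cursor += len(note.samples)
        segments.append(
            NoteSegment(bout_id, i, start, cursor / fs, animal.animal_id)
        )
        note_energy += float(np.sum(note.samples**2))
        note_samples += len(note.samples)
        if i < n_notes - 1:
            gap = float(truncated_normal(rng, config.gap_mean, config.gap_sd, 0.02))
            g = int(round(gap * fs))
            pieces.append(np.zeros(g))
            cursor += g
    pieces.append(np.zeros(pad))
    x = np.concatenate(pieces)
    rms = math.sqrt(note_energy / max(note_samples, 1))
    noise_sd = rms * 10.0 ** (-config.noise_snr / 20.0)
    x = x + rng.normal(0.0, noise_sd, len(x))
    wave = Waveform(x, fs).normalized(0.9)
    return wave, segments


def write_dataset(
    population: Sequence[AnimalRecord],
    config: SynthesisConfig,
    out_dir: str | Path,
    notes_per_animal: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write one WAV per bout plus metadata.csv and segments.csv.

    Bouts are generated per animal until its note target is reached
    (``notes_per_animal`` if given, else the animal's n_notes, never below
    20 so balanced analyses remain possible). Per-animal/per-bout RNG
    substreams are derived from the master seed by counter, so a dataset is
    byte-identical under a fixed (config, population) and unchanged for
    animal i even if other animals are regenerated.

    Returns (metadata, segments) as DataFrames; the same tables are written
    as CSV.
    """
    out = Path(out_dir)
    wav_dir = out / "wav"
    out.mkdir(parents=True, exist_ok=True)
    wav_dir.mkdir(exist_ok=True)
    seg_rows = []
    for ai, animal in enumerate(population):
        target = notes_per_animal if notes_per_animal is not None else animal.n_notes
        target = max(int(target), 20)
        got = 0
        bout_idx = 0
        while got < target:
            rng = default_rng(
                SeedSequence(entropy=config.seed, spawn_key=(1, ai, bout_idx))
            )
            bout_id = f"{animal.animal_id}_b{bout_idx:03d}"
            wave, segments = synthesize_bout(animal, config, rng, bout_id=bout_id)
            wav_path = wav_dir / f"{bout_id}.wav"
            write_wav(wav_path, wave)
            for seg in segments:
                seg_rows.append(
                    {
                        "wav_path": str(Path("wav") / wav_path.name),
                        "bout_id": seg.bout_id,
                        "note_index": seg.note_index,
                        "start_s": seg.start_s,
                        "end_s": seg.end_s,
                        "animal_id": seg.animal_id,
                    }
                )
            got += len(segments)
            bout_idx += 1
    metadata = population_frame(population)
    segments_df = pd.DataFrame(
        seg_rows,
        columns=["wav_path", "bout_id", "note_index", "start_s", "end_s", "animal_id"],
    )
    metadata.to_csv(out / "metadata.csv", index=False)
    segments_df.to_csv(out / "segments.csv", index=False)
    return metadata, segments_df


# ---------------------------------------------------------------------------
# statistical twin of the acoustic model


def simulate_note_features(
    population: Sequence[AnimalRecord],
    config: SynthesisConfig,
    rng: Generator | int,
    notes_per_animal: int | None = None,
) -> pd.DataFrame:
    """Draw the 13 per-note features directly from the statistical model.

    Mirrors the acoustic forward model (same latent per-animal signatures and
    per-note draws) without synthesising or re-tracking audio; used for
    Monte-Carlo calibration and power studies. Columns: animal_id plus the
    13 feature columns of :mod:`gigglekit.features`.
    """
    if isinstance(rng, (int, np.integer)):
        rng = default_rng(int(rng))
    rows = []
    n_comp = config.n_harmonics + 1
    for animal in population:
        n = notes_per_animal if notes_per_animal is not None else animal.n_notes
        r_eps = 1.0 + rng.normal(0.0, 0.02, size=(n, 2))
        for j in range(int(n)):
            dur, f0, depth, tilt = _draw_note_params(animal, config, rng)
            mean_s = f0 * _centroid_ratio(tilt, n_comp) * (1.0 + rng.normal(0, 0.03))
            q2 = mean_s * 0.87 * math.exp(rng.normal(0.0, 0.10))
            q1 = q2 * min(0.98, 0.75 * math.exp(rng.normal(0.0, 0.08)))
            q3 = q2 * (1.0 + abs(rng.normal(0.41, 0.20)))
            cv_f = 0.298 * depth * (1.0 + rng.normal(0.0, 0.10))
            rows.append(
                {
                    "animal_id": animal.animal_id,
                    "mean_f": f0,
                    "max_f": f0 * (1.0 + depth / 3.0) * abs(r_eps[j, 0]),
                    "min_f": f0 * (1.0 - 2.0 * depth / 3.0) * min(abs(r_eps[j, 1]), 1.0),
                    "cv_f": max(cv_f, 0.0),
                    "q1": q1,
                    "q2": q2,
                    "q3": q3,
                    "mean_s": mean_s,
                    "sd_s": mean_s * 0.8 * math.exp(rng.normal(0.0, 0.15)),
                    "skew": 2.56 * math.exp(rng.normal(0.0, 0.40)),
                    "kurt": 3.0 + 15.5 * math.exp(rng.normal(0.0, 0.60)),
                    "ent": float(np.clip(rng.normal(0.52, 0.08), 0.01, 0.99)),
                    "dur": dur,
                }
            )
    df = pd.DataFrame(rows)
    df["max_f"] = np.maximum(df["max_f"], df["mean_f"])
    df["min_f"] = np.minimum(df["min_f"], df["mean_f"])
    return df
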