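"""Per-note acoustic parameters and per-individual summaries.

Thirteen parameters describe each giggle note:

* from the tracked fundamental: MeanF, MaxF, MinF and the coefficient of
  variation CVF (sample SD / mean), over accepted frames only;
* from the Welch average periodogram (23.2 ms Hann windows, 50% overlap,
  band-limited to 15 kHz): the energy-quartile frequencies Q1, Q2, Q3, the
  spectrum mean MeanS and SD SDS, the standardised third and fourth moments
  Skew and Kurt (non-excess), and the normalised spectral entropy Ent;
* the note duration Dur (segment length).

Per individual, the cross-note mean and SD of MeanF and MeanS give
GrandMeanF/SDMeanF/CVMeanF and GrandMeanS/SDMeanS/CVMeanS -- a quantitative
measure of how much an animal varies the pitch and timbre of its notes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .audio import Waveform, read_wav
from .pitch import PitchTrack, TrackerParams, track_fundamental

__all__ = [
    "FEATURE_COLUMNS",
    "PowerSpectrum",
    "NoteFeatureVector",
    "IndividualProfile",
    "welch_spectrum",
    "pitch_stats",
    "spectral_shape",
    "extract_features",
    "individual_profile",
    "extract_dataset_features",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "mean_f",
    "max_f",
    "min_f",
    "cv_f",
    "q1",
    "q2",
    "q3",
    "mean_s",
    "sd_s",
    "skew",
    "kurt",
    "ent",
    "dur",
]

_WELCH_WINDOW_S = 0.0232
_BAND_MAX_HZ = 15000.0


@dataclass
class PowerSpectrum:
    """Normalised power spectrum: p(f_i) >= 0, sum p(f_i) = 1."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        total = self.power.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"power must sum to 1 (got {total})")

    @property
    def mean(self) -> float:
        return float(np.sum(self.frequencies * self.power))

    @property
    def variance(self) -> float:
        return float(np.sum((self.frequencies - self.mean) ** 2 * self.power))


@dataclass
class NoteFeatureVector:
    mean_f: float
    max_f: float
    min_f: float
    cv_f: float
    q1: float
    q2: float
    q3: float
    mean_s: float
    sd_s: float
    skew: float
    kurt: float
    ent: float
    dur: float

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}


@dataclass
class IndividualProfile:
    animal_id: str
    grand_mean_f: float
    sd_mean_f: float
    cv_mean_f: float
    grand_mean_s: float
    sd_mean_s: float
    cv_mean_s: float
    n_notes: int


def welch_spectrum(note: Waveform) -> PowerSpectrum:
    """Welch average periodogram of a note, normalised to unit total power.

    23.2 ms Hann windows with 50% overlap; the spectrum is band-limited to
    [0, 15 kHz] (the recording chain's response) before normalisation. A
    note shorter than one window is analysed as a single zero-padded window
    with a warning.
    """
    fs = note.sample_rate
    nperseg = int(round(_WELCH_WINDOW_S * fs))
    x = note.samples
    if len(x) < nperseg:
        warnings.warn("note shorter than one Welch window; zero-padding")
        x = np.pad(x, (0, nperseg - len(x)))
    freqs, pxx = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    band = freqs <= _BAND_MAX_HZ
    freqs, pxx = freqs[band], pxx[band]
    total = pxx.sum()
    if total <= 0:
        raise ValueError("zero-power note")
    return PowerSpectrum(freqs, pxx / total)


def pitch_stats(track: PitchTrack) -> tuple[float, float, float, float]:
    """(MeanF, MaxF, MinF, CVF) over accepted frames; sample SD (n-1).

    Raises ValueError when fewer than 2 frames were accepted (such notes
    are flagged and excluded downstream).
    """
    f0 = track.accepted_f0
    if len(f0) < 2:
        raise ValueError(f"only {len(f0)} accepted pitch frames (need >= 2)")
    mean = float(np.mean(f0))
    sd = float(np.std(f0, ddof=1))
    return mean, float(np.max(f0)), float(np.min(f0)), sd / mean


def spectral_shape(s: PowerSpectrum) -> tuple[float, ...]:
    """(Q1, Q2, Q3, MeanS, SDS, Skew, Kurt, Ent) of a normalised spectrum.

    Qk is the smallest frequency whose cumulative energy reaches k/4. Skew
    and Kurt are the standardised third/fourth central moments (kurtosis
    non-excess, Gaussian reference 3). Ent = -sum p log2 p / log2 N, in
    [0, 1]. With zero spectral variance Skew/Kurt are undefined (NaN).
    """
    f, p = s.frequencies, s.power
    cum = np.cumsum(p)
    quartiles = [float(f[np.searchsorted(cum, q)]) for q in (0.25, 0.50, 0.75)]
    mean_s = s.mean
    var = s.variance
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (f - mean_s) / sd
        skew = float(np.sum(z**3 * p))
        kurt = float(np.sum(z**4 * p))
    else:
        skew = float("nan")
        kurt = float("nan")
    nz = p[p > 0]
    n_bins = len(p)
    ent = float(-np.sum(nz * np.log2(nz)) / np.log2(n_bins)) if n_bins > 1 else 0.0
    return (*quartiles, mean_s, sd, skew, kurt, ent)


def extract_features(
    note: Waveform, track: PitchTrack, duration_s: float | None = None
) -> NoteFeatureVector:
    """Assemble the 13 parameters of one note.

    ``duration_s`` is the segment length; defaults to the note's own length.
    """
    mean_f, max_f, min_f, cv_f = pitch_stats(track)
    q1, q2, q3, mean_s, sd_s, skew, kurt, ent = spectral_shape(welch_spectrum(note))
    dur = float(duration_s) if duration_s is not None else note.duration
    if dur <= 0:
        raise ValueError("duration must be positive")
    return NoteFeatureVector(
        mean_f, max_f, min_f, cv_f, q1, q2, q3, mean_s, sd_s, skew, kurt, ent, dur
    )


def individual_profile(features: pd.DataFrame) -> pd.DataFrame:
    """Per-animal cross-note summaries of MeanF and MeanS.

    ``features`` must carry an ``animal_id`` column plus ``mean_f`` and
    ``mean_s``; every animal needs >= 2 notes. CV identities
    (CV = SD / mean) hold exactly.
    """
    rows = []
    for animal_id, grp in features.groupby("animal_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"animal {animal_id!r} has {len(grp)} note(s); need >= 2")
        gmf = float(grp["mean_f"].mean())
        sdf = float(grp["mean_f"].std(ddof=1))
        gms = float(grp["mean_s"].mean())
        sds = float(grp["mean_s"].std(ddof=1))
        rows.append(
            {
                "animal_id": animal_id,
                "grand_mean_f": gmf,
                "sd_mean_f": sdf,
                "cv_mean_f": sdf / gmf,
                "grand_mean_s": gms,
                "sd_mean_s": sds,
                "cv_mean_s": sds / gms,
                "n_notes": len(grp),
            }
        )
    return pd.DataFrame(rows)


def extract_dataset_features(
    data_dir: str | Path,
    segments: pd.DataFrame | None = None,
    tracker_params: TrackerParams | None = None,
) -> pd.DataFrame:
    """Track and featurise every note of a written dataset.

    Reads ``segments.csv`` (or the given table) and the bout WAVs under
    ``data_dir``; returns one row per note (ids + 13 features). Notes with
    fewer than 2 accepted pitch frames are dropped and logged.
    """
    root = Path(data_dir)
    if segments is None:
        segments = pd.read_csv(root / "segments.csv")
    rows = []
    n_dropped = 0
    for wav_path, grp in segments.groupby("wav_path", sort=True):
        wave = read_wav(root / wav_path)
        for _, seg in grp.iterrows():
            note = wave.slice(seg["start_s"], seg["end_s"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                track = track_fundamental(note, tracker_params)
            try:
                fv = extract_features(
                    note, track, duration_s=seg["end_s"] - seg["start_s"]
                )
            except ValueError:
                n_dropped += 1
                continue
            rows.append(
                {
                    "wav_path": wav_path,
                    "bout_id": seg["bout_id"],
                    "note_index": seg["note_index"],
                    "animal_id": seg["animal_id"],
                    **fv.as_dict(),
                }
            )
    if n_dropped:
        log.info("dropped %d notes with < 2 accepted pitch frames", n_dropped)
    return pd.DataFrame(rows)
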