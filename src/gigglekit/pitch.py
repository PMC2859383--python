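"""Bayesian fundamental-frequency tracking at 1 ms resolution.

Two independent per-frame F0 estimators are fused:

1. **cepstrum** -- the inverse time of the highest peak in the Fourier
   transform of the log spectrum;
2. **harmonic peak spacing** -- the smallest distance between successive
   major peaks of the short-time spectrum, with a peak prepended at 0 Hz.

Each estimator yields a set of candidate fundamentals with likelihoods; the
posterior over a 1 Hz grid combines both likelihoods with a history prior
(uniform below 1 kHz for the first frames, thereafter a Gaussian centred on
the linear extrapolation of the previous three accepted estimates). The best
guess and its posterior probability are returned per frame; low-probability
frames are dismissed as lacking clear periodicity.

The short-time analysis uses Gaussian windows with a time/frequency scale of
3.2 ms / 50 Hz (standard deviations).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .audio import Waveform

__all__ = [
    "TrackerParams",
    "Spectrogram",
    "CandidateSet",
    "PitchTrack",
    "compute_spectrogram",
    "cepstral_candidates",
    "peak_spacing_candidates",
    "candidate_density",
    "track_fundamental",
]


@dataclass
class TrackerParams:
    """Tunable constants of the tracker (defaults used throughout)."""

    window_time_sd: float = 0.0032  # s; Gaussian window SD
    hop: float = 0.001  # s; frame step
    nfft: int = 4096
    f0_min: float = 50.0  # below the recording chain's response
    f0_max: float = 1000.0  # prior support
    dismissal_threshold: float = 0.5  # posterior probability below -> dismissed
    prior_sd: float = 50.0  # Hz; one frequency-window SD
    candidate_sd: float = 15.0  # Hz; width of candidate likelihood bumps
    peak_prominence_db: float = 10.0  # "major" spectral peaks
    spacing_band_max: float = 10000.0  # Hz; spectrum band used for peak spacing
    prob_halfwidth: float = 50.0  # Hz; posterior mass window around the guess
    min_source_confidence: float = 0.15  # gate: at least one estimator must clear it
    cepstrum_snr: float = 3.0  # peak height vs band SD for full confidence
    # per-frame dynamic range; the log spectrum is clamped to (max - this)
    # so that floor-level window-truncation ripples cannot masquerade as
    # periodicity once the log scale magnifies them
    dynamic_range_db: float = 50.0


@dataclass
class Spectrogram:
    """Log-magnitude (dB) short-time spectra on a 1 ms frame grid."""

    frame_times: np.ndarray  # s
    frequencies: np.ndarray  # Hz
    values: np.ndarray  # dB, shape (n_frames, n_freq)
    window_time_sd: float  # s
    window_freq_sd: float  # Hz = 1 / (2 pi window_time_sd)
    sample_rate: int


@dataclass
class CandidateSet:
    """Candidate fundamentals from one estimator.

    ``likelihood`` entries are non-negative and sum to at most 1; the
    shortfall from 1 is the estimator's leftover mass on "no clear
    periodicity". ``primary`` is the estimator's single headline guess
    (highest cepstral peak / smallest major-peak spacing).
    """

    f0: np.ndarray
    likelihood: np.ndarray
    source: str
    primary: float | None = None

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if np.any(self.likelihood < 0):
            raise ValueError("likelihoods must be non-negative")
        if self.likelihood.sum() > 1.0 + 1e-9:
            raise ValueError("likelihoods must sum to <= 1")

    @property
    def confidence(self) -> float:
        return float(self.likelihood.sum())

    def __len__(self) -> int:
        return len(self.f0)


@dataclass
class PitchTrack:
    """Time-varying fundamental with per-frame posterior probability.

    Dismissed frames carry NaN in ``f0``.
    """

    times: np.ndarray
    f0: np.ndarray
    posterior_prob: np.ndarray
    dismissed: np.ndarray

    @property
    def accepted_f0(self) -> np.ndarray:
        return self.f0[~self.dismissed]

    @property
    def n_accepted(self) -> int:
        return int(np.sum(~self.dismissed))


def compute_spectrogram(w: Waveform, params: TrackerParams | None = None) -> Spectrogram:
    """Gaussian-window STFT with frames every 1 ms.

    Raises ValueError when the signal is shorter than one analysis window.
    """
    p = params or TrackerParams()
    fs = w.sample_rate
    if fs < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    sd_samp = p.window_time_sd * fs
    half = int(round(3.0 * sd_samp))
    win_len = 2 * half + 1
    if len(w.samples) < win_len:
        raise ValueError(
            f"signal of {len(w.samples)} samples is shorter than one "
            f"{win_len}-sample analysis window"
        )
    n_frames = max(1, int(round(w.duration / p.hop)))
    times = np.arange(n_frames) * p.hop
    centers = np.round(times * fs).astype(int)
    # offset-subtracted Gaussian: touches zero at the ends, so window
    # truncation adds no sidelobe ripple for the log scale to magnify
    window = np.exp(-0.5 * ((np.arange(win_len) - half) / sd_samp) ** 2) - np.exp(-4.5)
    padded = np.concatenate([np.zeros(half), w.samples, np.zeros(half + 1)])
    frames = padded[centers[:, None] + np.arange(win_len)[None, :]] * window
    spec = np.fft.rfft(frames, n=p.nfft, axis=1)
    mag = np.abs(spec)
    values = 20.0 * np.log10(mag + 1e-300)
    frame_max = values.max(axis=1, keepdims=True)
    values = np.maximum(values, frame_max - p.dynamic_range_db)
    freqs = np.fft.rfftfreq(p.nfft, 1.0 / fs)
    return Spectrogram(
        frame_times=times,
        frequencies=freqs,
        values=values,
        window_time_sd=p.window_time_sd,
        window_freq_sd=1.0 / (2.0 * np.pi * p.window_time_sd),
        sample_rate=fs,
    )


def _parabolic(y: np.ndarray, i: int) -> float:
    """Sub-sample peak refinement; returns fractional offset in [-0.5, 0.5]."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))


def cepstral_candidates(
    log_spectrum_db: np.ndarray,
    sample_rate: int,
    params: TrackerParams | None = None,
) -> CandidateSet:
    """Candidates from the Fourier transform of one frame's log spectrum.

    The quefrency band searched corresponds to F0 in [f0_min, f0_max];
    likelihoods are peak heights normalised over the retained peaks, scaled
    by an overall periodicity confidence (highest peak vs the band's SD).
    Returns an empty set when no peak clears the noise floor.
    """
    p = params or TrackerParams()
    ceps = np.fft.irfft(log_spectrum_db)
    q_lo = int(np.ceil(sample_rate / p.f0_max))
    q_hi = int(np.floor(sample_rate / p.f0_min))
    q_hi = min(q_hi, len(ceps) // 2 - 1)
    band = ceps[q_lo:q_hi]
    if len(band) < 5:
        return CandidateSet(np.array([]), np.array([]), "cepstrum")
    peaks, props = find_peaks(band, height=0.0)
    if len(peaks) == 0:
        return CandidateSet(np.array([]), np.array([]), "cepstrum")
    heights = props["peak_heights"]
    order = np.argsort(heights)[::-1][:4]
    peaks, heights = peaks[order], heights[order]
    sd = float(np.std(band)) + 1e-12
    rho = max(0.0, min(0.98, 1.0 - p.cepstrum_snr * sd / float(heights[0])))
    if rho <= 0.0:
        return CandidateSet(np.array([]), np.array([]), "cepstrum")
    # the cepstral oscillation rides a decaying envelope which displaces
    # each peak toward smaller quefrency; estimate the local envelope decay
    # and undo the first-order shift  delta_q = lambda q^2 / (4 pi^2)
    env = gaussian_filter1d(np.abs(band), 15.0) + 1e-12
    log_env = np.log(env)
    f0s = []
    for i in peaks:
        q = q_lo + i + _parabolic(band, i)
        m = 10
        if m <= i < len(band) - m:
            lam = -(log_env[i + m] - log_env[i - m]) / (2 * m)
            q += float(np.clip(lam * (i + q_lo) ** 2 / (4 * np.pi**2), -3.0, 3.0))
        f0s.append(sample_rate / q)
    f0s = np.array(f0s)
    keep = (f0s >= p.f0_min) & (f0s <= p.f0_max)
    if not np.any(keep):
        return CandidateSet(np.array([]), np.array([]), "cepstrum")
    f0s, heights = f0s[keep], heights[keep]
    weights = heights / heights.sum()
    return CandidateSet(f0s, rho * weights, "cepstrum", primary=float(f0s[0]))


def peak_spacing_candidates(
    spectrum_db: np.ndarray,
    frequencies: np.ndarray,
    params: TrackerParams | None = None,
) -> CandidateSet:
    """Candidates from spacings of successive major spectral peaks.

    Major peaks are local maxima at least ``peak_prominence_db`` above the
    band median. A peak at 0 Hz is prepended before differencing, so a lone
    peak at f yields the candidate f. The primary candidate is the smallest
    in-band spacing; likelihoods reflect how consistently each spacing
    recurs across successive peak pairs, damped when few peaks exist.
    """
    p = params or TrackerParams()
    band = frequencies <= p.spacing_band_max
    x = spectrum_db[band]
    f = frequencies[band]
    if len(x) < 5:
        return CandidateSet(np.array([]), np.array([]), "peak_spacing")
    df = f[1] - f[0]
    floor = float(np.median(x))
    min_dist = max(1, int(round(0.8 * p.f0_min / df)))
    peaks, _ = find_peaks(
        x, height=floor + p.peak_prominence_db, prominence=6.0, distance=min_dist
    )
    if len(peaks) == 0:
        return CandidateSet(np.array([]), np.array([]), "peak_spacing")
    pf = np.array([f[i] + _parabolic(x, i) * df for i in peaks])
    spacings = np.diff(np.concatenate([[0.0], pf]))
    # greedy clustering of spacings within 10%
    clusters: list[list[float]] = []
    for s in np.sort(spacings):
        if clusters and abs(s - np.mean(clusters[-1])) <= 0.1 * np.mean(clusters[-1]):
            clusters[-1].append(s)
        else:
            clusters.append([s])
    centers = np.array([np.mean(c) for c in clusters])
    counts = np.array([len(c) for c in clusters], dtype=float)
    in_band = (centers >= p.f0_min) & (centers <= p.f0_max)
    if not np.any(in_band):
        return CandidateSet(np.array([]), np.array([]), "peak_spacing")
    centers, counts = centers[in_band], counts[in_band]
    # damp confidence when the frame offers few peaks to corroborate
    n_peaks = len(peaks)
    rho = n_peaks / (n_peaks + 2.0)
    weights = rho * counts / spacings.size
    primary = float(centers[np.argmin(centers)])
    return CandidateSet(centers, weights, "peak_spacing", primary=primary)


def candidate_density(
    cands: CandidateSet, grid: np.ndarray, sigma: float = 15.0
) -> np.ndarray:
    """Likelihood of each grid frequency under one estimator.

    Mixture of Gaussian bumps at the candidates (weights = likelihoods) plus
    a uniform floor carrying the estimator's leftover mass; normalised to
    sum 1 over the grid.
    """
    dens = np.full(len(grid), max(1.0 - float(cands.likelihood.sum()), 1e-3) / len(grid))
    for f0, lik in zip(cands.f0, cands.likelihood):
        bump = np.exp(-0.5 * ((grid - f0) / sigma) ** 2)
        s = bump.sum()
        if s > 0:
            dens += lik * bump / s
    return dens / dens.sum()


def _prior_density(
    grid: np.ndarray,
    history_t: list[float],
    history_f: list[float],
    t: float,
    prior_sd: float,
) -> np.ndarray:
    if len(history_f) < 3:
        return np.full(len(grid), 1.0 / len(grid))
    ts = np.array(history_t[-3:])
    fs_ = np.array(history_f[-3:])
    slope, intercept = np.polyfit(ts, fs_, 1)
    pred = float(np.clip(slope * t + intercept, grid[0], grid[-1]))
    bump = np.exp(-0.5 * ((grid - pred) / prior_sd) ** 2)
    # a heavy uniform tail lets the track recover from an octave lock when
    # both estimators agree far from the extrapolation
    dens = 0.9 * bump / bump.sum() + 0.1 / len(grid)
    return dens / dens.sum()


def track_fundamental(
    w: Waveform, params: TrackerParams | None = None
) -> PitchTrack:
    """Track the fundamental of a (single-voiced) note at 1 ms steps.

    Per frame the posterior over a 1 Hz grid is prior x cepstral likelihood
    x peak-spacing likelihood; the guess is the posterior mode and its
    probability the posterior mass within ``prob_halfwidth`` of the mode.
    Frames below the dismissal threshold, or where neither estimator finds
    evidence of periodicity, are dismissed. An all-dismissed signal returns
    an empty-valued track with a warning rather than raising.
    """
    p = params or TrackerParams()
    spect = compute_spectrogram(w, p)
    grid = np.arange(p.f0_min, p.f0_max + 1.0, 1.0)
    n = len(spect.frame_times)
    f0 = np.full(n, np.nan)
    prob = np.zeros(n)
    dismissed = np.ones(n, dtype=bool)
    hist_t: list[float] = []
    hist_f: list[float] = []
    for i in range(n):
        row = spect.values[i]
        cep = cepstral_candidates(row, spect.sample_rate, p)
        ps = peak_spacing_candidates(row, spect.frequencies, p)
        if max(cep.confidence, ps.confidence) < p.min_source_confidence:
            continue  # no periodicity evidence in either estimator
        prior = _prior_density(grid, hist_t, hist_f, spect.frame_times[i], p.prior_sd)
        post = prior * candidate_density(cep, grid, p.candidate_sd)
        post *= candidate_density(ps, grid, p.candidate_sd)
        total = post.sum()
        if total <= 0:
            continue
        post /= total
        best = int(np.argmax(post))
        guess = grid[best]
        mass = float(post[np.abs(grid - guess) <= p.prob_halfwidth].sum())
        prob[i] = mass
        if mass >= p.dismissal_threshold:
            f0[i] = guess
            dismissed[i] = False
            hist_t.append(float(spect.frame_times[i]))
            hist_f.append(float(guess))
    if not np.any(~dismissed):
        warnings.warn("all frames dismissed: no clear periodicity found")
    return PitchTrack(spect.frame_times, f0, prob, dismissed)
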