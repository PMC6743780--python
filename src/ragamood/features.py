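"""Acoustic descriptors of raga excerpts: tonality, pulse clarity, tempo.

Tonality follows the tonic-interval histogram procedure: melodic pitch per
30 ms frame is expressed in cents relative to the tonic drone,
``1200 * log2(f1 / f0)``, collated into 100-cent bins spanning three octaves
(-1200..2400 cents), folded into one octave by summing corresponding bins,
and summarized as the minor-to-major occupancy ratio m/M.  Minor bins are
the komal positions plus the tritone {100, 300, 600, 800, 1000}; major bins
are the shuddh positions {0, 200, 400, 500, 700, 900, 1100}.

Rhythm is summarized by two descriptors: *pulse clarity*, one minus the
normalized Shannon entropy of the onset-envelope fluctuation spectrum
(0.25-10 Hz), high when energy fluctuates at a regular beat; and *event
density*, detected note onsets per second.  Both are deliberately simple
spectral-flux operationalizations: their absolute values are not comparable
to MIRtoolbox's, so analyses assert orderings and contrasts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .synth import (FRAME_HOP_S, MAJOR_CLASSES, MINOR_CLASSES, SAMPLE_RATE)

HIST_BIN_CENTS = np.arange(-1200, 2500, 100)   # 37 labels, -1200..2400
FOLDED_BIN_CENTS = np.arange(0, 1200, 100)

# onset detection / envelope parameters
ONSET_NFFT = 1024
ONSET_HOP = 256
ONSET_SMOOTH_S = 0.06         # moving-average width on the flux envelope
ONSET_BASELINE_S = 2.0        # local-median baseline window
ONSET_PEAK_THRESHOLD = 0.5    # fraction of the 98th-percentile detrended flux
ONSET_MIN_GAP_S = 0.15
FLUCTUATION_BAND_HZ = (0.25, 10.0)
FLUCTUATION_SEGMENT_S = 24.0  # Welch segment length for the fluctuation spectrum


def hz_to_cents(f1: float, f0: float):
    """Interval of ``f1`` above the reference ``f0``, in cents."""
    f1 = np.asarray(f1, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f1 <= 0) or np.any(f0 <= 0):
        raise ValueError("frequencies must be positive")
    return 1200.0 * np.log2(f1 / f0)


@dataclass
class PitchTrack:
    """Melodic pitch per 30 ms frame, referenced to a tonic.

    ``cents`` holds the tonic interval per frame; NaN marks unvoiced
    frames.  ``pitch_hz`` is derived on demand.
    """

    frame_times: np.ndarray
    cents: np.ndarray
    tonic_hz: float
    onset_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.tonic_hz <= 0:
            raise ValueError("tonic_hz must be positive")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.cents = np.asarray(self.cents, dtype=float)

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.cents)

    @property
    def pitch_hz(self) -> np.ndarray:
        return self.tonic_hz * 2.0 ** (self.cents / 1200.0)


@dataclass
class IntervalHistogram:
    """Tonic-interval counts in 100-cent bins from -1200 to 2400 cents."""

    counts: np.ndarray
    total_voiced: int
    n_out_of_range: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != HIST_BIN_CENTS.shape:
            raise ValueError(f"expected {HIST_BIN_CENTS.size} bins")

    @property
    def bin_cents(self) -> np.ndarray:
        return HIST_BIN_CENTS


@dataclass
class SwaraProfile:
    """Octave-folded 12-bin profile with the derived m/M tonality ratio."""

    folded: np.ndarray
    tonality_ratio: float = None
    undefined_ratio: bool = False

    def __post_init__(self):
        self.folded = np.asarray(self.folded, dtype=float)
        if self.folded.shape != FOLDED_BIN_CENTS.shape:
            raise ValueError("folded profile must have 12 bins")
        if self.tonality_ratio is None:
            total = self.folded.sum()
            props = self.folded / total if total > 0 else self.folded
            m = props[[FOLDED_BIN_CENTS.tolist().index(c) for c in MINOR_CLASSES]].sum()
            M = props[[FOLDED_BIN_CENTS.tolist().index(c) for c in MAJOR_CLASSES]].sum()
            if M == 0:
                self.tonality_ratio = np.inf
                self.undefined_ratio = True
            else:
                self.tonality_ratio = m / M

    @property
    def proportions(self) -> np.ndarray:
        total = self.folded.sum()
        return self.folded / total if total > 0 else self.folded


# ---------------------------------------------------------------------------
# Pitch estimation (for real recordings; synthetic tracks carry ground truth)
# ---------------------------------------------------------------------------

def estimate_pitch_track(waveform: np.ndarray, tonic_hz: float,
                         sr: int = SAMPLE_RATE, hop_s: float = FRAME_HOP_S,
                         fmin: float = 80.0, fmax: float = 1200.0,
                         voicing_threshold: float = 0.5) -> PitchTrack:
    """Frame-wise predominant-pitch estimate by windowed autocorrelation.

    A deliberately simple estimator for monophonic melody-over-drone audio:
    per 30 ms hop, the strongest normalized autocorrelation peak in the
    [fmin, fmax] lag range gives the pitch, refined by parabolic
    interpolation.  Frames are marked unvoiced when periodicity is weak or
    the frame energy falls to the drone-only floor (an adaptive RMS gate,
    which also suppresses drone-dominant frames between melody notes).
    """
    y = np.asarray(waveform, dtype=float)
    hop = int(round(hop_s * sr))
    win = 2048
    if y.size < win:
        y = np.pad(y, (0, win - y.size))
    n_frames = max(1, 1 + (y.size - win) // hop)
    times = np.arange(n_frames) * hop / sr
    cents = np.full(n_frames, np.nan)

    lag_min = int(sr / fmax)
    lag_max = int(sr / fmin)
    hann = np.hanning(win)

    rms = np.empty(n_frames)
    frames = np.empty((n_frames, win))
    for i in range(n_frames):
        fr = y[i * hop:i * hop + win]
        frames[i] = fr * hann
        rms[i] = np.sqrt(np.mean(fr ** 2))
    # energy gate: drone-only / silent frames sit well below the median
    # of active frames
    active_floor = 0.75 * np.median(rms[rms > 0]) if np.any(rms > 0) else 0.0

    for i in range(n_frames):
        if rms[i] <= max(active_floor, 1e-6):
            continue
        fr = frames[i]
        ac = signal.correlate(fr, fr, mode="full")[win - 1:]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        seg = ac[lag_min:lag_max + 1]
        k = int(np.argmax(seg))
        if seg[k] < voicing_threshold:
            continue
        lag = lag_min + k
        if 0 < lag < win - 1:  # parabolic refinement
            a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = a - 2 * b + c
            if denom != 0:
                lag = lag + 0.5 * (a - c) / denom
        f0 = sr / lag
        if fmin <= f0 <= fmax:
            cents[i] = hz_to_cents(f0, tonic_hz)
    return PitchTrack(frame_times=times, cents=cents, tonic_hz=tonic_hz)


# ---------------------------------------------------------------------------
# Tonality
# ---------------------------------------------------------------------------

def build_interval_histogram(track: PitchTrack) -> IntervalHistogram:
    """Collate voiced frames into the 100-cent tonic-interval histogram.

    Each voiced frame is assigned to the nearest bin label (label +/- 50
    cents); frames outside [-1250, 2450) are dropped and counted.
    """
    v = track.cents[track.voiced]
    if v.size == 0:
        raise ValueError("pitch track has no voiced frames")
    idx = np.round(v / 100.0).astype(int)
    in_range = (idx >= -12) & (idx <= 24)
    counts = np.bincount(idx[in_range] + 12, minlength=HIST_BIN_CENTS.size)
    return IntervalHistogram(counts=counts, total_voiced=int(v.size),
                             n_out_of_range=int((~in_range).sum()))


def fold_octaves(hist: IntervalHistogram) -> SwaraProfile:
    """Fold the three-octave histogram into one octave by summing bins.

    ``folded[k] = hist[k-1200] + hist[k] + hist[k+1200]`` for k in
    0..1100; the bin at +2400 cents folds onto the tonic class.  Total
    counts are conserved.
    """
    counts = hist.counts
    folded = np.zeros(12, dtype=float)
    for i, label in enumerate(HIST_BIN_CENTS):
        folded[(label % 1200) // 100] += counts[i]
    return SwaraProfile(folded=folded)


def tonality_ratio(profile: SwaraProfile) -> float:
    """Minor-to-major occupancy ratio m/M of a folded profile.

    Infinite (flagged on the profile) when the major bins carry no mass.
    """
    return profile.tonality_ratio


def tonality_from_track(track: PitchTrack) -> float:
    """Convenience: histogram -> fold -> m/M in one call."""
    return tonality_ratio(fold_octaves(build_interval_histogram(track)))


# ---------------------------------------------------------------------------
# Rhythm
# ---------------------------------------------------------------------------

def onset_strength(waveform: np.ndarray, sr: int = SAMPLE_RATE):
    """Spectral-flux onset envelope; returns (envelope, envelope rate Hz)."""
    y = np.asarray(waveform, dtype=float)
    if y.size < ONSET_NFFT:
        y = np.pad(y, (0, ONSET_NFFT - y.size))
    f, t, Z = signal.stft(y, fs=sr, nperseg=ONSET_NFFT, noverlap=ONSET_NFFT - ONSET_HOP,
                          boundary=None, padded=False)
    mag = np.log1p(100.0 * np.abs(Z))
    flux = np.maximum(np.diff(mag, axis=1), 0.0).sum(axis=0)
    return flux, sr / ONSET_HOP


def _conditioned_envelope(waveform: np.ndarray, sr: int):
    """Smoothed, median-detrended onset envelope shared by the rhythm
    descriptors: 60 ms moving average, minus a 2 s local-median baseline,
    half-wave rectified."""
    flux, env_rate = onset_strength(waveform, sr)
    if flux.size == 0:
        return flux, env_rate
    n = max(1, int(ONSET_SMOOTH_S * env_rate))
    f = np.convolve(flux, np.ones(n) / n, mode="same")
    base = ndimage.median_filter(f, size=max(3, int(ONSET_BASELINE_S * env_rate)))
    return np.maximum(f - base, 0.0), env_rate


def detect_onsets(waveform: np.ndarray, sr: int = SAMPLE_RATE) -> np.ndarray:
    """Note onset times via peak-picking on the spectral-flux envelope.

    Peaks of the conditioned envelope are kept above a fixed fraction of
    its 98th percentile with a 150 ms minimum inter-onset gap.
    """
    d, env_rate = _conditioned_envelope(waveform, sr)
    if d.size == 0 or d.max() <= 0:
        return np.array([])
    ref = np.percentile(d, 98)
    if ref <= 0:
        return np.array([])
    height = ONSET_PEAK_THRESHOLD * ref
    distance = max(1, int(ONSET_MIN_GAP_S * env_rate))
    peaks, _ = signal.find_peaks(d, height=height, distance=distance,
                                 prominence=height * 0.5)
    return (peaks + 1) / env_rate  # +1: flux[i] spans frames i -> i+1


def event_density(waveform_or_onsets, duration_s: float = None,
                  sr: int = SAMPLE_RATE) -> float:
    """Estimated note onsets per second.

    Accepts either a waveform (``duration_s`` omitted; onsets are detected
    and the duration inferred from the sample count) or a precomputed onset
    list with ``duration_s`` given explicitly.
    """
    x = np.atleast_1d(np.asarray(waveform_or_onsets, dtype=float))
    if duration_s is None:
        duration_s = x.size / sr
        onsets = detect_onsets(x, sr)
    else:
        onsets = x
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return onsets.size / duration_s


def pulse_clarity(waveform: np.ndarray, sr: int = SAMPLE_RATE) -> float:
    """Beat salience in [0, 1] from the fluctuation-spectrum entropy.

    The onset envelope's power spectrum restricted to 0.25-10 Hz is
    normalized to a probability distribution; pulse clarity is
    ``1 - H / log(nbins)`` where H is its Shannon entropy.  A strongly
    periodic envelope concentrates fluctuation power at the beat rate and
    its harmonics (low entropy, clarity near 1); an irregular envelope
    spreads it (clarity near 0).

    The spectrum is estimated by Welch averaging over 12 s segments, which
    stabilizes the noise floor so that only genuinely periodic envelopes
    concentrate power.
    """
    y = np.asarray(waveform, dtype=float)
    if y.size < 5 * sr:
        raise ValueError("pulse clarity needs at least 5 s of audio")
    env, env_rate = _conditioned_envelope(y, sr)
    env = env - env.mean()
    nperseg = min(env.size, int(FLUCTUATION_SEGMENT_S * env_rate))
    freqs, spec = signal.welch(env, fs=env_rate, nperseg=nperseg,
                               noverlap=nperseg // 2, detrend="constant")
    lo, hi = FLUCTUATION_BAND_HZ
    band = spec[(freqs >= lo) & (freqs <= hi)]
    return fluctuation_entropy_clarity(band)


def fluctuation_entropy_clarity(band_power: np.ndarray) -> float:
    """Clarity = 1 - normalized Shannon entropy of a fluctuation spectrum."""
    p = np.asarray(band_power, dtype=float)
    p = p[p >= 0]
    total = p.sum()
    if p.size < 2 or total <= 0:
        return 0.0
    q = p / total
    q = q[q > 0]
    H = -(q * np.log(q)).sum() / np.log(p.size)
    return float(np.clip(1.0 - H, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Stimulus validation
# ---------------------------------------------------------------------------

def paired_mode_test(values_alaap, values_gat):
    """Paired t-test between matched alaap/gat feature values.

    Returns (t, df, p) with df = n - 1 on the per-raga differences.
    """
    a = np.asarray(values_alaap, dtype=float)
    g = np.asarray(values_gat, dtype=float)
    if a.shape != g.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - g
    if np.all(diff == diff[0]):  # zero-variance differences: t is 0 or +/-inf
        if diff[0] == 0:
            return 0.0, a.size - 1, 1.0
        return float(np.sign(diff[0]) * np.inf), a.size - 1, 0.0
    res = stats.ttest_rel(a, g)
    return float(res.statistic), a.size - 1, float(res.pvalue)


def feature_table(stimuli) -> pd.DataFrame:
    """Per-excerpt descriptors for a rendered stimulus set.

    ``stimuli`` is the output of :func:`ragamood.synth.render_stimulus_set`.
    Tonality comes from the ground-truth pitch track; pulse clarity and
    event density from the waveform when present.
    """
    rows = []
    for s in stimuli:
        ton = tonality_from_track(s["pitch_track"])
        pc = dens = np.nan
        if s.get("waveform") is not None:
            pc = pulse_clarity(s["waveform"])
            dens = event_density(s["waveform"])
        rows.append(dict(raga=s["raga"], mode=s["mode"], tonality_ratio=ton,
                         pulse_clarity=pc, event_density=dens))
    return pd.DataFrame(rows)
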