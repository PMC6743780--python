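"""Synthetic raga-like stimuli and simulated emotion ratings.

This module generates the two kinds of data the analysis pipeline consumes:

1. Audio excerpts that emulate a Hindustani raga performance: a continuous
   tonic drone (Sa, default 261.5 Hz) with a monophonic melody drawn from a
   prescribed set of swaras (semitone classes with just-intonation cent
   offsets), rendered either in *alaap* style (free, unpulsed rhythm) or
   *gat* style (isochronous pulse with a percussive click layer).  Each
   excerpt comes with its exact ground-truth pitch track, so downstream
   tonal analysis can be validated without a pitch-extraction step.

2. Ratings tables that emulate a cross-cultural listening survey: two
   listener groups (enculturated "E" and non-enculturated "NE") rate each
   excerpt on eight emotions using a 0-4 integer scale.  Ratings follow a
   group-specific linear model in tonality, rhythm (binary alaap/gat) and
   listener familiarity, plus Gaussian noise, rounded and clipped to the
   instrument's integer scale.

Melody construction note: a raga prescribes which swaras occur and how much
they are dwelt upon.  The generator therefore allocates melody *time* to
swaras in proportion to ``swara_weights`` (an exact time-quota scheme, see
:func:`_assign_swaras`), while note onsets and order remain random per seed.
This makes the time-occupancy of the ground-truth pitch track match the
prescribed weights to within frame-rounding error, in both presentation
modes -- mirroring the fact that a raga's tonal material is invariant to
whether it is presented as alaap or gat.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

SAMPLE_RATE = 22050
FRAME_HOP_S = 0.030  # pitch-track frame hop
DEFAULT_TONIC_HZ = 261.5

EMOTIONS = (
    "happy", "romantic", "devotional", "calm",
    "angry", "longing", "tensed", "sad",
)
GROUPS = ("E", "NE")

#: Deviations (cents) of a 5-limit just-intonation scale from equal
#: temperament, keyed by semitone class in cents.  Applied by default so
#: synthetic swaras sit off the equal-tempered grid, as on a real sarod.
JUST_INTONATION_OFFSETS = {
    0: 0.0, 100: 11.7, 200: 3.9, 300: 15.6, 400: -13.7, 500: -2.0,
    600: -9.8, 700: 2.0, 800: 13.7, 900: -15.6, 1000: -3.9, 1100: -11.7,
}

#: Semitone classes counted as minor (komal/tivra-Ma) vs major (shuddh).
MINOR_CLASSES = (100, 300, 600, 800, 1000)
MAJOR_CLASSES = (0, 200, 400, 500, 700, 900, 1100)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class RagaSpec:
    """Tonal material of one synthetic raga.

    Parameters
    ----------
    name : str
        Raga label.
    tonic_hz : float
        Drone/reference frequency (Sa).
    swara_weights : dict[int, float]
        Target share of melody time per semitone class (cents 0..1100).
        Must sum to 1.
    cent_offsets : dict[int, float]
        Per-class deviation from equal temperament in cents (|offset| < 50).
    octave_weights : dict[int, float]
        Probabilities over octave displacements {-1, 0, +1}.
    """

    name: str
    tonic_hz: float = DEFAULT_TONIC_HZ
    swara_weights: dict = field(default_factory=lambda: {0: 1.0})
    cent_offsets: dict = field(default_factory=lambda: dict(JUST_INTONATION_OFFSETS))
    octave_weights: dict = field(default_factory=lambda: {-1: 0.15, 0: 0.7, 1: 0.15})

    def __post_init__(self):
        if self.tonic_hz <= 0:
            raise ValueError("tonic_hz must be positive")
        w = {int(k): float(v) for k, v in self.swara_weights.items()}
        if not w or all(v <= 0 for v in w.values()):
            raise ValueError(f"raga {self.name!r}: empty or zero swara set")
        bad = [k for k in w if k % 100 or not 0 <= k <= 1100]
        if bad:
            raise ValueError(f"swara classes must be in 0,100,...,1100 cents; got {bad}")
        total = sum(w.values())
        self.swara_weights = {k: v / total for k, v in sorted(w.items()) if v > 0}
        self.cent_offsets = {int(k): float(v) for k, v in self.cent_offsets.items()}
        if any(abs(v) >= 50 for v in self.cent_offsets.values()):
            raise ValueError("|cent_offset| must be < 50")
        ow = {int(k): float(v) for k, v in self.octave_weights.items()}
        tot = sum(ow.values())
        self.octave_weights = {k: v / tot for k, v in ow.items()}

    @property
    def target_tonality_ratio(self) -> float:
        """m/M ratio implied by the swara weights (time-occupancy basis)."""
        m = sum(self.swara_weights.get(k, 0.0) for k in MINOR_CLASSES)
        M = sum(self.swara_weights.get(k, 0.0) for k in MAJOR_CLASSES)
        return np.inf if M == 0 else m / M


@dataclass
class ModeSpec:
    """Rhythmic presentation of an excerpt: free alaap or pulsed gat."""

    mode: str = "alaap"
    event_rate: float = 0.5       # notes per second
    timing_jitter: float = 0.5    # fraction of the mean inter-onset interval
    pulse_track: bool = False     # percussive click on each onset
    duration_s: float = 180.0

    def __post_init__(self):
        if self.mode not in ("alaap", "gat"):
            raise ValueError("mode must be 'alaap' or 'gat'")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        if not 0 <= self.timing_jitter <= 1:
            raise ValueError("timing_jitter must be in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @classmethod
    def alaap(cls, duration_s: float = 180.0) -> "ModeSpec":
        """Free-rhythm default: slow, jittered, no percussion."""
        return cls("alaap", event_rate=0.5, timing_jitter=1.0,
                   pulse_track=False, duration_s=duration_s)

    @classmethod
    def gat(cls, duration_s: float = 180.0) -> "ModeSpec":
        """Pulsed default: faster isochronous grid with clicks."""
        return cls("gat", event_rate=1.5, timing_jitter=0.04,
                   pulse_track=True, duration_s=duration_s)


# ---------------------------------------------------------------------------
# Audio synthesis
# ---------------------------------------------------------------------------

def _draw_onsets(mode: ModeSpec, rng: np.random.Generator) -> np.ndarray:
    """Note onset times in seconds over [0, duration).

    Alaap uses exponential inter-onset intervals (a free-rhythm point
    process); gat uses an isochronous grid with small Gaussian jitter.
    """
    T, rate = mode.duration_s, mode.event_rate
    if mode.mode == "alaap":
        # over-draw, then truncate
        n = max(8, int(rate * T * 2 + 20))
        iois = rng.exponential(1.0 / rate, size=n)
        # bound IOIs so single notes cannot dominate the time budget
        iois = np.clip(iois, 0.25 / rate, 4.0 / rate)
        onsets = np.concatenate([[0.0], np.cumsum(iois)])
    else:
        grid = np.arange(0.0, T, 1.0 / rate)
        onsets = grid + rng.normal(0.0, mode.timing_jitter / rate, size=grid.size)
        onsets[0] = 0.0
    onsets = np.sort(onsets[onsets < T - 0.5 / rate])
    return onsets


def _assign_swaras(durations_frames: np.ndarray, weights: dict,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign a swara class to each note slot under an exact time quota.

    Targets per swara are ``weights * total_frames`` (largest-remainder
    rounding).  Slots are assigned longest-first to the swara with the
    largest remaining deficit, then each swara's slot lengths are nudged by
    whole frames so its total occupancy hits the target exactly.  Returns
    (swara class per slot, possibly adjusted slot durations in frames).
    """
    classes = np.array(list(weights.keys()))
    w = np.array(list(weights.values()))
    total = int(durations_frames.sum())
    raw = w * total
    targets = np.floor(raw).astype(int)
    rem = total - targets.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    targets[order[:rem]] += 1

    n = durations_frames.size
    assign = np.empty(n, dtype=int)
    deficit = targets.astype(float).copy()
    slot_order = np.argsort(-durations_frames)
    for i in slot_order:
        # random tie-breaking among near-maximal deficits
        j = int(np.argmax(deficit + rng.uniform(0, 1e-6, size=deficit.size)))
        assign[i] = j
        deficit[j] -= durations_frames[i]

    # repair: nudge slot durations so per-swara totals are exact
    dur = durations_frames.astype(int).copy()
    for j in range(classes.size):
        err = int(targets[j] - dur[assign == j].sum())  # frames still owed
        idx = np.flatnonzero(assign == j)
        if idx.size == 0:
            continue
        k = 0
        while err != 0:
            i = idx[np.argsort(-dur[idx])[k % idx.size]]
            step = int(np.sign(err)) * min(abs(err), max(dur[i] - 1, 1))
            if dur[i] + step < 1:
                k += 1
                continue
            dur[i] += step
            err -= step
            k += 1
    return classes[assign], dur


def _harmonic_tone(f0: float, n_samples: int, sr: int,
                   harmonics=(1.0, 0.5, 0.3, 0.15, 0.08),
                   attack_s: float = 0.02, release_s: float = 0.05) -> np.ndarray:
    t = np.arange(n_samples) / sr
    y = np.zeros(n_samples)
    for k, a in enumerate(harmonics, start=1):
        y += a * np.sin(2 * np.pi * k * f0 * t)
    env = np.ones(n_samples)
    na = min(int(attack_s * sr), n_samples)
    nr = min(int(release_s * sr), n_samples)
    if na:
        env[:na] = np.linspace(0, 1, na)
    if nr:
        env[-nr:] *= np.linspace(1, 0, nr)
    return y * env


def _click(sr: int, dur_s: float = 0.03) -> np.ndarray:
    """Short damped noise burst standing in for a tabla stroke."""
    n = int(dur_s * sr)
    t = np.arange(n)
    return np.sin(2 * np.pi * 180 * t / sr) * np.exp(-t / (0.004 * sr))


def generate_raga_audio(spec: RagaSpec, mode: ModeSpec, seed: int,
                        render_audio: bool = True):
    """Synthesize one raga excerpt and its ground-truth pitch track.

    Returns ``(waveform, pitch_track)`` where ``waveform`` is a float array
    in [-1, 1] at 22050 Hz (or ``None`` when ``render_audio`` is false) and
    ``pitch_track`` is a :class:`~ragamood.features.PitchTrack` giving the
    true melody pitch per 30 ms frame (NaN where only the drone sounds).
    Deterministic per seed.
    """
    from .features import PitchTrack  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    sr = SAMPLE_RATE
    hop = FRAME_HOP_S

    onsets = _draw_onsets(mode, rng)
    if onsets.size == 0:
        raise ValueError("duration too short: no note onsets fit")
    # note slots run onset-to-onset; last note ends at duration
    bounds = np.concatenate([onsets, [mode.duration_s]])
    dur_frames = np.maximum(1, np.round(np.diff(bounds) / hop).astype(int))
    swaras, dur_frames = _assign_swaras(dur_frames, spec.swara_weights, rng)

    octs = np.array(list(spec.octave_weights.keys()))
    octp = np.array(list(spec.octave_weights.values()))
    octaves = rng.choice(octs, size=swaras.size, p=octp)

    cents = np.array([c + spec.cent_offsets.get(int(c), 0.0) for c in swaras])
    cents_sounding = cents + 1200.0 * octaves

    # ground-truth track: frame-quantized note boundaries
    note_start_f = np.concatenate([[0], np.cumsum(dur_frames)])[:-1]
    n_frames = int(np.cumsum(dur_frames)[-1])
    frame_cents = np.full(n_frames, np.nan)
    for s, d, c in zip(note_start_f, dur_frames, cents_sounding):
        frame_cents[s:s + d] = c
    frame_times = np.arange(n_frames) * hop

    waveform = None
    if render_audio:
        n_total = int(round(mode.duration_s * sr))
        y = np.zeros(n_total + sr)  # slack for release tails
        t = np.arange(n_total) / sr
        # tonic drone: fundamental + octave below, mild amplitude
        drone = 0.22 * (np.sin(2 * np.pi * spec.tonic_hz * t)
                        + 0.5 * np.sin(2 * np.pi * spec.tonic_hz / 2 * t)
                        + 0.3 * np.sin(2 * np.pi * 2 * spec.tonic_hz * t))
        y[:n_total] += drone
        attack = 0.010 if mode.mode == "gat" else 0.120
        for s, d, c in zip(note_start_f, dur_frames, cents_sounding):
            f0 = spec.tonic_hz * 2.0 ** (c / 1200.0)
            i0 = int(s * hop * sr)
            ns = max(int(d * hop * sr), 32)
            tone = _harmonic_tone(f0, ns, sr, attack_s=attack)
            y[i0:i0 + ns] += 0.75 * tone
        if mode.pulse_track:
            clk = _click(sr)
            for s in note_start_f:
                i0 = int(s * hop * sr)
                y[i0:i0 + clk.size] += 1.2 * clk
        y = y[:n_total]
        peak = np.abs(y).max()
        if peak > 0:
            y = 0.9 * y / peak
        waveform = y

    track = PitchTrack(frame_times=frame_times,
                       cents=frame_cents,
                       tonic_hz=spec.tonic_hz)
    track.onset_times = bounds[:-1]  # ground-truth onsets, for validation
    return waveform, track


def write_wav(path, waveform: np.ndarray, sr: int = SAMPLE_RATE) -> None:
    """Write a mono float waveform as 16-bit PCM RIFF."""
    wavfile.write(str(path), sr, np.round(waveform * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Default stimulus set
# ---------------------------------------------------------------------------

def _w(classes, weights=None):
    if weights is None:
        weights = [1.0] * len(classes)
    tot = float(sum(weights))
    return {c: w / tot for c, w in zip(classes, weights)}


def default_raga_specs(tonic_hz: float = DEFAULT_TONIC_HZ) -> list[RagaSpec]:
    """Twelve synthetic ragas spanning tonality ratios from 0 to above 1.

    Swara sets follow the scale material of well-known Hindustani ragas
    (synthetic stand-ins, not transcriptions); weights emphasize Sa/Pa and
    each raga's prominent tones so the implied m/M ratios spread from all-
    shuddh (Bilawal, ratio 0) to komal-dominated (Malkauns, ratio > 1).
    """
    specs = [
        ("Bilawal",   _w([0, 200, 400, 500, 700, 900, 1100],
                         [3, 2, 2, 2, 3, 2, 1])),
        ("Khamaj",    _w([0, 200, 400, 500, 700, 900, 1000],
                         [3, 2, 2, 2, 3, 2, 1.2])),
        ("Desh",      _w([0, 200, 400, 500, 700, 1000, 1100],
                         [3, 3, 2, 2, 3, 1.4, 1.4])),
        ("Yaman",     _w([0, 200, 400, 600, 700, 900, 1100],
                         [3, 2, 3, 2, 3, 2, 2])),
        ("Kafi",      _w([0, 200, 300, 500, 700, 900, 1000],
                         [3, 2, 2.5, 2, 3, 1.5, 2])),
        ("Bageshri",  _w([0, 200, 300, 500, 700, 900, 1000],
                         [3, 1.5, 3, 3, 1.5, 2, 2.5])),
        ("Bhimpalasi", _w([0, 200, 300, 500, 700, 1000],
                          [3, 1.5, 3, 2.5, 3, 2.5])),
        ("Marwa",     _w([0, 100, 400, 600, 900, 1100],
                         [2.5, 3, 2.5, 2.5, 2.5, 2])),
        ("Shree",     _w([0, 100, 400, 600, 700, 800, 1100],
                         [3, 3, 2, 2.5, 2.5, 2.5, 1.5])),
        ("Darbari",   _w([0, 200, 300, 500, 700, 800, 1000],
                         [3, 2, 3, 2.5, 2.5, 3, 2.5])),
        ("Todi",      _w([0, 100, 300, 600, 700, 800, 1100],
                         [3, 2.8, 2.8, 2.5, 2, 2.8, 1.5])),
        ("Malkauns",  _w([0, 300, 500, 800, 1000],
                         [3, 3, 2.5, 3, 2.7])),
    ]
    return [RagaSpec(name=n, tonic_hz=tonic_hz, swara_weights=w) for n, w in specs]


def render_stimulus_set(specs=None, duration_s: float = 180.0, seed: int = 0,
                        render_audio: bool = True):
    """Render every raga in both modes.

    Returns a list of dicts with keys ``raga``, ``mode``, ``spec``,
    ``mode_spec``, ``waveform``, ``pitch_track``.  Per-excerpt seeds are
    spawned deterministically from ``seed``.
    """
    if specs is None:
        specs = default_raga_specs()
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * 2)
    i = 0
    for spec in specs:
        for mode_name in ("alaap", "gat"):
            mspec = (ModeSpec.alaap(duration_s) if mode_name == "alaap"
                     else ModeSpec.gat(duration_s))
            sub_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            wav, track = generate_raga_audio(spec, mspec, seed=sub_seed,
                                             render_audio=render_audio)
            out.append(dict(raga=spec.name, mode=mode_name, spec=spec,
                            mode_spec=mspec, waveform=wav, pitch_track=track))
            i += 1
    return out


# ---------------------------------------------------------------------------
# Ratings simulation
# ---------------------------------------------------------------------------

#: Group-specific generating coefficients (intercept, tonality, rhythm,
#: familiarity) per emotion.  The enculturated profile is tonality-dominant
#: for 7 of 8 emotions (devotional stays rhythm-led), the non-enculturated
#: profile rhythm-dominant for 7 of 8 (angry stays tonality-led); signs
#: follow the valence gradient whereby komal-heavy (high m/M) material
#: reads as plaintive.  Intercepts and slopes are laid out so that each
#: region of the stimulus design (low/mid/high tonality x alaap/gat) has a
#: clearly dominant emotion -- as real ragas do -- which keeps modal labels
#: well defined under rating noise.
DEFAULT_BETAS_E = {
    "happy":      (2.40, -1.20,  0.80, 0.10),
    "romantic":   (2.05, -0.70,  0.35, 0.10),
    "devotional": (2.55, -0.35, -0.85, 0.08),
    "calm":       (2.95, -1.90, -0.50, 0.10),
    "angry":      (0.10,  1.45,  0.55, 0.10),
    "longing":    (1.40,  1.25, -0.45, 0.08),
    "tensed":     (0.85,  1.20,  0.60, 0.10),
    "sad":        (0.45,  1.35, -0.60, 0.10),
}
DEFAULT_BETAS_NE = {
    "happy":      (2.30, -0.30,  1.10, 0.10),
    "romantic":   (2.00, -0.25,  0.70, 0.10),
    "devotional": (2.45, -0.20, -0.90, 0.08),
    "calm":       (2.70, -0.45, -1.10, 0.10),
    "angry":      (0.30,  1.20,  0.45, 0.10),
    "longing":    (1.55,  0.35,  0.90, 0.08),
    "tensed":     (1.00,  0.40,  1.00, 0.10),
    "sad":        (0.90,  0.40, -1.10, 0.10),
}

#: Familiarity score distributions on the 0-4 scale, per group.
DEFAULT_FAMILIARITY = {"E": (2.86, 1.09), "NE": (1.99, 1.02)}
DEFAULT_N_PARTICIPANTS = {"E": 143, "NE": 112}


@dataclass
class RatingSimParams:
    """Parameters of the simulated listening survey.

    ``betas`` maps group -> emotion -> (intercept, b_tonality, b_rhythm,
    b_familiarity).  ``noise_sd`` is the SD of the Gaussian rating noise in
    rating units, applied before rounding to the 0-4 integer scale.
    ``p_complete`` is the probability that a participant rates all 24
    excerpts; the rest rate a random half (6 ragas in each mode), which
    makes per-excerpt rater pools -- and hence mean familiarity -- vary
    across excerpts, as in a survey with an early opt-out.
    """

    betas: dict = field(default_factory=lambda: {
        "E": dict(DEFAULT_BETAS_E), "NE": dict(DEFAULT_BETAS_NE)})
    noise_sd: float = 0.8
    familiarity: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIARITY))
    n_participants: dict = field(default_factory=lambda: dict(DEFAULT_N_PARTICIPANTS))
    p_complete: float = 0.7
    integer_scale: bool = True
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_participants.items():
            if n < 1:
                raise ValueError(f"n_participants[{g!r}] must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g, em in self.betas.items():
            missing = [e for e in EMOTIONS if e not in em]
            if missing:
                raise ValueError(f"group {g!r} missing coefficients for {missing}")


def simulate_ratings(params: RatingSimParams, stimuli) -> pd.DataFrame:
    """Simulate the long-format ratings table.

    ``stimuli`` is a sequence of ``(raga, mode, tonality)`` triples (mode in
    {'alaap','gat'}).  Returns a DataFrame with columns participant_id,
    group, familiarity, raga, mode, emotion, rating.  Deterministic per
    ``params.seed``.
    """
    stimuli = list(stimuli)
    if not stimuli:
        raise ValueError("need at least one stimulus")
    rng = np.random.default_rng(params.seed)
    ragas = sorted({s[0] for s in stimuli})
    rows = []
    pid = 0
    for group in sorted(params.betas):
        n = params.n_participants[group]
        fmean, fsd = params.familiarity[group]
        fam = np.clip(rng.normal(fmean, fsd, size=n), 0.0, 4.0)
        complete = rng.random(n) < params.p_complete
        for i in range(n):
            pid += 1
            if complete[i] or len(ragas) < 2:
                rated = set((r, m) for r, m, _ in stimuli)
            else:
                half = len(ragas) // 2
                ra = rng.permutation(ragas)[:half]
                rg = rng.permutation(ragas)[:half]
                rated = {(r, "alaap") for r in ra} | {(r, "gat") for r in rg}
            for raga, mode, ton in stimuli:
                if (raga, mode) not in rated:
                    continue
                rhy = 1.0 if mode == "gat" else 0.0
                for emo in EMOTIONS:
                    b0, bt, br, bf = params.betas[group][emo]
                    mu = b0 + bt * ton + br * rhy + bf * fam[i]
                    val = mu + (rng.normal(0, params.noise_sd)
                                if params.noise_sd > 0 else 0.0)
                    if params.integer_scale:
                        val = int(np.clip(np.round(val), 0, 4))
                    rows.append((f"P{pid:04d}", group, fam[i], raga, mode,
                                 emo, val))
    return pd.DataFrame(rows, columns=["participant_id", "group", "familiarity",
                                       "raga", "mode", "emotion", "rating"])


def simulate_mean_matrix(betas: dict, tonality: np.ndarray, rhythm: np.ndarray,
                         familiarity: np.ndarray, noise_sd: float,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one group's 24 x 8 mean-rating matrix directly.

    Used for regression calibration studies where the quantity of interest
    is the excerpt-level mean, bypassing participant-level discretization.
    ``betas`` maps emotion -> (intercept, b_tonality, b_rhythm, b_fam).
    """
    cols = {}
    for emo, (b0, bt, br, bf) in betas.items():
        mu = b0 + bt * tonality + br * rhythm + bf * familiarity
        cols[emo] = mu + rng.normal(0, noise_sd, size=len(tonality))
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def specs_to_json(raga_specs, mode_specs=None, sim_params=None) -> str:
    """Serialize generator specs to a single JSON config document."""
    doc = {"ragas": [dataclasses.asdict(s) for s in raga_specs]}
    if mode_specs is not None:
        doc["modes"] = [dataclasses.asdict(m) for m in mode_specs]
    if sim_params is not None:
        doc["ratings"] = dataclasses.asdict(sim_params)
    return json.dumps(doc, indent=2)


def specs_from_json(text: str):
    """Inverse of :func:`specs_to_json`; returns (ragas, modes, params)."""
    doc = json.loads(text)
    def _intkeys(d):
        return {int(k): v for k, v in d.items()}
    ragas = []
    for r in doc.get("ragas", []):
        r = dict(r)
        for key in ("swara_weights", "cent_offsets", "octave_weights"):
            if key in r:
                r[key] = _intkeys(r[key])
        ragas.append(RagaSpec(**r))
    modes = [ModeSpec(**m) for m in doc.get("modes", [])] or None
    params = RatingSimParams(**doc["ratings"]) if "ratings" in doc else None
    return ragas, modes, params


def write_pitch_track_csv(path, track) -> None:
    pd.DataFrame({"time_s": track.frame_times, "cents": track.cents}).to_csv(
        path, index=False)


def read_pitch_track_csv(path, tonic_hz: float = DEFAULT_TONIC_HZ):
    from .features import PitchTrack
    df = pd.read_csv(path)
    return PitchTrack(frame_times=df["time_s"].to_numpy(),
                      cents=df["cents"].to_numpy(), tonic_hz=tonic_hz)
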