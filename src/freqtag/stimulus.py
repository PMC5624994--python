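"""Rhythmic speech-like stimulus model: timing and amplitude envelopes.

The stimulation paradigm presents isochronous 320-ms monosyllabic words.
Four words form a sentence (two-word noun phrase + two-word verb phrase),
twelve sentences are concatenated without gaps into one 15.36-s trial, so
linguistic units repeat at fixed rates: syllables at 1/0.32 Hz, phrases at
1/0.64 Hz, sentences at 1/1.28 Hz. Only the envelope of the stimulus is
modelled here — each syllable is an attack-decay amplitude kernel — because
every downstream statistic depends only on the periodicity of the envelope,
not on spectral detail of the audio.

The acoustic control condition cuts each syllable envelope into short
overlapping slices and shuffles slices at the same within-sentence position
across sentences. This destroys phrasal/sentential structure while leaving
syllable-rate periodicity (and total energy, up to crossfade ramps) intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = [
    "StimulusSpec",
    "EnvelopeTrial",
    "syllable_kernel",
    "build_stimulus_sequence",
    "make_control_sequence",
    "envelope_power_spectrum",
]


class StimulusSpec(BaseModel, frozen=True, extra="forbid"):
    """Timing structure of one session of rhythmic stimulation.

    Defaults encode the study design: 320-ms syllables, 4-syllable
    sentences, 12 sentences per trial (15.36 s), 30 trials of which 8
    contain behavioral outliers, and a 5-slice / 72-ms / 10-ms-overlap
    geometry for control-stimulus construction.
    """

    syllable_dur: float = 0.32
    syllables_per_sentence: int = 4
    sentences_per_trial: int = 12
    n_trials: int = 30
    n_outlier_trials: int = 8
    condition: Literal["sentence", "control"] = "sentence"
    slice_count: int = 5
    slice_dur: float = 0.072
    slice_overlap: float = 0.010
    ramp_dur: float = 0.010
    #: per-syllable peak-amplitude jitter, uniform in [1-j, 1+j] — spoken
    #: words differ in intensity, so the envelope is not perfectly periodic
    syllable_amp_jitter: float = 0.2

    @model_validator(mode="after")
    def _check_invariants(self) -> "StimulusSpec":
        span = self.slice_count * self.slice_dur - (self.slice_count - 1) * self.slice_overlap
        if abs(span - self.syllable_dur) > 1e-9:
            raise ValueError(
                f"slice geometry spans {span:.4f} s, syllable is {self.syllable_dur} s"
            )
        if self.n_outlier_trials > self.n_trials:
            raise ValueError("n_outlier_trials exceeds n_trials")
        if self.ramp_dur > self.slice_overlap + 1e-12:
            raise ValueError("ramp_dur cannot exceed slice_overlap")
        if min(self.syllable_dur, self.slice_dur) <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.syllable_amp_jitter < 1:
            raise ValueError("syllable_amp_jitter must be in [0, 1)")
        return self

    @property
    def sentence_dur(self) -> float:
        return self.syllables_per_sentence * self.syllable_dur

    @property
    def trial_duration(self) -> float:
        return self.sentences_per_trial * self.sentence_dur

    @property
    def syllables_per_trial(self) -> int:
        return self.sentences_per_trial * self.syllables_per_sentence

    def rates(self) -> dict[str, float]:
        """Stimulation rates in Hz for the three linguistic levels."""
        return {
            "sentential": 1.0 / self.sentence_dur,
            "phrasal": 2.0 / self.sentence_dur,
            "syllabic": 1.0 / self.syllable_dur,
        }


@dataclass
class EnvelopeTrial:
    """Amplitude envelope of one trial.

    ``samples`` is the nonnegative envelope at rate ``fs``;
    ``syllable_onsets`` are in seconds from trial start. ``outlier_syllables``
    lists the indices of replaced syllables for outlier trials (empty
    otherwise) — flagged only, their acoustic content is not modelled.
    """

    fs: float
    samples: np.ndarray
    syllable_onsets: np.ndarray
    is_outlier: bool = False
    outlier_syllables: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.syllable_onsets = np.asarray(self.syllable_onsets, dtype=float)
        self.outlier_syllables = np.asarray(self.outlier_syllables, dtype=int)
        if (self.samples < 0).any():
            raise ValueError("envelope samples must be nonnegative")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def syllable_kernel(fs: float, dur: float = 0.32, attack_frac: float = 0.15) -> np.ndarray:
    """Attack-decay envelope kernel of one syllable, unit peak.

    A gamma-like shape ``t^2 * exp(-t/tau)`` whose peak sits at
    ``attack_frac * dur`` — a fast rise and slower decay, the gross shape of
    a spoken syllable's intensity contour. The exact shape is immaterial to
    the spectral analyses; only its 320-ms repetition matters.
    """
    n = int(round(fs * dur))
    t = np.arange(n) / fs
    tau = attack_frac * dur / 2.0  # peak of t^2 exp(-t/tau) is at 2*tau
    kernel = t**2 * np.exp(-t / tau)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate syllable kernel; fs too low")
    return kernel / peak


def build_stimulus_sequence(
    spec: StimulusSpec, seed: int, fs: float = 100.0
) -> list[EnvelopeTrial]:
    """Render one session of envelope trials.

    Every trial repeats the syllable kernel isochronously (12 sentences x 4
    syllables, no gaps). ``spec.n_outlier_trials`` trials, chosen at random,
    are flagged as outliers with 3 consecutive syllables marked from a
    uniformly random (roved) position; the envelope itself is unchanged.
    """
    return render_envelope_trials(spec, fs=fs, seed=seed)


def render_envelope_trials(
    spec: StimulusSpec, fs: float, seed: int
) -> list[EnvelopeTrial]:
    """As :func:`build_stimulus_sequence` with an explicit sampling rate."""
    if fs < 2.0 / spec.syllable_dur:
        raise ValueError(
            f"fs={fs} Hz cannot represent the {spec.syllable_dur}-s syllable kernel "
            f"(need >= {2.0 / spec.syllable_dur} Hz)"
        )
    rng = np.random.default_rng(seed)
    kernel = syllable_kernel(fs, spec.syllable_dur)
    n_syll = spec.syllables_per_trial
    n_trial_samples = int(round(fs * spec.trial_duration))
    onsets = np.arange(n_syll) * spec.syllable_dur

    outlier_ids = set(
        rng.choice(spec.n_trials, size=spec.n_outlier_trials, replace=False).tolist()
    )
    trials = []
    for i in range(spec.n_trials):
        samples = np.zeros(n_trial_samples)
        jit = spec.syllable_amp_jitter
        amps = rng.uniform(1.0 - jit, 1.0 + jit, n_syll) if jit else np.ones(n_syll)
        for j in range(n_syll):
            start = int(round(j * spec.syllable_dur * fs))
            stop = min(start + kernel.size, n_trial_samples)
            samples[start:stop] += amps[j] * kernel[: stop - start]
        is_outlier = i in outlier_ids
        if is_outlier:
            # 3 consecutive syllables from a roved position are replaced
            start_syll = int(rng.integers(0, n_syll - 3 + 1))
            marked = np.arange(start_syll, start_syll + 3)
        else:
            marked = np.array([], dtype=int)
        trials.append(
            EnvelopeTrial(
                fs=fs,
                samples=samples,
                syllable_onsets=onsets.copy(),
                is_outlier=is_outlier,
                outlier_syllables=marked,
            )
        )
    return trials


def _slice_windows(spec: StimulusSpec, fs: float) -> list[tuple[int, int]]:
    """Sample windows (start, stop) of each slice within one syllable."""
    hop = spec.slice_dur - spec.slice_overlap
    windows = []
    for i in range(spec.slice_count):
        start = int(round(i * hop * fs))
        stop = int(round((i * hop + spec.slice_dur) * fs))
        windows.append((start, stop))
    return windows


def make_control_sequence(
    trials: list[EnvelopeTrial], spec: StimulusSpec, seed: int
) -> list[EnvelopeTrial]:
    """Build the acoustic-control session by within-position slice shuffling.

    Each 320-ms syllable envelope is cut into ``spec.slice_count`` slices of
    ``spec.slice_dur`` with ``spec.slice_overlap`` overlap; slice edges are
    crossfaded with a linear ramp of ``spec.ramp_dur``. A sentence exposes
    ``syllables_per_sentence * slice_count`` slice positions; for each
    position one random permutation exchanges slices across all sentences of
    the session (spanning trials). Timing, trial length and syllable-rate
    periodicity are preserved; phrasal/sentential regularities are destroyed.

    With the identity permutation the reassembly is exact: the up/down ramps
    of neighbouring slices sum to one over the overlap.
    """
    if spec.condition != "control":
        raise ValueError("make_control_sequence requires spec.condition == 'control'")
    if not trials:
        return []
    fs = trials[0].fs
    n_syll_samp = int(round(fs * spec.syllable_dur))
    windows = _slice_windows(spec, fs)
    if windows[-1][1] != n_syll_samp:
        raise ValueError("slice geometry does not tile the syllable at this fs")
    n_ramp = int(round(spec.ramp_dur * fs))

    n_sent_per_trial = spec.sentences_per_trial
    n_sents = len(trials) * n_sent_per_trial
    sylls_per_sent = spec.syllables_per_sentence
    sent_samp = int(round(fs * spec.sentence_dur))

    # slice bank: [sentence, position, samples]; position = (syllable, slice)
    n_pos = sylls_per_sent * spec.slice_count
    slice_len = [stop - start for start, stop in windows]
    bank = [[None] * n_pos for _ in range(n_sents)]
    for t_idx, trial in enumerate(trials):
        for s_idx in range(n_sent_per_trial):
            sent = t_idx * n_sent_per_trial + s_idx
            sent_start = int(round(s_idx * spec.sentence_dur * fs))
            for syl in range(sylls_per_sent):
                syl_start = sent_start + syl * n_syll_samp
                for sl, (a, b) in enumerate(windows):
                    pos = syl * spec.slice_count + sl
                    bank[sent][pos] = trial.samples[syl_start + a : syl_start + b].copy()

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_sents) for _ in range(n_pos)]

    # reassemble with overlap-add crossfade; up + down == 1 over the overlap
    up = np.linspace(0.0, 1.0, n_ramp, endpoint=False) if n_ramp else np.empty(0)
    down = 1.0 - up
    out = []
    for t_idx, trial in enumerate(trials):
        samples = np.zeros_like(trial.samples)
        for s_idx in range(n_sent_per_trial):
            sent = t_idx * n_sent_per_trial + s_idx
            sent_start = int(round(s_idx * spec.sentence_dur * fs))
            for syl in range(sylls_per_sent):
                syl_start = sent_start + syl * n_syll_samp
                for sl, (a, b) in enumerate(windows):
                    pos = syl * spec.slice_count + sl
                    src = perms[pos][sent]
                    piece = bank[src][pos].copy()
                    if n_ramp:
                        if sl > 0:
                            piece[:n_ramp] *= up
                        if sl < spec.slice_count - 1:
                            piece[-n_ramp:] *= down
                    samples[syl_start + a : syl_start + b] += piece
        out.append(
            EnvelopeTrial(
                fs=fs,
                samples=samples,
                syllable_onsets=trial.syllable_onsets.copy(),
                is_outlier=trial.is_outlier,
                outlier_syllables=trial.outlier_syllables.copy(),
            )
        )
    return out


def envelope_power_spectrum(trials: list[EnvelopeTrial]) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged DFT power spectrum of the envelopes (no taper/padding).

    Returns ``(freqs, power)`` with resolution ``1/duration``. The envelope
    mean is removed per trial so the DC bin does not dominate.
    """
    if not trials:
        raise ValueError("no trials")
    fs = trials[0].fs
    mat = np.stack([t.samples - t.samples.mean() for t in trials])
    coeffs = np.fft.rfft(mat, axis=-1)
    power = (np.abs(coeffs) ** 2).mean(axis=0)
    freqs = np.fft.rfftfreq(mat.shape[-1], d=1.0 / fs)
    return freqs, power
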