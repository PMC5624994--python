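"""Synthetic EEG with known entrainment structure.

Emulates the study design: 16 subjects, 2 conditions (sentence / acoustic
control), 30 trials per session (8 flagged outlier trials), 128 channels,
responses phase-locked to trial onset at the sentential (1/1.28 Hz), phrasal
(1/0.64 Hz) and syllabic (1/0.32 Hz) rates riding on 1/f background noise
plus a non-phase-locked alpha-band oscillation. The control condition
carries no sentential or phrasal response and a weaker syllabic response.

Default response amplitudes are calibrated against the magnitude of the
grand-average normalized-power F statistics the paradigm produces in real
recordings, given the 1/f noise model here: with per-channel pink noise of
10 uV (SD over the 25-Hz analysis band) the defaults of 3.5 / 2.0 / 6.5 uV
put the grand-average F in the ~5-10 range at the sentential and phrasal
rates and the ~50-100 range at the syllabic rate, and leave roughly half of
single subjects significant at the two slow rates — the regime EEG
frequency-tagging of phrases and sentences actually operates in.

Behavioral percent-correct scores are a linear function of each subject's
sentential-rate response amplitude plus Gaussian noise, clipped to
[0, 100]; the default slope/noise give a population neural-behavior
correlation near 0.7.

All randomness fans out from one root seed through named
``numpy.random.SeedSequence`` streams, so any subject/condition can be
re-simulated in isolation and identical seeds give bit-identical output.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator

from .containers import EEGRecording
from .stimulus import StimulusSpec, render_envelope_trials

__all__ = [
    "SimulationConfig",
    "make_layout",
    "simulate_eeg",
    "simulate_subject_eeg",
    "subject_traits",
    "simulate_behavior",
]

_LEVELS = ("sentential", "phrasal", "syllabic")
# stream tags for seed fan-out
_TRAITS, _NOISE, _BEHAVIOR = 101, 202, 303


class SimulationConfig(BaseModel, frozen=True, extra="forbid"):
    """Parameters of the synthetic-EEG generator (amplitudes in uV)."""

    n_subjects: int = 16
    n_channels: int = 128
    fs: float = 100.0
    amplitudes: dict[str, float] = {
        "sentential": 3.5,
        "phrasal": 2.0,
        "syllabic": 6.5,
    }
    #: lognormal sigma of the per-subject, per-level amplitude multiplier
    subject_amp_sigma: float = 0.4
    #: wrapped-normal SD (radians) of per-subject response phase around 0
    phase_dispersion: dict[str, float] = {
        "sentential": 0.5,
        "phrasal": 0.5,
        "syllabic": 0.5,
    }
    #: relative amplitude of an optional 2nd harmonic of each response
    second_harmonic: float = 0.0
    #: syllabic-response scaling in the control condition
    control_syllabic_factor: float = 0.65
    noise_exponent: float = 1.0
    noise_sd: float = 10.0
    osc_band: tuple[float, float] = (8.0, 12.0)
    osc_amplitude: float = 5.0
    topo_width: float = 0.35
    behavior_intercept: float = 57.0
    behavior_slope: float = 4.0
    behavior_noise_sd: float = 6.4
    lead_in: float = 2.0
    inter_trial_interval: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if set(self.amplitudes) != set(_LEVELS):
            raise ValueError(f"amplitudes must have keys {_LEVELS}")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("response amplitudes must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd < 0 or self.osc_amplitude < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0 < self.osc_band[0] < self.osc_band[1]:
            raise ValueError("osc_band must be an increasing positive pair")
        return self


def make_layout(n_channels: int = 128) -> np.ndarray:
    """Deterministic 2-D electrode layout on the unit disc.

    Concentric rings around a vertex electrode, the standard flattened
    head-plane geometry of high-density caps; ``layout[:, 1]`` (y) is the
    anterior-posterior coordinate, positive = anterior.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    positions = [(0.0, 0.0)]
    n_rings = max(int(np.ceil((n_channels - 1) / 20)), 3)
    remaining = n_channels - 1
    # ring capacity grows with circumference
    sizes = np.maximum(np.round(np.arange(1, n_rings + 1) * 2.0
                                / np.arange(1, n_rings + 1).sum() * remaining), 1)
    sizes = sizes.astype(int)
    while sizes.sum() > remaining:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < remaining:
        sizes[np.argmin(sizes)] += 1
    for ring, size in enumerate(sizes, start=1):
        radius = ring / n_rings
        angles = 2 * np.pi * np.arange(size) / size + 0.5 * ring  # stagger rings
        for a in angles:
            positions.append((radius * np.sin(a), radius * np.cos(a)))
    return np.array(positions[:n_channels])


def _gaussian_topo(layout: np.ndarray, center: tuple[float, float], width: float) -> np.ndarray:
    d2 = ((layout - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def response_topographies(layout: np.ndarray, width: float) -> dict[str, np.ndarray]:
    """Fixed unit-peak spatial patterns of the three responses.

    Syllabic centered at the vertex; sentential lateralized to the right of
    it; phrasal bilateral — a caricature of the scalp patterns this paradigm
    yields, cosmetic to all statistics.
    """
    return {
        "syllabic": _gaussian_topo(layout, (0.0, 0.0), width),
        "sentential": _gaussian_topo(layout, (0.45, 0.0), width),
        "phrasal": 0.5 * (_gaussian_topo(layout, (0.45, 0.0), width)
                          + _gaussian_topo(layout, (-0.45, 0.0), width)),
    }


def subject_traits(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-subject response amplitudes (uV) and phases (rad) per level.

    Drawn from a dedicated seed stream so they are identical across
    conditions for a given subject and root seed. Returns arrays of shape
    (n_subjects,) keyed ``amp_<level>`` / ``phase_<level>``.
    """
    out: dict[str, np.ndarray] = {}
    amps = np.empty((len(_LEVELS), cfg.n_subjects))
    phases = np.empty_like(amps)
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _TRAITS, s]))
        for i, level in enumerate(_LEVELS):
            amps[i, s] = cfg.amplitudes[level] * rng.lognormal(0.0, cfg.subject_amp_sigma)
            phases[i, s] = rng.normal(0.0, cfg.phase_dispersion[level])
    for i, level in enumerate(_LEVELS):
        out[f"amp_{level}"] = amps[i]
        out[f"phase_{level}"] = phases[i]
    return out


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent noise per channel, scaled to time-domain SD ``sd``.

    Spectral shaping of white noise; the shape is flattened below 0.1 Hz so
    the variance stays finite for exponents >= 1.
    """
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    f_floor = 0.1
    nonzero = freqs > 0
    shape[nonzero] = np.maximum(freqs[nonzero], f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    white = rng.standard_normal((n_channels, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * shape, n=n_samples, axis=-1)
    current = shaped.std(axis=-1, keepdims=True)
    current[current == 0] = 1.0
    return shaped * (sd / current)


def trial_onset_times(spec: StimulusSpec, cfg: SimulationConfig) -> np.ndarray:
    """Onset of each trial (seconds) in the continuous recording."""
    step = spec.trial_duration + cfg.inter_trial_interval
    return cfg.lead_in + np.arange(spec.n_trials) * step


def simulate_subject_eeg(
    spec: StimulusSpec,
    cfg: SimulationConfig,
    subject: int,
    condition: str,
    layout: np.ndarray | None = None,
    traits: dict[str, np.ndarray] | None = None,
) -> EEGRecording:
    """Simulate one subject's continuous session for one condition.

    EEG = sum over levels of amplitude x sinusoid (locked to each trial
    onset, per-subject phase) x spatial topography, plus pink noise and a
    non-phase-locked alpha-band oscillation with fresh random phase per
    trial. The control condition zeroes the sentential and phrasal
    responses and scales the syllabic one by ``cfg.control_syllabic_factor``.
    """
    if condition not in ("sentence", "control"):
        raise ValueError(f"unknown condition {condition!r}")
    rates = spec.rates()
    if max(rates.values()) * (2 if cfg.second_harmonic else 1) >= cfg.fs / 2:
        raise ValueError("target rate at or above Nyquist; raise cfg.fs")
    if layout is None:
        layout = make_layout(cfg.n_channels)
    if traits is None:
        traits = subject_traits(cfg)
    topos = response_topographies(layout, cfg.topo_width)

    onsets = trial_onset_times(spec, cfg)
    n_samples = int(round(cfg.fs * (onsets[-1] + spec.trial_duration + 1.0)))
    cond_code = 0 if condition == "sentence" else 1
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _NOISE, subject, cond_code])
    )

    data = _pink_noise(rng, cfg.n_channels, n_samples, cfg.fs,
                       cfg.noise_exponent, cfg.noise_sd)

    # per-subject oscillator: fixed frequency and topography, random phase per trial
    osc_freq = rng.uniform(*cfg.osc_band)
    osc_center = rng.uniform(-0.5, 0.5, size=2)
    osc_topo = _gaussian_topo(layout, tuple(osc_center), cfg.topo_width)

    n_trial_samples = int(round(cfg.fs * spec.trial_duration))
    t_trial = np.arange(n_trial_samples) / cfg.fs

    level_amp = {}
    for level in _LEVELS:
        a = traits[f"amp_{level}"][subject]
        if condition == "control":
            a = a * cfg.control_syllabic_factor if level == "syllabic" else 0.0
        level_amp[level] = a

    # outlier-trial flags share the stimulus-timing stream
    stim_seed = int(np.random.SeedSequence([cfg.seed, 7, cond_code]).generate_state(1)[0] % (2**31))
    env_trials = render_envelope_trials(spec, fs=cfg.fs, seed=stim_seed)
    outlier_idx = np.array([i for i, t in enumerate(env_trials) if t.is_outlier], dtype=int)

    for onset in onsets:
        start = int(round(onset * cfg.fs))
        sl = slice(start, start + n_trial_samples)
        trial_sig = np.zeros((cfg.n_channels, n_trial_samples))
        for level in _LEVELS:
            a = level_amp[level]
            if a == 0:
                continue
            phase = traits[f"phase_{level}"][subject]
            wave = np.sin(2 * np.pi * rates[level] * t_trial + phase)
            if cfg.second_harmonic:
                wave = wave + cfg.second_harmonic * np.sin(
                    2 * np.pi * 2 * rates[level] * t_trial + 2 * phase
                )
            trial_sig += a * np.outer(topos[level], wave)
        if cfg.osc_amplitude:
            osc_phase = rng.uniform(0, 2 * np.pi)
            osc = np.sin(2 * np.pi * osc_freq * t_trial + osc_phase)
            trial_sig += cfg.osc_amplitude * np.outer(osc_topo, osc)
        data[:, sl] += trial_sig

    return EEGRecording(
        subject_id=f"S{subject:02d}",
        condition=condition,
        fs=cfg.fs,
        data=data,
        layout=layout,
        trial_onsets=onsets,
        outlier_trials=outlier_idx,
        reference="vertex",
    )


def simulate_eeg(
    spec: StimulusSpec, cfg: SimulationConfig, condition: str = "sentence"
) -> list[EEGRecording]:
    """All subjects' recordings for one condition (see per-subject variant)."""
    layout = make_layout(cfg.n_channels)
    traits = subject_traits(cfg)
    return [
        simulate_subject_eeg(spec, cfg, s, condition, layout=layout, traits=traits)
        for s in range(cfg.n_subjects)
    ]


def simulate_behavior(
    cfg: SimulationConfig,
    sentential_amplitudes: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Percent-correct outlier-detection scores from sentential amplitudes.

    ``score = clip(intercept + slope * amplitude + N(0, noise_sd), 0, 100)``.
    """
    amps = np.asarray(sentential_amplitudes, dtype=float)
    if (amps < 0).any():
        raise ValueError("amplitudes must be >= 0")
    if seed is None:
        seed_seq = np.random.SeedSequence([cfg.seed, _BEHAVIOR])
    else:
        seed_seq = np.random.SeedSequence([seed, _BEHAVIOR])
    rng = np.random.default_rng(seed_seq)
    noise = rng.normal(0.0, cfg.behavior_noise_sd, size=amps.shape) \
        if cfg.behavior_noise_sd else np.zeros_like(amps)
    scores = cfg.behavior_intercept + cfg.behavior_slope * amps + noise
    return np.clip(scores, 0.0, 100.0)
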