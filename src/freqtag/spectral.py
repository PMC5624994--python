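"""Frequency-domain response statistics for frequency-tagged EEG.

From per-trial complex DFT coefficients ``X_k(f)`` (no taper, no padding,
resolution ``1/epoch_duration``) four spectra are derived:

- evoked power      ``E(f)  = |sum_k X_k(f)|^2 / K``  — phase-locked power;
  identical to the power spectrum of the trial-averaged waveform.
- phase coherence   ``R(f)  = (sum_k cos th_k)^2/K + (sum_k sin th_k)^2/K``
  — the Rayleigh Z statistic; 0 for uniform phases, K for identical phases.
- induced power     ``I(f)  = sum_k |X_k(f) - <X(f)>|^2 / K``  — power not
  phase-locked to the stimulus.
- normalized power  ``En(f) = E(f) / sum_w E(w), |w-f| < 0.5 Hz, w != f``
  — a local signal-to-noise ratio that removes the 1/f background; at the
  standard 14.08-s epoch this neighbourhood is 7 bins on each side.

For 14.08-s epochs the three stimulation rates fall exactly on DFT bins:
sentential 1/1.28 Hz -> bin 11, phrasal 1/0.64 Hz -> bin 22, syllabic
1/0.32 Hz -> bin 44.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

__all__ = [
    "SpectralCoefficients",
    "SpectrumSet",
    "TargetFrequencies",
    "dft_coefficients",
    "evoked_power",
    "phase_coherence",
    "induced_power",
    "normalize_power",
    "target_frequencies",
    "compute_spectra",
]

#: floor on the Eq.-4 denominator for degenerate (delta-like) spectra
DENOM_FLOOR = 1e-30


@dataclass
class SpectralCoefficients:
    """Per-trial complex DFT coefficients, trials x channels x frequency."""

    coeffs: np.ndarray
    freqs: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be trials x channels x freqs")
        if self.coeffs.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")

    @property
    def K(self) -> int:
        """Number of trials."""
        return self.coeffs.shape[0]

    @property
    def resolution(self) -> float:
        """Frequency bin spacing in Hz (1 / epoch duration)."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class SpectrumSet:
    """The four derived spectra on a shared frequency axis.

    ``E``, ``R``, ``I`` are (channels x freqs); ``En`` may be per channel or
    channel-averaged (1-D) depending on how it was computed, and is NaN
    where the +-0.5 Hz neighbourhood is incomplete.
    """

    freqs: np.ndarray
    E: np.ndarray
    R: np.ndarray
    I: np.ndarray
    En: np.ndarray | None
    K: int
    bins_per_side: int = 7


@dataclass(frozen=True)
class TargetFrequencies:
    """Stimulation rates, their DFT bins, and the harmonic-exclusion set."""

    rates: dict[str, float]
    bins: dict[str, int]
    sentential_bin: int
    harmonic_bins: frozenset[int]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.rates)


def dft_coefficients(epochs: EpochSet) -> SpectralCoefficients:
    """Unpadded, untapered per-trial DFT.

    Frequency resolution is ``1/epoch_duration`` (0.0710 Hz for 14.08-s
    epochs); bins cover [0, fs/2].
    """
    data = epochs.data
    coeffs = np.fft.rfft(data, axis=-1)
    freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / epochs.fs)
    return SpectralCoefficients(coeffs=coeffs, freqs=freqs, fs=epochs.fs)


def evoked_power(sc: SpectralCoefficients) -> np.ndarray:
    """Evoked (phase-locked) power ``E = |sum_k X_k|^2 / K`` per channel/bin."""
    total = sc.coeffs.sum(axis=0)
    return (np.abs(total) ** 2) / sc.K


def phase_coherence(sc: SpectralCoefficients) -> np.ndarray:
    """Inter-trial phase coherence: the Rayleigh Z per channel/bin.

    Trials whose coefficient magnitude is exactly zero at some bin have no
    defined phase; they are dropped from that bin's sums with a warning (the
    divisor stays the full K so the identical-phase maximum remains K).
    """
    mag = np.abs(sc.coeffs)
    zero = mag == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-magnitude coefficients dropped from "
            "phase-coherence sums",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(zero, 0.0, sc.coeffs / np.where(zero, 1.0, mag))
    resultant = unit.sum(axis=0)
    return (resultant.real**2 + resultant.imag**2) / sc.K


def induced_power(sc: SpectralCoefficients) -> np.ndarray:
    """Induced (non-phase-locked) power ``I = sum_k |X_k - <X>|^2 / K``.

    Satisfies exactly: mean single-trial power = I + E/K.
    """
    mean = sc.coeffs.mean(axis=0)
    return (np.abs(sc.coeffs - mean) ** 2).sum(axis=0) / sc.K


def _bins_per_side(resolution: float, half_width: float) -> int:
    # strict |w - f| < half_width: a bin exactly on the boundary is excluded
    return int(np.floor(half_width / resolution - 1e-9))


def normalize_power(
    spectrum: np.ndarray,
    resolution: float,
    half_width: float = 0.5,
    floor: float = DENOM_FLOOR,
) -> np.ndarray:
    """Normalized power ``En``: each bin over the sum of its neighbours.

    The neighbourhood is all bins strictly within ``half_width`` Hz of the
    target, excluding the target itself — 7 bins per side at 14.08-s
    resolution. Works on 1-D (channel-averaged) or 2-D (channels x freqs)
    input; bins whose neighbourhood would leave the axis are NaN. The
    denominator is floored at ``floor`` so delta-like spectra give a large
    finite value instead of dividing by zero.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    nps = _bins_per_side(resolution, half_width)
    if nps < 1:
        raise ValueError(
            f"half_width {half_width} Hz spans no bins at {resolution} Hz resolution"
        )
    one_d = spectrum.ndim == 1
    spec2 = spectrum[None, :] if one_d else spectrum
    n_freq = spec2.shape[1]
    if n_freq < 2 * nps + 1:
        raise ValueError("spectrum too short for the normalization neighbourhood")
    en = np.full_like(spec2, np.nan)
    # sliding neighbourhood sum via cumulative sums
    csum = np.concatenate(
        [np.zeros((spec2.shape[0], 1)), np.cumsum(spec2, axis=1)], axis=1
    )
    idx = np.arange(nps, n_freq - nps)
    window = csum[:, idx + nps + 1] - csum[:, idx - nps]  # 2*nps+1 bins incl. target
    denom = np.maximum(window - spec2[:, idx], floor)
    en[:, idx] = spec2[:, idx] / denom
    return en[0] if one_d else en


def target_frequencies(
    freqs: np.ndarray,
    syllable_dur: float = 0.32,
    sentence_dur: float = 1.28,
) -> TargetFrequencies:
    """Locate the three stimulation rates on a DFT frequency axis.

    Raises if any rate is more than half a bin from its nearest bin center
    (for 14.08-s epochs all three are exact bin multiples). The harmonic
    exclusion set contains every integer multiple of the sentential bin on
    the axis — these bins are never part of an empirical null pool.
    """
    rates = {
        "sentential": 1.0 / sentence_dur,
        "phrasal": 2.0 / sentence_dur,
        "syllabic": 1.0 / syllable_dur,
    }
    resolution = float(freqs[1] - freqs[0])
    bins = {}
    for label, rate in rates.items():
        b = int(round(rate / resolution))
        if b >= freqs.size or abs(freqs[b] - rate) > 1e-9:
            raise ValueError(
                f"{label} rate {rate} Hz does not fall on a bin center "
                f"(resolution {resolution:.6f} Hz); choose an epoch duration "
                f"that is a multiple of 1/{rate} s"
            )
        bins[label] = b
    sent_bin = bins["sentential"]
    harmonics = frozenset(range(sent_bin, freqs.size, sent_bin))
    return TargetFrequencies(
        rates=rates, bins=bins, sentential_bin=sent_bin, harmonic_bins=harmonics
    )


def compute_spectra(
    epochs: EpochSet,
    half_width: float = 0.5,
    channel_average_en: bool = True,
) -> SpectrumSet:
    """All four spectra for one epoch set.

    ``En`` follows the channel-averaged convention of the global analysis:
    E is averaged over channels first, then normalized. Set
    ``channel_average_en=False`` for per-channel En (topographies).
    """
    sc = dft_coefficients(epochs)
    E = evoked_power(sc)
    R = phase_coherence(sc)
    I = induced_power(sc)
    res = sc.resolution
    if channel_average_en:
        En = normalize_power(E.mean(axis=0), res, half_width)
    else:
        En = normalize_power(E, res, half_width)
    return SpectrumSet(
        freqs=sc.freqs,
        E=E,
        R=R,
        I=I,
        En=En,
        K=sc.K,
        bins_per_side=_bins_per_side(res, half_width),
    )
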