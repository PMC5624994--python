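"""In-memory containers for continuous and epoched EEG.

Voltages are microvolts throughout. Channel layouts are 2-D head-plane
coordinates in arbitrary units; the second coordinate (``y``) is the
anterior-posterior axis, larger values more anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Reference schemes a recording can be in.
REFERENCES = ("vertex", "common_average")


@dataclass
class EEGRecording:
    """One subject/condition session of continuous multichannel EEG.

    Attributes
    ----------
    subject_id : str
        Subject label, e.g. ``"S03"``.
    condition : str
        ``"sentence"`` or ``"control"``.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    layout : ndarray, shape (n_channels, 2)
        Electrode positions; ``layout[:, 1]`` is the anterior coordinate.
    trial_onsets : ndarray, shape (n_trials,)
        Trial onset times in seconds from recording start.
    outlier_trials : ndarray of int
        Indices into ``trial_onsets`` of trials flagged as outlier trials.
    reference : str
        One of :data:`REFERENCES`.
    """

    subject_id: str
    condition: str
    fs: float
    data: np.ndarray
    layout: np.ndarray
    trial_onsets: np.ndarray
    outlier_trials: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    reference: str = "vertex"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.layout = np.asarray(self.layout, dtype=float)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        self.outlier_trials = np.asarray(self.outlier_trials, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.layout.shape != (self.data.shape[0], 2):
            raise ValueError(
                f"layout has {self.layout.shape[0]} entries for "
                f"{self.data.shape[0]} channels"
            )
        if self.reference not in REFERENCES:
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.trial_onsets.size and np.any(np.diff(self.trial_onsets) <= 0):
            raise ValueError("trial_onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        """Return a copy with some fields replaced (arrays are not shared)."""
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)


@dataclass
class EpochSet:
    """Fixed-length analysis epochs extracted from one session.

    ``data`` has shape (n_trials, n_channels, n_samples) with
    ``n_samples == round(fs * epoch_duration)``.
    """

    data: np.ndarray
    fs: float
    epoch_duration: float
    condition: str
    subject_id: str
    layout: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        expected = int(round(self.fs * self.epoch_duration))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epochs have {self.data.shape[2]} samples, expected {expected} "
                f"({self.epoch_duration} s at {self.fs} Hz)"
            )
        if np.isnan(self.data).any():
            raise ValueError("epoched data contains NaNs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
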