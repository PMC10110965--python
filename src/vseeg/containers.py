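"""Core in-memory containers shared by all pipeline stages.

Conventions: positions in millimetres (head-centered RAS), potentials in
microvolts, dipole moments in nA*m, time in seconds, sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ContinuousRecording", "EpochArray"]


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording from one modality.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Unique channel identifiers, one per row of ``data``.
    modality : str
        ``"scalp"`` or ``"depth"``.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "ContinuousRecording":
        return replace(self, **kwargs)


@dataclass
class EpochArray:
    """Stimulus-locked trials: the common currency of all analysis stages.

    ``data`` has shape (n_trials, n_channels, n_samples).  The time axis is
    uniform at ``fs`` and contains t = 0 (stimulus onset) exactly:
    ``times = (first_sample + arange(n_samples)) / fs`` where
    ``first_sample <= 0``.

    ``space`` tags which representation the channels live in:
    scalp | seeg-bipolar | source | component | pooled.
    """

    data: np.ndarray
    fs: float
    first_sample: int
    labels: np.ndarray          # "OLD" / "NEW" per trial
    correct: np.ndarray         # bool per trial
    response_time_s: np.ndarray  # float per trial, NaN when absent
    subject: str
    channel_ids: list[str]
    space: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        self.labels = np.asarray(self.labels, dtype=object)
        self.correct = np.asarray(self.correct, dtype=bool)
        self.response_time_s = np.asarray(self.response_time_s, dtype=np.float64)
        n_trials, n_channels, n_samples = self.data.shape
        for name, arr in [("labels", self.labels), ("correct", self.correct),
                          ("response_time_s", self.response_time_s)]:
            if arr.shape != (n_trials,):
                raise ValueError(f"{name} must have one entry per trial")
        if len(self.channel_ids) != n_channels:
            raise ValueError("channel_ids length mismatch")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.first_sample <= 0 < self.first_sample + n_samples):
            raise ValueError("time axis must contain t = 0")
        bad = set(self.labels) - {"OLD", "NEW"}
        if bad:
            raise ValueError(f"labels must be OLD/NEW, got {bad}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return (self.first_sample + np.arange(self.n_samples)) / self.fs

    @property
    def onset_index(self) -> int:
        """Index of t = 0 on the time axis."""
        return -self.first_sample

    def y(self) -> np.ndarray:
        """Binary label vector: OLD -> 1, NEW -> 0."""
        return (self.labels == "OLD").astype(int)

    def select_trials(self, idx: np.ndarray) -> "EpochArray":
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            correct=self.correct[idx],
            response_time_s=self.response_time_s[idx],
        )

    def select_channels(self, idx: np.ndarray, space: str | None = None) -> "EpochArray":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[:, idx, :],
            channel_ids=[self.channel_ids[i] for i in idx],
            space=space if space is not None else self.space,
        )
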