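"""In-memory containers for continuous EEG recordings and epoched trial sets.

Trial sets round-trip through a small keyed HDF5 container with datasets
``trials`` (n_trials x n_channels x n_samples, float32), ``labels`` (int64),
``rate`` (scalar Hz) and ``channels`` (UTF-8 channel names).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Recording", "TrialSet"]


@dataclass
class Recording:
    """A continuous multichannel recording with cue markers.

    samples
        (n_channels, n_timepoints) array in microvolts.
    rate
        Sampling frequency in Hz.
    channel_names
        One label per row of ``samples``.
    event_markers
        List of ``(onset_sample_index, class_label)`` pairs; onsets are
        0-based sample indices into the time axis.
    """

    samples: np.ndarray
    rate: float
    channel_names: list[str]
    event_markers: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match the channel axis")
        n = self.samples.shape[1]
        for onset, _label in self.event_markers:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside recording of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class TrialSet:
    """Labeled epoched EEG trials, (n_trials, n_channels, n_samples)."""

    trials: np.ndarray
    labels: np.ndarray
    rate: float
    channel_names: list[str]

    def __post_init__(self):
        self.trials = np.asarray(self.trials)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_channels, n_samples)")
        if self.labels.shape != (self.trials.shape[0],):
            raise ValueError("one label per trial required")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.trials.shape[1]:
            raise ValueError("channel_names length must match the channel axis")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative integers")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def save(self, path) -> None:
        """Write the keyed-array HDF5 container."""
        with h5py.File(path, "w") as f:
            f.create_dataset("trials", data=self.trials.astype(np.float32))
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("rate", data=float(self.rate))
            f.create_dataset(
                "channels",
                data=np.array([c.encode("utf-8") for c in self.channel_names]))

    @classmethod
    def load(cls, path) -> "TrialSet":
        with h5py.File(path, "r") as f:
            return cls(
                trials=f["trials"][...],
                labels=f["labels"][...],
                rate=float(f["rate"][()]),
                channel_names=[c.decode("utf-8") for c in f["channels"][...]],
            )

    @classmethod
    def concatenate(cls, sets: list["TrialSet"]) -> "TrialSet":
        if not sets:
            raise ValueError("cannot concatenate zero trial sets")
        first = sets[0]
        for s in sets[1:]:
            if s.rate != first.rate:
                raise ValueError("sampling rates differ across trial sets")
            if s.channel_names != first.channel_names:
                raise ValueError("channel layouts differ across trial sets")
            if s.n_samples != first.n_samples:
                raise ValueError("trial lengths differ across trial sets")
        return cls(
            trials=np.concatenate([s.trials for s in sets], axis=0),
            labels=np.concatenate([s.labels for s in sets], axis=0),
            rate=first.rate,
            channel_names=list(first.channel_names),
        )
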