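"""Epoch extraction, resampling, channel selection and session splitting.

The preparation convention follows the within-subject motor-imagery protocol:
fixed 4.5 s windows anchored 0.5 s before the cue (half-open, 0-based sample
indices), optional integer-factor downsampling with a zero-phase polyphase
anti-alias filter, and selection of motor-cortex electrodes by name pattern.
No band-pass filtering or per-channel normalization is applied by default;
an optional per-channel z-score flag exists but is off.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import Recording, TrialSet

__all__ = [
    "extract_epochs",
    "resample",
    "select_motor_channels",
    "split_within_subject",
    "zscore_channels",
    "load_recording",
]

DEFAULT_PRE_ONSET_S = 0.5
DEFAULT_DURATION_S = 4.5


def extract_epochs(recording: Recording, pre_onset_s: float = DEFAULT_PRE_ONSET_S,
                   duration_s: float = DEFAULT_DURATION_S) -> TrialSet:
    """Cut one fixed-length epoch per event marker.

    Each epoch covers the half-open window
    ``[onset - round(pre_onset_s * rate), start + round(duration_s * rate))``;
    at 250 Hz a 4.5 s window yields 1125 samples.  A window that leaves the
    recording raises a ValueError naming the offending marker; zero markers
    yield an empty trial set.
    """
    if pre_onset_s < 0:
        raise ValueError("pre_onset_s must be nonnegative")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_samp = int(round(duration_s * recording.rate))
    pre = int(round(pre_onset_s * recording.rate))
    trials, labels = [], []
    for i, (onset, label) in enumerate(recording.event_markers):
        start = onset - pre
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            raise ValueError(
                f"epoch window [{start}, {stop}) for marker {i} (onset {onset}) "
                f"exceeds recording bounds [0, {recording.n_samples})")
        trials.append(recording.samples[:, start:stop])
        labels.append(label)
    if trials:
        data = np.stack(trials)
    else:
        data = np.empty((0, recording.n_channels, n_samp),
                        dtype=recording.samples.dtype)
    return TrialSet(data, np.asarray(labels, dtype=np.int64), recording.rate,
                    list(recording.channel_names))


def resample(trialset: TrialSet, target_rate: float) -> TrialSet:
    """Integer-factor downsampling with polyphase zero-phase anti-aliasing.

    Only downsampling by an integer ratio is supported (e.g. 500 -> 250 Hz,
    halving 2250-sample trials to 1125).  Requesting the current rate returns
    the trial set unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > trialset.rate:
        raise ValueError(
            f"upsampling not supported ({trialset.rate} Hz -> {target_rate} Hz)")
    ratio = trialset.rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"rate ratio {trialset.rate}/{target_rate} is not an integer")
    if factor == 1:
        return TrialSet(trialset.trials.copy(), trialset.labels.copy(),
                        trialset.rate, list(trialset.channel_names))
    data = signal.resample_poly(trialset.trials, up=1, down=factor, axis=-1)
    return TrialSet(data.astype(trialset.trials.dtype), trialset.labels.copy(),
                    target_rate, list(trialset.channel_names))


def select_motor_channels(trialset: TrialSet, name_pattern: str = "C") -> TrialSet:
    """Keep channels whose name contains ``name_pattern``, preserving order.

    The motor-cortex convention keeps the sensors with "C" in their name
    (C3, Cz, C4, CP1, ...).  Selecting zero channels is an error.
    """
    if not name_pattern:
        raise ValueError("name_pattern must be non-empty")
    keep = [i for i, name in enumerate(trialset.channel_names)
            if name_pattern in name]
    if not keep:
        raise ValueError(f"no channel name contains {name_pattern!r}")
    return TrialSet(trialset.trials[:, keep], trialset.labels.copy(), trialset.rate,
                    [trialset.channel_names[i] for i in keep])


def split_within_subject(sessions: list[TrialSet],
                         n_test_sessions: int = 1) -> tuple[TrialSet, TrialSet]:
    """Within-subject split: the last ``n_test_sessions`` sessions become the
    test set, all earlier sessions the training set."""
    if n_test_sessions < 1:
        raise ValueError("n_test_sessions must be positive")
    if n_test_sessions >= len(sessions):
        raise ValueError(
            f"need more sessions ({len(sessions)}) than test sessions "
            f"({n_test_sessions})")
    train = TrialSet.concatenate(sessions[:-n_test_sessions])
    test = TrialSet.concatenate(sessions[-n_test_sessions:])
    return train, test


def zscore_channels(trialset: TrialSet) -> TrialSet:
    """Optional per-channel z-scoring (per trial); off by default everywhere."""
    mu = trialset.trials.mean(axis=-1, keepdims=True)
    sd = trialset.trials.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return TrialSet((trialset.trials - mu) / sd, trialset.labels.copy(),
                    trialset.rate, list(trialset.channel_names))


def load_recording(path, fmt: str | None = None, drop_eog: bool = True) -> Recording:
    """Optional GDF/EDF reader adapter (requires ``mne``).

    Annotations become event markers with labels numbered by first appearance
    of each annotation description.  EOG channels (any name containing "EOG")
    are dropped at load time.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF/EDF recordings requires the 'mne' package") from exc
    path = str(path)
    fmt = fmt or ("gdf" if path.lower().endswith(".gdf") else "edf")
    reader = mne.io.read_raw_gdf if fmt == "gdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    if drop_eog:
        eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
        if eog:
            raw.drop_channels(eog)
    data = raw.get_data() * 1e6  # volts -> microvolts
    onsets, labels, seen = [], [], {}
    for ann in raw.annotations:
        desc = str(ann["description"])
        seen.setdefault(desc, len(seen))
        onsets.append(int(round(ann["onset"] * raw.info["sfreq"])))
        labels.append(seen[desc])
    markers = list(zip(onsets, labels))
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names), markers)
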