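"""Synthetic 4-class EEG motor-imagery trial generator.

Each class is identified by a band-limited oscillatory signature: a Hann-
windowed sinusoid at a class-specific center frequency placed on a class-
specific electrode subset (a crude stand-in for the spatially localized
band-power changes that make real motor imagery decodable).  Trials are the
deterministic class template plus white Gaussian noise scaled so the
signal-to-noise power ratio matches ``snr_db`` in expectation; a pink-noise
option exists for extra realism but is off by default.

The defaults mirror a 22-electrode, 1125-sample, 250 Hz four-class setup.
What the generator does *not* emulate: event-related (de)synchronization
dynamics, volume conduction, 1/f background spectra (unless pink noise is
requested), artifacts, or inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .containers import TrialSet

__all__ = ["SyntheticSpec", "class_template", "generate_trialset", "default_class_bands"]

N_CLASSES = 4


def default_class_bands(n_channels: int, rate: float) -> tuple[tuple[float, tuple[int, ...]], ...]:
    """One (center frequency, electrode subset) pair per class.

    Frequencies sit in the mu/beta range used for motor decoding; subsets are
    four disjoint electrode blocks so classes differ spatially as well as
    spectrally.
    """
    freqs = (8.0, 12.0, 20.0, 28.0)
    freqs = tuple(min(f, 0.45 * rate) for f in freqs)
    block = max(1, n_channels // N_CLASSES)
    subsets = tuple(tuple(range(c * block, min((c + 1) * block, n_channels)))
                    for c in range(N_CLASSES))
    return tuple(zip(freqs, subsets))


@dataclass
class SyntheticSpec:
    """Study conditions for one generated trial set."""

    n_per_class: int = 100
    n_channels: int = 22
    n_samples: int = 1125
    rate: float = 250.0
    snr_db: float = 6.0
    class_bands: tuple = None
    noise_color: str = "white"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_class, self.n_channels, self.n_samples) < 1 or self.rate <= 0:
            raise ValueError("sizes and rate must be positive")
        if self.class_bands is None:
            self.class_bands = default_class_bands(self.n_channels, self.rate)
        if len(self.class_bands) != N_CLASSES:
            raise ValueError(f"exactly {N_CLASSES} class bands required")
        for freq, subset in self.class_bands:
            if freq >= self.rate / 2:
                raise ValueError(f"center frequency {freq} Hz above Nyquist")
            if any(not 0 <= ch < self.n_channels for ch in subset):
                raise ValueError("class band channel subset out of range")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")


def class_template(class_id: int, spec: SyntheticSpec) -> np.ndarray:
    """Deterministic (seed-independent) signature of one class.

    A Hann-windowed sinusoid at the class center frequency, normalized to
    peak amplitude 1, on the class electrode subset; zeros elsewhere.
    """
    if not 0 <= class_id < N_CLASSES:
        raise ValueError(f"class_id must lie in [0, {N_CLASSES}), got {class_id}")
    freq, subset = spec.class_bands[class_id]
    t = np.arange(spec.n_samples) / spec.rate
    sig = hann(spec.n_samples) * np.sin(2 * np.pi * freq * t)
    peak = np.abs(sig).max()
    if peak > 0:
        sig = sig / peak
    template = np.zeros((spec.n_channels, spec.n_samples))
    template[list(subset)] = sig
    return template


def _noise(rng: np.random.Generator, shape, color: str) -> np.ndarray:
    white = rng.standard_normal(shape)
    if color == "white":
        return white
    # pink: shape the spectrum by 1/sqrt(f), renormalize to unit variance
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def generate_trialset(spec: SyntheticSpec) -> TrialSet:
    """Draw a balanced, fully seeded trial set.

    Per-trial: ``trial = template[label] + sigma[label] * noise`` with
    ``sigma`` chosen so mean template power / noise power equals
    ``10**(snr_db/10)`` in expectation (powers averaged over the full
    channels x samples matrix).  ``snr_db = inf`` gives noiseless trials.
    """
    rng = np.random.default_rng(spec.seed)
    templates = [class_template(c, spec) for c in range(N_CLASSES)]
    sigmas = []
    for tpl in templates:
        power = float(np.mean(tpl ** 2))
        if np.isinf(spec.snr_db) or power == 0.0:
            sigmas.append(0.0)
        else:
            sigmas.append(np.sqrt(power / 10.0 ** (spec.snr_db / 10.0)))
    labels = np.repeat(np.arange(N_CLASSES), spec.n_per_class)
    labels = labels[rng.permutation(labels.size)]
    trials = np.empty((labels.size, spec.n_channels, spec.n_samples))
    for i, lab in enumerate(labels):
        trials[i] = templates[lab]
        if sigmas[lab] > 0:
            trials[i] += sigmas[lab] * _noise(rng, trials[i].shape, spec.noise_color)
    names = [f"C{i + 1}" for i in range(spec.n_channels)]
    return TrialSet(trials, labels, spec.rate, names)
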