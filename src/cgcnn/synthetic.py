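"""Synthetic motor-imagery-like EEG with controllable class structure.

Each trial is 1/f ("pink") background noise plus white sensor noise on all
electrodes; trials of a given class additionally carry an amplitude-
modulated sinusoid (class-specific carrier frequency and envelope) on that
class's active electrode set.  This mimics the event-related band-power
topography that motor-imagery decoders exploit, without any claim of
physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage
from .representations import TrialSet

__all__ = ["ClassEffect", "SyntheticSpec", "generate", "default_easy_spec",
           "grid_montage"]


@dataclass(frozen=True)
class ClassEffect:
    """Oscillatory signature of one class."""

    active_electrodes: tuple  # electrode names
    carrier_freq: float       # Hz
    amplitude: float
    envelope: bool = True


@dataclass(frozen=True)
class SyntheticSpec:
    montage: Montage
    effects: tuple            # one ClassEffect per class
    trials_per_class: int = 50
    fs: float = 128.0
    duration: float = 2.0
    pink_exponent: float = 1.0
    pink_sigma: float = 1.0
    white_sigma: float = 0.5
    envelope_ramp_s: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        names = set(self.montage.names)
        for i, eff in enumerate(self.effects):
            if eff.amplitude < 0:
                raise ValueError(f"class {i}: amplitude must be >= 0")
            if not 0 < eff.carrier_freq < self.fs / 2:
                raise ValueError(
                    f"class {i}: carrier {eff.carrier_freq} Hz outside (0, fs/2)")
            stray = set(eff.active_electrodes) - names
            if stray:
                raise ValueError(f"class {i}: unknown electrodes {sorted(stray)}")

    @property
    def n_classes(self) -> int:
        return len(self.effects)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def grid_montage(n_rows: int, n_cols: int) -> Montage:
    """A full rectangular grid montage with electrodes named E{row}{col}."""
    names, rows, cols = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            names.append(f"E{r}{c}")
            rows.append(r)
            cols.append(c)
    return Montage.from_table(names, rows, cols)


def default_easy_spec(trials_per_class: int = 100, seed: int = 0,
                      fs: float = 128.0, duration: float = 2.0) -> SyntheticSpec:
    """The easy two-class benchmark: 3x3 grid, disjoint active triples,
    10 Hz vs 22 Hz carriers, carrier amplitude twice the background RMS."""
    montage = grid_montage(3, 3)
    noise_rms = np.hypot(1.0, 0.5)
    amp = 2.0 * noise_rms
    effects = (
        ClassEffect(("E00", "E01", "E02"), carrier_freq=10.0, amplitude=amp),
        ClassEffect(("E20", "E21", "E22"), carrier_freq=22.0, amplitude=amp),
    )
    return SyntheticSpec(montage=montage, effects=effects,
                         trials_per_class=trials_per_class, fs=fs,
                         duration=duration, seed=seed)


def _pink_noise(rng, shape, exponent: float, fs: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f^exponent, unit std."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # drop DC
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.maximum(sd, 1e-12)


def _envelope(n_samples: int, fs: float, ramp_s: float) -> np.ndarray:
    env = np.ones(n_samples)
    ramp = int(round(ramp_s * fs))
    ramp = min(ramp, n_samples // 2)
    if ramp > 0:
        up = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[:ramp] = up
        env[-ramp:] = up[::-1]
    return env


def generate(spec: SyntheticSpec) -> TrialSet:
    """Deterministically generate the balanced labelled trial set."""
    rng = np.random.default_rng(spec.seed)
    n_cls = spec.n_classes
    n_trials = n_cls * spec.trials_per_class
    N = spec.montage.n_electrodes
    T = spec.n_samples
    t = np.arange(T) / spec.fs
    name_to_idx = {n: i for i, n in enumerate(spec.montage.names)}
    labels = np.repeat(np.arange(n_cls), spec.trials_per_class)
    signals = np.empty((n_trials, N, T))
    for i, label in enumerate(labels):
        eff = spec.effects[label]
        trial = spec.pink_sigma * _pink_noise(rng, (N, T), spec.pink_exponent, spec.fs)
        trial += spec.white_sigma * rng.standard_normal((N, T))
        if eff.amplitude > 0 and eff.active_electrodes:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            carrier = np.sin(2.0 * np.pi * eff.carrier_freq * t + phase)
            if eff.envelope:
                carrier = carrier * _envelope(T, spec.fs, spec.envelope_ramp_s)
            idx = [name_to_idx[n] for n in eff.active_electrodes]
            trial[idx] += eff.amplitude * carrier
        signals[i] = trial
    return TrialSet(signals=signals, labels=labels, fs=spec.fs,
                    trial_ids=np.arange(n_trials),
                    electrode_names=tuple(spec.montage.names))
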