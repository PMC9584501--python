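"""Trial containers, graph-tensor representations and data augmentation.

A raw trial is an (N electrodes x T samples) array.  Two representations
feed the network: a spatial-temporal tensor (the signal resampled to a fixed
number of time steps) and a spatial-spectral tensor (per-electrode Welch
power spectral density mapped onto fixed frequency bins).  Two augmentation
schemes operate on whole trial sets: sliding-window segmentation and
additive white noise at a target SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "TrialSet",
    "GraphTensor",
    "RepresentationParams",
    "to_spatial_temporal",
    "welch_psd",
    "sliding_window_augment",
    "white_noise_augment",
    "zscore_per_electrode",
    "trialset_to_tensors",
]


@dataclass
class TrialSet:
    """Labelled multichannel EEG trials.

    signals : (n_trials, N, T_samples) float array, volts.
    labels : (n_trials,) int array in [0, n_classes).
    fs : sampling rate in Hz.
    trial_ids : provenance id per trial; augmented trials keep the id of
        their source trial so cross-validation can split leakage-free.
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float
    trial_ids: np.ndarray = None
    electrode_names: tuple = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 3:
            raise ValueError("signals must be (n_trials, n_electrodes, n_samples)")
        if len(self.labels) != len(self.signals):
            raise ValueError("labels and signals disagree on trial count")
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.signals))
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if len(self.trial_ids) != len(self.signals):
            raise ValueError("trial_ids and signals disagree on trial count")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def subset(self, index) -> "TrialSet":
        index = np.asarray(index)
        return replace(
            self,
            signals=self.signals[index],
            labels=self.labels[index],
            trial_ids=self.trial_ids[index],
        )


@dataclass
class GraphTensor:
    """One trial as an (N x L x C) tensor on the electrode graph.

    mode is ``"temporal"`` (L = number of time steps) or ``"spectral"``
    (L = number of frequency bins, values are non-negative PSD).
    ``axis_meta`` carries the per-step time in seconds or frequency in Hz.
    """

    values: np.ndarray
    mode: str
    axis_meta: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be (N, L, C)")
        if self.mode not in ("temporal", "spectral"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "spectral" and np.any(self.values < 0):
            raise ValueError("spectral-mode values must be non-negative")


def to_spatial_temporal(trial: np.ndarray, T_target: int, fs: float = None,
                        method: str = "poly") -> GraphTensor:
    """Resample one (N x T_samples) trial to exactly ``T_target`` time steps.

    ``method="poly"`` uses polyphase anti-aliased resampling; ``"decimate"``
    takes every k-th sample (only when T_samples is an integer multiple of
    T_target).
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be (n_electrodes, n_samples)")
    n_samples = trial.shape[1]
    if not 1 <= T_target <= n_samples:
        raise ValueError(f"T_target must lie in [1, {n_samples}], got {T_target}")
    if T_target == n_samples:
        out = trial.copy()
    elif method == "poly":
        g = np.gcd(T_target, n_samples)
        out = sps.resample_poly(trial, T_target // g, n_samples // g, axis=1,
                                padtype="line")
        # resample_poly can over/undershoot by a sample for awkward ratios
        out = out[:, :T_target]
        if out.shape[1] < T_target:
            out = np.pad(out, ((0, 0), (0, T_target - out.shape[1])), mode="edge")
    elif method == "decimate":
        if n_samples % T_target:
            raise ValueError("decimation requires T_samples divisible by T_target")
        out = trial[:, :: n_samples // T_target]
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    if fs is not None:
        times = np.arange(T_target) * (n_samples / fs) / T_target
    else:
        times = np.arange(T_target, dtype=float)
    return GraphTensor(values=out[:, :, None], mode="temporal", axis_meta=times)


def welch_psd(trial: np.ndarray, fs: float, F_target: int,
              band=(0.5, 50.5), nperseg: int = None, noverlap: int = None,
              window: str = "hann") -> GraphTensor:
    """Per-electrode Welch PSD mapped onto ``F_target`` equal-width bins.

    The PSD is estimated on the native Welch grid, then pooled into
    ``F_target`` bins spanning ``band`` by averaging the Welch frequencies
    falling in each bin; bins containing no Welch frequency are filled by
    linear interpolation at the bin centre.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be (n_electrodes, n_samples)")
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi <= fs / 2:
        raise ValueError(f"band must satisfy 0 <= f_lo < f_hi <= fs/2, got {band}")
    n_samples = trial.shape[1]
    if nperseg is None:
        nperseg = min(256, n_samples)
    if nperseg > n_samples:
        raise ValueError(
            f"Welch segment length {nperseg} exceeds trial length {n_samples}; "
            "shorten nperseg or provide longer trials"
        )
    freqs, psd = sps.welch(trial, fs=fs, window=window, nperseg=nperseg,
                           noverlap=noverlap, axis=1)
    edges = np.linspace(f_lo, f_hi, F_target + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    out = np.empty((trial.shape[0], F_target))
    idx = np.searchsorted(edges, freqs, side="right") - 1
    for b in range(F_target):
        mask = idx == b
        if mask.any():
            out[:, b] = psd[:, mask].mean(axis=1)
        else:
            out[:, b] = np.nan
    empty = np.isnan(out[0])
    if empty.any():
        for e in range(trial.shape[0]):
            out[e, empty] = np.interp(centers[empty], freqs, psd[e])
    out = np.maximum(out, 0.0)
    return GraphTensor(values=out[:, :, None], mode="spectral", axis_meta=centers)


def sliding_window_augment(trials: TrialSet, window_s: float, step_s: float) -> TrialSet:
    """Segment every trial into fixed windows; window and step in seconds.

    Produces floor((T - W) / S) + 1 windows per trial (W, S in samples,
    truncated toward zero); each window inherits the label and trial_id of
    its source trial.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    W = int(window_s * trials.fs)
    S = int(step_s * trials.fs)
    if W < 1 or S < 1:
        raise ValueError("window and step must each span at least one sample")
    T = trials.n_samples
    if W > T:
        raise ValueError(f"window of {W} samples exceeds trial length {T}")
    n_windows = (T - W) // S + 1
    starts = np.arange(n_windows) * S
    segs = np.stack([trials.signals[:, :, s:s + W] for s in starts], axis=1)
    segs = segs.reshape(-1, trials.n_electrodes, W)
    labels = np.repeat(trials.labels, n_windows)
    ids = np.repeat(trials.trial_ids, n_windows)
    return replace(trials, signals=segs, labels=labels, trial_ids=ids)


def white_noise_augment(trials: TrialSet, snr_db: float = 20.0, copies: int = 3,
                        seed: int = 0) -> TrialSet:
    """Append ``copies`` noisy replicas of every trial at the given SNR.

    Noise is zero-mean Gaussian, scaled per trial so that
    10*log10(signal power / noise power) = snr_db.  ``snr_db=inf`` disables
    the noise (replicas equal the originals).  Deterministic given ``seed``.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if np.isnan(snr_db):
        raise ValueError("snr_db must not be NaN")
    rng = np.random.default_rng(seed)
    sig_power = np.mean(trials.signals ** 2, axis=(1, 2), keepdims=True)
    blocks = [trials.signals]
    for _ in range(copies):
        if np.isinf(snr_db):
            noise = 0.0
        else:
            noise_power = sig_power / (10.0 ** (snr_db / 10.0))
            noise = rng.standard_normal(trials.signals.shape) * np.sqrt(noise_power)
        blocks.append(trials.signals + noise)
    signals = np.concatenate(blocks, axis=0)
    labels = np.concatenate([trials.labels] * (copies + 1))
    ids = np.concatenate([trials.trial_ids] * (copies + 1))
    return replace(trials, signals=signals, labels=labels, trial_ids=ids)


def zscore_per_electrode(values: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Z-score each electrode's feature vector within one (N, L, C) tensor."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    return (values - mu) / np.maximum(sd, eps)


@dataclass
class RepresentationParams:
    """How raw trials become the two graph-tensor network inputs."""

    T_target: int = 100
    F_target: int = 100
    band: tuple = (0.5, 50.5)
    nperseg: int = None
    noverlap: int = None
    window: str = "hann"
    resample: str = "poly"
    zscore: bool = True

    def __post_init__(self):
        self.band = tuple(self.band)


def trialset_to_tensors(trials: TrialSet, params: RepresentationParams = None):
    """All trials -> batched (x_st, x_ss) arrays of shape (B, N, L, 1).

    Applies per-trial, per-electrode z-scoring after the representation step
    when ``params.zscore`` is set (the default).
    """
    params = params or RepresentationParams()
    f_hi = min(params.band[1], trials.fs / 2)
    band = (params.band[0], f_hi)
    st, ss = [], []
    for trial in trials.signals:
        gt = to_spatial_temporal(trial, params.T_target, fs=trials.fs,
                                 method=params.resample)
        gs = welch_psd(trial, trials.fs, params.F_target, band=band,
                       nperseg=params.nperseg, noverlap=params.noverlap,
                       window=params.window)
        vt, vs = gt.values, gs.values
        if params.zscore:
            vt = zscore_per_electrode(vt)
            vs = zscore_per_electrode(vs)
        st.append(vt)
        ss.append(vs)
    return np.stack(st), np.stack(ss)
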