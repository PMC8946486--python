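"""Spectral preprocessing for amplitude-robust blood-pressure regression.

The pipeline turns raw ECG/PPG waveforms into network inputs in six
steps: (1) take the synchronized waveforms, (2) cut them into
non-overlapping 250-sample frames (2 s at 125 Hz), (3) multiply every
ECG and PPG frame by its own random positive factor so a model can only
learn amplitude-independent structure, (4) take the discrete Fourier
transform of each randomized frame, keeping magnitude and phase,
(5) z-score each of the four spectral channels (|ECG|, phase ECG,
|PPG|, phase PPG) per frame, (6) z-score the time-domain ABP frames
with one global mean/std pair to form labels that invert back to mmHg.

Because magnitude scales multiplicatively under a positive gain while
phase does not change at all, the per-channel z-score makes the final
4 x 250 input exactly invariant to any per-frame positive rescaling of
the raw signals — the property the amplitude randomization teaches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PreprocessConfig",
    "FrameSet",
    "SpectralInput",
    "LabelSet",
    "DegenerateSignalWarning",
    "frame_signal",
    "randomize_amplitude",
    "spectral_transform",
    "zscore",
    "build_model_input",
    "build_labels",
    "invert_labels",
    "save_dataset",
    "load_dataset",
    "SpectralPreprocessor",
    "CHANNEL_ORDER",
]

CHANNEL_ORDER = ("ecg_magnitude", "ecg_phase", "ppg_magnitude", "ppg_phase")


class DegenerateSignalWarning(UserWarning):
    """A window was constant (or empty) where variation was expected."""


@dataclass
class PreprocessConfig:
    """Knobs of the six-step preprocessing.

    ``window_len`` / ``fs`` fix the frame duration (250 / 125 Hz = 2 s).
    ``amp_low``/``amp_high`` bound the uniform random gain; the lower
    bound is kept strictly positive because a zero gain annihilates a
    window and makes its z-score degenerate.  ``spectrum`` selects the
    full two-sided DFT (default, keeps the channel width equal to the
    window length) or the one-sided half.
    """

    window_len: int = 250
    fs: float = 125.0
    amp_low: float = 1e-6
    amp_high: float = 1.0
    seed: int = 0
    spectrum: str = "full"
    zscore_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError(f"window_len must be >= 2, got {self.window_len}")
        if not (0 < self.amp_low < self.amp_high <= 1.0):
            raise ValueError(
                f"require 0 < amp_low < amp_high <= 1, got "
                f"[{self.amp_low}, {self.amp_high}]"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.spectrum not in ("full", "onesided"):
            raise ValueError(f"spectrum must be 'full' or 'onesided', got {self.spectrum!r}")

    @property
    def frame_duration_s(self) -> float:
        return self.window_len / self.fs


@dataclass
class FrameSet:
    """Non-overlapping, contiguous windows cut from one signal."""

    frames: np.ndarray  # (N, window_len)
    fs: float
    offsets: np.ndarray  # start index of each frame in the parent signal

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        self.offsets = np.asarray(self.offsets, dtype=np.int64)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def window_len(self) -> int:
        return self.frames.shape[1]


@dataclass
class SpectralInput:
    """Per-frame 4-channel z-scored spectral feature array, (N, 4, L)."""

    data: np.ndarray
    channel_order: tuple = CHANNEL_ORDER


@dataclass
class LabelSet:
    """Z-scored time-domain ABP frames plus the stats to invert to mmHg."""

    labels: np.ndarray  # (N, window_len)
    abp_mean: float
    abp_std: float


def frame_signal(signal: np.ndarray, window_len: int, fs: float = 125.0) -> FrameSet:
    """Cut ``signal`` into ``floor(len/window_len)`` contiguous frames.

    The trailing remainder shorter than one window is discarded;
    concatenating the frames reproduces the consumed prefix exactly.
    """
    if window_len < 2:
        raise ValueError(f"window_len must be >= 2, got {window_len}")
    signal = np.asarray(signal, dtype=np.float64).ravel()
    n = len(signal) // window_len
    if n == 0:
        warnings.warn(
            f"signal of length {len(signal)} yields no full {window_len}-sample frame",
            DegenerateSignalWarning,
            stacklevel=2,
        )
    frames = signal[: n * window_len].reshape(n, window_len)
    offsets = np.arange(n, dtype=np.int64) * window_len
    return FrameSet(frames=frames, fs=fs, offsets=offsets)


def randomize_amplitude(
    frameset: FrameSet,
    rng: np.random.Generator,
    cfg: PreprocessConfig | None = None,
) -> tuple[FrameSet, np.ndarray]:
    """Multiply each frame by an independent uniform random gain.

    Gains are drawn i.i.d. per frame from U[amp_low, amp_high] and
    returned alongside the scaled frames for audit.
    """
    cfg = cfg or PreprocessConfig()
    factors = rng.uniform(cfg.amp_low, cfg.amp_high, size=frameset.n_frames)
    scaled = frameset.frames * factors[:, None]
    return FrameSet(frames=scaled, fs=frameset.fs, offsets=frameset.offsets), factors


def spectral_transform(
    frame: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """DFT magnitude and principal-value phase of one frame.

    Standard ordering, zero-frequency bin first.  With the default
    ``spectrum='full'`` convention both outputs keep all ``window_len``
    bins (the conjugate-redundant half included) so the channel width
    matches the time window.
    """
    cfg = cfg or PreprocessConfig(window_len=max(2, np.size(frame)))
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("non-finite samples in frame")
    if cfg.spectrum == "onesided":
        spectrum = np.fft.rfft(frame, axis=-1)
    else:
        spectrum = np.fft.fft(frame, axis=-1)
    magnitude = np.abs(spectrum)
    # Bins that are real up to rounding (DC and Nyquist of a real frame)
    # carry imaginary noise of either sign; snapping them onto the real
    # axis makes the +/- pi choice at negative-real bins deterministic,
    # a scale-invariant tie-break since the criterion is relative.
    numerically_real = np.abs(spectrum.imag) <= 1e-9 * magnitude
    phase = np.angle(np.where(numerically_real, spectrum.real + 0j, spectrum))
    return magnitude, phase


def zscore(values: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """(x - mean) / population std; all-zero (with a warning) if constant.

    Uses the population (N) denominator.  A standard deviation below
    ``tol`` marks the vector as degenerate: the output is all zeros and
    a :class:`DegenerateSignalWarning` is emitted.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-1] < 2:
        raise ValueError(f"need at least 2 samples to z-score, got {values.shape[-1]}")
    mean = values.mean(axis=-1, keepdims=True)
    std = values.std(axis=-1, keepdims=True)  # population denominator
    degenerate = std < tol
    if np.any(degenerate):
        warnings.warn(
            "constant channel z-scored to all zeros", DegenerateSignalWarning,
            stacklevel=2,
        )
    safe_std = np.where(degenerate, 1.0, std)
    out = (values - mean) / safe_std
    return np.where(degenerate, 0.0, out)


def build_model_input(
    ppg_frames: FrameSet,
    ecg_frames: FrameSet,
    rng: np.random.Generator,
    cfg: PreprocessConfig | None = None,
) -> SpectralInput:
    """Compose randomization, DFT, and per-channel z-score into inputs.

    Channel order is fixed: (|ECG|, phase ECG, |PPG|, phase PPG).
    Amplitude gains are drawn independently for the ECG and the PPG
    window of each frame.
    """
    cfg = cfg or PreprocessConfig(window_len=ppg_frames.window_len)
    if ppg_frames.n_frames != ecg_frames.n_frames:
        raise ValueError(
            f"frame-count mismatch: ppg has {ppg_frames.n_frames}, "
            f"ecg has {ecg_frames.n_frames}"
        )
    if ppg_frames.window_len != ecg_frames.window_len:
        raise ValueError("window-length mismatch between ppg and ecg frames")
    ecg_rand, _ = randomize_amplitude(ecg_frames, rng, cfg)
    ppg_rand, _ = randomize_amplitude(ppg_frames, rng, cfg)
    ecg_mag, ecg_phase = spectral_transform(ecg_rand.frames, cfg)
    ppg_mag, ppg_phase = spectral_transform(ppg_rand.frames, cfg)
    with warnings.catch_warnings():
        # constant raw windows legitimately z-score to zero channels
        warnings.simplefilter("ignore", DegenerateSignalWarning)
        channels = [zscore(c, cfg.zscore_tol) for c in (ecg_mag, ecg_phase, ppg_mag, ppg_phase)]
    return SpectralInput(data=np.stack(channels, axis=1))


def build_labels(
    abp_frames: FrameSet,
    stats: tuple[float, float] | None = None,
    tol: float = 1e-12,
) -> LabelSet:
    """Z-score ABP frames with ONE global (mean, std) pair.

    The single global pair — computed over all supplied frames when
    ``stats`` is omitted — keeps the inverse transform to mmHg
    well-defined across frames.
    """
    frames = abp_frames.frames
    if frames.size == 0:
        raise ValueError("no ABP frames to label")
    if stats is None:
        mean, std = float(frames.mean()), float(frames.std())
    else:
        mean, std = float(stats[0]), float(stats[1])
    if std < tol:
        raise ValueError(f"degenerate ABP: global std {std} < {tol}")
    return LabelSet(labels=(frames - mean) / std, abp_mean=mean, abp_std=std)


def invert_labels(z: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    """Map z-scored labels (or predictions) back to mmHg: z * std + mean."""
    mean, std = float(stats[0]), float(stats[1])
    if not (np.isfinite(mean) and np.isfinite(std) and std > 0):
        raise ValueError(f"invalid inversion stats ({mean}, {std})")
    return np.asarray(z, dtype=np.float64) * std + mean


def save_dataset(
    path: str | Path,
    inputs: SpectralInput,
    labels: LabelSet,
    cfg: PreprocessConfig,
) -> None:
    """Store a preprocessed dataset as HDF5 (/inputs, /labels + attrs)."""
    with h5py.File(path, "w") as handle:
        handle.create_dataset("inputs", data=inputs.data)
        handle.create_dataset("labels", data=labels.labels)
        handle.attrs["abp_mean"] = labels.abp_mean
        handle.attrs["abp_std"] = labels.abp_std
        handle.attrs["fs"] = cfg.fs
        handle.attrs["window_len"] = cfg.window_len
        handle.attrs["seed"] = cfg.seed
        handle.attrs["channel_order"] = ",".join(inputs.channel_order)


def load_dataset(path: str | Path) -> tuple[SpectralInput, LabelSet, dict]:
    """Inverse of :func:`save_dataset`; returns (inputs, labels, attrs)."""
    with h5py.File(path, "r") as handle:
        data = np.asarray(handle["inputs"])
        labels = np.asarray(handle["labels"])
        attrs = dict(handle.attrs)
    order = tuple(str(attrs.get("channel_order", ",".join(CHANNEL_ORDER))).split(","))
    return (
        SpectralInput(data=data, channel_order=order),
        LabelSet(
            labels=labels,
            abp_mean=float(attrs["abp_mean"]),
            abp_std=float(attrs["abp_std"]),
        ),
        attrs,
    )


class SpectralPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer view of the six-step input preparation.

    ``transform`` expects raw frames stacked as an (N, 2, window_len)
    array in the channel order (ecg, ppg) and returns the (N, 4,
    window_len) z-scored spectral input.  The transformer is stateless
    apart from its random gain stream, which restarts from ``seed`` at
    every call so that repeated transforms of identical input are
    identical.
    """

    def __init__(
        self,
        window_len: int = 250,
        fs: float = 125.0,
        amp_low: float = 1e-6,
        amp_high: float = 1.0,
        spectrum: str = "full",
        seed: int = 0,
    ) -> None:
        self.window_len = window_len
        self.fs = fs
        self.amp_low = amp_low
        self.amp_high = amp_high
        self.spectrum = spectrum
        self.seed = seed

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            window_len=self.window_len,
            fs=self.fs,
            amp_low=self.amp_low,
            amp_high=self.amp_high,
            spectrum=self.spectrum,
            seed=self.seed,
        )

    def fit(self, X, y=None):  # noqa: N803 - sklearn signature
        X = self._check_input(X)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:  # noqa: N803
        X = self._check_input(X)
        cfg = self._config()
        rng = np.random.default_rng(self.seed)
        ecg = FrameSet(frames=X[:, 0, :], fs=self.fs,
                       offsets=np.arange(X.shape[0]) * self.window_len)
        ppg = FrameSet(frames=X[:, 1, :], fs=self.fs,
                       offsets=np.arange(X.shape[0]) * self.window_len)
        return build_model_input(ppg, ecg, rng, cfg).data

    def _check_input(self, X) -> np.ndarray:  # noqa: N803
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self.window_len:
            raise ValueError(
                f"expected raw frames of shape (N, 2, {self.window_len}), "
                f"got {X.shape}"
            )
        return X
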