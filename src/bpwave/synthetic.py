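"""Coupled ECG/PPG/ABP simulator with a transit-time↔pressure link.

The generator produces the statistical structure the estimation method
assumes, not a physiologically detailed heart model:

* the ECG is a beat-periodic train of narrow biphasic wavelets whose
  peak marks each beat (the R-wave);
* the ABP waveform is, per beat, a raised-cosine upstroke from the
  diastolic to the systolic level followed by an exponential decay
  back toward diastole; systolic and diastolic levels are shifted by
  ``bp_ptt_slope * (ptt - PTT_REF)`` so that a shorter pulse transit
  time means higher pressure (the inverse coupling that transit-time
  methods exploit);
* the PPG is the ABP pulse shape, low-pass smoothed and delayed by the
  transit time, so the optical pulse foot trails the R-wave by ``ptt``;
* ECG and PPG are corrupted by a slow multiplicative amplitude drift
  (sensor gain wobble) and additive Gaussian noise, while ABP — the
  calibrated label — stays in true mmHg.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signal_io import SignalRecord

__all__ = ["PhysioParams", "PTT_REF", "simulate_record", "sweep_bp_levels",
           "estimate_pulse_delay"]

#: anchor transit time (s) at which the configured base pressures hold exactly
PTT_REF = 0.25


@dataclass
class PhysioParams:
    """Physiological and corruption parameters of one simulated record.

    heart_rate is in beats per second; ptt in seconds (must fit inside
    one beat); pressures in mmHg; ``bp_ptt_slope`` in mmHg per second
    of transit time (negative for the physiological inverse coupling);
    ``drift_amp`` is the fractional depth of the slow sinusoidal gain
    drift on ECG/PPG and ``noise_sd`` the additive-noise level as a
    fraction of each channel's amplitude.
    """

    heart_rate: float = 1.2
    ptt: float = 0.25
    systolic_base: float = 120.0
    diastolic_base: float = 70.0
    bp_ptt_slope: float = -400.0
    drift_amp: float = 0.3
    drift_period: float = 30.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.heart_rate > 0:
            raise ValueError(f"heart_rate must be positive, got {self.heart_rate}")
        if not 0 < self.ptt < 1.0 / self.heart_rate:
            raise ValueError(
                f"ptt must lie in (0, 1/heart_rate) = (0, {1.0 / self.heart_rate:.3f}), "
                f"got {self.ptt}"
            )
        if not 0 < self.diastolic_base < self.systolic_base:
            raise ValueError(
                "require 0 < diastolic_base < systolic_base, got "
                f"{self.diastolic_base} / {self.systolic_base}"
            )
        if not 0 <= self.drift_amp <= 0.9:
            raise ValueError(f"drift_amp must be in [0, 0.9], got {self.drift_amp}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.drift_period <= 0:
            raise ValueError(f"drift_period must be positive, got {self.drift_period}")

    @property
    def systolic(self) -> float:
        """Effective systolic level after the transit-time coupling."""
        return self.systolic_base + self.bp_ptt_slope * (self.ptt - PTT_REF)

    @property
    def diastolic(self) -> float:
        """Effective diastolic level after the transit-time coupling."""
        return self.diastolic_base + self.bp_ptt_slope * (self.ptt - PTT_REF)


def _pulse_train(
    t: np.ndarray,
    beat_times: np.ndarray,
    beat_period: float,
    systolic: float,
    diastolic: float,
    rise_s: float,
) -> np.ndarray:
    """Per-beat pressure pulse: raised-cosine upstroke + exponential decay.

    The upstroke starts exactly at each beat time (the pulse foot sits
    at the per-beat minimum) and reaches the systolic level after
    ``rise_s``; the decay time constant is short enough that the wave
    returns to within a fraction of a mmHg of diastole before the next
    foot.
    """
    pressure = np.full_like(t, diastolic)
    decay_dur = beat_period - rise_s
    # exp(-decay_dur/tau) ~= 0.005 -> min within ~0.5% of pulse height of diastole
    tau = decay_dur / 5.3
    pulse = systolic - diastolic
    for bt in beat_times:
        local = t - bt
        rise = (local >= 0) & (local < rise_s)
        pressure[rise] = diastolic + pulse * 0.5 * (1 - np.cos(np.pi * local[rise] / rise_s))
        fall = (local >= rise_s) & (local < beat_period)
        pressure[fall] = diastolic + pulse * np.exp(-(local[fall] - rise_s) / tau)
    return pressure


def _ecg_train(t: np.ndarray, beat_times: np.ndarray, width_s: float = 0.02) -> np.ndarray:
    """Narrow biphasic wavelet (Gaussian first derivative mirrored to peak
    at the beat time) repeated at every beat."""
    ecg = np.zeros_like(t)
    for bt in beat_times:
        u = (t - bt) / width_s
        mask = np.abs(u) < 6
        # positive peak at the beat time with small negative side lobes
        ecg[mask] += (1 - u[mask] ** 2) * np.exp(-0.5 * u[mask] ** 2)
    return ecg


def simulate_record(
    params: PhysioParams, duration_s: float, fs: float = 125.0
) -> SignalRecord:
    """Generate one coupled ECG/PPG/ABP record of ``duration_s`` seconds."""
    n = int(round(duration_s * fs))
    beat_period = 1.0 / params.heart_rate
    if n < beat_period * fs:
        raise ValueError(
            f"duration {duration_s}s holds no full beat at {params.heart_rate} bps"
        )
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fs
    # first beat starts one period before t=0 so the record begins mid-cycle
    # but every visible beat is complete
    beat_times = np.arange(-beat_period, duration_s + beat_period, beat_period)

    rise_s = min(0.3 * beat_period, 0.25)
    abp = _pulse_train(t, beat_times, beat_period, params.systolic,
                       params.diastolic, rise_s)
    ecg = _ecg_train(t, beat_times)

    # PPG: smoothed ABP pulse shape delayed by the transit time, unit scale
    ppg_shape = _pulse_train(t - params.ptt, beat_times,
                             beat_period, 1.0, 0.0, rise_s)
    ppg = gaussian_filter1d(ppg_shape, sigma=max(1.0, 0.008 * fs), mode="nearest")

    drift = 1.0 + params.drift_amp * np.sin(2 * np.pi * t / params.drift_period)
    ecg = ecg * drift
    ppg = ppg * drift
    if params.noise_sd > 0:
        for channel in (ecg, ppg):
            amp = 0.5 * (channel.max() - channel.min())
            channel += rng.normal(0.0, params.noise_sd * amp, size=n)

    return SignalRecord(
        ppg=ppg, ecg=ecg, abp=abp, fs=fs,
        record_id=f"sim(seed={params.seed},ptt={params.ptt:g})",
    )


def sweep_bp_levels(
    n_records: int,
    systolic_range: tuple[float, float],
    diastolic_range: tuple[float, float],
    seed: int = 0,
    duration_s: float = 60.0,
    fs: float = 125.0,
    params: PhysioParams | None = None,
) -> list[SignalRecord]:
    """Records whose configured pressures tile the given ranges uniformly.

    Levels are linearly spaced (endpoints included); each record gets
    its own seed derived from ``seed``.  The transit time stays at the
    reference anchor so the configured levels are realized exactly.
    Records share fs and duration and can be concatenated for framing.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    for name, (lo, hi) in (("systolic", systolic_range), ("diastolic", diastolic_range)):
        if not lo <= hi:
            raise ValueError(f"empty {name} range ({lo}, {hi})")
    base = params or PhysioParams(drift_amp=0.2, noise_sd=0.02)
    systolics = np.linspace(*systolic_range, n_records)
    diastolics = np.linspace(*diastolic_range, n_records)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_records) % (2**31)
    records = []
    for sys_mmhg, dia_mmhg, child in zip(systolics, diastolics, child_seeds):
        p = replace(
            base,
            systolic_base=float(sys_mmhg),
            diastolic_base=float(dia_mmhg),
            ptt=PTT_REF,
            seed=int(child),
        )
        records.append(simulate_record(p, duration_s=duration_s, fs=fs))
    return records


def estimate_pulse_delay(record: SignalRecord, heart_rate: float) -> float:
    """Estimate the R-wave→PPG-foot delay (pulse transit time) in seconds.

    R-peaks are the per-beat ECG maxima; the PPG foot is the per-beat
    minimum just before the optical upstroke.  The median per-beat
    foot−R interval estimates the transit time; on noiseless output it
    matches the configured value to within one sample.
    """
    from scipy.signal import find_peaks

    fs = record.fs
    period = fs / heart_rate
    r_peaks, _ = find_peaks(
        record.ecg,
        height=0.4 * record.ecg.max(),
        distance=max(1, int(0.7 * period)),
    )
    if len(r_peaks) < 2:
        raise ValueError("record too short to estimate a pulse delay")
    delays = []
    for r_idx in r_peaks[:-1]:
        search = slice(r_idx, min(r_idx + int(period), record.n_samples))
        foot_idx = r_idx + int(np.argmin(record.ppg[search]))
        delays.append((foot_idx - r_idx) / fs)
    return float(np.median(delays))
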