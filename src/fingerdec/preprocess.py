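"""Epoch preparation: filtering, resampling, epoching, trial selection,
per-epoch z-scoring and window cropping.

Filters are zero-phase FIR (forward-backward application of a linear-phase
windowed-sinc design) so the lock point is never shifted.  The high-pass
design nulls DC exactly (spectral-inversion FIR), giving > 40 dB
attenuation at 0 Hz regardless of length; passband ripple of the Hamming
design is < 0.2 dB.  On short epoched signals the number of taps is capped
at one third of the epoch length so the forward-backward edge padding
remains valid; the resulting transition band is documented per call in the
provenance string.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .data import EpochSet, Recording
from .simulate import ConfigurationError

logger = logging.getLogger("fingerdec")


def _highpass_taps(cutoff_hz: float, sfreq: float, n_times: int) -> np.ndarray:
    # spectral inversion of a Hamming windowed-sinc low-pass: h = delta - lp,
    # which nulls DC exactly whatever the tap count; transition width is
    # ~3.3/numtaps in normalized frequency.
    desired = int(round(3.3 / (max(cutoff_hz, 0.25) / sfreq)))
    max_allowed = max((n_times - 1) // 3, 5)
    numtaps = min(desired, max_allowed)
    if numtaps % 2 == 0:
        numtaps -= 1
    lp = signal.firwin(numtaps, cutoff_hz, fs=sfreq, pass_zero=True)
    hp = -lp
    hp[numtaps // 2] += 1.0
    return hp


def _apply_filtfilt(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), data.shape[-1] - 1)
    return signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def highpass(x: EpochSet | Recording, cutoff_hz: float):
    """Zero-phase FIR high-pass, applied channel-wise.

    Accepts a continuous :class:`Recording` or an :class:`EpochSet`;
    returns the same type.  ``cutoff_hz`` must be below Nyquist.
    """
    if cutoff_hz <= 0 or cutoff_hz >= x.sfreq / 2:
        raise ConfigurationError(
            f"high-pass cutoff {cutoff_hz} Hz must lie in (0, Nyquist={x.sfreq / 2})"
        )
    taps = _highpass_taps(cutoff_hz, x.sfreq, x.data.shape[-1])
    out = _apply_filtfilt(x.data, taps)
    note = f"highpass({cutoff_hz} Hz, {len(taps)} taps, zero-phase)"
    if isinstance(x, EpochSet):
        return x.copy_with(data=out, provenance=x.provenance + [note])
    return Recording(out, x.sfreq, x.first_time)


def downsample(x: EpochSet | Recording, target_hz: float):
    """Anti-aliased polyphase resampling to ``target_hz`` (<= current rate)."""
    if target_hz > x.sfreq:
        raise ConfigurationError(
            f"target rate {target_hz} Hz exceeds current rate {x.sfreq} Hz"
        )
    if target_hz == x.sfreq:
        return x
    frac = Fraction(target_hz / x.sfreq).limit_denominator(1000)
    out = signal.resample_poly(x.data, frac.numerator, frac.denominator, axis=-1)
    note = f"downsample({x.sfreq} -> {target_hz} Hz)"
    if isinstance(x, EpochSet):
        n = out.shape[-1]
        times = x.times[0] + np.arange(n) / target_hz
        return x.copy_with(
            data=out, times=times, sfreq=target_hz, provenance=x.provenance + [note]
        )
    return Recording(out, target_hz, x.first_time)


def epoch(
    rec: Recording,
    event_times: np.ndarray,
    window: tuple[float, float] = (-0.5, 0.5),
    lock: str = "response",
    labels: np.ndarray | None = None,
    block: np.ndarray | None = None,
) -> EpochSet:
    """Cut a continuous recording into half-open ``[window[0], window[1])``
    epochs around each event.  Events too close to an edge are dropped
    with a warning; the returned set can therefore be shorter than
    ``event_times``."""
    event_times = np.asarray(event_times, dtype=float)
    n_times = int(round((window[1] - window[0]) * rec.sfreq))
    times = window[0] + np.arange(n_times) / rec.sfreq
    n_samp = rec.data.shape[1]

    starts = np.round((event_times - rec.first_time + window[0]) * rec.sfreq).astype(int)
    keep = (starts >= 0) & (starts + n_times <= n_samp)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("epoch(): dropped %d event(s) too close to the recording edge",
                       n_dropped)
        warnings.warn(f"dropped {n_dropped} event(s) outside the recording", stacklevel=2)
    kept = np.flatnonzero(keep)
    data = np.stack(
        [rec.data[:, s:s + n_times] for s in starts[kept]], axis=0
    ) if kept.size else np.empty((0, rec.n_channels, n_times))
    lab = (np.asarray(labels)[kept] if labels is not None
           else np.array(["NA"] * kept.size))
    blk = (np.asarray(block)[kept] if block is not None
           else np.zeros(kept.size, dtype=int))
    return EpochSet(
        data=data, times=times, sfreq=rec.sfreq, labels=lab, block=blk, lock=lock,
        provenance=[f"epoch(window={window}, lock={lock}, dropped={n_dropped})"],
    )


def select_correct(x: EpochSet, table: pd.DataFrame) -> EpochSet:
    """Keep only trials the trial table flags as correct."""
    if len(table) != x.n_trials:
        raise ValueError(
            f"trial table ({len(table)}) and epochs ({x.n_trials}) are misaligned"
        )
    mask = table["correct"].to_numpy().astype(bool)
    if not mask.any():
        warnings.warn("select_correct: no correct trials remain", stacklevel=2)
    return x.select(mask, note=f"select_correct({int(mask.sum())}/{mask.size})")


def zscore_epochs(x: EpochSet, per_channel: bool = False) -> EpochSet:
    """Standardize each epoch.

    Default (matching the decoder's training input): subtract the scalar
    mean and divide by the scalar SD pooled over all channels and samples
    of that epoch.  ``per_channel=True`` standardizes each channel's time
    course separately instead.
    """
    if x.n_trials == 0:
        return x
    axes = (2,) if per_channel else (1, 2)
    mean = x.data.mean(axis=axes, keepdims=True)
    sd = x.data.std(axis=axes, keepdims=True)
    bad = np.flatnonzero((sd <= 0).reshape(x.n_trials, -1).any(axis=1))
    if bad.size:
        raise ValueError(f"zero within-epoch SD for trial(s) {bad.tolist()}")
    mode = "per_channel" if per_channel else "pooled"
    return x.copy_with(
        data=(x.data - mean) / sd,
        provenance=x.provenance + [f"zscore_epochs({mode})"],
    )


def crop_window(x: EpochSet, center_s: float, width_s: float) -> EpochSet:
    """Restrict epochs to the half-open window [center - w/2, center + w/2)."""
    lo = center_s - width_s / 2.0
    hi = center_s + width_s / 2.0
    eps = 0.5 / x.sfreq
    t0, t_end = x.times[0], x.times[-1] + 1.0 / x.sfreq
    if lo < t0 - eps or hi > t_end + eps:
        raise ConfigurationError(
            f"crop window [{lo:.3f}, {hi:.3f}) exceeds epoch extent "
            f"[{t0:.3f}, {t_end:.3f})"
        )
    mask = (x.times >= lo - eps) & (x.times < hi - eps)
    n_expected = int(round(width_s * x.sfreq))
    idx = np.flatnonzero(mask)[:n_expected]
    return x.copy_with(
        data=x.data[:, :, idx],
        times=x.times[idx],
        provenance=x.provenance + [f"crop_window({center_s}, {width_s})"],
    )


def reject_amplitude(x: EpochSet, z_max: float = 8.0) -> tuple[EpochSet, np.ndarray]:
    """Amplitude-threshold trial rejection (stands in for visual inspection):
    drop trials whose peak |amplitude| exceeds ``z_max`` robust SDs of the
    set-wide amplitude distribution.  Returns (kept epochs, keep mask)."""
    scale = 1.4826 * np.median(np.abs(x.data - np.median(x.data)))
    peak = np.abs(x.data).reshape(x.n_trials, -1).max(axis=1)
    keep = peak <= z_max * max(scale, np.finfo(float).tiny)
    return x.select(keep, note=f"reject_amplitude(z_max={z_max})"), keep
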