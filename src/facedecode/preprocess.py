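"""Epoch-level EEG preprocessing.

The chain, applied in fixed order to a continuous recording:

band-pass filter -> bad-channel detection & interpolation -> average
re-reference -> downsample -> epoch -> per-epoch linear detrend -> crop.

Filtering is zero-phase (forward-backward) Butterworth; downsampling is
polyphase with built-in anti-aliasing.  Bad channels are found by a
probability criterion: each channel's samples are scored under a kernel
estimate of the pooled amplitude distribution, and channels whose mean
negative log-likelihood is an extreme outlier (robust z beyond the
threshold) are flagged.  No notch filter is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gaussian_kde

from .containers import EpochSet, time_grid


class PreprocError(ValueError):
    pass


@dataclass
class PreprocConfig:
    highpass_hz: float = 0.1
    lowpass_hz: float = 100.0
    target_rate_hz: float = 256.0
    bad_channel_sd_threshold: float = 5.0
    crop_window_ms: tuple[float, float] = (-100.0, 1000.0)
    extract_window_ms: tuple[float, float] = (-533.2, 1066.4)
    filter_order: int = 4

    def validate(self, sample_rate: float | None = None) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise PreprocError("need 0 < highpass < lowpass")
        if sample_rate is not None and self.lowpass_hz >= sample_rate / 2:
            raise PreprocError(
                f"lowpass {self.lowpass_hz} Hz is at or above Nyquist for {sample_rate} Hz"
            )
        if self.bad_channel_sd_threshold <= 0:
            raise PreprocError("bad_channel_sd_threshold must be positive")


def bandpass(raw: np.ndarray, sample_rate: float, cfg: PreprocConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    ``raw`` is channels x samples.  The two corners are applied as
    separate stages: the signal is demeaned and high-passed with a
    2nd-order filter run forward-backward with transient-minimizing
    initial conditions (the near-zero corner frequency otherwise leaves
    edge transients lasting many seconds), then low-passed with a
    ``filter_order`` filter in second-order sections.  Passband gain is
    ~1; DC is removed.
    """
    cfg.validate(sample_rate)
    x = np.asarray(raw, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    b, a = signal.butter(2, cfg.highpass_hz, btype="highpass", fs=sample_rate)
    x = signal.filtfilt(b, a, x, axis=-1, method="gust")
    sos = signal.butter(cfg.filter_order, cfg.lowpass_hz, btype="lowpass", fs=sample_rate, output="sos")
    padlen = min(x.shape[-1] - 1, int(4 * sample_rate))
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def detect_bad_channels(
    raw: np.ndarray,
    channels: list[str],
    cfg: PreprocConfig,
    max_pool: int = 5_000,
    max_eval_per_channel: int = 1_000,
) -> set[str]:
    """Flag channels whose amplitude distribution is improbable.

    Every channel's samples are evaluated under a Gaussian-kernel
    estimate of the pooled (all-channel) amplitude distribution; the
    per-channel mean negative log-likelihood is converted to a robust
    z-score (median / 1.4826*MAD across channels) and channels with
    z > ``bad_channel_sd_threshold`` are returned.  Deterministic:
    pooling subsamples by stride, not at random.
    """
    cfg.validate()
    raw = np.asarray(raw, dtype=float)
    n_ch, n_samp = raw.shape
    if n_ch < 8:
        raise PreprocError(f"bad-channel detection needs >= 8 channels, got {n_ch}")
    pooled = raw.ravel()
    if pooled.size > max_pool:
        pooled = pooled[:: int(np.ceil(pooled.size / max_pool))]
    kde = gaussian_kde(pooled)
    stride = max(1, n_samp // max_eval_per_channel)
    nll = np.empty(n_ch)
    for c in range(n_ch):
        dens = kde(raw[c, ::stride])
        nll[c] = -np.mean(np.log(np.maximum(dens, 1e-300)))
    med = np.median(nll)
    mad = np.median(np.abs(nll - med))
    scale = 1.4826 * mad
    if scale == 0:
        return set()
    z = (nll - med) / scale
    flagged = {channels[c] for c in range(n_ch) if z[c] > cfg.bad_channel_sd_threshold}
    if len(flagged) == n_ch:
        raise PreprocError("every channel was flagged as bad; recording unusable")
    return flagged


def interpolate_channels(
    raw: np.ndarray,
    channels: list[str],
    bad: set[str],
    positions: np.ndarray | None,
) -> np.ndarray:
    """Replace bad channels by the inverse-distance-weighted (power 2)
    average of the good channels; good channels pass through untouched."""
    if not bad:
        return np.array(raw, dtype=float, copy=True)
    if positions is None:
        raise PreprocError("channel positions are required for interpolation")
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != len(channels):
        raise PreprocError("one position per channel is required")
    unknown = set(bad) - set(channels)
    if unknown:
        raise PreprocError(f"bad channels not in montage: {sorted(unknown)}")
    out = np.array(raw, dtype=float, copy=True)
    good_idx = [i for i, ch in enumerate(channels) if ch not in bad]
    if len(good_idx) < 3:
        raise PreprocError("need at least 3 good channels to interpolate")
    for i, ch in enumerate(channels):
        if ch not in bad:
            continue
        d = np.linalg.norm(positions[good_idx] - positions[i], axis=1)
        d = np.maximum(d, 1e-12)
        w = 1.0 / d**2
        w /= w.sum()
        out[i] = w @ out[good_idx]
    return out


def ring_montage(n_channels: int, radius: float = 1.0) -> np.ndarray:
    """Synthetic 2-D electrode positions on a circle (for simulated data)."""
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def rereference_average(raw: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous across-channel mean (channels on axis -2)."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-2] < 2:
        raise PreprocError("average reference needs at least 2 channels")
    return raw - raw.mean(axis=-2, keepdims=True)


def downsample(raw: np.ndarray, sample_rate: float, cfg: PreprocConfig) -> tuple[np.ndarray, float]:
    """Anti-alias polyphase resampling to ``target_rate_hz`` along the last axis."""
    if cfg.target_rate_hz >= sample_rate:
        raise PreprocError(
            f"target rate {cfg.target_rate_hz} Hz must be below the original {sample_rate} Hz"
        )
    from fractions import Fraction

    frac = Fraction(cfg.target_rate_hz / sample_rate).limit_denominator(1000)
    out = signal.resample_poly(np.asarray(raw, dtype=float), frac.numerator, frac.denominator, axis=-1)
    return out, cfg.target_rate_hz


def epoch_and_detrend(
    raw: np.ndarray,
    sample_rate: float,
    events: pd.DataFrame,
    cfg: PreprocConfig,
    channels: list[str] | None = None,
) -> EpochSet:
    """Cut epochs around event onsets, linearly detrend, then crop.

    ``events`` must carry an ``onset_sample`` column (index into the
    continuous recording) plus the usual trial metadata.  The wide
    ``extract_window_ms`` epoch is detrended per channel by least
    squares before cropping to ``crop_window_ms``.  Events without full
    window support are dropped with a warning.
    """
    cfg.validate()
    raw = np.asarray(raw, dtype=float)
    n_ch, n_samp = raw.shape
    if channels is None:
        channels = [f"CH{i:02d}" for i in range(n_ch)]
    if "onset_sample" not in events.columns:
        raise PreprocError("events must have an onset_sample column")

    period = 1000.0 / sample_rate
    wide = time_grid(*cfg.extract_window_ms, sample_rate)
    crop = time_grid(*cfg.crop_window_ms, sample_rate)
    wide_k = np.round(wide / period).astype(int)
    crop_sel = np.isin(wide_k, np.round(crop / period).astype(int))

    kept, arrays = [], []
    for _, ev in events.iterrows():
        onset = int(ev["onset_sample"])
        lo, hi = onset + wide_k[0], onset + wide_k[-1]
        if lo < 0 or hi >= n_samp:
            warnings.warn(
                f"dropping event at sample {onset}: window [{lo}, {hi}] exceeds recording",
                stacklevel=2,
            )
            continue
        ep = raw[:, lo : hi + 1]
        ep = signal.detrend(ep, axis=-1, type="linear")
        arrays.append(ep[:, crop_sel])
        kept.append(ev)
    if not arrays:
        raise PreprocError("no event had full window support")
    events_out = pd.DataFrame(kept).reset_index(drop=True)
    for col in ("trial", "sequence", "block", "stimulus_id"):
        if col not in events_out.columns:
            events_out[col] = 0
    return EpochSet(
        data=np.stack(arrays),
        times=crop,
        sample_rate=sample_rate,
        channels=list(channels),
        events=events_out,
    )


def preprocess_continuous(
    raw: np.ndarray,
    sample_rate: float,
    events: pd.DataFrame,
    cfg: PreprocConfig,
    channels: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> EpochSet:
    """The full chain on a continuous recording (channels x samples).

    ``events.onset_sample`` indexes the *original* sampling grid and is
    rescaled after downsampling.
    """
    n_ch = raw.shape[0]
    if channels is None:
        channels = [f"CH{i:02d}" for i in range(n_ch)]
    if positions is None:
        positions = ring_montage(n_ch)
    filtered = bandpass(raw, sample_rate, cfg)
    bad = detect_bad_channels(filtered, channels, cfg)
    filtered = interpolate_channels(filtered, channels, bad, positions)
    filtered = rereference_average(filtered)
    down, new_rate = downsample(filtered, sample_rate, cfg)
    ev = events.copy()
    ev["onset_sample"] = np.round(ev["onset_sample"] * new_rate / sample_rate).astype(int)
    epochs = epoch_and_detrend(down, new_rate, ev, cfg, channels)
    epochs.bad_channels = bad
    return epochs


def preprocess_epochs(epochs: EpochSet, cfg: PreprocConfig) -> EpochSet:
    """Epoch-level tail of the chain for data that arrive already epoched:
    average re-reference, per-epoch linear detrend, crop."""
    cfg.validate()
    data = rereference_average(epochs.data)
    data = signal.detrend(data, axis=-1, type="linear")
    crop = time_grid(*cfg.crop_window_ms, epochs.sample_rate)
    sel = np.isin(np.round(epochs.times * epochs.sample_rate / 1000).astype(int),
                  np.round(crop * epochs.sample_rate / 1000).astype(int))
    return EpochSet(
        data=data[:, :, sel],
        times=epochs.times[sel],
        sample_rate=epochs.sample_rate,
        channels=list(epochs.channels),
        events=epochs.events.copy(),
        bad_channels=set(epochs.bad_channels),
    )
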