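"""Signal conditioning: band-pass, optional notch, downsample, epoch, baseline.

The chain mirrors a standard ERP preprocessing recipe: zero-phase Butterworth
band-pass (0.5–30 Hz, order 5) at the native rate, optional 60 Hz notch,
anti-aliased downsampling to 100 Hz, then epoching to [−200, 800) ms around
stimulus onsets with baseline correction over [−100, 0) ms. Filtering is
forward-backward (zero phase) so component latencies are preserved for the
downstream interval selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import gcd

import numpy as np
import pandas as pd
from scipy import signal as sps

from .channels import CHANNELS
from .epochs import META_COLUMNS, EpochSet
from .paradigm import InvalidSpecError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: Butterworth band edges, order, optional notch."""

    band: tuple[float, float] = (0.5, 30.0)
    order: int = 5
    family: str = "butterworth"
    notch: float | None = 60.0

    def validate(self, rate: float) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise InvalidSpecError("band must satisfy 0 < low < high")
        if hi >= rate / 2:
            raise InvalidSpecError(
                f"band edge {hi} Hz is at/above Nyquist ({rate / 2} Hz)"
            )
        if self.family.lower() != "butterworth":
            raise InvalidSpecError(f"unsupported filter family {self.family!r}")


def bandpass(x: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Applies the notch (if configured and below Nyquist) before the band-pass.
    A constant input maps to ~0 since DC lies outside the passband.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    spec.validate(rate)
    if spec.notch is not None and spec.notch < rate / 2:
        b, a = sps.iirnotch(spec.notch, Q=30.0, fs=rate)
        x = sps.filtfilt(b, a, x, axis=-1)
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def bandpass_gain(freq_hz: float, rate: float, spec: FilterSpec = FilterSpec()) -> float:
    """Amplitude gain of the (two-pass) band-pass at *freq_hz* — test oracle."""
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=rate)
    return float(np.abs(h[0]) ** 2)  # filtfilt applies the filter twice


def downsample(x: np.ndarray, rate_in: float, rate_out: float = 100.0) -> np.ndarray:
    """Anti-aliased rate reduction along the last axis (polyphase resampling)."""
    if rate_out > rate_in:
        raise InvalidSpecError("rate_out must not exceed rate_in")
    if rate_out == rate_in:
        return np.asarray(x, dtype=float)
    up, down = int(rate_out), int(rate_in)
    g = gcd(up, down)
    return sps.resample_poly(
        np.asarray(x, dtype=float), up // g, down // g, axis=-1, padtype="line"
    )


def epoch_and_baseline(
    continuous: np.ndarray,
    rate: float,
    onsets_ms: np.ndarray,
    meta: pd.DataFrame | None = None,
    window: tuple[float, float] = (-200.0, 800.0),
    baseline: tuple[float, float] = (-100.0, 0.0),
    channels: tuple[str, ...] | None = None,
) -> EpochSet:
    """Cut epochs around onsets and subtract the pre-stimulus baseline mean.

    The epoch window is half-open ``[window[0], window[1])`` (100 samples at
    100 Hz under the defaults). Onsets too close to the recording edge are
    dropped with a warning. ``meta`` rows (aligned with ``onsets_ms``) are
    carried over for kept trials; minimal metadata is fabricated otherwise.
    """
    x = np.asarray(continuous, dtype=float)
    if x.ndim != 2:
        raise ValueError("continuous must be (n_channels, n_samples)")
    if channels is None:
        channels = CHANNELS if x.shape[0] == len(CHANNELS) else tuple(
            f"ch{i}" for i in range(x.shape[0])
        )
    dt = 1000.0 / rate
    rel = np.arange(window[0], window[1] - 0.5 * dt, dt)
    n_t = len(rel)
    start_off = int(round(window[0] / dt))

    keep, slabs = [], []
    for i, onset in enumerate(np.asarray(onsets_ms, dtype=float)):
        i0 = int(round(onset / dt)) + start_off
        if i0 < 0 or i0 + n_t > x.shape[1]:
            logger.warning("dropping trial %d: onset %.1f ms too close to edge", i, onset)
            continue
        keep.append(i)
        slabs.append(x[:, i0 : i0 + n_t])
    data = np.stack(slabs, axis=0) if slabs else np.empty((0, x.shape[0], n_t))

    bl = (rel >= baseline[0]) & (rel < baseline[1])
    if bl.any() and len(data):
        data = data - data[:, :, bl].mean(axis=2, keepdims=True)

    if meta is not None:
        kept = meta.iloc[keep].reset_index(drop=True)
    else:
        kept = pd.DataFrame(
            {
                "subject": 0,
                "condition": "unknown",
                "phase": "unknown",
                "selection": 0,
                "sequence": np.arange(len(keep)),
                "stimulus": 0,
                "is_target": False,
                "onset_ms": np.asarray(onsets_ms, dtype=float)[keep],
            },
            columns=list(META_COLUMNS),
        )
    return EpochSet(data, rel, rate, kept, channels)


def preprocess_chain(
    continuous: np.ndarray,
    rate_in: float,
    onsets_ms: np.ndarray,
    meta: pd.DataFrame | None = None,
    filter_spec: FilterSpec = FilterSpec(),
    rate_out: float = 100.0,
    window: tuple[float, float] = (-200.0, 800.0),
    baseline: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Full chain: band-pass at the native rate → downsample → epoch/baseline."""
    filtered = bandpass(continuous, rate_in, filter_spec)
    down = downsample(filtered, rate_in, rate_out)
    return epoch_and_baseline(down, rate_out, onsets_ms, meta, window, baseline)
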