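"""Discriminative ERP features.

Pointwise class separability is measured by the signed r² statistic — the
squared point-biserial correlation with the sign of the mean difference
retained:

    r_i = sqrt(N1*N2)/(N1+N2) * (x̄_i1 − x̄_i2)/s_i,   signed r²_i = sign(r_i)·r_i²

where x̄_i1, x̄_i2 are the class means at sample i, N1/N2 the class sizes and
s_i the standard deviation of all trials pooled (ddof=1). Discriminant time
intervals are ranked on this trace at the reference channels (Cz, Pz, Oz) and
the spatio-temporal feature vector of a trial is the per-channel mean amplitude
inside each selected interval, concatenated channel-major (D = 32 × 8 = 256
under the defaults).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .epochs import EpochSet
from .templates import COMPONENT_POLARITY, COMPONENT_WINDOWS

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- signed r²
@dataclass
class SeparabilityTrace:
    """Signed r² per (channel, time sample), with class sizes."""

    values: np.ndarray  # (n_channels, n_times), in [-1, 1]
    channels: tuple[str, ...]
    times: np.ndarray
    n1: int
    n2: int

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channels.index(name)]


def signed_r_squared(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Signed r² between two trial groups, elementwise over trailing axes.

    ``x1``/``x2`` have trials on axis 0 (e.g. (n1, n_channels, n_times)).
    Points where the pooled sd is zero get value 0 (flagged via a log message).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per class")
    s = np.concatenate([x1, x2], axis=0).std(axis=0, ddof=1)
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    degenerate = s == 0
    if np.any(degenerate):
        logger.info("signed r²: %d degenerate points set to 0", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(n1 * n2) / (n1 + n2) * np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, s))
    return np.sign(r) * r**2


def separability(epochs: EpochSet) -> SeparabilityTrace:
    """Target vs non-target signed r² trace of an epoch set."""
    tgt = epochs.meta["is_target"].to_numpy()
    if tgt.all() or (~tgt).all():
        raise ValueError("both target and non-target trials are required")
    vals = signed_r_squared(epochs.data[tgt], epochs.data[~tgt])
    return SeparabilityTrace(vals, epochs.channels, epochs.times, int(tgt.sum()), int((~tgt).sum()))


def separability_between(a: EpochSet, b: EpochSet) -> SeparabilityTrace:
    """Signed r² between two epoch sets (e.g. passive vs imagery target trials)."""
    if not np.array_equal(a.times, b.times) or a.channels != b.channels:
        raise ValueError("epoch sets are not aligned")
    vals = signed_r_squared(a.data, b.data)
    return SeparabilityTrace(vals, a.channels, a.times, a.n_trials, b.n_trials)


# ----------------------------------------------------------- feature layout
@dataclass
class FeatureLayout:
    """Selected time intervals × channel order defining the feature vector.

    ``intervals`` are half-open (start_ms, end_ms) windows, non-overlapping and
    sorted by onset; features are concatenated channel-major (channel outer
    loop, interval inner loop).
    """

    intervals: list[tuple[float, float]]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        ints = sorted((float(a), float(b)) for a, b in self.intervals)
        for (a, b) in ints:
            if not a < b:
                raise ValueError("interval start must precede end")
        for (_, b), (a2, _) in zip(ints, ints[1:]):
            if a2 < b:
                raise ValueError("intervals must not overlap")
        self.intervals = ints

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def dim(self) -> int:
        """Feature dimensionality D = n_channels × n_intervals."""
        return len(self.channels) * len(self.intervals)

    def to_yaml(self, path) -> None:
        doc = {
            "channels": list(self.channels),
            "intervals_ms": [[float(a), float(b)] for a, b in self.intervals],
        }
        with open(path, "w") as f:
            yaml.safe_dump(doc, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureLayout":
        with open(path) as f:
            doc = yaml.safe_load(f)
        return cls(
            [tuple(iv) for iv in doc["intervals_ms"]], tuple(doc["channels"])
        )


DEFAULT_REFERENCE_CHANNELS = ("Cz", "Pz", "Oz")


def select_intervals(
    trace: SeparabilityTrace,
    reference_channels: tuple[str, ...] = DEFAULT_REFERENCE_CHANNELS,
    k: int = 8,
    width_ms: float = 50.0,
    tmin_ms: float = 0.0,
) -> FeatureLayout:
    """Pick k non-overlapping discriminant windows from the separability trace.

    Deterministic surrogate for by-eye interval selection: every window start
    on the sample grid in [tmin_ms, end] is scored by the mean |signed r²| over
    the reference channels and window samples; windows are taken greedily by
    score, discarding overlaps, ties broken toward the earliest onset. If fewer
    than k disjoint candidates exist, fewer intervals are returned with a
    warning.
    """
    ref_idx = [trace.channels.index(c) for c in reference_channels]
    times = trace.times
    dt = float(np.median(np.diff(times)))
    w = max(1, int(round(width_ms / dt)))
    starts = [
        i
        for i in range(len(times) - w + 1)
        if times[i] >= tmin_ms and times[i] + width_ms <= times[-1] + dt + 1e-9
    ]
    if not starts:
        raise ValueError("no candidate windows fit the epoch")
    mag = np.abs(trace.values[ref_idx])  # (n_ref, n_times)
    scores = np.array([mag[:, i : i + w].mean() for i in starts])
    order = np.lexsort((np.asarray(starts), -scores))  # score desc, onset asc

    chosen: list[int] = []
    for j in order:
        i = starts[j]
        if all(abs(i - c) >= w for c in chosen):
            chosen.append(i)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        logger.warning("only %d disjoint intervals available (requested %d)", len(chosen), k)
    intervals = [(float(times[i]), float(times[i]) + width_ms) for i in sorted(chosen)]
    return FeatureLayout(intervals, trace.channels)


def extract_features(epochs: EpochSet, layout: FeatureLayout) -> np.ndarray:
    """Spatio-temporal mean-amplitude features, (n_trials, D).

    Per trial, the mean amplitude of each channel inside each half-open layout
    interval, concatenated channel-major.
    """
    if epochs.channels != layout.channels:
        raise ValueError("epoch channels do not match layout channels")
    t = epochs.times
    cols = []
    for (a, b) in layout.intervals:
        m = (t >= a) & (t < b)
        if not m.any():
            raise ValueError(f"interval [{a}, {b}) contains no samples")
        cols.append(epochs.data[:, :, m].mean(axis=2))  # (n_trials, n_channels)
    stacked = np.stack(cols, axis=2)  # (n_trials, n_channels, n_intervals)
    return stacked.reshape(epochs.n_trials, layout.dim)


# --------------------------------------------------------- peak amplitudes
def peak_amplitudes(
    epochs: EpochSet,
    components: dict[str, tuple[tuple[float, float], int]] | None = None,
    electrodes: tuple[str, ...] = ("Oz", "Cz"),
) -> pd.DataFrame:
    """Mean-of-peak amplitude table across subjects.

    For every (condition, class, component, electrode): each subject's average
    ERP is reduced to its signed extremum inside the component window (min for
    negative components, max for positive), then mean ± sd are taken across
    subjects. Mirrors grand-average peak reporting of group ERP studies.

    ``components`` maps name → ((start_ms, end_ms), polarity); defaults to the
    built-in N200/P300/N500 windows.
    """
    if components is None:
        components = {
            name: (COMPONENT_WINDOWS[name], COMPONENT_POLARITY[name])
            for name in ("N200", "P300", "N500")
        }
    t = epochs.times
    rows = []
    grp_cols = ["condition", "is_target"]
    for (cond, flag), idx in epochs.meta.groupby(grp_cols).groups.items():
        sub_meta = epochs.meta.loc[idx]
        for name, (win, pol) in components.items():
            m = (t >= win[0]) & (t < win[1])
            for el in electrodes:
                ch = epochs.channel_index(el)
                peaks = []
                for _, sidx in sub_meta.groupby("subject").groups.items():
                    erp = epochs.data[np.asarray(sidx), ch][:, m].mean(axis=0)
                    peaks.append(erp.min() if pol < 0 else erp.max())
                peaks = np.asarray(peaks)
                rows.append(
                    {
                        "condition": cond,
                        "is_target": bool(flag),
                        "component": name,
                        "electrode": el,
                        "mean_uV": peaks.mean(),
                        "sd_uV": peaks.std(ddof=1) if len(peaks) > 1 else 0.0,
                        "n_subjects": len(peaks),
                    }
                )
    return pd.DataFrame(rows)


# ------------------------------------------------- sliding-window decoding
def sliding_window_trace(
    train: EpochSet,
    test: EpochSet,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
    shrinkage: float | str = "auto",
    tmin_ms: float = 0.0,
) -> pd.DataFrame:
    """Balanced target/non-target decoding accuracy per sliding time window.

    For each window the features are the per-channel mean amplitudes inside
    that window only; a shrinkage-LDA is trained on the training epochs and
    scored on the test epochs. Returns columns ``center_ms`` and ``accuracy``
    (mean of the two class-wise accuracies, so chance is 0.5 despite the 1:3
    class imbalance). Windows extending past the epoch are skipped.
    """
    from .decoders import score, train_rlda  # local import to avoid a cycle

    t = train.times
    out = []
    start = tmin_ms
    while start + window_ms <= t[-1] + (t[1] - t[0]) + 1e-9:
        layout = FeatureLayout([(start, start + window_ms)], train.channels)
        Xtr = extract_features(train, layout)
        ytr = train.meta["is_target"].to_numpy().astype(int)
        Xte = extract_features(test, layout)
        yte = test.meta["is_target"].to_numpy().astype(int)
        dec = train_rlda(Xtr, ytr, shrinkage=shrinkage)
        pred = (score(dec, Xte) > 0).astype(int)
        accs = [np.mean(pred[yte == c] == c) for c in (0, 1)]
        out.append({"center_ms": start + window_ms / 2, "accuracy": float(np.mean(accs))})
        start += step_ms
    return pd.DataFrame(out)
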