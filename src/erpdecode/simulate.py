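"""Forward model: synthetic epochs for the oddball paradigm.

Each trial is the sum of the configured component bumps — amplitude chosen by
the trial's (condition, target/non-target) cell plus a per-subject offset —
scaled over channels by the component's scalp profile, plus zero-mean noise
(white Gaussian by default, optionally 1/f^α-shaped along time). Epochs are
emitted directly on the post-preprocessing grid (100 Hz, −200..800 ms,
baseline-corrected over −100..0 ms); with ``noise_sd=0`` the output is the
deterministic template sum exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .channels import CHANNELS
from .epochs import META_COLUMNS, EpochSet
from .paradigm import FlashSchedule, ParadigmSpec, sample_schedule
from .templates import ComponentTemplate

SubjectEffects = dict[tuple[str, str, bool], float]


def draw_subject_effects(
    templates: list[ComponentTemplate],
    rng: np.random.Generator | int | None = None,
    conditions: tuple[str, ...] | None = None,
) -> SubjectEffects:
    """Draw one amplitude offset per (component, condition, class) for a subject.

    Offsets are N(0, amplitude_sd) in µV, drawn once and then fixed for every
    trial of that subject, reproducing the across-subject spread of the
    calibration table.
    """
    rng = np.random.default_rng(rng)
    out: SubjectEffects = {}
    for tpl in templates:
        for (cond, flag), sd in sorted(tpl.amplitude_sd.items()):
            if conditions is not None and cond not in conditions:
                continue
            out[(tpl.name, cond, flag)] = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
    return out


def _shaped_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sd: float,
    alpha: float,
    sfreq: float,
) -> np.ndarray:
    """Zero-mean noise with sd *sd*; alpha > 0 gives a 1/f^alpha power spectrum."""
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if alpha <= 0:
        return sd * white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    w = np.ones_like(freqs)
    w[1:] = freqs[1:] ** (-alpha / 2.0)
    w[0] = w[1]  # keep a finite DC weight; baseline correction removes offsets
    spec = np.fft.rfft(white, axis=-1) * w
    x = np.fft.irfft(spec, n=n, axis=-1)
    # analytic variance of the shaped series for unit-variance white input
    w_full = np.concatenate([w, w[-2:0:-1]]) if n % 2 == 0 else np.concatenate([w, w[-1:0:-1]])
    x /= np.sqrt(np.mean(w_full**2))
    return sd * x


def synthesize_epochs(
    spec: ParadigmSpec,
    templates: list[ComponentTemplate],
    *,
    condition: str,
    phase: str = "train",
    cued_targets: np.ndarray | list[int] | None = None,
    schedule: FlashSchedule | None = None,
    noise_sd: float = 12.0,
    noise_alpha: float = 0.0,
    subject_effects: SubjectEffects | None = None,
    subject: int = 0,
    amp_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
    sfreq: float = 100.0,
    window: tuple[float, float] = (-200.0, 800.0),
    baseline: tuple[float, float] = (-100.0, 0.0),
    dtype=np.float64,
) -> EpochSet:
    """Simulate one phase of one condition as an :class:`EpochSet`.

    Parameters
    ----------
    cued_targets
        Attended symbol per selection; drawn uniformly if omitted (and no
        ``schedule`` is given).
    subject_effects
        Fixed per-subject amplitude offsets from :func:`draw_subject_effects`;
        zeros if omitted.
    amp_scale
        Multiplicative factor on all component amplitudes (e.g. session drift
        in a test phase); default 1 (off).
    noise_alpha
        Spectral exponent of the additive noise; 0 = white.
    """
    if condition not in spec.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("template names must be unique")
    rng = np.random.default_rng(rng)

    if schedule is None:
        if cued_targets is None:
            cued_targets = rng.integers(0, spec.n_symbols, spec.n_selections_per_phase)
        schedule = sample_schedule(spec, cued_targets, rng)
    ev = schedule.events
    n_trials = len(ev)

    dt = 1000.0 / sfreq
    times = np.arange(window[0], window[1] - 0.5 * dt, dt)
    n_ch, n_t = len(CHANNELS), len(times)

    data = _shaped_noise(rng, (n_trials, n_ch, n_t), noise_sd, noise_alpha, sfreq)
    data = np.asarray(data, dtype=dtype)

    is_target = ev["is_target"].to_numpy()
    for tpl in templates:
        bump = tpl.time_course(times)
        kernel = np.outer(tpl.spatial_profile, bump)  # (n_ch, n_t)
        amp = np.empty(n_trials)
        for flag in (True, False):
            base = tpl.amplitude(condition, flag)
            off = 0.0
            if subject_effects is not None:
                off = subject_effects.get((tpl.name, condition, flag), 0.0)
            amp[is_target == flag] = (base + off) * amp_scale
        data += amp[:, None, None] * kernel[None, :, :]

    # baseline-correct over [-100, 0) ms per trial and channel
    bl = (times >= baseline[0]) & (times < baseline[1])
    if bl.any():
        data -= data[:, :, bl].mean(axis=2, keepdims=True)

    meta = pd.DataFrame(
        {
            "subject": np.full(n_trials, subject),
            "condition": np.full(n_trials, condition, dtype=object),
            "phase": np.full(n_trials, phase, dtype=object),
            "selection": ev["selection"].to_numpy(),
            "sequence": ev["sequence"].to_numpy(),
            "stimulus": ev["stimulus"].to_numpy(),
            "is_target": is_target,
            "onset_ms": ev["onset_ms"].to_numpy(),
        },
        columns=list(META_COLUMNS),
    )
    return EpochSet(data, times, sfreq, meta, CHANNELS)


def simulate_session(
    spec: ParadigmSpec,
    templates: list[ComponentTemplate],
    *,
    subject: int = 0,
    conditions: tuple[str, ...] | None = None,
    phases: tuple[str, ...] | None = None,
    noise_sd: float = 12.0,
    noise_alpha: float = 0.0,
    test_amp_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
    dtype=np.float64,
) -> EpochSet:
    """Simulate one subject's full session (all phases × conditions).

    Subject amplitude offsets are drawn once and shared across phases and
    conditions; ``test_amp_scale`` optionally attenuates amplitudes in the test
    phase (session drift), default off.
    """
    rng = np.random.default_rng(rng)
    conditions = conditions or spec.conditions
    phases = phases or spec.phases
    effects = draw_subject_effects(templates, rng, conditions=tuple(conditions))
    parts = []
    for cond in conditions:
        for phase in phases:
            parts.append(
                synthesize_epochs(
                    spec,
                    templates,
                    condition=cond,
                    phase=phase,
                    noise_sd=noise_sd,
                    noise_alpha=noise_alpha,
                    subject_effects=effects,
                    subject=subject,
                    amp_scale=test_amp_scale if phase == "test" else 1.0,
                    rng=rng,
                    dtype=dtype,
                )
            )
    return EpochSet.concatenate(parts)


def synthesize_continuous(
    spec: ParadigmSpec,
    templates: list[ComponentTemplate],
    *,
    condition: str,
    schedule: FlashSchedule,
    noise_sd: float = 0.0,
    subject_effects: SubjectEffects | None = None,
    rate: float = 1000.0,
    padding_ms: float = 1000.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous multichannel trace at a raw sampling rate plus flash onsets.

    Exercises the preprocessing chain end-to-end (filter → downsample → epoch).
    Returns ``(signal (n_channels, n_samples) µV, onsets_ms)``; onsets are
    shifted by ``padding_ms`` so every epoch window fits inside the recording.
    """
    rng = np.random.default_rng(rng)
    ev = schedule.events
    onsets = ev["onset_ms"].to_numpy() + padding_ms
    total_ms = onsets[-1] + 2 * padding_ms
    n_samp = int(round(total_ms * rate / 1000.0))
    t_ms = np.arange(n_samp) * 1000.0 / rate
    sig = noise_sd * rng.standard_normal((len(CHANNELS), n_samp)) if noise_sd else np.zeros((len(CHANNELS), n_samp))

    is_target = ev["is_target"].to_numpy()
    for tpl in templates:
        for onset, flag in zip(onsets, is_target):
            base = tpl.amplitude(condition, bool(flag))
            if subject_effects is not None:
                base += subject_effects.get((tpl.name, condition, bool(flag)), 0.0)
            lo = onset + tpl.window[0]
            hi = onset + tpl.window[1]
            m = (t_ms >= lo) & (t_ms <= hi)
            if not m.any():
                continue
            phase = (t_ms[m] - (onset + tpl.center)) / (0.5 * (tpl.window[1] - tpl.window[0]))
            bump = 0.5 * (1.0 + np.cos(np.pi * np.clip(phase, -1, 1)))
            sig[:, m] += base * np.outer(tpl.spatial_profile, bump)
    return sig, onsets
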