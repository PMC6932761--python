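"""Oddball flash paradigm: experiment geometry and randomized flash schedules.

The simulated experiment mirrors a 4-symbol visual oddball speller: in each
*selection* the user attends one cued symbol while all symbols flash once per
*sequence* in random order, for a fixed number of sequences. A flash lasts
``flash_duration`` ms and is followed by an inter-stimulus interval ``isi``;
consecutive flashes never repeat the same symbol, including across sequence
boundaries within a selection, so the attended symbol cannot flash twice in a
row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("passive", "counting", "pitch_imagery")
PHASES = ("train", "test")


class InvalidSpecError(ValueError):
    """Raised when a paradigm/filter specification is internally inconsistent."""


@dataclass(frozen=True)
class ParadigmSpec:
    """Geometry and timing of the simulated oddball experiment.

    Defaults reproduce the study conditions: 4 symbols, 10 sequences per
    selection, 20 selections per phase, 70 ms flashes with a 150 ms ISI,
    training and test phases, three attention conditions.
    """

    n_symbols: int = 4
    n_sequences: int = 10
    n_selections_per_phase: int = 20
    flash_duration: float = 70.0  # ms
    isi: float = 150.0  # ms
    phases: tuple[str, ...] = PHASES
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_symbols < 2:
            raise InvalidSpecError("need at least 2 symbols for an oddball paradigm")
        if self.n_sequences < 1:
            raise InvalidSpecError("n_sequences must be >= 1")
        if self.n_selections_per_phase < 1:
            raise InvalidSpecError("n_selections_per_phase must be >= 1")
        if self.flash_duration <= 0:
            raise InvalidSpecError("flash_duration must be positive")
        if self.isi < 0:
            raise InvalidSpecError("isi must be non-negative")

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony in ms (flash + ISI)."""
        return self.flash_duration + self.isi

    @property
    def flashes_per_phase(self) -> int:
        return self.n_selections_per_phase * self.n_sequences * self.n_symbols

    def targets_per_phase(self) -> tuple[int, int]:
        """(n_target, n_nontarget) flashes in one phase of one condition."""
        n_t = self.n_selections_per_phase * self.n_sequences
        return n_t, self.flashes_per_phase - n_t


@dataclass
class FlashSchedule:
    """Ordered flash events of one phase.

    ``events`` has one row per flash with columns ``selection``, ``sequence``,
    ``stimulus``, ``is_target`` and ``onset_ms``. Within every selection each
    sequence contains each stimulus exactly once and no two consecutive flashes
    share a stimulus.
    """

    events: pd.DataFrame
    spec: ParadigmSpec = field(repr=False, default_factory=ParadigmSpec)

    def __len__(self) -> int:
        return len(self.events)

    def validate(self) -> None:
        ev = self.events
        n_sym = self.spec.n_symbols
        for sel, grp in ev.groupby("selection", sort=True):
            stim = grp["stimulus"].to_numpy()
            if np.any(stim[1:] == stim[:-1]):
                raise ValueError(f"consecutive repeat within selection {sel}")
            for _, seq in grp.groupby("sequence", sort=True):
                if sorted(seq["stimulus"]) != list(range(n_sym)):
                    raise ValueError(f"incomplete sequence in selection {sel}")
            if grp["is_target"].sum() != self.spec.n_sequences:
                raise ValueError(f"wrong target count in selection {sel}")
        onset = ev["onset_ms"].to_numpy()
        if np.any(np.diff(onset) <= 0):
            raise ValueError("onsets not strictly increasing")

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: ParadigmSpec | None = None) -> "FlashSchedule":
        return cls(pd.read_csv(path), spec or ParadigmSpec())


def sample_schedule(
    spec: ParadigmSpec,
    cued_targets: list[int] | np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> FlashSchedule:
    """Draw a random legal flash schedule for one phase.

    Each sequence is a uniformly random permutation of the symbols, redrawn
    until its first flash differs from the previous sequence's last flash
    (rejection is cheap: acceptance probability is 1 - 1/n_symbols).

    Parameters
    ----------
    cued_targets
        The attended symbol index for each selection
        (length ``n_selections_per_phase``).
    """
    cued = np.asarray(cued_targets, dtype=int)
    if len(cued) != spec.n_selections_per_phase:
        raise InvalidSpecError(
            f"cued_targets must have length {spec.n_selections_per_phase}"
        )
    if np.any(cued < 0) or np.any(cued >= spec.n_symbols):
        raise InvalidSpecError("cued target index out of range")
    rng = np.random.default_rng(rng)

    soa = spec.soa
    rows_sel, rows_seq, rows_stim = [], [], []
    flash = 0
    for sel in range(spec.n_selections_per_phase):
        prev_last = -1  # no constraint at the start of a selection
        for seq in range(spec.n_sequences):
            order = rng.permutation(spec.n_symbols)
            while order[0] == prev_last:
                order = rng.permutation(spec.n_symbols)
            prev_last = order[-1]
            rows_sel.extend([sel] * spec.n_symbols)
            rows_seq.extend([seq] * spec.n_symbols)
            rows_stim.extend(order.tolist())
            flash += spec.n_symbols
    stim = np.asarray(rows_stim)
    sel_arr = np.asarray(rows_sel)
    events = pd.DataFrame(
        {
            "selection": sel_arr,
            "sequence": np.asarray(rows_seq),
            "stimulus": stim,
            "is_target": stim == cued[sel_arr],
            "onset_ms": np.arange(flash, dtype=float) * soa,
        }
    )
    return FlashSchedule(events, spec)
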