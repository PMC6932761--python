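"""ERP component templates for the forward model.

A :class:`ComponentTemplate` describes one event-related component as a smooth
unimodal bump: a raised-cosine time course whose support is the component's
literature window, scaled by a per-condition/per-class peak amplitude at a
reference electrode and spread over the scalp by a spatial profile.

Default templates encode the three components that drive decoding in this
paradigm: the occipital N200 (visual target detection, maximal at Oz), the
centro-parietal P300 (attention/oddball response, maximal around Cz/Pz) and the
central N500 — a late negativity whose amplitude grows with the mental effort
of the task performed on target flashes (passive gazing < silent counting <
pitch imagery). Mean peak amplitudes and their across-subject standard
deviations are calibrated per (condition, target/non-target) cell from
group-level measurements at the component's reference electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS, gaussian_profile
from .paradigm import CONDITIONS

AmplitudeKey = tuple[str, bool]  # (condition, is_target)


@dataclass(frozen=True)
class ComponentTemplate:
    """One simulated ERP component.

    Parameters
    ----------
    name
        Component label ("N200", "P300", "N500", ...).
    window
        (start, end) of the bump support in ms post-stimulus. The peak sits at
        the window center (snapped to the output sampling grid so that the
        configured amplitude is attained exactly by a sample).
    peak_amplitude
        Mean peak amplitude in µV at the reference electrode, keyed by
        (condition, is_target). Sign encodes polarity.
    amplitude_sd
        Across-subject standard deviation in µV, same keys.
    spatial_profile
        Per-channel scaling in [0, 1]; 1 at the reference electrode.
    reference
        Electrode at which ``peak_amplitude`` applies.
    """

    name: str
    window: tuple[float, float]
    peak_amplitude: dict[AmplitudeKey, float]
    amplitude_sd: dict[AmplitudeKey, float]
    spatial_profile: np.ndarray = field(repr=False)
    reference: str = "Cz"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"{self.name}: window start must precede end")
        if len(self.spatial_profile) != len(CHANNELS):
            raise ValueError(f"{self.name}: spatial_profile needs one entry per channel")
        if any(sd < 0 for sd in self.amplitude_sd.values()):
            raise ValueError(f"{self.name}: amplitude_sd must be non-negative")

    @property
    def center(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])

    def amplitude(self, condition: str, is_target: bool) -> float:
        key = (condition, bool(is_target))
        if key not in self.peak_amplitude:
            raise KeyError(
                f"{self.name}: no amplitude configured for condition "
                f"{condition!r} (target={is_target})"
            )
        return self.peak_amplitude[key]

    def time_course(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-peak raised-cosine bump evaluated on the ms grid *times_ms*.

        The peak is snapped to the grid sample nearest the window center, so a
        sampled trace attains the nominal amplitude exactly.
        """
        t = np.asarray(times_ms, dtype=float)
        lo, hi = self.window
        half = 0.5 * (hi - lo)
        center = t[np.argmin(np.abs(t - self.center))] if t.size else self.center
        phase = (t - center) / half
        bump = 0.5 * (1.0 + np.cos(np.pi * np.clip(phase, -1.0, 1.0)))
        bump[np.abs(phase) >= 1.0] = 0.0
        return bump


# Group-mean peak amplitude µV (mean, across-subject sd) at the reference
# electrode, per component / condition / class. N200 is referenced at Oz,
# P300 and N500 at Cz, matching each component's scalp maximum.
_CALIBRATION: dict[str, dict[AmplitudeKey, tuple[float, float]]] = {
    "N200": {  # Oz
        ("passive", True): (-2.217, 1.51),
        ("passive", False): (-0.427, 0.45),
        ("counting", True): (-2.213, 1.26),
        ("counting", False): (-0.553, 0.34),
        ("pitch_imagery", True): (-2.351, 1.18),
        ("pitch_imagery", False): (-0.493, 0.34),
    },
    "P300": {  # Cz
        ("passive", True): (1.817, 1.02),
        ("passive", False): (1.133, 0.49),
        ("counting", True): (3.029, 1.48),
        ("counting", False): (1.268, 0.60),
        ("pitch_imagery", True): (2.308, 1.70),
        ("pitch_imagery", False): (1.384, 0.89),
    },
    "N500": {  # Cz
        ("passive", True): (-1.094, 0.88),
        ("passive", False): (-0.663, 0.48),
        ("counting", True): (-2.226, 0.97),
        ("counting", False): (-0.532, 0.69),
        ("pitch_imagery", True): (-2.883, 1.36),
        ("pitch_imagery", False): (-0.541, 0.74),
    },
}

#: Component search windows in ms (also the bump supports of the defaults).
COMPONENT_WINDOWS: dict[str, tuple[float, float]] = {
    "N200": (180.0, 230.0),
    "P300": (290.0, 390.0),
    "N500": (500.0, 600.0),
}

#: Sign of each default component (+1 positive deflection, -1 negative).
COMPONENT_POLARITY: dict[str, int] = {"N200": -1, "P300": 1, "N500": -1}

_REFERENCE = {"N200": "Oz", "P300": "Cz", "N500": "Cz"}
# P300 topography is centro-parietal: profile centered between Cz and Pz.
_PROFILE_CENTER: dict[str, str | tuple[float, float]] = {
    "N200": "Oz",
    "P300": (0.0, -0.25),
    "N500": "Cz",
}


def default_templates(sigma: float = 0.4) -> list[ComponentTemplate]:
    """The three calibrated components (N200, P300, N500).

    ``sigma`` is the spatial decay scale of the scalp profiles in head-radius
    units.
    """
    out = []
    for name, cal in _CALIBRATION.items():
        out.append(
            ComponentTemplate(
                name=name,
                window=COMPONENT_WINDOWS[name],
                peak_amplitude={k: v[0] for k, v in cal.items()},
                amplitude_sd={k: v[1] for k, v in cal.items()},
                spatial_profile=gaussian_profile(
                    _PROFILE_CENTER[name], sigma=sigma, reference=_REFERENCE[name]
                ),
                reference=_REFERENCE[name],
            )
        )
    return out


def null_templates() -> list[ComponentTemplate]:
    """Templates with every amplitude zeroed — pure-noise simulations."""
    out = []
    for tpl in default_templates():
        out.append(
            ComponentTemplate(
                name=tpl.name,
                window=tpl.window,
                peak_amplitude={k: 0.0 for k in tpl.peak_amplitude},
                amplitude_sd={k: 0.0 for k in tpl.amplitude_sd},
                spatial_profile=tpl.spatial_profile,
                reference=tpl.reference,
            )
        )
    return out


def templates_from_config(cfg: list[dict]) -> list[ComponentTemplate]:
    """Build templates from a YAML-friendly list of dicts.

    Each entry: ``{name, window: [lo, hi], reference, profile_center (optional),
    sigma (optional), amplitudes: {condition: {target: [mean, sd],
    nontarget: [mean, sd]}}}``.
    """
    out = []
    for entry in cfg:
        amps: dict[AmplitudeKey, float] = {}
        sds: dict[AmplitudeKey, float] = {}
        for cond, classes in entry["amplitudes"].items():
            if cond not in CONDITIONS:
                raise KeyError(f"unknown condition {cond!r}")
            for label, (mean, sd) in classes.items():
                flag = {"target": True, "nontarget": False}[label]
                amps[(cond, flag)] = float(mean)
                sds[(cond, flag)] = float(sd)
        center = entry.get("profile_center", entry.get("reference", "Cz"))
        if isinstance(center, list):
            center = tuple(center)
        out.append(
            ComponentTemplate(
                name=entry["name"],
                window=tuple(entry["window"]),
                peak_amplitude=amps,
                amplitude_sd=sds,
                spatial_profile=gaussian_profile(
                    center,
                    sigma=float(entry.get("sigma", 0.4)),
                    reference=entry.get("reference", "Cz"),
                ),
                reference=entry.get("reference", "Cz"),
            )
        )
    return out
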