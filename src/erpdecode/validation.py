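"""Monte-Carlo validation experiments for the simulator + decoding pipeline.

These are the package's standing statistical checks: chance-level recovery of
both decoders under null (signal-free) simulations, calibration recovery of
the configured peak amplitudes, and the paired condition-ordering experiment.
They are used by the test suite and the reproduction script; all randomness
flows from one integer seed.

The ordering experiment uses common random numbers: for a given subject every
condition is generated from an identically seeded generator, so flash
schedules, noise tensors and subject-effect quantiles coincide across
conditions and only the calibrated amplitudes differ. This isolates the
condition effect and makes the passive < counting < pitch-imagery comparison
a paired one, which desk-scale simulation sizes can resolve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import peak_amplitudes
from .paradigm import ParadigmSpec
from .pipeline import active_accuracy, fit_active_pipeline, fit_target_pipeline, sequential_accuracy
from .simulate import draw_subject_effects, synthesize_epochs
from .templates import ComponentTemplate, default_templates, null_templates


def null_target_accuracy(
    seed: int,
    n_selections: int = 2000,
    chunk: int = 200,
    noise_sd: float = 12.0,
) -> tuple[float, int]:
    """4-class selection accuracy of the full pipeline on signal-free data.

    Trains interval selection and the RLDA on one noise-only training session,
    then decodes ``n_selections`` noise-only test selections at the full
    sequence count. Returns (accuracy fraction, n_selections); the expectation
    is exactly 1/n_symbols by symmetry.
    """
    root = np.random.SeedSequence(seed)
    spec = ParadigmSpec()
    tpls = null_templates()
    rng = np.random.default_rng(root.spawn(1)[0])
    train = synthesize_epochs(
        spec, tpls, condition="passive", phase="train", noise_sd=noise_sd,
        rng=rng, dtype=np.float32,
    )
    pipe = fit_target_pipeline(train, "passive")

    correct = total = 0
    done = 0
    while done < n_selections:
        m = min(chunk, n_selections - done)
        test_spec = ParadigmSpec(n_selections_per_phase=m)
        test = synthesize_epochs(
            test_spec, tpls, condition="passive", phase="test", noise_sd=noise_sd,
            rng=rng, dtype=np.float32,
        )
        acc = sequential_accuracy(pipe, test)
        last = acc[acc["n_sequences"] == spec.n_sequences].iloc[0]
        correct += round(last["accuracy"] * last["n_selections"])
        total += int(last["n_selections"])
        done += m
    return correct / total, total


def null_active_accuracy(
    seed: int,
    n_trials: int = 2000,
    chunk: int = 200,
    noise_sd: float = 12.0,
) -> tuple[float, int]:
    """Binary intention accuracy when both mental states share one distribution.

    Both "conditions" are generated from null templates (identical epoch
    distributions); the active decoder is trained on their training target
    trials and classifies held-out accumulative averages of test target trials
    (one per selection). Expectation is 1/2.
    """
    root = np.random.SeedSequence(seed + 1)
    spec = ParadigmSpec()
    tpls = null_templates()
    rng = np.random.default_rng(root.spawn(1)[0])
    parts = [
        synthesize_epochs(
            spec, tpls, condition=cond, phase="train", noise_sd=noise_sd,
            rng=rng, dtype=np.float32,
        )
        for cond in ("passive", "pitch_imagery")
    ]
    from .epochs import EpochSet

    train = EpochSet.concatenate(parts)
    pipe = fit_active_pipeline(train, "passive", "pitch_imagery")

    per_cond = n_trials // 2
    correct = total = 0
    done = 0
    while done < per_cond:
        m = min(chunk, per_cond - done)
        test = EpochSet.concatenate(
            [
                synthesize_epochs(
                    ParadigmSpec(n_selections_per_phase=m), tpls, condition=cond,
                    phase="test", noise_sd=noise_sd, rng=rng, dtype=np.float32,
                )
                for cond in ("passive", "pitch_imagery")
            ]
        )
        acc = active_accuracy(pipe, test)
        rows = acc[(acc["condition"] == "overall") & (acc["n_sequences"] == spec.n_sequences)]
        correct += round(float(rows["accuracy"].iloc[0]) * rows["n_selections"].iloc[0])
        total += int(rows["n_selections"].iloc[0])
        done += m
    return correct / total, total


def calibration_recovery(
    seed: int,
    n_subjects: int = 200,
    n_selections: int = 20,
    noise_sd: float = 1.0,
    condition: str = "pitch_imagery",
    templates: list[ComponentTemplate] | None = None,
) -> pd.DataFrame:
    """Recover configured peak amplitudes from simulated subjects.

    Simulates ``n_subjects`` sessions with per-subject amplitude effects,
    extracts each subject's signed-extremum peaks and compares the across-
    subject mean with the configured (population) amplitude at each
    component's reference electrode (where its scalp profile is 1 and the
    calibration value applies; Cz for P300/N500, Oz for N200). Returns one row
    per (component, class) with the recovery error and the standard error of
    the across-subject mean.

    The extremum estimator carries a small outward noise bias (extreme-value
    statistics over the window samples), so this check is run at low noise
    with many trials per subject; see the package methods note.
    """
    templates = templates or default_templates()
    spec = ParadigmSpec(n_selections_per_phase=n_selections)
    seeds = np.random.SeedSequence(seed + 2).spawn(n_subjects)
    electrodes = tuple(dict.fromkeys(t.reference for t in templates))
    tables = []
    for subj, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        effects = draw_subject_effects(templates, rng, conditions=(condition,))
        ep = synthesize_epochs(
            spec, templates, condition=condition, noise_sd=noise_sd,
            subject_effects=effects, subject=subj, rng=rng, dtype=np.float32,
        )
        tables.append(peak_amplitudes(ep, electrodes=electrodes))
    allp = pd.concat(tables, ignore_index=True)

    rows = []
    for tpl in templates:
        sub = allp[(allp.component == tpl.name) & (allp.electrode == tpl.reference)]
        for flag, vals in sub.groupby("is_target")["mean_uV"]:
            rows.append(
                {
                    "component": tpl.name,
                    "is_target": bool(flag),
                    "electrode": tpl.reference,
                    "configured_uV": tpl.amplitude(condition, flag),
                    "recovered_uV": vals.mean(),
                    "se_uV": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "n_subjects": len(vals),
                }
            )
    return pd.DataFrame(rows)


def paired_condition_curves(
    seed: int,
    n_subjects: int = 4,
    n_test_selections: int = 125,
    noise_sd: float = 12.0,
    conditions: tuple[str, ...] = ("passive", "counting", "pitch_imagery"),
) -> pd.DataFrame:
    """Mean sequential accuracy per condition under common random numbers.

    Returns a frame indexed by n_sequences with one column per condition; each
    cell is the mean accuracy over ``n_subjects × n_test_selections`` paired
    test selections.
    """
    spec_train = ParadigmSpec()
    spec_test = ParadigmSpec(n_selections_per_phase=n_test_selections)
    tpls = default_templates()
    curves: dict[str, np.ndarray] = {}
    for cond in conditions:
        per_subj = []
        for subj in range(n_subjects):
            rng = np.random.default_rng([seed + 3, subj])
            effects = draw_subject_effects(tpls, rng, conditions=(cond,))
            train = synthesize_epochs(
                spec_train, tpls, condition=cond, phase="train", noise_sd=noise_sd,
                subject_effects=effects, subject=subj, rng=rng, dtype=np.float32,
            )
            test = synthesize_epochs(
                spec_test, tpls, condition=cond, phase="test", noise_sd=noise_sd,
                subject_effects=effects, subject=subj, rng=rng, dtype=np.float32,
            )
            pipe = fit_target_pipeline(train, cond)
            per_subj.append(
                sequential_accuracy(pipe, test).set_index("n_sequences")["accuracy"]
            )
        curves[cond] = np.mean(per_subj, axis=0)
    n_seq = spec_train.n_sequences
    return pd.DataFrame(curves, index=pd.RangeIndex(1, n_seq + 1, name="n_sequences"))
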