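"""Experiment orchestration: simulate → preprocess-grid epochs → decode → report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epochs import EpochSet, count_trials
from .features import peak_amplitudes
from .paradigm import CONDITIONS, ParadigmSpec
from .pipeline import (
    active_accuracy,
    evaluate_sequential,
    evaluate_two_stage,
    fit_active_pipeline,
)
from .simulate import simulate_session
from .templates import default_templates, null_templates, templates_from_config


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulation + decoding experiment."""

    seed: int
    n_subjects: int = 5
    noise_sd: float = 12.0
    noise_alpha: float = 0.0
    test_amp_scale: float = 1.0
    conditions: tuple[str, ...] = CONDITIONS
    templates: str | list = "default"  # "default", "null", or explicit list
    paradigm: dict = field(default_factory=dict)
    k_intervals: int = 8
    width_ms: float = 50.0
    shrinkage: float | str = "auto"
    passive_condition: str = "passive"
    active_condition: str = "pitch_imagery"

    def spec(self) -> ParadigmSpec:
        return ParadigmSpec(conditions=tuple(self.conditions), **self.paradigm)

    def build_templates(self):
        if self.templates == "default":
            return default_templates()
        if self.templates in ("null", "none"):
            return null_templates()
        return templates_from_config(self.templates)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            doc = yaml.safe_load(f)
        if "seed" not in doc:
            raise ValueError("config must set a seed")
        if "conditions" in doc:
            doc["conditions"] = tuple(doc["conditions"])
        return cls(**doc)

    def digest(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    sequential: pd.DataFrame  # per subject × condition × n_sequences
    sequential_mean: pd.DataFrame  # mean over subjects
    active: pd.DataFrame
    two_stage: dict
    two_stage_decisions: pd.DataFrame
    peaks: pd.DataFrame
    counts: pd.DataFrame
    provenance: dict


def _aggregate_subject_peaks(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine single-subject peak tables into mean ± sd across subjects."""
    allp = pd.concat(tables, ignore_index=True)
    grp = allp.groupby(["condition", "is_target", "component", "electrode"])["mean_uV"]
    out = pd.DataFrame(
        {
            "mean_uV": grp.mean(),
            "sd_uV": grp.std(ddof=1),
            "n_subjects": grp.count(),
        }
    ).reset_index()
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate ``n_subjects`` sessions and run the full decoding analysis.

    Deterministic given the config (all randomness flows from ``config.seed``
    through per-subject spawned generators). Per-subject epochs are simulated,
    decoded and reduced one at a time, so memory stays at one session.
    """
    spec = config.spec()
    templates = config.build_templates()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)

    seq_rows, act_rows, peak_tables, count_tables, ts_rows = [], [], [], [], []
    for subj, ss in enumerate(seeds):
        epochs = simulate_session(
            spec,
            templates,
            subject=subj,
            noise_sd=config.noise_sd,
            noise_alpha=config.noise_alpha,
            test_amp_scale=config.test_amp_scale,
            rng=np.random.default_rng(ss),
            dtype=np.float32,
        )
        train = epochs.select(phase="train")
        test = epochs.select(phase="test")

        seq = evaluate_sequential(
            train, test, config.k_intervals, config.width_ms, config.shrinkage
        )
        seq.insert(0, "subject", subj)
        seq_rows.append(seq)

        if {config.passive_condition, config.active_condition} <= set(config.conditions):
            pipe = fit_active_pipeline(
                train,
                config.passive_condition,
                config.active_condition,
                config.k_intervals,
                config.width_ms,
                config.shrinkage,
            )
            act = active_accuracy(pipe, test)
            act.insert(0, "subject", subj)
            act_rows.append(act)

            _, dec = evaluate_two_stage(
                train,
                test,
                config.passive_condition,
                config.active_condition,
                k=config.k_intervals,
                width_ms=config.width_ms,
                shrinkage=config.shrinkage,
            )
            ts_rows.append(dec)

        peak_tables.append(peak_amplitudes(epochs))
        count_tables.append(count_trials(epochs).reset_index())

    sequential = pd.concat(seq_rows, ignore_index=True)
    sequential_mean = (
        sequential.groupby(["condition", "n_sequences"], sort=True)["accuracy"]
        .mean()
        .reset_index()
    )
    active = (
        pd.concat(act_rows, ignore_index=True) if act_rows else pd.DataFrame()
    )
    if ts_rows:
        decisions = pd.concat(ts_rows, ignore_index=True)
        from .decoders import confusion_from_decisions

        class _D:
            def __init__(self, symbol, intention):
                self.symbol, self.intention = symbol, intention

        two_stage = confusion_from_decisions(
            [_D(r.symbol, r.intention) for r in decisions.itertuples()],
            [(r.cue, r.true_intention) for r in decisions.itertuples()],
        )
    else:
        decisions, two_stage = pd.DataFrame(), {}

    counts = (
        pd.concat(count_tables, ignore_index=True)
        .groupby(["condition", "phase"])[["n_target", "n_nontarget"]]
        .sum()
        .reset_index()
    )
    provenance = {
        "package": "erpdecode",
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": asdict(config),
    }
    return ExperimentResult(
        sequential,
        sequential_mean,
        active,
        two_stage,
        decisions,
        _aggregate_subject_peaks(peak_tables),
        counts,
        provenance,
    )


def report(result: ExperimentResult, outdir, plot: bool = False) -> dict:
    """Write CSV/JSON artifacts and a human-readable summary; return the summary.

    Summary means are recomputed from the raw per-subject tables, so the text
    report can always be checked against the CSVs it sits next to.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.sequential.to_csv(outdir / "accuracy_by_sequence.csv", index=False)
    result.sequential_mean.to_csv(outdir / "accuracy_mean.csv", index=False)
    result.peaks.to_csv(outdir / "peak_amplitudes.csv", index=False)
    result.counts.to_csv(outdir / "trial_counts.csv", index=False)
    if len(result.active):
        result.active.to_csv(outdir / "active_accuracy.csv", index=False)
    if len(result.two_stage_decisions):
        result.two_stage_decisions.to_csv(outdir / "two_stage_decisions.csv", index=False)

    summary: dict = {"provenance": result.provenance}
    if len(result.sequential):
        mean = (
            result.sequential.groupby(["condition", "n_sequences"])["accuracy"]
            .mean()
            .unstack("n_sequences")
        )
        summary["sequential_accuracy_pct"] = {
            cond: {str(int(n)): round(100 * v, 2) for n, v in row.items()}
            for cond, row in mean.iterrows()
        }
    if len(result.active):
        ov = result.active[result.active["condition"] == "overall"]
        last = ov[ov["n_sequences"] == ov["n_sequences"].max()]
        summary["active_accuracy_pct"] = round(100 * float(
            np.average(last["accuracy"], weights=last["n_selections"])
        ), 2)
    if result.two_stage:
        summary["two_stage"] = {
            k: (round(float(v), 4) if isinstance(v, float) else int(v))
            for k, v in result.two_stage.items()
        }
    with open(outdir / "summary.json", "w") as f:
        json.dump(summary, f, indent=2)

    lines = [f"erpdecode {__version__}  (config {result.provenance['config_digest']})"]
    for cond, row in summary.get("sequential_accuracy_pct", {}).items():
        ns = sorted(row, key=int)
        lines.append(
            f"  {cond:>14}: " + "  ".join(f"n={n}:{row[n]:5.1f}%" for n in map(str, ns))
        )
    if "active_accuracy_pct" in summary:
        lines.append(f"  active decoder: {summary['active_accuracy_pct']:.1f}%")
    if "two_stage" in summary:
        ts = summary["two_stage"]
        lines.append(
            f"  two-stage: TP={ts['TP']} TN={ts['TN']} FP={ts['FP']} FN={ts['FN']}"
            f"  TPR={ts['TPR']:.3f} FPR={ts['FPR']:.3f}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    if plot and len(result.sequential):  # pragma: no cover - optional figure
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for cond, grp in result.sequential_mean.groupby("condition"):
            ax.plot(grp["n_sequences"], 100 * grp["accuracy"], marker="o", label=cond)
        ax.set_xlabel("sequences averaged (n)")
        ax.set_ylabel("selection accuracy (%)")
        ax.axhline(25, color="gray", ls=":", lw=1)
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "accuracy_vs_sequence.png", dpi=120)
        plt.close(fig)
    return summary
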