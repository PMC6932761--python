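"""End-to-end evaluation: train on the training phase, score the test phase.

Interval selection (the feature layout) is always fit on training-phase data
only and frozen before the test phase is touched, so no test information leaks
into the features. Each condition's pipeline is independent: its own
separability trace, layout and decoder.

A linear decoder commutes with trial averaging (f(mean x) = mean(wᵀx) + b), so
sequential evaluation projects every test trial once and forms cumulative
means of the projections — exactly equivalent to scoring the accumulatively
averaged feature vectors, but one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoders import (
    ACTIVE,
    PASSIVE,
    LinearDecoder,
    confusion_from_decisions,
    score,
    train_rlda,
)
from .epochs import EpochSet
from .features import (
    FeatureLayout,
    extract_features,
    select_intervals,
    separability,
    separability_between,
)


@dataclass
class TrainedTargetPipeline:
    """Frozen feature layout + target/non-target discriminant for one condition."""

    condition: str
    layout: FeatureLayout
    decoder: LinearDecoder


def fit_target_pipeline(
    train: EpochSet,
    condition: str,
    k: int = 8,
    width_ms: float = 50.0,
    shrinkage: float | str = "auto",
    reference_channels=("Cz", "Pz", "Oz"),
) -> TrainedTargetPipeline:
    tr = train.select(condition=condition)
    trace = separability(tr)
    layout = select_intervals(trace, reference_channels, k=k, width_ms=width_ms)
    X = extract_features(tr, layout)
    y = tr.meta["is_target"].to_numpy().astype(int)
    return TrainedTargetPipeline(condition, layout, train_rlda(X, y, shrinkage))


def _selection_projections(
    epochs: EpochSet, layout: FeatureLayout, decoder: LinearDecoder
) -> pd.DataFrame:
    """Per-trial decoder projections with selection bookkeeping columns."""
    X = extract_features(epochs, layout)
    proj = X @ decoder.w  # bias is common to all symbols; irrelevant for argmax
    df = epochs.meta[["subject", "phase", "selection", "sequence", "stimulus", "is_target"]].copy()
    df["proj"] = proj
    return df


def sequential_accuracy(
    pipeline: TrainedTargetPipeline, test: EpochSet
) -> pd.DataFrame:
    """4-class selection accuracy after n = 1..n_sequences accumulated sequences.

    For each test selection, symbol i's accumulated score after n sequences is
    the cumulative mean of its trial projections; the decoded symbol is the
    argmax and is compared with the cued target. Returns one row per
    (n_sequences,) with the fraction of correct selections.
    """
    te = test.select(condition=pipeline.condition)
    df = _selection_projections(te, pipeline.layout, pipeline.decoder)
    n_seq = int(df["sequence"].max()) + 1
    n_sym = int(df["stimulus"].max()) + 1

    correct = np.zeros(n_seq, dtype=int)
    n_sel = 0
    for _, grp in df.groupby(["subject", "phase", "selection"], sort=True):
        cue = int(grp.loc[grp["is_target"], "stimulus"].iloc[0])
        # (n_symbols, n_sequences) projection matrix
        P = np.full((n_sym, n_seq), np.nan)
        P[grp["stimulus"].to_numpy(), grp["sequence"].to_numpy()] = grp["proj"].to_numpy()
        cummean = np.cumsum(P, axis=1) / np.arange(1, n_seq + 1)
        correct += np.argmax(cummean, axis=0) == cue
        n_sel += 1
    return pd.DataFrame(
        {
            "condition": pipeline.condition,
            "n_sequences": np.arange(1, n_seq + 1),
            "accuracy": correct / n_sel,
            "n_selections": n_sel,
        }
    )


def evaluate_sequential(
    train: EpochSet,
    test: EpochSet,
    k: int = 8,
    width_ms: float = 50.0,
    shrinkage: float | str = "auto",
) -> pd.DataFrame:
    """Sequential target-decoding accuracy per condition present in the data."""
    out = []
    for cond in pd.unique(train.meta["condition"]):
        pipe = fit_target_pipeline(train, cond, k, width_ms, shrinkage)
        out.append(sequential_accuracy(pipe, test))
    return pd.concat(out, ignore_index=True)


# ------------------------------------------------------------ active decoder
@dataclass
class TrainedActivePipeline:
    """Passive-vs-active intention discriminant over target-trial features."""

    passive_condition: str
    active_condition: str
    layout: FeatureLayout
    decoder: LinearDecoder  # positive class = passive


def fit_active_pipeline(
    train: EpochSet,
    passive_condition: str = "passive",
    active_condition: str = "pitch_imagery",
    k: int = 8,
    width_ms: float = 50.0,
    shrinkage: float | str = "auto",
    reference_channels=("Cz", "Pz", "Oz"),
) -> TrainedActivePipeline:
    """Train the intention decoder on target trials of the two conditions.

    The passive condition is the positive class, so positive scores read
    "passive" and sgn(f) is the intention decision.
    """
    pa = train.select(condition=passive_condition, is_target=True)
    ac = train.select(condition=active_condition, is_target=True)
    trace = separability_between(pa, ac)
    layout = select_intervals(trace, reference_channels, k=k, width_ms=width_ms)
    X = np.vstack([extract_features(pa, layout), extract_features(ac, layout)])
    y = np.concatenate([np.ones(pa.n_trials, dtype=int), np.zeros(ac.n_trials, dtype=int)])
    return TrainedActivePipeline(
        passive_condition, active_condition, layout, train_rlda(X, y, shrinkage)
    )


def active_accuracy(pipeline: TrainedActivePipeline, test: EpochSet) -> pd.DataFrame:
    """Binary intention accuracy after n = 1..n accumulated target trials.

    Each test selection contributes one averaged target-trial feature vector
    per sequence count n; the decision sgn(f) is compared with the selection's
    true condition. Chance is 50%.
    """
    rows = []
    for cond, truth in (
        (pipeline.passive_condition, PASSIVE),
        (pipeline.active_condition, ACTIVE),
    ):
        te = test.select(condition=cond, is_target=True)
        df = _selection_projections(te, pipeline.layout, pipeline.decoder)
        n_seq = int(df["sequence"].max()) + 1
        correct = np.zeros(n_seq, dtype=int)
        n_sel = 0
        for _, grp in df.groupby(["subject", "phase", "selection"], sort=True):
            grp = grp.sort_values("sequence")
            cm = np.cumsum(grp["proj"].to_numpy()) / np.arange(1, len(grp) + 1)
            f = cm + pipeline.decoder.b
            decision = np.where(f >= 0, PASSIVE, ACTIVE)
            correct[: len(grp)] += decision == truth
            n_sel += 1
        rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "n_sequences": np.arange(1, n_seq + 1),
                    "accuracy": correct / n_sel,
                    "n_selections": n_sel,
                }
            )
        )
    both = pd.concat(rows, ignore_index=True)
    overall = (
        both.groupby("n_sequences")
        .apply(
            lambda g: pd.Series(
                {
                    "condition": "overall",
                    "accuracy": np.average(g["accuracy"], weights=g["n_selections"]),
                    "n_selections": g["n_selections"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return pd.concat([both, overall], ignore_index=True)


# --------------------------------------------------------------- two stage
def evaluate_two_stage(
    train: EpochSet,
    test: EpochSet,
    passive_condition: str = "passive",
    active_condition: str = "pitch_imagery",
    decoder_condition: str | None = None,
    n_sequences: int | None = None,
    k: int = 8,
    width_ms: float = 50.0,
    shrinkage: float | str = "auto",
) -> tuple[dict, pd.DataFrame]:
    """Two-stage decoding of test selections from the passive + active conditions.

    Stage 1 estimates the symbol with the target decoder (trained on
    ``decoder_condition``, default the active condition); stage 2 feeds the
    estimated symbol's averaged feature vector — under the active decoder's own
    layout — to the intention classifier. Returns the confusion summary (TP,
    TN, FP, FN, TPR, FPR) and a per-selection decision table.
    """
    decoder_condition = decoder_condition or active_condition
    tgt_pipe = fit_target_pipeline(train, decoder_condition, k, width_ms, shrinkage)
    act_pipe = fit_active_pipeline(
        train, passive_condition, active_condition, k, width_ms, shrinkage
    )

    records = []
    for cond, truth in ((passive_condition, PASSIVE), (active_condition, ACTIVE)):
        te = test.select(condition=cond)
        Xt = extract_features(te, tgt_pipe.layout)
        Xa = extract_features(te, act_pipe.layout)
        meta = te.meta
        n_sym = int(meta["stimulus"].max()) + 1
        for (subj, _, sel), idx in meta.groupby(["subject", "phase", "selection"]).groups.items():
            idx = np.asarray(idx)
            rows = meta.loc[idx]
            n = n_sequences or int(rows["sequence"].max()) + 1
            m = rows["sequence"].to_numpy() < n
            stim = rows["stimulus"].to_numpy()[m]
            cue = int(rows.loc[rows["is_target"], "stimulus"].iloc[0])
            v_t = np.stack([Xt[idx[m]][stim == i].mean(axis=0) for i in range(n_sym)])
            i_hat = int(np.argmax(score(tgt_pipe.decoder, v_t)))
            v_a = Xa[idx[m]][stim == i_hat].mean(axis=0)
            f_a = score(act_pipe.decoder, v_a)
            records.append(
                {
                    "subject": subj,
                    "selection": sel,
                    "condition": cond,
                    "true_intention": truth,
                    "cue": cue,
                    "symbol": i_hat,
                    "intention": PASSIVE if f_a >= 0 else ACTIVE,
                    "active_score": float(f_a),
                }
            )
    decisions = pd.DataFrame(records)

    class _D:
        def __init__(self, symbol, intention):
            self.symbol, self.intention = symbol, intention

    confusion = confusion_from_decisions(
        [_D(r.symbol, r.intention) for r in decisions.itertuples()],
        [(r.cue, r.true_intention) for r in decisions.itertuples()],
    )
    return confusion, decisions
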