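"""Linear decoders for sequential ERP classification.

The binary discriminant is shrinkage-regularized LDA: with pooled within-class
covariance Σ and shrinkage intensity λ ∈ [0, 1],

    Σ̃ = (1 − λ) Σ + λ (tr Σ / D) I,      w ∝ Σ̃⁻¹ (μ₁ − μ₂),
    f(x) = wᵀx + b,   b chosen so f = 0 at the midpoint of the projected means.

λ = "auto" uses the analytic Ledoit–Wolf estimate of the optimal intensity.
Target selection accumulates feature vectors over stimulus repetitions
(sequences): after n sequences the per-symbol running mean v_i is scored and
the symbol with the largest f(v_i) is chosen (chance 1/4). The active decoder
is the same discriminant trained on target-trial features of a passive versus
an imagery condition; its score sign is the intention decision (chance 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.covariance import LedoitWolf

logger = logging.getLogger(__name__)

#: Intention labels: active (intended command) vs passive (idle gazing).
ACTIVE, PASSIVE = -1, 1


@dataclass
class LinearDecoder:
    """Trained binary linear discriminant."""

    w: np.ndarray
    b: float
    shrinkage: float
    class_means: np.ndarray = field(repr=False)  # (2, D): negative, positive class
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    @property
    def dim(self) -> int:
        return self.w.shape[0]

    def to_yaml(self, path) -> None:
        doc = {
            "w": [float(v) for v in self.w],
            "b": float(self.b),
            "shrinkage": float(self.shrinkage),
            "classes": [int(c) for c in self.classes],
            "class_means": [[float(v) for v in row] for row in self.class_means],
        }
        with open(path, "w") as f:
            yaml.safe_dump(doc, f)

    @classmethod
    def from_yaml(cls, path) -> "LinearDecoder":
        with open(path) as f:
            doc = yaml.safe_load(f)
        return cls(
            np.asarray(doc["w"], dtype=float),
            float(doc["b"]),
            float(doc["shrinkage"]),
            np.asarray(doc["class_means"], dtype=float),
            np.asarray(doc["classes"]),
        )


def train_rlda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | str = "auto"
) -> LinearDecoder:
    """Fit the shrinkage-LDA discriminant.

    The positive class is the larger of the two label values (so target=1 /
    non-target=0 scores positive for targets). Swapping the labels negates
    both w and b.

    Raises
    ------
    np.linalg.LinAlgError
        If λ=0 and the pooled covariance is singular (message suggests
        regularizing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    neg, pos = classes[0], classes[1]
    mu_pos = X[y == pos].mean(axis=0)
    mu_neg = X[y == neg].mean(axis=0)
    d = X.shape[1]

    centered = X.copy()
    centered[y == pos] -= mu_pos
    centered[y == neg] -= mu_neg

    if shrinkage == "auto":
        lw = LedoitWolf(assume_centered=True).fit(centered)
        lam = float(lw.shrinkage_)
        sigma_t = lw.covariance_
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        sigma = centered.T @ centered / centered.shape[0]
        sigma_t = (1.0 - lam) * sigma + lam * (np.trace(sigma) / d) * np.eye(d)

    diff = mu_pos - mu_neg
    try:
        w = np.linalg.solve(sigma_t, diff)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase shrinkage "
            "(use shrinkage='auto' or λ > 0)"
        ) from err
    b = -float(w @ (mu_pos + mu_neg) / 2.0)
    return LinearDecoder(w, b, lam, np.stack([mu_neg, mu_pos]), classes)


def score(decoder: LinearDecoder, x: np.ndarray) -> np.ndarray | float:
    """Classifier output f(x) = wᵀx + b for one vector or a stack of vectors."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != decoder.dim:
        raise ValueError(f"feature dimension {x.shape[-1]} != decoder dim {decoder.dim}")
    out = x @ decoder.w + decoder.b
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------- sequential averaging
class SequenceState:
    """Running accumulative average of per-symbol feature vectors.

    After updating with sequences 1..n, ``means()[i]`` is exactly the mean of
    symbol i's feature vectors over those sequences.
    """

    def __init__(self, n_classes: int, dim: int):
        self.sums = np.zeros((n_classes, dim))
        self.counts = np.zeros(n_classes, dtype=int)

    def update(self, class_index: int, x: np.ndarray) -> None:
        self.sums[class_index] += x
        self.counts[class_index] += 1

    @property
    def n_sequences(self) -> int:
        n = int(self.counts[0])
        if not np.all(self.counts == n):
            raise ValueError("unequal sequence counts across classes")
        return n

    def means(self) -> np.ndarray:
        n = self.n_sequences
        if n < 1:
            raise ValueError("no sequences accumulated")
        return self.sums / n


def target_decode(v: np.ndarray | SequenceState, decoder: LinearDecoder) -> int:
    """Symbol estimate î = argmax_i f(v_i); ties go to the lowest index."""
    V = v.means() if isinstance(v, SequenceState) else np.asarray(v, dtype=float)
    scores = score(decoder, V)
    top = np.flatnonzero(scores == scores.max())
    if len(top) > 1:
        logger.warning("target_decode tie between classes %s; taking lowest", top)
    return int(top[0])


def active_decode(v: np.ndarray, decoder: LinearDecoder) -> int:
    """Intention decision y = sgn(f_A(v)) with sgn(0) → passive (+1).

    The active decoder must be trained with the passive condition as its
    positive class, so a positive score reads "passive"; zero maps to passive
    as the fail-safe (no command is issued).
    """
    s = score(decoder, v)
    return PASSIVE if s >= 0 else ACTIVE


@dataclass(frozen=True)
class TwoStageDecision:
    """Outcome of the two-stage classifier for one selection."""

    symbol: int
    intention: int  # ACTIVE (-1) or PASSIVE (+1)
    target_scores: np.ndarray
    active_score: float


def two_stage(
    V: np.ndarray, target_decoder: LinearDecoder, active_decoder: LinearDecoder
) -> TwoStageDecision:
    """Stage 1: pick the symbol; stage 2: gate it by the intention decision.

    ``V`` is the (n_symbols, D) stack of accumulatively averaged features; the
    active decoder sees only the feature vector of the estimated symbol.
    """
    i_hat = target_decode(V, target_decoder)
    f_t = score(target_decoder, V)
    f_a = score(active_decoder, V[i_hat])
    y = PASSIVE if f_a >= 0 else ACTIVE
    return TwoStageDecision(i_hat, y, np.asarray(f_t), float(f_a))


def confusion_from_decisions(decisions, truths) -> dict[str, float]:
    """Two-stage bookkeeping over labeled selections.

    ``truths`` holds (cued_symbol, true_intention) per selection. An
    active-state selection is a true positive only when both the symbol and the
    active state are decoded correctly, otherwise a false positive; a passive
    selection is a true negative when decoded passive (the symbol is not
    considered), otherwise a false negative. Hence TP+FP = #active and
    TN+FN = #passive; TPR = TP/#active and FPR = FN/#passive.
    """
    tp = tn = fp = fn = 0
    for dec, (cue, intention) in zip(decisions, truths):
        if intention == ACTIVE:
            if dec.intention == ACTIVE and dec.symbol == cue:
                tp += 1
            else:
                fp += 1
        else:
            if dec.intention == PASSIVE:
                tn += 1
            else:
                fn += 1
    n_active, n_passive = tp + fp, tn + fn
    return {
        "TP": tp,
        "TN": tn,
        "FP": fp,
        "FN": fn,
        "TPR": tp / n_active if n_active else float("nan"),
        "FPR": fn / n_passive if n_passive else float("nan"),
    }
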