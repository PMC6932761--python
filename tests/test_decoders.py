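import numpy as np
import pytest

from erpdecode import (
    ACTIVE,
    PASSIVE,
    LinearDecoder,
    SequenceState,
    active_decode,
    confusion_from_decisions,
    score,
    target_decode,
    train_rlda,
    two_stage,
)


def _gaussian_problem(rng, n=200, d=4, sep=3.0):
    cov = rng.normal(size=(d, d))
    cov = cov @ cov.T + d * np.eye(d)
    mu1 = rng.normal(size=d)
    mu2 = mu1 + sep * rng.normal(size=d) / np.sqrt(d)
    X = np.vstack(
        [
            rng.multivariate_normal(mu1, cov, size=n),
            rng.multivariate_normal(mu2, cov, size=n),
        ]
    )
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    return X, y


def test_rlda_matches_closed_form_at_zero_shrinkage(rng):
    X, y = _gaussian_problem(rng)
    dec = train_rlda(X, y, shrinkage=0.0)
    mu1 = X[y == 1].mean(axis=0)
    mu2 = X[y == 0].mean(axis=0)
    centered = X.copy()
    centered[y == 1] -= mu1
    centered[y == 0] -= mu2
    sigma = centered.T @ centered / len(X)
    w_ref = np.linalg.inv(sigma) @ (mu1 - mu2)
    cos = w_ref @ dec.w / (np.linalg.norm(w_ref) * np.linalg.norm(dec.w))
    assert cos > 0.999999
    assert np.max(np.abs(dec.w - w_ref)) / np.max(np.abs(w_ref)) < 1e-8


def test_rlda_full_shrinkage_is_mean_difference(rng):
    X, y = _gaussian_problem(rng)
    dec = train_rlda(X, y, shrinkage=1.0)
    diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
    cos = diff @ dec.w / (np.linalg.norm(diff) * np.linalg.norm(dec.w))
    assert cos == pytest.approx(1.0, abs=1e-12)


def test_rlda_label_swap_antisymmetry(rng):
    X, y = _gaussian_problem(rng)
    d1 = train_rlda(X, y, shrinkage=0.3)
    d2 = train_rlda(X, 1 - y, shrinkage=0.3)
    assert np.allclose(d1.w, -d2.w, atol=1e-10)
    assert d1.b == pytest.approx(-d2.b, abs=1e-10)


def test_rlda_auto_shrinkage_in_range(rng):
    X, y = _gaussian_problem(rng, n=30, d=20)
    dec = train_rlda(X, y, shrinkage="auto")
    assert 0.0 < dec.shrinkage <= 1.0
    assert np.all(np.isfinite(dec.w))


def test_rlda_singular_covariance_raises():
    X = np.zeros((10, 3))
    X[:5, 0] = 1.0
    y = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)]
    with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
        train_rlda(X, y, shrinkage=0.0)
    with pytest.raises(ValueError):
        train_rlda(X, np.zeros(10, dtype=int))  # one class only


def test_score_properties(rng):
    X, y = _gaussian_problem(rng)
    dec = train_rlda(X, y, shrinkage=0.2)
    mu1 = X[y == 1].mean(axis=0)
    mu2 = X[y == 0].mean(axis=0)
    assert score(dec, (mu1 + mu2) / 2) == pytest.approx(0.0, abs=1e-9)
    assert score(dec, mu1) > 0 > score(dec, mu2)  # training means separate
    x = rng.normal(size=dec.dim)
    a = 2.5
    assert score(dec, a * x) - dec.b == pytest.approx(a * (score(dec, x) - dec.b))
    with pytest.raises(ValueError):
        score(dec, np.zeros(dec.dim + 1))


def test_decoder_yaml_round_trip(tmp_path, rng):
    X, y = _gaussian_problem(rng)
    dec = train_rlda(X, y)
    path = tmp_path / "decoder.yaml"
    dec.to_yaml(path)
    back = LinearDecoder.from_yaml(path)
    assert np.allclose(back.w, dec.w)
    assert back.b == pytest.approx(dec.b)
    assert back.shrinkage == pytest.approx(dec.shrinkage)


def test_sequence_state_exact_means(rng):
    state = SequenceState(4, 3)
    xs = rng.normal(size=(4, 5, 3))
    for j in range(5):
        for i in range(4):
            state.update(i, xs[i, j])
    assert state.n_sequences == 5
    assert np.allclose(state.means(), xs.mean(axis=1), atol=1e-12)
    state.update(0, np.zeros(3))
    with pytest.raises(ValueError):
        state.means()  # unequal counts across classes


def test_target_decode_picks_constructed_class():
    w = np.array([1.0, 0.0])
    dec = LinearDecoder(w, 0.0, 0.0, np.zeros((2, 2)))
    V = np.array([[0.1, 0], [0.2, 0], [0.0, 0], [0.9, 0]])
    assert target_decode(V, dec) == 3
    # tie -> lowest index
    V_tie = np.array([[0.5, 0], [0.5, 0], [0.1, 0], [0.1, 0]])
    assert target_decode(V_tie, dec) == 0


def test_target_decode_common_shift_invariance(rng):
    w = rng.normal(size=6)
    dec = LinearDecoder(w, rng.normal(), 0.0, np.zeros((2, 6)))
    V = rng.normal(size=(4, 6))
    shift = rng.normal(size=6)
    assert target_decode(V, dec) == target_decode(V + shift, dec)


def test_active_decode_sign_convention():
    dec = LinearDecoder(np.array([1.0]), 0.0, 0.0, np.zeros((2, 1)))
    assert active_decode(np.array([2.0]), dec) == PASSIVE
    assert active_decode(np.array([-2.0]), dec) == ACTIVE
    assert active_decode(np.array([0.0]), dec) == PASSIVE  # sgn(0) fails safe
    flipped = LinearDecoder(-dec.w, -dec.b, 0.0, np.zeros((2, 1)))
    assert active_decode(np.array([2.0]), flipped) == ACTIVE


def test_two_stage_decision_and_bookkeeping():
    w = np.array([1.0, 0.0])
    target_dec = LinearDecoder(w, 0.0, 0.0, np.zeros((2, 2)))
    # active decoder keys on the second feature; positive = passive
    active_dec = LinearDecoder(np.array([0.0, 1.0]), 0.0, 0.0, np.zeros((2, 2)))

    V_active = np.array([[0.0, 0], [0.0, 0], [2.0, -1.0], [0.1, 0]])
    d1 = two_stage(V_active, target_dec, active_dec)
    assert d1.symbol == 2 and d1.intention == ACTIVE

    V_passive = np.array([[0.0, 1.0], [0.0, 0], [0.5, 1.0], [0.1, 0]])
    d2 = two_stage(V_passive, target_dec, active_dec)
    assert d2.intention == PASSIVE

    conf = confusion_from_decisions(
        [d1, d2, d1, d2],
        [(2, ACTIVE), (0, PASSIVE), (1, ACTIVE), (3, ACTIVE)],
    )
    # d1 on cue 2: TP; d2 passive on passive truth: TN; d1 on cue 1: wrong
    # symbol -> FP; d2 passive decision on active truth: FP
    assert conf["TP"] == 1 and conf["TN"] == 1 and conf["FP"] == 2 and conf["FN"] == 0
    assert conf["TP"] + conf["FP"] == 3  # all active-state selections
    assert conf["TN"] + conf["FN"] == 1
    assert conf["TPR"] == pytest.approx(1 / 3)
    assert conf["FPR"] == pytest.approx(0.0)
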