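import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpdecode import (
    EpochSet,
    FeatureLayout,
    default_templates,
    extract_features,
    peak_amplitudes,
    select_intervals,
    separability,
    signed_r_squared,
    sliding_window_trace,
    synthesize_epochs,
)
from erpdecode.channels import CHANNELS
from erpdecode.features import SeparabilityTrace
from erpdecode.paradigm import ParadigmSpec


def test_signed_r_squared_worked_example():
    """Two two-trial classes at a single point: hand-computed value +0.375."""
    x1 = np.array([[2.0], [4.0]])
    x2 = np.array([[0.0], [2.0]])
    # r = sqrt(2*2)/(2+2) * (3 - 1)/sd([2,4,0,2], ddof=1) = 0.6124; sign(r)*r^2
    assert signed_r_squared(x1, x2)[0] == pytest.approx(0.375, abs=1e-12)


def test_signed_r_squared_symmetries(rng):
    x1 = rng.normal(1.0, 1.0, size=(10, 4, 6))
    x2 = rng.normal(0.0, 1.0, size=(14, 4, 6))
    v = signed_r_squared(x1, x2)
    assert v.shape == (4, 6)
    assert np.all(np.abs(v) <= 1.0)
    assert np.allclose(signed_r_squared(x2, x1), -v)  # label-swap antisymmetry
    # identical class means -> 0
    same = signed_r_squared(x1, x1)
    assert np.allclose(same, 0.0, atol=1e-12)


def test_signed_r_squared_degenerate_points():
    x1 = np.ones((3, 2))
    x2 = np.ones((3, 2))
    assert np.allclose(signed_r_squared(x1, x2), 0.0)
    with pytest.raises(ValueError):
        signed_r_squared(np.ones((1, 2)), np.ones((3, 2)))


@settings(derandomize=True, max_examples=25)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.01, 100, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_signed_r_squared_affine_invariance(shift, scale, seed):
    """Adding a constant or positively rescaling all trials leaves r² unchanged."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0.5, 1.0, size=(8, 5))
    x2 = rng.normal(0.0, 1.2, size=(12, 5))
    base = signed_r_squared(x1, x2)
    assert np.allclose(signed_r_squared(x1 + shift, x2 + shift), base, atol=1e-9)
    assert np.allclose(signed_r_squared(x1 * scale, x2 * scale), base, atol=1e-9)


# ------------------------------------------------------------------ layout
def _toy_epochs(data, times=None):
    import pandas as pd

    n, n_ch, n_t = data.shape
    if times is None:
        times = np.arange(-200.0, 800.0, 10.0)[:n_t]
    meta = pd.DataFrame(
        {
            "subject": 0,
            "condition": "passive",
            "phase": "train",
            "selection": 0,
            "sequence": np.arange(n),
            "stimulus": 0,
            "is_target": [True, False] * (n // 2) + [True] * (n % 2),
            "onset_ms": 0.0,
        }
    )
    return EpochSet(data, times, 100.0, meta, CHANNELS[:n_ch])


def test_extract_features_matches_naive_loop(rng):
    data = rng.normal(size=(7, 32, 100))
    ep = _toy_epochs(data)
    layout = FeatureLayout([(0.0, 50.0), (100.0, 150.0), (500.0, 600.0)], CHANNELS)
    X = extract_features(ep, layout)
    assert X.shape == (7, 96)
    t = ep.times
    for trial in range(7):
        for c in range(32):
            for j, (a, b) in enumerate(layout.intervals):
                m = (t >= a) & (t < b)
                expected = data[trial, c, m].mean()
                assert X[trial, c * 3 + j] == pytest.approx(expected, rel=1e-12)


def test_extract_features_constant_and_dimension():
    ep = _toy_epochs(np.ones((3, 32, 100)))
    layout = FeatureLayout([(i * 100.0, i * 100.0 + 50.0) for i in range(8)], CHANNELS)
    X = extract_features(ep, layout)
    assert layout.dim == 256  # 32 channels x 8 intervals
    assert np.allclose(X, 1.0)


def test_layout_validation_and_yaml_round_trip(tmp_path):
    with pytest.raises(ValueError):
        FeatureLayout([(0.0, 50.0), (25.0, 75.0)], CHANNELS)  # overlap
    with pytest.raises(ValueError):
        FeatureLayout([(50.0, 50.0)], CHANNELS)
    layout = FeatureLayout([(100.0, 150.0), (0.0, 50.0)], CHANNELS)
    assert layout.intervals[0] == (0.0, 50.0)  # sorted by onset
    path = tmp_path / "layout.yaml"
    layout.to_yaml(path)
    back = FeatureLayout.from_yaml(path)
    assert back.intervals == layout.intervals
    assert back.channels == layout.channels


def _bump_trace(centers, times, width=50.0):
    vals = np.zeros((32, len(times)))
    for c in centers:
        m = (times >= c - width / 2) & (times < c + width / 2)
        for ch in ("Cz", "Pz", "Oz"):
            vals[CHANNELS.index(ch), m] = 0.5
    return SeparabilityTrace(vals, CHANNELS, times, 10, 30)


def test_select_intervals_recovers_bumps():
    times = np.arange(-200.0, 800.0, 10.0)
    centers = [50.0, 150.0, 250.0, 350.0, 450.0, 550.0, 650.0, 750.0]
    trace = _bump_trace(centers[:-1] + [740.0], times)
    layout = select_intervals(trace, k=8, width_ms=50.0)
    assert len(layout.intervals) == 8
    for c in centers[:-1]:
        assert any(a <= c < b for a, b in layout.intervals)


def test_select_intervals_flat_trace_deterministic():
    times = np.arange(-200.0, 800.0, 10.0)
    trace = SeparabilityTrace(np.zeros((32, 100)), CHANNELS, times, 5, 5)
    layout = select_intervals(trace, k=4, width_ms=50.0)
    # tie-break: earliest post-stimulus windows, deterministically
    assert layout.intervals == [(0.0, 50.0), (50.0, 100.0), (100.0, 150.0), (150.0, 200.0)]


def test_select_intervals_single_bump():
    times = np.arange(-200.0, 800.0, 10.0)
    trace = _bump_trace([300.0], times)
    layout = select_intervals(trace, k=1, width_ms=50.0)
    (a, b), = layout.intervals
    assert a <= 300.0 < b


def test_selection_permutation_invariance(rng, small_spec, templates):
    ep = synthesize_epochs(
        small_spec, templates, condition="counting", noise_sd=6.0, rng=rng
    )
    trace = separability(ep)
    perm = rng.permutation(ep.n_trials)
    shuffled = EpochSet(
        ep.data[perm], ep.times, ep.sfreq, ep.meta.iloc[perm], ep.channels
    )
    trace2 = separability(shuffled)
    assert np.allclose(trace.values, trace2.values, atol=1e-10)
    l1 = select_intervals(trace)
    l2 = select_intervals(trace2)
    assert l1.intervals == l2.intervals


# ------------------------------------------------------------------- peaks
def test_peak_amplitudes_deterministic_trial(small_spec, templates):
    ep = synthesize_epochs(
        small_spec, templates, condition="pitch_imagery", noise_sd=0.0, rng=0
    )
    table = peak_amplitudes(ep)
    row = table[
        (table.condition == "pitch_imagery")
        & table.is_target
        & (table.component == "N500")
        & (table.electrode == "Cz")
    ]
    assert row["mean_uV"].iloc[0] == pytest.approx(-2.883, abs=1e-9)
    n200 = table[
        (table.condition == "pitch_imagery")
        & table.is_target
        & (table.component == "N200")
        & (table.electrode == "Oz")
    ]
    assert n200["mean_uV"].iloc[0] == pytest.approx(-2.351, abs=1e-9)


def test_peak_amplitudes_zero_signal(small_spec):
    from erpdecode import null_templates

    ep = synthesize_epochs(
        small_spec, null_templates(), condition="passive", noise_sd=0.0, rng=0
    )
    table = peak_amplitudes(ep)
    assert np.allclose(table["mean_uV"], 0.0)


# --------------------------------------------------------- sliding window
def test_sliding_window_localizes_discriminative_interval(rng):
    """Class difference only in 500-600 ms: accuracy peaks there, chance elsewhere."""
    import pandas as pd

    n = 300
    times = np.arange(-200.0, 800.0, 10.0)
    data = rng.normal(0, 1.0, size=(2 * n, 32, 100))
    m = (times >= 500) & (times < 600)
    data[:n, :, m] += 1.5  # targets carry the late component
    meta = pd.DataFrame(
        {
            "subject": 0,
            "condition": "passive",
            "phase": "train",
            "selection": np.arange(2 * n) // 4,
            "sequence": 0,
            "stimulus": 0,
            "is_target": [True] * n + [False] * n,
            "onset_ms": 0.0,
        }
    )
    ep = EpochSet(data, times, 100.0, meta, CHANNELS)
    half = np.r_[0:n:2, n : 2 * n : 2]
    other = np.setdiff1d(np.arange(2 * n), half)
    trace = sliding_window_trace(
        ep.select(np.isin(np.arange(2 * n), half)),
        ep.select(np.isin(np.arange(2 * n), other)),
        shrinkage=0.5,
    )
    best = trace.loc[trace["accuracy"].idxmax(), "center_ms"]
    assert 450.0 <= best <= 650.0
    early = trace[trace["center_ms"] < 400.0]["accuracy"]
    assert early.max() < 0.65  # chance-ish away from the signal
    assert trace["accuracy"].max() > 0.9
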