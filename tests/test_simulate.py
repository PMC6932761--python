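import numpy as np
import pytest

from erpdecode import (
    ParadigmSpec,
    count_trials,
    default_templates,
    draw_subject_effects,
    null_templates,
    preprocess_chain,
    sample_schedule,
    simulate_session,
    synthesize_continuous,
    synthesize_epochs,
)
from erpdecode.epochs import EpochSet


def test_determinism_bit_identical(small_spec, templates):
    a = synthesize_epochs(small_spec, templates, condition="counting", noise_sd=8.0, rng=42)
    b = synthesize_epochs(small_spec, templates, condition="counting", noise_sd=8.0, rng=42)
    assert np.array_equal(a.data, b.data)
    assert a.meta.equals(b.meta)
    c = synthesize_epochs(small_spec, templates, condition="counting", noise_sd=8.0, rng=43)
    assert not np.array_equal(a.data, c.data)


def test_noiseless_trace_matches_calibration(spec, templates):
    """Deterministic single trials attain the configured peak amplitudes."""
    ep = synthesize_epochs(spec, templates, condition="pitch_imagery", noise_sd=0.0, rng=0)
    cz = ep.channel_index("Cz")
    t = ep.times
    n500 = (t >= 500) & (t < 600)
    tgt = ep.select(is_target=True)
    assert tgt.data[0, cz, n500].min() == pytest.approx(-2.883, abs=1e-12)

    pa = synthesize_epochs(spec, templates, condition="passive", noise_sd=0.0, rng=0)
    nt = pa.select(is_target=False)
    assert nt.data[0, cz, n500].min() == pytest.approx(-0.663, abs=1e-12)
    # all trials of one class are identical without noise
    assert np.allclose(tgt.data, tgt.data[0])


def test_pure_noise_statistics(small_spec):
    ep = synthesize_epochs(small_spec, null_templates(), condition="passive", noise_sd=1.0, rng=1)
    # baseline correction recenters each trial x channel, slightly shrinking sd
    assert abs(ep.data.mean()) < 0.01
    assert ep.data.std() == pytest.approx(1.0, abs=0.05)
    silent = synthesize_epochs(small_spec, [], condition="passive", noise_sd=0.0, rng=1)
    assert np.allclose(silent.data, 0.0)


def test_one_over_f_noise_spectrum(small_spec):
    ep = synthesize_epochs(
        small_spec, [], condition="passive", noise_sd=1.0, noise_alpha=1.0, rng=3
    )
    # baseline correction inflates correlated noise away from the baseline span
    assert 0.8 < ep.data.std() < 1.3
    spec_f = np.abs(np.fft.rfft(ep.data, axis=-1)) ** 2
    mean_psd = spec_f.mean(axis=(0, 1))
    freqs = np.fft.rfftfreq(ep.data.shape[-1], d=0.01)
    slope = np.polyfit(np.log(freqs[2:30]), np.log(mean_psd[2:30]), 1)[0]
    assert -1.6 < slope < -0.5  # ~1/f power


def test_trial_accounting(spec, templates):
    ep = synthesize_epochs(spec, templates, condition="counting", phase="train", noise_sd=0.0, rng=0)
    counts = count_trials(ep)
    assert tuple(counts.loc[("counting", "train")]) == (200, 600)

    both = simulate_session(
        spec, null_templates(), conditions=("passive",), noise_sd=0.0, rng=0
    )
    counts2 = count_trials(both)
    assert counts2["n_target"].sum() == 400
    assert counts2["n_nontarget"].sum() == 1200

    empty = ep.select(condition="nonexistent")
    assert len(count_trials(empty)) == 0


def test_target_flags_consistent_with_schedule(small_spec, templates, rng):
    ep = synthesize_epochs(small_spec, templates, condition="passive", noise_sd=1.0, rng=rng)
    per_seq = ep.meta.groupby(["selection", "sequence"])["is_target"].sum()
    assert (per_seq == 1).all()


def test_subject_effects_shift_amplitude(spec, templates):
    effects = {k: 0.0 for tpl in templates for k in (
        (tpl.name, "pitch_imagery", True), (tpl.name, "pitch_imagery", False))}
    effects[("N500", "pitch_imagery", True)] = -1.0
    ep = synthesize_epochs(
        spec, templates, condition="pitch_imagery", noise_sd=0.0,
        subject_effects=effects, rng=0,
    )
    cz = ep.channel_index("Cz")
    t = ep.times
    tgt = ep.select(is_target=True)
    assert tgt.data[0, cz, (t >= 500) & (t < 600)].min() == pytest.approx(-3.883, abs=1e-12)


def test_draw_subject_effects_scales_with_sd(templates):
    eff = draw_subject_effects(templates, rng=0)
    assert len(eff) == 3 * 3 * 2  # components x conditions x classes
    zero = draw_subject_effects(null_templates(), rng=0)
    assert all(v == 0.0 for v in zero.values())


def test_amp_scale_session_drift(spec, templates):
    ep = synthesize_epochs(
        spec, templates, condition="counting", noise_sd=0.0, amp_scale=0.5, rng=0
    )
    full = synthesize_epochs(spec, templates, condition="counting", noise_sd=0.0, rng=0)
    assert np.allclose(ep.data, 0.5 * full.data, atol=1e-12)


def test_epochset_h5_round_trip(tmp_path, small_spec, templates):
    ep = synthesize_epochs(small_spec, templates, condition="passive", noise_sd=2.0, rng=5)
    path = tmp_path / "epochs.h5"
    ep.save(path)
    back = EpochSet.load(path)
    assert np.allclose(back.data, ep.data)
    assert back.channels == ep.channels
    assert (back.meta["condition"] == "passive").all()
    assert back.meta["is_target"].astype(bool).equals(ep.meta["is_target"].astype(bool))


def test_raw_rate_chain_recovers_components(templates):
    """1000 Hz continuous mode -> filter/downsample/epoch recovers the N500."""
    # wide ISI so neighbouring flashes' slow components do not overlap epochs
    spec = ParadigmSpec(n_selections_per_phase=1, n_sequences=2, isi=1930.0)
    sched = sample_schedule(spec, [1], rng=0)
    sig, onsets = synthesize_continuous(
        spec, templates, condition="pitch_imagery", schedule=sched, noise_sd=0.0
    )
    import pandas as pd

    meta = pd.DataFrame(
        {
            "subject": 0,
            "condition": "pitch_imagery",
            "phase": "train",
            "selection": sched.events["selection"],
            "sequence": sched.events["sequence"],
            "stimulus": sched.events["stimulus"],
            "is_target": sched.events["is_target"],
            "onset_ms": onsets,
        }
    )
    ep = preprocess_chain(sig, 1000.0, onsets, meta)
    cz = ep.channel_index("Cz")
    t = ep.times
    tgt = ep.select(is_target=True)
    peak = tgt.data[:, cz, (t >= 500) & (t < 600)].min(axis=1)
    # band-pass ripple and 100 ms component width cost a few percent
    assert np.all(np.abs(peak - (-2.883)) < 0.3)
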