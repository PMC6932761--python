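# Methods

## The paradigm and its generative model

The simulated experiment is a 4-symbol visual oddball speller. One *selection*
cues one symbol; all four symbols then flash once per *sequence* in random
order for 10 sequences (70 ms flash + 150 ms inter-stimulus interval, so
onsets are spaced 220 ms). No symbol flashes twice in a row, including across
sequence boundaries within a selection; schedules are drawn by resampling each
sequence's permutation until its first flash differs from the previous
sequence's last (acceptance probability 1 − 1/n_symbols, so rejection is
cheap and the conditional distribution over legal schedules is uniform
per-sequence). A phase (training or test) holds 20 selections, hence 200
target and 600 non-target flashes per condition and phase, 400/1200 over both
phases.

Each flash yields one epoch: 32 channels × 100 samples on the 100 Hz grid
[−200, 800) ms relative to onset (half-open windows everywhere, which fixes
the sample-count ambiguity at exactly 100). A trial is

    x(c, t) = Σ_k a_k · p_k(c) · b_k(t) + ε(c, t)

with one term per ERP component k ∈ {N200, P300, N500}:

- `b_k(t)` is a raised-cosine bump supported on the component's literature
  window (N200 180–230 ms, P300 290–390 ms, N500 500–600 ms), peak at the
  window centre. The peak latency is snapped to the nearest sample of the
  output grid so that the configured amplitude is attained exactly by a
  sample; without the snap, off-grid peaks (N200's 205 ms at 100 Hz) would be
  systematically under-recovered by ~9.5% and calibration recovery could not
  close.
- `p_k(c)` is a Gaussian scalp profile on a schematic 10–20 layout
  (decay scale 0.4 head radii), equal to 1 at the component's reference
  electrode and clipped to [0, 1]: N200 is anchored at Oz, P300 midway
  between Cz and Pz (value 1 at both after normalisation), N500 at Cz.
- `a_k` is the calibrated mean peak amplitude (µV) for the trial's
  (condition, target/non-target) cell at the reference electrode, plus a
  per-subject offset drawn once per (component, condition, class) from the
  calibrated across-subject sd. The calibration table covers all 18 cells
  (3 components × 3 conditions × target/non-target); e.g. the N500 target
  amplitude at Cz is −1.094 (passive), −2.226 (counting), −2.883 µV
  (pitch imagery) with sds 0.88/0.97/1.36 µV. The effort-graded N500 is what
  separates the conditions; N200/P300 mainly separate target from non-target.
- `ε` is zero-mean Gaussian noise, white by default, optionally 1/f^α-shaped
  along time (α = 1 if enabled; spectrally normalised so the sample sd equals
  the requested value before baseline correction).

Epochs are baseline-corrected by subtracting the per-channel mean over
[−100, 0) ms, as the decoding contract assumes. With zero noise the generator
is exactly the deterministic template sum, which pins the calibration: a
noiseless pitch-imagery target trial has Cz minimum −2.883 µV in 500–600 ms.

**Default noise sd = 12 µV.** Band-limited (0.5–30 Hz) spontaneous EEG has a
single-trial RMS of order 10–15 µV against component amplitudes of 1–3 µV;
12 µV puts single-trial separability in the weak regime that makes sequence
averaging necessary, which is the phenomenon of interest. Simulated
accuracies at this level (e.g. ~40/60/60% at n = 4 for the three conditions)
sit between chance and ceiling.

What the generator deliberately does **not** model: overlap of slow
components from neighbouring flashes into the current epoch (trials are
generated independently; in recorded data the 220 ms SOA folds the previous
flash's P300/N500 into the baseline and early window), spatially correlated
noise and volume conduction, blink/EMG artifacts, latency jitter, and
non-stationarities other than an optional multiplicative per-phase amplitude
factor (default 1.0 = off; it emulates the N500 attenuation seen across
sessions). Passing tests therefore demonstrate correctness of the pipeline's
statistics and bookkeeping under the stated model, not performance on real
EEG. Because channels are independent and white, desk-scale accuracies are
not comparable with recorded-data accuracies; in particular the
counting-vs-pitch-imagery contrast is structurally smaller here than in real
recordings, where spatial noise correlations favour the focal N500.

## Preprocessing chain (1000 Hz mode)

The generator normally emits directly on the post-preprocessing grid. The
optional continuous mode produces a raw 1000 Hz multichannel trace, processed
as: 60 Hz notch and 0.5–30 Hz 5th-order Butterworth band-pass at the native
rate, applied forward–backward (zero phase, so component latencies are
preserved for interval selection; the effective magnitude response is the
square of the single-pass response, which is what the test oracle evaluates),
then polyphase anti-aliased decimation to 100 Hz, then epoching and baseline
correction. The notch only exists in this mode — 60 Hz is above the 100 Hz
grid's Nyquist band of interest.

## Feature construction

Pointwise separability of target vs non-target trials is the signed r²
statistic; the pooled sd `s_i` is the sd of *all* trials of both classes at
that point (ddof = 1), which keeps |r| ≤ 1 (point-biserial form). Points with
zero pooled sd are set to 0 and logged. Eight non-overlapping 50 ms windows
are chosen greedily by mean |signed r²| over the Cz/Pz/Oz reference channels,
ties broken toward the earliest onset, candidates restricted to post-stimulus
time; the layout is fit on training-phase data only and frozen for the test
phase (no leakage). Features are per-channel interval means concatenated
channel-major; the order is arbitrary for a linear decoder but fixed and
stable across save/load (layouts serialise to YAML).

Peak-amplitude extraction mirrors group ERP reporting: per subject, the
signed extremum (min for negative, max for positive components) of the
subject-average ERP inside the component window; then mean ± sd across
subjects. Note the estimator has an *outward noise bias* — the extremum of
signal-plus-noise over window samples exceeds the signal peak by an
extreme-value term of order the per-sample noise sd of the subject average.
The calibration-recovery validation therefore runs at 1 µV noise with ~200
target trials per subject, where the bias is well inside the 3-SE band; at
realistic noise it would need ~10⁴ trials per subject to vanish. This is a
property of peak-picking itself, not of the generator.

## Decoders

Binary discrimination is shrinkage-regularised LDA. The pooled within-class
covariance Σ (maximum-likelihood, class means subtracted) is shrunk toward
the scaled identity, `Σ̃ = (1−λ)Σ + λ(trΣ/D)I`, and `w = Σ̃⁻¹(μ₁−μ₂)`,
`b = −wᵀ(μ₁+μ₂)/2` so the midpoint of the projected class means scores zero.
λ defaults to the analytic Ledoit–Wolf intensity (deterministic, no
cross-validation); λ = 0 reproduces plain LDA and is verified against an
explicit matrix-inverse oracle, λ = 1 reduces to the mean-difference
direction. A singular Σ̃ at λ = 0 raises with a pointer toward regularising.

Target decoding scores each symbol's accumulative mean feature vector and
takes the argmax; ties (measure zero in practice) go to the lowest symbol
index with a warning. Since the decoder is linear, scoring the average equals
averaging the per-trial scores, and the evaluation code exploits this
(cumulative means of projections — algebraically identical, one pass).

The active decoder trains on *target trials only* of the passive vs
pitch-imagery conditions (passive-vs-counting selectable), with passive as
the positive class, so the intention decision is y = sgn(f); f = 0 maps to
passive as the fail-safe (no command issued). The two-stage classifier picks
the symbol with the target decoder — trained on the pitch-imagery condition
by default, the system's intended operating task — then feeds the estimated
symbol's averaged feature vector (under the active decoder's own layout) to
the intention decoder.

Two-stage bookkeeping follows the operational convention of
unintended-command suppression rather than textbook ROC: among active-state
selections, TP requires both the symbol and the active state to be decoded
correctly, anything else is FP; among passive selections, TN is a passive
decision regardless of symbol, FN an active decision. Hence TP+FP = number of
active selections, TN+FN = number of passive selections, TPR = TP/#active,
FPR = FN/#passive. One emergent effect worth knowing: stage 1's argmax
selects the feature average most extreme along the target-decoder direction,
which correlates with the "active" side of the intention decoder, so at low
SNR wrong-symbol passive selections lean toward false "active" decisions —
visible as an elevated FPR in noisy simulated sessions.

## Validation experiments

All standing checks draw every random quantity from one integer seed.

- *Chance levels.* With all component amplitudes zero, target and non-target
  epochs are exchangeable, so 4-class selection accuracy is exactly 25% and
  intention accuracy exactly 50% in expectation for any trained decoder; the
  null experiments decode ≥2000 held-out selections (4000 in the
  reproduction script, binomial SE ≈ 0.7 pp) after genuinely fitting the
  pipeline on null training data.
- *Calibration recovery.* 200 simulated subjects, 20 selections each, 1 µV
  noise; the across-subject mean of extracted peaks must sit within 3 SE of
  the configured amplitude at each component's reference electrode.
- *Monotonicity and ordering.* Accuracy should rise with n and order as
  passive < counting < pitch imagery at n = 4. Because the counting→pitch
  contrast is a few percentage points under this noise model, the experiment
  uses common random numbers: per subject, every condition is generated from
  an identically seeded generator, so schedules, noise tensors and
  subject-effect quantiles coincide and only the calibrated amplitudes
  differ. This pairing isolates the condition effect; 4 subjects × 125 test
  selections per condition resolve the ordering with clear margins
  (≈42/56/65% at n = 4). Monotonicity is checked as Spearman ρ > 0 between n
  and mean accuracy per condition.
- *Exact bookkeeping.* Trial accounting (200/600 per phase, 400/1200 per
  session) and the two-stage confusion tallies are recomputed by brute force
  in the tests and must match the pipeline exactly.

Problem sizes throughout (selection counts, subject counts, repetitions) are
chosen so each validation runs in seconds to a couple of minutes on one core
while keeping Monte-Carlo error far from the decision thresholds; they are
package defaults, not statements about the paradigm.

## Known limitations

- The generator's independence assumptions (across trials and channels) make
  absolute accuracies optimistic relative to recorded EEG at matched noise
  RMS, while making the condition contrast conservative; only orderings and
  chance-level behaviour are meaningful desk-scale quantities.
- Interval selection is a deterministic surrogate for the original manual
  step; with flat separability it falls back to the earliest windows, which
  is arbitrary but reproducible.
- The HDF5 epoch container is the package's own schema; converting recorded
  datasets into it (and validating against them) is out of scope here.
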