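# Methods

## Synthetic cohort

The generator produces labeled sessions that mimic the structure of a
waist-accelerometer fall study rather than its biomechanics. Defaults (all
fields of `GeneratorProfile`, units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_adults` / `n_elderly` | 23 / 15 | cohort composition (subject ids `SA…`/`SE…`) |
| `recording_duration_s` | 60 | one session per subject (s) |
| `sample_rate_hz` | 200 | native sensor rate (Hz) |
| `event_rates` | fall 2, hazard 1 | expected events per session (Poisson) |
| `adl_mix` | rest .4, walk .4, sit-stand .15, jump .05 | background activity weights |
| `noise_sd_g` | 0.05 | additive Gaussian sensor noise (g) |
| `gravity_g` | 1.0 | gravity magnitude (g) |

Event grammar: a fall is `ALERT` (hazard, U(0.5, 1.5) s of erratic 4–6 Hz,
~0.7 g oscillation) → `FALL` (impact, U(0.2, 0.4) s half-sine spike of
U(2.5, 3.5) g on top of gravity, so the peak magnitude always exceeds
2.5 g) → `BKG` (lying, U(2, 5) s at a rotated gravity vector). A
hazard-without-fall event is `ALERT` → `BKG` recovery. The hazard and
impact bounds were chosen so that, after three decimations, 32-sample
(1.28 s) blocks can still be majority-`ALERT` and carry ≥ 12.5% `FALL`
content; at the default rates a session's expected sample mix is ~95%
`BKG`, ~5% `ALERT`, ~1% `FALL`, which at block level becomes the strongly
imbalanced BKG ≫ FALL > ALERT regime the classifier must survive
(`expected_label_fractions` gives the closed form, and a generator test
checks pooled fractions against it).

Each subject draws from an independent random stream derived from
`(seed, crc32(subject_id))`, so the data for subject `SA07` do not change
when the cohort grows.

What the generator does **not** emulate: realistic fall biomechanics,
gyroscope channels, inter-subject signal variability beyond the random
streams (adult and elderly subjects differ only in metadata), sensor drift
and saturation. Class signatures (rest/walk vs. hazard oscillation vs.
impact spike) are well separated by construction, so a high macro-F1 here
demonstrates that the pipeline — labeling, decimation, training, evaluation
— is correct, not that the architecture would reach the same scores on real
falls.

## Windowing

Width 256, 50% stride; trailing part-windows are dropped, never padded
(padding would fabricate sensor values). Block count obeys
`floor((T−W)/s)+1` (property-tested against enumeration). Labeling
thresholds `fall_frac = 0.125` and `alert_frac = 0.5` are inclusive (≥) and
checked in relevance order FALL > ALERT > BKG, so a block meeting both
thresholds is `FALL`. At 200 Hz these defaults mean a block is flagged
`FALL` from 160 ms of impact content and `ALERT` from 640 ms of hazard
content; both are exposed in `SegmentationConfig`. Decimation removes the
samples in even *1-based* position, so the window's first sample is always
retained; it is applied to already-segmented blocks, keeping counts and
labels identical across frequency levels, and deliberately performs no
anti-alias filtering (raw sample dropping is the emulated reduction).

## Model and training

Both cells are implemented exactly as written in the README. Notes on the
deliberately ambiguous corners:

- **Peepholes.** The LSTM is written with peephole terms; common framework
  layers omit them. Both variants live behind `peepholes_enabled`
  (default off, which is also what the scalar-loop reference oracle and
  the float32 conversion study use); gradients cover both.
- **GRU candidate.** The reset gate multiplies the hidden state *before*
  the recurrent matrix (`W_hc (r ∘ h)`), and the candidate bias is
  optional with default zero.
- **Batch normalization** uses frozen channel statistics computed from the
  training set once before optimization, with trainable `gamma`/`beta`.
  This keeps BPTT exact, makes train- and test-time behaviour identical,
  and costs little at this scale; it forgoes the regularization effect of
  per-batch statistics.
- **Initial states** are zero; classification reads the final hidden state
  only.
- **Initialization**: Glorot-uniform input/dense weights, orthogonal
  recurrent matrices, zero biases except the LSTM forget bias at 1.
- **Optimizer**: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) by default, plain
  SGD available. Defaults: learning rate 1e−3, batch 32, 30 epochs,
  dropout 0. The searchable grid is learning rate {1e−3, 5e−4, 1e−4} ×
  batch {32, 48, 64} × dropout {0, 0.2, 0.35}.
- **Dropout** is inverted dropout on the dense-layer inputs only — no
  recurrent dropout.
- **Imbalance** is addressed by reporting macro metrics, not by
  resampling; `train` exposes no class weighting by default.
- **Determinism**: every stochastic choice (init, shuffling, dropout
  masks) comes from one `numpy` generator seeded by the config, so a
  seed reproduces training bit-for-bit on one platform.

Gradients are exact analytic BPTT; the test suite checks every parameter of
all four architectures against central finite differences (step 1e−5,
relative tolerance 1e−4) at toy size (N = 4, width 5), and the forward pass
against an independent pure-Python scalar-loop reference implementation.

## Evaluation protocol

Splits and folds are by subject. The 80/20 split preserves the
adult/elderly ratio to within one subject per group (38 subjects → 30/8).
k-fold cross-validation deals shuffled subjects round-robin into k folds;
the grid search scores each configuration by mean fold macro-F1 and returns
the argmax.

Macro precision and recall average the per-class ratios over the three
classes (dividing by the class count, the standard macro definition — the
per-class sums alone could exceed 1); macro F1 is the harmonic mean of the
two macro averages, not the mean of per-class F1 values. A class with an
empty denominator (never predicted, or absent from the truth) contributes 0
and raises a `RuntimeWarning` rather than being dropped, keeping values
comparable across runs. ROC curves sweep the distinct softmax scores
one-vs-rest, pinned to the (0,0) and (1,1) endpoints; trapezoid AUC equals
the pairwise-ranking probability (tested against an O(n²) oracle).

## Deployment emulation

The microcontroller conversion toolchain is emulated by precision
reduction: `float32` rounds every weight to single precision; fixed-point
Q(total, fraction) rounds weights — and optionally intermediate
activations, via a quantize-dequantize hook on the model — to a saturating
two's-complement grid while accumulators stay at full precision, matching
common embedded inference practice. Fidelity is measured by the relative L2
error `‖F_generated − F_original‖ / ‖F_generated‖` between flattened
softmax outputs (the *converted* model in the denominator, hence the
deliberate asymmetry) and by the fraction of blocks whose predicted label
flips.

Arithmetic cost is an exact per-inference MAC count: per step
`4(NM + N²)` for the LSTM (+3N with peepholes) vs `3(NM + N²)` for the
GRU, plus 3N elementwise gate products, one multiply per channel for batch
normalization, and `C·N` for the dense layer — so the GRU is always the
cheaper cell at equal sizes.

Battery life is a duty-cycle model: `hours = capacity / average current`,
averaging duty × current over continuous tasks, the stop-mode current
(10 µA, the spec-sheet bound taken as a point value) over the remaining
duty, and per-event transmission charges. Defaults: sensor read, transform
and RNN execution at 5 mA; Bluetooth transmit at 43 mA; 150 mAh battery.
The on-device designs use processing duty 82.5% (LSTM) / 57.5% (GRU),
giving 36.3 h and 52.1 h at zero events. The streaming design transmits
every sample; its per-task durations are not published for the emulated
hardware, so the defaults (read 1.5 ms, transform 1.5 ms, transmit 13.5 ms
— a 13-byte payload at 9600 baud — per 40 ms sampling period at 25 Hz) are
documented, overridable assumptions yielding ≈10 h.

## Problem sizes

The shipped study runs at desk scale by design: 38 subjects × 60 s gives
≈3,500 blocks per frequency level, and the training/evaluation cycle of
one single-layer model takes tens of seconds on one CPU. Tests use smaller
cohorts still (3–10 subjects) except the learnability check, which runs the
full default cohort.

## Known limitations

- Synthetic signals are stylized; scores here bound pipeline correctness,
  not real-world effectiveness (the optional SisFall-style reader exists
  precisely so real recordings can be substituted).
- No streaming/online segmentation; blocks are cut from complete
  recordings.
- Per-block evaluation only; event-level alarm latency is not measured.
- The fixed-point path quantizes activations between layers but not inside
  the gate arithmetic, so it underestimates the error of a fully
  fixed-point inference engine.
- Battery figures inherit every assumption listed above; they are design
  comparisons, not hardware measurements.
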