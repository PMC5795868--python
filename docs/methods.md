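# Methods

## Problem setting

High-density surface electromyography (HD-sEMG) places a grid of
closely spaced bipolar electrodes over one muscle region (here: 16
channels over the forearm flexor group, 10 mm inter-electrode
distance, sampled at 1 kHz). Because different motions recruit
different muscle compartments under the grid, the *spatial
distribution* of amplitude across channels carries motion information
that a single envelope cannot. `semgrid` implements the processing
chain that turns such recordings into discrete spatial activation
patterns and motion estimates:

1. band-pass (5–450 Hz) and power-line notch filtering per channel;
2. sliding-window RMS amplitude features (200 ms windows every 5 ms);
3. a one-dimensional Gaussian mixture model (GMM) fitted by
   expectation–maximization to the *pooled* RMS amplitudes of all
   channels, used to discretize every channel's amplitude into one of
   K cluster indices;
4. arrangement of each window's per-channel indices on the electrode
   grid — the simplified 2-D spatial pattern;
5. a small feed-forward classifier from patterns to motion labels,
   smoothed by a causal majority vote, plus a mutual-information
   channel-selection score.

## Signal model of the synthetic generator

The generator emulates the second-order statistics that the chain
actually consumes; it is not a physiological motor-unit model. Per
channel `c` during motion `m`:

    x_c(t) = a_{c,m} · e_c(t) + n_c(t)

* `e_c` — zero-mean Gaussian noise band-limited to the EMG band
  (default 20–450 Hz) by forward–backward 4th-order Butterworth
  filtering of white noise, renormalized to unit RMS over the
  realized draw. This makes the amplitude calibration exact: the
  EMG-like component of a steady segment has RMS `a_{c,m}` (μV).
* `n_c` — additive white Gaussian noise with standard deviation
  `noise_floor` (default 3 μV), modeling amplifier/electrode noise.
  Independent components add in quadrature, so a steady segment's
  measured RMS converges to `sqrt(a² + σ²)`; the generator tests
  verify this to 2% on ≥10 s segments.
* transitions between scheduled motions ramp the amplitude linearly
  over `onset_ramp` (default 100 ms) to avoid step discontinuities.

All randomness flows through one `numpy` generator seeded from the
config, so identical configs are bit-reproducible.

What the generator deliberately does **not** emulate: motor-unit
action-potential shapes and recruitment/firing statistics, volume
conduction and inter-channel crosstalk, electrode-skin impedance
drift, movement artifacts, and inter-subject anatomical variability.
Passing tests on this data therefore demonstrate the correctness of
the processing chain under the stated amplitude model, not expected
accuracy on recordings from human subjects.

### The finger-flexion study preset

`default_finger_flexion_config` encodes the qualitative spatial
structure observed on a forearm flexor grid: six classes (rest plus
thumb/index/middle/ring/little flexion); channels 1, 4 and 8
(1-based) active in *every* flexion (muscles shared across fingers,
40–50 μV); channel 5 active *only* during middle-finger flexion; one
additional selective channel per remaining finger (55 μV); and
graded 6–22 μV background amplitudes, distinct per class, on the
remaining channels. Rest is all-zero. Every pair of flexions differs
by at least 3× the noise floor in at least one channel, making the
classes mutually separable by design. The default schedule
interleaves rest with each flexion (2 s segments) over 4 cycles
(48 s, ~9.6k windows), so a contiguous train/test split keeps every
class on both sides; these sizes were chosen as the smallest session
at which held-out accuracies are stable run-to-run. A
`separation_scale` knob multiplies every amplitude toward the noise
floor for degradation studies.

## Filtering

The filter family is standard practice for sEMG conditioning:
order-4 Butterworth band-pass (5–450 Hz) and a second-order IIR notch
(default 60 Hz mains, quality factor 30 — the −3 dB width is
center/Q = 2 Hz). Both are applied per channel, either
forward–backward (`filtfilt`, zero phase; the offline default) or
causally (`lfilter`, as a real-time system would run, with the first
`max(3·order, 100)` samples flagged as warm-up). The two modes differ
— zero-phase squares the magnitude response and removes group delay —
and `frequency_response` reports the designed gain accordingly.
Records shorter than the warm-up/padding length are rejected with the
required length, never padded silently.

## RMS features

`sliding_rms` computes, per channel, `sqrt(mean(x²))` over contiguous
windows `[w·S, w·S + W)`; with `n` samples there are exactly
`floor((n − W)/S) + 1` windows and a ragged final partial window is
discarded. Window and step must be whole numbers of samples at the
record's rate; the error message reports the fractional remainder
otherwise. Implementation uses a cumulative sum of squares, so a
constant signal yields its magnitude exactly and a 100 Hz sinusoid of
amplitude A over an integer number of periods yields A/√2 to float
precision. A streaming extractor emits each window as its last sample
arrives and agrees with the batch path to ≤1e−9 relative.

Window labels are the modal per-sample motion label, ties resolved
toward the class appearing earlier in the record — needed because
windows straddling a transition contain two motions.

`moving_average` (centered, shrunken at the edges, default span 41
windows ≈ 205 ms at the 5 ms step) is provided for smoothing
Fig-style amplitude traces; it is **off** by default before GMM
training, since discretizing smoothed amplitudes blurs onsets.

## Pooled 1-D GMM discretization

All channels' window RMS values are pooled into one 1-D sample and a
K-component Gaussian mixture is fitted by EM:

* E-step: responsibilities `r_ik ∝ w_k · N(x_i; μ_k, σ_k²)`,
  computed in log space with the max-subtraction trick;
* M-step: standard weighted updates of weights, means, variances
  (via the `E[x²] − μ²` sufficient-statistic form);
* convergence when the relative log-likelihood improvement drops
  below 1e−8, or after 500 iterations;
* variance floor `1e−6 ×` pooled variance guards against singular
  collapse (flagged on the model when hit);
* initialization: means at the `(2i+1)/(2K)` quantiles of the pooled
  sample, pooled variance, uniform weights — deterministic and robust
  in 1-D — plus 4 seeded perturbed restarts (5 starts total), best
  final likelihood wins.

After fitting, components are relabeled in ascending-mean order so
that index 0 always denotes the quietest amplitude class; without
this, patterns from different fits would not be comparable.
Discretization assigns each amplitude the maximum-posterior component
(ties to the lower index), which for equal-variance equal-weight
neighbors is a fixed midpoint threshold — hence assignments are
monotone in amplitude. K defaults to 10 for classification and 5 for
exploration; an optional BIC scan reports alternatives but automatic
selection is deliberately not a default. Rest-period windows are
included in the pooled training sample (they populate the
low-amplitude components), and the mixture is refit per session since
amplitude distributions vary across placements and subjects.

Degenerate inputs: all-identical amplitudes return a single flagged
component at the variance floor; K exceeding the number of distinct
amplitudes is an error.

The EM code is authored here because it *is* the method under study;
scikit-learn's `GaussianMixture` is used in the test-suite only, as
an independent reference started from the identical initialization
(final log-likelihood agreement to 1e−4 on small samples).

## Classification and temporal smoothing

Each window's pattern row is one-hot encoded (`n_channels × K`
binary inputs) and classified by a single-hidden-layer perceptron
(20 logistic units, softmax output, cross-entropy loss, mini-batch
SGD with momentum, seeded; scikit-learn's `MLPClassifier` provides
the optimizer, and the learned weights are stored explicitly so saved
models reload without it). This is the smallest architecture
consistent with "a small neural network"; a nearest-centroid baseline
on the same encoding is included for sanity checks. Per-epoch losses
are recorded; non-finite loss aborts with the offending epoch.

Majority voting smooths the decision stream causally: the output at
window t is the modal label of the trailing `vote_span` (default 41,
odd enforced) predictions; ties keep the previous output. The vote
can only delay transitions by at most `(span−1)/2 × step` — it never
introduces a label absent from its window.

Evaluation uses contiguous-time (block-wise) train/test splits:
adjacent 200 ms windows at a 5 ms step share 97.5% of their samples,
so random per-window splits would leak test information into
training. "Steady-state" metrics additionally exclude windows within
a guard interval after a label change, where the true label is
ambiguous by construction; the default guard of 0.6 s covers the RMS
window (0.2 s) plus the onset ramp (0.1 s) plus the causal vote lag
(41 × 5 ms ≈ 0.2 s).

## Channel selection

The discriminability score of a channel is the mutual information
(bits) between its cluster index and the motion label, estimated from
empirical joint frequencies over windows. A channel whose index never
varies scores 0; a binary index perfectly aligned with a balanced
binary label scores 1 bit. On the flexion preset, the middle-only
channel 5 attains the top score for middle-vs-other-flexions, which
is the intended use: choosing a small electrode subset that retains
motion information.

## File formats

Delimited text (CSV with a `time_s` column, one column per channel,
optional `label`) round-trips exactly (shortest-repr floats,
`round_trip` parsing). EDF output uses per-channel physical range
±1.05×max|sample| over 16-bit integers, so round-trip error is
bounded by half a quantization step; the EDF reader/writer here
implements the minimal single-rate subset of the format (labels are
not representable and are dropped), and the writer's output is
cross-checked against MNE's EDF reader in the tests. The pipeline
runner writes every intermediate plus a manifest (config, SHA-256 of
each artifact); identical configs and seeds reproduce byte-identical
files.

## Known limitations

* The generator's Gaussian-envelope model cannot probe waveform-level
  effects (e.g., notch ringing on motor-unit spikes) or realistic
  inter-channel correlation.
* The classifier is trained and evaluated within one synthetic
  session; no cross-session or cross-subject transfer is claimed, and
  the spatial patterns are known to be placement-sensitive.
* The causal filtering mode is provided for parity with real-time
  deployments but the shipped pipeline is offline (zero-phase).
* Majority voting assumes static, held motions; it trades transition
  latency for steady-state stability and will blur rapid motion
  sequences.
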