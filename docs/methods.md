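# Methods

`pcgclassify` classifies short phonocardiogram (PCG) heart-sound events into
twelve classes — the four fundamental tones S1–S4 and eight variant or
pathological morphologies (ejection click, normal split S1/S2, opening snap,
early/late/pansystolic murmurs, diastolic rumble). The pipeline has three
stages: variable-window segmentation, all-pole (LPC) spectral features, and a
one-against-others SVM ensemble whose feature subset and per-classifier
kernels/penalties are chosen by a Modified Cuckoo Search (MCS).

## Signal model and segmentation

Heart sounds are non-stationary: each tone is a burst of 30–450 ms whose
length varies between beats and pathologies, so fixed-length framing (as in
speech LPC) is inappropriate. Segmentation instead fits a *variable-size
window* to every tone:

1. per-frame normalized Shannon energy, `-mean(x^2 log x^2)` with
   `0·log 0 := 0`, frames of 20 ms hopped by 10 ms, envelope rescaled to
   max 1 (Shannon energy de-emphasizes both the noise floor and isolated
   spikes relative to plain energy);
2. regions above a *relative* threshold (default 0.2 of the envelope
   maximum — relative, so inter-recording gain differences cannot change the
   segmentation);
3. regions closer than `merge_gap` (50 ms) are merged — this keeps a closely
   split tone inside one window;
4. regions shorter than `min_duration` (30 ms, about the shortest click) are
   dropped; survivors are padded by 10 ms per side and clamped.

All constants sit in `SegmentationConfig`. Intervals are half-open
`[start, end)` in seconds. No pre-filtering is applied before the envelope;
recordings are peak-normalized on load.

## LPC features

Each segment is modelled as white noise driven through an all-pole filter
`H(z) = G / (1 + a_1 z^-1 + ... + a_p z^-p)` fitted by the autocorrelation
method: Hamming window, biased autocorrelation (computed by FFT), and the
Levinson–Durbin recursion. The autocorrelation method guarantees a stable
filter (asserted; unstable estimates raise). The sign convention
`A(z) = 1 + Σ a_k z^-k` is fixed at the API boundary.

Order p = 24 is the default: a heart-tone spectrum can carry on the order of
a dozen resonance peaks, each peak needs a conjugate pole pair for real
coefficients (hence at least order 18), and 24 leaves headroom so
low-frequency detail is tracked without peak shift. The feature vector is
`a_1..a_24`; the gain is excluded because it only encodes loudness, making
the features amplitude-invariant.

The *fitness factor* quantifies spectral agreement. With both magnitude
spectra evaluated on one N = 512-point linear grid over [0, fs/2] and
peak-normalized (LPC gain matching is otherwise arbitrary):

    FF = 100 · (1 − Σ|Hf − Hs| / Σ|Hs|),  clamped below at 0.

On synthetic tones the mean FF rises monotonically with model order
(5 → 18 → 24), the property that motivates order 24. A statistical caveat
documented here because it bounds what tests can show: when the reference is
*estimated from data*, coefficient sampling noise of order `sqrt(2p/N)`
floors the achievable FF — at N = 8192 samples an order-24 fit cannot exceed
roughly 95 % against the true generating spectrum; FF ≥ 99 % requires on the
order of 10^6 samples (asserted at 2^20 in the test suite).

## SVM ensemble

Binary machines solve the usual soft-margin dual (scikit-learn's libsvm
backend); kernels are linear, quadratic `(x·y+1)^2`, polynomial `(x·y+1)^u`,
and RBF `exp(−‖x−y‖²/(2σ²))`. The quadratic kind is kept distinct from
polynomial-with-u=2 because it is a separate baseline in the comparison
protocol. Multiclass uses one-against-others: m = 12 machines, member i
trained with +1 for class i and −1 for the rest, all sharing one feature
mask. Prediction is the argmax of the members' real-valued decision values
(ties break to the lowest class index) — sign voting would be ambiguous when
zero or several members fire.

Decision values are always computed from the stored support vectors, dual
coefficients and bias, never from the fitting object, so a JSON-serialized
model reproduces its predictions exactly after reload (asserted to 1e-12).
Features are not standardized by default (LPC coefficients are already
scale-free); a config flag enables z-scoring and is recorded with the model.

## Model selection by Modified Cuckoo Search

The search space is `[0,1]^d`, d = 24 + 3m: 24 relaxed mask genes
(thresholded at 0.5) plus kernel-kind, kernel-parameter and penalty genes per
classifier. Multiplicative parameters decode log-uniformly — σ over
`[2^-10, 2^3]`, C over `[2^-5, 2^15]`, degree u over {1..6} (rounded) — since
linear decoding would waste most of each range. Genomes with an empty mask
are penalized with the worst fitness, never raised, so the search continues.

Fitness is either the leave-one-out average balanced accuracy (maximized) or
the support-vector count of the full-data ensemble (minimized, a complexity
proxy). Balanced accuracy `(sensitivity + specificity)/2` is used because
each one-against-others problem is 1:11 imbalanced; raw accuracy would
reward the always-negative classifier. Undefined metrics raise rather than
return 0 — a silent zero would corrupt fitness ranking.

MCS mechanics per generation G (population fixed, all randomness from one
seeded generator):

* the bottom `discard_fraction` of nests take Lévy flights (Mantegna's
  algorithm, exponent 1.5) at scale `A0/√G`, kept only if they improve;
* each top nest recombines with a random top nest: the candidate sits at the
  golden-ratio point on the line from the worse toward the better, and
  replaces a random nest if better; a nest paired with itself (or with an
  identical position) instead takes a local Lévy walk at scale
  `local_step_factor · A0 / G`, kept only if it improves that nest;
* elitism is structural — nothing is ever overwritten by a worse candidate —
  so the generation-best trace is monotone.

The local-walk schedule `0.3·A0/G` was chosen over the steeper `A0/G²`
because the faster decay freezes local refinement before the recombination
cluster reaches the optimum; with it, the optimizer drives a 10-dimensional
sphere below 1e-6 within 5000 evaluations on 10/10 seeds (population 10).
Fitness values are cached by decoded genome (thresholding maps many positions
onto one genome); cached and fresh evaluations agree exactly because the
fitness is deterministic in the genome.

## Synthetic data

No free heart-sound corpus ships with the package, so a seeded generator
emulates the twelve classes at the study scale of 6 recordings per class
(72 total). Each class is a recipe of components: damped sinusoids
`a·e^(−t/τ)·sin(2πft)` with τ set by a resonance bandwidth (valvular tones:
narrow low-frequency peaks) and Hann-enveloped bandpass noise (murmurs:
broadband turbulence), rendered at 4 kHz — PCG energy lies below 1 kHz, so
4 kHz keeps every component below Nyquist with headroom — plus white noise
at 30 dB SNR. Per-realization jitter: frequency ±10 %, duration ±20 %,
amplitude ±20 %. A dataset is a pure function of
`(per_class_count, sample_rate, seed)`.

Default recipes are designed for class separability rather than clinical
fidelity (the qualitative ordering — rumble lowest, clicks/snaps highest,
murmurs broadband — is preserved): tonal centers sit on a ~1.25-ratio
frequency ladder so ±10 % jitter cannot make neighbouring classes overlap,
decay bandwidths are narrower than inter-class gaps, and several classes are
distinguished by multi-band signatures (three-peak S2, dual-band pansystolic
murmur, high companion peaks for click and snap). Split tones are two damped
sinusoids 30–80 ms apart; one tone (or split pair) per recording, because the
classifier operates on segmented individual tones.

What the generator does *not* emulate — full cardiac cycles with rhythm,
respiration and ambient noise, inter-patient spectral variability, sensor
coloration — bounds the claims: passing tests show the pipeline recovers the
class structure it is pointed at, not clinical performance on real
recordings.

## Study protocol and problem sizes

`run_experiment` mirrors the comparison protocol: the MCS-tuned ensemble
against three fixed-kernel baselines (SVM-poly u=3, SVM-rbf σ=1, SVM-quad,
all with C=1 and all 24 coefficients), evaluated either by leave-one-out
over all 72 recordings or by a seeded stratified half split (3 train / 3
test per class). The reported table lists per-class balanced accuracy, the
unweighted mean over classes, and the sample variance (ddof=1) of the
per-class values; per-class raw accuracy `(TP+TN)/n` is also emitted.

The shipped search budget is 15 nests × 20 generations (~175 fitness
evaluations, each a 72-fold leave-one-out retraining of 12 machines), a few
minutes on one core. Larger budgets only increase the margin; the defaults
in `MCSConfig` (25 nests, discard 0.25) follow common MCS usage.

## Numerical choices and degenerate inputs

* Biased autocorrelation keeps the Yule–Walker system positive
  semi-definite; a non-positive prediction-error power mid-recursion raises.
* Silent segments, empty WAVs, single-class training sets, and classes with
  one sample under leave-one-out all raise typed errors naming the problem;
  silence at classification time yields an empty segment list, not an error.
* `signal_spectrum` zero-pads to an FFT length whose bin grid contains the
  512-point target grid, so filter and signal spectra are always compared on
  identical frequencies.
* Ties in the OvR argmax break to the lowest class index; the half-split
  partition and every stochastic stage derive from the run seed, so repeat
  runs are byte-identical.

## Known limitations

* LPC coefficients are compared in raw coefficient space; line-spectral or
  cepstral embeddings would likely separate classes with less data.
* The leave-one-out fitness is also the selection criterion, so the reported
  search fitness is an optimistically biased estimate of generalization; the
  half-split mode exists for an unbiased check.
* The support-vector-count fitness ignores accuracy entirely; it is the
  complexity-oriented alternative, not a replacement.
* Segmentation assumes tones rise clearly above the noise floor; heavily
  corrupted ambient recordings would need a denoising front end.
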