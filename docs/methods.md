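# Methods

## Model

`audass` treats severity estimation as a per-second pattern-recognition
problem over FACS action-unit intensities. The unit of prediction is a
31×30 *window*: 31 intensity-coded AUs (AU1–AU7, AU8–AU20, AU22–AU28,
AU33–AU35, AU43, AU45; AU41/42/46 are excluded because they are not coded
with intensity levels) by 30 frames, i.e. one second of 30 fps video.
Intensity levels map to fixed reals — O→0, A→0.2, B→0.4, C→0.6, D→0.8,
E→0.9 — and this non-uniform top step is kept exactly; it compresses the
D/E distinction on purpose, with the shortcut rules (below) handling the
D/E regime.

The severity network is a fully connected 930→75→65→3 net: tanh on the
first hidden layer, sigmoid on the second and the output layer, hidden
biases architecturally fixed at 0, output bias trainable. Windows enter
flattened column-major, so each frame's 31 values stay contiguous. The
three outputs in (0,1) band into the five severity levels at
0.15/0.3/0.6/0.8; shared printed endpoints are resolved half-open
lower-inclusive, except that 0.8 itself belongs to Severe because
Extremely Severe is "over 0.8". A disorder variant with hidden sizes
30/25 emits MDD/GAD/PTSD flags by thresholding at 0.5 (exact 0.5 → 0);
its binary training targets are encoded 0.1/0.9 so the relative-error
loss below never divides by a vanishing target.

### Loss, training and its failure modes

The training loss is the average absolute relative error
`AARE = (1/N) Σ |(y_p − y_e)/y_e|`, averaged over samples and the three
output components; y_p is the desired and y_e the estimated output, and
the denominator — the *estimate*, an unusual but deliberate convention —
is clamped at ε = 0.05. Band targets are interval midpoints (0.075,
0.225, 0.45, 0.7, 0.9), so desired values are never 0. Optimization is
full-batch gradient descent with classical momentum (rate 0.2, momentum
0.4), hidden biases held at 0, stopping when training AARE < 0.02 or at
7000 epochs; an 80:20 train/validation split is monitored. A per-sample
(pattern-mode) update is available behind `TrainingConfig(mode=...)`.

Two properties of this optimizer matter in practice. First, the loss is
piecewise smooth with non-vanishing gradients at the optimum, so with a
fixed step the iterates dither rather than converge once residuals are
small; whether the dither settles under 0.02 depends on how
well-conditioned the regression is. Second, if a training batch consists
of a single repeated pattern with one small target, nothing in the batch
averages out and the updates enter a limit cycle that never reaches the
stopping criterion — degenerate single-pattern datasets should be
avoided (the evaluation protocols always train on multi-band batches).

### Decision layer

Each scale has a four-AU signature (depression AU6/AU12/AU15/AU26,
anxiety AU2/AU9/AU25/AU45, stress AU1/AU6/AU12/AU15). If all four reach
level D or E anywhere within a window (a strict same-frame mode is a
flag), the scale is scored Extremely Severe directly. Because depression
and stress share three signature AUs, strong depressive displays
co-elevate the stress channel and vice versa; this cross-talk is
inherent to the rules, visible in the stream example, and a known
limitation. The rule-based classifier then requires the same prediction
for five consecutive seconds — by default the full band triple; a
per-scale mode (each scale's run found independently) decides more often
on streams whose scales stabilize at different times. Anything else is
`Undefined`: an explicit "not enough information" outcome, reported
separately by the evaluation harness rather than folded into error
counts, since mixing undecided streams into FP/FN would distort all
three metrics.

## AU classifier bank

Layer 1 classifies each AU's intensity independently from a
72-dimensional nonrigid feature vector: 31 six-class classifiers, each a
StandardScaler + support-vector machine with one-vs-one decomposition.
The default kernel is linear: in the synthetic feature model each AU's
level is encoded along its own orthonormal direction, making the true
discriminants hyperplanes, and an isotropic radial kernel demonstrably
fails to ignore the thirty interfering directions (held-out accuracy
plateaus near 0.8 where the linear machine reaches 0.95). The factory is
pluggable for other geometries. An AU observed at a single level during
training degenerates to a constant predictor with a logged warning.
Deriving the 72 features from images (AAM fitting) is out of scope;
features arrive via the data contract or the generator.

The geometric front end locates eye and mouth blocks in a binary face
mask from its row profile: the highest-count row in the upper half
(row/H < 1/2) is the eye-block median, in the lower half the mouth-block
median; ties break to the smallest row; validity flags require the row
fraction to fall in [2/20, 9/20] (eyes) or [11/20, 15/20] (mouth).
Invalid blocks are flagged, not raised, so streaming callers can skip
frames.

## Synthetic data

The generator simulates everything the pipeline eats; its defaults are
the package's study conditions.

**Cohorts.** Subjects draw per-scale bands from a configurable marginal
(default uniform over the five bands); mutually exclusive MDD/GAD/PTSD
flags at prevalences 20/128, 19/128, 17/128 raise the matched scale to
at least Severe. Session-to-session dynamics are a ±1-band random walk
with step probability 0.4 per scale.

**AU streams.** Per one-second window and scale, a coordinated
*signature burst* — all four signature AUs at D/E for a contiguous run —
occurs with probability `min(0.12·(2^rank − 1)·boost, 0.95)`, rank 0–4.
Burst length grows with rank (uniform over `rank·(4..6) + (2..4)`
frames), so both presence and extent carry severity; with
probability-only coding, windows from different ranks would be
indistinguishable. Induced emotions gate the signal: a scale-congruent
emotion (happiness/sadness → depression, surprise/disgust → anxiety,
sadness/disgust → stress) multiplies burst probability by 3, an
incongruent one by 0.15 — the induced expression crowds out the
spontaneous signature. These two constants were set, together, so that
training restricted to a scale's congruent emotions measurably beats
unfiltered training (the selectivity experiment); they are design
constants, not fitted quantities. Independently every AU flickers at
0.05/frame (levels mostly A–C, 15% D/E), and the induced emotion's
prototype AUs (classic FACS prototypes) activate at 0.25/frame at
levels B–D.

**Features.** A frame's feature vector is the sum over AUs of
`separation · level_rank` along a fixed orthonormal direction per AU
(QR of a seeded Gaussian 72×31 matrix) plus isotropic N(0, 0.3²) noise;
separation defaults to 1.5. Nearest-centroid decoding is exact as
separation → ∞.

**Questionnaires.** A target raw score is drawn uniformly inside each
scale's band interval and distributed over the scale's 14 items by
random unit increments, so scoring a generated response re-bands exactly
to the generating profile. The authentic DASS-42 item-to-scale map is
licensed material; the default partition (items 1–14/15–28/29–42) is a
synthetic placeholder and explicit configuration.

**Noiseless window dataset.** For network verification and the headline
training experiment, windows encode a severity triple deterministically:
each scale's distinctive signature AU (AU26, AU2, AU1 — the one not
shared with any other scale) carries a per-rank column pattern whose
level values sum to {0, 0.6, 1.5, 2.5, 3.3}, making that row's window
mean *exactly affine* in the band-midpoint target
(`t = 0.075 + 7.5·mean`); the remaining three rows carry filler patterns
with the same average mass but at most one D-level row below rank 4, so
the four-AU D/E signature completes only at Extremely Severe. The affine
encoding is what makes the fixed-step momentum optimizer reach the 0.02
criterion (at roughly 2500–5500 epochs depending on seed); with a
step-function encoding the zero-bias architecture leaves the dither
floor near 0.05–0.10. Scales write to disjoint column blocks so shared
signature AUs do not collide.

What the generator does **not** emulate: real AU co-articulation and
head pose, temporal autocorrelation beyond single bursts, annotator
disagreement, demographic effects, and any empirical link between facial
behaviour and clinical state. Passing tests therefore demonstrate that
the implementation recovers structure the generator put in — parameter
recovery, not clinical validity.

## Evaluation protocols

Metrics are one-vs-rest per band: AC = (TP+TN)/total, SE = TP/(TP+FN),
SP = TN/(TN+FP), with undefined ratios reported as not-applicable, never
as 0. Leave-one-out runs either across subjects (intersubject) or across
one subject's recordings (intrasubject), with train/test drawn from the
DSC (emotion-induced) or DSR (spontaneous) splits and an optional
training-emotion filter; every fold retrains the network from scratch
and the fold manifest is audited for train/test disjointness. The
average seconds of stream consumed before the consensus rule decides is
reported, with undecided streams counted at full length. The emotion
selectivity experiment uses band-stratified cohorts with the two
nuisance scales held at Normal — random small cohorts leave bands
unrepresented, and the depression/stress signature overlap otherwise
confounds the comparison — and scores per-window band accuracy on
held-out spontaneous recordings.

## Problem sizes and numerical choices

Experiments are sized for a single CPU: the headline training uses 200
windows (160 after the 80:20 split) and stops around epoch 2500–3000;
protocol tests use cohorts of 2–10 subjects with 6–12-second recordings;
the classifier bank is validated at 900 training frames with 20% AU
activation. Random number generation is `numpy.random.default_rng`
throughout, with every public generator a pure function of its
arguments and seed; training curves are bit-reproducible under a fixed
seed. Gradient correctness is checked against central finite differences
away from the |·| kink and the ε-clamp. Model artifacts are a single
versioned JSON document so identical runs serialize byte-identically.

## Known limitations

* The depression/stress signature overlap (AU6/AU12/AU15) makes the two
  channels partially confounded at high severity, for both the shortcut
  rules and the learned network.
* The strict full-triple consensus leaves many mixed-severity streams
  Undefined; intermediate bands fluctuate between neighbours from second
  to second. The per-scale consensus mode mitigates but does not remove
  this.
* The fixed-step momentum optimizer is faithful to the stated training
  regime but fragile: convergence below the 0.02 criterion depends on a
  well-conditioned target encoding, and degenerate single-pattern
  batches cycle forever.
* All accuracies reported by the examples and tests are on synthetic
  data and say nothing about real faces or clinical populations.
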