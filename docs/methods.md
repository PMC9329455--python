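# Methods

## Scope and model

The package classifies fixed-length numeric records with a feedforward
network containing exactly two hidden layers. Data flow is strictly
input → hidden 1 → hidden 2 → output, with tanh hidden units and a
softmax output layer trained by mean cross-entropy against one-hot
targets. Gradients are exact reverse-mode derivatives; the test suite
verifies them against central finite differences (relative deviation
≤ 1e-5 over 100 random small networks).

The reference protocol names only the trainers, not the output
nonlinearity or loss. We fix softmax + cross-entropy because it is the
standard pattern-classification configuration of the toolbox generation
the protocol comes from, and because it makes the 0.17 selection
threshold meaningful: outputs are then probabilities on the simplex, and
0.17 sits just above six-class chance (1/6 ≈ 0.1667).

## Hidden-layer sizing

Widths come from Huang's two-hidden-layer learnability bound:
layer 1 = √((m+2)N) + 2√(N/(m+2)), layer 2 = m√(N/(m+2)), where N is the
number of distinct samples and m the number of output neurons. Raw sizes
are rounded **up**: ceiling is the only rule consistent with the
reference instantiations 259.81 → 260, 155.88 → 156 and 40.39 → 41. The
formulas are always evaluated with m = the output-class count (6 for the
behavior problem, 2 for the component problem).

## Initialization and standardization

The protocol is silent on both, so the package specifies them fully:

* Weights are drawn uniformly in ±√(6/(fan_in+fan_out)) per layer from a
  seeded generator; biases start at zero. This keeps early tanh
  activations in their linear range and makes runs bit-reproducible.
* Features are z-scored per column using the mean and standard deviation
  of the **training split only**; constant columns get scale 1. The
  identifier elements (participant id, trial index, condition) are
  standardized like any other feature. Without scaling, raw id values
  would dominate the 6003-element trial vectors.

## Training protocol

Both optimizers are full-batch on the training split:

* **Scaled conjugate gradient** (Møller): conjugate directions with a
  curvature estimate from a finite gradient perturbation (σ = 5e-5) and
  Levenberg-style damping starting at λ₀ = 5e-7; the direction restarts
  to steepest descent every P successful steps, P = parameter count.
  Unsuccessful steps leave the weights unchanged, so the training loss is
  non-increasing across epochs.
* **Rprop** (iRprop⁻, Riedmiller–Braun constants): per-parameter step
  sizes start at Δ₀ = 0.07 (the toolbox default), grow by η⁺ = 1.2 on
  consistent gradient signs up to Δmax = 50, shrink by η⁻ = 0.5 on a sign
  change, and the pending update is skipped after a sign change.

Data are split 70% training / 15% validation / 15% test; validation and
test sizes are floored, the remainder goes to training, and the
assignment is one seeded shuffle. After every epoch the validation split
is classified in a fixed seeded order (one shuffle, reused every epoch)
and training stops when some run of `consecutive_correct` cases (100,
150 or 200 in the reference grid) is correct **within that single pass**;
"correct" means the argmax class matches the target — the 0.17 threshold
is an evaluation-time device only. Whether such runs may span epoch
boundaries is ambiguous in the source protocol; the within-pass reading
makes the criterion well defined and reproducible. An epoch cap (default
2000) and a gradient-norm tolerance (1e-6) guard against non-convergence;
a `consecutive_correct` larger than the validation split is rejected as a
configuration error because the rule could never fire.

## The behavior rule system

Thresholds are fractions of the device maximum (full joystick deflection
= 1.0), not per-participant empirical maxima — the percentage criteria
are stated as properties of the joystick range. "Backward movement
speed" is read as backward deflection magnitude (the joystick drives
virtual speed); both readings are flagged as ambiguities of the manual
criteria. The 3000 samples cover 13 s uniformly (≈ 230.8 Hz), so the
"first 8 s" window is 1846 samples and the "first 4 s" window is 923.

Rules are evaluated in a fixed precedence that makes categories mutually
exclusive (the manual criteria state no order):

a. **Conflict by latency** — movement onset (first sample with
   max(|x|,|y|) > 0.10) later than 1.5 s.
b. **Reach-out (4 left / 5 right)** — forward deflection above 0.50 for
   at least the dwell fraction of the 8 s window, and backward deflection
   below 0.10 throughout the first 4 s.
c. **Fleeing (1)** — backward deflection above 0.75 for at least the
   dwell fraction of the window, with |x| under 0.50 throughout it.
d. **Approach-safety (2 left / 3 right)** — some |x| above 0.15 in the
   window plus a backward-to-forward sign change of y with each phase
   sustained ≥ 0.25 s.
e. **Conflict by behavior change or degraded execution** — both a
   backward- and a forward-dominant segment of ≥ 1 s in a pattern not
   already matched by (d); or, when the participant's other trials are
   available, a performance outlier.
f. **Unclassified** otherwise.

Turn direction is the sign of x at the sample of maximal |x| within the
8 s window (negative = left). Sustained-threshold semantics (default
dwell 20% of the window) replace single-sample crossings, which would be
brittle under measurement noise.

"Very bad performance" is operationalized — the manual criteria leave it
qualitative — as a robust outlier rule on a roughness score (mean
absolute per-sample change of x plus y): a trial is an outlier if its
score exceeds the participant's median by more than 3 robust standard
deviations (1.4826·MAD), with at least 5 reference trials required. The
score choice is configurable and explicitly a design decision of this
package.

## Synthetic data

The trajectory generator emulates the *structure* of the study (54
participants × 5 conditions × 20 trials at full scale; category mixes per
condition; onset latency N(0.5 s, 0.15 s) clipped to [0.15, 1.2];
additive Gaussian measurement noise, default σ = 0.02 of full
deflection). Templates are parameterized splines, not physics: the
classifier consumes joystick deflection only, so template realism is
judged by rule-consistency (the rule system recovers the intended label
for 100% of zero-noise trials and ≥ 99% at σ = 0.02) and by end-to-end
learnability. Conflict trials mix three mechanistic variants mirroring
the three conflict triggers: late onset (uniform 1.8–3.0 s), a mid-trial
backward→forward reversal without turning, and a high-jitter "sloppy"
reversal whose bounded smooth jitter (amplitude 0.25 on y) leaves the
change-of-behavior clause detectable without participant context.

The component generator produces kind-specific recipes for five artifact
families (blink, lateral eye movement, muscle, cardiac pulse, 50 Hz line
noise) and two signal families (posterior alpha, broadband 1/f), each
with a characteristic time-course, topography over a fixed 32-slot
montage (frontal/temporal/posterior/edge index sets are documented
constants; no real electrode coordinates are used) and 70-band spectrum,
plus Gaussian measurement noise (default σ = 0.05). The default artifact
fraction is 0.4, a typical share of artifact ICs in a 32-channel
decomposition. Kinds are separable by nearest-centroid in
(topography, spectrum) space at zero noise.

What passing tests on these data do **not** show: robustness to real
inter-participant variability, drifting baselines, correlated sensor
noise, or behavior outside the six templates. The generators define
controlled conditions for verifying the pipeline, not a claim about
field data.

## Evaluation choices

* Missed trials (no probability above the threshold) are excluded from
  confusion counts but stay in the overall-accuracy denominator and are
  reported separately. This matches reference tables whose per-class
  totals fall slightly short of the trial count.
* Ties in category selection go to the lowest class index.
* McNemar uses (b−c)²/(b+c) without continuity correction — the printed
  reference statistic 3.769 for discordants (3, 10) requires the
  uncorrected form — with an upper-tail χ²(1) p-value.
* ROC curves sweep the decision threshold over all distinct scores,
  predicting positive at score ≥ threshold, with endpoints (0,0), (1,1).
* Percentages are rounded half-up to one decimal, computed on exact
  rational ratios to avoid binary-float rounding artifacts.
* The model-selection grid trains the 2 × 3 algorithm/validation-trials
  cells and flags the best network in two stages: highest overall
  accuracy, with rows whose pairwise McNemar statistic against it stays
  below 3.841 (χ²₁ at 5%) treated as statistical ties broken by the
  fewest missed trials on new data.

## Problem sizes used in the test suite

End-to-end checks run at sizes chosen to keep the default suite fast
while leaving the protocol intact: the component problem at full study
scale (51 × 32 = 1632 components; validation split 244, so the default
consecutive-correct run of 100 applies literally) and the behavior
problem at 10 participants × 5 conditions × 20 trials (1000 trials,
6003-element vectors, a 112 × 68 network; validation split 150). Under
these conditions scaled conjugate gradient reaches ≥ 95% (behavior,
6-class) and ≥ 90% (components, 2-class) held-out accuracy.

## Known limitations

* Only the two-hidden-layer architecture is provided — no recurrent,
  convolutional, deeper or shallower variants, and no minibatch or
  adaptive-learning-rate optimizers beyond the two named.
* The rule system's precedence order and dwell semantics are this
  package's resolution of underspecified manual criteria; other
  operationalizations could label borderline trials differently.
* Model files store the exact float64 weights (bit-exact round trip) but
  no training data or history.
* The synthetic generators make no attempt to match the distributional
  properties of any deposited dataset beyond counts and feature layouts.
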