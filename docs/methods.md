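# Methods

## Model

Windows are [T × C] arrays (time × channel) treated as single-channel
images; convolutions and pooling act along the time axis only, so channel
identity is preserved through the stack. The network is

    conv(L×1, K) → ReLU → maxpool(P×1) → conv(L×1, K) → ReLU → maxpool(P×1)
    → flatten → FC(d) → ReLU  [feature tap]  → FC(A) → softmax

with defaults K = 50 kernels, L = 5, P = 3, d = 1024 FC units. Convolutions
are *valid* (no padding) and pooling is non-overlapping with stride P;
under that arithmetic the default stack needs T ≥ 25 (the constructor
reports the minimum when violated). ReLU follows each convolution and the
first FC layer; the literature this follows leaves stride, padding and the
nonlinearity unstated, so these are package choices exposed in `NetConfig`.
All adaptation losses operate at the feature tap; `fc_units=2` yields
directly plottable features (the 2-D diagnostic protocol).

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 1e-4 by
default; plain SGD is selectable to match the textbook update rule
literally. Forward and backward passes are hand-written NumPy (reshaped
matmuls for the convolutions); every gradient path — network parameters,
MMD, center loss, gradient penalty — is verified against central finite
differences in the test suite. Max-pool backward distributes gradient
equally over exact ties; ties only occur at ReLU zeros, where the
downstream ReLU mask annihilates them, so the subgradient choice is inert.

## Objectives

Per iteration, batch_size/2 labeled source windows and batch_size/2
unlabeled target windows are drawn from one seeded stream (half/half
composition is a package choice). The methods differ only in what is added
to the source cross-entropy L_s at the feature tap:

- **MK-MMD (L_m)** — biased (V-statistic) estimator of the squared MMD per
  Gaussian bandwidth, averaged with equal weights over the bank. The
  V-statistic is always ≥ 0 and exactly 0 for identical batches; an
  unbiased variant sits behind a flag. Bandwidths default to the median
  pairwise distance of the joint batch scaled by {¼, ½, 1, 2, 4}
  (median heuristic); a fixed σ list is configurable. MMD is computed once,
  at the first-FC tap only.
- **Center loss (L_c)** — ½ Σ‖f_i − C_{y_i}‖² over *source* features only.
  Centers start at zero and follow the running update
  C_j ← C_j − α·ΔC_j with ΔC_j = Σ_{y_i=j}(C_j − f_i)/(1 + n_j), α = 0.5 by
  default (the update rate is a free parameter; 0.5 is the package
  default). The indicator-weighted form above is the original center-loss
  update; classes absent from a batch are untouched. Centers are updated
  once per iteration after the parameter step, from the same forward-pass
  features the gradients used, so the ordering has no effect on the
  computed gradients.
- **CMMD** — L = L_s + λ·L_c + β·L_m. Default λ = 1e-3 (the magnitude that
  balances a summed center loss against a mean cross-entropy at these
  feature scales), β = 1.
- **DANN** — a one-hidden-layer ReLU domain classifier (64 units) on the
  features, trained with binary cross-entropy (source = 0, target = 1); the
  extractor receives its feature gradient multiplied by −λ_d (gradient
  reversal), λ_d = 1 constant by default. Adversarial runs can fail to
  converge; grid execution isolates such failures per run rather than
  patching the method.
- **WD** — a one-hidden-layer critic maximizes mean f(x_s) − mean f(x_t)
  with a gradient penalty (coefficient 10) on interpolates between source
  and target features enforcing the 1-Lipschitz constraint; 5 critic steps
  per extractor step, on the current feature batch with fresh interpolation
  draws. The penalty's parameter gradient is derived in closed form for the
  ReLU critic (masks locally constant) and finite-difference checked.

`final_center_loss`, reported for every method, is computed uniformly at
the end of training as the center loss of all source-train features around
their *empirical* class means — a method-agnostic measure of inner-class
spread, comparable across objectives that do and do not maintain running
centers. The diagnostics module likewise uses empirical means, kept
deliberately distinct from the optimizer's running centers.

## Synthetic population

The simulator emulates the structure of multi-subject daily-activity
datasets: balanced fixed-length windows, a shared activity vocabulary, and
subject-specific distribution shift. Activity a of subject s on channel c is

    Σ_{h=1..H} (g_s · w_{c,h} / h) · sin(2π h f_a r_s t + φ) + b_{s,c} + ε

- f_a: class base frequency (defaults spread over 0.8–3.5 Hz — cadence-like
  rates), H = 3 harmonics with 1/h decay and population-level channel
  weights w_{c,h} ~ U(0.3, 1); the Nyquist constraint max(f)·H < fs/2 is
  enforced (fs = 25 Hz default).
- Subject shift: amplitude gain g_s = exp(N(0, 0.4)) (log-normal),
  frequency warp r_s = 1 + N(0, 0.1), channel offsets b_{s,c} ~ N(0, 0.5),
  and independent phase draws φ per window and harmonic. These four
  mechanisms are the minimum that reproduces the observed cross-subject
  behaviour: mixed, dispersed target features under a source-only model.
- Noise ε ~ N(0, 0.3) i.i.d.

Phases are drawn per *window* (not per subject/activity cell): a window's
start time within a periodic movement is arbitrary, and per-window phases
give each class a genuine within-class distribution rather than a single
noisy prototype. Consequently "subjects identical up to phase" is asserted
phase-invariantly, via amplitude spectra.

What the simulator does **not** model: non-stationary activities,
transitions between activities, sensor drift over time, heavy-tailed or
correlated noise, class imbalance, and real within-class variation beyond
phase/noise. Passing tests therefore show that the adaptation machinery
behaves correctly under controlled covariate shift of realistic magnitude —
not that any accuracy level carries over to real recordings.

## Protocols and sizes

Normalization is per-channel z-scoring with statistics from the source
training set, applied to both domains (the source defines the deployment
scale; per-domain normalization is available through the same function).
Target data splits stratified by class into an adaptation portion and a
held-out test portion (default 2:1), via seeded stratified sampling. The
experiment grid runs every ordered subject pair × method × repeat with
per-repeat seed = base_seed + repeat; a fixed-initialization mode pins the
network-init seed while splits vary, for replication studies of
initialization-driven instability. Model selection defaults to the
final-iterate accuracy; a best-over-trace selector exists to mirror the
common "best result during the run" protocol and is labelled optimistically
biased.

The standard synthetic transfer study used by `scripts/acceptance.py` and
the heavier tests: 2 subjects, 3 activities, 200 windows/class, 64 × 6
windows, amplitude sd 0.4 / frequency sd 0.1 / noise sd 0.3; network with
32 kernels and 256 FC units; 500 iterations at batch 64; 3 seeds. These
desk-scale sizes keep a full study in the minutes range on one CPU while
leaving the cross-subject effect large (source-only ≈ 0.45 target accuracy
vs ≈ 1.0 source accuracy).

## Numerical choices and degenerate inputs

- Pairwise squared distances are clipped at 0 before exponentiation;
  the median heuristic falls back to σ = 1 when all points coincide.
- Softmax and cross-entropy use the log-sum-exp shift; argmax prediction
  breaks ties toward the lowest class index.
- Zero-variance channels make z-scoring impossible and are reported by
  index; empty batches, out-of-range labels, Nyquist violations, and
  too-short time axes raise immediately with the offending quantity.
- A non-finite training loss aborts with the iteration index rather than
  continuing silently; half-batches larger than the available windows fall
  back to sampling with replacement with a logged warning.
- Training never reads target_train labels on any path; the suite asserts
  bit-identical parameters after label poisoning for every method.

## Known limitations

- No GPU path and no autodiff: the architecture is fixed to the two-stage
  conv/pool stack (depth is not configurable without extending the
  backward pass).
- DANN stability is sensitive to λ_d and initialization, as adversarial
  objectives are; failures are surfaced, not suppressed.
- The loader expects `<activity>/<subject>/<segment>` plain-text CSV
  layout; other layouts need pre-arrangement.
- Best-over-trace selection peeks at target-test accuracy during the run;
  it exists for protocol compatibility and should not be used for unbiased
  comparison.
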