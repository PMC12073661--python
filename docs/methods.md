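# Methods

## Model

The simulator is a three-layer feedforward network with hand-imposed
anatomical structure rather than learned structure. The hidden layer is an
abstraction of the descending motor system: corticospinal (CS) neurons
carry fine, fractionated drive; reticulospinal (RS) neurons carry gross
force drive shared across fingers. Spiking dynamics, conduction delays and
spinal interneuron circuitry are all folded into a static sigmoid
nonlinearity — the model is per-trial static, with no temporal force
trajectories.

Six hidden clusters are laid out as contiguous index blocks (focal
excitatory F1/F2, focal inhibitory F1/F2, shared CS, RS; sizes
40/40/40/40/80/160 at N = 400). "Inhibitory" CS neurons model excitatory
pyramidal cells that recruit inhibitory spinal interneurons; their output
enters the downstream sum with sign −1 via the status variable NS.
Connectivity masks are fixed: each finger's command reaches every hidden
neuron except the other finger's inhibitory cluster; finger-k CST is driven
by focal-exc-k, focal-inh-k and shared CS; finger-k RST by focal-inh-k and
RS. Focal excitatory and shared CS neurons do **not** project to RST
outputs — the strictest reading of the stated connectivity, taken as a
design decision.

### Command/force encoding

A command is instructed (+1) or uninstructed (−1) per finger, with the
demanded force FRC ∈ (0, 1] (0 illegal). Two encodings coexist and both are
used:

- the **target** side uses the binary command: sCMD = (1+CMD)/2,
  eCMD = max(sCMD) − sCMD, EO = FRC·sCMD + 0.06·FRC·eCMD + 0.02·eCMD, with
  the four-channel target (EO₁, EO₁, EO₂, EO₂);
- the **forward** side uses the force-encoded input u_i = FRC for an
  instructed finger and −1 for an uninstructed one, so the commanded force
  directly modulates the hidden-layer drive.

At FRC = 1 the two coincide. Without force encoding on the input the
network's output could not depend on the force target at evaluation time
and the force-sweep analysis would be meaningless; this is a deliberate
design decision, recorded here because the forward input is sometimes
described as strictly binary.

### Biases

The bias constants −6 (hidden) and −1 (output) are treated as *scales*:
per-neuron biases are drawn from the same truncated normal(0.5, 1/12) on
(0, 1) as the weights and multiplied by the scale, giving every neuron a
distinct activation threshold in (−6, 0) (hidden) or (−1, 0) (output).
Biases are fixed constants during training; gradients update only WH and
WO. Rationale: with all-equal constant biases of −6 and initial weights in
(0, 1), every hidden unit sits at f ≈ 0.0025, all gradients are of order
10⁻⁶ per step, and the network provably cannot leave its initial state
within the ~27,000-repetition schedule — the graded-threshold population is
what makes a subset of neurons recruitable and learning possible at
η = 0.01. This is the package's single intentional departure from the
constant-bias description, and it follows the alternative description of
biases "generated like the weights".

### Learning rule

Standard backpropagation of the squared error with two deliberate
literalisms:

- the hidden derivative is the surrogate HO·(1−HO) **as stated**, including
  for inhibitory units where the calculus derivative of NS·f would be
  f·(1−f). Consequence: finite-difference oracles match analytic gradients
  exactly for all output weights and for input weights of excitatory units;
  inhibitory input-weight gradients follow the surrogate (verified in tests
  against an independent element-wise evaluation).
- masks multiply the *entire* update (not just the old weights), so
  non-connected weights are exactly zero after arbitrarily many steps.

Weights are not clamped to stay positive; sign crossings of connected
weights are counted on the state (`negative_weight_events`). The bias shift
is the model's mechanism for keeping the excitatory regime plausible, and
in practice the inhibitory clusters' input weights do cross zero while
learning to fire when their finger is uninstructed.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `n_hidden` | 400 | neurons | hidden-layer size |
| group fractions | 0.2/0.2/0.2/0.4 | — | focal exc / focal inh / shared CS / RS |
| `hidden_bias_value` | −6 | — | hidden bias scale |
| `output_bias_value` | −1 | — | output bias scale |
| `learning_rate` η | 0.01 | — | gradient step |
| `n_days` | 360 | days | phase length |
| `dosage` | 50/200/50/0 ×90 | reps/day | four equal 90-day blocks (27,000 reps/phase) |
| weight init | N(0.5, 1/12) on (0,1) | — | rejection-sampled truncated normal |
| force grid | 0.4, 0.5, 0.75, 1.0 | fraction of max | default training/evaluation forces |
| severity | per experiment | fraction | per-cluster dead fraction (CS and/or RS) |

The dosage pattern's block lengths are not uniquely determined by its
stated shape; four equal blocks is the package's choice and is
configurable. Task order is a deterministic round-robin (the two
single-instructed commands alternate within a day, forces cycle), so a
(config, seed) pair reproduces every number bit-for-bit. The (−1, −1) and
(1, 1) command pairs are representable but excluded from default training
sets.

## Lesion and recovery

A stroke sets NS = 0 for exactly round(severity × cluster size) neurons per
cluster ("each cluster affected to the same extent"), chosen uniformly at
random under a lesion seed that is independent of the training seed. Dead
neurons are permanently silent: HO = 0, no gradient flows through them, and
their incident weights freeze. Weights themselves are untouched — the
acute deficit is evaluated with zero weight updates.

Recovery retrains with the same schedule at a reduced learning rate. The
reduction rule is *not* specified by the model description beyond
"in accordance with lesion severity"; the default here is linear,
η′ = η·(1 − overall dead fraction), pluggable via
`LesionSpec.plasticity_rule`. This is the single most consequential free
choice in the package (see Limitations).

Because convergence quality depends strongly on the random initialisation,
pre-stroke training uses a restart protocol: deterministically derived
seeds are tried until the mean absolute output error over the final
training day falls below 0.15 (`pretrain`, threshold configurable). This
mirrors the need for several trials to obtain a well-converged healthy
network and is applied uniformly before any lesion comparison.

## Experiments and problem sizes

All protocols run at full scale (N = 400, 27,000 reps per phase; a complete
lifecycle takes ~3 s on one CPU). The packaged defaults are: three 50%
lesion conditions (CS+RS, CS-only, RS-only) trained/evaluated at 100%
force; enslaving slopes from one lifecycle per replicate trained on the
four-level force grid and evaluated per phase; a 10-point severity sweep
sharing one pre-trained network per seed; the weight-change analysis at
65% severity with recovery driven by the Finger-1-instructed command only
(alternating-command recovery is finger-symmetric and cannot produce a
finger-antisymmetric weight pattern); and a noise-robustness grid with
additive zero-mean normal noise on the initial WO (SD 0.05–2.25) and inside
every hidden-activation evaluation (SD 0.01–0.675), compared against the
unperturbed same-seed reference by RMSE, OLS slope and VAF. "Regression
coefficient" is interpreted as the OLS slope of model output on reference
output. Stochastic summaries average five replicate seeds; the test suite
uses three seeds for the severity sweep and toy-scale networks (N = 10–40,
8-day schedules) for exact properties.

## Numerical choices

- Sigmoid via `scipy.special.expit`; outputs are strictly inside (0, 1) for
  finite states, so the individuation index is defined except at exactly
  zero fine-motor sum (flagged, not raised).
- Slope CIs are classical OLS t-intervals (n − 2 df); zero-width on
  noiseless affine data; degenerate abscissae rejected.
- Paired t-tests are per (cluster → output) pairing over surviving,
  connected neurons at α = 0.05 with no multiple-testing correction
  (matching per-pairing reporting); zero-variance differences are reported
  as degenerate rather than p = 0.
- Lesion counts round half up; a request exceeding the alive population is
  clipped with a warning.
- Training aborts with a diagnostic if a day's mean |error| exceeds a
  divergence ceiling (default 10); there is no early stopping — the fixed
  schedule defines the phase end.
- State snapshots are JSON with a SHA-256 payload checksum; floats
  round-trip exactly, so save/load reproduces forward passes bit-for-bit.

## What the simulations do and do not show

The generator *is* the study object here — there is no external data; all
inputs are configuration. Passing tests therefore validate the model's
internal consistency and its qualitative phenomenology (enslaving rises
acutely and partially recedes with retraining; CS lesions hurt
individuation more than RS lesions hurt it; severe lesions recover little),
not correspondence with any patient dataset.

Two structural properties of the implementation are worth stating because
they bound what a faithful rebuild can reproduce:

1. **Acute means are pinned by linearity.** Uniform random per-cluster
   lesioning at severity s scales the expected output-layer drive by
   (1 − s). For a converged network the expected acute instructed output
   after a 50% lesion is therefore σ((x_pre − BO)/2 + BO) ≈ 0.7–0.8 —
   moderate weakening. Individual draws vary widely, but no replicate mean
   under these equations can show an acute collapse of the instructed
   finger to ~33% of maximum; such a value can only be a single
   wide-variance realisation.
2. **Recovery completeness depends on the unspecified plasticity rule.**
   With linear η scaling and the full reused 360-day schedule, the
   lesioned network re-converges almost completely (recovered I ≈ 0.8 after
   a 50% CS+RS lesion), so strongly partial recovery values require a much
   more aggressive η reduction or a shortened recovery dosage, neither of
   which is specified. The rule is exposed as configuration.

## Limitations

Two fingers only; no graded neuron damage, lesion growth, or neurogenesis;
no rubrospinal pathway; static per-trial forces; reinforcement-learning
variants and adaptive optimisers out of scope. The linear plasticity rule
and the four-equal-block dosage are package choices where the model
description is silent, and both materially shape recovery-phase numbers.
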