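# Methods

## Model

`stoverann` fits a fully connected 6-*n*-2 feedforward network mapping six
operating conditions of a dilute-acid pretreatment + enzymatic hydrolysis
of corn stover to the glucose concentration and total phenolic content of
the resulting hydrolysate. The hidden layer uses tanh units and the output
layer is linear — the conventional pairing with [−1, 1] min–max scaling;
both activations are configurable. The Garson importance statistic (below)
uses only absolute weights and is therefore independent of this choice.

Inputs are min–max normalized to [−1, 1],

V′ = (V − V_min) / (V_max − V_min) · (V′_max − V′_min) + V′_min,

with bounds fitted **on the training split only** (standard leakage
avoidance); validation/test values that fall outside the training extremes
are transformed, not clipped. Targets are normalized the same way by
default (`normalize_targets` flag): with a linear output layer this only
affects optimization conditioning, and every reported RMSE is computed
after inverting the transform, i.e. on the original g/L scale.

## Training

Minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), learning rate 0.001,
batch size 2. One *iteration* is one epoch — a full pass over the training
set, reshuffled each epoch with the run seed; the final short batch is kept
(57 samples do not divide by 2). The loss is the plain mean over samples
and both outputs of the squared normalized residual (equal output
weighting). Initial weights are uniform(−0.5, 0.5) with zero biases, from
a seeded generator; all training is bitwise reproducible for a fixed seed.
Backpropagation is implemented directly in numpy and verified against
central finite differences (relative error < 1e−5 in the tests).

RMSE is the standard √(1/m · Σ (y_pred − y_exp)²). The parity evaluation
fits predictions against measurements by ordinary least squares through an
intercept and reports the slope and the coefficient of determination of
that fit.

## Data handling

Runs live in a canonical CSV schema (`run_id, k_IA, C_IA_mol_L, T_C,
t_min, R_SL_frac, E_FPU_g, C_Glc_g_L, C_Phe_g_L`). The solid-to-liquid
ratio is stored as a fraction; readers accept a percent form (a `%` suffix
or a value > 1) and convert. The acid kind is kept as the ordinal code
1/2/3 rather than one-hot, because the network and the importance analysis
treat it as a single variable.

The 75:15:10 split takes ⌊0.75·N⌋ records for training; the remainder is
shared between validation and test in proportion 15:10, validation taking
the rounded (half-up) share. For N = 77 this gives 57/12/8 — the training
count is the anchor; the 12/8 division of the remainder is this package's
convention. Assignment is a seeded uniform shuffle without stratification.

## Architecture search

Candidate hidden sizes follow n = √(i + k) + α with α an integer in a
configured range (default 1–10). Since √8 + α is fractional, the window is
taken from ⌊√(i+k) + α_min⌋ to round-half-up(√(i+k) + α_max); for 6 inputs
and 2 outputs this enumerates the 11 candidates 3–13. An explicit
candidate list can override the rule. Each candidate trains independently
for 500 epochs (default) with its own seed derived deterministically from
(base seed, n), so sweep results do not depend on evaluation order and the
non-monotone RMSE-vs-n patterns typical of independent restarts are
expected. The selected size minimizes the sum over outputs of validation
RMSE divided by that output's observed range — a scale-free way to combine
a g/L-scale error with a sub-g/L one — with ties broken toward the smaller
network. The iteration sweep records train/validation RMSE at fixed
checkpoints of a single run; the final model retrains at a configured
iteration count (default 800, where the validation error has typically
plateaued). There is no early stopping.

## Garson importance

For output k, input i:

I_i = Σ_j [ (|IW_ji| / Σ_i′ |IW_ji′|) · |LW_kj| ] / Σ_i″ Σ_j [ (|IW_ji″| / Σ_i′ |IW_ji′|) · |LW_kj| ].

Biases are excluded (the statistic references only the two weight
matrices). Fractions are reported both unrounded and as round-half-up
integer percents; rounded values are *not* forced to sum to 100. The
implementation is vectorized and tested to 1e−12 against an explicit
nested-loop evaluation; scale invariance (rescaling LW_k, or any single
hidden row of IW) and permutation equivariance are property-tested. The
report also aggregates the five pretreatment variables (everything except
the enzyme dose) into a group subtotal per output.

## Synthetic campaign generator

The generator emulates a 77-run pretreatment/hydrolysis campaign for
pipeline testing. Conditions come from a seeded Latin-hypercube over the
design intervals with uniform acid-code assignment. Outputs derive from a
latent severity

s = 0.45·z(C_IA·p(k_IA)) + 0.25·z(T) + 0.10·z(t) − 0.20·z(R_SL),

where z(·) is min–max scaling over the design space and p maps the acid
code to an effective-strength multiplier (HCl 1.0, H₂SO₄ 1.2, H₃PO₄ 0.7,
reproducing the qualitative glucose ordering H₂SO₄ > HCl > H₃PO₄).
Glucose rises with severity through a concave ramp √(clip(s, 0, 1)) and
saturates in enzyme dose via E/(E + K_E) with K_E = 5 FPU/g; phenolics
follow a logistic 1/(1 + e^{−4(s−0.5)}) in severity alone. Noise is
multiplicative Gaussian with coefficient of variation 0.05 by default,
with the z-score truncated at ±2.5 sd and the result truncated at zero;
runs default to the mean of three simulated replicates. The noiseless
calibration bands (8.6–25.6 g/L glucose before the enzyme factor,
0.85–3.0 g/L phenolics) are set strictly inside the observed measurement
spans (7.5–25 and 0.8–3.0 g/L) so that noisy draws at the default CV stay
inside them; the truncation shrinks the realized CV by about 2%, well
inside the ±20% tolerance of the CV-recovery test.

What the generator does *not* emulate: real campaigns are not
space-filling designs; the acid term couples C_IA and k_IA
multiplicatively, so a network trained on synthetic data spreads the acid
importance across both carrier inputs (the parameter-recovery test
accordingly accepts either carrier at rank one); phenolics here are
independent of enzyme dose, whereas real hydrolysates show an
enzyme-phenolics interaction; and no hemicellulose/lignin solubilization
kinetics (combined severity factors etc.) are modelled. Passing tests on
synthetic data therefore demonstrate that the pipeline recovers the
structure it was given, not that the fitted surface transfers to real corn
stover.

A small forward model of the Folin–Ciocalteu assay is included:
C_Phe = (a · A₇₆₀ / V_s) · N, with a the gallic-acid standard-curve
coefficient, A₇₆₀ the absorbance, V_s the reaction-mixture volume and N
the dilution ratio.

## Pipeline and problem sizes

`run_pipeline` chains load/generate → range validation → split →
normalizer fit → hidden-size sweep → iteration sweep → final training →
test parity → importance report, writing all artifacts with the config
hash and every derived seed; two runs with the same configuration are
byte-identical. The default study size is the 77-run campaign with the
full 3–13 sweep at 500 epochs, a 1000-epoch iteration sweep and an
800-epoch final fit (about 15 s on one core). The test-suite and
determinism checks use scaled-down campaigns (30–50 runs, two candidates,
tens of epochs); the properties they check — partitioning, reproducibility,
oracle equivalence — are size-free. The parameter-recovery acceptance test
uses the full spec: 77 runs at CV 0.02, ten seeds, 6-12-2, 800 epochs.

## Known limitations

* The published weight table is printed to four decimals; importances
  computed from it round to the reported integers, but higher-precision
  internal weights could differ in the second decimal of a percent.
* The ordinal acid code imposes an artificial metric on acid kind
  (H₂SO₄ "between" HCl and H₃PO₄); the importance statistic inherits it.
* Garson importance is a weight-partitioning heuristic, not a causal or
  variance-based sensitivity measure; alternatives (Olden, permutation
  importance) are out of scope.
* With an 8-run test split, parity statistics carry wide sampling
  variability; they are reported as descriptive diagnostics.
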