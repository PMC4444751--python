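# Methods

## Model

`cueret` implements declarative-memory retrieval in the ACT-R tradition as
used in sentence processing.  A retrieval event is a contest among memory
items (chunks): each item *i* is scored

```
A_i = B_i + Σ_j W_j · (S − ln fan'_ji) − MP · m_i + ε_i
```

where the sum runs over the retrieval cues the item matches, `m_i` is the
number of cues it fails to match, `B_i` is its base-level activation, and
`ε_i` is zero-mean logistic noise drawn independently per item per trial.
The item with the highest score is retrieved, and its (noisy) score maps to
a latency `T = latency_unit_scale · LF · e^(−A)`.

Two mechanisms extend the standard equations, both acting on the fan:

**Graded fan (cue confusion).**  For an item matching cue *j*,

```
fan_ji = 1 + Σ_k (1 + Q_jk)
```

where *k* ranges over the feature tokens borne by the *other* items in
memory and `Q_jk ∈ [−1, 0]` is the cue–feature associative strength
(diagonal entries are 0, unstored off-diagonal entries −1).  The leading 1
is the item's own directly matching feature.  At the all-or-nothing limit
(`Q_jk = −1` off the diagonal) this is exactly the classical item count.
The index set — other items' tokens rather than all tokens in memory — is a
deliberate choice: the two conventions agree on every configuration with
single-feature items (including all published worked examples), but the
all-tokens convention lets a fully matching target's own second feature
inflate the fan of its other cue.  Because the prominence correction only
applies when an associated competitor exists, that self-inflation is
asymmetric across conditions that differ only in the distractor, and it
produces spurious facilitatory interference in distractor-mismatch controls.
The other-items convention removes the artifact while preserving the
equations' printed behavior.

**Prominence correction.**  The fan is rescaled by a logistic function of
the target's activation advantage:

```
fan'_ji = fan_ji / (1 + e^(−C(x0 − Diff)))   if C > 0, else fan_ji
```

`Diff` is the difference between the item's activation and the mean
activation of the competitors associated with cue *j* (competitor = any
other item with some feature at `Q_jk > −1` for that cue).  Activations
entering `Diff` are *first-pass* activations: base level plus weighted
spread with the uncorrected fan minus mismatch penalties, with no noise.
This measure is non-circular (the correction never feeds its own input) and
carries cue-match quality, which is what lets a perfectly matching
antecedent escape interference from a partially matching distractor — the
mechanism's central claim.  Using bare base-level activations instead would
make the correction a constant whenever candidates are encoded with equal
salience, i.e. inert in exactly the designs of interest.

Inside the activation composition the corrected fan is floored at 1, so the
spread from a matched cue approaches but never exceeds `S`: under a strong
prominence advantage the dilution term `ln fan'` approaches 0 rather than
turning into an activation bonus.  Without the floor, corrections beyond the
halfway point (`Diff > x0`) convert fan values below 1 into spread *above*
`S`, and a fully matching target in a distractor-match condition ends up
hundreds of ms *faster* than in the distractor-mismatch control — an
overshoot artifact, not reduced interference.  The pure functions
`prominence_multiplier`, `corrected_fan` and `spreading_activation` are
floor-free, so the halved-fan identity (`fan 2 → 1` at `Diff = x0`) and the
above-`S` regime remain available for inspection.

If no competitor is associated with a cue, `Diff` is +∞ by convention and
the correction is skipped (the fan has no competitor contribution to
remove).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `S` (MAS) | 1 | maximum associative strength, ceiling of the spread |
| `LF` | 1.5 | latency factor (reported value; see unit conventions) |
| `ANS` | 1.5 | activation-noise parameter (reported value; see below) |
| `MP` | 1.5 | activation penalty per mismatched cue |
| `C` | 5 | steepness of the prominence correction; 0 disables it |
| `x0` | 1.3 | offset of the correction: the fan is halved at `Diff = x0` |
| `W_j` | 1/#cues | cue weights; total source activation 1 |
| `B_i` | 0 | base-level activation, a direct input (no decay schedule) |
| `latency_exponent` | 1 | exponent on activation in the latency map |
| `latency_unit_scale` | 100 | ms per unit of `LF · e^(−A)` |
| `noise_unit_scale` | 0.1 | logistic noise scale = `noise_unit_scale · ANS` |

**Unit conventions for LF and ANS.**  The package keeps the reported
numerals `LF = ANS = 1.5` as defaults and interprets both through a 0.1
architecture-unit rescale: the effective latency factor is 0.15 s (100 ms
per latency unit) and the effective logistic noise scale is 0.15, the scale
on which the architecture's published simulations operate (latency factor
≈ 0.14–0.15 s; noise ≈ 0.15; `MP = 1.5` is already on that scale).  Two
internal-consistency observations force this reading.  First, at a latency
factor of 1.5 s the model's retrieval latencies are 550–1500 ms against
observed first-pass times of ~260 ms, an order of magnitude off the ms scale
on which its predicted effects are stated.  Second, and decisively, logistic
noise with scale 1.5 makes `e^(−A−ε)` so heavy-tailed that condition means
are dominated by rare extreme trials (for a two-item memory the tail index
is 2/1.5, i.e. infinite variance and near-divergent means): every simulated
interference effect then comes out facilitatory at thousands of ms, and the
model's own signature predictions — inhibitory interference at high cue
confusion, a baseline inhibitory match effect — cannot arise under *any*
tested reading of 1.5 as a noise scale, SD, or variance.  Under the 0.1
rescale all signature patterns emerge, and the predicted antecedent-mismatch
effect at 55% confusion lands at ≈ +20 ms, the size of the observed
first-pass effect.  Both scales are ordinary `ModelParams` fields; setting
`latency_unit_scale=1000, noise_unit_scale=1` recovers the literal seconds
reading.

## Simulation protocol

One `SeedSequence` per condition is split deterministically into one child
stream per trial, so identical (inputs, seed, n) give bit-identical results
and per-trial outcomes are independent of execution order.  Within a sweep
the same seed is reused for every (level × prominence × pair) cell, making
effects paired differences with common noise.  Noise is drawn per item in
ascending item-id order; exact activation ties (probability zero under
noise) resolve to the lowest item id.  Every trial retrieves some item —
there is no retrieval-failure threshold, matching the model's published
predictions, which are condition mean latencies and misretrieval
proportions.  Condition means include misretrieval trials by default
(`run_condition(include_misretrievals=False)` excludes them); the packaged
qualitative predictions hold under both settings.

Default problem sizes: 2000 trials per condition for prediction sweeps
(matching the published protocol) and 10⁵ trials where a Monte-Carlo rate is
checked against the quadrature oracle; at these sizes the full 11-level
sweep runs in a few seconds on one CPU.

## Experiment builders and what they idealize

`build_exp1(antecedent_match, distractor_match)` encodes the single-distractor
eye-tracking design: a c-commanding antecedent (animate or not) and a
structurally inaccessible distractor (animate or not), retrieval cues
{structural, animate} with equal weights.  `build_exp2(distractors_match)`
encodes the memory-load design: a fully matching antecedent plus three
distractors, all animate or all inanimate.  The builders idealize aggressively:

* All items are encoded with equal base-level activation 0.  Real
  subjecthood, topicality, recency or embedding-environment differences in
  distractor salience are not modeled (a config hook allows unequal values).
* The structural requirement (c-command within the binding domain, subject
  orientation) is a single atomic feature; inanimate items carry an inert
  `inanimate` feature with no association to either cue.
* The locality manipulation of the memory-load experiment (local vs
  non-local binding) is not modeled, and no linking function beyond latency
  difference = reading-time effect is assumed.
* Only the two-cue retrieval at the reflexive is simulated — no parsing,
  encoding or decay dynamics.

Consequently, passing tests show that the *mechanisms* produce the claimed
interference landscape under symmetric encoding; they do not show that the
model fits reading-time data quantitatively.  Absolute effect magnitudes
depend on base activations and the latency convention, neither of which is
identified by the published record; only signs, orderings and approximate
magnitudes are meaningful, and the ~55% confusion calibration is treated as
a qualitative landmark, not a fitted constant.

The synthetic fixture generator (`generate_fixture`) emits random small
memory/cue configurations — random feature bundles, base activations in
[−1, 1], random valid `Q` entries — for property tests; it emulates the
*structure* of retrieval problems, not any empirical distribution of
linguistic features.

## Numerical notes

* Logistic noise at scale 0 (ANS = 0) short-circuits to exact zeros.
* `prominence_multiplier` saturates to 0/1 at ±∞ `Diff` and guards the
  exponential overflow region.
* Latency standard errors use the n−1 sample variance; a single-trial
  condition reports SE 0.
* Breakdown components reconstruct totals to < 10⁻¹²; the reduction to the
  original model (C = 0, crossed Q ≡ −1) is bit-exact because both paths
  combine components in the same order.

## Known limitations

* The fan's index-set convention and the first-pass `Diff` measure are the
  package's resolutions of genuinely underdetermined points; alternative
  conventions (all-token fans, base-only `Diff`, no fan floor) are
  constructible through the public functions but are not the packaged
  defaults, for the reasons given above.
* Cue weights are equal by construction in the builders; weighted-cue
  accounts (e.g. structural cues outweighing semantic ones) can be expressed
  via `CueSpec` weights but are untested territory.
* No speed–accuracy decomposition, retrieval-failure modeling, or parameter
  fitting.
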