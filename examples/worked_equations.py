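"""The model's core equations evaluated on small hand-checkable inputs.

Builds a two-item memory (a target bearing the structural feature, a
distractor bearing the animacy feature) and prints the graded fan under
different cue-feature association strengths, the logistic prominence
multiplier, and the activation-to-latency mapping.
"""

from cueret import (
    MemoryItem,
    ModelParams,
    confusable_fan,
    confusion_to_Q,
    corrected_fan,
    prominence_multiplier,
    retrieval_latency,
    spreading_activation,
)

memory = [
    MemoryItem("target", ["c-com"]),
    MemoryItem("distractor", ["animate"]),
]

# Graded fan of the structural cue: the distractor's animacy feature
# contributes 1 + Q to the fan. At Q = -0.5 the fan is 1.5 (interference from
# a feature the distractor does not even share with the cue); at Q = -1 the
# classical value 1.
for level in (50.0, 0.0):
    fan = confusable_fan("c-com", memory, confusion_to_Q(level))
    print(f"fan of +c-com at {level:>5.1f}% cue confusion: {fan}")

# Prominence correction: a logistic in the target's activation advantage.
# At Diff = x0 = 1.3 the fan is halved; far below it is untouched.
params = ModelParams()
for diff in (-2.0, 0.0, 1.3, 3.0):
    m = prominence_multiplier(diff, params.C, params.x0)
    print(f"prominence multiplier at Diff={diff:+.1f}: {m:.4f} "
          f"(fan 2 -> {corrected_fan(2.0, diff, params):.4f})")

# Spreading activation and latency: fan dilutes the spread S - ln(fan), and
# latency decays exponentially in activation (default scale: 100 ms per
# latency unit, i.e. an architecture latency factor of 0.15 s).
for fan in (1.0, 1.5, 2.0, 4.0):
    spread = spreading_activation(fan, params.S)
    print(f"fan {fan}: spread {spread:+.4f}, latency at that activation "
          f"{retrieval_latency(spread, params):.1f} ms")
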