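"""Observed interference effects from the packaged reading-time tables.

Loads the printed condition means of both eye-tracking experiments and prints
the distractor-match minus distractor-mismatch differences for the first-pass
measures at the reflexive, the quantities the model's predictions are
compared against.
"""

from cueret import empirical_effect, load_empirical_table

for exp, slices in ((1, ["antecedent-match", "antecedent-mismatch"]),
                    (2, ["local", "non-local"])):
    table = load_empirical_table(exp)
    print(f"Experiment {exp} (reflexive region):")
    for measure in ("FFD", "FPRT"):
        for sl in slices:
            eff = empirical_effect(table, measure, "reflexive", sl)
            print(f"  {measure:4s} {sl:20s} {eff:+.0f} ms")
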