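"""Unit and property tests for the deterministic activation mathematics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cueret import (
    AssociationMatrix,
    CueSpec,
    MemoryItem,
    ModelParams,
    confusable_fan,
    corrected_fan,
    diff_for_cue,
    prominence_multiplier,
    retrieval_latency,
    spreading_activation,
    total_activation,
)


class TestTypes:
    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MemoryItem("x", ["a", "a"])

    def test_nonfinite_base_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MemoryItem("x", ["a"], base_activation=float("nan"))

    def test_cuespec_defaults_to_equal_weights(self):
        spec = CueSpec(["a", "b"])
        assert spec.weights == (0.5, 0.5)
        assert spec.total_source_activation == pytest.approx(1.0)

    def test_cuespec_requires_cues(self):
        with pytest.raises(ValueError):
            CueSpec([])

    def test_q_range_enforced(self):
        with pytest.raises(ValueError, match=r"\[-1, 0\]"):
            AssociationMatrix({("a", "b"): -1.2})
        with pytest.raises(ValueError, match=r"\[-1, 0\]"):
            AssociationMatrix({("a", "b"): 0.1})

    def test_q_defaults(self):
        q = AssociationMatrix()
        assert q.get("a", "a") == 0.0
        assert q.get("a", "b") == -1.0

    def test_params_defaults_are_the_reported_values(self):
        p = ModelParams()
        assert (p.LF, p.ANS, p.MP, p.S, p.C, p.x0) == (1.5, 1.5, 1.5, 1.0, 5.0, 1.3)


class TestConfusableFan:
    def test_crossed_association_half(self, two_item_memory, crossed_q):
        assert confusable_fan("c-com", two_item_memory, crossed_q) == pytest.approx(1.5)

    def test_no_association_is_original_limit(self, two_item_memory):
        q = AssociationMatrix({("c-com", "animate"): -1.0})
        assert confusable_fan("c-com", two_item_memory, q) == pytest.approx(1.0)

    def test_three_exact_matches(self):
        mem = [MemoryItem(f"i{k}", ["c-com"]) for k in range(3)]
        assert confusable_fan("c-com", mem, AssociationMatrix()) == pytest.approx(3.0)

    def test_per_item_form_matches_global_on_single_feature_items(
        self, two_item_memory, crossed_q
    ):
        g = confusable_fan("c-com", two_item_memory, crossed_q)
        p = confusable_fan(
            "c-com", two_item_memory, crossed_q, exclude_item="antecedent"
        )
        assert g == pytest.approx(p)

    def test_empty_memory_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            confusable_fan("c-com", [], AssociationMatrix())

    @settings(max_examples=50, deadline=None)
    @given(q=st.floats(min_value=-1.0, max_value=0.0))
    def test_monotone_in_association_strength(self, q):
        memory = [MemoryItem("antecedent", ["c-com"]),
                  MemoryItem("distractor", ["animate"])]
        fan = confusable_fan(
            "c-com", memory, AssociationMatrix({("c-com", "animate"): q})
        )
        fan_weaker = confusable_fan(
            "c-com", memory, AssociationMatrix({("c-com", "animate"): -1.0})
        )
        assert fan >= fan_weaker

    def test_monotone_in_memory_inclusion(self, crossed_q):
        small = [MemoryItem("a", ["c-com"])]
        large = small + [MemoryItem("b", ["animate"])]
        assert confusable_fan("c-com", large, crossed_q) >= confusable_fan(
            "c-com", small, crossed_q
        )


class TestProminence:
    def test_half_at_offset(self):
        assert prominence_multiplier(1.3, 5.0, 1.3) == pytest.approx(0.5)

    def test_identity_branch_when_C_zero(self):
        assert prominence_multiplier(123.0, 0.0, 1.3) == 1.0

    def test_saturates_to_one_for_very_negative_diff(self):
        assert abs(prominence_multiplier(-10.0, 5.0, 1.3) - 1.0) < 1e-20

    def test_bounded_and_monotone_on_grid(self):
        grid = [x / 10 for x in range(-50, 51)]
        vals = [prominence_multiplier(d, 5.0, 1.3) for d in grid]
        assert all(0.0 < v < 1.0 for v in vals)
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_corrected_fan_examples(self, default_params):
        assert corrected_fan(2.0, 1.3, default_params) == pytest.approx(1.0)
        p0 = ModelParams(C=0.0)
        assert corrected_fan(2.0, 0.0, p0) == pytest.approx(2.0)
        # closed form evaluated independently: 1.5 / (1 + e^-6.5)
        assert corrected_fan(1.5, 0.0, default_params) == pytest.approx(
            1.4977482266148945, abs=1e-12
        )

    def test_corrected_fan_has_no_floor(self, default_params):
        assert corrected_fan(2.0, 5.0, default_params) < 1.0


class TestSpreadingActivation:
    @pytest.mark.parametrize(
        "fan_prime,S,expected",
        [
            (1.0, 1.0, 1.0),
            (math.e, 1.0, 0.0),
            (1.5, 1.0, 0.5945348918918356),
        ],
    )
    def test_examples(self, fan_prime, S, expected):
        assert spreading_activation(fan_prime, S) == pytest.approx(expected, abs=1e-12)

    def test_exceeds_S_below_unit_fan(self):
        assert spreading_activation(0.5, 1.0) > 1.0

    def test_nonpositive_fan_rejected(self):
        with pytest.raises(ValueError):
            spreading_activation(0.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        f1=st.floats(min_value=0.01, max_value=50.0),
        f2=st.floats(min_value=0.01, max_value=50.0),
    )
    def test_strictly_decreasing(self, f1, f2):
        if f1 < f2:
            assert spreading_activation(f1, 1.0) > spreading_activation(f2, 1.0)


class TestDiffForCue:
    def test_equal_activations(self):
        mem = [MemoryItem("t", ["c"], 1.0), MemoryItem("d", ["c"], 1.0)]
        assert diff_for_cue(mem[0], "c", mem, AssociationMatrix()) == 0.0

    def test_mean_over_associated_competitors(self):
        mem = [
            MemoryItem("t", ["c"], 2.0),
            MemoryItem("d1", ["c"], 1.0),
            MemoryItem("d2", ["c"], 0.0),
            MemoryItem("d3", ["c"], 0.5),
        ]
        assert diff_for_cue(mem[0], "c", mem, AssociationMatrix()) == pytest.approx(1.5)

    def test_no_associated_competitor_gives_inf(self):
        mem = [MemoryItem("t", ["c"], 1.0), MemoryItem("d", ["x"], 5.0)]
        assert diff_for_cue(mem[0], "c", mem, AssociationMatrix()) == math.inf

    def test_target_must_be_in_memory(self):
        mem = [MemoryItem("t", ["c"])]
        with pytest.raises(ValueError, match="not in memory"):
            diff_for_cue(MemoryItem("z", ["c"]), "c", mem, AssociationMatrix())


class TestTotalActivation:
    def test_single_matching_cue(self, default_params):
        mem = [MemoryItem("t", ["c"], 0.0)]
        b = total_activation(mem[0], CueSpec(["c"], [1.0]), mem, default_params)
        assert b.total == pytest.approx(1.0)

    def test_double_mismatch_penalty(self, default_params):
        mem = [MemoryItem("t", ["x"], 0.0), MemoryItem("d", ["c"], 0.0)]
        b = total_activation(mem[0], CueSpec(["c", "a"]), mem, default_params)
        assert b.total == pytest.approx(-3.0)
        assert b.penalty == pytest.approx(-3.0)
        assert b.spread_per_cue == {}

    def test_two_cue_worked_value(self):
        # fans (1.5, 1) via a crossed feature; C = 0 so no correction applies
        params = ModelParams(
            C=0.0, Q=AssociationMatrix({("c-com", "other"): -0.5})
        )
        mem = [
            MemoryItem("t", ["c-com", "animate"], 0.5),
            MemoryItem("d", ["other"], 0.0),
        ]
        b = total_activation(mem[0], CueSpec(["c-com", "animate"]), mem, params)
        assert b.total == pytest.approx(1.2972674459459177, abs=1e-12)

    def test_breakdown_components_sum_to_total(self, default_params, crossed_q):
        params = ModelParams(Q=crossed_q)
        mem = [
            MemoryItem("t", ["c-com"], 0.3),
            MemoryItem("d", ["animate"], -0.2),
        ]
        b = total_activation(
            mem[0], CueSpec(["c-com", "animate"]), mem, params, noise=0.7
        )
        reconstructed = b.base + sum(b.spread_per_cue.values()) + b.penalty + b.noise
        assert abs(reconstructed - b.total) < 1e-12


class TestRetrievalLatency:
    @pytest.mark.parametrize(
        "A,expected",
        [
            (0.0, 1500.0),
            (math.log(1.5), 1000.0),
            (1.0, 551.8191617571636),
        ],
    )
    def test_seconds_scale_examples(self, A, expected):
        params = ModelParams(latency_unit_scale=1000.0)
        assert retrieval_latency(A, params) == pytest.approx(expected, abs=1e-9)

    def test_strictly_decreasing_in_activation(self, default_params):
        lats = [retrieval_latency(a / 4, default_params) for a in range(-8, 9)]
        assert all(x > y for x, y in zip(lats, lats[1:]))


# --- reduction to the original formulation -------------------------------

def original_activation(item, cues, memory, params, noise=0.0):
    """Independently coded original-model activation: integer fan counts,
    no prominence correction, no graded associations.  Components are
    combined base + spread + penalty + noise, the breakdown convention."""
    spreads = []
    mismatches = 0
    for cue, w in zip(cues.cues, cues.weights):
        if item.has(cue):
            fan = sum(1 for m in memory if m.has(cue))
            spreads.append(w * (params.S - math.log(fan)))
        else:
            mismatches += 1
    return item.base_activation + sum(spreads) + (-params.MP * mismatches) + noise


@settings(max_examples=100, deadline=None)
@given(data=st.data())
def test_reduction_to_original_model(data):
    """With C = 0 and all crossed associations at -1 the extended activation
    equals the original formulation bit-for-bit on random configurations."""
    n_items = data.draw(st.integers(1, 5))
    feature_pool = ["f0", "f1", "f2", "f3"]
    memory = []
    for i in range(n_items):
        bundle = data.draw(
            st.sets(st.sampled_from(feature_pool), min_size=1, max_size=4)
        )
        base = data.draw(
            st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)
        )
        memory.append(MemoryItem(f"item{i}", sorted(bundle), base))
    cues = CueSpec(data.draw(st.permutations(feature_pool[:2])))
    params = ModelParams(C=0.0)  # default Q: off-diagonal -1
    noise = data.draw(st.floats(min_value=-2.0, max_value=2.0, allow_nan=False))
    for item in memory:
        extended = total_activation(item, cues, memory, params, noise).total
        assert extended == original_activation(item, cues, memory, params, noise)
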