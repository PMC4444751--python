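import pytest

from cueret import AssociationMatrix, CueSpec, MemoryItem, ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def crossed_q() -> AssociationMatrix:
    """The printed worked-example association: Q(c-com, animate) = -0.5."""
    return AssociationMatrix({("c-com", "animate"): -0.5})


@pytest.fixture
def two_item_memory() -> list[MemoryItem]:
    """Antecedent-mismatch configuration: target matches only the structural
    cue, distractor only the animacy cue."""
    return [
        MemoryItem("antecedent", ["c-com"]),
        MemoryItem("distractor", ["animate"]),
    ]


@pytest.fixture
def both_cues() -> CueSpec:
    return CueSpec(["c-com", "animate"])
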