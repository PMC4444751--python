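"""Domain types and deterministic activation mathematics for cue-based retrieval.

The model is an extension of ACT-R declarative memory retrieval as used in
sentence processing: a retrieval cue spreads activation to every memory item
that matches it, diluted by the *fan* — the amount of material associated
with that cue.  Two extensions are implemented on top of the standard
equations:

* **Cue confusion** — the fan is a graded sum over feature tokens, weighted
  by cue–feature associative strengths ``Q_jk`` on [-1, 0], so that a cue can
  draw interference from features it is merely *associated* with, not only
  from exact matches.
* **Prominence correction** — the fan is rescaled by a logistic function of
  the activation advantage ``Diff`` of the target over the mean of its
  competitors, so that a clearly superior target suffers little
  similarity-based interference.

All functions here are pure and deterministic; Monte-Carlo noise lives in
:mod:`cueret.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FeatureValue",
    "MemoryItem",
    "CueSpec",
    "AssociationMatrix",
    "ModelParams",
    "ActivationBreakdown",
    "confusable_fan",
    "prominence_multiplier",
    "corrected_fan",
    "spreading_activation",
    "diff_for_cue",
    "first_pass_activation",
    "total_activation",
    "retrieval_latency",
]


@dataclass(frozen=True)
class FeatureValue:
    """A symbolic feature borne by a memory item (e.g. ``c-com``, ``animate``).

    ``present=False`` marks an explicitly absent feature; absent features
    never contribute to fans and never satisfy a retrieval cue.
    """

    name: str
    present: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")


@dataclass(frozen=True)
class MemoryItem:
    """A retrievable chunk: identifier, feature bundle, base-level activation.

    Base-level activation is a direct input (default 0); the package does not
    model encoding-time decay schedules.
    """

    id: str
    features: frozenset[FeatureValue] = frozenset()
    base_activation: float = 0.0

    def __init__(
        self,
        id: str,
        features: Iterable[FeatureValue | str] = (),
        base_activation: float = 0.0,
    ) -> None:
        feat_list = [
            f if isinstance(f, FeatureValue) else FeatureValue(f) for f in features
        ]
        names = [f.name for f in feat_list]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate feature names in item {id!r}")
        feats = frozenset(feat_list)
        if not math.isfinite(base_activation):
            raise ValueError(f"base_activation of {id!r} must be finite")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "base_activation", float(base_activation))

    def has(self, feature_name: str) -> bool:
        """True iff the item bears ``feature_name`` with present polarity."""
        return any(f.name == feature_name and f.present for f in self.features)

    def present_features(self) -> list[str]:
        return sorted(f.name for f in self.features if f.present)


@dataclass(frozen=True)
class CueSpec:
    """Ordered retrieval cues with per-cue source-activation weights.

    Weights default to 1/(number of cues) so they sum to a total source
    activation W = 1, the conventional architecture default.
    """

    cues: tuple[str, ...]
    weights: tuple[float, ...]

    def __init__(self, cues: Sequence[str], weights: Sequence[float] | None = None):
        cues = tuple(cues)
        if not cues:
            raise ValueError("at least one retrieval cue is required")
        if len(set(cues)) != len(cues):
            raise ValueError("retrieval cues must be distinct")
        if weights is None:
            weights = tuple(1.0 / len(cues) for _ in cues)
        else:
            weights = tuple(float(w) for w in weights)
            if len(weights) != len(cues):
                raise ValueError("one weight per cue is required")
            if any(w < 0 for w in weights):
                raise ValueError("cue weights must be nonnegative")
        object.__setattr__(self, "cues", cues)
        object.__setattr__(self, "weights", weights)

    @property
    def total_source_activation(self) -> float:
        return sum(self.weights)


class AssociationMatrix:
    """Graded cue–feature associative strengths Q_jk on the scale [-1, 0].

    -1 means no association, 0 maximum association.  Unstored entries default
    to -1, except the diagonal (a cue and its own feature) which defaults
    to 0.  Stored entries are validated into [-1, 0].
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._q: dict[tuple[str, str], float] = {}
        if entries:
            for (j, k), v in entries.items():
                self.set(j, k, v)

    def set(self, cue: str, feature: str, value: float) -> None:
        value = float(value)
        if not -1.0 <= value <= 0.0:
            raise ValueError(
                f"Q({cue!r}, {feature!r}) = {value} outside the range [-1, 0]"
            )
        if cue == feature and value != 0.0:
            raise ValueError(f"diagonal entry Q({cue!r}, {cue!r}) must be 0")
        self._q[(cue, feature)] = value

    def get(self, cue: str, feature: str) -> float:
        if (cue, feature) in self._q:
            return self._q[(cue, feature)]
        return 0.0 if cue == feature else -1.0

    def entries(self) -> dict[tuple[str, str], float]:
        return dict(self._q)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return self._q == other._q

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AssociationMatrix({self._q!r})"


@dataclass(frozen=True)
class ModelParams:
    """All scalar model parameters plus the association matrix.

    Architecture parameters carry the values reported for the Mandarin
    reflexive simulations: latency factor LF = 1.5, activation noise
    ANS = 1.5, mismatch penalty MP = 1.5, maximum associative strength
    S = 1, prominence correction factor C = 5 and offset x0 = 1.3.

    ``noise_unit_scale`` and ``latency_unit_scale`` convert the reported LF
    and ANS numerals into architecture units: the logistic activation-noise
    scale is ``noise_unit_scale * ANS`` and one latency unit is
    ``latency_unit_scale`` milliseconds per unit of ``LF * exp(-A)``.  The
    defaults (0.1 and 100) put retrieval latencies and noise on the scale of
    the underlying sentence-processing architecture (latency factor ~0.15 s,
    noise scale ~0.15), which is the scale on which the model's
    reading-time predictions are stated; see docs/methods.md.  Setting them
    to 1 and 1000 recovers the literal seconds reading of LF and ANS.
    """

    S: float = 1.0
    LF: float = 1.5
    ANS: float = 1.5
    MP: float = 1.5
    C: float = 5.0
    x0: float = 1.3
    Q: AssociationMatrix = field(default_factory=AssociationMatrix)
    latency_exponent: float = 1.0
    latency_unit_scale: float = 100.0
    noise_unit_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.LF <= 0:
            raise ValueError("latency factor LF must be positive")
        if self.ANS < 0:
            raise ValueError("activation noise ANS must be nonnegative")
        if self.MP < 0:
            raise ValueError("mismatch penalty MP must be nonnegative")
        if self.C < 0:
            raise ValueError("prominence correction factor C must be nonnegative")
        if self.latency_unit_scale <= 0 or self.noise_unit_scale < 0:
            raise ValueError("unit scales must be positive")

    @property
    def noise_scale(self) -> float:
        """Scale of the per-item logistic activation noise, in activation units."""
        return self.noise_unit_scale * self.ANS


@dataclass(frozen=True)
class ActivationBreakdown:
    """Per-item decomposition of total activation A_i.

    ``total = base + sum(spread_per_cue.values()) + penalty + noise`` with
    ``penalty <= 0`` (−MP per mismatched cue).
    """

    item_id: str
    base: float
    spread_per_cue: Mapping[str, float]
    penalty: float
    noise: float
    total: float


def _degenerate(memory: Sequence[MemoryItem]) -> None:
    if not memory:
        raise ValueError("degenerate memory configuration: no items")


def confusable_fan(
    cue: str,
    memory: Sequence[MemoryItem],
    Q: AssociationMatrix,
    exclude_item: str | None = None,
) -> float:
    """Graded fan of ``cue``: sum of (1 + Q_jk) over feature tokens in memory.

    With the convention Q_jj = 0, an exactly matching feature contributes 1
    and a fully unassociated feature (Q_jk = -1) contributes 0, so a cue
    whose only crossed association has Q = -0.5 sees a fan of 1.5 where the
    all-or-nothing model sees 1.

    When ``exclude_item`` is given, the per-item form used in the activation
    composition is returned: 1 for the excluded item's own direct match plus
    the graded contributions of *other* items' features.  The two forms agree
    whenever the matching item bears no feature that is crossed-associated
    with the cue (which covers every single-feature item).
    """
    _degenerate(memory)
    total = 0.0
    for item in memory:
        if exclude_item is not None and item.id == exclude_item:
            continue
        for name in item.present_features():
            total += 1.0 + Q.get(cue, name)
    if exclude_item is not None:
        total += 1.0
    return total


def prominence_multiplier(diff: float, C: float, x0: float) -> float:
    """Logistic prominence correction 1/(1 + e^(−C(x0 − Diff))); 1 when C = 0.

    Strictly decreasing in ``diff`` for C > 0 and equal to 0.5 exactly at
    ``diff == x0``.  ``diff`` may be ±inf (saturates to 0 / 1).
    """
    if C < 0:
        raise ValueError("C must be nonnegative")
    if C == 0:
        return 1.0
    if math.isinf(diff):
        return 0.0 if diff > 0 else 1.0
    z = -C * (x0 - diff)
    if z > 700.0:  # avoid overflow; logistic is 0 to double precision anyway
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def corrected_fan(fan: float, diff: float, params: ModelParams) -> float:
    """Prominence-corrected fan': multiplier(Diff) × fan.

    No floor is applied here; fan' may fall below 1, in which case
    :func:`spreading_activation` would exceed S.  The activation composition
    in :func:`total_activation` saturates the corrected fan at 1.
    """
    if fan < 0:
        raise ValueError("fan must be nonnegative")
    return prominence_multiplier(diff, params.C, params.x0) * fan


def spreading_activation(fan_prime: float, S: float) -> float:
    """Spreading activation S_ji = S − ln(fan'_ji)."""
    if fan_prime <= 0:
        raise ValueError(
            "fan' must be positive; a nonpositive fan signals a degenerate "
            "memory configuration upstream"
        )
    return S - math.log(fan_prime)


def _associated(item: MemoryItem, cue: str, Q: AssociationMatrix) -> bool:
    """Item is associated with a cue if any of its features has Q_jk > -1."""
    return any(Q.get(cue, name) > -1.0 for name in item.present_features())


def diff_for_cue(
    target: MemoryItem,
    cue: str,
    memory: Sequence[MemoryItem],
    Q: AssociationMatrix,
    activations: Mapping[str, float] | None = None,
) -> float:
    """Activation advantage Diff = A_target − mean(A of associated competitors).

    Competitors are all items other than the target that are associated with
    the cue (direct feature match or any Q_jk > −1).  By default base-level
    activations are compared; passing ``activations`` substitutes another
    per-item activation measure (the engine passes noise-free first-pass
    activations so that match quality enters the prominence correction).
    Returns +inf when no competitor is associated with the cue; callers skip
    the correction in that case.
    """
    ids = {m.id for m in memory}
    if target.id not in ids:
        raise ValueError(f"target {target.id!r} not in memory")

    def act(item: MemoryItem) -> float:
        if activations is None:
            return item.base_activation
        return activations[item.id]

    comps = [m for m in memory if m.id != target.id and _associated(m, cue, Q)]
    if not comps:
        return math.inf
    return act(target) - sum(act(m) for m in comps) / len(comps)


def first_pass_activation(
    item: MemoryItem,
    cues: CueSpec,
    memory: Sequence[MemoryItem],
    params: ModelParams,
) -> float:
    """Noise-free activation with the *uncorrected* fan.

    This is the match-quality measure that feeds the prominence correction:
    base activation, plus weighted spread S − ln(fan) for each matched cue,
    minus MP for each mismatched cue.  It never depends on the correction
    itself, so the correction is non-circular.
    """
    a = item.base_activation
    for cue, w in zip(cues.cues, cues.weights):
        if item.has(cue):
            fan = confusable_fan(cue, memory, params.Q, exclude_item=item.id)
            a += w * spreading_activation(fan, params.S)
        else:
            a -= params.MP
    return a


def total_activation(
    item: MemoryItem,
    cues: CueSpec,
    memory: Sequence[MemoryItem],
    params: ModelParams,
    noise: float = 0.0,
) -> ActivationBreakdown:
    """Total activation A_i of one item under a retrieval cue set.

    For each cue the item matches it receives weighted spreading activation
    computed from the prominence-corrected confusable fan; for each cue it
    mismatches it is penalized by MP.  The corrected fan is saturated at 1
    (spread never exceeds S): under a strong prominence advantage the
    dilution term ln(fan') approaches 0 rather than turning into a bonus.
    """
    _degenerate(memory)
    fp = {m.id: first_pass_activation(m, cues, memory, params) for m in memory}
    spread: dict[str, float] = {}
    mismatches = 0
    for cue, w in zip(cues.cues, cues.weights):
        if item.has(cue):
            fan = confusable_fan(cue, memory, params.Q, exclude_item=item.id)
            diff = diff_for_cue(item, cue, memory, params.Q, activations=fp)
            if params.C > 0 and math.isfinite(diff):
                fan_prime = corrected_fan(fan, diff, params)
            else:
                fan_prime = fan
            spread[cue] = w * spreading_activation(max(fan_prime, 1.0), params.S)
        else:
            mismatches += 1
    penalty = -params.MP * mismatches
    total = item.base_activation + sum(spread.values()) + penalty + noise
    return ActivationBreakdown(
        item_id=item.id,
        base=item.base_activation,
        spread_per_cue=spread,
        penalty=penalty,
        noise=noise,
        total=total,
    )


def retrieval_latency(A: float, params: ModelParams) -> float:
    """Retrieval latency in ms: latency_unit_scale × LF × e^(−f·A).

    Strictly decreasing in activation.  With the default unit scale of
    100 ms per latency unit, LF = 1.5 corresponds to an architecture latency
    factor of 0.15 s.
    """
    if not math.isfinite(A):
        raise ValueError("activation must be finite")
    return params.latency_unit_scale * params.LF * math.exp(
        -params.latency_exponent * A
    )
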