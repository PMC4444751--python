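"""Seeded Monte-Carlo simulation of retrieval events.

A retrieval trial adds independent logistic activation noise to every memory
item, retrieves the item with the highest total activation, and maps the
winner's (noisy) activation to a latency.  Conditions aggregate trials into
mean latencies, standard errors and misretrieval proportions.

Noise streams: one root :class:`numpy.random.SeedSequence` per condition is
split deterministically into one child per trial, so per-trial results do not
depend on execution order and identical (inputs, seed, n) give bit-identical
results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .memory import (
    ActivationBreakdown,
    CueSpec,
    MemoryItem,
    ModelParams,
    retrieval_latency,
    total_activation,
)

__all__ = [
    "RetrievalOutcome",
    "ConditionResult",
    "run_trial",
    "run_condition",
    "interference_effect",
]


@dataclass(frozen=True)
class RetrievalOutcome:
    """One stochastic retrieval: winner, latency, per-item breakdowns."""

    winner_id: str
    latency_ms: float
    breakdowns: Mapping[str, ActivationBreakdown]
    correct: bool


@dataclass(frozen=True)
class ConditionResult:
    """Monte-Carlo aggregate over n trials of one condition."""

    label: str
    n: int
    mean_latency_ms: float
    se_latency_ms: float
    misretrieval_rate: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.misretrieval_rate <= 1.0:
            raise ValueError("misretrieval rate must lie in [0, 1]")
        if self.se_latency_ms < 0:
            raise ValueError("standard error must be nonnegative")


def _sorted_memory(memory: Sequence[MemoryItem]) -> list[MemoryItem]:
    items = sorted(memory, key=lambda m: m.id)
    if not items:
        raise ValueError("cannot retrieve from an empty memory")
    return items


def _deterministic_breakdowns(
    memory: Sequence[MemoryItem], cues: CueSpec, params: ModelParams
) -> list[ActivationBreakdown]:
    return [total_activation(m, cues, memory, params, noise=0.0) for m in memory]


def _draw_noise(rng: np.random.Generator, k: int, scale: float) -> np.ndarray:
    if scale == 0.0:
        return np.zeros(k)
    return rng.logistic(0.0, scale, size=k)


def run_trial(
    memory: Sequence[MemoryItem],
    cues: CueSpec,
    target_id: str,
    params: ModelParams,
    rng: np.random.Generator,
    _det: Sequence[ActivationBreakdown] | None = None,
) -> RetrievalOutcome:
    """Simulate one retrieval event.

    Noise is drawn independently per item, in ascending item-id order; the
    winner is the item with maximal total activation (exact ties, probability
    zero under noise, go to the lowest item id) and its noisy activation sets
    the latency.
    """
    items = _sorted_memory(memory)
    if target_id not in {m.id for m in items}:
        raise ValueError(f"target {target_id!r} not in memory")
    det = _det if _det is not None else _deterministic_breakdowns(items, cues, params)
    noise = _draw_noise(rng, len(items), params.noise_scale)
    totals = np.array([b.total for b in det]) + noise
    w = int(np.argmax(totals))  # first max = lowest id on exact ties
    breakdowns = {
        b.item_id: ActivationBreakdown(
            item_id=b.item_id,
            base=b.base,
            spread_per_cue=b.spread_per_cue,
            penalty=b.penalty,
            noise=float(noise[i]),
            total=float(totals[i]),
        )
        for i, b in enumerate(det)
    }
    winner = items[w].id
    return RetrievalOutcome(
        winner_id=winner,
        latency_ms=retrieval_latency(float(totals[w]), params),
        breakdowns=breakdowns,
        correct=winner == target_id,
    )


def run_condition(
    memory: Sequence[MemoryItem],
    cues: CueSpec,
    target_id: str,
    params: ModelParams,
    n: int,
    seed: int,
    label: str = "",
    include_misretrievals: bool = True,
) -> ConditionResult:
    """Aggregate ``n`` independent trials of one condition.

    ``include_misretrievals`` controls whether misretrieval trials enter the
    latency mean (they always enter the misretrieval proportion).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    items = _sorted_memory(memory)
    if target_id not in {m.id for m in items}:
        raise ValueError(f"target {target_id!r} not in memory")
    det = _deterministic_breakdowns(items, cues, params)
    det_totals = np.array([b.total for b in det])

    children = np.random.SeedSequence(seed).spawn(n)
    scale = params.noise_scale
    if scale == 0.0:
        noise = np.zeros((n, len(items)))
    else:
        noise = np.stack(
            [np.random.default_rng(c).logistic(0.0, scale, len(items)) for c in children]
        )
    totals = det_totals[None, :] + noise
    winners = totals.argmax(axis=1)
    winner_acts = totals[np.arange(n), winners]
    latencies = (
        params.latency_unit_scale
        * params.LF
        * np.exp(-params.latency_exponent * winner_acts)
    )
    target_idx = next(i for i, m in enumerate(items) if m.id == target_id)
    incorrect = winners != target_idx

    sample = latencies if include_misretrievals else latencies[~incorrect]
    if sample.size == 0:
        raise ValueError("no correct retrievals to average over")
    mean = float(sample.mean())
    se = float(sample.std(ddof=1) / math.sqrt(sample.size)) if sample.size > 1 else 0.0
    return ConditionResult(
        label=label,
        n=n,
        mean_latency_ms=mean,
        se_latency_ms=se,
        misretrieval_rate=float(incorrect.mean()),
        seed=seed,
    )


def interference_effect(match: ConditionResult, mismatch: ConditionResult) -> float:
    """Predicted interference effect in ms: distractor-match − distractor-mismatch.

    Positive values are inhibitory (the cue-matching distractor slows
    retrieval), negative values facilitatory.
    """
    if match.n != mismatch.n:
        warnings.warn(
            "comparing conditions with different trial counts "
            f"({match.n} vs {mismatch.n})",
            stacklevel=2,
        )
    return match.mean_latency_ms - mismatch.mean_latency_ms
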