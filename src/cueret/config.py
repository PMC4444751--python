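"""YAML run configuration: parsing, validation, serialization, fixtures.

A config document has up to four blocks::

    params:      scalar model parameters and Q entries (all optional)
    experiment:  exp1 | exp2 | custom memory/cue description
    sweep:       levels, n, seed, prominence
    output:      path

Unspecified parameters take the packaged defaults.  Unknown keys are
rejected by name; range violations name the field and the bound.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from .experiments import ExperimentCondition, build_exp1, build_exp2
from .memory import AssociationMatrix, CueSpec, MemoryItem, ModelParams

__all__ = [
    "RunConfig",
    "SweepSettings",
    "parse_config",
    "serialize_config",
    "parse_levels",
    "generate_fixture",
]

_PARAM_FIELDS = (
    "S",
    "LF",
    "ANS",
    "MP",
    "C",
    "x0",
    "latency_exponent",
    "latency_unit_scale",
    "noise_unit_scale",
)


@dataclass(frozen=True)
class SweepSettings:
    levels: tuple[float, ...] = tuple(float(x) for x in range(0, 101, 10))
    n: int = 2000
    seed: int = 1
    prominence: str = "both"

    def __post_init__(self) -> None:
        for lv in self.levels:
            if not 0.0 <= lv <= 100.0:
                raise ValueError(f"sweep level {lv} outside [0, 100]")
        if self.n < 1:
            raise ValueError("sweep n must be at least 1")
        if self.prominence not in ("on", "off", "both"):
            raise ValueError("sweep prominence must be 'on', 'off' or 'both'")


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    experiment: ExperimentCondition | None = None
    sweep: SweepSettings = field(default_factory=SweepSettings)
    output_path: str | None = None


def parse_levels(spec: Any) -> tuple[float, ...]:
    """Parse a level grid: a list of percents or 'start:stop:step' (inclusive)."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"level grid {spec!r} is not 'start:stop:step'")
        start, stop, step = (float(p) for p in parts)
        if step <= 0:
            raise ValueError("level grid step must be positive")
        levels = []
        x = start
        while x <= stop + 1e-9:
            levels.append(round(x, 9))
            x += step
        return tuple(levels)
    return tuple(float(x) for x in spec)


def _reject_unknown(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in {where} block")


def _parse_q(qblock: Mapping[str, Any]) -> AssociationMatrix:
    entries: dict[tuple[str, str], float] = {}
    for cue, feats in qblock.items():
        if not isinstance(feats, Mapping):
            raise ValueError(f"Q entry for cue {cue!r} must map features to values")
        for feat, val in feats.items():
            entries[(str(cue), str(feat))] = float(val)
    return AssociationMatrix(entries)


def _parse_params(block: Mapping[str, Any]) -> ModelParams:
    _reject_unknown(block, set(_PARAM_FIELDS) | {"Q"}, "params")
    kwargs: dict[str, Any] = {
        k: float(block[k]) for k in _PARAM_FIELDS if k in block
    }
    if "Q" in block:
        kwargs["Q"] = _parse_q(block["Q"] or {})
    return ModelParams(**kwargs)


def _parse_experiment(block: Mapping[str, Any]) -> ExperimentCondition:
    design = block.get("design")
    if design == "exp1":
        _reject_unknown(
            block, {"design", "antecedent_match", "distractor_match"}, "experiment"
        )
        return build_exp1(
            bool(block.get("antecedent_match", True)),
            bool(block.get("distractor_match", True)),
        )
    if design == "exp2":
        _reject_unknown(block, {"design", "distractors_match"}, "experiment")
        return build_exp2(bool(block.get("distractors_match", True)))
    if design == "custom":
        _reject_unknown(
            block, {"design", "label", "memory", "cues", "weights", "target"},
            "experiment",
        )
        memory = []
        for item in block["memory"]:
            _reject_unknown(item, {"id", "features", "base_activation"}, "memory item")
            memory.append(
                MemoryItem(
                    str(item["id"]),
                    [str(f) for f in item.get("features", [])],
                    float(item.get("base_activation", 0.0)),
                )
            )
        ids = [m.id for m in memory]
        if len(ids) != len(set(ids)):
            raise ValueError("memory item ids must be unique")
        cues = CueSpec(
            [str(c) for c in block["cues"]],
            block.get("weights"),
        )
        return ExperimentCondition(
            str(block.get("label", "custom")), tuple(memory), cues, str(block["target"])
        )
    raise ValueError(f"experiment design must be exp1, exp2 or custom, got {design!r}")


def _parse_sweep(block: Mapping[str, Any]) -> SweepSettings:
    _reject_unknown(block, {"levels", "n", "seed", "prominence"}, "sweep")
    kwargs: dict[str, Any] = {}
    if "levels" in block:
        kwargs["levels"] = parse_levels(block["levels"])
    if "n" in block:
        kwargs["n"] = int(block["n"])
    if "seed" in block:
        kwargs["seed"] = int(block["seed"])
    if "prominence" in block:
        val = block["prominence"]
        if isinstance(val, bool):  # YAML 1.1 reads bare on/off as booleans
            val = "on" if val else "off"
        kwargs["prominence"] = str(val)
    return SweepSettings(**kwargs)


def parse_config(text: str) -> RunConfig:
    """Parse and validate a YAML configuration document."""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, Mapping):
        raise ValueError("config must be a mapping of blocks")
    _reject_unknown(doc, {"params", "experiment", "sweep", "output"}, "top-level")
    params = _parse_params(doc.get("params") or {})
    experiment = (
        _parse_experiment(doc["experiment"]) if doc.get("experiment") else None
    )
    sweep = _parse_sweep(doc.get("sweep") or {})
    output_path = None
    if doc.get("output"):
        _reject_unknown(doc["output"], {"path"}, "output")
        output_path = str(doc["output"]["path"])
    return RunConfig(params, experiment, sweep, output_path)


def _experiment_to_dict(cond: ExperimentCondition) -> dict[str, Any]:
    return {
        "design": "custom",
        "label": cond.label,
        "memory": [
            {
                "id": m.id,
                "features": m.present_features(),
                "base_activation": m.base_activation,
            }
            for m in cond.memory
        ],
        "cues": list(cond.cues.cues),
        "weights": list(cond.cues.weights),
        "target": cond.target_id,
    }


def serialize_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to YAML (lossless round trip)."""
    p = cfg.params
    qdict: dict[str, dict[str, float]] = {}
    for (j, k), v in sorted(p.Q.entries().items()):
        qdict.setdefault(j, {})[k] = v
    doc: dict[str, Any] = {
        "params": {**{f: getattr(p, f) for f in _PARAM_FIELDS}, "Q": qdict},
        "sweep": {
            "levels": list(cfg.sweep.levels),
            "n": cfg.sweep.n,
            "seed": cfg.sweep.seed,
            "prominence": cfg.sweep.prominence,
        },
    }
    if cfg.experiment is not None:
        doc["experiment"] = _experiment_to_dict(cfg.experiment)
    if cfg.output_path is not None:
        doc["output"] = {"path": cfg.output_path}
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False)
    return buf.getvalue()


def generate_fixture(seed: int, n_items: int, n_cues: int) -> str:
    """Emit a random but valid custom configuration (YAML text).

    Feature bundles, base activations in [-1, 1] and Q entries in [-1, 0]
    are drawn from a generator seeded with ``seed``; the same seed always
    yields the identical document, and the document parses with
    :func:`parse_config`.
    """
    if n_items < 1 or n_cues < 1:
        raise ValueError("n_items and n_cues must be at least 1")
    rng = np.random.default_rng(seed)
    n_features = max(n_cues, int(rng.integers(n_cues, n_cues + 3)))
    features = [f"feat{i}" for i in range(n_features)]
    cues = list(rng.choice(features, size=n_cues, replace=False))

    memory = []
    for i in range(n_items):
        k = int(rng.integers(1, n_features + 1))
        bundle = sorted(rng.choice(features, size=k, replace=False))
        memory.append(
            {
                "id": f"item{i}",
                "features": [str(f) for f in bundle],
                "base_activation": round(float(rng.uniform(-1.0, 1.0)), 6),
            }
        )

    qdict: dict[str, dict[str, float]] = {}
    for cue in cues:
        for feat in features:
            if feat != cue and rng.random() < 0.5:
                qdict.setdefault(str(cue), {})[str(feat)] = round(
                    float(rng.uniform(-1.0, 0.0)), 6
                )

    doc = {
        "params": {"Q": qdict},
        "experiment": {
            "design": "custom",
            "label": f"fixture-{seed}",
            "memory": memory,
            "cues": [str(c) for c in cues],
            "target": "item0",
        },
        "sweep": {"n": 100, "seed": int(seed) % (2**31), "prominence": "both"},
    }
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False)
    return buf.getvalue()
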