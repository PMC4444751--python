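"""The two Mandarin-reflexive interference designs and the prediction sweep.

Experiment 1 is a two-item retrieval contest at the reflexive *ziji*: a
c-commanding subject antecedent (animate or inanimate) and a structurally
inaccessible sentence-internal distractor (animate or inanimate).
Experiment 2 keeps a fully matching antecedent and adds three memory-load
distractor nouns (all animate or all inanimate).  Retrieval always uses the
structural cue and the animacy cue with equal weights.

Cue confusion is expressed as a percentage: at level p the crossed
associations between the structural cue and the animacy feature (and vice
versa) are Q = p/100 − 1, so 0% is the classical fully separated cue model
and 100% makes both cues maximally associated with both features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .engine import ConditionResult, interference_effect, run_condition
from .memory import AssociationMatrix, CueSpec, MemoryItem, ModelParams

__all__ = [
    "CUE_STRUCTURAL",
    "CUE_ANIMATE",
    "FEATURE_INANIMATE",
    "ExperimentCondition",
    "SweepResult",
    "EmpiricalTable",
    "confusion_to_Q",
    "build_exp1",
    "build_exp2",
    "default_pairs",
    "sweep_confusion",
    "load_empirical_table",
    "empirical_effect",
]

CUE_STRUCTURAL = "c-com"
CUE_ANIMATE = "animate"
FEATURE_INANIMATE = "inanimate"


@dataclass(frozen=True)
class ExperimentCondition:
    """One simulated condition: memory configuration, cues and target."""

    label: str
    memory: tuple[MemoryItem, ...]
    cues: CueSpec
    target_id: str

    def __post_init__(self) -> None:
        if self.target_id not in {m.id for m in self.memory}:
            raise ValueError(f"target {self.target_id!r} not in memory")


def confusion_to_Q(level: float) -> AssociationMatrix:
    """Map a cue-confusion percentage in [0, 100] to an association matrix.

    Only the crossed structural/animacy entries are raised above −1:
    Q(c-com, animate) = Q(animate, c-com) = level/100 − 1.
    """
    if not 0.0 <= level <= 100.0:
        raise ValueError(f"confusion level {level} outside [0, 100]")
    q = level / 100.0 - 1.0
    return AssociationMatrix(
        {(CUE_STRUCTURAL, CUE_ANIMATE): q, (CUE_ANIMATE, CUE_STRUCTURAL): q}
    )


def _animacy(matches: bool) -> str:
    return CUE_ANIMATE if matches else FEATURE_INANIMATE


def _default_cues() -> CueSpec:
    return CueSpec([CUE_STRUCTURAL, CUE_ANIMATE])


def build_exp1(antecedent_match: bool, distractor_match: bool) -> ExperimentCondition:
    """Two-item memory of Experiment 1.

    The antecedent bears the structural feature and is animate iff
    ``antecedent_match``; the distractor bears no structural feature and is
    animate iff ``distractor_match``.  The antecedent is the designated
    target and base activations are symmetric.
    """
    label = (
        "exp1/antecedent-" + ("match" if antecedent_match else "mismatch")
        + "/distractor-" + ("match" if distractor_match else "mismatch")
    )
    memory = (
        MemoryItem("antecedent", [CUE_STRUCTURAL, _animacy(antecedent_match)]),
        MemoryItem("distractor", [_animacy(distractor_match)]),
    )
    return ExperimentCondition(label, memory, _default_cues(), "antecedent")


def build_exp2(distractors_match: bool) -> ExperimentCondition:
    """Four-item memory of Experiment 2 (antecedent-match only).

    A fully matching animate c-commanding antecedent plus three memory-load
    distractors, each animate iff ``distractors_match`` and none bearing the
    structural feature.
    """
    label = "exp2/distractors-" + ("match" if distractors_match else "mismatch")
    memory = [MemoryItem("antecedent", [CUE_STRUCTURAL, CUE_ANIMATE])]
    for i in range(1, 4):
        memory.append(MemoryItem(f"distractor{i}", [_animacy(distractors_match)]))
    return ExperimentCondition(label, tuple(memory), _default_cues(), "antecedent")


def default_pairs() -> dict[str, tuple[ExperimentCondition, ExperimentCondition]]:
    """The three condition pairs of the prediction figure.

    Each pair is (distractor-match, distractor-mismatch); the interference
    effect is the difference of their mean latencies.
    """
    return {
        "exp1/antecedent-match": (build_exp1(True, True), build_exp1(True, False)),
        "exp1/antecedent-mismatch": (build_exp1(False, True), build_exp1(False, False)),
        "exp2/antecedent-match": (build_exp2(True), build_exp2(False)),
    }


@dataclass(frozen=True)
class SweepResult:
    """Grid of predicted interference effects over confusion levels.

    ``table`` has one row per (level, prominence, condition_pair) with the
    effect in ms, its standard error, trial count and seed.
    """

    table: pd.DataFrame
    params: ModelParams
    seed: int

    def to_csv(self, path) -> None:
        """Write the grid with self-describing '#' metadata header lines."""
        p = self.params
        header = (
            f"# cueret sweep: seed={self.seed}\n"
            f"# params: S={p.S} LF={p.LF} ANS={p.ANS} MP={p.MP} C={p.C} "
            f"x0={p.x0} latency_exponent={p.latency_exponent} "
            f"latency_unit_scale={p.latency_unit_scale} "
            f"noise_unit_scale={p.noise_unit_scale}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.table.to_csv(fh, index=False, float_format="%.9g")


def read_sweep_csv(path) -> pd.DataFrame:
    """Read a sweep CSV back, skipping the metadata header lines."""
    return pd.read_csv(path, comment="#")


def sweep_confusion(
    levels: Sequence[float],
    pairs: Mapping[str, tuple[ExperimentCondition, ExperimentCondition]] | None = None,
    params: ModelParams | None = None,
    n: int = 2000,
    seed: int = 1,
    prominence: str = "both",
) -> SweepResult:
    """Predicted interference effect by cue-confusion level.

    For every level × prominence setting (C as configured vs C = 0) ×
    condition pair, runs ``n`` trials per condition and records the effect
    (distractor-match − distractor-mismatch).  The same seed is reused for
    every condition so that cells are paired (common noise draws) and the
    whole grid is deterministic under (inputs, seed, n).
    """
    if not levels:
        raise ValueError("at least one confusion level is required")
    if prominence not in ("on", "off", "both"):
        raise ValueError("prominence must be 'on', 'off' or 'both'")
    if pairs is None:
        pairs = default_pairs()
    if params is None:
        params = ModelParams()

    settings = {"on": [True], "off": [False], "both": [True, False]}[prominence]
    rows = []
    for level in levels:
        q = confusion_to_Q(level)
        for prom in settings:
            p = replace(params, Q=q, C=params.C if prom else 0.0)
            for pair_label, (cond_m, cond_mm) in pairs.items():
                res_m = run_condition(
                    cond_m.memory, cond_m.cues, cond_m.target_id, p, n, seed,
                    label=cond_m.label,
                )
                res_mm = run_condition(
                    cond_mm.memory, cond_mm.cues, cond_mm.target_id, p, n, seed,
                    label=cond_mm.label,
                )
                rows.append(
                    {
                        "level": float(level),
                        "prominence": "on" if prom else "off",
                        "condition_pair": pair_label,
                        "effect_ms": interference_effect(res_m, res_mm),
                        "se_ms": (res_m.se_latency_ms**2 + res_mm.se_latency_ms**2)
                        ** 0.5,
                        "n": n,
                        "seed": seed,
                    }
                )
    return SweepResult(table=pd.DataFrame(rows), params=params, seed=seed)


@dataclass(frozen=True)
class EmpiricalTable:
    """Printed condition means of one eye-tracking experiment (read-only).

    Cells are keyed by (measure, region, slice, distractor); values are mean
    and standard error in ms (FPRP in %).
    """

    experiment: int
    data: pd.DataFrame

    def cell(self, measure: str, region: str, slice_label: str, distractor: str):
        sel = self.data[
            (self.data["measure"] == measure)
            & (self.data["region"] == region)
            & (self.data["slice"] == slice_label)
            & (self.data["distractor"] == distractor)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"no cell (experiment={self.experiment}, measure={measure!r}, "
                f"region={region!r}, slice={slice_label!r}, "
                f"distractor={distractor!r})"
            )
        row = sel.iloc[0]
        return float(row["mean"]), float(row["se"])


def load_empirical_table(experiment: int) -> EmpiricalTable:
    """Load the packaged condition means for experiment 1 or 2."""
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    with resources.files("cueret.data").joinpath("empirical_means.csv").open() as fh:
        df = pd.read_csv(fh)
    return EmpiricalTable(experiment, df[df["experiment"] == experiment].copy())


def empirical_effect(
    table: EmpiricalTable, measure: str, region: str, slice_label: str
) -> float:
    """Observed interference effect: distractor-match − distractor-mismatch.

    Computed from the printed condition means within the stated antecedent
    (experiment 1) or locality (experiment 2) slice.
    """
    match, _ = table.cell(measure, region, slice_label, "match")
    mismatch, _ = table.cell(measure, region, slice_label, "mismatch")
    return match - mismatch
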