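"""In silico patient simulation: the preclinical validation protocol.

Virtual patients answer 15 successive scorings. Three answer patterns are
supported for a chosen target dimension (all other dimensions are held at
their lowest-severity answers so cross-dimension effects stay isolated):

* ``constant_lowest`` — every scoring at the lowest severity;
* ``immediate_worsening`` — lowest for the first ``onset − 1`` scorings,
  then a jump to the highest-severity answers from ``onset`` to the end;
* ``progressive_worsening`` — lowest before onset, then the underlying
  true level ramps linearly from lowest to highest across
  ``onset..n_steps``.

Answers are either the deterministic extreme answer for the current true
level, or sampled from P(answer | IF = true level) with a fixed seed.
Trajectories log every answer set and belief state and are exportable as
CSV tables for expert review.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .engine import AnswerSet, BeliefState, init_belief, step
from .errors import ScenarioError
from .levels import LEVEL_NAMES, N_LEVELS, LevelDistribution, SeverityLevel
from .model import ContextProfile, ModelSpec

__all__ = [
    "PATTERNS",
    "ScenarioSpec",
    "TrajectoryRecord",
    "generate_answer_sequence",
    "run_scenario",
    "extreme_profiles",
    "convergence_steps",
    "export_review_tables",
    "load_scenario",
]

PATTERNS = ("constant_lowest", "immediate_worsening", "progressive_worsening")
ANSWER_MODES = ("deterministic_extreme", "sampled")


@dataclass(frozen=True)
class ScenarioSpec:
    """One in silico patient protocol."""

    pattern: str
    target_dimension: str
    context: ContextProfile
    n_steps: int = 15
    onset_step: int = 10
    answer_mode: str = "deterministic_extreme"
    seed: int = 0

    def validate(self, model: ModelSpec) -> None:
        if self.pattern not in PATTERNS:
            raise ScenarioError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.answer_mode not in ANSWER_MODES:
            raise ScenarioError(f"unknown answer mode {self.answer_mode!r}")
        if not 1 <= self.onset_step <= self.n_steps:
            raise ScenarioError(
                f"onset step {self.onset_step} outside 1..{self.n_steps}"
            )
        try:
            model.dimension(self.target_dimension)
        except KeyError as exc:
            raise ScenarioError(str(exc)) from exc

    def as_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "target_dimension": self.target_dimension,
            "context": self.context.key,
            "n_steps": self.n_steps,
            "onset_step": self.onset_step,
            "answer_mode": self.answer_mode,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-step log of one simulated patient: answers in, belief out."""

    scenario: ScenarioSpec
    initial: BeliefState
    answers: tuple[AnswerSet, ...]
    states: tuple[BeliefState, ...]
    model_version: str = ""

    def __post_init__(self):
        if len(self.answers) != len(self.states):
            raise ValueError("answers and states must have matching lengths")
        object.__setattr__(self, "answers", tuple(self.answers))
        object.__setattr__(self, "states", tuple(self.states))

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[BeliefState]:
        return iter(self.states)

    def state_at(self, step_no: int) -> BeliefState:
        """Belief state after scoring ``step_no`` (1-based); 0 = a priori."""
        if step_no == 0:
            return self.initial
        return self.states[step_no - 1]

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario.as_dict(),
            "model_version": self.model_version,
            "initial": self.initial.as_dict(),
            "steps": [
                {"answers": a.as_dict(), "state": s.as_dict()}
                for a, s in zip(self.answers, self.states)
            ],
        }


def _true_level(scenario: ScenarioSpec, t: int) -> int:
    """Underlying severity level of the target dimension at scoring t."""
    if scenario.pattern == "constant_lowest" or t < scenario.onset_step:
        return 0
    if scenario.pattern == "immediate_worsening":
        return N_LEVELS - 1
    # progressive: linear ramp in level index across onset..n_steps
    onset, n = scenario.onset_step, scenario.n_steps
    if n == onset:
        return N_LEVELS - 1
    return int(round((N_LEVELS - 1) * (t - onset) / (n - onset)))


def generate_answer_sequence(model: ModelSpec, scenario: ScenarioSpec) -> list[AnswerSet]:
    """The per-scoring answer sets a virtual patient produces.

    Deterministic-extreme mode answers every question of the target
    dimension at the index of the current true level; sampled mode draws
    each answer from P(answer | IF = true level) with the scenario seed, so
    repeated calls give identical sequences. Non-target dimensions always
    answer at the lowest severity.
    """
    scenario.validate(model)
    rng = np.random.default_rng(scenario.seed)
    sequence = []
    for t in range(1, scenario.n_steps + 1):
        level = _true_level(scenario, t)
        answers: dict[str, int] = {}
        for q in model.questions:
            if q.dimension_id != scenario.target_dimension:
                answers[q.id] = 0
            elif scenario.answer_mode == "deterministic_extreme":
                answers[q.id] = level
            else:
                answers[q.id] = int(rng.choice(N_LEVELS, p=q.likelihood[level]))
        sequence.append(AnswerSet(step=t, answers=answers))
    return sequence


def run_scenario(model: ModelSpec, scenario: ScenarioSpec) -> TrajectoryRecord:
    """Initialize, feed every generated answer set through the engine, log all."""
    scenario.validate(model)
    answer_sets = generate_answer_sequence(model, scenario)
    initial = init_belief(model, scenario.context)
    states = []
    state = initial
    for answers in answer_sets:
        state = step(model, state, answers)
        states.append(state)
    return TrajectoryRecord(
        scenario=scenario,
        initial=initial,
        answers=tuple(answer_sets),
        states=tuple(states),
        model_version=str(model.metadata.get("version", "")),
    )


def extreme_profiles(
    model: ModelSpec, dimension_id: str, context: ContextProfile
) -> tuple[LevelDistribution, LevelDistribution, LevelDistribution]:
    """(a priori, P(++), P(−−)) state distributions for one dimension.

    P(++) is the posterior when every question of the dimension is answered
    at the highest severity, P(−−) with every answer at the lowest; both
    start from the context prior.
    """
    from .engine import if_posterior

    dim = model.dimension(dimension_id)
    prior = dim.prior_for(context)

    def _post(answer_idx: int) -> LevelDistribution:
        answers = AnswerSet(step=1, answers={qid: answer_idx for qid in dim.question_ids})
        return if_posterior(model, dimension_id, prior, answers)

    return prior, _post(N_LEVELS - 1), _post(0)


def convergence_steps(trajectory: TrajectoryRecord) -> int:
    """Smallest scoring s after which the full advice ranking never changes.

    The ranking at every step ≥ s equals the ranking at the final step; a
    trajectory whose ranking never moves returns 1.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    final = trajectory.states[-1].ranking()
    s = len(trajectory)  # final step always matches itself
    for t in range(len(trajectory) - 1, 0, -1):
        if trajectory.states[t - 1].ranking() != final:
            break
        s = t
    return s


def export_review_tables(trajectory: TrajectoryRecord, path: "str | os.PathLike") -> list[str]:
    """Write the expert-review artifacts; returns the written file paths.

    ``states.csv`` holds per step and dimension the IF distribution
    (positive) and the CS distribution (negated, the plotting convention
    that puts immediate state above zero and contextual severity below);
    ``advice.csv`` the absolute and normalized advice scores;
    ``trajectory.json`` the full bundle. Re-export is byte-identical.
    """
    os.makedirs(path, exist_ok=True)
    states_path = os.path.join(path, "states.csv")
    advice_path = os.path.join(path, "advice.csv")
    bundle_path = os.path.join(path, "trajectory.json")

    with open(states_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["step", "dimension"]
            + [f"if_{n}" for n in LEVEL_NAMES]
            + [f"cs_{n}" for n in LEVEL_NAMES]
        )
        for state in trajectory.states:
            for dim_id, belief in state.dimensions.items():
                writer.writerow(
                    [state.step, dim_id]
                    + [f"{belief.if_posterior[lvl]:.10g}" for lvl in SeverityLevel]
                    + [f"{-belief.cs[lvl]:.10g}" for lvl in SeverityLevel]
                )

    with open(advice_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        advice_ids = list(trajectory.initial.advice_absolute)
        writer.writerow(
            ["step"]
            + [f"abs_{a}" for a in advice_ids]
            + [f"norm_{a}" for a in advice_ids]
        )
        for state in trajectory.states:
            writer.writerow(
                [state.step]
                + [f"{state.advice_absolute[a]:.10g}" for a in advice_ids]
                + [f"{state.advice_normalized[a]:.10g}" for a in advice_ids]
            )

    with open(bundle_path, "w", encoding="utf-8") as fh:
        json.dump(trajectory.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    return [states_path, advice_path, bundle_path]


def load_scenario(path: "str | os.PathLike") -> ScenarioSpec:
    """Read a scenario document (YAML/JSON)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ScenarioError(f"{path}: scenario document must be a mapping")
    try:
        return ScenarioSpec(
            pattern=doc["pattern"],
            target_dimension=doc["target_dimension"],
            context=ContextProfile.from_key(doc["context"]),
            n_steps=int(doc.get("n_steps", 15)),
            onset_step=int(doc.get("onset_step", 10)),
            answer_mode=doc.get("answer_mode", "deterministic_extreme"),
            seed=int(doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ScenarioError(f"{path}: missing required key {exc}") from exc
    except ValueError as exc:
        raise ScenarioError(f"{path}: {exc}") from exc
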