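"""Knowledge-base data model: structure plus all elicited probability tables.

A model is the pair *B = [G, Θ]*: the directed structure *G* is implied by
the parent lists (context → IF, IF → questions, (IF, CF) → CS, CS → advice)
and Θ is the collection of conditional tables elicited from the expert panel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ModelValidationError
from .levels import LEVEL_NAMES, N_LEVELS, LevelDistribution, SeverityLevel

__all__ = [
    "ContextProfile",
    "CONTEXTS",
    "QuestionSpec",
    "DimensionSpec",
    "AdviceSpec",
    "ModelSpec",
    "Violation",
    "validate_model",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ContextProfile:
    """Patient context used to select a priori state distributions.

    Only age and gender enter the model; the four combinations are the four
    rows of the elicited prior table.
    """

    gender: str  # "man" | "woman"
    age_group: str  # "under_18" | "over_18"

    def __post_init__(self):
        if self.gender not in ("man", "woman"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.age_group not in ("under_18", "over_18"):
            raise ValueError(f"unknown age group {self.age_group!r}")

    @property
    def key(self) -> str:
        return f"{self.gender}_{self.age_group}"

    @classmethod
    def from_key(cls, key: str) -> "ContextProfile":
        gender, _, age = key.partition("_")
        return cls(gender=gender, age_group=age)

    def __str__(self) -> str:
        return self.key


#: the four admissible profiles, in the elicitation table's order
CONTEXTS = (
    ContextProfile("man", "over_18"),
    ContextProfile("man", "under_18"),
    ContextProfile("woman", "over_18"),
    ContextProfile("woman", "under_18"),
)


@dataclass(frozen=True, eq=False)
class QuestionSpec:
    """One four-level question attached to a clinical dimension.

    ``likelihood`` holds P(answer = j | IF = k) as a (4, 4) array with
    ``likelihood[k, j]`` the probability of answer *j* given latent level *k*;
    each row (fixed latent level) sums to 1. ``vas_thresholds`` are the three
    increasing cut points binning a 0–100 visual-analog score into the four
    answer bins.
    """

    id: str
    dimension_id: str
    text: str
    answer_labels: tuple[str, str, str, str]
    likelihood: np.ndarray
    vas_thresholds: tuple[float, float, float] = (25.0, 50.0, 75.0)

    def __post_init__(self):
        lik = np.asarray(self.likelihood, dtype=float)
        lik.setflags(write=False)
        object.__setattr__(self, "likelihood", lik)
        object.__setattr__(self, "answer_labels", tuple(self.answer_labels))
        object.__setattr__(self, "vas_thresholds", tuple(float(t) for t in self.vas_thresholds))

    def __eq__(self, other) -> bool:
        if not isinstance(other, QuestionSpec):
            return NotImplemented
        return (
            self.id == other.id
            and self.dimension_id == other.dimension_id
            and self.text == other.text
            and self.answer_labels == other.answer_labels
            and self.vas_thresholds == other.vas_thresholds
            and np.array_equal(self.likelihood, other.likelihood)
        )

    def __hash__(self):
        return hash((self.id, self.dimension_id, self.likelihood.tobytes()))

    def answer_likelihood(self, answer: int) -> np.ndarray:
        """P(this answer | IF = k) for every latent level k, absent..high."""
        return self.likelihood[:, answer]

    def bin_vas(self, score: float) -> int:
        """Map a visual-analog score in [0, 100] to an answer index 0..3.

        A score equal to a cut point falls in the upper bin.
        """
        if not 0.0 <= score <= 100.0:
            raise ValueError(f"VAS score {score} outside [0, 100]")
        return int(np.searchsorted(np.asarray(self.vas_thresholds), score, side="right"))


@dataclass(frozen=True)
class DimensionSpec:
    """One clinical dimension: context-conditional prior and severity table.

    ``prior`` maps each context key (e.g. ``man_over_18``) to P(IF | context).
    ``severity_cpt`` maps a (CF level, IF level) pair to the distribution of
    contextual severity P(CS | IF, CF).
    """

    id: str
    name: str
    prior: Mapping[str, LevelDistribution]
    severity_cpt: Mapping[tuple[SeverityLevel, SeverityLevel], LevelDistribution]
    question_ids: tuple[str, ...] = ()
    provenance: str = "elicited"

    def __post_init__(self):
        object.__setattr__(self, "prior", dict(self.prior))
        object.__setattr__(
            self,
            "severity_cpt",
            {
                (SeverityLevel(cf), SeverityLevel(if_)): dist
                for (cf, if_), dist in self.severity_cpt.items()
            },
        )
        object.__setattr__(self, "question_ids", tuple(self.question_ids))

    def prior_for(self, context: ContextProfile) -> LevelDistribution:
        return self.prior[context.key]

    def severity_row(self, cf: SeverityLevel, if_: SeverityLevel) -> LevelDistribution:
        return self.severity_cpt[(SeverityLevel(cf), SeverityLevel(if_))]


@dataclass(frozen=True)
class AdviceSpec:
    """One piece of advice with a noisy-OR dependence on parent severities.

    ``activation[(dim_id, level)]`` is the probability that the parent
    dimension at that contextual-severity level makes this advice relevant on
    its own; an unlisted (dim, level) pair — in particular severity *absent* —
    activates with probability 0. ``leak`` is the background probability that
    the advice is relevant with no active cause. The noisy-OR form keeps the
    elicitation burden linear in the number of parents (3 non-absent levels
    per parent + 1 leak = 3p + 1 free parameters, versus 4^p full-table rows).
    """

    id: str
    name: str
    parent_dimension_ids: tuple[str, ...]
    activation: Mapping[tuple[str, SeverityLevel], float]
    leak: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "parent_dimension_ids", tuple(self.parent_dimension_ids))
        object.__setattr__(
            self,
            "activation",
            {(d, SeverityLevel(lvl)): float(p) for (d, lvl), p in self.activation.items()},
        )

    def activation_for(self, dimension_id: str, level: SeverityLevel | int) -> float:
        return self.activation.get((dimension_id, SeverityLevel(level)), 0.0)

    def activation_vector(self, dimension_id: str) -> np.ndarray:
        """Activation per severity level, absent..high, zeros where unlisted."""
        return np.array(
            [self.activation_for(dimension_id, lvl) for lvl in SeverityLevel], dtype=float
        )

    @property
    def n_free_parameters(self) -> int:
        """Stored parameters under the noisy-OR parameterization: 3p + 1."""
        return 3 * len(self.parent_dimension_ids) + 1


@dataclass(frozen=True)
class ModelSpec:
    """The full knowledge base: dimensions, questions, advice and α."""

    dimensions: tuple[DimensionSpec, ...]
    questions: tuple[QuestionSpec, ...]
    advice: tuple[AdviceSpec, ...]
    alpha: float = 0.5
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        object.__setattr__(self, "questions", tuple(self.questions))
        object.__setattr__(self, "advice", tuple(self.advice))
        object.__setattr__(self, "metadata", dict(self.metadata))

    # -- lookups -----------------------------------------------------------
    def dimension(self, dim_id: str) -> DimensionSpec:
        for d in self.dimensions:
            if d.id == dim_id:
                return d
        raise KeyError(f"unknown dimension {dim_id!r}")

    def question(self, question_id: str) -> QuestionSpec:
        for q in self.questions:
            if q.id == question_id:
                return q
        raise KeyError(f"unknown question {question_id!r}")

    def advice_by_id(self, advice_id: str) -> AdviceSpec:
        for a in self.advice:
            if a.id == advice_id:
                return a
        raise KeyError(f"unknown advice {advice_id!r}")

    def questions_for(self, dim_id: str) -> tuple[QuestionSpec, ...]:
        return tuple(q for q in self.questions if q.dimension_id == dim_id)

    def with_alpha(self, alpha: float) -> "ModelSpec":
        return dataclasses.replace(self, alpha=alpha)

    def validated(self) -> "ModelSpec":
        report = validate_model(self)
        if report:
            raise ModelValidationError(report)
        return self


@dataclass(frozen=True)
class Violation:
    """One invariant violation: where it is, which rule, and what happened."""

    path: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: [{self.rule}] {self.message}"

    def as_dict(self) -> dict[str, str]:
        return {"path": self.path, "rule": self.rule, "message": self.message}


def _check_dist(report, path, probs) -> None:
    p = np.asarray(probs, dtype=float)
    if np.any(p < -_SUM_TOL) or np.any(p > 1 + _SUM_TOL):
        report.append(Violation(path, "range", f"entries outside [0,1]: {p.tolist()}"))
    if abs(float(p.sum()) - 1.0) > _SUM_TOL:
        report.append(Violation(path, "normalization", f"sums to {p.sum():.12f}, not 1"))


def validate_model(model: ModelSpec) -> list[Violation]:
    """Check every structural and probabilistic invariant of a knowledge base.

    Returns an empty list iff the model is valid; otherwise one
    :class:`Violation` per broken invariant, with its location. Nothing is
    repaired silently.
    """
    report: list[Violation] = []

    if not 0.0 <= model.alpha <= 1.0:
        report.append(Violation("alpha", "range", f"forgetting factor {model.alpha} not in [0,1]"))

    for kind, ids in (
        ("dimensions", [d.id for d in model.dimensions]),
        ("questions", [q.id for q in model.questions]),
        ("advice", [a.id for a in model.advice]),
    ):
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            report.append(Violation(kind, "unique-ids", f"duplicate ids {sorted(dupes)}"))

    dim_ids = {d.id for d in model.dimensions}
    q_by_id = {q.id: q for q in model.questions}

    for d in model.dimensions:
        base = f"dimensions.{d.id}"
        for ctx in CONTEXTS:
            if ctx.key not in d.prior:
                report.append(Violation(f"{base}.prior", "context-coverage", f"missing {ctx.key}"))
            else:
                _check_dist(report, f"{base}.prior.{ctx.key}", d.prior[ctx.key].probs)
        extra = set(d.prior) - {c.key for c in CONTEXTS}
        if extra:
            report.append(
                Violation(f"{base}.prior", "context-coverage", f"unknown contexts {sorted(extra)}")
            )
        for cf in SeverityLevel:
            for if_ in SeverityLevel:
                key = (cf, if_)
                if key not in d.severity_cpt:
                    report.append(
                        Violation(
                            f"{base}.severity_cpt",
                            "cpt-coverage",
                            f"missing row cf={cf.label}, if={if_.label}",
                        )
                    )
                else:
                    _check_dist(
                        report,
                        f"{base}.severity_cpt[cf={cf.label},if={if_.label}]",
                        d.severity_cpt[key].probs,
                    )
        if not d.question_ids:
            report.append(Violation(base, "questions-nonempty", "dimension has no questions"))
        for qid in d.question_ids:
            if qid not in q_by_id:
                report.append(
                    Violation(base, "dangling-reference", f"question {qid!r} does not exist")
                )
            elif q_by_id[qid].dimension_id != d.id:
                report.append(
                    Violation(
                        base,
                        "cross-reference",
                        f"question {qid!r} belongs to {q_by_id[qid].dimension_id!r}",
                    )
                )

    for q in model.questions:
        base = f"questions.{q.id}"
        if q.dimension_id not in dim_ids:
            report.append(
                Violation(base, "dangling-reference", f"dimension {q.dimension_id!r} missing")
            )
        else:
            owner = model.dimension(q.dimension_id)
            if q.id not in owner.question_ids:
                report.append(
                    Violation(base, "cross-reference", f"not listed by {q.dimension_id!r}")
                )
        if q.likelihood.shape != (N_LEVELS, N_LEVELS):
            report.append(
                Violation(base, "shape", f"likelihood shape {q.likelihood.shape}, expected (4,4)")
            )
        else:
            for k, lvl in enumerate(LEVEL_NAMES):
                _check_dist(report, f"{base}.likelihood[if={lvl}]", q.likelihood[k])
        th = q.vas_thresholds
        if len(th) != 3 or not (0 < th[0] < th[1] < th[2] < 100):
            report.append(
                Violation(
                    base,
                    "vas-thresholds",
                    f"{th} must be 3 strictly increasing cut points in (0, 100)",
                )
            )

    for a in model.advice:
        base = f"advice.{a.id}"
        if not a.parent_dimension_ids:
            report.append(Violation(base, "parents-nonempty", "advice has no parent dimensions"))
        for pd in a.parent_dimension_ids:
            if pd not in dim_ids:
                report.append(
                    Violation(base, "dangling-reference", f"parent dimension {pd!r} missing")
                )
        for (pd, lvl), p in a.activation.items():
            if pd not in a.parent_dimension_ids:
                report.append(
                    Violation(base, "activation-parent", f"activation for non-parent {pd!r}")
                )
            if not 0.0 <= p <= 1.0:
                report.append(
                    Violation(base, "range", f"activation({pd},{lvl.label})={p} not in [0,1]")
                )
        if not 0.0 <= a.leak <= 1.0:
            report.append(Violation(base, "range", f"leak {a.leak} not in [0,1]"))
        # monotone elicitation: a worse severity never activates less
        for pd in a.parent_dimension_ids:
            vec = a.activation_vector(pd)
            for lo, hi in zip(SeverityLevel, list(SeverityLevel)[1:]):
                if vec[hi] < vec[lo] - _SUM_TOL:
                    report.append(
                        Violation(
                            base,
                            "activation-monotone",
                            f"activation({pd},{hi.label})={vec[hi]} < "
                            f"activation({pd},{lo.label})={vec[lo]}",
                        )
                    )

    return report
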