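"""One full belief-update cycle per scoring.

For every clinical dimension the engine maintains three quantities on the
shared four-level domain:

* **IF** — the immediate state, a naive-Bayes posterior combining the
  current prior with this scoring's answers (answers are conditionally
  independent given IF);
* **CF** — the cumulated state, an exponentially forgetting aggregate
  ``CF_new = (1 − α)·IF + α·CF_old`` applied elementwise to the two
  distribution vectors;
* **CS** — the contextual severity, marginalized through the elicited
  P(CS | IF, CF) table treating IF and CF as independent inputs within the
  step (their coupling lives entirely in the CF recurrence).

Advice relevance is scored with the noisy-OR model over the parent
dimensions' CS distributions, then normalized across all advice to a
relative ranking.

Within a step the IF posterior uses the *current CF* as its prior (the
static context prior applies only at step 0), so a patient's habitual state
shapes how new answers are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ContextError, InconsistentEvidenceError, ParameterError
from .levels import LevelDistribution, N_LEVELS, SeverityLevel
from .model import CONTEXTS, AdviceSpec, ContextProfile, DimensionSpec, ModelSpec

__all__ = [
    "AnswerSet",
    "DimensionBelief",
    "BeliefState",
    "init_belief",
    "if_posterior",
    "cf_update",
    "cs_infer",
    "advice_score",
    "normalize_advice",
    "advice_ranking",
    "step",
]


@dataclass(frozen=True)
class AnswerSet:
    """The answers of one scoring session.

    ``answers`` maps a question id to either an integer answer index in
    0..3 (int) or a raw visual-analog score in [0, 100] (float), which is
    binned through that question's ``vas_thresholds``. ``step`` is the
    1-based scoring number.
    """

    step: int
    answers: Mapping[str, "int | float"] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "answers", dict(self.answers))

    def resolved(self, model: ModelSpec) -> dict[str, int]:
        """Answer indices per question, with VAS floats binned."""
        out: dict[str, int] = {}
        for qid, value in self.answers.items():
            q = model.question(qid)  # raises KeyError for unknown ids
            if isinstance(value, bool):
                raise ValueError(f"{qid}: boolean is not a valid answer")
            if isinstance(value, int) or (isinstance(value, np.integer)):
                idx = int(value)
                if not 0 <= idx < N_LEVELS:
                    raise ValueError(f"{qid}: answer index {idx} outside 0..{N_LEVELS - 1}")
            else:
                idx = q.bin_vas(float(value))
            out[qid] = idx
        return out

    def as_dict(self) -> dict:
        return {"step": self.step, "answers": dict(self.answers)}


@dataclass(frozen=True)
class DimensionBelief:
    """Posterior state of one dimension after a scoring."""

    if_posterior: LevelDistribution
    cf: LevelDistribution
    cs: LevelDistribution

    def as_dict(self) -> dict:
        return {
            "if": self.if_posterior.as_dict(),
            "cf": self.cf.as_dict(),
            "cs": self.cs.as_dict(),
        }


@dataclass(frozen=True)
class BeliefState:
    """Full engine state after scoring ``step`` (0 = a priori)."""

    step: int
    context: ContextProfile
    dimensions: Mapping[str, DimensionBelief]
    advice_absolute: Mapping[str, float]
    advice_normalized: Mapping[str, float]
    degenerate_advice: bool = False

    def __post_init__(self):
        object.__setattr__(self, "dimensions", dict(self.dimensions))
        object.__setattr__(self, "advice_absolute", dict(self.advice_absolute))
        object.__setattr__(self, "advice_normalized", dict(self.advice_normalized))

    def ranking(self) -> tuple[str, ...]:
        """Advice ids by descending absolute score; ties keep model order."""
        ids = list(self.advice_absolute)
        return tuple(sorted(ids, key=lambda a: (-self.advice_absolute[a], ids.index(a))))

    def as_dict(self) -> dict:
        return {
            "step": self.step,
            "context": self.context.key,
            "dimensions": {d: b.as_dict() for d, b in self.dimensions.items()},
            "advice": {
                a: {
                    "absolute": self.advice_absolute[a],
                    "normalized": self.advice_normalized[a],
                }
                for a in self.advice_absolute
            },
            "degenerate_advice": self.degenerate_advice,
        }


def if_posterior(
    model: ModelSpec,
    dimension_id: str,
    prior: LevelDistribution,
    answers: AnswerSet,
) -> LevelDistribution:
    """Naive-Bayes posterior over the immediate state of one dimension.

    ``posterior(k) ∝ prior(k) · Π_q P(answer_q | IF = k)`` over this
    dimension's answered questions; unanswered questions contribute no
    factor. The product is accumulated in log space so that a zero posterior
    cell can only come from an exact zero in an elicited table, in which
    case an all-zero posterior raises :class:`InconsistentEvidenceError`.
    """
    dim = model.dimension(dimension_id)
    resolved = answers.resolved(model)

    with np.errstate(divide="ignore"):
        log_w = np.log(prior.probs)
        for qid in dim.question_ids:
            if qid not in resolved:
                continue
            q = model.question(qid)
            log_w = log_w + np.log(q.answer_likelihood(resolved[qid]))

    if np.all(np.isneginf(log_w)):
        raise InconsistentEvidenceError(
            f"dimension {dimension_id!r}: every level has zero probability "
            "under the observed answers (structural zeros in the elicited tables)"
        )
    w = np.exp(log_w - np.max(log_w[np.isfinite(log_w)]))
    w[np.isneginf(log_w)] = 0.0
    return LevelDistribution(w / w.sum())


def cf_update(
    cf_old: LevelDistribution, if_new: LevelDistribution, alpha: float
) -> LevelDistribution:
    """Forgetting-factor aggregation ``CF_new = (1 − α)·IF + α·CF_old``.

    α = 0 discards history (CF = IF); α = 1 freezes CF. The update is an
    elementwise convex combination, hence an exact L1 contraction toward
    ``if_new`` with factor α.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"forgetting factor {alpha} not in [0, 1]")
    return LevelDistribution((1.0 - alpha) * if_new.probs + alpha * cf_old.probs)


def cs_infer(
    dimension: DimensionSpec,
    if_dist: LevelDistribution,
    cf_dist: LevelDistribution,
) -> LevelDistribution:
    """Contextual severity marginal ``Σ_{cf,if} P(cf)·P(if)·P(CS | if, cf)``.

    IF and CF enter as independent distributions; on point-mass inputs this
    reads a single row of the elicited severity table.
    """
    out = np.zeros(N_LEVELS)
    for cf in SeverityLevel:
        w_cf = cf_dist[cf]
        if w_cf == 0.0:
            continue
        for if_ in SeverityLevel:
            w = w_cf * if_dist[if_]
            if w == 0.0:
                continue
            out += w * dimension.severity_row(cf, if_).probs
    return LevelDistribution(out / out.sum())


def advice_score(
    advice: AdviceSpec, cs_dists: Mapping[str, LevelDistribution]
) -> float:
    """Exact marginal relevance of one advice under the noisy-OR model.

    ``P(relevant) = E[1 − (1 − leak)·Π_p (1 − activation(p, CS_p))]`` with
    the expectation over independent parent severities. Independence lets
    the expectation factorize over parents, so the exhaustive 4^p sum
    collapses to a product of per-parent expectations.
    """
    survive = 1.0 - advice.leak
    for pd in advice.parent_dimension_ids:
        if pd not in cs_dists:
            raise KeyError(f"advice {advice.id!r}: missing CS distribution for parent {pd!r}")
        survive *= float(np.dot(cs_dists[pd].probs, 1.0 - advice.activation_vector(pd)))
    return 1.0 - survive


def normalize_advice(absolute: Mapping[str, float]) -> tuple[dict[str, float], bool]:
    """Relative scores across every advice; uniform (flagged) if all zero."""
    total = float(sum(absolute.values()))
    if total <= 0.0:
        n = len(absolute)
        return ({a: 1.0 / n for a in absolute}, True) if n else ({}, True)
    return {a: v / total for a, v in absolute.items()}, False


def advice_ranking(absolute: Mapping[str, float]) -> tuple[str, ...]:
    ids = list(absolute)
    return tuple(sorted(ids, key=lambda a: (-absolute[a], ids.index(a))))


def _score_all(
    model: ModelSpec, cs_dists: Mapping[str, LevelDistribution]
) -> tuple[dict[str, float], dict[str, float], bool]:
    absolute = {a.id: advice_score(a, cs_dists) for a in model.advice}
    normalized, degenerate = normalize_advice(absolute)
    return absolute, normalized, degenerate


def init_belief(model: ModelSpec, context: ContextProfile) -> BeliefState:
    """A priori state: IF and CF both equal the context prior; step 0."""
    if context.key not in {c.key for c in CONTEXTS}:
        raise ContextError(f"unknown context {context.key!r}")
    beliefs: dict[str, DimensionBelief] = {}
    for d in model.dimensions:
        try:
            prior = d.prior_for(context)
        except KeyError as exc:
            raise ContextError(f"dimension {d.id!r} has no prior for {context.key!r}") from exc
        beliefs[d.id] = DimensionBelief(
            if_posterior=prior, cf=prior, cs=cs_infer(d, prior, prior)
        )
    cs_dists = {d: b.cs for d, b in beliefs.items()}
    absolute, normalized, degenerate = _score_all(model, cs_dists)
    return BeliefState(
        step=0,
        context=context,
        dimensions=beliefs,
        advice_absolute=absolute,
        advice_normalized=normalized,
        degenerate_advice=degenerate,
    )


def step(model: ModelSpec, state: BeliefState, answers: AnswerSet) -> BeliefState:
    """Advance the belief state by one scoring; the input state is untouched.

    Per dimension: IF posterior from the current CF (acting as prior) and
    this scoring's answers, then the forgetting update of CF, then CS from
    the new IF and updated CF; finally noisy-OR advice scores and their
    normalization.
    """
    beliefs: dict[str, DimensionBelief] = {}
    for d in model.dimensions:
        old = state.dimensions[d.id]
        if_new = if_posterior(model, d.id, old.cf, answers)
        cf_new = cf_update(old.cf, if_new, model.alpha)
        beliefs[d.id] = DimensionBelief(
            if_posterior=if_new, cf=cf_new, cs=cs_infer(d, if_new, cf_new)
        )
    cs_dists = {d: b.cs for d, b in beliefs.items()}
    absolute, normalized, degenerate = _score_all(model, cs_dists)
    return BeliefState(
        step=state.step + 1,
        context=state.context,
        dimensions=beliefs,
        advice_absolute=absolute,
        advice_normalized=normalized,
        degenerate_advice=degenerate,
    )
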