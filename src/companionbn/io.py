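"""Reading and writing knowledge-base documents (``companion-bn/1`` dialect).

The on-disk form is a single YAML document (JSON is a subset and also
parses). All probability tables are stored as probabilities in the fixed
level order ``[absent, low, medium, high]``; the per-100-counts form in
which priors and answer tables are elicited may be used instead via the
``*_counts`` keys and is converted on load.

Schema sketch::

    format: companion-bn/1
    alpha: 0.5
    metadata: {name: ..., version: ...}
    dimensions:
      - id: anxiety
        name: Anxiety
        provenance: elicited
        prior:                    # or prior_counts (per-100 integers)
          man_over_18: [0.3, 0.4, 0.15, 0.15]
          ...
        questions: [anxiety_level, ...]
        severity_cpt:             # outer key CF level, inner key IF level
          high: {high: [0, 0, 0.01, 0.99], ...}
    questions:
      - id: anxiety_level
        dimension: anxiety
        text: "..."
        answers: [..., ..., ..., ...]
        likelihood:               # or likelihood_counts; key = IF level,
          absent: [1.0, 0, 0, 0]  # value = distribution over the 4 answers
          ...
        vas_thresholds: [25, 50, 75]
    advice:
      - id: call_friends
        name: "..."
        leak: 0.0
        parents:                  # activation per CS level; absent omitted = 0
          anxiety: {low: 0.5, medium: 0.8, high: 0.99}
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import yaml

from .errors import ModelFormatError, ModelValidationError
from .levels import LEVEL_NAMES, N_LEVELS, LevelDistribution, SeverityLevel, counts_to_distribution
from .model import AdviceSpec, DimensionSpec, ModelSpec, QuestionSpec, validate_model

__all__ = ["FORMAT_TAG", "load_model", "save_model", "model_from_dict", "model_to_dict"]

FORMAT_TAG = "companion-bn/1"


def _require(mapping: dict, key: str, where: str) -> Any:
    if key not in mapping:
        raise ModelFormatError(f"{where}: missing required key {key!r}")
    return mapping[key]


def _dist(value, where: str, counts: bool = False) -> LevelDistribution:
    try:
        if counts:
            return LevelDistribution(counts_to_distribution(value))
        return LevelDistribution(value)
    except (ValueError, TypeError) as exc:
        raise ModelFormatError(f"{where}: {exc}") from exc


def _level_keyed(mapping: dict, where: str) -> dict[str, Any]:
    unknown = set(mapping) - set(LEVEL_NAMES)
    if unknown:
        raise ModelFormatError(f"{where}: unknown level keys {sorted(unknown)}")
    return mapping


def model_from_dict(doc: dict) -> ModelSpec:
    """Build a (validated) :class:`ModelSpec` from a parsed document."""
    if not isinstance(doc, dict):
        raise ModelFormatError("top level must be a mapping")
    tag = doc.get("format")
    if tag != FORMAT_TAG:
        raise ModelFormatError(f"format: expected {FORMAT_TAG!r}, found {tag!r}")

    dimensions = []
    for dd in _require(doc, "dimensions", "document"):
        did = _require(dd, "id", "dimensions[]")
        where = f"dimensions.{did}"
        if "prior_counts" in dd:
            prior_raw, prior_counts = dd["prior_counts"], True
        else:
            prior_raw, prior_counts = _require(dd, "prior", where), False
        prior = {
            ctx: _dist(v, f"{where}.prior.{ctx}", counts=prior_counts)
            for ctx, v in prior_raw.items()
        }
        cpt_raw = _require(dd, "severity_cpt", where)
        cpt = {}
        for cf_name, inner in _level_keyed(cpt_raw, f"{where}.severity_cpt").items():
            for if_name, row in _level_keyed(inner, f"{where}.severity_cpt.{cf_name}").items():
                cpt[(SeverityLevel.from_name(cf_name), SeverityLevel.from_name(if_name))] = _dist(
                    row, f"{where}.severity_cpt.{cf_name}.{if_name}"
                )
        dimensions.append(
            DimensionSpec(
                id=did,
                name=dd.get("name", did),
                prior=prior,
                severity_cpt=cpt,
                question_ids=tuple(_require(dd, "questions", where)),
                provenance=dd.get("provenance", "elicited"),
            )
        )

    questions = []
    for qd in _require(doc, "questions", "document"):
        qid = _require(qd, "id", "questions[]")
        where = f"questions.{qid}"
        if "likelihood_counts" in qd:
            lik_raw, lik_counts = qd["likelihood_counts"], True
        else:
            lik_raw, lik_counts = _require(qd, "likelihood", where), False
        lik = np.zeros((N_LEVELS, N_LEVELS))
        for lvl_name, row in _level_keyed(lik_raw, f"{where}.likelihood").items():
            lik[SeverityLevel.from_name(lvl_name)] = _dist(
                row, f"{where}.likelihood.{lvl_name}", counts=lik_counts
            ).probs
        answers = _require(qd, "answers", where)
        if len(answers) != N_LEVELS:
            raise ModelFormatError(f"{where}: expected {N_LEVELS} answer labels")
        questions.append(
            QuestionSpec(
                id=qid,
                dimension_id=_require(qd, "dimension", where),
                text=_require(qd, "text", where),
                answer_labels=tuple(answers),
                likelihood=lik,
                vas_thresholds=tuple(qd.get("vas_thresholds", (25, 50, 75))),
            )
        )

    advice = []
    for ad in _require(doc, "advice", "document"):
        aid = _require(ad, "id", "advice[]")
        where = f"advice.{aid}"
        activation = {}
        parents = _require(ad, "parents", where)
        for dim_id, per_level in parents.items():
            for lvl_name, p in _level_keyed(per_level, f"{where}.parents.{dim_id}").items():
                activation[(dim_id, SeverityLevel.from_name(lvl_name))] = float(p)
        advice.append(
            AdviceSpec(
                id=aid,
                name=ad.get("name", aid),
                parent_dimension_ids=tuple(parents),
                activation=activation,
                leak=float(ad.get("leak", 0.0)),
            )
        )

    try:
        alpha = float(doc.get("alpha", 0.5))
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"alpha: {exc}") from exc

    return ModelSpec(
        dimensions=tuple(dimensions),
        questions=tuple(questions),
        advice=tuple(advice),
        alpha=alpha,
        metadata=doc.get("metadata", {}),
    )


def _dist_list(d: LevelDistribution) -> list[float]:
    return [float(x) for x in d.probs]


def model_to_dict(model: ModelSpec) -> dict:
    """Serialize a model back to the document form (probabilities only)."""
    return {
        "format": FORMAT_TAG,
        "metadata": dict(model.metadata),
        "alpha": float(model.alpha),
        "levels": list(LEVEL_NAMES),
        "dimensions": [
            {
                "id": d.id,
                "name": d.name,
                "provenance": d.provenance,
                "prior": {ctx: _dist_list(p) for ctx, p in sorted(d.prior.items())},
                "questions": list(d.question_ids),
                "severity_cpt": {
                    cf.label: {
                        if_.label: _dist_list(d.severity_cpt[(cf, if_)]) for if_ in SeverityLevel
                    }
                    for cf in SeverityLevel
                },
            }
            for d in model.dimensions
        ],
        "questions": [
            {
                "id": q.id,
                "dimension": q.dimension_id,
                "text": q.text,
                "answers": list(q.answer_labels),
                "likelihood": {
                    lvl.label: [float(x) for x in q.likelihood[lvl]] for lvl in SeverityLevel
                },
                "vas_thresholds": [float(t) for t in q.vas_thresholds],
            }
            for q in model.questions
        ],
        "advice": [
            {
                "id": a.id,
                "name": a.name,
                "leak": float(a.leak),
                "parents": {
                    pd: {
                        lvl.label: float(a.activation_for(pd, lvl))
                        for lvl in SeverityLevel
                        if (pd, lvl) in a.activation
                    }
                    for pd in a.parent_dimension_ids
                },
            }
            for a in model.advice
        ],
    }


def load_model(path: "str | os.PathLike", validate: bool = True) -> ModelSpec:
    """Load and validate a knowledge base from a YAML/JSON document.

    Raises :class:`ModelFormatError` on parse problems and
    :class:`ModelValidationError` (carrying the full violation report) if the
    parsed model breaks an invariant.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelFormatError(f"{path}: not parseable as YAML/JSON: {exc}") from exc
    model = model_from_dict(doc)
    if validate:
        report = validate_model(model)
        if report:
            raise ModelValidationError(report)
    return model


def save_model(model: ModelSpec, path: "str | os.PathLike") -> None:
    """Write a model document; ``load_model(save_model(m)) == m``."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False, allow_unicode=True)
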