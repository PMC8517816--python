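"""Inference engine: posterior updates, forgetting, severity, advice scores."""

import numpy as np
import pytest

from companionbn import (
    AnswerSet,
    ContextProfile,
    ContextError,
    InconsistentEvidenceError,
    LevelDistribution,
    ParameterError,
    advice_score,
    cf_update,
    cs_infer,
    if_posterior,
    init_belief,
    normalize_advice,
    step,
)

pm = LevelDistribution.point_mass


class TestInitBelief:
    @pytest.mark.parametrize(
        "context_key, expected_prior",
        [
            ("man_over_18", (0.30, 0.40, 0.15, 0.15)),
            ("woman_under_18", (0.20, 0.20, 0.30, 0.30)),
        ],
    )
    def test_anxiety_prior_by_context(self, model, context_key, expected_prior):
        state = init_belief(model, ContextProfile.from_key(context_key))
        belief = state.dimensions["anxiety"]
        assert tuple(belief.if_posterior) == pytest.approx(expected_prior, abs=1e-12)

    def test_cf_initialized_to_prior(self, model, man_over_18):
        state = init_belief(model, man_over_18)
        assert state.step == 0
        for belief in state.dimensions.values():
            assert belief.cf == belief.if_posterior

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            ContextProfile("child", "over_18")


class TestIfPosterior:
    def test_single_high_answer_from_uniform_prior(self, model):
        # P(high answer | IF) = (0, 0, 0.05, 0.80): posterior 0.05/0.85, 0.80/0.85
        answers = AnswerSet(step=1, answers={"anxiety_level": 3})
        post = if_posterior(model, "anxiety", LevelDistribution.uniform(), answers)
        assert tuple(post) == pytest.approx((0.0, 0.0, 1 / 17, 16 / 17), abs=1e-12)

    def test_single_lowest_answer_from_context_prior(self, model):
        # prior (0.3, 0.4, 0.15, 0.15); P(no-anxiety answer | IF) = (1, 0.05, 0, 0)
        prior = LevelDistribution([0.3, 0.4, 0.15, 0.15])
        answers = AnswerSet(step=1, answers={"anxiety_level": 0})
        post = if_posterior(model, "anxiety", prior, answers)
        assert tuple(post) == pytest.approx((0.9375, 0.0625, 0.0, 0.0), abs=1e-12)

    def test_no_answers_returns_prior(self, model):
        prior = LevelDistribution([0.1, 0.2, 0.3, 0.4])
        post = if_posterior(model, "anxiety", prior, AnswerSet(step=1))
        assert post.allclose(prior, tol=1e-12)

    def test_answers_for_other_dimensions_ignored(self, model):
        prior = LevelDistribution([0.1, 0.2, 0.3, 0.4])
        answers = AnswerSet(step=1, answers={"sleep_quality": 3})
        post = if_posterior(model, "anxiety", prior, answers)
        assert post.allclose(prior, tol=1e-12)

    def test_question_order_irrelevant(self, model):
        prior = LevelDistribution([0.3, 0.4, 0.15, 0.15])
        fwd = AnswerSet(step=1, answers={"anxiety_level": 2, "anxiety_coping": 1, "anxiety_duration": 2})
        rev = AnswerSet(step=1, answers={"anxiety_duration": 2, "anxiety_coping": 1, "anxiety_level": 2})
        assert if_posterior(model, "anxiety", prior, fwd).allclose(
            if_posterior(model, "anxiety", prior, rev), tol=0
        )

    def test_contradictory_evidence_is_typed_error(self, model):
        # a point-mass-absent prior excludes every level compatible with a
        # highest-severity answer (structural zeros), which must not be
        # silently renormalized
        answers = AnswerSet(step=1, answers={"anxiety_level": 3})
        with pytest.raises(InconsistentEvidenceError):
            if_posterior(model, "anxiety", pm(0), answers)

    def test_vas_scores_are_binned(self, model):
        prior = LevelDistribution.uniform()
        by_index = if_posterior(
            model, "anxiety", prior, AnswerSet(step=1, answers={"anxiety_level": 3})
        )
        by_vas = if_posterior(
            model, "anxiety", prior, AnswerSet(step=1, answers={"anxiety_level": 92.5})
        )
        assert by_index.allclose(by_vas, tol=0)


class TestCfUpdate:
    def test_alpha_one_keeps_history(self):
        cf, if_new = pm(0), pm(3)
        assert cf_update(cf, if_new, 1.0) == cf

    def test_alpha_zero_drops_history(self):
        cf, if_new = pm(0), pm(3)
        assert cf_update(cf, if_new, 0.0) == if_new

    def test_even_blend(self):
        out = cf_update(pm(0), pm(3), 0.5)
        assert tuple(out) == pytest.approx((0.5, 0.0, 0.0, 0.5), abs=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            cf_update(pm(0), pm(3), 1.2)

    def test_contraction_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cf = LevelDistribution(rng.dirichlet(np.ones(4)))
            if_new = LevelDistribution(rng.dirichlet(np.ones(4)))
            alpha = float(rng.random())
            out = cf_update(cf, if_new, alpha)
            lhs = np.abs(out.probs - if_new.probs).sum()
            rhs = alpha * np.abs(cf.probs - if_new.probs).sum()
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestCsInfer:
    @pytest.mark.parametrize(
        "if_level, cf_level, expected_high",
        [
            (3, 3, 0.99),  # acutely high on a high background: near-certain severe
            (1, 3, 0.90),  # low moment, high background: background dominates
            (3, 0, 0.05),  # isolated spike on an absent background: rarely severe
        ],
    )
    def test_elicited_severity_cells(self, anxiety, if_level, cf_level, expected_high):
        cs = cs_infer(anxiety, pm(if_level), pm(cf_level))
        assert cs[3] == pytest.approx(expected_high, abs=1e-12)

    def test_point_mass_inputs_read_single_row(self, anxiety):
        cs = cs_infer(anxiety, pm(3), pm(3))
        assert tuple(cs) == pytest.approx((0.0, 0.0, 0.01, 0.99), abs=1e-12)

    def test_mixed_if_averages_rows(self, anxiety):
        cs = cs_infer(anxiety, LevelDistribution([0, 0.5, 0, 0.5]), pm(3))
        expected = 0.5 * anxiety.severity_row(3, 1).probs + 0.5 * anxiety.severity_row(3, 3).probs
        assert np.allclose(cs.probs, expected, atol=1e-12)

    def test_matches_brute_force_sixteen_pair_sum(self, anxiety):
        rng = np.random.default_rng(3)
        for _ in range(20):
            if_d = LevelDistribution(rng.dirichlet(np.ones(4)))
            cf_d = LevelDistribution(rng.dirichlet(np.ones(4)))
            expected = np.zeros(4)
            for cf in range(4):
                for if_ in range(4):
                    expected += cf_d[cf] * if_d[if_] * anxiety.severity_row(cf, if_).probs
            assert np.allclose(cs_infer(anxiety, if_d, cf_d).probs, expected, atol=1e-12)


class TestAdviceScore:
    def test_elicited_call_friends_cell(self, model):
        advice = model.advice_by_id("call_friends")
        assert advice_score(advice, {"anxiety": pm(3)}) == pytest.approx(0.99, abs=1e-12)

    def test_no_active_cause_no_leak_gives_zero(self, model):
        advice = model.advice_by_id("call_emergency")
        cs = {pd: pm(0) for pd in advice.parent_dimension_ids}
        assert advice_score(advice, cs) == 0.0

    def test_two_parent_noisy_or_combination(self, model):
        from companionbn import AdviceSpec, SeverityLevel

        advice = AdviceSpec(
            id="toy",
            name="toy",
            parent_dimension_ids=("a", "b"),
            activation={("a", SeverityLevel.HIGH): 0.5, ("b", SeverityLevel.HIGH): 0.5},
        )
        assert advice_score(advice, {"a": pm(3), "b": pm(3)}) == pytest.approx(0.75)

    def test_missing_parent_distribution(self, model):
        advice = model.advice_by_id("call_emergency")
        with pytest.raises(KeyError):
            advice_score(advice, {"anxiety": pm(3)})


class TestNormalizeAdvice:
    def test_already_normalized_passthrough(self):
        scores, degenerate = normalize_advice({"a": 0.2, "b": 0.2, "c": 0.6})
        assert scores == pytest.approx({"a": 0.2, "b": 0.2, "c": 0.6})
        assert not degenerate

    def test_symmetry(self):
        scores, _ = normalize_advice({"a": 0.99, "b": 0.99})
        assert scores == pytest.approx({"a": 0.5, "b": 0.5})

    def test_all_zero_flags_degenerate_uniform(self):
        scores, degenerate = normalize_advice({"a": 0.0, "b": 0.0})
        assert degenerate
        assert scores == pytest.approx({"a": 0.5, "b": 0.5})


class TestStep:
    def test_no_answers_full_memory_is_fixed_point(self, model, man_over_18):
        frozen = model.with_alpha(1.0)
        state = init_belief(frozen, man_over_18)
        after = step(frozen, state, AnswerSet(step=1))
        assert after.step == 1
        for dim_id, belief in state.dimensions.items():
            assert after.dimensions[dim_id].if_posterior.allclose(belief.if_posterior, tol=1e-12)
            assert after.dimensions[dim_id].cf.allclose(belief.cf, tol=1e-12)
            assert after.dimensions[dim_id].cs.allclose(belief.cs, tol=1e-12)

    def test_input_state_unmodified(self, model, man_over_18):
        state = init_belief(model, man_over_18)
        before = state.dimensions["anxiety"].cf.probs.copy()
        step(model, state, AnswerSet(step=1, answers={"anxiety_level": 3}))
        assert np.array_equal(state.dimensions["anxiety"].cf.probs, before)
        assert state.step == 0

    def test_step_composes_the_component_operations(self, model, man_over_18):
        """One engine step chains posterior -> forgetting -> severity -> scoring."""
        answers = AnswerSet(step=1, answers={"anxiety_level": 3})
        state = init_belief(model, man_over_18)
        after = step(model, state, answers)

        by_hand = {}
        for d in model.dimensions:
            prior = state.dimensions[d.id].cf
            if_new = if_posterior(model, d.id, prior, answers)
            cf_new = cf_update(prior, if_new, model.alpha)
            by_hand[d.id] = (if_new, cf_new, cs_infer(d, if_new, cf_new))

        for d in model.dimensions:
            if_new, cf_new, cs_new = by_hand[d.id]
            assert after.dimensions[d.id].if_posterior.allclose(if_new, tol=1e-12)
            assert after.dimensions[d.id].cf.allclose(cf_new, tol=1e-12)
            assert after.dimensions[d.id].cs.allclose(cs_new, tol=1e-12)

        cs_dists = {d: b[2] for d, b in by_hand.items()}
        for advice in model.advice:
            assert after.advice_absolute[advice.id] == pytest.approx(
                advice_score(advice, cs_dists), abs=1e-12
            )
        assert sum(after.advice_normalized.values()) == pytest.approx(1.0, abs=1e-9)

    def test_ranking_sorted_by_absolute_score(self, model, man_over_18):
        state = init_belief(model, man_over_18)
        ranking = state.ranking()
        scores = [state.advice_absolute[a] for a in ranking]
        assert scores == sorted(scores, reverse=True)

    def test_snapshot_serialization_roundtrips_through_json(self, model, man_over_18):
        import json

        state = init_belief(model, man_over_18)
        payload = json.loads(json.dumps(state.as_dict()))
        assert payload["step"] == 0
        assert payload["context"] == "man_over_18"
        assert set(payload["dimensions"]) == {d.id for d in model.dimensions}
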