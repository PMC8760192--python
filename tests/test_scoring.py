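import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmp_tsat.registry import Category
from nmp_tsat.scoring import (
    ConsensusRule,
    DiscordanceError,
    EvaluationError,
    SizeContext,
    consensus,
    particle_size_context,
    suggest_dose_response_score,
    summarize,
    tas_percent,
    validate_evaluation,
)

from conftest import make_eval, make_registry, random_eval


class TestValidateEvaluation:
    def test_complete_all_zeros_is_valid(self, invivo_reg):
        assert validate_evaluation(make_eval(invivo_reg, 0), invivo_reg) == []

    def test_missing_criterion_reported(self, invivo_reg):
        ev = make_eval(invivo_reg, 1)
        scores = dict(ev.scores)
        del scores["pc_shape"]
        ev = type(ev)(ev.study_id, ev.rater_id, ev.registry_name, scores, ev.metadata)
        issues = validate_evaluation(ev, invivo_reg)
        assert [(i.rule, i.criterion_id) for i in issues] == [
            ("missing_criterion", "pc_shape")
        ]

    def test_out_of_range_and_unknown_reported(self, invivo_reg):
        ev = make_eval(invivo_reg, 1)
        scores = dict(ev.scores, pc_size=3, bogus=1)
        ev = type(ev)(ev.study_id, ev.rater_id, ev.registry_name, scores, ev.metadata)
        rules = {i.rule for i in validate_evaluation(ev, invivo_reg)}
        assert rules == {"out_of_range", "unknown_criterion"}

    def test_metadata_system_mismatch_reported(self, invivo_reg, invitro_reg):
        ev = make_eval(invitro_reg, 1)  # in vitro metadata
        ev = type(ev)(
            ev.study_id,
            ev.rater_id,
            ev.registry_name,
            {cid: 1 for cid in invivo_reg.ids},
            ev.metadata,
        )
        assert any(
            i.rule == "system_mismatch" for i in validate_evaluation(ev, invivo_reg)
        )


class TestConsensus:
    def test_identical_raters_agree_under_every_rule(self, invivo_reg):
        evs = [make_eval(invivo_reg, 1, rater_id=r) for r in ("r1", "r2")]
        for rule in ConsensusRule:
            merged = consensus(evs, rule)
            assert merged.scores == evs[0].scores
            assert merged.discordant == ()

    def test_min_takes_pointwise_minimum(self, invivo_reg):
        a = make_eval(invivo_reg, {"pc_size": 2}, rater_id="r1")
        b = make_eval(invivo_reg, {"pc_size": 1}, rater_id="r2")
        merged = consensus([a, b], "min")
        assert merged.scores["pc_size"] == 1
        assert [cid for cid, _ in merged.discordant] == ["pc_size"]

    @pytest.mark.parametrize(
        "levels, expected",
        [((2, 1, 1), 1), ((2, 1), 1), ((2, 2, 1), 2), ((0, 2), 0), ((2, 2), 2)],
    )
    def test_mode_majority_with_ties_to_lower(self, invivo_reg, levels, expected):
        evs = [
            make_eval(invivo_reg, {"ra_statistics": lvl}, rater_id=f"r{i}")
            for i, lvl in enumerate(levels)
        ]
        assert consensus(evs, "mode").scores["ra_statistics"] == expected

    def test_strict_raises_naming_criteria(self, invivo_reg):
        a = make_eval(invivo_reg, {"pc_size": 2, "pc_shape": 1}, rater_id="r1")
        b = make_eval(invivo_reg, {"pc_size": 1, "pc_shape": 1}, rater_id="r2")
        with pytest.raises(DiscordanceError, match="pc_size"):
            consensus([a, b], "strict")

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="at least one"):
            consensus([], "min")

    def test_mixed_studies_rejected(self, invivo_reg):
        a = make_eval(invivo_reg, 1, study_id="s1")
        b = make_eval(invivo_reg, 1, study_id="s2")
        with pytest.raises(ValueError, match="multiple studies"):
            consensus([a, b], "min")

    def test_min_consensus_pointwise_below_all_raters(self, invivo_reg, rng):
        evs = [
            random_eval(invivo_reg, rng, rater_id=f"r{i}") for i in range(3)
        ]
        merged = consensus(evs, "min")
        for cid in invivo_reg.ids:
            assert all(merged.scores[cid] <= e.scores[cid] for e in evs)

    def test_idempotent_on_single_evaluation(self, invivo_reg, rng):
        ev = random_eval(invivo_reg, rng)
        for rule in ConsensusRule:
            assert consensus([ev], rule).scores == ev.scores


class TestSummarize:
    def test_all_twos_hits_the_maximum(self, invivo_reg):
        s = summarize(make_eval(invivo_reg, 2), invivo_reg)
        assert (s.tas, s.tas_max, s.tas_percent) == (52, 52, 100)
        assert s.max_score_fraction == 1.0 and s.n_zero == 0

    def test_all_ones_is_half_the_maximum(self, invivo_reg):
        s = summarize(make_eval(invivo_reg, 1), invivo_reg)
        assert (s.tas, s.tas_percent, s.max_score_fraction) == (26, 50, 0.0)

    def test_all_zeros(self, invivo_reg):
        s = summarize(make_eval(invivo_reg, 0), invivo_reg)
        assert (s.tas, s.tas_percent, s.n_zero) == (0, 0, 26)

    def test_subtotals_sum_to_tas_on_random_evaluations(self, invivo_reg, rng):
        for _ in range(50):
            ev = random_eval(invivo_reg, rng)
            s = summarize(ev, invivo_reg)
            assert s.tas == sum(ev.scores.values())  # naive recount oracle
            assert s.tas == sum(s.subtotals.values())
            assert 0 <= s.tas <= s.tas_max

    def test_category_subtotals_follow_the_registry(self, invivo_reg):
        ev = make_eval(invivo_reg, {"pc_size": 2, "sd_stability": 1, "ra_statistics": 1})
        s = summarize(ev, invivo_reg)
        assert s.subtotals[Category.PARTICLE_CHARACTERIZATION] == 2
        assert s.subtotals[Category.STUDY_DESIGN] == 1
        assert s.subtotals[Category.RISK_ASSESSMENT] == 1

    def test_invalid_evaluation_raises_with_issues(self, invivo_reg, invitro_reg):
        with pytest.raises(EvaluationError) as err:
            summarize(make_eval(invitro_reg, 1), invivo_reg)
        assert err.value.issues

    def test_single_upgrade_never_decreases_statistics(self, invivo_reg, rng):
        for _ in range(25):
            ev = random_eval(invivo_reg, rng)
            upgradable = [cid for cid, v in ev.scores.items() if v < 2]
            if not upgradable:
                continue
            cid = upgradable[rng.integers(len(upgradable))]
            before = summarize(ev, invivo_reg)
            up = type(ev)(
                ev.study_id,
                ev.rater_id,
                ev.registry_name,
                dict(ev.scores, **{cid: ev.scores[cid] + 1}),
                ev.metadata,
            )
            after = summarize(up, invivo_reg)
            assert after.tas > before.tas
            assert after.tas_percent >= before.tas_percent
            assert after.max_score_fraction >= before.max_score_fraction


class TestTasPercent:
    @pytest.mark.parametrize(
        "tas, tmax, pct",
        [(44, 52, 85), (37, 52, 71), (34, 46, 74), (12, 52, 23), (16, 46, 35),
         (26, 52, 50), (0, 52, 0), (52, 52, 100)],
    )
    def test_published_pairs_reproduce(self, tas, tmax, pct):
        assert tas_percent(tas, tmax) == pct

    def test_half_rounds_away_from_zero(self):
        assert tas_percent(1, 8) == 13  # 12.5 -> 13

    @given(tmax=st.integers(1, 200))
    @settings(deadline=None)
    def test_extremes_for_every_maximum(self, tmax):
        assert tas_percent(tmax, tmax) == 100
        assert tas_percent(0, tmax) == 0

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            tas_percent(1, 0)
        with pytest.raises(ValueError):
            tas_percent(5, 4)


class TestAdvisoryHelpers:
    @pytest.mark.parametrize(
        "n_doses, control, ratio, level",
        [
            (3, True, 3.0, 2),
            (4, True, 10.0, 2),
            (2, True, 10.0, 1),
            (3, True, 2.0, 1),
            (3, False, 3.0, 0),
            (1, False, None, 0),
            (0, True, None, 0),
        ],
    )
    def test_dose_response_rule(self, n_doses, control, ratio, level):
        assert suggest_dose_response_score(n_doses, control, ratio) == level

    def test_dose_response_rejects_negative_doses(self):
        with pytest.raises(ValueError):
            suggest_dose_response_score(-1, True, 3.0)

    @pytest.mark.parametrize(
        "size, ctx",
        [
            (200, SizeContext.UNLIKELY_ABSORBED_LOCAL_EFFECTS),
            (151, SizeContext.UNLIKELY_ABSORBED_LOCAL_EFFECTS),
            (150, SizeContext.INTERMEDIATE_LIMITED_ABSORPTION),
            (50, SizeContext.INTERMEDIATE_LIMITED_ABSORPTION),
            (1.5, SizeContext.INTERMEDIATE_LIMITED_ABSORPTION),
            (1.0, SizeContext.EPITHELIAL_CROSSING_POSSIBLE),
            (0.01, SizeContext.EPITHELIAL_CROSSING_POSSIBLE),
        ],
    )
    def test_particle_size_context_bounds(self, size, ctx):
        assert particle_size_context(size) == ctx

    def test_particle_size_context_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            particle_size_context(0)
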