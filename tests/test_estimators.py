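"""Unit and property tests for the three estimation engines."""

import dataclasses
import itertools

import pytest

from dentage import (
    AtlasChartSet,
    DentitionRecord,
    JawScope,
    Method,
    NollaTable,
    OlzeTable,
    Proximity,
    ReferenceTableSet,
    Scheme,
    Sex,
    StageAssessment,
    ToothId,
    atlas_mismatch,
    demirjian_age,
    demirjian_maturity_score,
    estimate_demirjian_olze,
    estimate_london_atlas,
    estimate_nolla,
    lookup_age,
    nolla_sum,
    nolla_tooth_value,
    olze_age,
)
from dentage.estimators import (
    IncomparableError,
    IncompleteDentitionError,
    EstimationFailureError,
    TableError,
)
from dentage.reference_model import DemirjianAgeTable, DemirjianScoreTable


def nolla_record(values, sex=Sex.MALE, age=12.0, quadrant=3):
    """Record with Nolla stages at positions 1..len(values) of one quadrant.

    Each value is (stage, proximity) or a bare int stage.
    """
    assessments = []
    for pos, v in enumerate(values, start=1):
        stage, prox = v if isinstance(v, tuple) else (v, Proximity.EXACT)
        assessments.append(
            StageAssessment(ToothId(quadrant * 10 + pos), Scheme.NOLLA, stage, proximity=prox)
        )
    return DentitionRecord("t", sex, age, assessments)


class TestNollaToothValue:
    @pytest.mark.parametrize(
        "stage,prox,expected",
        [
            (6, Proximity.PLUS02, 6.2),
            (6, Proximity.PLUS05, 6.5),
            (6, Proximity.EXACT, 6.0),
            (6, Proximity.PLUS07, 6.7),
            (1, Proximity.EXACT, 1.0),
            (10, Proximity.EXACT, 10.0),
        ],
    )
    def test_value(self, stage, prox, expected):
        assert nolla_tooth_value(stage, prox) == pytest.approx(expected)

    def test_terminal_stage_admits_no_qualifier(self):
        with pytest.raises(ValueError):
            nolla_tooth_value(10, Proximity.PLUS02)

    @pytest.mark.parametrize("stage", [0, 11, 5.5])
    def test_invalid_stage(self, stage):
        with pytest.raises(ValueError):
            nolla_tooth_value(stage)


class TestNollaSum:
    def test_maximal_sum_seven_pairs(self):
        rec = nolla_record([10] * 7)
        total, used, subs = nolla_sum(rec, JawScope.MANDIBLE, include_third_molars=False)
        assert total == pytest.approx(70.0)
        assert len(used) == 7 and subs == []

    def test_hand_sum_with_qualifiers(self):
        rec = nolla_record(
            [(6, Proximity.PLUS02), (7, Proximity.PLUS05), 8, (9, Proximity.PLUS02), 10, 10, 10]
        )
        total, _, _ = nolla_sum(rec, JawScope.MANDIBLE, False)
        assert total == pytest.approx(60.9)

    def test_right_member_substitutes_for_missing_left(self):
        rec = nolla_record([5] * 7, quadrant=4)  # right side only
        total, used, subs = nolla_sum(rec, JawScope.MANDIBLE, False)
        assert total == pytest.approx(35.0)
        assert all(t.quadrant == 4 for t in used)
        assert subs == [31, 32, 33, 34, 35, 36, 37]

    def test_missing_pair_is_an_error_naming_it(self):
        rec = nolla_record([5] * 6)  # position 7 absent on both sides
        with pytest.raises(IncompleteDentitionError, match="37"):
            nolla_sum(rec, JawScope.MANDIBLE, False)


class TestLookupAge:
    KNOTS = [(50.0, 10.0), (54.0, 11.0)]

    @pytest.mark.parametrize(
        "x,age,clamped",
        [
            (50.0, 10.0, False),  # knot identity
            (52.0, 10.5, False),  # linear interpolation
            (60.0, 11.0, True),   # clamp above
            (40.0, 10.0, True),   # clamp below
            (54.0, 11.0, False),
        ],
    )
    def test_lookup(self, x, age, clamped):
        assert lookup_age(self.KNOTS, x) == (pytest.approx(age), clamped)

    def test_knot_identity_is_exact(self, tables):
        for t in tables.nolla:
            for x, age in t.knots[:: max(1, len(t.knots) // 10)]:
                got, clamped = lookup_age(t.knots, x)
                assert abs(got - age) <= 1e-12 and not clamped

    def test_singleton_table_rejected(self):
        with pytest.raises(TableError):
            lookup_age([(50.0, 10.0)], 50.0)


def toy_table_set(tables, nolla_knots):
    """Replace every mandible Nolla table's knots with ``nolla_knots``."""
    new = [
        dataclasses.replace(t, knots=list(nolla_knots)) if t.jaw_scope is JawScope.MANDIBLE else t
        for t in tables.nolla
    ]
    return dataclasses.replace(tables, nolla=new)


class TestEstimateNolla:
    def test_composition_sum_to_age(self, tables):
        toy = toy_table_set(tables, [(10.0, 4.0), (60.9, 11.3), (70.0, 17.0)])
        rec = nolla_record(
            [(6, Proximity.PLUS02), (7, Proximity.PLUS05), 8, (9, Proximity.PLUS02), 10, 10, 10]
        )
        res = estimate_nolla(rec, toy, include_third_molars=False)
        assert res.age_est == pytest.approx(11.3)
        assert res.intermediate["sum_of_values"] == pytest.approx(60.9)
        assert not res.clamped

    def test_sum_at_table_maximum_is_a_knot_not_a_clamp(self, tables):
        toy = toy_table_set(tables, [(10.0, 4.0), (70.0, 17.0)])
        res = estimate_nolla(nolla_record([10] * 7), toy, include_third_molars=False)
        assert res.age_est == pytest.approx(17.0) and not res.clamped

    def test_missing_pair_propagates(self, tables):
        with pytest.raises(IncompleteDentitionError):
            estimate_nolla(nolla_record([5] * 6), tables, include_third_molars=False)

    def test_third_molar_auto_inclusion(self, tables):
        rec = nolla_record([10] * 7, age=18.0)
        res = estimate_nolla(rec, tables)
        assert res.intermediate["third_molars_included"] is False
        rec_m3 = nolla_record([10] * 7 + [5], age=18.0)
        res_m3 = estimate_nolla(rec_m3, tables)
        assert res_m3.intermediate["third_molars_included"] is True
        assert len(res_m3.intermediate["teeth_used"]) == 8

    def test_missing_table_variant_is_table_error(self, tables):
        pruned = dataclasses.replace(
            tables, nolla=[t for t in tables.nolla if t.jaw_scope is not JawScope.BOTH]
        )
        with pytest.raises(TableError):
            estimate_nolla(nolla_record([5] * 7), pruned, jaw_scope=JawScope.BOTH,
                           include_third_molars=False)


def demirjian_record(stages, sex=Sex.MALE, age=12.0, quadrant=3, third_molar=None):
    assessments = [
        StageAssessment(ToothId(quadrant * 10 + pos), Scheme.DEMIRJIAN, s)
        for pos, s in enumerate(stages, start=1)
    ]
    if third_molar is not None:
        fdi, stage = third_molar
        assessments.append(StageAssessment(ToothId(fdi), Scheme.DEMIRJIAN, stage))
    return DentitionRecord("t", sex, age, assessments)


SCORES = DemirjianScoreTable(
    Sex.MALE,
    {
        (p, s): v
        for p, stage_scores in enumerate(
            [
                {"0": 0.0, "C": 1.0, "E": 1.7, "H": 13.0},
                {"0": 0.0, "C": 1.1, "E": 3.1, "H": 13.5},
                {"0": 0.0, "C": 1.2, "E": 5.4, "H": 14.0},
                {"0": 0.0, "C": 1.3, "E": 4.0, "H": 14.0},  # not monotone in E; unit scope only
                {"0": 0.0, "C": 1.4, "E": 7.3, "H": 14.5},
                {"0": 0.0, "C": 1.5, "E": 10.1, "H": 15.0},
                {"0": 0.0, "C": 1.6, "E": 8.0, "H": 16.0},
            ],
            start=1,
        )
        for s, v in stage_scores.items()
    },
)


class TestDemirjianScore:
    def test_zero_scores_give_zero(self):
        S, stages, subs = demirjian_maturity_score(demirjian_record(["0"] * 7), SCORES)
        assert S == 0.0 and len(stages) == 7 and subs == []

    def test_hand_sum(self):
        S, _, _ = demirjian_maturity_score(demirjian_record(["E"] * 7), SCORES)
        assert S == pytest.approx(39.6)

    def test_right_substitutes_for_left(self):
        rec = demirjian_record(["E"] * 7, quadrant=4)
        S, _, subs = demirjian_maturity_score(rec, SCORES)
        assert S == pytest.approx(39.6)
        assert subs == [31, 32, 33, 34, 35, 36, 37]

    def test_unstageable_position_is_an_error(self):
        with pytest.raises(IncompleteDentitionError, match="position 7"):
            demirjian_maturity_score(demirjian_record(["E"] * 6), SCORES)


class TestDemirjianAge:
    TABLE = DemirjianAgeTable(Sex.MALE, [(0.0, 3.0), (90.0, 14.0), (94.0, 15.0), (100.0, 17.0)])

    @pytest.mark.parametrize(
        "S,age",
        [(92.0, 14.5), (90.0, 14.0), (93.0, 14.75), (94.0, 15.0)],
    )
    def test_midpoint_knot_and_interpolation(self, S, age):
        got, clamped = demirjian_age(S, self.TABLE)
        assert got == pytest.approx(age) and not clamped

    def test_midpoint_rule_equals_linear_interpolation(self):
        # the stated midpoint-average rule and linear interpolation coincide
        for (s0, a0), (s1, a1) in zip(self.TABLE.knots, self.TABLE.knots[1:]):
            mid, _ = demirjian_age((s0 + s1) / 2, self.TABLE)
            assert mid == pytest.approx((a0 + a1) / 2, abs=1e-12)

    def test_score_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            demirjian_age(101.0, self.TABLE)


OLZE = OlzeTable(Sex.MALE, {"D": 16.0, "E": 16.8, "F": 17.4, "G": 19.2, "H": 21.0})


class TestOlze:
    def test_tooth_38_direct(self):
        rec = demirjian_record(["H"] * 7, age=18.0, third_molar=(38, "F"))
        assert olze_age(rec, OLZE) == (pytest.approx(17.4), ToothId(38))

    def test_tooth_48_substitutes(self):
        rec = demirjian_record(["H"] * 7, age=18.0, third_molar=(48, "F"))
        age, tooth = olze_age(rec, OLZE)
        assert age == pytest.approx(17.4) and tooth == ToothId(48)

    def test_no_third_molar_returns_absent(self):
        rec = demirjian_record(["H"] * 7, age=18.0)
        assert olze_age(rec, OLZE) is None

    def test_unmapped_stage_is_an_error(self):
        from dentage.estimators import UnmappedStageError

        rec = demirjian_record(["H"] * 7, age=18.0, third_molar=(38, "A"))
        with pytest.raises(UnmappedStageError):
            olze_age(rec, OLZE)


class TestEstimateDemirjianOlze:
    def _tables(self, tables):
        return dataclasses.replace(
            tables,
            demirjian_scores={Sex.MALE: SCORES, Sex.FEMALE: SCORES},
            demirjian_age={Sex.MALE: TestDemirjianAge.TABLE, Sex.FEMALE: TestDemirjianAge.TABLE},
            olze={Sex.MALE: OLZE, Sex.FEMALE: OLZE},
        )

    def test_below_threshold_keeps_base_age(self, tables):
        rec = demirjian_record(["E"] * 7)  # S=39.6 -> well below 16 y
        res = estimate_demirjian_olze(rec, self._tables(tables))
        assert res.age_est < 16 and not res.intermediate["olze_triggered"]
        assert not res.intermediate["olze_attempted"]

    def test_above_threshold_replaced_by_olze(self, tables):
        rec = demirjian_record(["H"] * 7, age=18.0, third_molar=(38, "G"))
        res = estimate_demirjian_olze(rec, self._tables(tables))  # base 17 > 16
        assert res.intermediate["base_age"] == pytest.approx(17.0)
        assert res.age_est == pytest.approx(19.2)
        assert res.intermediate["olze_triggered"]
        assert res.intermediate["olze_tooth"] == 38

    def test_above_threshold_without_third_molars_falls_back(self, tables):
        rec = demirjian_record(["H"] * 7, age=18.0)
        res = estimate_demirjian_olze(rec, self._tables(tables))
        assert res.age_est == pytest.approx(17.0)
        assert res.intermediate["olze_attempted"] and not res.intermediate["olze_triggered"]


def chart(age, stages):
    return (age, {ToothId(fdi): s for fdi, s in stages.items()})


class TestAtlasMismatch:
    def test_identical_patterns_score_zero(self):
        p = {ToothId(11): 3, ToothId(16): 5, ToothId(46): 7}
        assert atlas_mismatch(p, dict(p)) == 0.0

    def test_mean_absolute_discrepancy(self):
        obs = {ToothId(11): 3, ToothId(16): 5, ToothId(46): 7}
        cha = {ToothId(11): 3, ToothId(16): 6, ToothId(46): 7}
        assert atlas_mismatch(obs, cha) == pytest.approx(1 / 3)

    def test_disjoint_teeth_incomparable(self):
        with pytest.raises(IncomparableError):
            atlas_mismatch({ToothId(11): 3}, {ToothId(46): 3})


class TestEstimateLondonAtlas:
    def _record(self, stages, age=10.0):
        return DentitionRecord(
            "t", Sex.MALE, age,
            [StageAssessment(ToothId(fdi), Scheme.ATLAS, s) for fdi, s in stages.items()],
        )

    def test_exact_match_returns_chart_age(self):
        atlas = AtlasChartSet([
            chart(11.0, {11: 4, 46: 5}),
            chart(12.0, {11: 5, 46: 6}),
            chart(13.0, {11: 6, 46: 8}),
        ])
        res = estimate_london_atlas(self._record({11: 5, 46: 6}, age=12.0), atlas)
        assert res.age_est == pytest.approx(12.0)
        assert res.intermediate["min_mismatch"] == 0.0

    def test_exact_tie_between_adjacent_charts_averages(self):
        atlas = AtlasChartSet([
            chart(9.5, {11: 4, 46: 4}),
            chart(10.5, {11: 6, 46: 6}),
            chart(11.5, {11: 9, 46: 9}),
        ])
        res = estimate_london_atlas(self._record({11: 5, 46: 5}), atlas)
        assert res.age_est == pytest.approx(10.0)
        assert res.intermediate["matched_chart_ages"] == [9.5, 10.5]

    def test_brute_force_nearest_chart(self):
        charts = [
            chart(8.0, {11: 2, 16: 3, 46: 3}),
            chart(9.0, {11: 4, 16: 4, 46: 5}),
            chart(10.0, {11: 6, 16: 7, 46: 7}),
        ]
        obs = {11: 4, 16: 5, 46: 5}
        by_hand = min(
            ((sum(abs(obs[f] - p[ToothId(f)]) for f in obs) / 3, a) for a, p in charts),
        )
        res = estimate_london_atlas(self._record(obs, age=9.0), AtlasChartSet(charts))
        assert res.age_est == pytest.approx(by_hand[1]) == pytest.approx(9.0)

    def test_chart_order_never_changes_the_estimate(self):
        charts = [
            chart(9.5, {11: 4, 46: 4}),
            chart(10.5, {11: 6, 46: 6}),
            chart(11.5, {11: 9, 46: 9}),
        ]
        rec = self._record({11: 5, 46: 5})
        baseline = estimate_london_atlas(rec, AtlasChartSet(charts)).age_est
        for perm in itertools.permutations(charts):
            atlas = AtlasChartSet(sorted(perm))  # construction order fixed...
            assert estimate_london_atlas(rec, atlas).age_est == baseline
        # ...and even unsorted chart lists give the same answer
        assert estimate_london_atlas(rec, AtlasChartSet(list(reversed(charts)))).age_est == baseline

    def test_left_tooth_substitutes_for_uncharted_right(self):
        atlas = AtlasChartSet([chart(11.0, {11: 4}), chart(12.0, {11: 5})])
        rec = self._record({21: 5}, age=12.0)  # only the left mirror assessed
        res = estimate_london_atlas(rec, atlas)
        assert res.age_est == pytest.approx(12.0)
        assert res.substitutions == [11]

    def test_no_comparable_chart_is_a_failure(self):
        atlas = AtlasChartSet([chart(11.0, {11: 4})])
        with pytest.raises(EstimationFailureError):
            estimate_london_atlas(self._record({46: 5}), atlas)


class TestEngineProperties:
    """Cross-engine invariants on the model-consistent synthetic tables."""

    def _bump(self, record):
        from dataclasses import replace

        bumped = []
        for a in record.assessments:
            if a.scheme is Scheme.NOLLA:
                bumped.append(
                    a if a.stage >= 10 else replace(a, stage=a.stage + 1, proximity=Proximity.EXACT)
                )
            elif a.scheme is Scheme.DEMIRJIAN:
                from dentage.reference_model import DEMIRJIAN_STAGES

                i = DEMIRJIAN_STAGES.index(a.stage)
                bumped.append(a if i >= 8 else replace(a, stage=DEMIRJIAN_STAGES[i + 1]))
            else:
                bumped.append(a if a.stage >= 10 else replace(a, stage=a.stage + 1))
        return DentitionRecord(record.subject_id, record.sex, record.age_true, bumped)

    def test_monotone_in_stage_input(self, zero_cohort, tables):
        for record in zero_cohort[::9]:
            bumped = self._bump(record)
            assert (
                estimate_nolla(bumped, tables).age_est
                >= estimate_nolla(record, tables).age_est - 1e-9
            )
            assert (
                estimate_demirjian_olze(bumped, tables).age_est
                >= estimate_demirjian_olze(record, tables).age_est - 1e-9
            )
            assert (
                estimate_london_atlas(bumped, tables.atlas).age_est
                >= estimate_london_atlas(record, tables.atlas).age_est - 1e-9
            )

    def test_engines_are_deterministic(self, zero_cohort, tables):
        for record in zero_cohort[::40]:
            assert estimate_nolla(record, tables) == estimate_nolla(record, tables)
            assert estimate_demirjian_olze(record, tables) == estimate_demirjian_olze(record, tables)
            assert estimate_london_atlas(record, tables.atlas) == estimate_london_atlas(record, tables.atlas)
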