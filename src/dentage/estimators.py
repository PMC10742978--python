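"""The three dental-age-estimation engines.

* Nolla: each assessed tooth gets a calcification value 1-10 (refined by
  +0.2/+0.5/+0.7 between stages); one value is retained per left/right
  pair, values are summed over the chosen jaw scope and the sum is mapped
  to age through sex-specific knot tables, with or without third molars.
* Demirjian (+ Olze supplement): the seven left mandibular teeth are
  staged A-H, converted to sex-specific self-weighted scores summing to a
  maturity score S in [0, 100], which is mapped to dental age.  When the
  Demirjian estimate exceeds 16 years the third-molar (38, else 48) stage
  is looked up in Olze's table and replaces the estimate.
* London-atlas pattern matching: the observed ordinal stage pattern is
  compared to age-indexed charts; the estimate is the age of the most
  similar chart (mean absolute stage discrepancy over shared teeth), with
  ties resolved by averaging the tied chart ages.

All lookups interpolate linearly between knots — which subsumes the
"exact midpoint -> average of the two ages" rule — and clamp to boundary
ages outside the tabulated range, setting a flag instead of erroring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

from .reference_model import (
    AtlasChartSet,
    DentitionRecord,
    JawScope,
    OlzeTable,
    Proximity,
    ReferenceTableSet,
    Scheme,
    Sex,
    DemirjianScoreTable,
    DemirjianAgeTable,
    ToothId,
    contralateral_substitute,
)

__all__ = [
    "Method",
    "EstimateResult",
    "EstimationError",
    "IncompleteDentitionError",
    "TableError",
    "UnmappedStageError",
    "IncomparableError",
    "EstimationFailureError",
    "nolla_tooth_value",
    "nolla_sum",
    "lookup_age",
    "estimate_nolla",
    "demirjian_maturity_score",
    "demirjian_age",
    "olze_age",
    "estimate_demirjian_olze",
    "atlas_mismatch",
    "estimate_london_atlas",
    "OLZE_TRIGGER_AGE",
]

#: Demirjian estimates strictly above this age invoke the Olze supplement.
OLZE_TRIGGER_AGE = 16.0


class Method(str, enum.Enum):
    NOLLA = "NOLLA"
    DEMIRJIAN_OLZE = "DEMIRJIAN_OLZE"
    LONDON_ATLAS = "LONDON_ATLAS"


class EstimationError(Exception):
    """Base class for engine failures."""


class IncompleteDentitionError(EstimationError):
    """A tooth (pair) the method requires is not assessable."""


class TableError(EstimationError):
    """A lookup table is missing or unusable."""


class UnmappedStageError(EstimationError):
    """An observed stage has no entry in the relevant table."""


class IncomparableError(EstimationError):
    """An observation shares no teeth with a chart pattern."""


class EstimationFailureError(EstimationError):
    """No chart could be compared with the observation at all."""


@dataclass
class EstimateResult:
    """One method's age estimate with full provenance.

    ``intermediate`` carries method-specific detail (Nolla sum of values
    and teeth used; Demirjian maturity score S and the Olze trigger
    outcome; atlas matched chart ages and mismatch scores).
    ``substitutions`` lists the FDI codes whose contralateral partner was
    read in their place.  ``clamped`` marks a lookup outside the table
    range, in which case the estimate equals a table boundary age.
    """

    method: Method
    age_est: float
    intermediate: dict = field(default_factory=dict)
    substitutions: list[int] = field(default_factory=list)
    clamped: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.age_est <= 0:
            raise ValueError("age_est must be positive")


# ---------------------------------------------------------------------------
# Nolla
# ---------------------------------------------------------------------------


def nolla_tooth_value(stage: int, proximity: Proximity = Proximity.EXACT) -> float:
    """Nolla value of one tooth: integer stage plus between-stage refinement.

    A tooth between stages k and k+1 scores k+0.2 (closer to k), k+0.5
    (equidistant) or k+0.7 (closer to k+1); stage 10 is terminal and
    admits no refinement.
    """
    if not (isinstance(stage, int) and 1 <= stage <= 10):
        raise ValueError(f"Nolla stage must be an integer 1-10, got {stage!r}")
    if stage == 10 and proximity is not Proximity.EXACT:
        raise ValueError("stage 10 admits no between-stage qualifier")
    return stage + proximity.offset


def _scope_quadrant_pairs(jaw_scope: JawScope) -> list[tuple[int, int]]:
    # (left quadrant, right quadrant) per jaw in scope; left member preferred.
    if jaw_scope is JawScope.MANDIBLE:
        return [(3, 4)]
    if jaw_scope is JawScope.MAXILLA:
        return [(2, 1)]
    return [(3, 4), (2, 1)]


def nolla_sum(
    record: DentitionRecord,
    jaw_scope: JawScope = JawScope.MANDIBLE,
    include_third_molars: bool = False,
) -> tuple[float, list[ToothId], list[int]]:
    """Sum of Nolla values, one per left/right tooth pair in scope.

    Left and right development is near-identical, so only one value is
    retained per pair: the left member's when assessable, otherwise the
    right member's (recorded as a substitution).  Returns
    (sum, teeth used, substituted FDI codes); a pair with neither member
    assessable raises :class:`IncompleteDentitionError`.
    """
    positions = range(1, 9) if include_third_molars else range(1, 8)
    total = 0.0
    used: list[ToothId] = []
    subs: list[int] = []
    for left_q, right_q in _scope_quadrant_pairs(jaw_scope):
        for pos in positions:
            preferred = ToothId(left_q * 10 + pos)
            a = contralateral_substitute(record, preferred, Scheme.NOLLA)
            if a is None:
                raise IncompleteDentitionError(
                    f"no Nolla stage for pair {preferred}/{preferred.contralateral()}"
                )
            total += nolla_tooth_value(a.stage, a.proximity)
            used.append(a.tooth)
            if a.substituted:
                subs.append(preferred.fdi_code)
    return total, used, subs


def lookup_age(knots: Sequence[tuple[float, float]], x: float) -> tuple[float, bool]:
    """Map an abscissa to age through ordered (x, age) knots.

    Exact knot hits return the tabulated age exactly; values strictly
    between knots are linearly interpolated; values outside the tabulated
    range return the nearest boundary age with ``clamped=True``.
    """
    if len(knots) < 2:
        raise TableError("lookup table needs at least 2 knots")
    xs = [k[0] for k in knots]
    ages = [k[1] for k in knots]
    if x <= xs[0]:
        return ages[0], x < xs[0]
    if x >= xs[-1]:
        return ages[-1], x > xs[-1]
    # binary search for the bracketing interval
    lo, hi = 0, len(xs) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    if x == xs[lo]:
        return ages[lo], False
    frac = (x - xs[lo]) / (xs[hi] - xs[lo])
    return ages[lo] + frac * (ages[hi] - ages[lo]), False


def estimate_nolla(
    record: DentitionRecord,
    tables: ReferenceTableSet,
    jaw_scope: JawScope = JawScope.MANDIBLE,
    include_third_molars: bool | None = None,
) -> EstimateResult:
    """Nolla estimate for one subject.

    ``include_third_molars=None`` (the default) includes the third-molar
    pairs exactly when every pair in scope has an assessable member, and
    selects the matching sex-specific table variant.
    """
    if include_third_molars is None:
        include_third_molars = all(
            contralateral_substitute(record, ToothId(lq * 10 + 8), Scheme.NOLLA) is not None
            for lq, _ in _scope_quadrant_pairs(jaw_scope)
        )
    try:
        table = tables.nolla_table(record.sex, jaw_scope, include_third_molars)
    except KeyError as exc:
        raise TableError(str(exc)) from exc
    total, used, subs = nolla_sum(record, jaw_scope, include_third_molars)
    age, clamped = lookup_age(table.knots, total)
    return EstimateResult(
        method=Method.NOLLA,
        age_est=age,
        intermediate={
            "sum_of_values": total,
            "teeth_used": [t.fdi_code for t in used],
            "jaw_scope": jaw_scope.value,
            "third_molars_included": include_third_molars,
        },
        substitutions=subs,
        clamped=clamped,
        subject_id=record.subject_id,
    )


# ---------------------------------------------------------------------------
# Demirjian + Olze
# ---------------------------------------------------------------------------

#: FDI codes of the seven left mandibular teeth, central incisor to second
#: molar, indexed by Demirjian position 1-7.
_DEMIRJIAN_TEETH = tuple(ToothId(30 + p) for p in range(1, 8))


def demirjian_maturity_score(
    record: DentitionRecord, score_table: DemirjianScoreTable
) -> tuple[float, list[tuple[int, str]], list[int]]:
    """Maturity score S: sum of self-weighted scores over positions 1-7.

    Uses the left mandibular teeth 31-37, reading the right-side
    contralateral when a left tooth is missing.  Returns
    (S, [(position, stage)], substituted FDI codes).
    """
    total = 0.0
    stages: list[tuple[int, str]] = []
    subs: list[int] = []
    for pos, tooth in enumerate(_DEMIRJIAN_TEETH, start=1):
        a = contralateral_substitute(record, tooth, Scheme.DEMIRJIAN)
        if a is None:
            raise IncompleteDentitionError(f"no Demirjian stage for position {pos} ({tooth}/{tooth.contralateral()})")
        try:
            total += score_table.score(pos, a.stage)
        except KeyError as exc:
            raise UnmappedStageError(str(exc)) from exc
        stages.append((pos, a.stage))
        if a.substituted:
            subs.append(tooth.fdi_code)
    return total, stages, subs


def demirjian_age(S: float, age_table: DemirjianAgeTable) -> tuple[float, bool]:
    """Dental age for maturity score S.

    Knot hits return the tabulated age; a score exactly midway between two
    adjacent knots returns the mean of their ages (the classical reading
    rule), which linear interpolation generalises; out-of-range scores
    clamp to the boundary age.
    """
    if not (0.0 <= S <= 100.0):
        raise ValueError(f"maturity score must be in [0, 100], got {S!r}")
    return lookup_age(age_table.knots, S)


def olze_age(
    record: DentitionRecord, olze_table: OlzeTable
) -> tuple[float, ToothId] | None:
    """Third-molar age: tooth 38's Demirjian stage read in Olze's table.

    Tooth 48 is analysed when 38 is missing; returns None when neither
    third molar is stageable, and raises :class:`UnmappedStageError` for a
    stage absent from the table (early stages precede the table's range).
    """
    a = contralateral_substitute(record, ToothId(38), Scheme.DEMIRJIAN)
    if a is None:
        return None
    if a.stage not in olze_table.entries:
        raise UnmappedStageError(
            f"third-molar stage {a.stage!r} not mapped by the Olze table ({olze_table.sex.value})"
        )
    return olze_table.entries[a.stage], a.tooth


def estimate_demirjian_olze(
    record: DentitionRecord,
    tables: ReferenceTableSet,
    trigger_age: float = OLZE_TRIGGER_AGE,
) -> EstimateResult:
    """Demirjian estimate with the Olze third-molar supplement.

    The base estimate comes from the maturity score; when it is strictly
    above ``trigger_age`` (the method's 16-year calibration ceiling) and a
    third molar is stageable in Olze's table, the Olze age replaces it.
    Both ages are kept in the intermediate detail.
    """
    try:
        score_table = tables.demirjian_scores[record.sex]
        age_table = tables.demirjian_age[record.sex]
        olze_table = tables.olze[record.sex]
    except KeyError as exc:
        raise TableError(f"missing Demirjian/Olze table for sex {record.sex.value}") from exc
    S, stages, subs = demirjian_maturity_score(record, score_table)
    base_age, clamped = demirjian_age(S, age_table)
    intermediate = {
        "maturity_score": S,
        "stages": stages,
        "base_age": base_age,
        "olze_triggered": False,
        "olze_attempted": False,
    }
    age = base_age
    if base_age > trigger_age:
        intermediate["olze_attempted"] = True
        try:
            olze = olze_age(record, olze_table)
        except UnmappedStageError:
            olze = None
            intermediate["olze_unmapped_stage"] = True
        if olze is not None:
            age, tooth = olze
            intermediate["olze_triggered"] = True
            intermediate["olze_age"] = age
            intermediate["olze_tooth"] = tooth.fdi_code
            if tooth.fdi_code == 48:
                subs = subs + [38]
            clamped = False
    return EstimateResult(
        method=Method.DEMIRJIAN_OLZE,
        age_est=age,
        intermediate=intermediate,
        substitutions=subs,
        clamped=clamped,
        subject_id=record.subject_id,
    )


# ---------------------------------------------------------------------------
# London-atlas pattern matching
# ---------------------------------------------------------------------------


def atlas_mismatch(
    pattern_observed: dict[ToothId, int], chart_pattern: dict[ToothId, int]
) -> float:
    """Mean absolute ordinal stage discrepancy over shared teeth.

    Zero iff the patterns agree on every shared tooth; raises
    :class:`IncomparableError` when the patterns share no tooth.
    """
    shared = pattern_observed.keys() & chart_pattern.keys()
    if not shared:
        raise IncomparableError("observation and chart share no teeth")
    return sum(abs(pattern_observed[t] - chart_pattern[t]) for t in shared) / len(shared)


def _observed_atlas_pattern(
    record: DentitionRecord, atlas: AtlasChartSet
) -> tuple[dict[ToothId, int], list[int]]:
    # Charts follow the atlas convention of right-side teeth; the mirror
    # tooth substitutes when the charted tooth was not assessed.
    chart_teeth: set[ToothId] = set()
    for _, pattern in atlas.charts:
        chart_teeth.update(pattern)
    observed: dict[ToothId, int] = {}
    subs: list[int] = []
    for tooth in sorted(chart_teeth):
        a = contralateral_substitute(record, tooth, Scheme.ATLAS)
        if a is not None:
            observed[tooth] = a.stage
            if a.substituted:
                subs.append(tooth.fdi_code)
    return observed, subs


def estimate_london_atlas(
    record: DentitionRecord, atlas: AtlasChartSet, tie_tol: float = 1e-9
) -> EstimateResult:
    """Atlas estimate: age of the most similar chart.

    Charts tying for minimal mismatch (an observation "between two
    figures") contribute the arithmetic mean of their ages.  Sex is
    ignored: the atlas makes no distinction between males and females.
    """
    observed, subs = _observed_atlas_pattern(record, atlas)
    scored: list[tuple[float, float]] = []  # (mismatch, chart_age)
    for chart_age, pattern in atlas.charts:
        try:
            scored.append((atlas_mismatch(observed, pattern), chart_age))
        except IncomparableError:
            continue
    if not scored:
        raise EstimationFailureError(
            f"subject {record.subject_id}: observation comparable with no atlas chart"
        )
    best = min(m for m, _ in scored)
    tied = sorted(a for m, a in scored if m <= best + tie_tol)
    age = sum(tied) / len(tied)
    return EstimateResult(
        method=Method.LONDON_ATLAS,
        age_est=age,
        intermediate={
            "matched_chart_ages": tied,
            "min_mismatch": best,
            "n_charts_compared": len(scored),
        },
        substitutions=subs,
        clamped=False,
        subject_id=record.subject_id,
    )
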