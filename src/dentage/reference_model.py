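"""Domain model for table-driven dental age estimation.

Tooth identity (FDI two-digit notation), developmental-stage assessments
under the three staging schemes (Nolla 10-stage, Demirjian A-H,
atlas ordinal), per-subject dentition records, and the reference lookup
tables that parameterise each estimation engine, together with schema
validation and JSON (de)serialisation for table sets.

All ages are decimal years; chronological age is carried at one-month
resolution (years + months/12).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "Scheme",
    "Sex",
    "JawScope",
    "Proximity",
    "ToothId",
    "StageAssessment",
    "DentitionRecord",
    "NollaTable",
    "DemirjianScoreTable",
    "DemirjianAgeTable",
    "OlzeTable",
    "AtlasChartSet",
    "ReferenceTableSet",
    "Violation",
    "validate_table_set",
    "contralateral_substitute",
    "parse_stage_token",
    "stage_token",
    "TableFormatError",
    "DEMIRJIAN_STAGES",
    "TABLE_SCHEMA_VERSION",
]

TABLE_SCHEMA_VERSION = "dentage-tables/1"

#: Demirjian stage letters in developmental order. "0" is the absent-crypt
#: token that precedes A (tooth not yet visible radiographically).
DEMIRJIAN_STAGES: tuple[str, ...] = ("0", "A", "B", "C", "D", "E", "F", "G", "H")


class TableFormatError(ValueError):
    """A reference-table document could not be parsed or fails its schema."""


class Scheme(str, enum.Enum):
    """Staging scheme under which a tooth was assessed."""

    NOLLA = "NOLLA"
    DEMIRJIAN = "DEMIRJIAN"
    ATLAS = "ATLAS"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class JawScope(str, enum.Enum):
    """Which jaw(s) a Nolla sum is taken over."""

    MANDIBLE = "mandible"
    MAXILLA = "maxilla"
    BOTH = "both"


class Proximity(str, enum.Enum):
    """Nolla between-stage qualifier.

    A tooth strictly between integer stages k and k+1 is scored k + 0.2 if
    closer to k, k + 0.7 if closer to k+1, and k + 0.5 if equidistant; a
    tooth exactly at a stage is scored k.  Encoding the qualifier (rather
    than a free decimal) makes invalid refinements such as 6.3
    unrepresentable.
    """

    EXACT = "exact"
    PLUS02 = "plus02"
    PLUS05 = "plus05"
    PLUS07 = "plus07"

    @property
    def offset(self) -> float:
        return _PROXIMITY_OFFSET[self]


_PROXIMITY_OFFSET = {
    Proximity.EXACT: 0.0,
    Proximity.PLUS02: 0.2,
    Proximity.PLUS05: 0.5,
    Proximity.PLUS07: 0.7,
}


@dataclass(frozen=True, order=True)
class ToothId:
    """A permanent tooth in FDI two-digit notation.

    First digit is the quadrant (1 upper right, 2 upper left, 3 lower left,
    4 lower right); second is the position from the midline (1 central
    incisor ... 8 third molar).  Tooth 38 is the lower-left third molar.
    """

    fdi_code: int

    def __post_init__(self) -> None:
        if not (self.quadrant in (1, 2, 3, 4) and 1 <= self.position <= 8):
            raise ValueError(f"invalid FDI code {self.fdi_code!r}")

    @property
    def quadrant(self) -> int:
        return self.fdi_code // 10

    @property
    def position(self) -> int:
        return self.fdi_code % 10

    @property
    def is_mandibular(self) -> bool:
        return self.quadrant in (3, 4)

    @property
    def is_left(self) -> bool:
        return self.quadrant in (2, 3)

    @property
    def is_third_molar(self) -> bool:
        return self.position == 8

    def contralateral(self) -> "ToothId":
        """Mirror tooth across the midline (38 <-> 48, 11 <-> 21)."""
        return ToothId(_MIRROR_QUADRANT[self.quadrant] * 10 + self.position)

    def pair_partner(self) -> "ToothId":
        """Antagonist: same side and position in the opposing jaw (18 <-> 48)."""
        return ToothId(_ANTAGONIST_QUADRANT[self.quadrant] * 10 + self.position)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.fdi_code)


_MIRROR_QUADRANT = {1: 2, 2: 1, 3: 4, 4: 3}
_ANTAGONIST_QUADRANT = {1: 4, 4: 1, 2: 3, 3: 2}

#: All 32 permanent teeth.
ALL_TEETH: tuple[ToothId, ...] = tuple(
    ToothId(q * 10 + p) for q in (1, 2, 3, 4) for p in range(1, 9)
)


@dataclass(frozen=True)
class StageAssessment:
    """One tooth's developmental stage under one staging scheme.

    ``stage`` is scheme-specific: an integer 1-10 for Nolla (with
    ``proximity`` refining it), a letter A-H or the "0" absent-crypt token
    for Demirjian, and a non-negative ordinal index for atlas patterns.
    A tooth that is not observable on the image carries ``present=False``
    and no stage.
    """

    tooth: ToothId
    scheme: Scheme
    stage: int | str | None
    present: bool = True
    proximity: Proximity = Proximity.EXACT
    substituted: bool = False

    def __post_init__(self) -> None:
        if not self.present:
            if self.stage is not None:
                raise ValueError("a missing tooth carries no stage")
            return
        if self.scheme is Scheme.NOLLA:
            if not (isinstance(self.stage, int) and 1 <= self.stage <= 10):
                raise ValueError(f"Nolla stage must be an integer 1-10, got {self.stage!r}")
            if self.proximity is not Proximity.EXACT and self.stage > 9:
                raise ValueError("stage 10 admits no between-stage qualifier")
        elif self.scheme is Scheme.DEMIRJIAN:
            if self.stage not in DEMIRJIAN_STAGES:
                raise ValueError(f"Demirjian stage must be one of {DEMIRJIAN_STAGES}, got {self.stage!r}")
        elif self.scheme is Scheme.ATLAS:
            if not (isinstance(self.stage, int) and self.stage >= 0):
                raise ValueError(f"atlas stage must be a non-negative ordinal, got {self.stage!r}")


def stage_token(assessment: StageAssessment) -> str:
    """Render a stage as the text token used in record files."""
    if not assessment.present:
        return ""
    if assessment.scheme is Scheme.NOLLA:
        off = assessment.proximity.offset
        return str(assessment.stage) if off == 0.0 else f"{assessment.stage + off:.1f}"
    return str(assessment.stage)


def parse_stage_token(scheme: Scheme, token: str) -> tuple[int | str, Proximity]:
    """Parse a text stage token for ``scheme``.

    Nolla tokens are "6", "6.2", "6.5" or "6.7" (any other decimal part is
    rejected); Demirjian tokens are the letters A-H or "0"; atlas tokens
    are non-negative integers.  Returns (stage, proximity); proximity is
    EXACT except for refined Nolla tokens.
    """
    token = token.strip()
    if scheme is Scheme.NOLLA:
        if "." in token:
            whole, _, frac = token.partition(".")
            try:
                stage = int(whole)
            except ValueError:
                raise ValueError(f"malformed Nolla stage token {token!r}") from None
            prox = {"2": Proximity.PLUS02, "5": Proximity.PLUS05, "7": Proximity.PLUS07, "0": Proximity.EXACT}.get(frac)
            if prox is None:
                raise ValueError(f"Nolla refinement must be .2, .5 or .7, got {token!r}")
            return stage, prox
        try:
            return int(token), Proximity.EXACT
        except ValueError:
            raise ValueError(f"malformed Nolla stage token {token!r}") from None
    if scheme is Scheme.DEMIRJIAN:
        up = token.upper()
        if up not in DEMIRJIAN_STAGES:
            raise ValueError(f"unknown Demirjian stage token {token!r}")
        return up, Proximity.EXACT
    try:
        return int(token), Proximity.EXACT
    except ValueError:
        raise ValueError(f"malformed atlas stage token {token!r}") from None


@dataclass
class DentitionRecord:
    """A subject's sex, chronological age and per-tooth stage assessments.

    ``age_true`` is decimal years at one-month resolution.  At most one
    assessment per (tooth, scheme) is allowed; cohorts emulating the study
    design are soft-validated to ages 4-21 (a warning, not an error).
    """

    subject_id: str
    sex: Sex
    age_true: float
    assessments: list[StageAssessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_true <= 0:
            raise ValueError("age_true must be positive")
        if not (4.0 <= self.age_true <= 21.0):
            warnings.warn(
                f"subject {self.subject_id}: age {self.age_true:.2f} outside the 4-21 y design range",
                stacklevel=2,
            )
        seen: set[tuple[int, Scheme]] = set()
        for a in self.assessments:
            key = (a.tooth.fdi_code, a.scheme)
            if key in seen:
                raise ValueError(f"duplicate assessment for tooth {a.tooth} under {a.scheme.value}")
            seen.add(key)

    def find(self, tooth: ToothId, scheme: Scheme) -> StageAssessment | None:
        for a in self.assessments:
            if a.tooth == tooth and a.scheme == scheme and a.present:
                return a
        return None


def contralateral_substitute(
    record: DentitionRecord, tooth: ToothId, scheme: Scheme
) -> StageAssessment | None:
    """Assessment for ``tooth``, falling back to its left/right mirror.

    Returns the tooth's own assessment when present; otherwise the
    contralateral tooth's assessment flagged ``substituted=True`` (left and
    right development is near-identical, so a mirror tooth is an accepted
    stand-in — the classic case being tooth 48 read in place of a missing
    38); otherwise None.
    """
    own = record.find(tooth, scheme)
    if own is not None:
        return own
    mirror = record.find(tooth.contralateral(), scheme)
    if mirror is not None:
        return replace(mirror, substituted=True)
    return None


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------


@dataclass
class NollaTable:
    """Sex-specific sum-of-values -> age knots for one jaw scope.

    ``knots`` are (sum_of_values, age) pairs, strictly increasing in the
    sum and non-decreasing in age; ages between knots are obtained by
    linear interpolation, outside them by clamping.
    """

    sex: Sex
    jaw_scope: JawScope
    includes_third_molars: bool
    knots: list[tuple[float, float]]


@dataclass
class DemirjianScoreTable:
    """Sex-specific self-weighted scores: (position 1-7, stage) -> score."""

    sex: Sex
    entries: dict[tuple[int, str], float]

    def score(self, position: int, stage: str) -> float:
        try:
            return self.entries[(position, stage)]
        except KeyError:
            raise KeyError(f"no score for position {position} stage {stage!r} ({self.sex.value})") from None


@dataclass
class DemirjianAgeTable:
    """Maturity score S (0-100) -> dental age knots, per sex.

    The method is calibrated only up to ``usable_max_age`` (16 years by
    convention); knots may extend slightly beyond it so that saturated
    scores still yield an estimate, which is what triggers the third-molar
    supplement.
    """

    sex: Sex
    knots: list[tuple[float, float]]
    usable_max_age: float = 16.0


@dataclass
class OlzeTable:
    """Third-molar Demirjian stage -> age, per sex (stages D-H typically)."""

    sex: Sex
    entries: dict[str, float]


@dataclass
class AtlasChartSet:
    """Age-indexed whole-dentition stage patterns (sex-agnostic).

    Each chart is (chart_age, {ToothId: ordinal stage}); charts are ordered
    by strictly increasing age at 0.5-1.0 year steps over the covered span.
    """

    charts: list[tuple[float, dict[ToothId, int]]]
    sex_agnostic: bool = True


@dataclass
class ReferenceTableSet:
    """Every lookup table the three engines need, plus provenance.

    ``provenance`` maps a table-family name to a free-text source citation;
    a set shipped with this package is synthetic (derived from a maturation
    model) and says so in its provenance strings.
    """

    nolla: list[NollaTable]
    demirjian_scores: dict[Sex, DemirjianScoreTable]
    demirjian_age: dict[Sex, DemirjianAgeTable]
    olze: dict[Sex, OlzeTable]
    atlas: AtlasChartSet
    provenance: dict[str, str] = field(default_factory=dict)

    def nolla_table(self, sex: Sex, jaw_scope: JawScope, includes_third_molars: bool) -> NollaTable:
        for t in self.nolla:
            if (t.sex, t.jaw_scope, t.includes_third_molars) == (sex, jaw_scope, includes_third_molars):
                return t
        raise KeyError(
            f"no Nolla table for sex={sex.value}, scope={jaw_scope.value}, "
            f"third_molars={includes_third_molars}"
        )


@dataclass(frozen=True)
class Violation:
    """One schema violation: which table, which field, which rule failed."""

    table: str
    fld: str
    rule: str

    def __str__(self) -> str:
        return f"{self.table}.{self.fld}: {self.rule}"


def _check_knots(
    name: str, knots: Sequence[tuple[float, float]], out: list[Violation], x_name: str = "x"
) -> None:
    if len(knots) < 2:
        out.append(Violation(name, "knots", "at least 2 knots required"))
        return
    xs = [k[0] for k in knots]
    ages = [k[1] for k in knots]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        out.append(Violation(name, "knots", f"knots not strictly increasing in {x_name}"))
    if any(b < a for a, b in zip(ages, ages[1:])):
        out.append(Violation(name, "knots", "knot ages not non-decreasing"))


def validate_table_set(tables: ReferenceTableSet) -> list[Violation]:
    """Validate every invariant of a reference-table set.

    Returns an empty list iff the set is well-formed and complete: Nolla
    knots monotone, Demirjian scores strictly increasing along the stage
    order at every position, age knots monotone, Olze ages non-decreasing
    along the stage order, atlas chart ages strictly increasing at 0.5-1 y
    steps, and one table per required (engine, sex) slot.
    """
    out: list[Violation] = []

    if not tables.nolla:
        out.append(Violation("nolla", "tables", "no Nolla tables present"))
    seen_nolla = set()
    for t in tables.nolla:
        name = f"nolla[{t.sex.value},{t.jaw_scope.value},M3={t.includes_third_molars}]"
        key = (t.sex, t.jaw_scope, t.includes_third_molars)
        if key in seen_nolla:
            out.append(Violation(name, "identity", "duplicate table for this (sex, scope, M3) slot"))
        seen_nolla.add(key)
        _check_knots(name, t.knots, out, "sum_of_values")
    for sex in Sex:
        if not any(t.sex == sex and t.jaw_scope == JawScope.MANDIBLE for t in tables.nolla):
            out.append(Violation("nolla", "tables", f"missing mandible table for sex {sex.value}"))

    for sex in Sex:
        st = tables.demirjian_scores.get(sex)
        if st is None:
            out.append(Violation("demirjian_scores", "tables", f"missing score table for sex {sex.value}"))
        else:
            name = f"demirjian_scores[{sex.value}]"
            order = {s: i for i, s in enumerate(DEMIRJIAN_STAGES)}
            positions = sorted({p for p, _ in st.entries})
            if not positions:
                out.append(Violation(name, "entries", "empty score table"))
            for p in positions:
                staged = sorted(
                    ((order[s], st.entries[(p, s)]) for q, s in st.entries if q == p),
                )
                scores = [v for _, v in staged]
                if any(b <= a for a, b in zip(scores, scores[1:])):
                    out.append(Violation(name, "entries", f"scores not strictly increasing at position {p}"))

        at = tables.demirjian_age.get(sex)
        if at is None:
            out.append(Violation("demirjian_age", "tables", f"missing age table for sex {sex.value}"))
        else:
            name = f"demirjian_age[{sex.value}]"
            _check_knots(name, at.knots, out, "S")
            if at.knots and not all(0.0 <= k[0] <= 100.0 for k in at.knots):
                out.append(Violation(name, "knots", "maturity score outside [0, 100]"))

        ot = tables.olze.get(sex)
        if ot is None:
            out.append(Violation("olze", "tables", f"missing Olze table for sex {sex.value}"))
        else:
            name = f"olze[{sex.value}]"
            order = {s: i for i, s in enumerate(DEMIRJIAN_STAGES)}
            unknown = [s for s in ot.entries if s not in order]
            if unknown:
                out.append(Violation(name, "entries", f"unknown stage tokens {unknown}"))
            else:
                staged = sorted(ot.entries.items(), key=lambda kv: order[kv[0]])
                ages = [v for _, v in staged]
                if any(b < a for a, b in zip(ages, ages[1:])):
                    out.append(Violation(name, "entries", "ages not non-decreasing along stage order"))
            if not ot.entries:
                out.append(Violation(name, "entries", "empty Olze table"))

    charts = tables.atlas.charts
    if not charts:
        out.append(Violation("atlas", "charts", "no charts present"))
    else:
        ages = [a for a, _ in charts]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            out.append(Violation("atlas", "charts", "chart ages not strictly increasing"))
        else:
            steps = [round(b - a, 6) for a, b in zip(ages, ages[1:])]
            if any(not (0.5 - 1e-9 <= s <= 1.0 + 1e-9) for s in steps):
                out.append(Violation("atlas", "charts", "consecutive chart ages must differ by 0.5-1.0 years"))
        if not (ages[0] <= 4.0 and ages[-1] >= 23.0):
            out.append(Violation("atlas", "charts", "charts must cover at least ages 4-23"))
        for age, pattern in charts:
            if not pattern:
                out.append(Violation("atlas", f"chart[{age}]", "empty pattern"))

    return out


# ---------------------------------------------------------------------------
# JSON (de)serialisation — schema "dentage-tables/1"
# ---------------------------------------------------------------------------


def table_set_to_dict(tables: ReferenceTableSet) -> dict:
    return {
        "schema": TABLE_SCHEMA_VERSION,
        "provenance": dict(tables.provenance),
        "nolla": [
            {
                "sex": t.sex.value,
                "jaw_scope": t.jaw_scope.value,
                "includes_third_molars": t.includes_third_molars,
                "knots": [[s, a] for s, a in t.knots],
            }
            for t in tables.nolla
        ],
        "demirjian_scores": {
            sex.value: {f"{p}{s}": v for (p, s), v in st.entries.items()}
            for sex, st in tables.demirjian_scores.items()
        },
        "demirjian_age": {
            sex.value: {"knots": [[s, a] for s, a in t.knots], "usable_max_age": t.usable_max_age}
            for sex, t in tables.demirjian_age.items()
        },
        "olze": {sex.value: dict(t.entries) for sex, t in tables.olze.items()},
        "atlas": {
            "sex_agnostic": tables.atlas.sex_agnostic,
            "charts": [
                {"age": age, "pattern": {str(t.fdi_code): st for t, st in pattern.items()}}
                for age, pattern in tables.atlas.charts
            ],
        },
    }


def table_set_from_dict(doc: Mapping) -> ReferenceTableSet:
    try:
        if doc.get("schema") != TABLE_SCHEMA_VERSION:
            raise TableFormatError(f"unsupported schema {doc.get('schema')!r}; expected {TABLE_SCHEMA_VERSION!r}")
        nolla = [
            NollaTable(
                sex=Sex(t["sex"]),
                jaw_scope=JawScope(t["jaw_scope"]),
                includes_third_molars=bool(t["includes_third_molars"]),
                knots=[(float(s), float(a)) for s, a in t["knots"]],
            )
            for t in doc["nolla"]
        ]
        scores = {
            Sex(sx): DemirjianScoreTable(
                sex=Sex(sx),
                entries={(int(k[0]), k[1:]): float(v) for k, v in ent.items()},
            )
            for sx, ent in doc["demirjian_scores"].items()
        }
        age = {
            Sex(sx): DemirjianAgeTable(
                sex=Sex(sx),
                knots=[(float(s), float(a)) for s, a in t["knots"]],
                usable_max_age=float(t.get("usable_max_age", 16.0)),
            )
            for sx, t in doc["demirjian_age"].items()
        }
        olze = {
            Sex(sx): OlzeTable(sex=Sex(sx), entries={k: float(v) for k, v in ent.items()})
            for sx, ent in doc["olze"].items()
        }
        atlas = AtlasChartSet(
            charts=[
                (float(c["age"]), {ToothId(int(k)): int(v) for k, v in c["pattern"].items()})
                for c in doc["atlas"]["charts"]
            ],
            sex_agnostic=bool(doc["atlas"].get("sex_agnostic", True)),
        )
        return ReferenceTableSet(
            nolla=nolla,
            demirjian_scores=scores,
            demirjian_age=age,
            olze=olze,
            atlas=atlas,
            provenance={str(k): str(v) for k, v in doc.get("provenance", {}).items()},
        )
    except TableFormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise TableFormatError(f"malformed table document: {exc}") from exc


def write_table_set(tables: ReferenceTableSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(table_set_to_dict(tables), indent=1, sort_keys=True))


def read_table_set(path: str | Path) -> ReferenceTableSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise TableFormatError(f"{path}:{exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise TableFormatError(f"{path}: top-level document must be an object")
    return table_set_from_dict(doc)
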