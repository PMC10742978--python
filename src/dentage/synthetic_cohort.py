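"""Synthetic staged-dentition cohorts with known chronological ages.

A single latent maturation state per subject drives the stages emitted
under all three staging schemes, so the engines are correlated across
schemes the way they are in real dentitions.  Each tooth type carries,
per sex, a strictly increasing list of mean stage-entry ages for each
scheme grid (10 Nolla stages, 8 Demirjian letters, a 10-point atlas
ordinal).  A subject of chronological age ``a`` receives a tempo shift
``z ~ Normal(0, individual_effect_sd)``; a tooth's latent stage is the
highest stage whose entry age is at or below ``a − z``, refined into
Nolla between-stage qualifiers by quartiles of the inter-stage interval.
Optional observation noise mis-stages a tooth by ±1 stage with a given
probability, truncated at the scheme boundaries.

:func:`derive_tables` evaluates the model's median (zero-shift)
trajectory on a fine age grid and collapses it into lookup tables that
are exactly consistent with the generating process — the round-trip
"estimate your own cohort" error is then bounded by the table
resolution.  :func:`bias_scenario` shifts every entry age earlier so
estimation against the unshifted tables overestimates by a known amount.

The default cohort composition reproduces the published study design:
324 subjects (156 males, 168 females) aged 4-20, with the published
per-age-category counts and ages drawn uniformly on the one-month grid
within each category.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .reference_model import (
    ALL_TEETH,
    AtlasChartSet,
    DEMIRJIAN_STAGES,
    DemirjianAgeTable,
    DemirjianScoreTable,
    DentitionRecord,
    JawScope,
    NollaTable,
    OlzeTable,
    Proximity,
    ReferenceTableSet,
    Scheme,
    Sex,
    StageAssessment,
    ToothId,
)
from .study_reference import STUDY_COUNTS, STUDY_N_MALE

__all__ = [
    "MaturationModel",
    "CohortSpec",
    "InvalidModelError",
    "simulate_cohort",
    "derive_tables",
    "bias_scenario",
]


class InvalidModelError(ValueError):
    """A maturation model violates its invariants."""


# Tooth type key: (jaw 'U'|'L', position 1-8); left/right members of a
# pair share one maturation trajectory.
ToothKey = tuple[str, int]

# Per-position development windows (start of crypt/calcification, apex
# closure), in years, for the mandible; the maxilla runs ~0.3 y later.
# Values are plausible for permanent teeth: first molars and incisors
# earliest, second molars latest except the third molar (~9 to ~21.5 y).
_MANDIBLE_WINDOWS: dict[int, tuple[float, float]] = {
    1: (0.7, 9.5),
    2: (1.0, 10.0),
    3: (0.7, 12.8),
    4: (1.9, 13.2),
    5: (2.6, 14.2),
    6: (0.7, 10.5),
    7: (2.8, 15.5),
    8: (9.0, 21.5),
}

#: Females develop earlier than males by about this many years.
_SEX_OFFSET = {Sex.MALE: +0.15, Sex.FEMALE: -0.15}

#: Self-weighted score budget per Demirjian position (sums to 100, molars
#: and premolars weighted heaviest, mirroring the self-weighted flavour
#: of maturity scoring).
_DEMIRJIAN_WEIGHTS: dict[int, float] = {1: 8, 2: 8, 3: 10, 4: 12, 5: 14, 6: 22, 7: 26}

_N_STAGES = {Scheme.NOLLA: 10, Scheme.DEMIRJIAN: 8, Scheme.ATLAS: 10}


def _entries(window: tuple[float, float], n: int) -> tuple[float, ...]:
    start, end = window
    return tuple(start + k * (end - start) / (n - 1) for k in range(n))


@dataclass
class MaturationModel:
    """Stage-entry ages per (sex, tooth type, scheme) plus variation knobs.

    ``entry_ages[sex][(jaw, pos)][scheme]`` is the ordered tuple of mean
    ages (years) at which each stage of that scheme's grid is entered;
    ``individual_effect_sd`` is the SD of the per-subject tempo shift in
    years; ``observation_noise`` is the probability of mis-staging a
    tooth by ±1 stage.
    """

    entry_ages: dict[Sex, dict[ToothKey, dict[Scheme, tuple[float, ...]]]]
    individual_effect_sd: float = 0.8
    observation_noise: float = 0.08

    def __post_init__(self) -> None:
        if self.individual_effect_sd < 0:
            raise InvalidModelError("individual_effect_sd must be >= 0")
        if not (0.0 <= self.observation_noise < 0.5):
            raise InvalidModelError("observation_noise must be in [0, 0.5)")
        for sex, teeth in self.entry_ages.items():
            for key, grids in teeth.items():
                for scheme, ages in grids.items():
                    if any(a <= 0 for a in ages):
                        raise InvalidModelError(f"non-positive entry age for {key} ({sex.value})")
                    if any(b <= a for a, b in zip(ages, ages[1:])):
                        raise InvalidModelError(
                            f"entry ages not strictly increasing for {key} {scheme.value} ({sex.value})"
                        )

    @classmethod
    def default(
        cls, individual_effect_sd: float = 0.8, observation_noise: float = 0.08
    ) -> "MaturationModel":
        """Study-emulating model built from the per-position windows."""
        entry_ages: dict[Sex, dict[ToothKey, dict[Scheme, tuple[float, ...]]]] = {}
        for sex in Sex:
            off = _SEX_OFFSET[sex]
            teeth: dict[ToothKey, dict[Scheme, tuple[float, ...]]] = {}
            for pos, (s, e) in _MANDIBLE_WINDOWS.items():
                for jaw, jaw_off in (("L", 0.0), ("U", 0.3)):
                    window = (s + off + jaw_off, e + off + jaw_off)
                    teeth[(jaw, pos)] = {
                        scheme: _entries(window, n) for scheme, n in _N_STAGES.items()
                    }
            entry_ages[sex] = teeth
        return cls(entry_ages, individual_effect_sd, observation_noise)

    def grid(self, sex: Sex, key: ToothKey, scheme: Scheme) -> tuple[float, ...]:
        return self.entry_ages[sex][key][scheme]

    def pooled_grid(self, key: ToothKey, scheme: Scheme) -> tuple[float, ...]:
        """Sex-pooled entry ages (the atlas makes no sex distinction)."""
        m = self.entry_ages[Sex.MALE][key][scheme]
        f = self.entry_ages[Sex.FEMALE][key][scheme]
        return tuple((a + b) / 2 for a, b in zip(m, f))


def _tooth_key(tooth: ToothId) -> ToothKey:
    return ("L" if tooth.is_mandibular else "U", tooth.position)


def _stage_count(entries: tuple[float, ...], m: float) -> int:
    """Number of stage-entry ages at or below latent maturation age m."""
    c = 0
    for e in entries:
        if e <= m:
            c += 1
        else:
            break
    return c


# Quartile thresholds of the inter-stage interval mapping latent progress
# to the Nolla between-stage qualifier.
_PROX_BREAKS = ((0.125, Proximity.EXACT), (0.375, Proximity.PLUS02), (0.625, Proximity.PLUS05))


def _nolla_parts(entries: tuple[float, ...], m: float) -> tuple[int, Proximity]:
    c = _stage_count(entries, m)
    if c == 0:
        return 1, Proximity.EXACT  # crypt forming: scored as stage 1
    if c >= len(entries):
        return len(entries), Proximity.EXACT
    frac = (m - entries[c - 1]) / (entries[c] - entries[c - 1])
    for brk, prox in _PROX_BREAKS:
        if frac < brk:
            return c, prox
    return c, Proximity.PLUS07


def _nolla_value(entries: tuple[float, ...], m: float) -> float:
    stage, prox = _nolla_parts(entries, m)
    return stage + prox.offset


# ---------------------------------------------------------------------------
# Cohort specification and simulation
# ---------------------------------------------------------------------------


def _split_males(counts: dict[int, int], n_male_total: int) -> dict[int, int]:
    """Largest-remainder allocation of the male total across categories."""
    total = sum(counts.values())
    quota = {c: n * n_male_total / total for c, n in counts.items()}
    males = {c: int(q) for c, q in quota.items()}
    shortfall = n_male_total - sum(males.values())
    by_frac = sorted(counts, key=lambda c: (quota[c] - males[c], -c), reverse=True)
    for c in by_frac[:shortfall]:
        males[c] += 1
    return males


@dataclass
class CohortSpec:
    """Cohort composition: subjects per (age category, sex) cell.

    ``counts[category] = (n_male, n_female)``.  Within a category, ages
    are drawn uniformly over [k, k+1) on the one-month grid.  The default
    reproduces the published study composition (324 subjects, 156 M /
    168 F, categories 4-20 with the published per-age counts).
    """

    counts: dict[int, tuple[int, int]]
    seed: int | None = None

    def __post_init__(self) -> None:
        for cat, (nm, nf) in self.counts.items():
            if nm < 0 or nf < 0:
                raise ValueError(f"negative count at category {cat}")

    @property
    def n_total(self) -> int:
        return sum(nm + nf for nm, nf in self.counts.values())

    @classmethod
    def study_default(cls, seed: int | None = None) -> "CohortSpec":
        males = _split_males(STUDY_COUNTS, STUDY_N_MALE)
        return cls(
            counts={c: (males[c], STUDY_COUNTS[c] - males[c]) for c in sorted(STUDY_COUNTS)},
            seed=seed,
        )


def _perturb(stage: int, lo: int, hi: int, rng: np.random.Generator) -> int:
    step = 1 if rng.random() < 0.5 else -1
    return min(hi, max(lo, stage + step))


def simulate_cohort(
    spec: CohortSpec, model: MaturationModel, seed: int | None = None
) -> list[DentitionRecord]:
    """Generate one staged cohort.

    Every (category, sex) cell receives exactly the requested count.
    Each subject's latent maturation age is ``age_true − z`` with
    ``z ~ Normal(0, individual_effect_sd)``; all 32 teeth are staged
    under all three schemes from that one latent state, except third
    molars before crypt formation, which are absent.  Mis-staging noise
    is applied independently per (tooth, scheme).  Deterministic given
    the seed (argument overrides ``spec.seed``).
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    records: list[DentitionRecord] = []
    idx = 0
    for cat in sorted(spec.counts):
        nm, nf = spec.counts[cat]
        for sex, n in ((Sex.MALE, nm), (Sex.FEMALE, nf)):
            for _ in range(n):
                idx += 1
                age = cat + int(rng.integers(0, 12)) / 12.0
                z = rng.normal(0.0, model.individual_effect_sd) if model.individual_effect_sd else 0.0
                m = age - z
                assessments: list[StageAssessment] = []
                for tooth in ALL_TEETH:
                    key = _tooth_key(tooth)
                    grids = model.entry_ages[sex][key]
                    if tooth.is_third_molar and m < grids[Scheme.NOLLA][0]:
                        continue  # crypt not yet visible
                    # Nolla
                    stage, prox = _nolla_parts(grids[Scheme.NOLLA], m)
                    if model.observation_noise and rng.random() < model.observation_noise:
                        stage, prox = _perturb(stage, 1, 10, rng), Proximity.EXACT
                    assessments.append(
                        StageAssessment(tooth, Scheme.NOLLA, stage, proximity=prox)
                    )
                    # Demirjian
                    d_idx = _stage_count(grids[Scheme.DEMIRJIAN], m)
                    if model.observation_noise and rng.random() < model.observation_noise:
                        d_idx = _perturb(d_idx, 0, 8, rng)
                    assessments.append(
                        StageAssessment(tooth, Scheme.DEMIRJIAN, DEMIRJIAN_STAGES[d_idx])
                    )
                    # Atlas ordinal
                    a_idx = _stage_count(grids[Scheme.ATLAS], m)
                    if model.observation_noise and rng.random() < model.observation_noise:
                        a_idx = _perturb(a_idx, 0, 10, rng)
                    assessments.append(StageAssessment(tooth, Scheme.ATLAS, a_idx))
                records.append(
                    DentitionRecord(
                        subject_id=f"S{idx:04d}", sex=sex, age_true=age, assessments=assessments
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Table derivation (noise-free median trajectory -> lookup tables)
# ---------------------------------------------------------------------------


def _collapse(xs: list[float], ages: list[float]) -> list[tuple[float, float]]:
    """Collapse a monotone step function sampled on a grid into knots.

    Each run of equal ordinate becomes one knot at the mean age of the
    run, so knots are strictly increasing in x and non-decreasing in age.
    """
    knots: list[tuple[float, float]] = []
    run_x, run_ages = xs[0], [ages[0]]
    for x, a in zip(xs[1:], ages[1:]):
        if x == run_x:
            run_ages.append(a)
        else:
            knots.append((run_x, sum(run_ages) / len(run_ages)))
            run_x, run_ages = x, [a]
    knots.append((run_x, sum(run_ages) / len(run_ages)))
    return knots


def _scope_keys(jaw_scope: JawScope, include_m3: bool) -> list[ToothKey]:
    jaws = {"mandible": ["L"], "maxilla": ["U"], "both": ["L", "U"]}[jaw_scope.value]
    positions = range(1, 9) if include_m3 else range(1, 8)
    return [(j, p) for j in jaws for p in positions]


def derive_tables(
    model: MaturationModel,
    atlas_step: float = 0.5,
    grid_step: float = 1.0 / 24.0,
    demirjian_max_age: float = 17.0,
    nolla_max_age: float = 17.0,
    nolla_m3_max_age: float = 22.0,
    max_age: float | None = None,
) -> ReferenceTableSet:
    """Build a reference-table set exactly consistent with the model.

    Tables are read off the model's zero-shift trajectory on a fine age
    grid: Nolla sum-to-age knots per (sex, jaw scope, third-molar flag),
    Demirjian score and score-to-age tables per sex (age knots end at
    ``demirjian_max_age``, a little past the method's 16-year calibration
    ceiling so saturated scores still trigger the third-molar
    supplement), Olze stage-to-age entries per sex from the mandibular
    third molar, and sex-pooled atlas charts at ``atlas_step`` covering
    ages 4-23.  ``max_age`` truncates every table at that age (used to
    study precision loss beyond a table's ceiling); a truncated set
    deliberately no longer covers the full cohort range.
    """
    if model.observation_noise:
        model = copy.deepcopy(model)
        model.observation_noise = 0.0

    def capped(x: float) -> float:
        return min(x, max_age) if max_age is not None else x

    nolla_tables: list[NollaTable] = []
    for sex in Sex:
        for scope in JawScope:
            for include_m3 in (False, True):
                keys = _scope_keys(scope, include_m3)
                start = max(model.grid(sex, k, Scheme.NOLLA)[0] for k in keys) + 1e-9
                end = capped(nolla_m3_max_age if include_m3 else nolla_max_age)
                ages = list(np.arange(start, end, grid_step))
                sums = [
                    sum(_nolla_value(model.grid(sex, k, Scheme.NOLLA), a) for k in keys)
                    for a in ages
                ]
                nolla_tables.append(
                    NollaTable(sex, scope, include_m3, _collapse(sums, ages))
                )

    score_tables: dict[Sex, DemirjianScoreTable] = {}
    age_tables: dict[Sex, DemirjianAgeTable] = {}
    olze_tables: dict[Sex, OlzeTable] = {}
    for sex in Sex:
        entries = {
            (pos, DEMIRJIAN_STAGES[i]): _DEMIRJIAN_WEIGHTS[pos] * i / 8.0
            for pos in range(1, 8)
            for i in range(9)
        }
        score_tables[sex] = DemirjianScoreTable(sex, entries)

        def S_at(a: float) -> float:
            return sum(
                _DEMIRJIAN_WEIGHTS[p]
                * _stage_count(model.grid(sex, ("L", p), Scheme.DEMIRJIAN), a)
                / 8.0
                for p in range(1, 8)
            )

        end = capped(demirjian_max_age)
        ages = list(np.arange(1.0, end, grid_step))
        age_tables[sex] = DemirjianAgeTable(
            sex, _collapse([S_at(a) for a in ages], ages), usable_max_age=16.0
        )

        m3 = model.grid(sex, ("L", 8), Scheme.DEMIRJIAN)
        olze_entries: dict[str, float] = {}
        for i in range(4, 9):  # stages D-H
            e = m3[i - 1]
            rep = (e + m3[i]) / 2 if i < 8 else e + 0.75
            if max_age is None or rep <= max_age:
                olze_entries[DEMIRJIAN_STAGES[i]] = rep
        olze_tables[sex] = OlzeTable(sex, olze_entries)

    charts: list[tuple[float, dict[ToothId, int]]] = []
    for age in np.arange(4.0, capped(23.0) + 1e-9, atlas_step):
        pattern: dict[ToothId, int] = {}
        for quadrant in (1, 4):  # atlas convention: right-side teeth
            for pos in range(1, 9):
                tooth = ToothId(quadrant * 10 + pos)
                grid = model.pooled_grid(_tooth_key(tooth), Scheme.ATLAS)
                c = _stage_count(grid, float(age))
                if tooth.is_third_molar and c == 0:
                    continue
                pattern[tooth] = c
        charts.append((round(float(age), 6), pattern))

    note = "synthetic: derived from a dentage maturation model; not a published table"
    return ReferenceTableSet(
        nolla=nolla_tables,
        demirjian_scores=score_tables,
        demirjian_age=age_tables,
        olze=olze_tables,
        atlas=AtlasChartSet(charts=charts),
        provenance={k: note for k in ("nolla", "demirjian_scores", "demirjian_age", "olze", "atlas")},
    )


def bias_scenario(model: MaturationModel, bias_years: float) -> MaturationModel:
    """Model whose stages appear ``bias_years`` earlier.

    Estimating such a cohort against tables derived from the *unshifted*
    model overestimates age by about ``bias_years`` — the construction
    used to reproduce systematic overestimation at a known effect size.
    """
    shifted = copy.deepcopy(model)
    for sex, teeth in shifted.entry_ages.items():
        for key, grids in teeth.items():
            for scheme, ages in grids.items():
                new = tuple(a - bias_years for a in ages)
                if any(a <= 0 for a in new):
                    raise InvalidModelError(
                        f"bias of {bias_years} y makes entry ages non-positive for {key}"
                    )
                grids[scheme] = new
    return shifted
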