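"""End-to-end orchestration: estimate every subject, evaluate every method.

Thin glue between the engines and the evaluation layer, shared by the
command-line interface and by scripted analyses.  Subjects for whom an
engine fails (e.g. an incomplete dentition) are skipped with a logged
warning rather than aborting the run; the evaluation then covers the
subjects the method could actually estimate, as a reading session would.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from . import estimators, evaluation
from .estimators import EstimateResult, EstimationError, Method
from .evaluation import CategoryStats, ComparisonResult, DegenerateTestError, ErrorRecord
from .reference_model import DentitionRecord, JawScope, ReferenceTableSet

__all__ = ["estimate_all", "evaluate_methods", "log_provenance"]

logger = logging.getLogger("dentage")

_METHOD_KEYS = {"nolla": Method.NOLLA, "demirjian": Method.DEMIRJIAN_OLZE, "atlas": Method.LONDON_ATLAS}


def estimate_all(
    records: Iterable[DentitionRecord],
    tables: ReferenceTableSet,
    methods: Sequence[str] = ("nolla", "demirjian", "atlas"),
    jaw_scope: JawScope = JawScope.MANDIBLE,
    include_third_molars: bool | None = None,
    olze_trigger_age: float = estimators.OLZE_TRIGGER_AGE,
) -> dict[Method, list[EstimateResult]]:
    """Run the selected engines over a cohort.

    Returns one result list per method; failures are logged and skipped.
    """
    unknown = set(methods) - set(_METHOD_KEYS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {sorted(_METHOD_KEYS)}")
    out: dict[Method, list[EstimateResult]] = {_METHOD_KEYS[m]: [] for m in methods}
    for record in records:
        for key in methods:
            method = _METHOD_KEYS[key]
            try:
                if method is Method.NOLLA:
                    est = estimators.estimate_nolla(
                        record, tables, jaw_scope=jaw_scope, include_third_molars=include_third_molars
                    )
                elif method is Method.DEMIRJIAN_OLZE:
                    est = estimators.estimate_demirjian_olze(record, tables, trigger_age=olze_trigger_age)
                else:
                    est = estimators.estimate_london_atlas(record, tables.atlas)
            except EstimationError as exc:
                logger.warning("subject %s: %s estimate failed: %s", record.subject_id, method.value, exc)
                continue
            log_provenance(est)
            out[method].append(est)
    return out


def log_provenance(est: EstimateResult) -> None:
    """Log every substitution, clamp and supplement trigger of one result."""
    for fdi in est.substitutions:
        logger.info("subject %s %s: contralateral substitution for tooth %s", est.subject_id, est.method.value, fdi)
    if est.clamped:
        logger.info("subject %s %s: lookup clamped to table boundary", est.subject_id, est.method.value)
    if est.intermediate.get("olze_triggered"):
        logger.info(
            "subject %s: Olze supplement used (tooth %s)", est.subject_id, est.intermediate.get("olze_tooth")
        )


def evaluate_methods(
    estimates: Mapping[Method, list[EstimateResult]],
    records: Iterable[DentitionRecord],
    margins: Sequence[float] = evaluation.DEFAULT_MARGINS,
) -> tuple[
    dict[Method, list[ErrorRecord]],
    dict[Method, tuple[list[CategoryStats], CategoryStats]],
    dict,
    dict[str, ComparisonResult],
]:
    """Errors, per-category stats, report tables and paired comparisons.

    Comparisons cover each method's estimated-vs-real ages (paired t) and
    each method pair's absolute errors on the common subjects; degenerate
    comparisons are reported as notes rather than results.
    """
    records = list(records)
    ages = {r.subject_id: r.age_true for r in records}
    errors = {m: evaluation.compute_errors(ests, records) for m, ests in estimates.items()}
    stats = {m: evaluation.aggregate_by_category(errs, margins) for m, errs in errors.items() if errs}
    tables = evaluation.report_tables(stats, margins) if stats else {}

    comparisons: dict[str, ComparisonResult] = {}
    for m, ests in estimates.items():
        if len(ests) < 2:
            continue
        est_ages = [e.age_est for e in ests]
        true_ages = [ages[e.subject_id] for e in ests]
        try:
            comparisons[f"{m.value}_vs_real_age"] = evaluation.paired_t_test(est_ages, true_ages)
        except DegenerateTestError:
            logger.warning("%s vs real age: zero-variance differences, test skipped", m.value)
    methods = [m for m in estimates if errors[m]]
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            shared = {e.subject_id for e in errors[ma]} & {e.subject_id for e in errors[mb]}
            a = [e for e in errors[ma] if e.subject_id in shared]
            b = [e for e in errors[mb] if e.subject_id in shared]
            if len(a) < 2:
                continue
            try:
                comparisons[f"{ma.value}_vs_{mb.value}_abs_error"] = evaluation.compare_methods(a, b)
            except DegenerateTestError:
                logger.warning("%s vs %s: zero-variance differences, test skipped", ma.value, mb.value)
    return errors, stats, tables, comparisons
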