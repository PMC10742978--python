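"""Published per-age accuracy summaries used as reference inputs.

These are the per-age-category summary statistics reported by a published
comparative evaluation of the Nolla, Demirjian(+Olze) and London-atlas
methods on a 324-subject multiethnic hospital sample (156 males,
168 females, ages 4-20, chronological age known to one month).  Only the
printed aggregates are public — the underlying per-subject data are not
deposited — so these tables serve two roles here:

* the per-age values and counts are inputs to :func:`dentage.evaluation.
  weighted_totals`, whose count-weighted means reproduce the published
  total rows; and
* the per-age subject counts are the default cohort composition of
  :class:`dentage.synthetic_cohort.CohortSpec`.

Note: the published per-age rates at categories 10 and 16 imply
denominators (19 and 21) inconsistent with the printed counts (20 and 20);
the count-weighted totals therefore reproduce the printed rate totals only
to about 0.1 percentage point.  The discrepancy is in the source and is
reported, not corrected.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STUDY_AGE_CATEGORIES",
    "STUDY_COUNTS",
    "STUDY_N",
    "STUDY_N_MALE",
    "STUDY_N_FEMALE",
    "study_table1",
    "study_table2",
]

STUDY_AGE_CATEGORIES: tuple[int, ...] = tuple(range(4, 21))

#: Subjects per integer age category (floor of chronological age).
STUDY_COUNTS: dict[int, int] = {
    4: 7, 5: 26, 6: 18, 7: 18, 8: 14, 9: 16, 10: 20, 11: 20, 12: 19,
    13: 20, 14: 21, 15: 20, 16: 20, 17: 24, 18: 21, 19: 20, 20: 20,
}

STUDY_N = 324
STUDY_N_MALE = 156
STUDY_N_FEMALE = 168

# Per-age mean error and mean absolute error (years), by method.
_TABLE1 = {
    "nolla_mean_error": [0.58, 0.49, 0.63, 0.13, 0.09, -0.35, 0.00, 0.59,
                         -0.19, 0.38, 0.34, 0.03, -0.74, -0.89, -1.37, -2.42, -3.55],
    "nolla_mean_abs_error": [0.58, 0.72, 0.67, 0.65, 0.89, 0.82, 1.23, 1.61,
                             0.88, 1.02, 1.09, 1.03, 1.23, 0.89, 1.37, 2.42, 3.55],
    "demirjian_olze_mean_error": [2.02, 1.86, 1.57, 1.33, 1.91, 1.57, 1.94, 1.57,
                                  1.19, 1.59, 1.56, 1.28, 1.73, 1.45, 3.11, 2.02, 0.54],
    "demirjian_olze_mean_abs_error": [2.02, 1.86, 1.57, 1.33, 1.92, 1.71, 1.94, 1.58,
                                      1.41, 1.59, 1.62, 1.36, 2.09, 2.16, 3.39, 2.57, 2.49],
    "london_atlas_mean_error": [0.44, 0.36, 0.43, 0.65, 0.48, 0.72, 0.97, 0.82,
                                0.12, 0.71, 0.48, 0.36, 0.63, 0.30, 1.25, 0.63, -0.30],
    "london_atlas_mean_abs_error": [0.56, 0.49, 0.67, 1.00, 1.27, 1.05, 1.29, 0.87,
                                    0.89, 0.82, 0.85, 1.14, 1.27, 1.75, 1.67, 1.70, 2.08],
}

#: Published total rows (full-sample values as printed).
STUDY_TABLE1_TOTALS = {
    "nolla_mean_error": -0.42,
    "nolla_mean_abs_error": 1.25,
    "demirjian_olze_mean_error": 1.65,
    "demirjian_olze_mean_abs_error": 1.93,
    "london_atlas_mean_error": 0.53,
    "london_atlas_mean_abs_error": 1.16,
}

# Per-age correct-estimation rates (percent) with 1- and 2-year margins.
_TABLE2 = {
    "nolla_rate_1y": [71.43, 73.08, 83.33, 77.78, 50.00, 62.50, 52.63, 20.00,
                      52.63, 45.00, 52.38, 45.00, 66.67, 62.50, 0.00, 0.00, 0.00],
    "nolla_rate_2y": [100.00, 100.00, 100.00, 100.00, 100.00, 93.75, 89.47, 75.00,
                      94.74, 90.00, 85.71, 95.00, 71.43, 91.67, 95.24, 0.00, 0.00],
    "demirjian_olze_rate_1y": [0.00, 0.00, 5.56, 33.33, 21.43, 25.00, 15.79, 35.00,
                               47.37, 30.00, 42.86, 50.00, 42.86, 41.67, 4.76, 15.00, 0.00],
    "demirjian_olze_rate_2y": [57.14, 50.00, 88.89, 94.44, 50.00, 62.50, 68.42, 65.00,
                               73.68, 55.00, 66.67, 85.00, 47.62, 66.67, 14.29, 20.00, 25.00],
    "london_atlas_rate_1y": [85.71, 76.92, 66.67, 61.11, 35.71, 56.25, 47.37, 70.00,
                             57.89, 75.00, 61.90, 65.00, 57.14, 37.50, 47.62, 45.00, 35.00],
    "london_atlas_rate_2y": [100.00, 96.15, 100.00, 83.33, 85.71, 81.25, 84.21, 90.00,
                             100.00, 90.00, 95.24, 85.00, 76.19, 75.00, 76.19, 70.00, 50.00],
}

STUDY_TABLE2_TOTALS = {
    "nolla_rate_1y": 46.91,
    "nolla_rate_2y": 80.25,
    "demirjian_olze_rate_1y": 25.00,
    "demirjian_olze_rate_2y": 57.72,
    "london_atlas_rate_1y": 57.10,
    "london_atlas_rate_2y": 83.95,
}


def study_table1() -> pd.DataFrame:
    """Per-age counts, mean errors and mean absolute errors, by method."""
    df = pd.DataFrame({"age_category": STUDY_AGE_CATEGORIES, **_TABLE1})
    df.insert(1, "n", [STUDY_COUNTS[c] for c in STUDY_AGE_CATEGORIES])
    return df


def study_table2() -> pd.DataFrame:
    """Per-age correct-estimation rates (percent), by method and margin."""
    df = pd.DataFrame({"age_category": STUDY_AGE_CATEGORIES, **_TABLE2})
    df.insert(1, "n", [STUDY_COUNTS[c] for c in STUDY_AGE_CATEGORIES])
    return df
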