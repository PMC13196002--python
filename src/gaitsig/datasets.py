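"""Bundled reference values from a 3D motion-capture study of iNPH gait.

The study compared 23 adults with idiopathic normal pressure hydrocephalus
(iNPH) against 18 age-matched healthy controls (HC).  Three kinds of
reference data are bundled here:

* the per-patient clinical/radiological table for the iNPH group
  (:func:`load_clinical_table`),
* group-level demographic and spatiotemporal summary statistics
  (:data:`DEMOGRAPHICS_SUMMARY`, :data:`SPATIOTEMPORAL_SUMMARY`),
* the sex contingency table and the gait-cycle regions where the two
  groups' joint-angle waveforms differed (:data:`SEX_TABLE`,
  :data:`STUDY_REGIONS`).

These serve as defaults for the synthetic-cohort generator and as inputs
for recomputing the study's summary statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_clinical_table",
    "DEMOGRAPHICS_SUMMARY",
    "SPATIOTEMPORAL_SUMMARY",
    "SEX_TABLE",
    "STUDY_REGIONS",
]

# Per-patient clinical and radiological values for the iNPH group.
# Columns: id, sex, age (years), iNPH scale (0-100, 100 = healthy 70-year-old),
# mRS (0-6), ACE-III (0-100), tap-test result, shunted, shunt responder, DESH,
# Evans index, Radscale (0-12), Fazekas (0-3).
_CLINICAL_ROWS = [
    (1, "M", 89, 29, 3, 77, "pos", "no", None, "yes", 0.39, 11, 3),
    (2, "M", 76, 78, 1, 81, "pos", "yes", "yes", "yes", 0.40, 11, 3),
    (3, "M", 76, 77, 1, 88, "pos", "yes", "yes", "yes", 0.39, 8, 0),
    (4, "F", 77, 35, 3, 86, "pos", "yes", "yes", "yes", 0.31, 8, 1),
    (5, "M", 84, 25, 4, 74, "pos", "yes", "no", "yes", 0.45, 11, 2),
    (6, "F", 79, 20, 4, 43, "neg", "yes", "yes", "yes", 0.32, 9, 3),
    (7, "F", 72, 48, 3, 72, "neg", "no", None, "no", 0.36, 6, 1),
    (8, "M", 76, 43, 3, 72, "pos", "yes", "yes", "yes", 0.50, 11, 2),
    (9, "F", 68, 50, 2, 77, "pos", "yes", "yes", "yes", 0.35, 9, 1),
    (10, "M", 77, 49, 1, 80, "pos", "yes", "yes", "yes", 0.37, 10, 2),
    (11, "M", 80, 61, 2, 95, "neg", "yes", "yes", "yes", 0.39, 9, 1),
    (12, "M", 76, 58, 3, 83, "pos", "yes", "yes", "yes", 0.39, 10, 2),
    (13, "M", 83, 38, 3, 83, "neg", "deceased", None, "yes", 0.37, 9, 3),
    (14, "F", 74, 55, 1, 89, "pos", "no", None, "yes", 0.31, 9, 2),
    (15, "M", 64, 51, 2, 76, "pos", "yes", "no", "yes", 0.40, 11, 3),
    (16, "M", 83, 83, 2, 78, "pos", "yes", "no", "yes", 0.41, 9, 2),
    (17, "M", 76, 49, 2, 82, "pos", "yes", "yes", "yes", 0.37, 9, 3),
    (18, "M", 70, 59, 2, 73, "pos", "yes", "no", "yes", 0.35, 8, 1),
    (19, "M", 78, 34, 3, 66, "pos", "yes", "yes", "no", 0.36, 5, 2),
    (20, "M", 79, 51, 2, 82, "pos", "yes", "yes", "yes", 0.38, 11, 1),
    (21, "M", 78, 70, 3, 85, "pos", "no", None, "yes", 0.34, 10, 2),
    (22, "M", 88, 55, 2, 65, "pos", "yes", "yes", "yes", 0.40, 8, 1),
    (23, "M", 74, 48, 3, 87, "neg", "yes", "yes", "yes", 0.43, 11, 1),
]

_CLINICAL_COLUMNS = [
    "id", "sex", "age", "inph_scale", "mrs", "ace", "tap_test",
    "shunted", "responder", "desh", "evans_index", "radscale", "fazekas",
]


def load_clinical_table() -> pd.DataFrame:
    """Per-patient clinical and radiological table for the iNPH group (n=23)."""
    return pd.DataFrame(_CLINICAL_ROWS, columns=_CLINICAL_COLUMNS)


# Group demographics as (mean, sd) — plus male:female counts.
DEMOGRAPHICS_SUMMARY = {
    "case": {
        "n": 23,
        "age": (77.26, 5.8),
        "mass": (78.88, 13.9),
        "height": (1.63, 0.07),
        "males": 18,
        "females": 5,
    },
    "control": {
        "n": 18,
        "age": (73.78, 6.1),
        "mass": (74.52, 19.5),
        "height": (1.62, 0.09),
        "males": 4,
        "females": 14,
    },
}

# Spatiotemporal gait parameters as (mean, sd, n) per group.
SPATIOTEMPORAL_SUMMARY = {
    "case": {
        "gait_speed_ms": (0.48, 0.25, 23),
        "cycle_time_s": (1.35, 0.23, 23),
        "stride_length_m": (0.63, 0.30, 23),
        "stride_width_m": (0.18, 0.04, 23),
    },
    "control": {
        "gait_speed_ms": (1.20, 0.18, 18),
        "cycle_time_s": (1.08, 0.08, 18),
        "stride_length_m": (1.31, 0.15, 18),
        "stride_width_m": (0.11, 0.03, 17),  # one control lacked width data
    },
}

# 2x2 sex table: rows (case, control), columns (male, female).
SEX_TABLE = ((18, 5), (4, 14))

# Gait-cycle regions (% of cycle, inclusive) where the case group's
# joint-angle waveforms differed from controls, with the direction of the
# case-minus-control difference.  These parameterise the generator's
# effect presets and the region-feature extraction defaults.
STUDY_REGIONS = [
    # (joint, plane, start %GC, end %GC, direction)
    ("pelvis", "frontal", 6, 35, -1),      # reduced obliquity, early-mid stance
    ("pelvis", "frontal", 57, 84, -1),     # reduced obliquity, late stance-mid swing
    ("pelvis", "transverse", 34, 57, -1),  # reduced rotation, mid-late stance
    ("pelvis", "transverse", 81, 100, -1),  # reduced rotation, late swing
    ("hip", "sagittal", 25, 64, -1),       # reduced/delayed extension
    ("hip", "frontal", 0, 53, -1),         # reduced adduction into stance
    ("hip", "frontal", 88, 100, -1),       # reduced adduction, late swing
    ("knee", "sagittal", 57, 76, -1),      # reduced/delayed swing flexion
    ("knee", "sagittal", 87, 100, -1),     # less extension at terminal swing
    ("ankle", "sagittal", 36, 49, 1),      # prolonged dorsiflexion mid-late stance
    ("ankle", "sagittal", 55, 74, -1),     # blunted push-off plantarflexion
    ("ankle", "frontal", 47, 68, -1),      # reduced abduction, late stance
]
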