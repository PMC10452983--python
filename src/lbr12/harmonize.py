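"""Cohort harmonization for multi-trial lesion-level measurement data.

Raw first-line trial data collected under different response criteria is
reduced to a common analysis form: per patient, at most five target
lesions (the largest at baseline), the single restaging scan closest to
12 weeks after registration, and the per-lesion percent change between
the two timepoints. Patients that cannot be harmonized are excluded with
exactly one reason each, evaluated as a fixed cascade, and written to an
auditable exclusion ledger.

Measurements are longest diameters only, internally in millimetres. A
restaging diameter recorded as 0 means the lesion disappeared; a lesion
simply absent from the restaging scan means it was not evaluated, which
excludes the patient (``incomplete_restaging``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ExclusionReason",
    "HarmonizedCohort",
    "select_target_lesions",
    "select_restaging_assessment",
    "build_analysis_cohort",
    "cohort_to_input_tables",
    "LESION_COLUMNS",
    "PATIENT_COLUMNS",
]

LESION_COLUMNS = [
    "trial_id", "arm_id", "patient_id", "lesion_id", "assessment_day", "diameter",
]
PATIENT_COLUMNS = [
    "patient_id", "trial_id", "arm_id", "regimen_class", "age", "sex",
    "ecog", "os_day", "os_event",
]

REGIMEN_CLASSES = ("chemo_only", "VEGFi", "EGFRi", "VEGFi_and_EGFRi")


class ExclusionReason(str, enum.Enum):
    """Cascade of exclusion reasons; a patient gets the first that applies."""

    NO_BASELINE_MEASUREMENT = "no_baseline_measurement"
    SINGLE_TARGET_LESION = "single_target_lesion"
    NO_RESTAGING_WITHIN_WINDOW = "no_restaging_within_window"
    INCOMPLETE_RESTAGING = "incomplete_restaging"
    NONTARGET_PROGRESSION = "nontarget_progression_flag"
    NO_POST_RESTAGING_SURVIVAL = "no_post_restaging_survival"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CohortConfig:
    """Harmonization parameters.

    ``window_days`` is the restaging window (12 weeks = 84 days); scans
    on days in ``(0, window_days + window_tolerance_days]`` qualify.
    ``max_lesions`` caps the number of target lesions per patient.
    """

    window_days: int = 84
    window_tolerance_days: int = 0
    max_lesions: int = 5

    @property
    def window_upper(self) -> int:
        return self.window_days + self.window_tolerance_days


DEFAULT_CONFIG = CohortConfig()


@dataclass
class HarmonizedCohort:
    """Analysis cohort after harmonization.

    records
        One row per retained patient: identity, covariates, restaging
        day, diameter sums (mm), landmark survival.
    lesions
        One row per retained lesion: baseline and restaging diameter,
        fractional percent change.
    ledger
        One row per excluded patient: ``patient_id, reason``.
    """

    records: pd.DataFrame
    lesions: pd.DataFrame
    ledger: pd.DataFrame

    def exclusion_counts(self) -> pd.Series:
        order = [r.value for r in ExclusionReason]
        return (
            self.ledger["reason"].value_counts().reindex(order, fill_value=0)
        )


def select_target_lesions(
    baseline_diameters: Mapping[str, float] | pd.Series,
    max_lesions: int = 5,
) -> list[str]:
    """Choose the target lesions: all if few, else the ``max_lesions`` largest.

    Ties in baseline diameter are broken by ascending lesion id so the
    selection is deterministic and independent of input order.
    """
    items = list(pd.Series(baseline_diameters).items())
    if not items:
        raise ValueError("patient has no baseline lesions")
    for lid, d in items:
        if not d > 0:
            raise ValueError(f"baseline diameter must be > 0 (lesion {lid!r}: {d})")
    items.sort(key=lambda kv: (-kv[1], str(kv[0])))
    return [lid for lid, _ in items[:max_lesions]]


def select_restaging_assessment(
    assessment_days: Iterable[int],
    window_days: int = 84,
    upper: Optional[int] = None,
) -> Optional[int]:
    """Pick the post-baseline scan day closest to the 12-week mark.

    Only days in ``(0, upper]`` qualify (``upper`` defaults to
    ``window_days``; a larger value models a tolerance beyond the
    window). Among qualifying days the one minimizing
    ``|day - window_days|`` is chosen, equidistant ties going to the
    later day. Returns None when no scan qualifies.
    """
    if upper is None:
        upper = window_days
    qualifying = [int(d) for d in assessment_days if 0 < d <= upper]
    if not qualifying:
        return None
    return min(qualifying, key=lambda d: (abs(d - window_days), -d))


def _validate_lesions(lesions: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LESION_COLUMNS if c not in lesions.columns]
    if missing:
        raise ValueError(f"lesion table missing columns: {missing}")
    df = lesions.copy()
    df["diameter"] = pd.to_numeric(df["diameter"], errors="raise")
    df["assessment_day"] = pd.to_numeric(df["assessment_day"], errors="raise").astype(int)
    bad = df.index[df["diameter"] < 0]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"negative diameter in lesion table row {bad[0]} "
            f"(patient {row['patient_id']!r}, lesion {row['lesion_id']!r}, "
            f"day {row['assessment_day']})"
        )
    dup = df.duplicated(subset=["patient_id", "lesion_id", "assessment_day"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (patient, lesion, day) key: "
            f"({row['patient_id']!r}, {row['lesion_id']!r}, {row['assessment_day']})"
        )
    return df


def _validate_patients(patients: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")
    df = patients.copy()
    if df["patient_id"].duplicated().any():
        pid = df.loc[df["patient_id"].duplicated().idxmax(), "patient_id"]
        raise ValueError(f"duplicate patient_id in patient table: {pid!r}")
    df["os_day"] = pd.to_numeric(df["os_day"], errors="raise")
    if (df["os_day"] < 0).any():
        pid = df.loc[(df["os_day"] < 0).idxmax(), "patient_id"]
        raise ValueError(f"negative os_day for patient {pid!r}")
    if "nontarget_progression" not in df.columns:
        df["nontarget_progression"] = 0
    df["nontarget_progression"] = (
        df["nontarget_progression"].fillna(0).astype(int)
    )
    return df


def build_analysis_cohort(
    lesions: pd.DataFrame,
    patients: pd.DataFrame,
    config: CohortConfig = DEFAULT_CONFIG,
) -> HarmonizedCohort:
    """Harmonize raw lesion and patient tables into the analysis cohort.

    The exclusion cascade, applied per patient in order (first matching
    reason wins): no baseline measurement; fewer than two target lesions
    at baseline; no restaging scan within the window; retained lesions
    not all measured at the chosen scan; non-target progression flag
    set; no survival time beyond the restaging scan. Every input patient
    lands in exactly one of cohort or ledger.
    """
    lesions = _validate_lesions(lesions)
    patients = _validate_patients(patients)

    unknown = set(lesions["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise ValueError(
            f"lesion table references unknown patient ids: {sorted(unknown)[:5]}"
        )

    excluded: list[tuple[str, str]] = []
    record_rows: list[dict] = []
    lesion_rows: list[dict] = []

    baseline = lesions[(lesions["assessment_day"] == 0) & (lesions["diameter"] > 0)]
    base_by_pat = {
        pid: grp.set_index("lesion_id")["diameter"]
        for pid, grp in baseline.groupby("patient_id", sort=False)
    }
    post = lesions[lesions["assessment_day"] > 0]
    post_by_pat = dict(iter(post.groupby("patient_id", sort=False)))

    for prow in patients.itertuples(index=False):
        pid = prow.patient_id
        base = base_by_pat.get(pid)
        if base is None or base.empty:
            excluded.append((pid, ExclusionReason.NO_BASELINE_MEASUREMENT.value))
            continue
        retained = select_target_lesions(base, config.max_lesions)
        if len(retained) < 2:
            excluded.append((pid, ExclusionReason.SINGLE_TARGET_LESION.value))
            continue
        post_p = post_by_pat.get(pid)
        days = post_p["assessment_day"].unique() if post_p is not None else []
        day = select_restaging_assessment(days, config.window_days, config.window_upper)
        if day is None:
            excluded.append((pid, ExclusionReason.NO_RESTAGING_WITHIN_WINDOW.value))
            continue
        at_scan = post_p[post_p["assessment_day"] == day].set_index("lesion_id")[
            "diameter"
        ]
        if not all(lid in at_scan.index for lid in retained):
            excluded.append((pid, ExclusionReason.INCOMPLETE_RESTAGING.value))
            continue
        if prow.nontarget_progression:
            excluded.append((pid, ExclusionReason.NONTARGET_PROGRESSION.value))
            continue
        landmark = float(prow.os_day) - day
        if landmark <= 0:
            excluded.append((pid, ExclusionReason.NO_POST_RESTAGING_SURVIVAL.value))
            continue

        l0 = base.loc[retained].astype(float)
        l12 = at_scan.loc[retained].astype(float)
        record_rows.append(
            {
                "patient_id": pid,
                "trial_id": prow.trial_id,
                "arm_id": prow.arm_id,
                "regimen_class": prow.regimen_class,
                "age": prow.age,
                "sex": prow.sex,
                "ecog": prow.ecog,
                "n_lesions": len(retained),
                "restaging_day": day,
                "baseline_sum": float(l0.sum()),
                "restaging_sum": float(l12.sum()),
                "all_disappeared": bool((l12 == 0).all()),
                "os_day": float(prow.os_day),
                "os_event": int(prow.os_event),
                "landmark_os_day": landmark,
            }
        )
        for lid in retained:
            lesion_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": lid,
                    "baseline_diameter": float(l0[lid]),
                    "restaging_diameter": float(l12[lid]),
                    "percent_change": (float(l12[lid]) - float(l0[lid])) / float(l0[lid]),
                }
            )

    records = pd.DataFrame(
        record_rows,
        columns=[
            "patient_id", "trial_id", "arm_id", "regimen_class", "age", "sex",
            "ecog", "n_lesions", "restaging_day", "baseline_sum",
            "restaging_sum", "all_disappeared", "os_day", "os_event",
            "landmark_os_day",
        ],
    )
    lesion_df = pd.DataFrame(
        lesion_rows,
        columns=[
            "patient_id", "lesion_id", "baseline_diameter",
            "restaging_diameter", "percent_change",
        ],
    )
    ledger = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return HarmonizedCohort(records=records, lesions=lesion_df, ledger=ledger)


def cohort_to_input_tables(cohort: HarmonizedCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-express a harmonized cohort in the raw input table layout.

    Useful for round-trip checks: harmonizing the result again is the
    identity (up to the exclusion ledger, which is empty by then).
    """
    rec = cohort.records
    les = cohort.lesions.merge(
        rec[["patient_id", "trial_id", "arm_id", "restaging_day"]], on="patient_id"
    )
    base = les.assign(assessment_day=0, diameter=les["baseline_diameter"])
    restage = les.assign(
        assessment_day=les["restaging_day"], diameter=les["restaging_diameter"]
    )
    lesion_tbl = pd.concat([base, restage], ignore_index=True)[LESION_COLUMNS]
    patient_tbl = rec[PATIENT_COLUMNS].copy()
    patient_tbl["nontarget_progression"] = 0
    return lesion_tbl, patient_tbl
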