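"""Lesion-based response classification at 12 weeks (LBR12).

Two-step criterion for intratumoral response heterogeneity in patients
with multiple target lesions:

1. Each lesion is classified from its percent change in longest diameter
   between baseline and the ~12-week restaging scan: responding lesion
   (RL, >=30% reduction, including complete disappearance), progressing
   lesion (PL, >=20% increase), stable lesion (SL, neither).
2. The patient is classified from the best and worst lesion class into
   one of six growth patterns: RL only, RL/SL, SL only, RL/PL, SL/PL,
   PL only. Patterns mixing classes (RL/SL, RL/PL, SL/PL) are "varied
   responses".

The module also recomputes RECIST 1.1 target-lesion response from the
harmonized two-timepoint sums (no new-lesion information), the
prevalence sub-classification within RL/PL patients, the LBR12 x RECIST
cross-tabulation, and a cutoff sensitivity grid.

Boundary convention: by default the thresholds are inclusive (a change
of exactly +20% is PL and exactly -30% is RL), matching RECIST usage;
``inclusive_boundaries=False`` switches to strict inequalities.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LesionClass",
    "GrowthPattern",
    "PrevalenceSubclass",
    "RecistCategory",
    "CutoffConfig",
    "DEFAULT_CUTOFFS",
    "DEFAULT_SENSITIVITY_GRID",
    "VARIED_PATTERNS",
    "classify_lesion",
    "classify_lesion_deltas",
    "classify_patient",
    "prevalence_subclass",
    "classify_recist",
    "classify_cohort",
    "crosstab_lbr_recist",
    "run_sensitivity",
    "SensitivityResult",
]


class LesionClass(enum.IntEnum):
    """Per-lesion response class; ordered best to worst (RL < SL < PL)."""

    RL = 0
    SL = 1
    PL = 2


class GrowthPattern(str, enum.Enum):
    """Patient-level growth pattern from the (best, worst) lesion classes."""

    RL_ONLY = "RL_only"
    RL_SL = "RL_SL"
    SL_ONLY = "SL_only"
    RL_PL = "RL_PL"
    SL_PL = "SL_PL"
    PL_ONLY = "PL_only"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Patterns with more than one lesion class present ("varied responses").
VARIED_PATTERNS = frozenset(
    {GrowthPattern.RL_SL, GrowthPattern.RL_PL, GrowthPattern.SL_PL}
)


class PrevalenceSubclass(str, enum.Enum):
    """Within RL/PL: which of the two extreme classes is more prevalent."""

    MORE_RL = "more_RL"
    EQUAL_RL_PL = "equal_RL_PL"
    MORE_PL = "more_PL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RecistCategory(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CutoffConfig:
    """Percent-change thresholds for per-lesion classification.

    Parameters
    ----------
    c_pl
        Progression threshold on the fractional change from baseline
        (default +0.20: a 20% increase).
    c_rl
        Response threshold (default -0.30: a 30% reduction).
    inclusive_boundaries
        If True (default), ``delta >= c_pl`` is PL and ``delta <= c_rl``
        is RL; if False the comparisons are strict.
    """

    c_pl: float = 0.20
    c_rl: float = -0.30
    inclusive_boundaries: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 <= self.c_rl < 0.0 < self.c_pl):
            raise ValueError(
                f"cutoffs must satisfy -1 <= c_rl < 0 < c_pl; "
                f"got c_rl={self.c_rl}, c_pl={self.c_pl}"
            )

    def label(self) -> str:
        return f"PL>={self.c_pl:+.0%}/RL<={self.c_rl:+.0%}"


DEFAULT_CUTOFFS = CutoffConfig()

#: The six alternative cutoff combinations of the sensitivity analysis:
#: PL at >=20/15/10% increase crossed with RL at >=25/20/30% decrease.
DEFAULT_SENSITIVITY_GRID: tuple[CutoffConfig, ...] = (
    CutoffConfig(c_pl=0.20, c_rl=-0.25),
    CutoffConfig(c_pl=0.20, c_rl=-0.20),
    CutoffConfig(c_pl=0.15, c_rl=-0.30),
    CutoffConfig(c_pl=0.15, c_rl=-0.25),
    CutoffConfig(c_pl=0.10, c_rl=-0.30),
    CutoffConfig(c_pl=0.10, c_rl=-0.20),
)


def classify_lesion_deltas(
    deltas: np.ndarray | pd.Series | Sequence[float],
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Vectorized per-lesion classification from fractional changes.

    Returns an int array of :class:`LesionClass` values.
    """
    d = np.asarray(deltas, dtype=float)
    if cutoffs.inclusive_boundaries:
        rl = d <= cutoffs.c_rl
        pl = d >= cutoffs.c_pl
    else:
        rl = d < cutoffs.c_rl
        pl = d > cutoffs.c_pl
    return np.where(rl, LesionClass.RL, np.where(pl, LesionClass.PL, LesionClass.SL))


def classify_lesion(
    baseline_diameter: float,
    restaging_diameter: float,
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
) -> LesionClass:
    """Classify one lesion as RL, SL or PL.

    ``baseline_diameter`` must be positive; ``restaging_diameter`` of 0
    means the lesion disappeared completely (always RL).
    """
    if baseline_diameter <= 0:
        raise ValueError(f"baseline diameter must be > 0, got {baseline_diameter}")
    if restaging_diameter < 0:
        raise ValueError(f"restaging diameter must be >= 0, got {restaging_diameter}")
    delta = (restaging_diameter - baseline_diameter) / baseline_diameter
    return LesionClass(int(classify_lesion_deltas([delta], cutoffs)[0]))


_PATTERN_BY_BEST_WORST = {
    (LesionClass.RL, LesionClass.RL): GrowthPattern.RL_ONLY,
    (LesionClass.RL, LesionClass.SL): GrowthPattern.RL_SL,
    (LesionClass.SL, LesionClass.SL): GrowthPattern.SL_ONLY,
    (LesionClass.RL, LesionClass.PL): GrowthPattern.RL_PL,
    (LesionClass.SL, LesionClass.PL): GrowthPattern.SL_PL,
    (LesionClass.PL, LesionClass.PL): GrowthPattern.PL_ONLY,
}


def classify_patient(lesion_classes: Iterable[LesionClass]) -> GrowthPattern:
    """Map a patient's lesion classes to one of the six growth patterns.

    The pattern is determined solely by the best (min) and worst (max)
    lesion class under the order RL < SL < PL, so it is invariant to
    lesion order and to the multiplicity of intermediate classes.
    """
    classes = [LesionClass(c) for c in lesion_classes]
    if not classes:
        raise ValueError("lesion class vector must be nonempty")
    return _PATTERN_BY_BEST_WORST[(min(classes), max(classes))]


def prevalence_subclass(lesion_classes: Iterable[LesionClass]) -> PrevalenceSubclass:
    """Sub-classify an RL/PL patient by count of RL vs PL lesions.

    Stable lesions are ignored. Raises if the vector is not RL/PL
    (i.e. does not contain at least one RL and one PL).
    """
    classes = [LesionClass(c) for c in lesion_classes]
    n_rl = sum(c == LesionClass.RL for c in classes)
    n_pl = sum(c == LesionClass.PL for c in classes)
    if n_rl == 0 or n_pl == 0:
        raise ValueError(
            "prevalence subclass is defined only for RL/PL patients "
            f"(got {n_rl} RL and {n_pl} PL lesions)"
        )
    if n_rl > n_pl:
        return PrevalenceSubclass.MORE_RL
    if n_rl < n_pl:
        return PrevalenceSubclass.MORE_PL
    return PrevalenceSubclass.EQUAL_RL_PL


def classify_recist(
    baseline_sum: float,
    restaging_sum: float,
    all_disappeared: bool = False,
    apply_5mm_rule: bool = True,
) -> RecistCategory:
    """RECIST 1.1 target-lesion response from two-timepoint diameter sums.

    With only baseline and one restaging scan the nadir is the baseline,
    so: CR if every lesion disappeared; PD if the sum increased >=20%
    (and by >=5 mm absolute when ``apply_5mm_rule``); PR if the sum
    decreased >=30%; SD otherwise. New lesions are out of scope.
    """
    if baseline_sum <= 0:
        raise ValueError(f"baseline sum must be > 0, got {baseline_sum}")
    if restaging_sum < 0:
        raise ValueError(f"restaging sum must be >= 0, got {restaging_sum}")
    if all_disappeared and restaging_sum != 0:
        raise ValueError("all_disappeared requires restaging sum == 0")
    if all_disappeared:
        return RecistCategory.CR
    change = (restaging_sum - baseline_sum) / baseline_sum
    if change >= 0.20 and (not apply_5mm_rule or restaging_sum - baseline_sum >= 5.0):
        return RecistCategory.PD
    if change <= -0.30:
        return RecistCategory.PR
    return RecistCategory.SD


def classify_cohort(
    cohort,
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    apply_5mm_rule: bool = True,
) -> pd.DataFrame:
    """Classify every patient of a harmonized cohort.

    Parameters
    ----------
    cohort
        A :class:`~lbr12.harmonize.HarmonizedCohort` (or any object with
        ``records`` and ``lesions`` frames in the same layout).

    Returns
    -------
    DataFrame indexed like ``cohort.records`` with columns
    ``patient_id, lesion_classes, growth_pattern, prevalence_subclass,
    recist, n_lesions, baseline_sum, restaging_sum, restaging_day``.
    ``lesion_classes`` is a semicolon-joined string in lesion order;
    ``prevalence_subclass`` is NA outside RL/PL.
    """
    records, lesions = cohort.records, cohort.lesions
    if records.empty:
        return pd.DataFrame(
            columns=[
                "patient_id", "lesion_classes", "growth_pattern",
                "prevalence_subclass", "recist", "n_lesions",
                "baseline_sum", "restaging_sum", "restaging_day",
            ]
        )

    les = lesions.copy()
    les["lesion_class"] = classify_lesion_deltas(les["percent_change"], cutoffs)
    grouped = les.groupby("patient_id", sort=False)["lesion_class"]
    best = grouped.min()
    worst = grouped.max()
    n_rl = grouped.apply(lambda s: int((s == LesionClass.RL).sum()))
    n_pl = grouped.apply(lambda s: int((s == LesionClass.PL).sum()))
    class_str = grouped.apply(
        lambda s: ";".join(LesionClass(int(c)).name for c in s)
    )

    out = records[
        ["patient_id", "n_lesions", "baseline_sum", "restaging_sum",
         "all_disappeared", "restaging_day"]
    ].copy()
    out["lesion_classes"] = out["patient_id"].map(class_str)
    out["growth_pattern"] = [
        _PATTERN_BY_BEST_WORST[(LesionClass(int(b)), LesionClass(int(w)))].value
        for b, w in zip(out["patient_id"].map(best), out["patient_id"].map(worst))
    ]
    rl_counts = out["patient_id"].map(n_rl)
    pl_counts = out["patient_id"].map(n_pl)
    sub = np.select(
        [rl_counts > pl_counts, rl_counts < pl_counts],
        [PrevalenceSubclass.MORE_RL.value, PrevalenceSubclass.MORE_PL.value],
        default=PrevalenceSubclass.EQUAL_RL_PL.value,
    )
    out["prevalence_subclass"] = np.where(
        out["growth_pattern"] == GrowthPattern.RL_PL.value, sub, None
    )
    out["recist"] = [
        classify_recist(s0, s12, bool(gone), apply_5mm_rule).value
        for s0, s12, gone in zip(
            out["baseline_sum"], out["restaging_sum"], out["all_disappeared"]
        )
    ]
    out = out.drop(columns="all_disappeared")
    cols = [
        "patient_id", "lesion_classes", "growth_pattern", "prevalence_subclass",
        "recist", "n_lesions", "baseline_sum", "restaging_sum", "restaging_day",
    ]
    return out[cols].reset_index(drop=True)


PATTERN_ORDER = [p.value for p in GrowthPattern]
RECIST_ORDER = [c.value for c in RecistCategory]


def crosstab_lbr_recist(classifications: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table of growth pattern (rows) x RECIST category (columns).

    Returns ``(counts, row_percentages)``; rows/columns are in the
    canonical best-to-worst order and include empty levels.
    """
    if classifications.empty:
        raise ValueError("cannot cross-tabulate an empty classification table")
    counts = pd.crosstab(
        classifications["growth_pattern"], classifications["recist"]
    ).reindex(index=PATTERN_ORDER, columns=RECIST_ORDER, fill_value=0)
    counts.index.name = "growth_pattern"
    counts.columns.name = "recist"
    row_tot = counts.sum(axis=1)
    pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100.0
    return counts, pct


@dataclass
class SensitivityResult:
    """Classification tables and agreement for one alternative cutoff."""

    cutoffs: CutoffConfig
    classifications: pd.DataFrame
    pattern_distribution: pd.Series
    agreement_with_default: float


def run_sensitivity(
    cohort,
    grid: Sequence[CutoffConfig] = DEFAULT_SENSITIVITY_GRID,
    reference_cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    apply_5mm_rule: bool = True,
) -> list[SensitivityResult]:
    """Re-classify the cohort under each cutoff configuration in ``grid``.

    Agreement is the fraction of patients whose growth pattern is
    unchanged relative to ``reference_cutoffs``.
    """
    if not grid:
        raise ValueError("sensitivity grid must be nonempty")
    for cfg in grid:
        if not isinstance(cfg, CutoffConfig):
            raise TypeError(f"invalid cutoff config: {cfg!r}")
    baseline = classify_cohort(cohort, reference_cutoffs, apply_5mm_rule)
    base_patterns = baseline.set_index("patient_id")["growth_pattern"]
    results = []
    for cfg in grid:
        cls = classify_cohort(cohort, cfg, apply_5mm_rule)
        dist = (
            cls["growth_pattern"].value_counts().reindex(PATTERN_ORDER, fill_value=0)
        )
        if len(cls):
            agree = float(
                (cls.set_index("patient_id")["growth_pattern"] == base_patterns).mean()
            )
        else:
            agree = float("nan")
        results.append(SensitivityResult(cfg, cls, dist, agree))
    return results
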