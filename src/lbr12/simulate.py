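"""Synthetic multi-trial cohort generator.

Emulates a pooled first-line metastatic colorectal cancer cohort with
the structure the analysis assumes: 2-5 target lesions per patient with
log-normal baseline longest diameters, a restaging scan shortly before
the 12-week mark, per-lesion percent changes drawn from the region of
the intended lesion class, and overall survival from the landmark drawn
per growth pattern from an exponential (optionally Weibull) distribution
whose median matches the configured pattern-specific median, with
independent exponential censoring plus an administrative cutoff.

Each patient's growth pattern is drawn first and the lesion classes are
constructed to realize it exactly (one lesion is forced into the best
class and one into the worst, the rest drawn from the classes in
between), so harmonizing and classifying the output recovers the drawn
pattern for every patient. Percent changes are sampled from class
regions shrunk by a small epsilon so no lesion sits exactly on a cutoff
boundary.

All randomness flows through one seeded generator; the same
configuration (including seed) reproduces the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import GrowthPattern, LesionClass
from .survival import DAYS_PER_MONTH

__all__ = ["SimulationConfig", "simulate_cohort", "make_toy_fixtures"]

# (best, worst) lesion classes realizing each growth pattern
_PATTERN_BOUNDS = {
    GrowthPattern.RL_ONLY: (LesionClass.RL, LesionClass.RL),
    GrowthPattern.RL_SL: (LesionClass.RL, LesionClass.SL),
    GrowthPattern.SL_ONLY: (LesionClass.SL, LesionClass.SL),
    GrowthPattern.RL_PL: (LesionClass.RL, LesionClass.PL),
    GrowthPattern.SL_PL: (LesionClass.SL, LesionClass.PL),
    GrowthPattern.PL_ONLY: (LesionClass.PL, LesionClass.PL),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror a large pooled mCRC cohort.

    Pattern proportions and per-pattern median OS (months from the
    landmark) follow the published marginal distribution of the six
    growth patterns and their median survivals; the regimen mix, age,
    sex, ECOG and lesion-count distributions follow the same cohort's
    baseline characteristics. Survival is exponential per pattern
    (``weibull_shape`` = 1; other shapes available for robustness
    checks) with independent exponential censoring and an
    administrative cutoff, together yielding roughly 30% censoring.
    """

    n_patients: int = 10_000
    seed: int = 0
    n_trials: int = 5
    arms_per_trial: int = 2
    regimen_probs: dict = field(
        default_factory=lambda: {
            "chemo_only": 0.3766, "VEGFi": 0.4135,
            "EGFRi": 0.1374, "VEGFi_and_EGFRi": 0.0725,
        }
    )
    lesion_count_probs: dict = field(
        default_factory=lambda: {2: 0.20, 3: 0.30, 4: 0.30, 5: 0.20}
    )
    pattern_probs: dict = field(
        default_factory=lambda: {
            GrowthPattern.RL_ONLY: 0.167, GrowthPattern.RL_SL: 0.420,
            GrowthPattern.SL_ONLY: 0.310, GrowthPattern.RL_PL: 0.033,
            GrowthPattern.SL_PL: 0.063, GrowthPattern.PL_ONLY: 0.007,
        }
    )
    median_os_months: dict = field(
        default_factory=lambda: {
            GrowthPattern.RL_ONLY: 25.8, GrowthPattern.RL_SL: 19.9,
            GrowthPattern.SL_ONLY: 16.8, GrowthPattern.RL_PL: 15.4,
            GrowthPattern.SL_PL: 9.0, GrowthPattern.PL_ONLY: 8.0,
        }
    )
    weibull_shape: float = 1.0
    censoring_median_months: float = 40.0
    admin_cutoff_months: float = 72.0
    baseline_diameter_log_mm: float = float(np.log(30.0))  # median 30 mm
    baseline_diameter_sigma: float = 0.55
    disappearance_prob: float = 0.05  # per-lesion: an RL lesion measures exactly 0
    complete_response_prob: float = 0.05  # per RL-only patient: every lesion disappears
    c_pl: float = 0.20
    c_rl: float = -0.30
    epsilon: float = 1e-6
    max_delta: float = 1.0
    scan_day_range: tuple[int, int] = (70, 84)
    age_mean: float = 60.0
    age_sd: float = 11.0
    male_prob: float = 0.60
    ecog_probs: tuple[float, float, float] = (0.562, 0.422, 0.016)
    ecog_missing_prob: float = 0.0072

    def __post_init__(self) -> None:
        for name, probs in (
            ("pattern_probs", self.pattern_probs),
            ("regimen_probs", self.regimen_probs),
            ("lesion_count_probs", self.lesion_count_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        if any(m <= 0 for m in self.median_os_months.values()):
            raise ValueError("all median OS values must be positive")


def _sample_deltas(classes: np.ndarray, cfg: SimulationConfig, rng) -> np.ndarray:
    """Fractional diameter change per lesion, inside the class region."""
    u = rng.uniform(size=len(classes))
    eps = cfg.epsilon
    lo = np.empty(len(classes))
    hi = np.empty(len(classes))
    rl = classes == LesionClass.RL
    sl = classes == LesionClass.SL
    pl = classes == LesionClass.PL
    lo[rl], hi[rl] = -1.0, cfg.c_rl - eps
    lo[sl], hi[sl] = cfg.c_rl + eps, cfg.c_pl - eps
    lo[pl], hi[pl] = cfg.c_pl + eps, cfg.max_delta
    delta = lo + u * (hi - lo)
    gone = rl & (rng.uniform(size=len(classes)) < cfg.disappearance_prob)
    delta[gone] = -1.0
    return delta


def simulate_cohort(
    config: SimulationConfig, return_patterns: bool = False
) -> tuple[pd.DataFrame, ...]:
    """Generate (lesion table, patient table) in the harmonizer's input layout.

    Deterministic given the configuration; diameters are in mm. With
    ``return_patterns=True`` a third frame carries the drawn ground
    truth per patient (growth pattern and scan day) for recovery checks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    patterns = list(cfg.pattern_probs)
    pat_idx = rng.choice(len(patterns), size=n, p=list(cfg.pattern_probs.values()))
    counts = np.array(list(cfg.lesion_count_probs))
    k = rng.choice(counts, size=n, p=list(cfg.lesion_count_probs.values()))

    trial = rng.integers(0, cfg.n_trials, size=n)
    arm = rng.integers(0, cfg.arms_per_trial, size=n)
    regimen = rng.choice(
        list(cfg.regimen_probs), size=n, p=list(cfg.regimen_probs.values())
    )
    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, size=n)), 18, 89)
    sex = np.where(rng.uniform(size=n) < cfg.male_prob, "male", "female")
    ecog = rng.choice([0, 1, 2], size=n, p=list(cfg.ecog_probs)).astype(float)
    ecog[rng.uniform(size=n) < cfg.ecog_missing_prob] = np.nan
    scan_day = rng.integers(cfg.scan_day_range[0], cfg.scan_day_range[1] + 1, size=n)

    # lesion classes: force one best and one worst per patient, fill the rest
    total = int(k.sum())
    pat_of_lesion = np.repeat(np.arange(n), k)
    offsets = np.concatenate([[0], np.cumsum(k)[:-1]])
    best = np.array([_PATTERN_BOUNDS[patterns[i]][0] for i in pat_idx])
    worst = np.array([_PATTERN_BOUNDS[patterns[i]][1] for i in pat_idx])
    span = worst[pat_of_lesion] - best[pat_of_lesion] + 1
    classes = best[pat_of_lesion] + rng.integers(0, span)
    j1 = rng.integers(0, k)
    j2 = (j1 + 1 + rng.integers(0, k - 1)) % k
    classes[offsets + j1] = best
    classes[offsets + j2] = worst

    delta = _sample_deltas(classes, cfg, rng)
    # patient-level complete response: all lesions of an RL-only patient vanish
    rl_only = np.array([patterns[i] == GrowthPattern.RL_ONLY for i in pat_idx])
    cr_patient = rl_only & (rng.uniform(size=n) < cfg.complete_response_prob)
    delta[cr_patient[pat_of_lesion]] = -1.0
    l0 = rng.lognormal(cfg.baseline_diameter_log_mm, cfg.baseline_diameter_sigma, total)
    l12 = l0 * (1.0 + delta)

    # survival from the landmark, per drawn pattern
    medians = np.array([cfg.median_os_months[patterns[i]] for i in pat_idx])
    t_months = medians * (rng.exponential(1.0, size=n) / np.log(2.0)) ** (
        1.0 / cfg.weibull_shape
    )
    c_months = np.minimum(
        rng.exponential(cfg.censoring_median_months / np.log(2.0), size=n),
        cfg.admin_cutoff_months,
    )
    obs_months = np.minimum(t_months, c_months)
    event = (t_months <= c_months).astype(int)
    os_day = scan_day + np.maximum(1, np.round(obs_months * DAYS_PER_MONTH)).astype(int)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    trial_id = np.array([f"T{t + 1:02d}" for t in trial])
    arm_id = np.array([f"A{a + 1}" for a in arm])

    lesion_index = np.arange(total) - offsets[pat_of_lesion]
    lesion_tbl = pd.DataFrame(
        {
            "trial_id": trial_id[pat_of_lesion],
            "arm_id": arm_id[pat_of_lesion],
            "patient_id": pid[pat_of_lesion],
            "lesion_id": [f"L{j + 1}" for j in lesion_index],
            "assessment_day": 0,
            "diameter": l0,
        }
    )
    restage_tbl = lesion_tbl.copy()
    restage_tbl["assessment_day"] = scan_day[pat_of_lesion]
    restage_tbl["diameter"] = l12
    lesions = pd.concat([lesion_tbl, restage_tbl], ignore_index=True)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "trial_id": trial_id,
            "arm_id": arm_id,
            "regimen_class": regimen,
            "age": age,
            "sex": sex,
            "ecog": ecog,
            "os_day": os_day,
            "os_event": event,
            "nontarget_progression": 0,
        }
    )
    if return_patterns:
        truth = pd.DataFrame(
            {
                "patient_id": pid,
                "growth_pattern": [patterns[i].value for i in pat_idx],
                "restaging_day": scan_day,
            }
        )
        return lesions, patients, truth
    return lesions, patients


def make_toy_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tiny deterministic cohort for documentation and unit tests.

    Twelve patients: one per growth pattern (the RL-only patient doubles
    as the complete-disappearance / CR case, and the RL/PL patient sits
    exactly on the -30% and +20% lesion boundaries) plus one per
    exclusion reason.
    """
    # patient_id -> [(lesion_id, day, diameter), ...]
    lesion_data = {
        # six growth patterns
        "RL1":   [("L1", 0, 50), ("L2", 0, 20), ("L1", 84, 0), ("L2", 84, 0)],
        "RLSL1": [("L1", 0, 60), ("L2", 0, 20), ("L1", 84, 30), ("L2", 84, 20)],
        "SL1":   [("L1", 0, 40), ("L2", 0, 30), ("L1", 84, 40), ("L2", 84, 33)],
        "RLPL1": [("L1", 0, 50), ("L2", 0, 40), ("L3", 0, 30),
                  ("L1", 84, 35), ("L2", 84, 40), ("L3", 84, 36)],
        "SLPL1": [("L1", 0, 40), ("L2", 0, 30), ("L1", 84, 40), ("L2", 84, 36)],
        "PL1":   [("L1", 0, 30), ("L2", 0, 20), ("L1", 84, 40), ("L2", 84, 28)],
        # six exclusion reasons
        "X_SINGLE": [("L1", 0, 30), ("L1", 84, 45)],
        "X_NOBASE": [("L1", 56, 20), ("L2", 56, 30)],
        "X_LATE":   [("L1", 0, 30), ("L2", 0, 25), ("L1", 90, 35), ("L2", 90, 30)],
        "X_PARTIAL": [("L1", 0, 30), ("L2", 0, 25), ("L3", 0, 20),
                      ("L1", 84, 35), ("L2", 84, 30)],
        "X_NONTGT": [("L1", 0, 30), ("L2", 0, 25), ("L1", 84, 30), ("L2", 84, 25)],
        "X_DEATH":  [("L1", 0, 30), ("L2", 0, 25), ("L1", 84, 30), ("L2", 84, 25)],
    }
    patient_data = [
        # pid, trial, arm, regimen, age, sex, ecog, os_day, event, ntp
        ("RL1", "T01", "A1", "chemo_only", 58, "female", 0, 870, 1, 0),
        ("RLSL1", "T01", "A1", "VEGFi", 64, "male", 1, 690, 1, 0),
        ("SL1", "T01", "A2", "chemo_only", 55, "male", 0, 560, 1, 0),
        ("RLPL1", "T01", "A2", "EGFRi", 61, "female", 1, 540, 0, 0),
        ("SLPL1", "T02", "A1", "VEGFi", 67, "male", 1, 360, 1, 0),
        ("PL1", "T02", "A1", "chemo_only", 59, "male", 2, 320, 1, 0),
        ("X_SINGLE", "T02", "A2", "chemo_only", 62, "female", 0, 400, 1, 0),
        ("X_NOBASE", "T02", "A2", "VEGFi", 57, "male", 1, 380, 1, 0),
        ("X_LATE", "T01", "A1", "EGFRi", 66, "female", 0, 420, 1, 0),
        ("X_PARTIAL", "T01", "A2", "VEGFi_and_EGFRi", 53, "male", 1, 450, 1, 0),
        ("X_NONTGT", "T02", "A1", "chemo_only", 60, "female", 1, 310, 1, 1),
        ("X_DEATH", "T02", "A2", "VEGFi", 65, "male", 0, 84, 1, 0),
    ]
    pat_df = pd.DataFrame(
        patient_data,
        columns=["patient_id", "trial_id", "arm_id", "regimen_class", "age",
                 "sex", "ecog", "os_day", "os_event", "nontarget_progression"],
    )
    meta = pat_df.set_index("patient_id")[["trial_id", "arm_id"]]
    rows = [
        {
            "trial_id": meta.loc[pid, "trial_id"],
            "arm_id": meta.loc[pid, "arm_id"],
            "patient_id": pid,
            "lesion_id": lid,
            "assessment_day": day,
            "diameter": float(diam),
        }
        for pid, les in lesion_data.items()
        for lid, day, diam in les
    ]
    return pd.DataFrame(rows), pat_df
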