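"""CSV ingest/egress and run configuration.

Lesion tables are long-format (one row per lesion per assessment) and
patient tables one row per patient; see ``harmonize.LESION_COLUMNS`` /
``PATIENT_COLUMNS``. Diameters are stored internally in millimetres;
readers accept a unit declaration (``mm`` or ``cm``) and convert on
ingest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .classify import CutoffConfig, SensitivityResult
from .harmonize import LESION_COLUMNS, PATIENT_COLUMNS, HarmonizedCohort

__all__ = [
    "read_lesion_table",
    "read_patient_table",
    "write_classifications",
    "write_exclusion_ledger",
    "write_crosstab",
    "write_km_curves",
    "report_to_jsonable",
    "load_run_config",
    "cutoffs_from_config",
    "sensitivity_grid_from_config",
]

UNIT_FACTORS = {"mm": 1.0, "cm": 10.0}


def read_lesion_table(path, unit: str = "mm") -> pd.DataFrame:
    """Read a lesion measurement CSV, converting diameters to mm."""
    if unit not in UNIT_FACTORS:
        raise ValueError(f"unknown diameter unit {unit!r}; expected one of {sorted(UNIT_FACTORS)}")
    df = pd.read_csv(path, dtype={"trial_id": str, "arm_id": str,
                                  "patient_id": str, "lesion_id": str})
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion CSV {path} missing columns: {missing}")
    df["diameter"] = pd.to_numeric(df["diameter"]) * UNIT_FACTORS[unit]
    return df


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trial_id": str, "arm_id": str, "patient_id": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient CSV {path} missing columns: {missing}")
    return df


def write_classifications(classifications: pd.DataFrame, path) -> None:
    classifications.to_csv(path, index=False)


def write_exclusion_ledger(cohort: HarmonizedCohort, path) -> None:
    cohort.ledger.to_csv(path, index=False)


def write_crosstab(counts: pd.DataFrame, pct: pd.DataFrame, out_dir) -> None:
    out_dir = Path(out_dir)
    counts.to_csv(out_dir / "crosstab_counts.csv")
    pct.to_csv(out_dir / "crosstab_row_pct.csv")


def write_km_curves(report: dict, path) -> None:
    """Flatten the KM step functions of the overall fits to one CSV."""
    rows = []
    for key in ("lbr12_overall", "recist_overall"):
        fit = report.get(key)
        if fit is None:
            continue
        for level, km in fit.km_by_level.items():
            for t, s in zip(km.times, km.survival):
                rows.append(
                    {"grouping": key, "level": level,
                     "time_months": t, "survival": s}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return None if not np.isfinite(obj) else obj
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return str(obj)


def report_to_jsonable(report: dict) -> dict:
    """Convert a survival report bundle to plain JSON-serializable data."""
    return _jsonable(report)


def write_sensitivity_report(results: list[SensitivityResult], out_dir) -> None:
    out_dir = Path(out_dir)
    summary = []
    for i, res in enumerate(results, start=1):
        res.classifications.to_csv(out_dir / f"sensitivity_{i}.csv", index=False)
        summary.append(
            {
                "config": res.cutoffs.label(),
                "c_pl": res.cutoffs.c_pl,
                "c_rl": res.cutoffs.c_rl,
                "agreement_with_default": res.agreement_with_default,
                "pattern_distribution": res.pattern_distribution.to_dict(),
            }
        )
    with open(out_dir / "sensitivity_summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)


DEFAULT_RUN_CONFIG = {
    "unit": "mm",
    "cutoffs": {"c_pl": 0.20, "c_rl": -0.30, "inclusive_boundaries": True},
    "recist": {"apply_5mm_rule": True},
    "survival": {"strata": ["trial_id", "arm_id"],
                 "covariates": ["age", "sex", "ecog"]},
    "sensitivity_grid": None,  # None -> the built-in six-combination grid
}


def load_run_config(path=None) -> dict:
    """Merge a YAML config file (if given) over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_RUN_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def cutoffs_from_config(cfg: dict) -> CutoffConfig:
    c = cfg.get("cutoffs", {})
    return CutoffConfig(
        c_pl=float(c.get("c_pl", 0.20)),
        c_rl=float(c.get("c_rl", -0.30)),
        inclusive_boundaries=bool(c.get("inclusive_boundaries", True)),
    )


def sensitivity_grid_from_config(cfg: dict):
    from .classify import DEFAULT_SENSITIVITY_GRID

    grid = cfg.get("sensitivity_grid")
    if not grid:
        return DEFAULT_SENSITIVITY_GRID
    return tuple(
        CutoffConfig(
            c_pl=float(g["c_pl"]), c_rl=float(g["c_rl"]),
            inclusive_boundaries=bool(g.get("inclusive_boundaries", True)),
        )
        for g in grid
    )
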