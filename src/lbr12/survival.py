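"""Landmark overall-survival evaluation of response classifications.

Survival is measured from the restaging scan that defined the response
(the landmark), so patients contribute no immortal time before their
classification exists. The module provides Kaplan-Meier estimation per
group, a stratified log-rank test, stratified multivariable Cox models
(Efron tie handling, via lifelines) adjusting for age, sex and ECOG
performance status, Harrell's concordance index with a jackknife CI, and
a report builder comparing the lesion-based criterion with RECIST 1.1
overall, per treatment-regimen subgroup, and within RECIST strata.

Times are computed internally in days; months (= days / 30.4375) are
used for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import median_survival_times
from scipy import stats

from .classify import GrowthPattern, PrevalenceSubclass, RecistCategory

__all__ = [
    "DAYS_PER_MONTH",
    "KMEstimate",
    "LogrankResult",
    "SurvivalFitResult",
    "km_estimate",
    "stratified_logrank",
    "fit_cox",
    "concordance",
    "compare_classifications",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375


@dataclass
class KMEstimate:
    """Kaplan-Meier survival estimate for one group.

    ``median`` is ``inf`` when the curve never drops to 0.5 (reported
    as "NE", not estimable); CI bounds may likewise be ``inf``.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    events: int

    @property
    def median_label(self) -> str:
        return "NE" if not np.isfinite(self.median) else f"{self.median:.1f}"


def km_estimate(durations, events) -> KMEstimate:
    """Product-limit estimator with log-log CIs.

    The median CI is read off the pointwise confidence band
    (Brookmeyer-Crowley style interval).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(durations) == 0:
        raise ValueError("cannot estimate survival from an empty group")
    if (durations <= 0).any():
        raise ValueError("all survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        median_ci=(lo, hi),
        n=len(durations),
        events=int(events.sum()),
    )


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def stratified_logrank(durations, events, groups, strata=None) -> LogrankResult:
    """Stratified log-rank test across ``groups``.

    Observed-minus-expected score vectors and their covariance are
    accumulated per stratum and summed; the statistic is the quadratic
    form of the pooled score, chi-square with (#groups - 1) df. With a
    single stratum this is the ordinary (unstratified) log-rank test.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    strata = (
        np.zeros(len(durations), dtype=int) if strata is None else np.asarray(strata)
    )
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    G = len(levels)
    gidx = np.searchsorted(levels, groups)

    score = np.zeros(G)
    cov = np.zeros((G, G))
    for s in np.unique(strata):
        m = strata == s
        t, e, g = durations[m], events[m], gidx[m]
        ut, t_idx = np.unique(t, return_inverse=True)
        T = len(ut)
        # per-group counts at each unique time, then at-risk via suffix sums
        present = np.zeros((G, T))
        np.add.at(present, (g, t_idx), 1.0)
        at_risk = np.cumsum(present[:, ::-1], axis=1)[:, ::-1]
        deaths = np.zeros((G, T))
        np.add.at(deaths, (g[e == 1], t_idx[e == 1]), 1.0)

        d_t = deaths.sum(axis=0)
        has_event = d_t > 0
        n_t = at_risk.sum(axis=0)[has_event]
        d_t = d_t[has_event]
        n_gt = at_risk[:, has_event]
        d_gt = deaths[:, has_event]
        p = n_gt / n_t
        score += (d_gt - d_t * p).sum(axis=1)
        w = np.where(n_t > 1, d_t * (n_t - d_t) / np.maximum(n_t - 1, 1), 0.0)
        cov += np.diag((w * p).sum(axis=1)) - np.einsum("t,it,jt->ij", w, p, p)

    z = score[:-1]
    V = cov[:-1, :-1]
    stat = float(z @ np.linalg.pinv(V) @ z)
    df = G - 1
    return LogrankResult(stat, df, float(stats.chi2.sf(stat, df)))


def concordance(
    risk_scores,
    durations,
    events,
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with 95% CI.

    An ordered pair (i, j) is comparable when ``t_i < t_j`` and subject
    i died; it is concordant when the earlier death also has the higher
    risk score, and predictor ties count 0.5. The default CI is
    leave-one-subject-out jackknife (computed exactly from per-subject
    pair sums); ``n_bootstrap > 0`` switches to a seeded percentile
    bootstrap over subjects.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(r)
    conc_i, comp_i = _pair_sums(r, t, e)
    Q = comp_i.sum() / 2.0
    if Q == 0:
        raise ValueError("no comparable pairs (all times tied or no events)")
    P = conc_i.sum() / 2.0
    c = float(P / Q)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            ci_, qi_ = _pair_sums(r[idx], t[idx], e[idx])
            if qi_.sum() > 0:
                reps.append(ci_.sum() / qi_.sum())
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return c, (float(lo), float(hi))

    # exact leave-one-out: removing subject i removes pair sums (conc_i, comp_i)
    q_loo = 2 * Q - comp_i
    valid = q_loo > 0
    c_loo = np.where(valid, (2 * P - conc_i) / np.where(valid, q_loo, 1.0), c)
    se = float(np.sqrt((n - 1) / n * ((c_loo - c_loo.mean()) ** 2).sum()))
    lo = max(0.0, c - 1.959963984540054 * se)
    hi = min(1.0, c + 1.959963984540054 * se)
    return c, (lo, hi)


def _pair_sums(r, t, e, chunk: int = 512):
    """Per-subject concordant / comparable pair counts (both pair roles)."""
    n = len(r)
    conc = np.zeros(n)
    comp = np.zeros(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        comparable = (t[sl, None] < t[None, :]) & (e[sl, None] == 1)
        score = np.where(
            r[sl, None] > r[None, :], 1.0, np.where(r[sl, None] == r[None, :], 0.5, 0.0)
        )
        contrib = comparable * score
        conc[sl] += contrib.sum(axis=1)
        conc += contrib.sum(axis=0)
        comp[sl] += comparable.sum(axis=1)
        comp += comparable.sum(axis=0)
    return conc, comp


@dataclass
class SurvivalFitResult:
    """Stratified multivariable Cox fit summarized per group level."""

    group_col: str
    reference: str
    levels: pd.DataFrame  # level, hr, ci_low, ci_high, p, n, events, estimable
    lr_statistic: float
    lr_df: int
    lr_p: float
    concordance: float
    concordance_ci: tuple[float, float]
    n_used: int
    n_events: int
    n_dropped_missing: int
    strata_cols: tuple[str, ...]
    covariates: tuple[str, ...]
    km_by_level: dict[str, KMEstimate] = field(default_factory=dict)

    def hr(self, level: str) -> float:
        row = self.levels.set_index("level").loc[level]
        return float(row["hr"])

    def to_dict(self) -> dict:
        return {
            "group": self.group_col,
            "reference": self.reference,
            "levels": self.levels.to_dict(orient="records"),
            "lr_statistic": self.lr_statistic,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "concordance": self.concordance,
            "concordance_ci": list(self.concordance_ci),
            "n_used": self.n_used,
            "n_events": self.n_events,
            "n_dropped_missing": self.n_dropped_missing,
            "strata": list(self.strata_cols),
            "covariates": list(self.covariates),
            "km_median_months": {
                lvl: {"median": km.median, "ci": list(km.median_ci),
                      "n": km.n, "events": km.events}
                for lvl, km in self.km_by_level.items()
            },
        }


def _build_design(
    df: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, int, list[str]]:
    """Covariate design matrix with complete-case handling.

    sex -> male indicator; ecog -> indicator columns vs ECOG 0; age is
    numeric. Returns (design, n dropped for missingness, column names).
    """
    design = pd.DataFrame(index=df.index)
    keep = pd.Series(True, index=df.index)
    cols: list[str] = []
    for cov in covariates:
        col = df[cov]
        if cov == "sex":
            keep &= col.notna()
            design["sex_male"] = (col == "male").astype(float)
            cols.append("sex_male")
        elif cov == "ecog":
            keep &= col.notna()
            ecog = pd.to_numeric(col, errors="coerce")
            keep &= ecog.notna()
            for lvl in (1, 2):
                name = f"ecog_{lvl}"
                design[name] = (ecog == lvl).astype(float)
                cols.append(name)
        else:
            num = pd.to_numeric(col, errors="coerce")
            keep &= num.notna()
            design[cov] = num
            cols.append(cov)
    dropped = int((~keep).sum())
    return design.loc[keep, cols], dropped, cols


def fit_cox(
    data: pd.DataFrame,
    group_col: str,
    reference: str,
    duration_col: str = "landmark_months",
    event_col: str = "os_event",
    covariates: Sequence[str] = ("age", "sex", "ecog"),
    strata_cols: Sequence[str] = ("trial_id", "arm_id"),
    min_level_events: int = 1,
) -> SurvivalFitResult:
    """Stratified multivariable Cox model for a group factor.

    Hazard ratios are reported per non-reference level against
    ``reference``; the global p-value is the likelihood-ratio test of
    the group factor (full vs covariate-only model on identical rows).
    Rows with missing covariates are excluded (complete case) with the
    count logged. Group levels with fewer than ``min_level_events``
    events (default: any level with zero events) are flagged
    non-estimable and left out of the fit — with many strata a level
    carrying a couple of events gives a singular partial likelihood.
    Ties use Efron's method (lifelines default).
    """
    df = data.copy()
    levels = [lvl for lvl in pd.unique(df[group_col]) if pd.notna(lvl)]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from {group_col}")
    if len(levels) < 2:
        raise ValueError(f"{group_col} needs >=2 levels, got {levels}")

    design, n_dropped, cov_cols = _build_design(df, covariates)
    df = df.loc[design.index]
    if n_dropped:
        logger.info("fit_cox: dropped %d rows with missing covariates", n_dropped)

    # flag separated/sparse levels as non-estimable, exclude from fit
    ev_by_level = df.groupby(group_col, observed=True)[event_col].sum()
    inestimable = [
        lvl for lvl in levels
        if lvl != reference and ev_by_level.get(lvl, 0) < max(min_level_events, 1)
    ]
    for lvl in inestimable:
        logger.warning(
            "fit_cox: level %r has %d events (< %d); HR not estimable",
            lvl, int(ev_by_level.get(lvl, 0)), max(min_level_events, 1),
        )
    fit_levels = [lvl for lvl in levels if lvl not in inestimable]
    fit_df = df[df[group_col].isin(fit_levels)]
    design_f = design.loc[fit_df.index]

    dummies = pd.get_dummies(fit_df[group_col]).astype(float)
    dummy_cols = [str(lvl) for lvl in fit_levels if lvl != reference]
    dummies.columns = [str(c) for c in dummies.columns]
    dummies = dummies[dummy_cols]
    dummies.columns = [f"grp_{c}" for c in dummy_cols]

    strata_key = (
        fit_df[list(strata_cols)].astype(str).agg("|".join, axis=1)
        if strata_cols
        else None
    )
    model_df = pd.concat(
        [fit_df[[duration_col, event_col]], dummies, design_f], axis=1
    )
    if strata_key is not None:
        model_df["_stratum"] = strata_key

    def _fit(frame, drop_group: bool):
        cols = [c for c in frame.columns if not (drop_group and c.startswith("grp_"))]
        sub = frame[cols]
        if drop_group and not cov_cols:
            return None
        cph = CoxPHFitter()
        try:
            cph.fit(
                sub,
                duration_col=duration_col,
                event_col=event_col,
                strata="_stratum" if strata_key is not None else None,
                fit_options={"precision": 1e-9},
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"Cox model for {group_col!r} failed to converge "
                f"(n={len(sub)}, events={int(sub[event_col].sum())}): {err}"
            ) from err
        return cph

    full = _fit(model_df, drop_group=False)
    reduced = _fit(model_df, drop_group=True)
    lr_df_ = len(dummies.columns)
    if reduced is not None:
        lr_stat = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    else:
        lr_stat = full.log_likelihood_ratio_test().test_statistic
    lr_p = float(stats.chi2.sf(lr_stat, lr_df_))

    summ = full.summary
    rows = []
    for lvl in levels:
        n_lvl = int((df[group_col] == lvl).sum())
        e_lvl = int(ev_by_level.get(lvl, 0))
        if lvl == reference:
            rows.append((str(lvl), 1.0, np.nan, np.nan, np.nan, n_lvl, e_lvl, True))
        elif lvl in inestimable:
            rows.append((str(lvl), np.nan, np.nan, np.nan, np.nan, n_lvl, e_lvl, False))
        else:
            s = summ.loc[f"grp_{lvl}"]
            rows.append(
                (str(lvl), float(s["exp(coef)"]),
                 float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"]),
                 float(s["p"]), n_lvl, e_lvl, True)
            )
    level_tbl = pd.DataFrame(
        rows,
        columns=["level", "hr", "ci_low", "ci_high", "p", "n", "events", "estimable"],
    )

    lp = full.predict_log_partial_hazard(model_df)
    c, c_ci = concordance(
        lp.to_numpy(), fit_df[duration_col].to_numpy(), fit_df[event_col].to_numpy()
    )

    km = {
        str(lvl): km_estimate(
            grp[duration_col].to_numpy(), grp[event_col].to_numpy()
        )
        for lvl, grp in df.groupby(group_col, observed=True)
    }

    return SurvivalFitResult(
        group_col=group_col,
        reference=str(reference),
        levels=level_tbl,
        lr_statistic=float(lr_stat),
        lr_df=lr_df_,
        lr_p=lr_p,
        concordance=c,
        concordance_ci=c_ci,
        n_used=len(fit_df),
        n_events=int(fit_df[event_col].sum()),
        n_dropped_missing=n_dropped,
        strata_cols=tuple(strata_cols),
        covariates=tuple(covariates),
        km_by_level=km,
    )


# canonical reference levels: stable-disease-like middle categories
LBR_REFERENCE = GrowthPattern.SL_ONLY.value
RECIST_REFERENCE = RecistCategory.SD.value
WITHIN_PR_REFERENCE = GrowthPattern.RL_ONLY.value
WITHIN_SD_REFERENCE = GrowthPattern.RL_SL.value


def _merged(records: pd.DataFrame, classifications: pd.DataFrame) -> pd.DataFrame:
    df = records.merge(
        classifications[
            ["patient_id", "growth_pattern", "prevalence_subclass", "recist"]
        ],
        on="patient_id",
        how="inner",
    )
    df["landmark_months"] = df["landmark_os_day"] / DAYS_PER_MONTH
    return df


def _try_fit(df, group_col, reference, label, **kw) -> Optional[SurvivalFitResult]:
    present = [lvl for lvl in pd.unique(df[group_col]) if pd.notna(lvl)]
    if len(present) < 2 or reference not in present:
        warnings.warn(f"{label}: fewer than 2 usable levels; fit skipped")
        return None
    try:
        return fit_cox(df, group_col, reference, min_level_events=5, **kw)
    except (ConvergenceError, ValueError) as err:
        warnings.warn(f"{label}: fit skipped ({err})")
        return None


def compare_classifications(
    records: pd.DataFrame,
    classifications: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "ecog"),
    strata_cols: Sequence[str] = ("trial_id", "arm_id"),
) -> dict:
    """Full landmark-survival comparison of LBR12 vs RECIST 1.1.

    Produces stratified adjusted Cox fits of the growth pattern
    (reference SL only) and of RECIST (reference SD), overall and per
    treatment-regimen subgroup; the prevalence sub-classification fit
    among RL/PL patients (unstratified — the subgroup is small); fits of
    the growth pattern within the RECIST PR and SD subsets (references
    RL only and RL/SL); and the side-by-side concordance table. Entries
    whose subgroup has fewer than two levels are None with a warning.
    """
    df = _merged(records, classifications)
    kw = dict(covariates=covariates, strata_cols=strata_cols)

    report: dict = {}
    report["lbr12_overall"] = _try_fit(
        df, "growth_pattern", LBR_REFERENCE, "LBR12 overall", **kw
    )
    report["recist_overall"] = _try_fit(
        df, "recist", RECIST_REFERENCE, "RECIST overall", **kw
    )

    report["lbr12_by_regimen"] = {}
    report["recist_by_regimen"] = {}
    for regimen, sub in df.groupby("regimen_class", observed=True):
        report["lbr12_by_regimen"][regimen] = _try_fit(
            sub, "growth_pattern", LBR_REFERENCE, f"LBR12 {regimen}", **kw
        )
        report["recist_by_regimen"][regimen] = _try_fit(
            sub, "recist", RECIST_REFERENCE, f"RECIST {regimen}", **kw
        )

    rl_pl = df[df["growth_pattern"] == GrowthPattern.RL_PL.value]
    report["prevalence"] = (
        _try_fit(
            rl_pl, "prevalence_subclass", PrevalenceSubclass.EQUAL_RL_PL.value,
            "prevalence subclass", covariates=covariates, strata_cols=(),
        )
        if len(rl_pl)
        else None
    )

    report["within_recist"] = {}
    for cat, ref in ((RecistCategory.PR.value, WITHIN_PR_REFERENCE),
                     (RecistCategory.SD.value, WITHIN_SD_REFERENCE)):
        sub = df[df["recist"] == cat]
        report["within_recist"][cat] = (
            _try_fit(sub, "growth_pattern", ref, f"LBR12 within RECIST {cat}", **kw)
            if len(sub)
            else None
        )
        if not len(sub):
            warnings.warn(f"RECIST {cat} subset empty; within-{cat} fit skipped")

    conc_rows = []
    populations = [("overall", df)] + [
        (str(r), g) for r, g in df.groupby("regimen_class", observed=True)
    ]
    for name, sub in populations:
        lb = report["lbr12_overall"] if name == "overall" else report["lbr12_by_regimen"].get(name)
        rc = report["recist_overall"] if name == "overall" else report["recist_by_regimen"].get(name)
        if lb is None or rc is None:
            continue
        conc_rows.append(
            {
                "population": name,
                "lbr12_concordance": lb.concordance,
                "lbr12_ci_low": lb.concordance_ci[0],
                "lbr12_ci_high": lb.concordance_ci[1],
                "recist_concordance": rc.concordance,
                "recist_ci_low": rc.concordance_ci[0],
                "recist_ci_high": rc.concordance_ci[1],
            }
        )
    report["concordance_table"] = pd.DataFrame(conc_rows)
    return report
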