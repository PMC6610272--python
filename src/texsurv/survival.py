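"""Cox proportional-hazards screening and Kaplan-Meier stratification.

Survival records live in a pandas DataFrame with one row per patient:

    patient_id, age, sex, t_stage (1-4), n_stage (0-3), overall_stage (1-4),
    pfs_months, event

plus any number of continuous covariate columns (texture features,
volume_cm3).  ``event`` is 1 for progression, 0 for censoring; progression-
free survival (PFS) is in months from the start of treatment.

The Cox partial likelihood is maximized with the Efron tie correction by
default (Breslow available), via lifelines.  Stage variables enter
dichotomized: T 1-2 vs 3-4, N 0-1 vs 2-3, overall stage I-II vs III-IV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning

__all__ = [
    "CoxFit",
    "KMCurve",
    "ScreenResult",
    "validate_records",
    "add_dichotomized_stages",
    "cox_fit",
    "univariate_screen",
    "km_curve",
    "log_rank",
    "DICHOTOMIZED",
]

REQUIRED_COLUMNS = ("pfs_months", "event")

# raw column -> (binary column, rule)
DICHOTOMIZED = {
    "t_stage": ("t_stage_34", lambda s: (s >= 3).astype(int)),
    "n_stage": ("n_stage_23", lambda s: (s >= 2).astype(int)),
    "overall_stage": ("stage_34", lambda s: (s >= 3).astype(int)),
    "sex": ("male", lambda s: (s.astype(str).str.upper().str[0] == "M").astype(int)),
}


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the record invariants; returns the frame unchanged."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"records missing required column {col!r}")
    if (df["pfs_months"] < 0).any():
        raise ValueError("pfs_months must be >= 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (progressed)")
    ranges = {"t_stage": (1, 4), "n_stage": (0, 3), "overall_stage": (1, 4)}
    for col, (lo, hi) in ranges.items():
        if col in df.columns and not df[col].between(lo, hi).all():
            raise ValueError(f"{col} codes out of range [{lo}, {hi}]")
    return df


def add_dichotomized_stages(df: pd.DataFrame) -> pd.DataFrame:
    """Append the dichotomized stage/sex columns used by the analysis."""
    out = df.copy()
    for raw, (binary, rule) in DICHOTOMIZED.items():
        if raw in out.columns:
            out[binary] = rule(out[raw])
    return out


@dataclass(frozen=True)
class CoxFit:
    """One Cox PH fit: per-covariate estimates plus fit diagnostics.

    ``table`` has one row per covariate with columns
    coef, hr, hr_ci_low, hr_ci_high, se, p  (Wald CIs exp(beta +/- 1.96 SE)).
    """

    covariates: tuple[str, ...]
    table: pd.DataFrame = field(repr=False)
    log_likelihood: float
    converged: bool
    ties: str = "efron"

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        """Risk score sum(beta_k x_k) for each row of ``df`` (uncentred)."""
        beta = self.table["coef"].to_numpy()
        X = df[list(self.covariates)].to_numpy(dtype=float)
        return X @ beta


def cox_fit(
    records: pd.DataFrame,
    covariate_names: Sequence[str],
    *,
    ties: str = "efron",
    duration_col: str = "pfs_months",
    event_col: str = "event",
) -> CoxFit:
    """Maximize the Cox partial likelihood for the named covariates.

    Monotone-likelihood / separation problems are reported through
    ``converged=False`` (with NaN estimates where lifelines produced none)
    rather than raised, so screening loops can continue.
    """
    if ties != "efron":
        raise NotImplementedError(
            "only the Efron tie correction is implemented"
        )
    names = list(covariate_names)
    if not names:
        raise ValueError("covariate_names must be non-empty")
    data = records[[duration_col, event_col, *names]].astype(float)
    if data[event_col].sum() < 1:
        raise ValueError("at least one event is required")
    for c in names:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                cph.fit(data, duration_col=duration_col, event_col=event_col)
            except ConvergenceWarning:
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        nan = np.full(len(names), np.nan)
        table = pd.DataFrame(
            {"coef": nan, "hr": nan, "hr_ci_low": nan, "hr_ci_high": nan,
             "se": nan, "p": nan},
            index=pd.Index(names, name="covariate"),
        )
        return CoxFit(tuple(names), table, np.nan, False, ties)
    s = cph.summary
    table = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "hr_ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "se": s["se(coef)"],
            "p": s["p"],
        }
    ).loc[names]
    table.index.name = "covariate"
    return CoxFit(tuple(names), table, float(cph.log_likelihood_), converged, ties)


@dataclass(frozen=True)
class ScreenResult:
    """Univariate screening outcome: retained names and all per-name fits."""

    retained: tuple[str, ...]
    fits: dict[str, CoxFit] = field(repr=False)
    failures: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    def table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            r = fit.table.loc[name].to_dict()
            r["covariate"] = name
            r["retained"] = name in self.retained
            rows.append(r)
        return pd.DataFrame(rows).set_index("covariate")


def univariate_screen(
    records: pd.DataFrame,
    candidate_names: Sequence[str],
    alpha: float = 0.05,
    *,
    ties: str = "efron",
) -> ScreenResult:
    """Fit one single-covariate Cox model per candidate; retain p < alpha.

    Per-candidate failures (constant covariate, separation without an
    estimate) are recorded and screening continues.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    fits: dict[str, CoxFit] = {}
    failures: dict[str, str] = {}
    retained = []
    for name in candidate_names:
        try:
            fit = cox_fit(records, [name], ties=ties)
        except ValueError as exc:
            failures[name] = str(exc)
            continue
        fits[name] = fit
        p = fit.table.loc[name, "p"]
        if np.isfinite(p) and p < alpha:
            retained.append(name)
    return ScreenResult(tuple(retained), fits, failures, alpha)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate on the observed event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(
    records: pd.DataFrame,
    group_label: str = "",
    *,
    duration_col: str = "pfs_months",
    event_col: str = "event",
) -> KMCurve:
    """Kaplan-Meier estimate for one group of records."""
    if len(records) == 0:
        raise ValueError(f"group {group_label!r} has zero subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(records[duration_col], records[event_col], label=group_label or None)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk, label=group_label)


def log_rank(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    *,
    duration_col: str = "pfs_months",
    event_col: str = "event",
) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups need at least one subject")
    res = _ll_logrank(
        records_a[duration_col], records_b[duration_col],
        event_observed_A=records_a[event_col], event_observed_B=records_b[event_col],
    )
    return float(res.test_statistic), float(res.p_value)
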