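"""Cutpoints, fixed-horizon ROC and Harrell C-index model comparison.

Prognostic models are compared on two scales:

* a fixed-horizon binary outcome (progression by ``horizon`` months,
  default 24) with ROC analysis — AUC with the Hanley-McNeil standard
  error, the Youden-index cutpoint, and sensitivity / specificity / PPV /
  NPV with Clopper-Pearson exact intervals; correlated AUCs are compared
  with the Hanley-McNeil (1983) paired z-test;
* the full (time, event) scale with Harrell's concordance index; two
  models' C-indices are compared with a Z-test whose variance comes from a
  leave-one-patient-out jackknife of the C difference (a paired-bootstrap
  alternative is provided).

The binary horizon outcome is only defined for patients who either
progressed by the horizon or were followed at least to the horizon;
records censored earlier are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCReport",
    "ConcordanceReport",
    "binary_horizon_outcome",
    "youden_cutoff",
    "auc",
    "compare_auc",
    "c_index",
    "compare_c",
    "combined_risk_score",
    "roc_report",
]


# ---------------------------------------------------------------- outcomes


def binary_horizon_outcome(
    records: pd.DataFrame,
    horizon_months: float = 24.0,
    *,
    duration_col: str = "pfs_months",
    event_col: str = "event",
) -> pd.Series:
    """Progression-by-horizon indicator, NaN where undefined.

    1 if the event occurred at or before the horizon; 0 if follow-up
    reached the horizon without progression; undefined (excluded, with a
    warning) for records censored before the horizon.
    """
    t = records[duration_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy()
    out = np.full(len(records), np.nan)
    progressed = (e == 1) & (t <= horizon_months)
    out[progressed] = 1.0
    out[~progressed & (t >= horizon_months)] = 0.0
    n_undef = int(np.isnan(out).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} record(s) censored before {horizon_months} months: "
            "binary horizon outcome undefined, excluded",
            stacklevel=2,
        )
    return pd.Series(out, index=records.index, name="progressed_by_horizon")


def _check_two_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both outcome classes must be present")
    return y == 1, y == 0


# ------------------------------------------------------------- Youden cut


def youden_cutoff(
    scores: np.ndarray,
    outcomes: np.ndarray,
    *,
    positive: str = "high",
) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Every observed score value is tried as a threshold.  ``positive="high"``
    predicts the event when score >= cutoff; ``"low"`` when score < cutoff
    (for protective markers such as uniformity).  Ties in J are broken
    toward the lower cutoff value.  Returns (cutoff, sensitivity,
    specificity) at the chosen cutoff.
    """
    s = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(np.asarray(outcomes, dtype=float))
    if positive not in ("high", "low"):
        raise ValueError("positive must be 'high' or 'low'")
    best = None
    for t in np.sort(np.unique(s)):
        pred = s >= t if positive == "high" else s < t
        sens = pred[pos].mean()
        spec = (~pred[neg]).mean()
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, cut, sens, spec = best
    return float(cut), float(sens), float(spec)


# -------------------------------------------------------------------- AUC


def auc(scores: np.ndarray, outcomes: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a Hanley-McNeil 95% CI.

    AUC = P(score_pos > score_neg) + 0.5 P(tie) over all positive/negative
    pairs; SE per Hanley & McNeil (1982), CI clipped to [0, 1].
    """
    a = _auc_point(scores, outcomes)
    pos, neg = _check_two_classes(np.asarray(outcomes, dtype=float))
    se = _hanley_mcneil_se(a, int(pos.sum()), int(neg.sum()))
    lo, hi = np.clip([a - 1.96 * se, a + 1.96 * se], 0.0, 1.0)
    return a, (float(lo), float(hi))


def _auc_point(scores, outcomes) -> float:
    s = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(np.asarray(outcomes, dtype=float))
    # Mann-Whitney via midranks: exact half-credit for ties
    r = stats.rankdata(s)
    n1, n0 = int(pos.sum()), int(neg.sum())
    u = r[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _hanley_mcneil_se(a: float, n1: int, n0: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def compare_auc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    outcomes: np.ndarray,
) -> tuple[float, float]:
    """Hanley-McNeil (1983) z-test for two correlated (paired) AUCs.

    Both scores must be computed on the same patients.  The correlation
    between the two AUC estimates is approximated by the average of the
    Pearson correlations of the two scores within the positive and within
    the negative class, following the common implementation of the 1983
    table.  Returns (z, two-sided p).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired comparison requires scores on the same patients")
    pos, neg = _check_two_classes(y)
    a1, a2 = _auc_point(sa, y), _auc_point(sb, y)
    se1 = _hanley_mcneil_se(a1, int(pos.sum()), int(neg.sum()))
    se2 = _hanley_mcneil_se(a2, int(pos.sum()), int(neg.sum()))
    r = np.nanmean([_safe_corr(sa[pos], sb[pos]), _safe_corr(sa[neg], sb[neg])])
    if np.isnan(r):
        r = 0.0
    denom = np.sqrt(max(se1**2 + se2**2 - 2 * r * se1 * se2, 1e-300))
    z = (a1 - a2) / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _safe_corr(x, y) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


# ------------------------------------------------------------ concordance


def _c_counts(time, event, risk) -> tuple[float, float]:
    """(weighted concordant count, usable pair count) for Harrell's C.

    A pair is usable when the subject with the shorter time had an event
    (or both had events at different times).  Ties in risk get half credit;
    tied event times are not usable pairs.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    r = np.asarray(risk, dtype=float)
    n = len(t)
    conc = 0.0
    usable = 0.0
    for i in range(n):
        if e[i] != 1:
            continue
        later = (t > t[i]) | ((t == t[i]) & (e == 0))
        usable += later.sum()
        conc += (r[i] > r[later]).sum() + 0.5 * (r[i] == r[later]).sum()
    return conc, usable


def c_index(
    time: np.ndarray,
    event: np.ndarray,
    risk: np.ndarray,
    *,
    ci: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with a jackknife 95% CI.

    C = P(higher risk score -> earlier progression) over usable pairs.
    """
    conc, usable = _c_counts(time, event, risk)
    if usable == 0:
        raise ValueError("no usable (comparable) pair")
    c = conc / usable
    if not ci:
        return float(c), (np.nan, np.nan)
    se = _jackknife_se(time, event, lambda idx: _c_of(time, event, risk, idx))
    lo, hi = np.clip([c - 1.96 * se, c + 1.96 * se], 0.0, 1.0)
    return float(c), (float(lo), float(hi))


def _c_of(time, event, risk, keep_idx) -> float:
    conc, usable = _c_counts(time[keep_idx], event[keep_idx], risk[keep_idx])
    return conc / usable if usable > 0 else np.nan


def _jackknife_se(time, event, stat_of_subset) -> float:
    t = np.asarray(time)
    n = len(t)
    vals = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        vals[i] = stat_of_subset(keep)
    vals = vals[np.isfinite(vals)]
    m = len(vals)
    if m < 2:
        return np.nan
    return float(np.sqrt((m - 1) / m * ((vals - vals.mean()) ** 2).sum()))


def compare_c(
    time: np.ndarray,
    event: np.ndarray,
    risk_a: np.ndarray,
    risk_b: np.ndarray,
    *,
    method: str = "jackknife",
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Z-test for the difference of two correlated Harrell C-indices.

    ``method="jackknife"`` (default): leave-one-patient-out variance of
    C_a - C_b.  ``method="bootstrap"``: paired patient bootstrap SE.
    Returns (z, two-sided p).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    ra = np.asarray(risk_a, dtype=float)
    rb = np.asarray(risk_b, dtype=float)
    ca, _ = c_index(t, e, ra, ci=False)
    cb, _ = c_index(t, e, rb, ci=False)
    delta = ca - cb
    if method == "jackknife":
        se = _jackknife_se(
            t, e, lambda idx: _c_of(t, e, ra, idx) - _c_of(t, e, rb, idx)
        )
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(t)
        deltas = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                deltas.append(_c_of(t, e, ra, idx) - _c_of(t, e, rb, idx))
            except ZeroDivisionError:  # pragma: no cover - no usable pairs
                continue
        se = float(np.nanstd(deltas, ddof=1))
    else:
        raise ValueError("method must be 'jackknife' or 'bootstrap'")
    if not np.isfinite(se) or se == 0:
        # identical scores (or no resampling variation): no evidence of a difference
        return 0.0, 1.0
    z = delta / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


# --------------------------------------------------------- combined score


def combined_risk_score(
    records: pd.DataFrame,
    component_names: list[str],
    *,
    ties: str = "efron",
) -> np.ndarray:
    """Cox linear predictor sum(beta_hat x) over the named components.

    With a single component this reduces to the raw covariate up to sign
    and scale, which leaves AUC and C-index unchanged (the sign orients the
    score so that higher = higher risk).
    """
    from .survival import cox_fit  # local import to avoid a cycle

    fit = cox_fit(records, component_names, ties=ties)
    if not fit.converged:
        raise ValueError(
            f"Cox fit over {component_names} did not converge; no risk score"
        )
    return fit.linear_predictor(records)


# ------------------------------------------------------------ ROC report


@dataclass(frozen=True)
class ROCReport:
    """Fixed-horizon ROC summary for one model (Table-style row)."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    n_positive: int
    n_negative: int


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    alpha = 1 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return (float(lo), float(hi))


def roc_report(
    scores: np.ndarray,
    outcomes: np.ndarray,
    *,
    positive: str = "high",
) -> ROCReport:
    """AUC, Youden cutpoint and the four predictive values with exact CIs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    pos, neg = _check_two_classes(y)
    oriented = s if positive == "high" else -s
    a, a_ci = auc(oriented, y)
    cut, sens, spec = youden_cutoff(s, y, positive=positive)
    pred = s >= cut if positive == "high" else s < cut
    tp = int((pred & pos).sum())
    fp = int((pred & neg).sum())
    tn = int((~pred & neg).sum())
    fn = int((~pred & pos).sum())
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return ROCReport(
        auc=a,
        auc_ci=a_ci,
        cutoff=cut,
        sensitivity=sens,
        sensitivity_ci=_clopper_pearson(tp, tp + fn),
        specificity=spec,
        specificity_ci=_clopper_pearson(tn, tn + fp),
        ppv=ppv,
        ppv_ci=_clopper_pearson(tp, tp + fp),
        npv=npv,
        npv_ci=_clopper_pearson(tn, tn + fn),
        n_positive=int(pos.sum()),
        n_negative=int(neg.sum()),
    )
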