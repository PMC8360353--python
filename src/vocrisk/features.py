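"""Per-subject feature assembly and candidate screening.

The classifier consumes a fixed 20-entry feature vector per subject:
10 clinical/subject covariates, 4 sleep indices, the median 5-min RRI
mean, the median 5-min PPGa coefficient of variation, and 4
vasoconstriction descriptors (median M_vasoc, median A_RRI-, median
A_RRI+, N_vasoc). Pain rates (hospitalization-requiring crises per year)
are dichotomized at 1.5 episodes/year into high (>= 1.5) and low (< 1.5)
categories.

The screening procedure that originally reduced a 44-candidate pool to
these 20 is reimplemented here: candidates are ranked within their group
by a rank-based association with the pain category and accepted greedily,
rejecting candidates that are rank-redundant (|Spearman rho| above a
threshold) with an already-accepted feature of the same group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import UniformSeries
from .vasoconstriction import SubjectEventSummary

__all__ = [
    "PAIN_RATE_THRESHOLD",
    "FEATURE_NAMES",
    "CANDIDATE_GROUPS",
    "windowed_stats",
    "assign_pain_category",
    "build_feature_vector",
    "build_candidate_pool",
    "screen_features",
    "ScreenResult",
]

#: Pain-rate dichotomization threshold, episodes/year; high pain iff >=.
PAIN_RATE_THRESHOLD = 1.5

#: Canonical order of the 20 model inputs.
FEATURE_NAMES: tuple[str, ...] = (
    # clinical / subject (10)
    "age",
    "sex",
    "hemoglobin",
    "white_blood_cell_count",
    "reticulocyte_count",
    "neutrophil_count",
    "diastolic_bp",
    "systolic_bp",
    "bmi",
    "hydroxyurea_use",
    # sleep (4)
    "arousal_index",
    "ahi",
    "limb_movements",
    "effective_sleep_duration",
    # all-night series statistics (2)
    "median_rri_mean_5min",
    "median_ppga_cv_5min",
    # vasoconstriction descriptors (4)
    "median_M_vasoc",
    "median_A_RRI_minus",
    "median_A_RRI_plus",
    "n_vasoc",
)

#: The 44-candidate pool, grouped; the first entries of each group are the
#: retained model inputs, the rest are documented decoys / alternates.
CANDIDATE_GROUPS: dict[str, tuple[str, ...]] = {
    "clinical": (
        "age", "sex", "hemoglobin", "white_blood_cell_count",
        "reticulocyte_count", "neutrophil_count", "diastolic_bp",
        "systolic_bp", "bmi", "hydroxyurea_use",
        "platelet_count", "bilirubin", "ldh", "fetal_hemoglobin",
    ),
    "sleep": (
        "arousal_index", "ahi", "limb_movements", "effective_sleep_duration",
        "sleep_efficiency", "rem_fraction", "sleep_latency",
    ),
    "rri_hrv": (
        "median_rri_mean_5min",
        "median_rri_sd_5min", "rmssd", "pnn50", "sdnn",
        "mean_rri_all_night", "rri_iqr", "median_hr_5min",
    ),
    "ppga": (
        "median_ppga_cv_5min",
        "median_ppga_mean_5min", "ppga_sd_all_night",
        "ppga_iqr", "median_ppga_min_5min", "ppga_skewness",
    ),
    "vasoconstriction": (
        "median_M_vasoc", "median_A_RRI_minus", "median_A_RRI_plus", "n_vasoc",
        "median_T_vasoc", "median_A_vasoc", "max_M_vasoc",
        "vasoc_per_hour", "mean_M_vasoc",
    ),
}

#: How many features the screen retains per group (10 + 4 + 1 + 1 + 4 = 20).
GROUP_QUOTAS: dict[str, int] = {
    "clinical": 10,
    "sleep": 4,
    "rri_hrv": 1,
    "ppga": 1,
    "vasoconstriction": 4,
}


def windowed_stats(
    series: UniformSeries, window: float = 300.0
) -> tuple[float, float]:
    """Median of per-window means and CVs over consecutive 5-min windows.

    The series is cut into non-overlapping windows; windows with more than
    50% masked samples are dropped; per-window mean and coefficient of
    variation (SD/mean) are computed over valid samples only. Returns
    (median of means, median of CVs); (nan, nan) when no window survives.
    """
    w = int(round(window * series.rate))
    n_win = len(series) // w
    means, cvs = [], []
    for i in range(n_win):
        vals = series.values[i * w : (i + 1) * w]
        m = series.mask[i * w : (i + 1) * w]
        if m.sum() <= w // 2:
            continue
        v = vals[m]
        mu = v.mean()
        means.append(mu)
        cvs.append(v.std() / mu if mu != 0 else np.nan)
    if not means:
        return (np.nan, np.nan)
    return (float(np.median(means)), float(np.nanmedian(cvs)))


def assign_pain_category(rate: float, threshold: float = PAIN_RATE_THRESHOLD) -> str:
    """Dichotomize an annual pain rate: 'high' iff rate >= threshold."""
    if rate < 0:
        raise ValueError("pain rate must be non-negative")
    return "high" if rate >= threshold else "low"


_CLINICAL_SLEEP = FEATURE_NAMES[:14]


def build_feature_vector(
    subject: dict,
    summary: SubjectEventSummary,
    windowed: dict[str, float],
) -> pd.Series:
    """Assemble the 20 model inputs for one subject, in canonical order.

    ``subject`` supplies the clinical/sleep covariates, ``summary`` the
    vasoconstriction medians (NaN for event-free subjects — imputed later
    inside cross-validation folds, never here), and ``windowed`` the
    all-night 5-min statistics (keys ``median_rri_mean_5min`` and
    ``median_ppga_cv_5min``).
    """
    row: dict[str, float] = {}
    for name in _CLINICAL_SLEEP:
        if name not in subject:
            raise KeyError(f"missing clinical/sleep field: {name}")
        row[name] = float(subject[name])
    for key in ("median_rri_mean_5min", "median_ppga_cv_5min"):
        row[key] = float(windowed[key])
    row["median_M_vasoc"] = summary.median_M_vasoc
    row["median_A_RRI_minus"] = summary.median_A_RRI_minus
    row["median_A_RRI_plus"] = summary.median_A_RRI_plus
    row["n_vasoc"] = float(summary.n_vasoc)
    return pd.Series(row, index=list(FEATURE_NAMES), dtype=float)


# --- candidate pool and screening ------------------------------------------


def build_candidate_pool(
    roster_row: dict,
    summary: SubjectEventSummary,
    ppga: UniformSeries,
    rri: UniformSeries,
    metrics_T: list[float] | None = None,
    metrics_A: list[float] | None = None,
    metrics_M: list[float] | None = None,
    sleep_hours: float | None = None,
) -> pd.Series:
    """Compute the full 44-candidate row for one subject.

    Includes the 20 retained inputs plus decoy clinical/sleep covariates
    and alternate signal statistics, so the screening procedure has a
    realistic pool to reduce.
    """
    w = int(round(300.0 * rri.rate))
    rri_valid = rri.valid_values()
    ppga_valid = ppga.valid_values()
    rri_means, rri_sds, hr_meds = [], [], []
    ppga_means, ppga_cvs, ppga_mins = [], [], []
    for i in range(len(rri) // w):
        m = rri.mask[i * w : (i + 1) * w]
        if m.sum() <= w // 2:
            continue
        v = rri.values[i * w : (i + 1) * w][m]
        rri_means.append(v.mean())
        rri_sds.append(v.std())
        hr_meds.append(60.0 / np.median(v))
        vp = ppga.values[i * w : (i + 1) * w][ppga.mask[i * w : (i + 1) * w]]
        if len(vp):
            ppga_means.append(vp.mean())
            ppga_cvs.append(vp.std() / vp.mean() if vp.mean() != 0 else np.nan)
            ppga_mins.append(vp.min())

    d_rri = np.diff(rri_valid)
    row = {
        name: float(roster_row[name])
        for g in ("clinical", "sleep")
        for name in CANDIDATE_GROUPS[g]
    }
    row.update(
        {
            "median_rri_mean_5min": float(np.median(rri_means)) if rri_means else np.nan,
            "median_rri_sd_5min": float(np.median(rri_sds)) if rri_sds else np.nan,
            "rmssd": float(np.sqrt(np.mean(d_rri**2))) if len(d_rri) else np.nan,
            "pnn50": float(np.mean(np.abs(d_rri) > 0.05)) if len(d_rri) else np.nan,
            "sdnn": float(rri_valid.std()) if len(rri_valid) else np.nan,
            "mean_rri_all_night": float(rri_valid.mean()) if len(rri_valid) else np.nan,
            "rri_iqr": float(np.subtract(*np.percentile(rri_valid, [75, 25]))) if len(rri_valid) else np.nan,
            "median_hr_5min": float(np.median(hr_meds)) if hr_meds else np.nan,
            "median_ppga_cv_5min": float(np.nanmedian(ppga_cvs)) if ppga_cvs else np.nan,
            "median_ppga_mean_5min": float(np.median(ppga_means)) if ppga_means else np.nan,
            "ppga_sd_all_night": float(ppga_valid.std()) if len(ppga_valid) else np.nan,
            "ppga_iqr": float(np.subtract(*np.percentile(ppga_valid, [75, 25]))) if len(ppga_valid) else np.nan,
            "median_ppga_min_5min": float(np.median(ppga_mins)) if ppga_mins else np.nan,
            "ppga_skewness": float(stats.skew(ppga_valid)) if len(ppga_valid) > 2 else np.nan,
            "median_M_vasoc": summary.median_M_vasoc,
            "median_A_RRI_minus": summary.median_A_RRI_minus,
            "median_A_RRI_plus": summary.median_A_RRI_plus,
            "n_vasoc": float(summary.n_vasoc),
            "median_T_vasoc": float(np.median(metrics_T)) if metrics_T else np.nan,
            "median_A_vasoc": float(np.median(metrics_A)) if metrics_A else np.nan,
            "max_M_vasoc": float(np.max(metrics_M)) if metrics_M else np.nan,
            "vasoc_per_hour": summary.n_vasoc / sleep_hours if sleep_hours else np.nan,
            "mean_M_vasoc": float(np.mean(metrics_M)) if metrics_M else np.nan,
        }
    )
    order = [n for g in CANDIDATE_GROUPS.values() for n in g]
    return pd.Series(row, index=order, dtype=float)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the candidate screen."""

    selected: list[str]
    report: pd.DataFrame  # feature, group, association, status, reason


def _association(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-biserial effect size of a feature against the binary label.

    Derived from the Mann-Whitney U statistic; 0 means identical rank
    distributions in the two classes, +/-1 perfect separation.
    """
    x1, x0 = x[y == 1], x[y == 0]
    ok1, ok0 = x1[~np.isnan(x1)], x0[~np.isnan(x0)]
    if len(ok1) == 0 or len(ok0) == 0:
        return 0.0
    u = stats.mannwhitneyu(ok1, ok0, alternative="two-sided").statistic
    return float(2.0 * u / (len(ok1) * len(ok0)) - 1.0)


def screen_features(
    pool: pd.DataFrame,
    labels: np.ndarray,
    quotas: dict[str, int] | None = None,
    redundancy_rho: float = 0.7,
) -> ScreenResult:
    """Greedy per-group feature screen.

    Within each candidate group, features are ranked by the absolute
    rank-biserial association with the binary pain category and accepted
    in rank order, rejecting any candidate whose |Spearman rho| with an
    already-accepted feature of the same group exceeds
    ``redundancy_rho``. Selection stops at the group quota; if redundancy
    rejections leave a quota unfilled, the least-redundant remaining
    candidates top it up so the screen always returns the contracted 20
    features. Constant (degenerate) features are excluded with a warning.
    """
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    quotas = quotas or GROUP_QUOTAS
    selected: list[str] = []
    rows = []
    for group, names in CANDIDATE_GROUPS.items():
        names = [n for n in names if n in pool.columns]
        scores = {}
        for n in names:
            x = pool[n].to_numpy(dtype=float)
            finite = x[~np.isnan(x)]
            if len(finite) == 0 or np.nanstd(x) == 0:
                warnings.warn(f"degenerate candidate feature {n!r} excluded")
                rows.append((n, group, 0.0, "rejected", "degenerate"))
                continue
            scores[n] = _association(x, y)
        ranked = sorted(scores, key=lambda n: abs(scores[n]), reverse=True)
        accepted: list[str] = []
        deferred: list[str] = []
        for n in ranked:
            if len(accepted) >= quotas.get(group, 0):
                rows.append((n, group, scores[n], "rejected", "quota filled"))
                continue
            redundant = False
            for a in accepted:
                rho = stats.spearmanr(
                    pool[n], pool[a], nan_policy="omit"
                ).statistic
                if np.isfinite(rho) and abs(rho) > redundancy_rho:
                    redundant = True
                    break
            if redundant:
                deferred.append(n)
                rows.append((n, group, scores[n], "rejected", "redundant"))
            else:
                accepted.append(n)
                rows.append((n, group, scores[n], "accepted", ""))
        # top up from deferred (least redundant first by rank) to meet quota
        for n in deferred:
            if len(accepted) >= quotas.get(group, 0):
                break
            accepted.append(n)
            rows.append((n, group, scores[n], "accepted", "quota top-up"))
        selected.extend(accepted)
    report = pd.DataFrame(
        rows, columns=["feature", "group", "association", "status", "reason"]
    )
    return ScreenResult(selected=selected, report=report)
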