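"""Survival statistics: maximally selected log-rank cutpoints, Kaplan-Meier /
log-rank comparisons, multivariate Cox models, and repeated random-split
validation of dichotomized scores.

The cutpoint search evaluates the two-group log-rank statistic at every
candidate threshold; the reported p value at the maximum is the *naive*
log-rank p and is anti-conservative because the threshold was selected to
maximise the statistic.  This inflation is deliberate (downstream analyses
re-test the selected threshold on an independent validation split); a
permutation-corrected p value is available via ``corrected="permutation"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2


REQUIRED_SURVIVAL_COLUMNS = ("time", "event")


def validate_survival_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check time/event sanity for the analyzed rows."""
    for col in REQUIRED_SURVIVAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    sub = df.dropna(subset=list(REQUIRED_SURVIVAL_COLUMNS))
    t = sub["time"].to_numpy(float)
    e = sub["event"].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("event indicators must be 0 or 1")
    return sub


def logrank_chi2(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test, vectorized.

    Returns ``(chi2_statistic, p)``.  ``group`` is a boolean or 0/1 array.
    Identical groups (or no events) give statistic 0 and p = 1.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    group = np.asarray(group).astype(bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]

    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 0.0, 1.0

    # at-risk counts just before each distinct event time
    n = len(t)
    # searchsorted gives the number of subjects with t < event_time
    n_at_risk = n - np.searchsorted(t, event_times, side="left")
    cum_g = np.concatenate([[0], np.cumsum(g)])
    n1_before = cum_g[np.searchsorted(t, event_times, side="left")]
    n1_at_risk = int(g.sum()) - n1_before

    # events at each distinct event time, total and in group 1
    is_event = e == 1
    d_total = np.zeros(event_times.size)
    d_group1 = np.zeros(event_times.size)
    idx = np.searchsorted(event_times, t[is_event])
    np.add.at(d_total, idx, 1.0)
    np.add.at(d_group1, idx, g[is_event].astype(float))

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1_at_risk / n_at_risk
        expected = d_total * frac
        var = d_total * frac * (1 - frac) * (n_at_risk - d_total) / (n_at_risk - 1)
    var = np.where(n_at_risk > 1, var, 0.0)
    O_minus_E = float(np.sum(d_group1 - expected))
    V = float(np.nansum(var))
    if V <= 0:
        return 0.0, 1.0
    stat = O_minus_E**2 / V
    return stat, float(chi2.sf(stat, df=1))


@dataclass
class CutpointResult:
    """Outcome of a maximally selected log-rank search."""

    threshold: float
    statistic: float
    p_naive: float  # log-rank p at the maximum; selection-biased, see module docstring
    candidates: np.ndarray = field(repr=False)
    p_corrected: Optional[float] = None


def optimal_cutpoint(
    table: pd.DataFrame,
    variable: str,
    min_prop: float = 0.1,
    min_events: int = 10,
    corrected: Optional[str] = None,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> CutpointResult:
    """Maximally selected log-rank dichotomization of a continuous variable.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values that leave at least ``min_prop`` of subjects on each side.  The
    returned threshold maximises the two-group log-rank statistic.  Set
    ``corrected="permutation"`` to additionally estimate a selection-adjusted
    p by re-running the full search on permuted survival labels.
    """
    df = validate_survival_table(table.dropna(subset=[variable]))
    values = df[variable].to_numpy(float)
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(float)
    if int(event.sum()) < min_events:
        raise ValueError(f"need >= {min_events} events, got {int(event.sum())}")
    uniq = np.unique(values)
    if uniq.size < 3:
        raise ValueError("variable needs >= 3 distinct values for a cutpoint search")

    candidates = _candidate_thresholds(values, min_prop)
    if candidates.size == 0:
        raise ValueError("no candidate threshold satisfies the min_prop constraint")

    stats = np.array(
        [logrank_chi2(time, event, values > c)[0] for c in candidates]
    )
    best = int(np.argmax(stats))
    stat = float(stats[best])
    p_naive = float(chi2.sf(stat, df=1))
    result = CutpointResult(float(candidates[best]), stat, p_naive, candidates)

    if corrected == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(values))
            perm_stats = max(
                logrank_chi2(time[perm], event[perm], values > c)[0]
                for c in candidates
            )
            if perm_stats >= stat:
                count += 1
        result.p_corrected = (count + 1) / (n_permutations + 1)
    return result


def _candidate_thresholds(values: np.ndarray, min_prop: float) -> np.ndarray:
    n = len(values)
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    keep = []
    srt = np.sort(values)
    for m in mids:
        n_high = n - np.searchsorted(srt, m, side="right")
        n_low = n - n_high
        if n_low >= min_prop * n and n_high >= min_prop * n:
            keep.append(m)
    return np.asarray(keep)


def km_logrank(
    table: pd.DataFrame, group_col: str
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus a log-rank test across groups.

    Returns ``(curves, statistic, p)`` where ``curves`` maps group label to
    the product-limit survival function (index: time).
    """
    df = validate_survival_table(table.dropna(subset=[group_col]))
    groups = df[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank comparison needs >= 2 groups")
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = df[df[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[str(g)] = kmf.survival_function_
    res = multivariate_logrank_test(df["time"], df[group_col], df["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_fit(
    table: pd.DataFrame,
    covariates: Sequence[str],
    categorical: Sequence[str] = ("stage",),
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards model (Efron tie handling).

    Categorical covariates are expanded to treatment-coded dummies.  Returns
    the per-covariate summary (HR, 95% CI, p).  Zero events is an error;
    lifelines convergence warnings surface as flags.
    """
    df = validate_survival_table(table.dropna(subset=list(covariates)))
    if df["event"].sum() == 0:
        raise ValueError("no events: Cox model undefined")
    model_df = df[["time", "event", *covariates]].copy()
    cat_present = [c for c in categorical if c in covariates]
    if cat_present:
        model_df = pd.get_dummies(
            model_df, columns=cat_present, drop_first=True, dtype=float
        )
    n_params = model_df.shape[1] - 2
    if int(df["event"].sum()) <= n_params:
        raise ValueError("more parameters than events")
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col="time", event_col="event")
    summary = cph.summary[
        ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_lower",
            "exp(coef) upper 95%": "hr_upper",
        }
    )
    return summary


@dataclass
class SplitValidationResult:
    """Summary of the repeated discovery/validation split procedure."""

    fraction_significant: float
    n_significant: int
    n_valid_splits: int
    n_skipped: int
    p_mean: float
    p_sd: float
    p_ci_low: float
    p_ci_high: float
    p_values: np.ndarray = field(repr=False)


def repeated_split_validation(
    table: pd.DataFrame,
    variable: str,
    n_splits: int = 100,
    seed: Optional[int] = None,
    min_prop: float = 0.1,
    alpha: float = 0.05,
) -> SplitValidationResult:
    """Repeated 1:1 discovery/validation splitting.

    Per split: find the maximally selected log-rank threshold on the
    discovery half, dichotomize the validation half with it, and record the
    validation log-rank p.  Splits where the threshold search fails or where
    the dichotomized validation groups are degenerate (an empty side or no
    events on one side) are skipped and counted.  Reports the fraction of
    valid splits with p < alpha plus the mean/SD/95% CI of validation p
    values.
    """
    df = validate_survival_table(table.dropna(subset=[variable])).reset_index(drop=True)
    if len(df) < 40:
        raise ValueError("repeated-split validation needs >= 40 subjects")
    rng = np.random.default_rng(seed)
    n = len(df)
    pvals = []
    n_skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        disc_idx, val_idx = perm[: n // 2], perm[n // 2:]
        disc = df.iloc[disc_idx]
        val = df.iloc[val_idx]
        try:
            cut = optimal_cutpoint(disc, variable, min_prop=min_prop)
        except ValueError:
            n_skipped += 1
            continue
        high = val[variable].to_numpy(float) > cut.threshold
        ev = val["event"].to_numpy(float)
        if high.all() or (~high).all() or ev[high].sum() == 0 or ev[~high].sum() == 0:
            n_skipped += 1
            continue
        _, p = logrank_chi2(val["time"].to_numpy(float), ev, high)
        pvals.append(p)

    pvals = np.asarray(pvals)
    n_valid = len(pvals)
    if n_valid == 0:
        raise ValueError("all splits were degenerate")
    mean = float(pvals.mean())
    sd = float(pvals.std(ddof=1)) if n_valid > 1 else 0.0
    half = 1.96 * sd / np.sqrt(n_valid) if n_valid > 1 else 0.0
    n_sig = int(np.sum(pvals < alpha))
    return SplitValidationResult(
        fraction_significant=n_sig / n_valid,
        n_significant=n_sig,
        n_valid_splits=n_valid,
        n_skipped=n_skipped,
        p_mean=mean,
        p_sd=sd,
        p_ci_low=mean - half,
        p_ci_high=mean + half,
        p_values=pvals,
    )
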