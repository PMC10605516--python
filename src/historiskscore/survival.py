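"""Prognostic evaluation: Kaplan-Meier, log-rank, Cox PH, discrimination.

Wraps the standard survival toolchain (lifelines, scikit-survival)
behind the interfaces the scoring pipeline needs: per-group
Kaplan-Meier curves with median survival, the log-rank test, uni- and
multivariate Cox proportional-hazards fits with Wald statistics,
AIC/BIC and variance-inflation factors, Harrell's concordance index and
the time-dependent (cumulative/dynamic, IPCW-weighted) AUROC at a fixed
horizon — by default the fifth follow-up year (60 months).

Follow-up times are in months throughout.  Censoring follows the
censored-at-last-contact convention (event = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "KMEstimate",
    "HazardFit",
    "km_estimate",
    "logrank",
    "cox_fit",
    "vif",
    "time_dependent_auroc",
    "c_index",
]

DEFAULT_HORIZON_MONTHS = 60.0


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN when S(t) never drops to 0.5
    n: int
    n_events: int


@dataclass(frozen=True)
class HazardFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate with columns ``hr``,
    ``ci_low``, ``ci_high``, ``z``, ``p``; ``vif`` is indexed the same
    way (NaN for single-covariate models).
    """

    summary: pd.DataFrame
    aic: float
    bic: float
    vif: pd.Series
    n: int
    n_events: int
    log_likelihood: float


def km_estimate(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> dict[str, KMEstimate]:
    """Kaplan-Meier curve and median survival per group.

    The median is the earliest time at which the survival estimate drops
    to 0.5 or below; NaN when never reached.  With no events at all the
    estimate is identically 1 and every median is NaN.  Empty groups are
    omitted with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    groups = np.asarray(groups)
    if (time < 0).any():
        raise ValueError("negative follow-up times")
    out: dict[str, KMEstimate] = {}
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            warnings.warn(f"group {g!r} has no cases; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        med = float(kmf.median_survival_time_)
        out[str(g)] = KMEstimate(
            group=str(g),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            median=med if np.isfinite(med) else float("nan"),
            n=int(m.sum()),
            n_events=int(event[m].sum()),
        )
    return out


def logrank(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Two-sided log-rank test across 2+ groups -> (chi-square, p)."""
    groups = np.asarray(groups)
    if pd.unique(groups).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(time, float), groups, np.asarray(event))
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> HazardFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Categorical/string covariates are dummy-coded against their first
    level.  AIC is the partial-likelihood AIC; BIC uses the number of
    events as the effective sample size, the usual convention for the
    partial likelihood.  VIFs are computed on the design matrix when it
    has two or more columns.

    Raises a diagnostic error when the fit does not converge (e.g.
    complete separation or too few events).
    """
    if covariates is None:
        covariates = [
            c for c in data.columns if c not in (duration_col, event_col, "case_id")
        ]
    cov_df = data[covariates].copy()
    for c in cov_df.columns:
        if cov_df[c].dtype == object:
            levels = sorted(cov_df[c].dropna().unique())
            # low/high risk groups: keep "low" as the reference level
            if set(levels) == {"low", "high"}:
                levels = ["low", "high"]
            cov_df[c] = pd.Categorical(cov_df[c], categories=levels)
    design = pd.get_dummies(cov_df, drop_first=True, dtype=float)
    df = pd.concat([data[[duration_col, event_col]].reset_index(drop=True),
                    design.reset_index(drop=True)], axis=1)
    n_events = int(df[event_col].sum())
    k = design.shape[1]
    if n_events < k:
        raise ValueError(
            f"only {n_events} events for {k} coefficients; fit is unidentifiable"
        )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(
            f"Cox model failed to converge ({exc}); check for separation "
            "or collinear covariates"
        ) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "z": s["z"],
            "p": s["p"],
        }
    )
    ll = float(cph.log_likelihood_)
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * np.log(max(n_events, 1))
    if k >= 2:
        vifs = vif(design.to_numpy())
        vif_series = pd.Series(vifs, index=design.columns)
    else:
        vif_series = pd.Series(np.nan, index=design.columns)
    return HazardFit(
        summary=summary,
        aic=aic,
        bic=bic,
        vif=vif_series,
        n=len(df),
        n_events=n_events,
        log_likelihood=ll,
    )


def vif(covariate_matrix: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from regressing
    column j on the remaining columns plus an intercept.  A perfectly
    collinear column yields ``inf``.
    """
    X = np.asarray(covariate_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 covariates")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than covariates")
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        out[j] = np.inf if (1 - r2) < 1e-12 else 1.0 / (1.0 - r2)
    return out


def time_dependent_auroc(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = DEFAULT_HORIZON_MONTHS,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Cumulative/dynamic AUROC at a fixed horizon with IPCW weights.

    Cases are subjects with an observed event at or before ``horizon``;
    controls are subjects still at risk beyond it; censoring is handled
    by inverse-probability-of-censoring weights.  Returns ``(auc, se)``;
    the standard error is estimated by a case bootstrap when
    ``n_bootstrap > 0``, else ``None``.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not (event & (time <= horizon)).any():
        raise ValueError(f"no events at or before horizon {horizon}")
    if horizon >= time.max():
        raise ValueError(
            f"horizon {horizon} is beyond the last observed time {time.max()}"
        )
    y = Surv.from_arrays(event=event, time=time)
    auc_vals, _ = cumulative_dynamic_auc(y, y, scores, [horizon])
    auc = float(auc_vals[0])
    se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = len(scores)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            t_b, e_b, s_b = time[idx], event[idx], scores[idx]
            if not (e_b & (t_b <= horizon)).any() or horizon >= t_b.max():
                continue
            y_b = Surv.from_arrays(event=e_b, time=t_b)
            try:
                v, _ = cumulative_dynamic_auc(y_b, y_b, s_b, [horizon])
            except ValueError:
                continue
            boots.append(float(v[0]))
        if len(boots) >= 2:
            se = float(np.std(boots, ddof=1))
    return auc, se


def c_index(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index of a risk score.

    Fraction of comparable case pairs in which the higher-scored case
    fails earlier; tied scores count 0.5.  Raises when no pair is
    comparable (e.g. no events).
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if event.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    # lifelines orients concordance toward higher prediction = longer
    # survival, so negate the risk score
    return float(concordance_index(time, -scores, event))
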