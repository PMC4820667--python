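"""Outcome analysis by SRS group.

Kaplan-Meier curves with Greenwood variance and log-log confidence
intervals, the two-group log-rank test, Cox proportional hazards with
Efron tie handling (via lifelines, plus an own-score statistic at beta=0
whose chi-square equals the log-rank statistic for a binary covariate
without ties), fixed-horizon mortality with exact binomial intervals, and
a covariate comparison table (Welch t for continuous columns, chi-square
or Fisher for categoricals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = ["KmCurve", "CoxResult", "km_estimate", "logrank_test", "cox_fit",
           "cox_score_statistic", "mortality_at", "compare_covariates"]

log = logging.getLogger(__name__)


@dataclass
class KmCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects: int
    n_events: int

    def at(self, t: float) -> float:
        """Step-function value of the survival estimate at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "greenwood_var": self.variance,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def km_estimate(time, event, group=None) -> dict:
    """Product-limit survival estimate per group with 95% log-log CIs."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    groups = np.asarray(group) if group is not None else np.array(["all"] * len(time))
    out = {}
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"group {g} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], alpha=0.05)
        tab = kmf.survival_function_.join(kmf.confidence_interval_)
        t = tab.index.to_numpy(float)
        s = tab.iloc[:, 0].to_numpy(float)
        lo = tab.iloc[:, 1].to_numpy(float)
        hi = tab.iloc[:, 2].to_numpy(float)
        # Greenwood variance reconstructed from the at-risk table
        ev = kmf.event_table
        with np.errstate(divide="ignore", invalid="ignore"):
            term = ev["observed"] / (ev["at_risk"] * (ev["at_risk"] - ev["observed"]))
        gw = (s ** 2) * np.cumsum(np.nan_to_num(term.to_numpy(float)))
        out[str(g)] = KmCurve(str(g), t, s, gw, lo, hi,
                              int(m.sum()), int(event[m].sum()))
    return out


def logrank_test(time, event, group) -> tuple:
    """Standard two-group O-E log-rank chi-square (1 df) and p-value."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = pd.unique(np.asarray(group))
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed")
    m = np.asarray(group) == groups[0]
    res = _ll_logrank(time[m], time[~m], event[m], event[~m])
    return float(res.test_statistic), float(res.p_value)


def cox_score_statistic(time, event, x) -> float:
    """Partial-likelihood score chi-square at beta=0 for one covariate.

    With Breslow handling of ties this equals the log-rank chi-square for
    a binary covariate (exactly so when event times are distinct).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    order = np.argsort(time, kind="mergesort")
    t_s, e_s, x_s = time[order], event[order], x[order]
    U = 0.0
    I = 0.0
    for et in np.unique(t_s[e_s == 1]):
        at_risk = t_s >= et
        d = int(np.sum((t_s == et) & (e_s == 1)))
        xr = x_s[at_risk]
        xbar = xr.mean()
        U += x_s[(t_s == et) & (e_s == 1)].sum() - d * xbar
        n_r = int(at_risk.sum())
        if n_r > 1:
            # hypergeometric variance; reduces to the log-rank variance term
            I += d * (n_r - d) / (n_r - 1) * np.sum((xr - xbar) ** 2) / n_r
    if I <= 0:
        return 0.0
    return float(U ** 2 / I)


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    score_p: float
    n_events: int
    n_subjects: int
    covariate: str
    converged: bool = True
    monotone_flag: bool = False

    def summary(self) -> str:
        ci = (f"{self.ci_low:.2f}-{self.ci_high:.2f}"
              if np.isfinite(self.ci_high) else f">{self.ci_low:.2f}")
        s = (f"Cox PH ({self.covariate}): HR {self.hr:.2f}, 95% CI {ci}, "
             f"Wald p={self.wald_p:.3g}, score p={self.score_p:.3g}, "
             f"{self.n_events}/{self.n_subjects} events")
        if self.monotone_flag:
            s += " [monotone likelihood: CI unbounded]"
        return s


def cox_fit(time, event, covariates: pd.DataFrame,
            covariate_of_interest: str | None = None) -> CoxResult:
    """Cox proportional hazards with Efron tie correction.

    The model is fitted on all covariate columns; the reported HR is for
    ``covariate_of_interest`` (default: first column). A group with no
    events produces a monotone partial likelihood; the fit is flagged and
    the CI reported as unbounded on the affected side.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    X = covariates.copy()
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate column(s): {const}")
    name = covariate_of_interest or X.columns[0]
    df = X.astype(float)
    df["time"] = time
    df["event"] = event

    monotone = False
    x = X[name].to_numpy(float)
    if X.shape[1] == 1 and set(np.unique(x)) <= {0.0, 1.0}:
        per_group_events = [event[x == v].sum() for v in (0.0, 1.0)]
        monotone = any(e == 0 for e in per_group_events)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event", show_progress=False)
    row = cph.summary.loc[name]
    log_hr = float(row["coef"])
    se = float(row["se(coef)"])
    score_chi2 = cox_score_statistic(time, event, x) if X.shape[1] == 1 else np.nan
    score_p = float(stats.chi2.sf(score_chi2, 1)) if np.isfinite(score_chi2) else np.nan
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(log_hr - 1.96 * se))
        ci_high = float(np.exp(log_hr + 1.96 * se))
    if monotone:
        log.warning("monotone partial likelihood (a group has no events); "
                    "Wald CI unreliable")
        if log_hr > 0:
            ci_high = np.inf
        else:
            ci_low = 0.0
    return CoxResult(
        log_hr=log_hr, hr=float(np.exp(log_hr)), ci_low=ci_low, ci_high=ci_high,
        wald_p=float(row["p"]), score_p=score_p,
        n_events=int(event.sum()), n_subjects=len(time),
        covariate=name, monotone_flag=monotone,
    )


def mortality_at(time, event, group, horizon_days: float,
                 complete_followup: bool = True) -> pd.DataFrame:
    """Deaths by the horizon per group, with exact (Clopper-Pearson) 95% CI.

    With administratively complete follow-up this is the raw proportion of
    subjects dying at or before the horizon; otherwise the KM estimate of
    1 - S(horizon) is substituted and flagged in the ``method`` column.
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(group)
    censored_early = (event == 0) & (time < horizon_days)
    use_km = (not complete_followup) or bool(censored_early.any())
    rows = []
    for g in pd.unique(groups):
        m = groups == g
        n = int(m.sum())
        deaths = int(((time <= horizon_days) & (event == 1) & m).sum())
        if use_km:
            curve = km_estimate(time[m], event[m])["all"]
            prop = 1.0 - curve.at(horizon_days)
            method = "kaplan-meier"
            lo, hi = np.nan, np.nan
        else:
            prop = deaths / n
            method = "binomial"
            ci = stats.binomtest(deaths, n).proportion_ci(0.95, method="exact")
            lo, hi = float(ci.low), float(ci.high)
        rows.append((g, n, deaths, prop, lo, hi, method))
    return pd.DataFrame(rows, columns=["group", "n", "deaths", "proportion",
                                       "ci_low", "ci_high", "method"])


def compare_covariates(metadata: pd.DataFrame, group: pd.Series,
                       categorical_max_levels: int = 6) -> pd.DataFrame:
    """Table-style two-group covariate comparison.

    Continuous columns: Welch t test, reported as mean (SD) per group.
    Categorical columns (few levels): chi-square, switching to Fisher for
    2x2 tables with any expected count below 5. Constant columns are
    skipped with a note.
    """
    groups = pd.unique(group)
    if len(groups) != 2:
        raise ValueError("comparison requires exactly 2 groups")
    g1, g2 = sorted(map(str, groups))
    gser = group.astype(str)
    rows = []
    for col in metadata.columns:
        s = metadata[col]
        if s.nunique(dropna=True) <= 1:
            rows.append((col, "skipped (constant)", "", "", np.nan))
            continue
        is_cat = (not pd.api.types.is_numeric_dtype(s)) or \
            s.nunique(dropna=True) <= min(categorical_max_levels, 2)
        a = s[gser == g1].dropna()
        b = s[gser == g2].dropna()
        if not is_cat:
            tstat, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append((col, "welch-t",
                         f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                         f"{b.mean():.2f} ({b.std(ddof=1):.2f})", float(p)))
        else:
            tab = pd.crosstab(gser, s)
            expected = stats.contingency.expected_freq(tab.to_numpy())
            if tab.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(tab.to_numpy())
                test = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(tab.to_numpy())
                test = "chi-square"
            fmt = lambda x: "; ".join(f"{k}:{v}" for k, v in x.value_counts().items())
            rows.append((col, test, fmt(a), fmt(b), float(p)))
    return pd.DataFrame(rows, columns=["covariate", "test", g1, g2, "p"])
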