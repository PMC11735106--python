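"""Survival comparisons over signature / co-loss groups.

Kaplan-Meier product-limit curves per group, the log-rank test across
groups, and Cox proportional-hazards fits (univariable or adjusted for
clinical covariates) with Efron tie handling by default. Estimation is
delegated to lifelines; results are repackaged into small containers with
Wald 95% confidence intervals computed at z = 1.959964.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2 as chi2_dist

from .io import SiglossError

Z95 = 1.959964


@dataclass
class SurvivalCurve:
    group: str
    event_times: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)
    at_risk: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
        })


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxResult:
    """Per-covariate Cox summary: index = covariate, columns beta/se/hr/ci/p."""

    summary: pd.DataFrame
    ties_method: str = "efron"
    n: int = 0
    n_events: int = 0

    def hr(self, covariate: str | None = None) -> float:
        cov = covariate or self.summary.index[0]
        return float(self.summary.loc[cov, "hr"])

    def ci(self, covariate: str | None = None) -> tuple[float, float]:
        cov = covariate or self.summary.index[0]
        return (float(self.summary.loc[cov, "ci_low"]),
                float(self.summary.loc[cov, "ci_high"]))


def _check_clinical(clinical: pd.DataFrame) -> None:
    if (clinical["time"] <= 0).any():
        raise SiglossError("survival times must be positive")
    if not clinical["event"].isin([0, 1]).all():
        raise SiglossError("event indicator must be 0/1")


def km_fit(clinical: pd.DataFrame, group_labels: pd.Series) -> dict[str, SurvivalCurve]:
    """Product-limit survival curve per group label."""
    _check_clinical(clinical)
    group_labels = group_labels.reindex(clinical.index)
    if group_labels.isna().any():
        raise SiglossError("group labels missing for some clinical samples")
    curves: dict[str, SurvivalCurve] = {}
    for g, sub in clinical.groupby(group_labels):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table[kmf.event_table.index > 0]
        times = tab.index.to_numpy(float)
        surv = kmf.survival_function_at_times(times).to_numpy()
        curves[str(g)] = SurvivalCurve(
            group=str(g), event_times=times, survival=surv,
            at_risk=tab["at_risk"].to_numpy(), events=tab["observed"].to_numpy(),
        )
    return curves


def logrank(clinical: pd.DataFrame, group_labels: pd.Series) -> LogRankResult:
    """Log-rank test of equal hazards across the label groups."""
    _check_clinical(clinical)
    group_labels = group_labels.reindex(clinical.index)
    groups = pd.unique(group_labels.dropna())
    if len(groups) < 2:
        raise SiglossError("log-rank test needs at least 2 groups")
    if clinical["event"].sum() < 1:
        raise SiglossError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(clinical["time"], group_labels, clinical["event"])
    df = len(groups) - 1
    chi2 = float(res.test_statistic)
    return LogRankResult(chi2=chi2, df=df, p=float(chi2_dist.sf(chi2, df)))


def cox_fit(clinical: pd.DataFrame, covariates: list[str],
            ties_method: str = "efron",
            categorical: list[str] | None = None) -> CoxResult:
    """Cox proportional-hazards fit on the named covariate columns.

    Categorical covariates are dummy-coded against their first (sorted)
    level as reference. Rows with missing covariates are dropped with their
    count noted in the error-free path (mirrors complete-case analysis).
    """
    _check_clinical(clinical)
    if ties_method not in ("efron", "breslow"):
        raise SiglossError(f"unknown ties method {ties_method!r}")
    missing = [c for c in covariates if c not in clinical.columns]
    if missing:
        raise SiglossError(f"covariates absent from clinical table: {missing}")
    df = clinical[["time", "event", *covariates]].dropna()
    if df["event"].sum() < 1:
        raise SiglossError("Cox fit needs at least 1 event")
    categorical = list(categorical or [])
    categorical += [c for c in covariates
                    if df[c].dtype == object and c not in categorical]
    if categorical:
        df = pd.get_dummies(df, columns=categorical, drop_first=True, dtype=float)
    design_cols = [c for c in df.columns if c not in ("time", "event")]
    for c in design_cols:
        if df[c].nunique() <= 1:
            raise SiglossError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise SiglossError(f"Cox model failed to converge: {err}") from err
    beta = cph.params_
    se = cph.standard_errors_
    summary = pd.DataFrame({
        "beta": beta,
        "se": se,
        "hr": np.exp(beta),
        "ci_low": np.exp(beta - Z95 * se),
        "ci_high": np.exp(beta + Z95 * se),
        "p": cph.summary["p"],
    })
    return CoxResult(summary=summary, ties_method=ties_method,
                     n=len(df), n_events=int(df["event"].sum()))


def cox_fit_groups(clinical: pd.DataFrame, group_labels: pd.Series,
                   reference: str | None = None,
                   adjust: list[str] | None = None, **kwargs) -> CoxResult:
    """Cox fit with group labels as indicator covariates against a reference.

    The reference level defaults to the lexicographically first label (use
    ``reference='neither'`` etc. for co-loss contrasts); optional ``adjust``
    columns enter as additional covariates.
    """
    group_labels = group_labels.reindex(clinical.index)
    levels = sorted(pd.unique(group_labels.dropna().astype(str)))
    if len(levels) < 2:
        raise SiglossError("need at least 2 group levels for a Cox contrast")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise SiglossError(f"reference level {ref!r} not among group labels {levels}")
    df = clinical.copy()
    for lvl in levels:
        if lvl != ref:
            df[f"group_{lvl}"] = (group_labels.astype(str) == lvl).astype(float)
    covs = [f"group_{lvl}" for lvl in levels if lvl != ref] + list(adjust or [])
    return cox_fit(df, covs, **kwargs)
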