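"""Survival analysis of score-defined expression groups.

Kaplan-Meier product-limit curves with Greenwood standard errors, log-rank
comparisons (Bonferroni-corrected pairwise p-values for three or more
groups), and hazard ratios (high group / low group) from a single
binary-covariate Cox proportional-hazards fit with Efron tie handling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .io_formats import ClinicalTable, ValidationError, logger
from .scoring import ScoreTable


@dataclass
class SurvivalTable:
    """Right-censored time/event records with a group label per sample.

    ``time`` is days_to_death for expired samples, days_to_last_followup
    otherwise; ``event`` is 1 for expired, 0 for living (censored).
    """

    data: pd.DataFrame  # index sample_id; columns time, event, group

    def __post_init__(self) -> None:
        d = self.data
        if (d["time"] < 0).any():
            raise ValidationError("survival times must be non-negative")
        if not d["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0/1")
        if d["group"].isna().any():
            raise ValidationError("every sample needs a group label")

    def subset(self, groups: list[str]) -> "SurvivalTable":
        return SurvivalTable(self.data[self.data["group"].isin(groups)])


@dataclass(frozen=True)
class HazardResult:
    """high/low hazard ratio with Wald 95% CI and log-rank p."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n_high: int
    n_low: int
    unbounded_ci: bool = False


def build_survival_table(clinical: ClinicalTable, scores: ScoreTable,
                         score: str = "ip", k: int = 2,
                         exclude: dict[str, list[str]] | None = None) -> SurvivalTable:
    """Join clinical follow-up with stratification labels.

    ``exclude`` maps a clinical label name to values removed before analysis
    (e.g. ``{"FAB": ["M3"]}`` to drop acute promyelocytic leukemia, which is
    treated with a different regimen).
    """
    group = scores.group(score, k)
    df = clinical.to_frame()
    shared = [s for s in df.index if s in group.index]
    if not shared:
        raise ValidationError("clinical table and score table share no samples")
    df = df.loc[shared]
    n0 = len(df)
    for label, values in (exclude or {}).items():
        if label not in df.columns:
            raise ValidationError(f"exclusion label {label!r} absent from clinical table")
        df = df[~df[label].isin(values)]
        logger.info("build_survival_table: excluded %s in %s -> %d of %d rows remain",
                    values, label, len(df), n0)
    expired = df["vital_status"] == "expired"
    bad = expired & df["days_to_death"].isna()
    if bad.any():
        logger.warning("build_survival_table: dropping %d expired records without "
                       "days_to_death: %s", int(bad.sum()), list(df.index[bad]))
        df = df[~bad]
        expired = df["vital_status"] == "expired"
    time = df["days_to_death"].where(expired, df["days_to_last_followup"])
    out = pd.DataFrame(
        {"time": time.astype(float), "event": expired.astype(int),
         "group": group.reindex(df.index)}
    )
    return SurvivalTable(out)


def km_estimate(surv: SurvivalTable, group: str) -> "KMResult":
    """Product-limit survival curve for one group, with Greenwood SE queries."""
    sub = surv.data[surv.data["group"] == group]
    if sub.empty:
        raise ValidationError(f"group {group!r} is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], sub["event"], label=str(group))
    all_censored = sub["event"].sum() == 0
    if all_censored:
        logger.warning("km_estimate: group %s has no events; S(t)=1 everywhere", group)
    return KMResult(kmf=kmf, all_censored=bool(all_censored))


@dataclass
class KMResult:
    kmf: KaplanMeierFitter
    all_censored: bool

    def survival_at(self, t: float) -> float:
        return float(self.kmf.survival_function_at_times(t).iloc[0])

    def greenwood_se_at(self, t: float) -> float:
        """Greenwood standard error of S(t): S(t) * sqrt(sum d/(n(n-d)))."""
        tab = self.kmf.event_table
        ev = tab[(tab.index <= t) & (tab["observed"] > 0)]
        with np.errstate(divide="ignore"):
            var_sum = (ev["observed"] /
                       (ev["at_risk"] * (ev["at_risk"] - ev["observed"]))).sum()
        return float(self.survival_at(t) * np.sqrt(var_sum))

    @property
    def step_function(self) -> pd.DataFrame:
        return self.kmf.survival_function_.rename(
            columns=lambda _: "survival").rename_axis("time")


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float] | None  # Bonferroni-corrected


def logrank(surv: SurvivalTable) -> LogrankResult:
    """Log-rank test over all groups; pairwise Bonferroni p-values for >= 3."""
    d = surv.data
    groups = sorted(d["group"].unique())
    if len(groups) < 2:
        raise ValidationError("logrank needs >= 2 non-empty groups")
    for g in groups:
        if d.loc[d["group"] == g, "time"].sum() == 0:
            raise ValidationError(f"group {g!r} has zero at-risk time")
    res = multivariate_logrank_test(d["time"], d["group"], d["event"])
    pairwise = None
    if len(groups) > 2:
        m = len(groups) * (len(groups) - 1) // 2
        pairwise = {}
        for a, b in itertools.combinations(groups, 2):
            sub = d[d["group"].isin([a, b])]
            r = multivariate_logrank_test(sub["time"], sub["group"], sub["event"])
            pairwise[(a, b)] = min(1.0, r.p_value * m)
    return LogrankResult(float(res.test_statistic), float(res.p_value), pairwise)


def cox_hr(surv: SurvivalTable, reference: str = "low",
           comparison: str = "high") -> HazardResult:
    """Hazard ratio comparison/reference from a binary-covariate Cox model.

    Mid groups (3-group stratification) are excluded.  Complete separation
    is reported with an ``unbounded_ci`` flag rather than raised.
    """
    d = surv.data[surv.data["group"].isin([reference, comparison])].copy()
    d["x"] = (d["group"] == comparison).astype(float)
    n_high = int((d["x"] == 1).sum())
    n_low = int((d["x"] == 0).sum())
    for name, n in ((reference, n_low), (comparison, n_high)):
        if d.loc[d["group"] == name, "event"].sum() < 1:
            raise ValidationError(f"group {name!r} has no events")
    lr = logrank(SurvivalTable(d[["time", "event", "group"]]))
    cph = CoxPHFitter()
    fit_df = d[["time", "event", "x"]]
    unbounded = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
        coef = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        if not np.isfinite(se) or se > 50:
            unbounded = True
    except ConvergenceError:
        # complete separation: report the direction with an unbounded CI
        logger.warning("cox_hr: Cox fit did not converge (separation?); flagged")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="time", event_col="event",
                        fit_options={"step_size": 0.1, "max_steps": 20})
            coef = float(cph.params_["x"])
        except Exception:
            # fall back to the crude event-rate ratio for the direction
            rate = d.groupby("x").apply(
                lambda g: g["event"].sum() / max(g["time"].sum(), 1e-12))
            coef = float(np.log(max(rate.get(1.0, 1e-12), 1e-12) /
                                max(rate.get(0.0, 1e-12), 1e-12)))
        se = np.inf
        unbounded = True
    hr = float(np.exp(coef))
    z = 1.959963984540054  # Phi^-1(0.975)
    if unbounded or not np.isfinite(se):
        ci_low, ci_high = 0.0, np.inf
    else:
        ci_low = float(np.exp(coef - z * se))
        ci_high = float(np.exp(coef + z * se))
    return HazardResult(hazard_ratio=hr, ci_low=ci_low, ci_high=ci_high,
                        logrank_p=lr.p_value, n_high=n_high, n_low=n_low,
                        unbounded_ci=unbounded)
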