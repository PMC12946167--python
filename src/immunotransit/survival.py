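"""Signature-survival association: median-split Cox model and Kaplan-Meier.

The composite signature score (high vs low by median split) enters an
age-adjusted Cox proportional-hazards regression of overall survival; the
proportional-hazards assumption is checked with the Schoenfeld residuals
test.  Group-level survival is summarized by Kaplan-Meier medians with a
two-sided log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from lifelines.utils import median_survival_times

from .errors import AnalysisError

__all__ = ["CoxResult", "cox_age_adjusted", "km_logrank", "KMResult"]

logger = logging.getLogger(__name__)


@dataclass
class CoxResult:
    """Hazard ratio for high vs low signature activity, age adjusted."""

    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    log_hr: float
    log_hr_se: float
    schoenfeld_p: dict[str, float]
    penalized: bool
    model: CoxPHFitter

    def summary(self) -> str:
        lines = [
            "Age-adjusted Cox proportional-hazards model (high vs low signature)",
            f"  HR = {self.hr:.3f}  (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}),"
            f"  two-sided Wald p = {self.wald_p:.3g}",
            "  Schoenfeld residuals test (proportional hazards):",
        ]
        for cov, p in self.schoenfeld_p.items():
            lines.append(f"    {cov}: p = {p:.3g}")
        if self.penalized:
            lines.append("  note: penalized fit (complete separation fallback)")
        return "\n".join(lines)


def cox_age_adjusted(
    survival: pd.DataFrame,
    score_groups: pd.Series,
    extra_covariates: tuple[str, ...] = ("age",),
) -> CoxResult:
    """Cox regression of OS on the binary score group plus covariates.

    ``survival`` needs columns patient, os_months, event, plus the extra
    covariates; ``score_groups`` maps patient to "high"/"low".  If all events
    fall in one group (complete separation), a ridge-penalized fit is used
    and flagged.
    """
    df = survival.set_index("patient").loc[score_groups.index].copy()
    df["high"] = (score_groups == "high").astype(float)
    cols = ["os_months", "event", "high", *extra_covariates]
    df = df[cols].astype(float)
    if df["high"].nunique() < 2:
        raise AnalysisError("score group is constant; hazard ratio undefined")
    for cov in list(extra_covariates):
        if df[cov].nunique() < 2:
            logger.warning("dropping constant covariate %r", cov)
            df = df.drop(columns=[cov])
    if df["event"].sum() == 0:
        raise AnalysisError("no events observed; Cox model undefined")
    events_by_group = df.groupby("high")["event"].sum()
    penalized = len(events_by_group) == 2 and bool((events_by_group == 0).any())
    if penalized:
        logger.warning("all events in one score group; using penalized Cox fit")
    cph = CoxPHFitter(penalizer=0.1 if penalized else 0.0)
    cph.fit(df, duration_col="os_months", event_col="event")
    row = cph.summary.loc["high"]
    try:
        ph = proportional_hazard_test(cph, df, time_transform="km")
        schoenfeld = {str(k): float(v) for k, v in ph.summary["p"].items()}
    except Exception as exc:  # small-n degeneracies
        logger.warning("Schoenfeld test failed: %s", exc)
        schoenfeld = {}
    return CoxResult(
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        wald_p=float(row["p"]),
        log_hr=float(row["coef"]),
        log_hr_se=float(row["se(coef)"]),
        schoenfeld_p=schoenfeld,
        penalized=penalized,
        model=cph,
    )


@dataclass
class KMResult:
    """Kaplan-Meier medians (with 95% CIs) per group and the log-rank p."""

    medians: pd.DataFrame  # group, median, ci_low, ci_high, n, events
    logrank_p: float

    def summary(self) -> str:
        out = ["Kaplan-Meier survival by group (log-rank p = %.3g)" % self.logrank_p]
        for _, r in self.medians.iterrows():
            med = "not reached" if np.isinf(r["median"]) else f"{r['median']:.2f} mo"
            out.append(
                f"  {r['group']}: median {med} (n={int(r['n'])}, events={int(r['events'])})"
            )
        return "\n".join(out)


def km_logrank(survival: pd.DataFrame, groups: pd.Series) -> KMResult:
    """Product-limit median survival per group and a two-sided log-rank test.

    Groups with no events have an undefined median, reported as infinity
    ("not reached").
    """
    df = survival.set_index("patient").loc[groups.index]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise AnalysisError("log-rank comparison needs >= 2 groups")
    rows = []
    for lab in labels:
        sel = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[sel.values, "os_months"], df.loc[sel.values, "event"])
        med = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = (float(v) for v in np.asarray(ci).ravel()[:2])
        rows.append(
            {
                "group": lab,
                "median": med,
                "ci_low": lo,
                "ci_high": hi,
                "n": int(sel.sum()),
                "events": int(df.loc[sel.values, "event"].sum()),
            }
        )
    lr = multivariate_logrank_test(
        df["os_months"], groups.values, df["event"]
    )
    return KMResult(medians=pd.DataFrame(rows), logrank_p=float(lr.p_value))
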