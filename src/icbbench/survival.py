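"""Kaplan-Meier estimation, log-rank comparison, and median-split survival.

The survival workflow mirrors the benchmark's clinical-efficacy analysis:
patients contributing more than one sample are excluded entirely, each
biomarker's scores dichotomize the cohort at the median (median-tied
samples joining the smaller strict group, the same rule the response
analysis uses), and the high and low groups are compared with a log-rank
test on OS or PFS.  Landmark survival (default 24 weeks, configurable) is
reported with a Greenwood 95% CI computed on the log-survival scale.

Product-limit curves and the Mantel-Haenszel statistic are computed via
lifelines; events precede censorings at tied times (the estimator's
standard convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2, norm

from .evaluation import median_split

logger = logging.getLogger("icbbench")

#: default landmark time for survival-rate reporting, in weeks
LANDMARK_WEEKS = 24.0


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_survival: float  # nan when never reached
    landmark_time: float | None = None
    landmark_survival: float | None = None
    landmark_ci: tuple[float, float] | None = None


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int = 1


@dataclass
class SurvivalComparison:
    endpoint: str
    km_high: KMCurve | None
    km_low: KMCurve | None
    logrank: LogrankResult | None
    significant: bool | None
    degenerate: bool = False
    n_high: int = 0
    n_low: int = 0
    notes: list[str] = field(default_factory=list)


def dedupe_patients(clinical: pd.DataFrame) -> pd.DataFrame:
    """Drop every sample of any patient contributing more than one sample."""
    if "patient_id" not in clinical.columns:
        logger.warning("no patient_id column; multi-sample patients cannot be excluded")
        return clinical
    counts = clinical["patient_id"].value_counts()
    multi = counts[counts > 1].index
    if len(multi):
        logger.info("excluding %d multi-sample patients from survival analysis", len(multi))
    return clinical[~clinical["patient_id"].isin(multi)]


def km_fit(times, events, landmark_time: float | None = None) -> KMCurve:
    """Product-limit survival estimate.

    Median survival is the earliest time with S(t) <= 0.5 (NaN when never
    reached).  The landmark survival CI uses the Greenwood variance of
    log S(t): S * exp(+-1.96 * sqrt(sum d/(n(n-d)))), clipped to [0, 1].
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    below = surv[surv <= 0.5]
    median = float(below.index[0]) if len(below) else float("nan")
    lm_s = lm_ci = None
    if landmark_time is not None:
        lm_s = float(kmf.predict(landmark_time))
        ev = table[(table.index <= landmark_time) & (table["observed"] > 0)]
        n_i = ev["at_risk"].to_numpy(float)
        d_i = ev["observed"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_log = np.sum(d_i / (n_i * (n_i - d_i)))
        if lm_s > 0 and np.isfinite(var_log):
            half = norm.ppf(0.975) * np.sqrt(var_log)
            lm_ci = (
                float(np.clip(lm_s * np.exp(-half), 0.0, 1.0)),
                float(np.clip(lm_s * np.exp(half), 0.0, 1.0)),
            )
        else:
            lm_ci = (lm_s, lm_s)
    return KMCurve(
        times=surv.index.to_numpy(float),
        survival=surv.to_numpy(float),
        at_risk=table["at_risk"].to_numpy(float),
        median_survival=median,
        landmark_time=landmark_time,
        landmark_survival=lm_s,
        landmark_ci=lm_ci,
    )


def logrank_test(group_a, group_b) -> LogrankResult:
    """Mantel-Haenszel log-rank comparison of two survival samples.

    ``group_a`` / ``group_b``: (times, events) pairs.  With no events in
    either group the statistic is 0 and p = 1 (warned).
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() == 0 and eb.sum() == 0:
        logger.warning("no events in either group; log-rank p = 1")
        return LogrankResult(statistic=0.0, p=1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    return LogrankResult(statistic=stat, p=float(chi2.sf(stat, df=1)))


def biomarker_survival(
    scores,
    clinical: pd.DataFrame,
    endpoint: str = "OS",
    landmark_time: float | None = LANDMARK_WEEKS,
    alpha: float = 0.05,
) -> SurvivalComparison:
    """Median-split survival comparison for one biomarker.

    ``clinical`` must already be patient-deduplicated; ``scores`` is a
    per-sample Series aligned to it.  Returns KM fits for the high and
    low groups, the log-rank result, and a significance flag at p < alpha.
    """
    if endpoint not in ("OS", "PFS"):
        raise ValueError("endpoint must be OS or PFS")
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("pfs_time", "pfs_event")
    s = pd.Series(scores).reindex(clinical.index)
    mask = s.notna() & clinical[tcol].notna() & clinical[ecol].notna()
    sub = clinical[mask]
    s = s[mask]
    notes: list[str] = []
    if len(s) < 2 or s.nunique() < 2:
        return SurvivalComparison(endpoint, None, None, None, None,
                                  degenerate=True, notes=["no usable split"])
    groups = median_split(s.to_numpy())
    hi = groups == "high"
    if hi.all() or (~hi).all():
        return SurvivalComparison(endpoint, None, None, None, None, degenerate=True,
                                  n_high=int(hi.sum()), n_low=int((~hi).sum()),
                                  notes=["one median-split group empty"])
    t = sub[tcol].to_numpy(float)
    e = sub[ecol].to_numpy(int)
    km_hi = km_fit(t[hi], e[hi], landmark_time)
    km_lo = km_fit(t[~hi], e[~hi], landmark_time)
    lr = logrank_test((t[hi], e[hi]), (t[~hi], e[~hi]))
    return SurvivalComparison(
        endpoint=endpoint,
        km_high=km_hi,
        km_low=km_lo,
        logrank=lr,
        significant=bool(lr.p < alpha),
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
        notes=notes,
    )


def km_curves_frame(comparison: SurvivalComparison) -> pd.DataFrame:
    """KM curves of a comparison as a tidy (time, S, at_risk, group) table."""
    frames = []
    for name, km in (("high", comparison.km_high), ("low", comparison.km_low)):
        if km is None:
            continue
        frames.append(pd.DataFrame({
            "time": km.times,
            "survival": km.survival,
            "at_risk": km.at_risk,
            "group": name,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time", "survival", "at_risk", "group"])
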