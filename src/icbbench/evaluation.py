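"""Association, discrimination, and aggregation statistics.

Per (biomarker, dataset) the benchmark reports:

* a two-sided Wilcoxon rank-sum comparison of scores between responders
  and non-responders, with reported p floored at 1e-5;
* a univariate logistic regression of response on the standardized score
  (odds ratio per score SD, Wald 95% CI);
* ROC/AUC on direction-oriented scores (ties count one half);
* sensitivity/specificity with the cohort median as threshold;
* Fisher's exact association of the median split with objective response
  (only in datasets with more than 20 intention-to-treat patients).

Across datasets, per-dataset AUCs aggregate into the sample-size-weighted
Prediction Score, with a biomarker's own training datasets excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, mannwhitneyu, norm, rankdata
import statsmodels.api as sm

logger = logging.getLogger("icbbench")

#: reported Wilcoxon p-values are floored here
P_FLOOR = 1e-5
#: datasets must exceed this many patients for the ORR association test
ORR_MIN_N = 21


@dataclass
class WilcoxonResult:
    raw_p: float
    reported_p: float
    direction: int


@dataclass
class LogisticResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    separation: bool = False


@dataclass
class FisherResult:
    eligible: bool
    p: float | None = None
    table: np.ndarray | None = None


@dataclass
class EvalResult:
    biomarker_id: str
    dataset_id: str
    n_responders: int
    n_non_responders: int
    wilcoxon_p: float
    wilcoxon_raw_p: float
    wilcoxon_direction: int
    logistic_or: float
    logistic_ci: tuple[float, float]
    logistic_p: float
    separation: bool
    auc: float
    auc_raw: float
    sensitivity_at_median: float
    specificity_at_median: float


def wilcoxon_response_test(scores_r, scores_nr) -> WilcoxonResult:
    """Two-sided rank-sum test between responder and non-responder scores.

    Exact null distribution when the pooled sample is small (<= 20) and
    tie-free; otherwise a normal approximation with tie correction and a
    continuity correction applied toward zero (so groups with identical
    score distributions report p = 1).  The reported p is floored at
    ``P_FLOOR``; the raw value is retained.
    """
    x = np.asarray(scores_r, float)
    y = np.asarray(scores_nr, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    n = n1 + n2
    tie_free = len(np.unique(pooled)) == n
    if n <= 20 and tie_free:
        raw = float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        ranks = rankdata(pooled)
        u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raw = 1.0
        else:
            d = u1 - mu
            z = (d - np.sign(d) * 0.5) / np.sqrt(var)
            raw = float(min(1.0, 2.0 * norm.sf(abs(z))))
    direction = int(np.sign(np.median(x) - np.median(y)))
    return WilcoxonResult(raw_p=raw, reported_p=max(raw, P_FLOOR), direction=direction)


def logistic_association(score, labels) -> LogisticResult:
    """Univariate logistic fit of response on the standardized score.

    The covariate is scaled to unit (population) SD so the odds ratio
    reads per-SD.  Perfect separation is flagged with an infinite-OR
    sentinel instead of raising.
    """
    s = np.asarray(score, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError("score is constant; logistic fit undefined")
    z = (s - s.mean()) / sd
    s1, s0 = z[y == 1], z[y == 0]
    if s0.max() < s1.min() or s1.max() < s0.min():
        or_ = np.inf if np.median(s1) > np.median(s0) else 0.0
        return LogisticResult(or_, np.nan, np.nan, np.nan, separation=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, sm.add_constant(z)).fit(disp=0, maxiter=200)
        beta = model.params[1]
        se = model.bse[1]
        if not np.isfinite(se) or se > 1e3:
            raise RuntimeError("unstable fit")
        return LogisticResult(
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            p=float(model.pvalues[1]),
        )
    except Exception:
        or_ = np.inf if np.mean(s1) > np.mean(s0) else 0.0
        return LogisticResult(or_, np.nan, np.nan, np.nan, separation=True)


def roc_auc(score, labels, direction: int = 1) -> tuple[float, np.ndarray]:
    """AUC (concordant pairs, ties one half) on direction-oriented scores.

    Negative-direction biomarkers are negated first so every AUC reads
    'higher = more predictive in the biomarker's documented direction'.
    Also returns the empirical ROC step curve as (fpr, tpr) rows.
    """
    s = np.asarray(score, float) * direction
    y = np.asarray(labels, int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(s)
    auc = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    order = np.argsort(-s, kind="stable")
    sorted_y = y[order]
    sorted_s = s[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(1 - sorted_y)
    # collapse tied thresholds to the last index of each tie block
    keep = np.r_[sorted_s[1:] != sorted_s[:-1], True]
    points = np.column_stack([fps[keep] / n0, tps[keep] / n1])
    points = np.vstack([[0.0, 0.0], points])
    return auc, points


def prediction_score(entries) -> float:
    """Sample-size-weighted mean of per-dataset AUCs.

    ``entries``: iterables of (AUC_i, Size_i) or (AUC_i, Size_i, excluded);
    entries flagged as a biomarker's training data are dropped first.
    """
    kept = []
    for entry in entries:
        auc, size, *rest = entry
        if rest and rest[0]:
            continue
        if size <= 0:
            raise ValueError("dataset sizes must be positive")
        kept.append((float(auc), float(size)))
    if not kept:
        raise ValueError("no dataset left after training-set exclusion")
    total = sum(size for _, size in kept)
    return sum(auc * size for auc, size in kept) / total


def median_split(scores) -> np.ndarray:
    """Dichotomize at the median; median-tied samples join the smaller side.

    Strictly above the median -> 'high', strictly below -> 'low'; samples
    equal to the median join whichever strict group is smaller (ties in
    group size broken toward 'low').  All-equal scores admit no split.
    """
    s = np.asarray(scores, float)
    if len(s) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = np.median(s)
    high = s > med
    low = s < med
    at = ~(high | low)
    if not high.any() and not low.any():
        raise ValueError("all scores equal; no median split possible")
    groups = np.where(high, "high", "low")
    tie_side = "high" if high.sum() < low.sum() else "low"
    groups[at] = tie_side
    return groups


def sensitivity_specificity_at_median(score, labels, direction: int = 1) -> tuple[float, float]:
    """Sensitivity/specificity with the cohort median score as threshold.

    Predicted positives are the 'high' group of the median split on
    direction-oriented scores.
    """
    s = np.asarray(score, float) * direction
    y = np.asarray(labels, int)
    groups = median_split(s)
    pred = groups == "high"
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return sens, spec


def fisher_orr_association(score, objective_response, min_n: int = ORR_MIN_N) -> FisherResult:
    """Fisher's exact test of median-split group vs objective response.

    Only computed in datasets with more than 20 patients (``n >= min_n``);
    smaller datasets are marked ineligible.  Two-sided by the
    point-probability rule (the scipy convention).
    """
    s = np.asarray(score, float)
    y = np.asarray(objective_response, int)
    if len(s) < min_n:
        return FisherResult(eligible=False)
    groups = median_split(s)
    high = groups == "high"
    table = np.array([
        [int((high & (y == 1)).sum()), int((high & (y == 0)).sum())],
        [int((~high & (y == 1)).sum()), int((~high & (y == 0)).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate margin in ORR association table; p = 1")
        return FisherResult(eligible=True, p=1.0, table=table)
    _, p = fisher_exact(table, alternative="two-sided")
    return FisherResult(eligible=True, p=float(p), table=table)


def biomarker_correlation_clustering(scores: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlation of biomarker scores + dendrogram order.

    Correlations use shared non-missing samples per pair; constant rows
    are excluded with a warning.  Average-linkage clustering on 1 - rho.
    """
    usable = scores.dropna(how="all")
    keep = [i for i in usable.index if usable.loc[i].dropna().nunique() > 1]
    dropped = set(usable.index) - set(keep)
    if dropped:
        logger.warning("excluding constant/empty biomarkers from clustering: %s",
                       sorted(dropped))
    usable = usable.loc[keep]
    if usable.shape[0] < 2 or usable.shape[1] < 3:
        raise ValueError("clustering needs >= 2 biomarkers and >= 3 samples")
    corr = usable.T.corr(method="spearman")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [corr.index[i] for i in leaves_list(z)]
    return corr, order


def evaluate_biomarker(
    biomarker_id: str,
    dataset_id: str,
    score,
    labels,
    direction: int = 1,
) -> EvalResult:
    """All per-dataset association and discrimination statistics at once."""
    s = np.asarray(score, float)
    y = np.asarray(labels, int)
    wil = wilcoxon_response_test(s[y == 1], s[y == 0])
    logit = logistic_association(s, y)
    auc, _ = roc_auc(s, y, direction)
    auc_raw, _ = roc_auc(s, y, 1)
    sens, spec = sensitivity_specificity_at_median(s, y, direction)
    return EvalResult(
        biomarker_id=biomarker_id,
        dataset_id=dataset_id,
        n_responders=int((y == 1).sum()),
        n_non_responders=int((y == 0).sum()),
        wilcoxon_p=wil.reported_p,
        wilcoxon_raw_p=wil.raw_p,
        wilcoxon_direction=wil.direction,
        logistic_or=logit.odds_ratio,
        logistic_ci=(logit.ci_low, logit.ci_high),
        logistic_p=logit.p,
        separation=logit.separation,
        auc=auc,
        auc_raw=auc_raw,
        sensitivity_at_median=sens,
        specificity_at_median=spec,
    )
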