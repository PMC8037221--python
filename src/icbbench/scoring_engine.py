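"""Biomarker score computation.

Every score family used by the benchmark is implemented here against a
genes x samples log2(TPM+1) matrix:

* single-gene expression (PD-1, PD-L1, PD-L2, CTLA-4);
* unweighted means (CYT, gene.CD8, IFN-gamma, Expanded, EMT, CRMA, IS);
* weighted sums (T cell-inflamed GEP);
* pairwise inequality counts (IMPRES);
* single-sample gene-set enrichment, ssGSEA (APM, C-ECM-up, and the
  nine-subset TIS composite);
* GSVA-style kernel-CDF enrichment averaged over a set collection (IPRES);
* first-principal-component scores (Pan-F-TBRS);
* up-minus-down program means (IRP);
* the immunophenoscore weighted z-score scheme (IPS, 0-10 scale);
* MCP-counter marker-gene averages for 10 microenvironment populations;
* pass-through of externally precomputed columns (CIBERSORT.CD8, TIDE).

All operations are deterministic and permutation-equivariant in samples.
Scores for signatures whose genes are not fully measured are emitted as
missing (NaN) rather than computed from partial gene sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .cohort_io import Cohort, z_score_genes
from .signature_registry import (
    ConfigError,
    SignatureDefinition,
    validate_signature_coverage,
)

logger = logging.getLogger("icbbench")

#: immunophenoscore affine map: aggregate z-average <= 0 -> 0, >= IPS_AGG_CAP -> 10
IPS_AGG_CAP = 3.0
IPS_SCALE = 10.0


@dataclass
class EnrichmentParams:
    """Tunables of the rank-walk enrichment scores.

    rank_weight_exponent: exponent alpha on the rank weight of in-set genes
        in the ssGSEA walk (0.25 by default; 0 gives the unweighted KS walk).
    normalize: divide the ssGSEA integral ES by N - |set|.
    kernel_bandwidth_rule: per-gene bandwidth for the GSVA kernel CDF;
        only Silverman's rule is implemented.
    """

    rank_weight_exponent: float = 0.25
    normalize: bool = False
    kernel_bandwidth_rule: str = "gaussian_silverman"

    def __post_init__(self):
        if self.rank_weight_exponent < 0:
            raise ValueError("rank_weight_exponent must be >= 0")


# ---------------------------------------------------------------------------
# simple families
# ---------------------------------------------------------------------------

def score_single_gene(expr: pd.DataFrame, gene: str) -> pd.Series:
    """The gene's log2(TPM+1) row, as-is."""
    return expr.loc[gene].astype(float)


def score_mean_signature(expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Unweighted arithmetic mean of member-gene log-expression per sample."""
    return expr.loc[sig.genes].mean(axis=0)


def score_weighted_sum(expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """sum_g w_g * x_gs per sample."""
    if sig.weights is None or len(sig.weights) != len(sig.genes):
        raise ConfigError(f"signature {sig.id}: weights do not align with genes")
    w = np.asarray(sig.weights, float)
    sub = expr.loc[sig.genes].to_numpy(dtype=float)
    return pd.Series(w @ sub, index=expr.columns)


def score_impres(expr: pd.DataFrame, pairs) -> pd.Series:
    """Count of pairs (g1, g2) with x_g1 strictly greater than x_g2.

    Ties contribute 0, so the score is an integer in [0, n_pairs].
    """
    counts = np.zeros(expr.shape[1], dtype=int)
    for g1, g2 in pairs:
        counts += (expr.loc[g1].to_numpy() > expr.loc[g2].to_numpy()).astype(int)
    return pd.Series(counts, index=expr.columns)


def score_up_down(expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Mean gene-centered expression over up-genes minus over down-genes."""
    gs = sig.gene_sets or {}
    up, down = gs.get("up"), gs.get("down")
    if not up or not down:
        raise ConfigError(f"signature {sig.id}: up_down needs nonempty up and down lists")
    centered = expr.sub(expr.mean(axis=1), axis=0)
    return centered.loc[up].mean(axis=0) - centered.loc[down].mean(axis=0)


def score_mcp(expr: pd.DataFrame, population_markers: dict[str, list[str]]) -> pd.DataFrame:
    """MCP-counter abundances: per-population marker-gene mean on the log scale."""
    rows = {
        pop: expr.loc[markers].mean(axis=0)
        for pop, markers in population_markers.items()
    }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# rank-walk enrichment
# ---------------------------------------------------------------------------

def _descending_ranks(col: np.ndarray) -> np.ndarray:
    """Rank values with the top-expressed gene ranked N (ties -> average)."""
    return rankdata(col, method="average")


def score_ssgsea(
    expr: pd.DataFrame,
    gene_set: list[str],
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """Single-sample GSEA enrichment score (integral form).

    Per sample, genes are ordered by decreasing expression and walked top
    to bottom: an in-set gene advances the walk by its rank value raised
    to ``rank_weight_exponent`` (normalized over the set), a miss retreats
    it by 1/(N - |set|).  The ES is the sum of the walk over all steps.
    """
    params = params or EnrichmentParams()
    genes = list(expr.index)
    in_set = np.array([g in set(gene_set) for g in genes])
    if not in_set.any():
        raise ValueError("no gene of the set is present in the matrix")
    n = len(genes)
    n_out = n - int(in_set.sum())
    if n_out == 0:
        raise ValueError("gene set equals the gene universe")
    alpha = params.rank_weight_exponent
    vals = expr.to_numpy(dtype=float)
    out = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        ranks = _descending_ranks(vals[:, j])
        order = np.argsort(-ranks, kind="stable")  # walk from top-ranked down
        hits = in_set[order]
        weights = ranks[order] ** alpha
        step = np.where(hits, weights / weights[hits].sum(), -1.0 / n_out)
        es = float(np.cumsum(step).sum())
        out[j] = es / n_out if params.normalize else es
    return pd.Series(out, index=expr.columns)


def score_tis(
    expr: pd.DataFrame,
    subset_sets: dict[str, list[str]],
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """T-cell infiltration score: per-subset ssGSEA, z-scored, averaged.

    Every subset must be fully measured; otherwise the whole score is
    missing (NaN) per the coverage rule.
    """
    for name, members in subset_sets.items():
        if any(g not in expr.index for g in members):
            logger.info("TIS subset %s not fully measured; score missing", name)
            return pd.Series(np.nan, index=expr.columns)
    es = pd.DataFrame({name: score_ssgsea(expr, members, params)
                       for name, members in subset_sets.items()}).T
    z, _ = z_score_genes(es)
    return z.mean(axis=0)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    return h if h > 0 else 1e-8


def gsva_kernel_cdf(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Gaussian-kernel cumulative density across samples.

    z_gj = (1/n) sum_k Phi((x_gj - x_gk) / h_g), Silverman-rule h_g.
    Location shifts of a gene leave its statistic unchanged.
    """
    vals = expr.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for i, row in enumerate(vals):
        h = _silverman_bandwidth(row)
        out[i] = norm.cdf((row[:, None] - row[None, :]) / h).mean(axis=1)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def score_gsva_set(
    kcdf: pd.DataFrame,
    gene_set: list[str],
) -> pd.Series:
    """Max-deviation rank walk on the kernel-CDF statistic for one set.

    Per sample, genes are ranked by decreasing statistic and walked with
    linear rank weights at hits and a uniform retreat at misses; the ES is
    the walk value of largest magnitude (sign preserved).
    """
    genes = list(kcdf.index)
    in_set = np.array([g in set(gene_set) for g in genes])
    if not in_set.any():
        raise ValueError("no gene of the set is present in the matrix")
    n = len(genes)
    n_out = n - int(in_set.sum())
    if n_out == 0:
        raise ValueError("gene set equals the gene universe")
    vals = kcdf.to_numpy(dtype=float)
    out = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        ranks = _descending_ranks(vals[:, j])
        order = np.argsort(-ranks, kind="stable")
        hits = in_set[order]
        weights = ranks[order]
        step = np.where(hits, weights / weights[hits].sum(), -1.0 / n_out)
        walk = np.cumsum(step)
        out[j] = walk[np.argmax(np.abs(walk))]
    return pd.Series(out, index=kcdf.columns)


def score_gsva_mean(
    expr: pd.DataFrame,
    gene_set_collection: dict[str, list[str]],
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """GSVA over a collection of sets, averaged (the IPRES construction)."""
    params = params or EnrichmentParams()
    if expr.shape[1] < 2:
        raise ValueError("GSVA requires at least 2 samples (across-sample density)")
    if params.kernel_bandwidth_rule != "gaussian_silverman":
        raise ConfigError(f"unknown kernel rule {params.kernel_bandwidth_rule!r}")
    kcdf = gsva_kernel_cdf(expr)
    per_set = pd.DataFrame(
        {name: score_gsva_set(kcdf, members)
         for name, members in gene_set_collection.items()}
    )
    return per_set.mean(axis=1)


# ---------------------------------------------------------------------------
# PCA and IPS schemes
# ---------------------------------------------------------------------------

def score_pc1(expr: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """First principal component of the z-scored member submatrix.

    Samples are the observations.  The sign is fixed so the score
    correlates positively with the members' mean expression (a TGF-beta
    response score must increase with its response genes).
    """
    if expr.shape[1] < 3:
        raise ValueError("PC1 scoring requires at least 3 samples")
    sub = expr.loc[sig.genes]
    z, flagged = z_score_genes(sub)
    if len(flagged) == len(sig.genes):
        raise ValueError(f"signature {sig.id}: all member genes constant")
    if len(sig.genes) - len(flagged) < 2:
        raise ValueError(f"signature {sig.id}: fewer than 2 variable member genes")
    data = z.to_numpy(dtype=float).T  # samples x genes, columns centered
    u, s, _vt = np.linalg.svd(data, full_matrices=False)
    scores = u[:, 0] * s[0]
    ref = sub.mean(axis=0).to_numpy(dtype=float)
    if np.std(ref) > 0 and np.corrcoef(scores, ref)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.columns)


def score_ips(expr: pd.DataFrame, components: list[dict]) -> pd.Series:
    """Immunophenoscore: weighted z-score components mapped to [0, 10].

    Per sample, gene z-scores (across samples) are averaged within each
    component, multiplied by the component weight, averaged per category
    (MHC / EC / SC / CP), and the four category scores averaged.  The
    aggregate maps affinely to [0, 10]: 0 at <= 0, 10 at >= 3.
    """
    cats = {c["category"] for c in components}
    missing = {"MHC", "EC", "SC", "CP"} - cats
    if missing:
        raise ConfigError(f"IPS components missing categories {sorted(missing)}")
    genes: list[str] = []
    for c in components:
        genes.extend(g for g in c["genes"] if g not in genes)
    z, _ = z_score_genes(expr.loc[genes])
    cat_scores: dict[str, list[pd.Series]] = {k: [] for k in ("MHC", "EC", "SC", "CP")}
    for comp in components:
        comp_mean = z.loc[comp["genes"]].mean(axis=0)
        cat_scores[comp["category"]].append(float(comp["weight"]) * comp_mean)
    per_cat = pd.DataFrame(
        {cat: pd.concat(series, axis=1).mean(axis=1) for cat, series in cat_scores.items()}
    )
    agg = per_cat.mean(axis=1)
    return (agg.clip(lower=0.0, upper=IPS_AGG_CAP) * (IPS_SCALE / IPS_AGG_CAP))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _score_one(
    cohort: Cohort,
    sig: SignatureDefinition,
    params: EnrichmentParams,
) -> pd.Series:
    expr = cohort.expression
    if sig.method == "single_gene":
        return score_single_gene(expr, sig.genes[0])
    if sig.method in ("mean",):
        return score_mean_signature(expr, sig)
    if sig.method == "mcp":
        return score_mean_signature(expr, sig)  # marker average == mean family
    if sig.method == "weighted_sum":
        return score_weighted_sum(expr, sig)
    if sig.method == "pairwise":
        return score_impres(expr, sig.pairs).astype(float)
    if sig.method == "ssgsea":
        if sig.gene_sets:  # multi-subset composite (TIS)
            return score_tis(expr, sig.gene_sets, params)
        return score_ssgsea(expr, sig.genes, params)
    if sig.method == "gsva_mean":
        return score_gsva_mean(expr, sig.gene_sets or {"set": sig.genes}, params)
    if sig.method == "pc1":
        return score_pc1(expr, sig)
    if sig.method == "up_down":
        return score_up_down(expr, sig)
    if sig.method == "ips_scheme":
        return score_ips(expr, sig.components)
    if sig.method == "external":
        col = sig.external_column or sig.id
        if cohort.external_scores is not None and col in cohort.external_scores.columns:
            ext = cohort.external_scores[col].reindex(expr.columns)
            return ext.astype(float)
        return pd.Series(np.nan, index=expr.columns)
    raise ConfigError(f"unknown scoring method {sig.method!r} for {sig.id}")


def score_all(
    cohort: Cohort,
    registry: dict[str, SignatureDefinition],
    params: EnrichmentParams | None = None,
    coverage_threshold: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Score every registered biomarker on an aligned cohort.

    Returns (score matrix, coverage report dict).  Non-evaluable
    signatures (coverage below threshold) get all-NaN rows.
    """
    params = params or EnrichmentParams()
    rows: dict[str, pd.Series] = {}
    coverage: dict[str, dict] = {}
    for sig_id, sig in registry.items():
        report = validate_signature_coverage(sig, cohort.expression, coverage_threshold)
        coverage[sig_id] = asdict(report)
        if not report.evaluable:
            logger.info("signature %s not evaluable (coverage %.2f)", sig_id, report.fraction)
            rows[sig_id] = pd.Series(np.nan, index=cohort.expression.columns)
            continue
        rows[sig_id] = _score_one(cohort, sig, params)
    scores = pd.DataFrame(rows).T
    scores.columns = cohort.expression.columns
    scores.index.name = "biomarker"
    return scores, coverage


def write_score_matrix(scores: pd.DataFrame, path, coverage: dict | None = None,
                       params: EnrichmentParams | None = None) -> None:
    """Write biomarkers x samples scores ('NA' for missing) + JSON sidecar."""
    scores.to_csv(path, sep="\t", na_rep="NA", index_label="biomarker",
                  float_format="%.17g")
    sidecar = {
        "coverage": coverage or {},
        "params": asdict(params) if params else asdict(EnrichmentParams()),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_score_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA",
                       float_precision="round_trip")
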