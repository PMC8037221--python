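"""End-to-end orchestration: score -> label -> evaluate -> survival -> report.

The pipeline runs every registered biomarker over a list of dataset
cohorts and assembles a :class:`BenchmarkReport`:

* per (biomarker, dataset) association/discrimination statistics under
  the chosen responder definition (default the progressive-disease
  strategy);
* per-biomarker Prediction Scores (sample-size-weighted AUC) overall and
  within cancer-type and therapy strata, with each biomarker's declared
  training datasets excluded;
* median-split survival comparisons (OS and PFS) on patient-deduplicated
  cohorts;
* Fisher's exact ORR association in datasets with more than 20 patients;
* a Spearman correlation matrix of biomarker scores with an
  average-linkage clustering order.

Scoring stages never read clinical fields, so switching the labeling
strategy leaves the score matrix bitwise unchanged.  All randomness lives
in the synthetic-cohort generator; the pipeline itself is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .evaluation import (
    ORR_MIN_N,
    biomarker_correlation_clustering,
    evaluate_biomarker,
    fisher_orr_association,
    prediction_score,
)
from .response_labeling import (
    DAYS_PER_6MO,
    DAYS_PER_YEAR,
    assign_labels,
    labels_to_binary,
    objective_response_rate,
)
from .scoring_engine import EnrichmentParams, score_all, write_score_matrix
from .signature_registry import SignatureDefinition
from .survival import LANDMARK_WEEKS, biomarker_survival, dedupe_patients

logger = logging.getLogger("icbbench")


@dataclass
class BenchmarkConfig:
    strategy: str = "PD"
    coverage_threshold: float = 1.0
    time_units_per_year: float = DAYS_PER_YEAR
    time_units_per_6mo: float = DAYS_PER_6MO
    landmark_time: float = LANDMARK_WEEKS
    orr_min_n: int = ORR_MIN_N
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    seed: int | None = None


@dataclass
class BenchmarkReport:
    eval_table: pd.DataFrame
    prediction_scores: pd.DataFrame
    survival_table: pd.DataFrame
    orr_table: pd.DataFrame
    correlation: pd.DataFrame | None
    cluster_order: list[str]
    scores: dict[str, pd.DataFrame]
    coverage: dict[str, dict]
    metadata: dict
    log_lines: list[str] = field(default_factory=list)


def _config_hash(config: BenchmarkConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_benchmark(
    cohorts: dict[str, Cohort] | list[Cohort],
    registry: dict[str, SignatureDefinition],
    config: BenchmarkConfig | None = None,
) -> BenchmarkReport:
    """Execute the full benchmark over per-dataset cohorts."""
    config = config or BenchmarkConfig()
    if isinstance(cohorts, list):
        cohorts = {str(c.clinical["dataset_id"].iloc[0]): c for c in cohorts}
    if not cohorts:
        raise ValueError("at least one cohort is required")
    log_lines: list[str] = []

    # stage 1: scoring (expression only; clinical fields untouched)
    scores: dict[str, pd.DataFrame] = {}
    coverage: dict[str, dict] = {}
    for ds_id, cohort in cohorts.items():
        sm, cov = score_all(cohort, registry, config.enrichment,
                            config.coverage_threshold)
        scores[ds_id] = sm
        coverage[ds_id] = cov
        for sig_id, rep in cov.items():
            if not rep["evaluable"]:
                log_lines.append(f"coverage: {sig_id} not evaluable in {ds_id} "
                                 f"(fraction {rep['fraction']:.2f})")

    # stage 2: labels and per-dataset statistics
    eval_rows, orr_rows, surv_rows = [], [], []
    ds_meta: dict[str, dict] = {}
    for ds_id, cohort in cohorts.items():
        labels = assign_labels(cohort.clinical, config.strategy,
                               config.time_units_per_year, config.time_units_per_6mo)
        binary = labels_to_binary(labels)
        try:
            orr = objective_response_rate(cohort.clinical)
        except ValueError:
            orr = np.nan
        ds_meta[ds_id] = {
            "n_samples": int(cohort.expression.shape[1]),
            "n_evaluable": int(len(binary)),
            "cancer_type": str(cohort.clinical["cancer_type"].iloc[0]),
            "therapy": str(cohort.clinical["therapy"].iloc[0]),
            "orr": None if np.isnan(orr) else float(orr),
        }
        objective = cohort.clinical["recist"].isin(["CR", "PR"]).astype(int)
        evaluable_recist = cohort.clinical["recist"].isin(["CR", "PR", "SD", "PD"])
        deduped = dedupe_patients(cohort.clinical)

        for sig_id, sig in registry.items():
            row = scores[ds_id].loc[sig_id]
            usable = row.reindex(binary.index).dropna()
            y = binary.reindex(usable.index)
            if len(usable) >= 4 and y.nunique() == 2 and usable.nunique() > 1:
                try:
                    eval_rows.append(asdict(evaluate_biomarker(
                        sig_id, ds_id, usable.to_numpy(), y.to_numpy(), sig.direction)))
                except ValueError as exc:
                    log_lines.append(f"eval skipped for {sig_id} in {ds_id}: {exc}")
            else:
                log_lines.append(f"eval skipped for {sig_id} in {ds_id}: "
                                 "degenerate scores or labels")

            # objective-response association (eligibility: n > 20 ITT patients)
            orr_scores = row[evaluable_recist.reindex(row.index, fill_value=False)].dropna()
            if len(orr_scores) >= config.orr_min_n and orr_scores.nunique() > 1:
                fr = fisher_orr_association(
                    orr_scores.to_numpy() * sig.direction,
                    objective.reindex(orr_scores.index).to_numpy(),
                    config.orr_min_n)
                orr_rows.append({
                    "biomarker_id": sig_id, "dataset_id": ds_id,
                    "n": len(orr_scores), "eligible": fr.eligible,
                    "fisher_p": fr.p,
                    "table": fr.table.tolist() if fr.table is not None else None,
                })
            else:
                log_lines.append(f"ORR association ineligible for {sig_id} in {ds_id} "
                                 f"(n = {len(orr_scores)})")

            # survival on deduplicated patients
            surv_scores = row.reindex(deduped.index).dropna()
            for endpoint in ("OS", "PFS"):
                comp = biomarker_survival(
                    surv_scores * sig.direction, deduped.loc[surv_scores.index],
                    endpoint, config.landmark_time)
                surv_rows.append({
                    "biomarker_id": sig_id, "dataset_id": ds_id,
                    "endpoint": endpoint,
                    "degenerate": comp.degenerate,
                    "n_high": comp.n_high, "n_low": comp.n_low,
                    "logrank_p": comp.logrank.p if comp.logrank else None,
                    "significant": comp.significant,
                    "median_high": comp.km_high.median_survival if comp.km_high else None,
                    "median_low": comp.km_low.median_survival if comp.km_low else None,
                    "landmark_high": comp.km_high.landmark_survival if comp.km_high else None,
                    "landmark_low": comp.km_low.landmark_survival if comp.km_low else None,
                })
                if comp.degenerate:
                    log_lines.append(f"degenerate survival split for {sig_id} in "
                                     f"{ds_id} ({endpoint})")

    eval_table = pd.DataFrame(eval_rows)
    if eval_table.empty:
        raise ValueError("no biomarker was evaluable in any cohort")

    # stage 3: prediction scores per stratum
    pred_rows = []
    strata: dict[tuple[str, str], list[str]] = {("overall", "all"): list(cohorts)}
    for ds_id, meta in ds_meta.items():
        strata.setdefault(("cancer_type", meta["cancer_type"]), []).append(ds_id)
        strata.setdefault(("therapy", meta["therapy"]), []).append(ds_id)
    for sig_id, sig in registry.items():
        sub = eval_table[eval_table["biomarker_id"] == sig_id]
        for (kind, value), ds_ids in strata.items():
            entries = []
            for ds_id in ds_ids:
                match = sub[sub["dataset_id"] == ds_id]
                if match.empty:
                    continue
                n = int(match["n_responders"].iloc[0] + match["n_non_responders"].iloc[0])
                excluded = ds_id in sig.training_datasets
                if excluded:
                    log_lines.append(f"prediction score: {ds_id} excluded as "
                                     f"training data of {sig_id}")
                entries.append((float(match["auc"].iloc[0]), n, excluded))
            if not entries:
                continue
            try:
                ps = prediction_score(entries)
            except ValueError:
                continue
            pred_rows.append({
                "biomarker_id": sig_id, "stratum_kind": kind, "stratum": value,
                "n_datasets": sum(1 for e in entries if not e[2]),
                "total_n": sum(e[1] for e in entries if not e[2]),
                "prediction_score": ps,
            })
    prediction_scores = pd.DataFrame(pred_rows)

    # stage 4: biomarker correlation structure over the pooled samples
    pooled = pd.concat(scores.values(), axis=1)
    correlation, order = None, []
    try:
        correlation, order = biomarker_correlation_clustering(pooled)
    except ValueError as exc:
        log_lines.append(f"correlation clustering skipped: {exc}")

    metadata = {
        "strategy": config.strategy,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "datasets": ds_meta,
        "n_biomarkers": len(registry),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    return BenchmarkReport(
        eval_table=eval_table,
        prediction_scores=prediction_scores,
        survival_table=pd.DataFrame(surv_rows),
        orr_table=pd.DataFrame(orr_rows),
        correlation=correlation,
        cluster_order=list(order),
        scores=scores,
        coverage=coverage,
        metadata=metadata,
        log_lines=log_lines,
    )


def write_report(report: BenchmarkReport, out_dir) -> dict[str, str]:
    """Write the report as tab-delimited tables + one JSON summary + a log.

    Missing values are written as 'NA', never as empty cells; output is
    byte-identical across reruns on identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", **kw)
        paths[name] = str(path)

    _write(report.eval_table, "evaluation.tsv", index=False)
    _write(report.prediction_scores, "prediction_scores.tsv", index=False)
    _write(report.survival_table, "survival.tsv", index=False)
    orr = report.orr_table.copy()
    if "table" in orr.columns:
        orr["table"] = orr["table"].map(json.dumps)
    _write(orr, "orr_association.tsv", index=False)
    if report.correlation is not None:
        _write(report.correlation, "correlation.tsv", index_label="biomarker")
    for ds_id, sm in report.scores.items():
        write_score_matrix(sm, out / f"scores_{ds_id}.tsv",
                           report.coverage.get(ds_id))
        paths[f"scores_{ds_id}.tsv"] = str(out / f"scores_{ds_id}.tsv")

    summary = {
        "metadata": report.metadata,
        "cluster_order": report.cluster_order,
        "prediction_scores": report.prediction_scores.to_dict(orient="records"),
    }
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    paths["summary.json"] = str(summary_path)

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        fh.write("\n".join(report.log_lines) + ("\n" if report.log_lines else ""))
    paths["run.log"] = str(log_path)
    return paths
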