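"""Synthetic multi-dataset ICB cohorts with planted biomarker effects.

The generator emulates the structure of the public ICB benchmark cohorts:
several datasets of modest size (tens to a few hundred patients each),
RECIST response categories, right-censored OS/PFS, and a bulk expression
matrix in log2(TPM+1) units.  A latent responder class drives everything:

* background gene expression is Gaussian in log space (truncated at 0)
  around gene-specific baselines;
* planted signatures shift their member genes by ``d`` noise-SD units in
  latent responders (sign flipped for negative-direction biomarkers);
* RECIST categories are drawn from per-class probability vectors whose
  defaults give roughly half responders under the progressive-disease
  labeling and an overall objective response rate near 28%, matching the
  make-up of the real benchmark cohorts;
* survival is exponential per class (responders by default at half the
  non-responder hazard) with independent uniform censoring calibrated to
  a configurable censoring fraction.

For a k-gene mean signature with planted shift ``d`` the analytic AUC of
the score against the latent class is Phi(d * sqrt(k) / sqrt(2)); this is
the recovery target the tests check the whole pipeline against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort_io import Cohort, align_cohort, validate_clinical_table, write_expression_matrix
from .signature_registry import SignatureDefinition

RECIST_ORDER = ("CR", "PR", "SD", "PD")

#: default per-latent-class RECIST probabilities (CR, PR, SD, PD)
DEFAULT_RECIST_PROBS = {
    "responder": (0.10, 0.46, 0.44, 0.0),
    "non_responder": (0.0, 0.0, 0.0, 1.0),
}


@dataclass
class PlantedSignature:
    signature_id: str
    effect_size: float  # shift in noise-SD units
    genes: list[str] | None = None  # resolved from the registry when None
    direction: int = 1


@dataclass
class DatasetConfig:
    dataset_id: str
    n_samples: int = 50
    responder_fraction: float = 0.5
    therapy: str = "anti_pd1"
    cancer_type: str = "melanoma"


@dataclass
class SimConfig:
    datasets: list[DatasetConfig] = field(
        default_factory=lambda: [DatasetConfig("sim1"), DatasetConfig("sim2"),
                                 DatasetConfig("sim3")])
    n_genes: int = 200  # background genes beyond signature members
    planted_signatures: list[PlantedSignature] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (3.0, 8.0)
    hazard_responder: float = np.log(2) / 60.0   # per week; 60-week median OS
    hazard_non_responder: float = np.log(2) / 30.0
    pfs_hazard_factor: float = 2.0               # progression precedes death
    censoring_rate: float = 0.2
    recist_probs: dict = field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_RECIST_PROBS.items()})
    dup_patient_fraction: float = 0.0            # patients with two samples
    seed: int = 0

    def validate(self) -> None:
        for cls, probs in self.recist_probs.items():
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"recist_probs[{cls!r}] must be 4 probabilities summing to 1")
        if self.hazard_responder <= 0 or self.hazard_non_responder <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        for p in self.planted_signatures:
            if not np.isfinite(p.effect_size):
                raise ValueError("planted effect sizes must be finite")


def expected_planted_auc(d: float, k_genes: int) -> float:
    """Analytic AUC of a k-gene mean score under an equal per-gene shift d."""
    return float(norm.cdf(d * np.sqrt(k_genes) / np.sqrt(2.0)))


def _censoring_horizon(rate: float, hazards: np.ndarray) -> float:
    """Uniform-censoring horizon giving the target expected censored fraction."""
    if rate <= 0:
        return np.inf

    def censored_fraction(h):
        # P(C < T) with C ~ U(0, h), T ~ Exp(lam): E[e^(-lam C)]
        lam_h = hazards * h
        return float(np.mean((1.0 - np.exp(-lam_h)) / lam_h))

    lo, hi = 1e-9, 1e9
    return brentq(lambda h: censored_fraction(h) - rate, lo, hi, xtol=1e-9)


def _resolve_planted(
    config: SimConfig,
    registry: dict[str, SignatureDefinition] | None,
) -> list[PlantedSignature]:
    resolved = []
    for p in config.planted_signatures:
        genes, direction = p.genes, p.direction
        if genes is None:
            if registry is None or p.signature_id not in registry:
                raise ValueError(
                    f"planted signature {p.signature_id!r} has no gene list and "
                    "is not in the registry")
            sig = registry[p.signature_id]
            genes = sig.all_genes
            direction = sig.direction
        resolved.append(PlantedSignature(p.signature_id, p.effect_size, list(genes), direction))
    return resolved


def simulate_cohort(
    config: SimConfig,
    registry: dict[str, SignatureDefinition] | None = None,
) -> Cohort:
    """Generate one multi-dataset cohort, fully reproducible from the seed.

    The clinical table carries a ``dataset_id`` column; use
    :func:`split_by_dataset` to obtain per-dataset cohorts.
    """
    config.validate()
    planted = _resolve_planted(config, registry)
    planted_genes = {g for p in planted for g in p.genes}
    registry_genes = sorted(
        set().union(*(sig.all_genes for sig in registry.values())) if registry else set()
    )
    background = [f"BG{i:05d}" for i in range(config.n_genes)]
    genes = sorted(set(registry_genes) | planted_genes) + background
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    streams = np.random.SeedSequence(config.seed).spawn(len(config.datasets) + 1)
    master = np.random.default_rng(streams[0])
    lo, hi = config.baseline_range
    baseline = master.uniform(lo, hi, size=n_genes)  # shared across datasets

    expr_blocks, clin_rows = [], []
    hazards = np.array([config.hazard_responder, config.hazard_non_responder])
    horizon_os = _censoring_horizon(config.censoring_rate, hazards)
    horizon_pfs = _censoring_horizon(config.censoring_rate,
                                     hazards * config.pfs_hazard_factor)

    for ds, stream in zip(config.datasets, streams[1:]):
        rng = np.random.default_rng(stream)
        n = ds.n_samples
        sample_ids = [f"{ds.dataset_id}_S{i:04d}" for i in range(n)]
        is_resp = rng.random(n) < ds.responder_fraction

        vals = rng.normal(baseline[:, None], config.noise_sd, size=(n_genes, n))
        for p in planted:
            shift = p.effect_size * config.noise_sd * p.direction
            idx = [gene_pos[g] for g in p.genes]
            vals[np.ix_(idx, np.flatnonzero(is_resp))] += shift
        vals = np.maximum(vals, 0.0)  # log2(TPM+1) floor
        expr_blocks.append(pd.DataFrame(vals, index=genes, columns=sample_ids))

        recist = np.empty(n, dtype=object)
        for cls, mask in (("responder", is_resp), ("non_responder", ~is_resp)):
            k = int(mask.sum())
            if k:
                recist[mask] = rng.choice(RECIST_ORDER, size=k,
                                          p=config.recist_probs[cls])

        lam_os = np.where(is_resp, config.hazard_responder, config.hazard_non_responder)
        lam_pfs = lam_os * config.pfs_hazard_factor
        os_t = rng.exponential(1.0 / lam_os)
        pfs_t = rng.exponential(1.0 / lam_pfs)
        if np.isfinite(horizon_os):
            cens_os = rng.uniform(0.0, horizon_os, size=n)
            cens_pfs = rng.uniform(0.0, horizon_pfs, size=n)
        else:
            cens_os = np.full(n, np.inf)
            cens_pfs = np.full(n, np.inf)
        os_event = (os_t <= cens_os).astype(int)
        pfs_event = (pfs_t <= cens_pfs).astype(int)
        os_obs = np.minimum(os_t, cens_os)
        pfs_obs = np.minimum(pfs_t, cens_pfs)

        patient_ids = [f"{ds.dataset_id}_P{i:04d}" for i in range(n)]
        if config.dup_patient_fraction > 0:
            n_dup = int(round(config.dup_patient_fraction * n / 2)) * 2
            for j in range(0, n_dup, 2):
                patient_ids[j + 1] = patient_ids[j]

        for i, sid in enumerate(sample_ids):
            clin_rows.append({
                "sample_id": sid,
                "patient_id": patient_ids[i],
                "dataset_id": ds.dataset_id,
                "cancer_type": ds.cancer_type,
                "therapy": ds.therapy,
                "recist": recist[i],
                "os_time": float(os_obs[i]),
                "os_event": int(os_event[i]),
                "pfs_time": float(pfs_obs[i]),
                "pfs_event": int(pfs_event[i]),
                "latent_responder": bool(is_resp[i]),
            })

    expr = pd.concat(expr_blocks, axis=1)
    clinical = validate_clinical_table(pd.DataFrame(clin_rows))
    return align_cohort(expr, clinical)


def split_by_dataset(cohort: Cohort) -> dict[str, Cohort]:
    """Per-dataset sub-cohorts keyed by dataset_id (input order preserved)."""
    out: dict[str, Cohort] = {}
    for ds_id in pd.unique(cohort.clinical["dataset_id"]):
        samples = cohort.clinical.index[cohort.clinical["dataset_id"] == ds_id]
        ext = (cohort.external_scores.loc[samples]
               if cohort.external_scores is not None else None)
        out[str(ds_id)] = Cohort(
            expression=cohort.expression[samples],
            clinical=cohort.clinical.loc[samples],
            external_scores=ext,
        )
    return out


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write expression / clinical tsv files in the formats cohort_io reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / "expression.tsv"
    clin_path = out / "clinical.tsv"
    write_expression_matrix(cohort.expression, expr_path)
    cohort.clinical.drop(columns=["latent_responder"], errors="ignore").to_csv(
        clin_path, sep="\t", index=False)
    return {"expression": str(expr_path), "clinical": str(clin_path)}


def sim_config_from_yaml(path) -> SimConfig:
    """Build a SimConfig from a structured-text config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    datasets = [DatasetConfig(**d) for d in raw.pop("datasets", [])]
    planted = [PlantedSignature(**p) for p in raw.pop("planted_signatures", [])]
    recist = raw.pop("recist_probs", None)
    cfg = SimConfig(**raw)
    if datasets:
        cfg.datasets = datasets
    if planted:
        cfg.planted_signatures = planted
    if recist is not None:
        cfg.recist_probs = {k: tuple(v) for k, v in recist.items()}
    return cfg
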