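"""Reading, validation and harmonization of expression matrices and clinical tables.

Expression data are gene x sample matrices of log2(TPM+1) values held as
pandas DataFrames (genes as the index, samples as columns).  Clinical tables
are per-sample DataFrames indexed by ``sample_id``.  A :class:`Cohort` pairs
the two (plus optional precomputed external score columns such as a
CIBERSORT CD8 fraction or a TIDE score) after restriction to the shared
sample set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("icbbench")

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")
CANCER_TYPES = ("melanoma", "ccRCC", "UC", "NSCLC", "other")
THERAPIES = (
    "anti_pd1",
    "anti_ctla4",
    "anti_ctla4_prog_anti_pd1",
    "combination",
    "anti_pdl1",
    "mixed",
)

#: required columns of a clinical table
CLINICAL_REQUIRED = (
    "sample_id",
    "dataset_id",
    "recist",
    "os_time",
    "os_event",
    "pfs_time",
    "pfs_event",
)
CLINICAL_OPTIONAL = ("patient_id", "cancer_type", "therapy")


class CohortError(ValueError):
    """Raised when expression and clinical inputs cannot form a cohort."""


class ParseError(ValueError):
    """Raised on malformed expression / clinical input files."""


@dataclass
class Cohort:
    """An aligned expression + clinical pair over the same sample set."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    external_scores: pd.DataFrame | None = None
    dropped: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


def read_expression_matrix(path, format: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    ``tsv``: genes in the first column, sample ids in the header.
    ``mtx``: MatrixMarket triplet file; gene and sample identifiers are read
    from sibling ``<path>.genes.txt`` / ``<path>.samples.txt`` index files
    (one identifier per line).

    Duplicate gene symbols are collapsed by the per-sample maximum; the
    number of collapsed rows is logged.
    """
    path = str(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        except Exception as exc:  # surface pandas' message with file context
            raise ParseError(f"cannot parse expression tsv {path}: {exc}") from exc
        if df.columns.size == 0 or df.index.name is None:
            raise ParseError(
                f"malformed header in {path}: expected gene column followed by sample ids"
            )
        non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        if len(non_numeric):
            col = non_numeric[0]
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(
                f"non-numeric cell in {path} at gene {bad[0]!r}, sample {col!r}"
            )
    elif format == "mtx":
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path))
        genes = _read_index_file(path + ".genes.txt")
        samples = _read_index_file(path + ".samples.txt")
        if mat.shape != (len(genes), len(samples)):
            raise ParseError(
                f"mtx shape {mat.shape} does not match index files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ParseError(f"non-finite values in expression matrix {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        raise ParseError(f"duplicate sample ids in {path}")
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        df = df.groupby(level=0, sort=False).max()
        logger.info("collapsed %d duplicate gene rows by per-sample maximum", n_dup)
    df.index.name = "gene"
    return df.astype(float)


def _read_index_file(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    """Write a matrix in the tsv dialect `read_expression_matrix` accepts.

    17 significant digits so a write -> read round trip is lossless for
    float64 values.
    """
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate a tab-delimited clinical table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_clinical_table(df)


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table lacks required columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id in clinical table: {dup!r}")
    if (df["dataset_id"].astype(str).str.len() == 0).any():
        raise ParseError("empty dataset_id in clinical table")
    df["recist"] = df["recist"].fillna("missing").astype(str)
    bad = set(df["recist"]) - set(RECIST_CATEGORIES) - {"missing"}
    if bad:
        sample = df.loc[df["recist"].isin(bad), "sample_id"].iloc[0]
        raise ParseError(f"unknown RECIST token {bad.pop()!r} for sample {sample!r}")
    for col in ("os_time", "pfs_time"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise ParseError(f"negative {col} in clinical table")
        df[col] = vals
    for col in ("os_event", "pfs_event"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if not vals.dropna().isin([0, 1]).all():
            raise ParseError(f"{col} must be binary 0/1")
        df[col] = vals
    if "patient_id" not in df.columns:
        df["patient_id"] = df["sample_id"]
    df["patient_id"] = df["patient_id"].astype(str)
    if "cancer_type" not in df.columns:
        df["cancer_type"] = "other"
    if "therapy" not in df.columns:
        df["therapy"] = "mixed"
    return df.set_index("sample_id", drop=False)


def read_external_scores(path) -> pd.DataFrame:
    """Read tab-delimited precomputed per-sample score columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError("external score table lacks a sample_id column")
    return df.set_index("sample_id")


def tpm_log_transform(tpm) -> pd.DataFrame:
    """log2(TPM + 1) transform; the packaged expression unit convention."""
    arr = tpm.to_numpy(dtype=float) if isinstance(tpm, pd.DataFrame) else np.asarray(tpm, float)
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = np.log2(arr + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    return out


def align_cohort(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    external_scores: pd.DataFrame | None = None,
) -> Cohort:
    """Restrict expression and clinical data to their shared samples.

    Sample order follows the expression matrix restricted to the
    intersection, so aligning an aligned cohort is a no-op.
    """
    expr_samples = list(expr.columns)
    clin_samples = list(clinical.index)
    shared = [s for s in expr_samples if s in set(clin_samples)]
    if not shared:
        raise CohortError("expression and clinical tables share no sample ids")
    dropped = {
        "expression": sorted(set(expr_samples) - set(shared)),
        "clinical": sorted(set(clin_samples) - set(shared)),
    }
    if dropped["expression"] or dropped["clinical"]:
        logger.info(
            "align_cohort dropped %d expression / %d clinical samples",
            len(dropped["expression"]),
            len(dropped["clinical"]),
        )
    ext = None
    if external_scores is not None:
        ext = external_scores.reindex(shared)
    return Cohort(
        expression=expr.loc[:, shared],
        clinical=clinical.loc[shared],
        external_scores=ext,
        dropped=dropped,
    )


def z_score_genes(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise z-scores (population SD, ddof=0).

    Zero-variance rows are set to all-zero and returned as the flagged
    list.  Requires at least two samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = expr.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (vals - mu) / sd
    z[flat, :] = 0.0
    flagged = list(expr.index[flat])
    return pd.DataFrame(z, index=expr.index, columns=expr.columns), flagged
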