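"""Machine-readable biomarker definitions and coverage validation.

The registry houses the 22 transcriptomic ICB-response biomarkers (seven
categories: immune-checkpoint molecules, tumor-infiltrating lymphocytes,
effector molecules, antigen-associated, antigen-presenting, immune
resistance, comprehensive) plus the 10 MCP-counter microenvironment
populations.  Gene lists, weights, pairwise relations and scoring-scheme
tables are transcriptions from the original publications and ship as a
versioned YAML data file so users can substitute corrected versions.

Signatures built from genes a platform does not measure (e.g. NanoString
panels) are declared non-evaluable and the scoring engine emits missing
values for them rather than partial scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml
from scipy.stats import hypergeom

CATEGORIES = (
    "immune_checkpoint",
    "TIL",
    "effector",
    "antigen_associated",
    "antigen_presenting",
    "immune_resistance",
    "comprehensive",
    "tme",
)
METHODS = (
    "single_gene",
    "mean",
    "weighted_sum",
    "pairwise",
    "ssgsea",
    "gsva_mean",
    "pc1",
    "up_down",
    "ips_scheme",
    "mcp",
    "external",
)


class ConfigError(ValueError):
    """Raised on malformed signature configuration."""


@dataclass
class SignatureDefinition:
    id: str
    category: str
    method: str
    direction: int
    genes: list[str] = field(default_factory=list)
    weights: list[float] | None = None
    pairs: list[tuple[str, str]] | None = None
    gene_sets: dict[str, list[str]] | None = None
    components: list[dict] | None = None  # ips_scheme tables
    external_column: str | None = None
    training_datasets: list[str] = field(default_factory=list)
    source: str = ""

    @property
    def all_genes(self) -> list[str]:
        """Every gene the signature needs measured, deduplicated in order."""
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g)
        if self.pairs:
            for a, b in self.pairs:
                seen.setdefault(a)
                seen.setdefault(b)
        if self.gene_sets:
            for members in self.gene_sets.values():
                for g in members:
                    seen.setdefault(g)
        if self.components:
            for comp in self.components:
                for g in comp["genes"]:
                    seen.setdefault(g)
        return list(seen)


@dataclass
class CoverageReport:
    signature_id: str
    genes_required: int
    genes_present: int
    fraction: float
    evaluable: bool


def _parse_signature(entry: dict) -> SignatureDefinition:
    for key in ("id", "category", "method", "direction"):
        if key not in entry:
            raise ConfigError(f"signature entry missing {key!r}: {entry}")
    if entry["category"] not in CATEGORIES:
        raise ConfigError(f"unknown category {entry['category']!r} for {entry['id']}")
    if entry["method"] not in METHODS:
        raise ConfigError(f"unknown method {entry['method']!r} for {entry['id']}")
    direction = int(entry["direction"])
    if direction not in (1, -1):
        raise ConfigError(f"direction must be +1 or -1 for {entry['id']}")
    sig = SignatureDefinition(
        id=str(entry["id"]),
        category=entry["category"],
        method=entry["method"],
        direction=direction,
        genes=[str(g) for g in entry.get("genes", [])],
        weights=[float(w) for w in entry["weights"]] if "weights" in entry else None,
        pairs=[tuple(p) for p in entry["pairs"]] if "pairs" in entry else None,
        gene_sets={k: list(v) for k, v in entry["gene_sets"].items()}
        if "gene_sets" in entry
        else None,
        components=entry.get("components"),
        external_column=entry.get("external_column"),
        training_datasets=list(entry.get("training_datasets", [])),
        source=entry.get("source", ""),
    )
    if sig.method != "external" and not sig.all_genes:
        raise ConfigError(f"signature {sig.id} declares no genes")
    if sig.weights is not None and len(sig.weights) != len(sig.genes):
        raise ConfigError(
            f"signature {sig.id}: {len(sig.weights)} weights for {len(sig.genes)} genes"
        )
    if sig.method == "pairwise" and not sig.pairs:
        raise ConfigError(f"pairwise signature {sig.id} declares no pairs")
    if sig.method == "up_down":
        gs = sig.gene_sets or {}
        if not gs.get("up") or not gs.get("down"):
            raise ConfigError(f"up_down signature {sig.id} needs nonempty up and down lists")
    if sig.method == "ips_scheme":
        if not sig.components:
            raise ConfigError(f"ips_scheme signature {sig.id} declares no components")
        cats = {c.get("category") for c in sig.components}
        missing = {"MHC", "EC", "SC", "CP"} - cats
        if missing:
            raise ConfigError(f"ips_scheme signature {sig.id} missing categories {sorted(missing)}")
    return sig


def load_signature_definitions(path=None) -> dict[str, SignatureDefinition]:
    """Load signature definitions from YAML (the packaged defaults if no path).

    Returns an id -> definition mapping preserving file order.
    """
    if path is None:
        text = resources.files("icbbench.data").joinpath("signatures.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "signatures" not in raw:
        raise ConfigError("signature config must contain a top-level 'signatures' list")
    registry: dict[str, SignatureDefinition] = {}
    for entry in raw["signatures"]:
        sig = _parse_signature(entry)
        if sig.id in registry:
            raise ConfigError(f"duplicate signature id {sig.id!r}")
        registry[sig.id] = sig
    return registry


def load_gmt(path, category: str = "comprehensive", direction: int = 1) -> dict[str, SignatureDefinition]:
    """Read plain gene sets from a GMT file as mean-scored signatures."""
    registry: dict[str, SignatureDefinition] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            if name in registry:
                raise ConfigError(f"duplicate signature id {name!r} in GMT")
            registry[name] = SignatureDefinition(
                id=name, category=category, method="mean",
                direction=direction, genes=[g for g in genes if g],
            )
    return registry


def validate_signature_coverage(
    sig: SignatureDefinition,
    expr: pd.DataFrame,
    threshold: float = 1.0,
) -> CoverageReport:
    """Fraction of a signature's genes present in the matrix.

    ``evaluable`` is ``fraction >= threshold``; the default threshold 1.0
    requires every gene (incompletely measured signatures are excluded
    from evaluation).  External signatures carry no gene requirement.
    """
    required = sig.all_genes
    if not required:
        return CoverageReport(sig.id, 0, 0, 1.0, True)
    present = sum(g in expr.index for g in required)
    fraction = present / len(required)
    return CoverageReport(sig.id, len(required), present, fraction, fraction >= threshold)


def signature_overlap_test(
    sig_a: SignatureDefinition,
    sig_b: SignatureDefinition,
    universe_size: int,
) -> tuple[float, list[str]]:
    """Upper-tail hypergeometric test of gene overlap between two signatures.

    p = P(X >= observed overlap) drawing |B| genes from a universe
    containing |A| marked genes.  Symmetric in its arguments.
    """
    genes_a = set(sig_a.all_genes)
    genes_b = set(sig_b.all_genes)
    union = genes_a | genes_b
    if universe_size < len(union):
        raise ValueError(
            f"universe size {universe_size} smaller than the gene union ({len(union)})"
        )
    overlap = sorted(genes_a & genes_b)
    k = len(overlap)
    p = float(hypergeom.sf(k - 1, universe_size, len(genes_a), len(genes_b)))
    return min(p, 1.0), overlap


def registry_gene_universe(registry: dict[str, SignatureDefinition]) -> set[str]:
    """Union of all genes any registered signature uses (default overlap universe)."""
    universe: set[str] = set()
    for sig in registry.values():
        universe.update(sig.all_genes)
    return universe
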