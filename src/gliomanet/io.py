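"""Shared data model and tab-separated readers/writers.

Every tabular object the pipeline touches lives here: log2 expression
matrices with per-sample grade metadata, tumor-vs-normal log-ratio
matrices, gene-category annotations, subtype centroid tables, per-gene
mutation (methylation / copy-number) log-ratios, the inferred regulatory
network's edge list, and the flat pipeline configuration.

All expression values are on the log2 scale; a "log-ratio" is a
difference of log2 values between a tumor sample and the mean of its
normal-brain reference samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants and errors
# ---------------------------------------------------------------------------

#: WHO-grade labels: normal brain reference plus the four astrocytoma grades
#: (pilocytic astrocytoma I, diffuse astrocytoma II, anaplastic astrocytoma
#: III, glioblastoma IV).
GRADES = ("NORMAL", "PA1", "AS2", "AS3", "GBM4")
TUMOR_GRADES = ("PA1", "AS2", "AS3", "GBM4")
ADULT_GRADES = ("AS2", "AS3", "GBM4")

ACTIVATOR = "activator"
REPRESSOR = "repressor"

MUTATION_LAYERS = ("methylation", "copy_number")


class FormatError(ValueError):
    """A file or table violates its format contract (duplicates, bad cells)."""


class ConsistencyError(ValueError):
    """Two objects that must agree (values vs metadata, signs vs labels) do not."""


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            raise FormatError(f"duplicate {what}: {it!r}")
        seen.add(it)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample grade metadata.

    ``values`` is a DataFrame indexed by gene with one column per sample;
    ``metadata`` is indexed by sample with at least a ``grade`` column
    (one of :data:`GRADES`) and an optional ``cohort`` tag.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene identifier")
        _check_unique(list(self.values.columns), "sample identifier")
        self.values.index.name = "gene"
        self.values.columns.name = None
        self.metadata.index.name = "sample"
        if "grade" not in self.metadata.columns:
            raise ConsistencyError("metadata must contain a 'grade' column")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ConsistencyError(
                f"samples absent from metadata: {', '.join(map(str, missing))}"
            )
        self.metadata = self.metadata.loc[list(self.values.columns)]
        bad = [
            (s, g)
            for s, g in self.metadata["grade"].items()
            if g not in GRADES
        ]
        if bad:
            raise ConsistencyError(f"unknown grade labels: {bad}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise FormatError("expression values must be numeric")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def grade_samples(self, grade: str) -> list[str]:
        """Sample identifiers carrying ``grade``."""
        return list(self.metadata.index[self.metadata["grade"] == grade])


@dataclass
class LogRatioMatrix:
    """Genes x tumor-samples log2-ratios relative to a reference grade."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    reference_grade: str = "NORMAL"

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene identifier")
        _check_unique(list(self.values.columns), "sample identifier")
        self.values.index.name = "gene"
        self.values.columns.name = None
        self.metadata.index.name = "sample"
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ConsistencyError(
                f"samples absent from metadata: {', '.join(map(str, missing))}"
            )
        self.metadata = self.metadata.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def grade_samples(self, grade: str) -> list[str]:
        return list(self.metadata.index[self.metadata["grade"] == grade])


def to_log_ratios(
    expr: ExpressionMatrix, reference_grade: str = "NORMAL"
) -> LogRatioMatrix:
    """Subtract the mean reference profile; drop the reference columns.

    value[g, d] = expr[g, d] - mean over reference samples of expr[g, .].
    """
    refs = expr.grade_samples(reference_grade)
    if not refs:
        raise ConsistencyError(f"no samples with reference grade {reference_grade!r}")
    ref_mean = expr.values[refs].mean(axis=1)
    tumors = [s for s in expr.samples if s not in set(refs)]
    values = expr.values[tumors].sub(ref_mean, axis=0)
    return LogRatioMatrix(
        values=values,
        metadata=expr.metadata.loc[tumors].copy(),
        reference_grade=reference_grade,
    )


# ---------------------------------------------------------------------------
# Annotations, centroids, mutation layers
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Named gene categories (TF, kinase, oncogene, ...); sets may overlap."""

    categories: dict[str, set[str]]

    def __post_init__(self) -> None:
        _check_unique(list(self.categories), "category name")

    def __getitem__(self, name: str) -> set[str]:
        return self.categories[name]

    def __contains__(self, name: str) -> bool:
        return name in self.categories


@dataclass
class CentroidSet:
    """Gene x subtype centroid expression table (e.g. the four glioblastoma
    expression subtypes: neural, proneural, classical, mesenchymal)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene identifier")
        self.values.index.name = "gene"
        self.values.columns.name = None
        if self.values.shape[1] < 2:
            raise FormatError("a centroid set needs at least two subtypes")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MutationTable:
    """Per-gene average mutation log-ratio (tumor vs normal) for one layer."""

    values: pd.Series
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in MUTATION_LAYERS:
            raise FormatError(
                f"layer must be one of {MUTATION_LAYERS}, got {self.layer!r}"
            )
        _check_unique(list(self.values.index), "gene identifier")


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["tf", "target", "coefficient", "sign", "p_value"]


@dataclass
class RegulatoryNetwork:
    """Directed, signed, weighted TF -> target edges with selection p-values.

    ``sign`` is ``activator`` iff the coefficient is positive and
    ``repressor`` iff negative; self-edges are forbidden.
    """

    edges: pd.DataFrame
    tfs: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise FormatError(f"edge table missing columns: {missing}")
        self.edges = self.edges[EDGE_COLUMNS].reset_index(drop=True)
        for _, row in self.edges.iterrows():
            if row["tf"] == row["target"]:
                raise ConsistencyError(f"self-edge on {row['tf']!r}")
            coef = float(row["coefficient"])
            expected = ACTIVATOR if coef > 0 else REPRESSOR
            if coef == 0 or row["sign"] != expected:
                raise ConsistencyError(
                    f"edge {row['tf']}->{row['target']}: coefficient {coef} "
                    f"inconsistent with sign {row['sign']!r}"
                )
        if not self.tfs:
            self.tfs = sorted(set(self.edges["tf"]))
        if not self.genes:
            self.genes = sorted(set(self.edges["tf"]) | set(self.edges["target"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_degree(self, targets: Iterable[str] | None = None) -> pd.Series:
        """Outgoing edge counts per TF, optionally restricted to ``targets``."""
        edges = self.edges
        if targets is not None:
            edges = edges[edges["target"].isin(set(targets))]
        counts = edges.groupby("tf").size()
        return counts.reindex(self.tfs, fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds the pipeline actually uses, plus the run seed.

    q_threshold         FDR cut for calling a gene differentially expressed.
    lfc_threshold       minimum |class-mean log-ratio difference| (log2 units)
                        for signature membership.
    subtype_alpha       one-sided significance level for centroid correlation.
    network_p_threshold covariance-test p cut for accepting a regulator.
    deviation_threshold log2 cut for "strongly deviating" TFs in the
                        expression-vs-mutation map.
    """

    q_threshold: float = 1e-4
    lfc_threshold: float = 2.0
    subtype_alpha: float = 0.05
    network_p_threshold: float = 5e-5
    deviation_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_threshold", "subtype_alpha", "network_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")
        if self.deviation_threshold <= 0:
            raise ValueError("deviation_threshold must be > 0")
        self.seed = int(self.seed)

    _FLOAT_FIELDS = (
        "q_threshold",
        "lfc_threshold",
        "subtype_alpha",
        "network_p_threshold",
        "deviation_threshold",
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key: value`` text document."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "seed":
                kwargs[key] = int(value)
            elif key in cls._FLOAT_FIELDS:
                kwargs[key] = float(value)
            else:
                raise FormatError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{name}: {getattr(self, name)!r}" for name in self._FLOAT_FIELDS]
        lines.append(f"seed: {self.seed}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample log2 TSV plus a sample -> grade metadata TSV."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    _check_unique(list(raw.index), "gene identifier")
    _check_unique(list(raw.columns), "sample identifier")
    try:
        values = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression cell in {path}: {exc}") from exc
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values=values, metadata=metadata)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_log_ratios(
    path: str | Path, metadata_path: str | Path, reference_grade: str = "NORMAL"
) -> LogRatioMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}).astype(float)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return LogRatioMatrix(
        values=raw, metadata=metadata, reference_grade=reference_grade
    )


def write_log_ratios(
    lr: LogRatioMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    lr.values.to_csv(path, sep="\t", index_label="gene")
    if metadata_path is not None:
        lr.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Long-format TSV with columns ``category`` and ``gene``."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"category", "gene"} <= set(table.columns):
        raise FormatError("annotation TSV needs 'category' and 'gene' columns")
    cats: dict[str, set[str]] = {}
    for cat, sub in table.groupby("category", sort=False):
        cats[str(cat)] = set(sub["gene"])
    return AnnotationTable(categories=cats)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    rows = [
        {"category": cat, "gene": gene}
        for cat, genes in ann.categories.items()
        for gene in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["category", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_centroids(path: str | Path) -> CentroidSet:
    values = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}).astype(float)
    return CentroidSet(values=values)


def write_centroids(centroids: CentroidSet, path: str | Path) -> None:
    centroids.values.to_csv(path, sep="\t", index_label="gene")


def read_mutation_table(path: str | Path) -> MutationTable:
    table = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "log_ratio", "layer"} <= set(table.columns):
        raise FormatError(
            "mutation TSV needs 'gene', 'log_ratio' and 'layer' columns"
        )
    layers = set(table["layer"])
    if len(layers) != 1:
        raise FormatError(f"mutation TSV must carry exactly one layer, got {layers}")
    values = pd.Series(
        table["log_ratio"].astype(float).values, index=table["gene"].values
    )
    return MutationTable(values=values, layer=layers.pop())


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "gene": table.values.index,
            "log_ratio": table.values.values,
            "layer": table.layer,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    edges = pd.read_csv(
        path, sep="\t", dtype={"tf": str, "target": str, "sign": str}
    )
    if edges.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    return RegulatoryNetwork(edges=edges)


def hash_file(path: str | Path) -> str:
    """SHA-256 digest of a file, for run manifests."""
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
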