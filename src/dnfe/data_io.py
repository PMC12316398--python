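"""Readers and writers for expression matrices, sample designs, networks and score tables.

Expression data are genes-in-rows tables. Dense TSV/CSV files carry the gene ID
in the first column and sample IDs in the header row. Sparse single-cell input
uses MatrixMarket coordinate format plus ``genes.txt`` / ``samples.txt``
sidecars (one ID per line). A sample design is a TSV with columns
``sample_id``, ``time_point`` and ``role`` (``reference`` or ``case``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "phenotype_vector",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "write_network",
    "write_scores",
]

VALID_ROLES = ("reference", "case")


class DataValidationError(ValueError):
    """Raised when an input file violates the documented contracts."""


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes × samples real-valued expression matrix.

    Units are arbitrary (counts, TPM or simulated concentrations); every
    downstream statistic is either correlation-based or normalized per gene,
    so a global positive rescaling never changes results.

    Attributes
    ----------
    gene_ids, sample_ids
        Ordered, duplicate-free identifier lists matching ``values`` rows
        and columns.
    values
        Dense float array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise DataValidationError(f"duplicate {name} IDs: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}; "
                "missing values are not imputed"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataValidationError(f"unknown sample IDs: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise DataValidationError(f"unknown gene IDs: {missing[:5]}")
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx, :])

    def zero_variance_genes(self, sample_ids: Sequence[str] | None = None) -> list[str]:
        """Gene IDs whose expression is constant across the given samples.

        These genes have undefined Pearson correlations and are excluded
        from network construction by the pipeline (never silently dropped
        at read time).
        """
        mat = self if sample_ids is None else self.subset_samples(sample_ids)
        flat = np.ptp(mat.values, axis=1) == 0
        return [g for g, z in zip(mat.gene_ids, flat) if z]


@dataclasses.dataclass(frozen=True)
class SampleDesign:
    """One row of the sample design: which time point and role a sample has."""

    sample_id: str
    time_point: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise DataValidationError(
                f"unknown role {self.role!r} for sample {self.sample_id!r}; "
                f"expected one of {VALID_ROLES}"
            )


def ordered_time_points(design: Sequence[SampleDesign],
                        order: Sequence[str] | None = None) -> list[str]:
    """Time points in declared order, or file order of first appearance."""
    seen = list(dict.fromkeys(d.time_point for d in design))
    if order is None:
        return seen
    order = [str(t) for t in order]
    unknown = sorted(set(seen) - set(order))
    if unknown:
        raise DataValidationError(f"time points missing from declared order: {unknown}")
    return [t for t in order if t in seen]


def phenotype_vector(design: Sequence[SampleDesign],
                     sample_ids: Sequence[str]) -> np.ndarray:
    """Binary 0/1 labels (0 = reference, 1 = case) for the given samples."""
    roles = {d.sample_id: d.role for d in design}
    missing = [s for s in sample_ids if s not in roles]
    if missing:
        raise DataValidationError(f"samples absent from design: {missing[:5]}")
    return np.array([0 if roles[s] == "reference" else 1 for s in sample_ids], dtype=int)


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from dense TSV/CSV or MTX triplet.

    For ``mtx`` input the files ``genes.txt`` and ``samples.txt`` must sit
    next to the matrix file. Gene and sample order is taken from the files
    verbatim; nothing is reordered or dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0,
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"malformed {fmt} file {path}: {exc}") from exc
    if frame.isna().any().any():
        row = frame.index[frame.isna().any(axis=1)][0]
        raise DataValidationError(
            f"missing value in gene {row!r} of {path}; NA values are not imputed"
        )
    return ExpressionMatrix.from_frame(frame)


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(suffix, "tsv")


def _read_mtx(path: Path) -> ExpressionMatrix:
    genes_file = path.parent / "genes.txt"
    samples_file = path.parent / "samples.txt"
    for sidecar in (genes_file, samples_file):
        if not sidecar.exists():
            raise FileNotFoundError(f"MTX sidecar missing: {sidecar}")
    matrix = scipy.io.mmread(path)
    if scipy.sparse.issparse(matrix):
        matrix = matrix.toarray()
    gene_ids = genes_file.read_text().split()
    sample_ids = samples_file.read_text().split()
    return ExpressionMatrix(gene_ids, sample_ids, np.asarray(matrix, dtype=float))


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        (path.parent / "genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        (path.parent / "samples.txt").write_text("\n".join(matrix.sample_ids) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id",
                             float_format="%.17g")


# ---------------------------------------------------------------------------
# design I/O


def read_design(path: str | Path,
                expression: ExpressionMatrix | None = None,
                time_point_order: Sequence[str] | None = None) -> list[SampleDesign]:
    """Read a sample design table and validate it against the expression matrix."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "time_point", "role"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise DataValidationError(f"design table missing columns: {sorted(missing_cols)}")
    design = [
        SampleDesign(row.sample_id, row.time_point, row.role)
        for row in table.itertuples(index=False)
    ]
    validate_design(design, expression)
    ordered_time_points(design, time_point_order)  # raises on inconsistency
    return design


def validate_design(design: Sequence[SampleDesign],
                    expression: ExpressionMatrix | None = None) -> None:
    ids = [d.sample_id for d in design]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise DataValidationError(f"duplicate sample IDs in design: {dupes[:5]}")
    if expression is not None:
        known = set(expression.sample_ids)
        absent = [s for s in ids if s not in known]
        if absent:
            raise DataValidationError(
                f"design references samples absent from expression matrix: {absent[:5]}"
            )
    n_ref = sum(d.role == "reference" for d in design)
    if n_ref < 3:
        raise DataValidationError(
            f"need >= 3 reference samples for perturbed correlations, found {n_ref}"
        )


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(d) for d in design]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# network and score export


def write_network(net: nx.DiGraph, path: str | Path, format: str = "edgelist") -> None:
    """Export a directed network as a 3-column edge list (source, target, omega)
    or as GraphML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    rows = [
        {"source": u, "target": v, "omega": data.get("omega", np.nan)}
        for u, v, data in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "omega"]).to_csv(
        path, sep="\t", index=False
    )


def write_scores(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
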