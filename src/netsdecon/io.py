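"""Readers/writers, normalization, variable-gene selection and PCA.

Conventions
-----------
Count and expression matrices are genes-by-samples :class:`pandas.DataFrame`
objects: the index holds gene identifiers, the columns sample identifiers.
TSV matrices carry gene IDs in the first column and sample IDs in the header
row.  MatrixMarket (``.mtx``) matrices come with sidecar ``genes.txt`` /
``samples.txt`` files, one identifier per line.  Sample metadata is a CSV
with a header; gene sets follow the MSigDB GMT convention
(``name<TAB>description<TAB>gene1<TAB>gene2...``).
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: The sorted cerebellar populations of the study design, plus "unsorted".
CELL_TYPES = (
    "astrocyte",
    "basket",
    "golgi",
    "granule",
    "microglia",
    "oligodendrocyte",
    "opc",
    "purkinje",
)
UNSORTED = "unsorted"
VALID_CELL_TYPES = CELL_TYPES + (UNSORTED,)

METADATA_COLUMNS = (
    "sample_id",
    "donor_id",
    "cell_type",
    "condition",
    "age",
    "sex",
    "pmi",
    "batch",
)
CONDITIONS = ("control", "AT")


class ParseError(ValueError):
    """Malformed input file (bad header, negative count, duplicate ID...)."""


@dataclass
class Expression:
    """Normalized expression: genes-by-samples values plus a scale tag.

    ``scale`` is ``"linear_pm"`` (per-million counts; every column sums to
    1e6) or ``"log2_pm"`` (``log2(per_million + pseudocount)``).
    """

    values: pd.DataFrame
    scale: str  # "linear_pm" | "log2_pm"

    def __post_init__(self) -> None:
        if self.scale not in ("linear_pm", "log2_pm"):
            raise ValueError(f"unknown scale tag: {self.scale!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def to_linear(self) -> pd.DataFrame:
        """Per-million-scale values, inverting the log transform if needed."""
        if self.scale == "linear_pm":
            return self.values
        return np.exp2(self.values) - 1.0


@dataclass
class GeneSetCollection:
    """Named gene sets; genes within a set are unique, order preserved."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class PcaResult:
    """PCA of a genes-by-samples matrix after gene-wise centering.

    ``scores`` is samples-by-components, ``loadings`` genes-by-components
    (orthonormal columns).  The sign convention fixes each loading vector's
    largest-magnitude entry to be positive, so results are deterministic.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


# ---------------------------------------------------------------------------
# Validation helpers


def _check_unique(ids, kind: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {kind} identifier(s): {dup[:5]}")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants: unique IDs, finite, non-negative."""
    _check_unique(counts.index, "gene")
    _check_unique(counts.columns, "sample")
    values = counts.to_numpy()
    if not np.all(np.isfinite(values)):
        bad = counts.index[~np.isfinite(values).all(axis=1)][0]
        raise ParseError(f"non-finite value in row for gene {bad!r}")
    if (values < 0).any():
        bad = counts.index[(values < 0).any(axis=1)][0]
        raise ParseError(f"negative count in row for gene {bad!r}")
    return counts


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata missing required column(s): {missing}")
    _check_unique(meta["sample_id"], "sample_id")
    bad_ct = sorted(set(meta["cell_type"]) - set(VALID_CELL_TYPES))
    if bad_ct:
        raise ParseError(
            f"unknown cell_type label(s) {bad_ct}; allowed: {sorted(VALID_CELL_TYPES)}"
        )
    bad_cond = sorted(set(meta["condition"]) - set(CONDITIONS))
    if bad_cond:
        raise ParseError(
            f"unknown condition label(s) {bad_cond}; allowed: {list(CONDITIONS)}"
        )
    if (meta["age"].astype(float) < 0).any():
        raise ParseError("negative age in metadata")
    return meta


# ---------------------------------------------------------------------------
# Readers / writers


def _infer_format(path: Path) -> str:
    return "mtx" if path.suffix.lower() == ".mtx" else "tsv"


def read_counts(
    path: str | Path, format: str | None = None, transpose: bool = False
) -> pd.DataFrame:
    """Read a genes-by-samples count matrix from TSV or MatrixMarket.

    Parameters
    ----------
    path
        TSV file, or ``.mtx`` file with ``genes.txt`` and ``samples.txt``
        sidecars in the same directory.
    format
        ``"tsv"`` or ``"mtx"``; inferred from the suffix when omitted.
    transpose
        Set when the file stores samples in rows; the result is always
        genes-by-samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        try:
            counts = counts.astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric value in {path}: {exc}") from exc
    elif fmt == "mtx":
        genes_file = path.parent / "genes.txt"
        samples_file = path.parent / "samples.txt"
        for side in (genes_file, samples_file):
            if not side.exists():
                raise ParseError(f"missing MTX sidecar file: {side}")
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        genes = genes_file.read_text().split()
        samples = samples_file.read_text().split()
        if matrix.shape != (len(genes), len(samples)):
            raise ParseError(
                f"MTX shape {matrix.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        counts = pd.DataFrame(np.asarray(matrix, dtype=float), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'mtx'")
    if transpose:
        counts = counts.T
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a genes-by-samples matrix; round-trips with :func:`read_counts`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        out = counts
        if np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
            out = counts.astype(np.int64)
        out.to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
        (path.parent / "genes.txt").write_text("\n".join(counts.index) + "\n")
        (path.parent / "samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata CSV."""
    meta = pd.read_csv(path)
    return validate_metadata(meta)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (MSigDB convention).

    Duplicate genes within a set are dropped with a warning; duplicate set
    names and empty sets are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene set {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning("set %s: %d duplicate gene(s) dropped", name, len(genes) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Normalization, variable genes, PCA


def normalize(counts: pd.DataFrame, log: bool = True, pseudocount: float = 1.0) -> Expression:
    """Per-million scaling of raw counts, optionally log2-transformed.

    Each sample's counts are scaled to sum to 1e6 (no gene-length
    correction: nuclear, intron-inclusive counting makes length correction
    ill-defined).  With ``log=True`` values become
    ``log2(per_million + pseudocount)``.
    """
    validate_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total count: {zero}")
    pm = counts / totals * 1.0e6
    if log:
        return Expression(np.log2(pm + pseudocount), "log2_pm")
    return Expression(pm, "linear_pm")


def top_variable_genes(expr: Expression, n: int = 500) -> list[str]:
    """The ``n`` genes with largest across-sample variance of log2 expression.

    Ties are broken by gene identifier so the selection is reproducible.
    """
    if expr.scale != "log2_pm":
        raise ValueError("top_variable_genes expects log2_pm expression")
    if n <= 0:
        raise ValueError("n must be positive")
    if n > expr.values.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {expr.values.shape[0]}")
    variances = expr.values.var(axis=1, ddof=1)
    order = sorted(variances.index, key=lambda g: (-variances[g], g))
    return order[:n]


def pca(
    expr: Expression, genes: list[str] | None = None, n_components: int | None = None
) -> PcaResult:
    """PCA of expression over samples after gene-wise centering.

    Deterministic up to the fixed sign convention (each loading vector's
    largest-magnitude entry is positive).  Explained variances use the
    unbiased (ddof=1) normalization and sum to the total gene-wise variance.
    """
    values = expr.values
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise KeyError(f"gene(s) not in expression matrix: {missing[:5]}")
        values = values.loc[genes]
    n_samples = values.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    centered = values.sub(values.mean(axis=1), axis=0)
    # SVD of the samples-by-genes matrix
    u, s, vt = np.linalg.svd(centered.to_numpy().T, full_matrices=False)
    k = min(n_samples, values.shape[0]) if n_components is None else n_components
    u, s, vt = u[:, :k], s[:k], vt[:k]
    loadings = vt.T  # genes x k, orthonormal columns
    # sign convention: largest-|.| entry of each loading vector positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = u * s * flip
    explained = s**2 / (n_samples - 1)
    total_var = centered.to_numpy().var(axis=1, ddof=1).sum()
    ratio = explained / total_var if total_var > 0 else np.zeros_like(explained)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=values.index, columns=comp_names),
        explained_variance=explained,
        explained_variance_ratio=ratio,
    )
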