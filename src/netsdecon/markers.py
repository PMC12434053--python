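"""Specificity-index marker discovery and cell-type-specificity diagnostics.

The specificity index (SI) of gene *g* for cell type *A* is the mean, over
every other cell type *B*, of the descending rank of the log-expression
difference ``mean_A(g) - mean_B(g)`` among all genes.  SI = 1 means the gene
tops every pairwise comparison; low SI marks a specific marker.  Ranks are
averaged over bootstrap iterations that resample samples (donors) with
replacement within each cell type, which propagates donor-level variability
into the ranking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from netsdecon.io import Expression

logger = logging.getLogger(__name__)

__all__ = [
    "specificity_index",
    "select_specific_genes",
    "assign_tertiles",
    "contamination_score",
    "crossplatform_correlation",
]


def _group_samples(groups: pd.Series, samples: pd.Index) -> dict[str, list[str]]:
    groups = groups.reindex(samples)
    if groups.isna().any():
        missing = samples[groups.isna()].tolist()
        raise ValueError(f"no cell-type label for sample(s): {missing[:5]}")
    by_type: dict[str, list[str]] = {}
    for sample, cell_type in groups.items():
        by_type.setdefault(cell_type, []).append(sample)
    return by_type


def specificity_index(
    expr: Expression,
    groups: pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap-averaged specificity index for every (gene, cell type).

    Parameters
    ----------
    expr
        log2 per-million expression, genes by samples.
    groups
        sample -> cell-type label, covering every sample in ``expr``.
    n_iter
        bootstrap iterations; each resamples the samples of every cell type
        with replacement before computing type means and pairwise ranks.
        Ties get average (fractional) ranks, so identical types rank all
        genes equally.

    Returns
    -------
    DataFrame genes x cell_types of SI values (all >= 1).
    """
    if expr.scale != "log2_pm":
        raise ValueError("specificity_index expects log2_pm expression")
    by_type = _group_samples(groups, expr.samples)
    if len(by_type) < 2:
        raise ValueError("specificity_index needs at least 2 cell types")
    for cell_type, members in by_type.items():
        if not members:
            raise ValueError(f"cell type {cell_type!r} has no samples")

    cell_types = sorted(by_type)
    values = expr.values
    rng = np.random.default_rng(seed)
    n_genes = values.shape[0]
    si_sum = np.zeros((n_genes, len(cell_types)))
    for _ in range(n_iter):
        means = np.empty((n_genes, len(cell_types)))
        for j, cell_type in enumerate(cell_types):
            members = by_type[cell_type]
            take = [members[i] for i in rng.integers(0, len(members), len(members))]
            means[:, j] = values[take].mean(axis=1)
        for j in range(len(cell_types)):
            delta = means[:, [j]] - np.delete(means, j, axis=1)
            ranks = rankdata(-delta, axis=0, method="average")
            si_sum[:, j] += ranks.mean(axis=1)
    return pd.DataFrame(si_sum / n_iter, index=values.index, columns=cell_types)


def select_specific_genes(si_table: pd.DataFrame, k: int = 500) -> dict[str, list[str]]:
    """Top-k most specific genes per cell type (ascending SI, ties by gene ID)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > si_table.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {si_table.shape[0]}")
    out = {}
    for cell_type in si_table.columns:
        order = sorted(si_table.index, key=lambda g: (si_table.at[g, cell_type], g))
        out[cell_type] = order[:k]
    return out


def assign_tertiles(
    expr: Expression,
    specific_genes: dict[str, list[str]],
    groups: pd.Series,
) -> pd.DataFrame:
    """Stratify each type's specific genes into low/medium/high expression bins.

    Cutpoints are the empirical 33% and 66% quantiles (linear interpolation)
    of the mean expression of the type's specific genes over the type's own
    samples; labels use half-open intervals ``[0, q33)``, ``[q33, q66)``,
    ``[q66, inf)``.
    """
    by_type = _group_samples(groups, expr.samples)
    rows = []
    for cell_type, genes in specific_genes.items():
        if len(genes) < 3:
            raise ValueError(f"{cell_type}: need >= 3 specific genes for tertiles")
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise KeyError(f"{cell_type}: gene(s) not in expression: {missing[:5]}")
        if cell_type not in by_type:
            raise ValueError(f"no samples for cell type {cell_type!r}")
        means = expr.values.loc[genes, by_type[cell_type]].mean(axis=1)
        q33, q66 = np.percentile(means, [33.0, 66.0])
        if q33 == q66:
            logger.warning("%s: degenerate tertile cutpoints (q33 == q66)", cell_type)
        for gene, value in means.items():
            tertile = "low" if value < q33 else ("medium" if value < q66 else "high")
            rows.append(dict(gene=gene, cell_type=cell_type, tertile=tertile))
    return pd.DataFrame(rows)


def contamination_score(
    expr: Expression,
    source_markers: list[str],
    groups: pd.Series,
    source_type: str | None = None,
) -> pd.DataFrame:
    """How much of one type's marker signal shows up in every other group.

    For each cell-type group, reports the mean log2 expression of the source
    markers and the fraction of (marker, sample) pairs with expression > 0.
    The source group's own row serves as the reference level.
    """
    if not source_markers:
        raise ValueError("empty marker list")
    missing = [g for g in source_markers if g not in expr.values.index]
    if missing:
        raise KeyError(f"marker(s) absent from matrix: {missing[:5]}")
    by_type = _group_samples(groups, expr.samples)
    rows = []
    for cell_type in sorted(by_type):
        block = expr.values.loc[source_markers, by_type[cell_type]]
        rows.append(
            dict(
                cell_type=cell_type,
                mean_log2=float(block.to_numpy().mean()),
                frac_positive=float((block.to_numpy() > 0).mean()),
                is_source=(cell_type == source_type),
                n_samples=block.shape[1],
            )
        )
    return pd.DataFrame(rows).set_index("cell_type")


def crossplatform_correlation(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Pearson correlation between two platforms' per-type mean profiles.

    Operates on the inner join of the gene universes.  Inputs are expected
    on the log scale; pass ``log_transform=True`` to apply ``log2(x + 1)``
    to linear-scale matrices first.
    """
    shared = means_a.index.intersection(means_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    a = means_a.loc[shared].astype(float)
    b = means_b.loc[shared].astype(float)
    if log_transform:
        a, b = np.log2(a + 1), np.log2(b + 1)
    corr = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ta in a.columns:
        for tb in b.columns:
            corr.at[ta, tb] = float(np.corrcoef(a[ta], b[tb])[0, 1])
    return corr
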