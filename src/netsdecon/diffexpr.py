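"""Simplified covariate-aware differential expression and age association.

This is deliberately *not* a negative-binomial reimplementation of DESeq2:
each gene is fit by ordinary least squares on log2 per-million expression,
with a t-test on the coefficient of interest and Benjamini-Hochberg
correction across genes.  Hidden (surrogate-like) covariates are estimated
as principal components of the residuals after removing the primary design
— a documented simplification of iterative surrogate-variable analysis.
Downstream stages consume only (baseMean, log2FC, stat, pvalue, padj), so
the interface matches the full pipeline's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from netsdecon.io import Expression

__all__ = [
    "CovariateSet",
    "estimate_hidden_covariates",
    "fit_de",
    "age_association",
    "de_specificity_frequency",
    "write_rnk",
]

DE_COLUMNS = ["baseMean", "log2FC", "stat", "pvalue", "padj"]


@dataclass
class CovariateSet:
    """Observed covariates plus inferred residual-PCA components."""

    observed: pd.DataFrame  # samples x observed covariates (may be empty)
    inferred: pd.DataFrame  # samples x k residual components
    k: int = 0

    def design_columns(self, samples: pd.Index) -> pd.DataFrame:
        parts = []
        if not self.observed.empty:
            parts.append(self.observed.reindex(samples))
        if not self.inferred.empty:
            parts.append(self.inferred.reindex(samples))
        if not parts:
            return pd.DataFrame(index=samples)
        out = pd.concat(parts, axis=1)
        if out.isna().any().any():
            raise ValueError("covariates missing for some samples")
        return out


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode non-numeric covariate columns (first level dropped)."""
    if covariates.empty:
        return covariates
    return pd.get_dummies(covariates, drop_first=True, dtype=float).astype(float)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # locate collinear columns by incremental rank
        collinear = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(
                design[:, :j]
            ):
                collinear.append(names[j])
        raise ValueError(f"design is rank deficient; collinear column(s): {collinear}")


def estimate_hidden_covariates(
    expr: Expression,
    primary_design: pd.DataFrame,
    k: int = 2,
) -> CovariateSet:
    """Residual-PCA estimate of unobserved structure (batch-like effects).

    The primary design (with intercept) is regressed out of every gene;
    the top-``k`` principal components of the residual matrix are returned
    as inferred covariates.  Deterministic: component signs follow the
    PCA convention (largest-magnitude loading entry positive).
    """
    values = expr.values
    samples = values.columns
    design = np.column_stack(
        [np.ones(len(samples)), _encode_covariates(primary_design.reindex(samples)).to_numpy()]
    )
    if len(samples) < design.shape[1] + k + 2:
        raise ValueError(
            f"k={k} too large: {len(samples)} samples for "
            f"{design.shape[1]} design columns"
        )
    names = ["intercept", *primary_design.columns]
    _check_full_rank(design, names)
    y = values.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ beta
    if k == 0:
        return CovariateSet(
            observed=_encode_covariates(primary_design.reindex(samples)),
            inferred=pd.DataFrame(index=samples),
            k=0,
        )
    u, s, vt = np.linalg.svd(residuals - residuals.mean(axis=0), full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    inferred = pd.DataFrame(
        scores * flip, index=samples, columns=[f"SV{i + 1}" for i in range(k)]
    )
    return CovariateSet(
        observed=_encode_covariates(primary_design.reindex(samples)),
        inferred=inferred,
        k=k,
    )


def _fit_lm(
    expr: Expression,
    variable: pd.Series,
    covariates: CovariateSet | pd.DataFrame | None,
    coef_name: str,
) -> pd.DataFrame:
    """Per-gene OLS on log2 expression; t-test on ``variable``'s coefficient."""
    if expr.scale != "log2_pm":
        raise ValueError("expected log2_pm expression")
    values = expr.values
    samples = values.columns
    variable = variable.reindex(samples).astype(float)
    if variable.isna().any():
        raise ValueError("variable missing for some samples")

    if covariates is None:
        extra = pd.DataFrame(index=samples)
    elif isinstance(covariates, CovariateSet):
        extra = covariates.design_columns(samples)
    else:
        extra = _encode_covariates(covariates.reindex(samples))
    design = np.column_stack(
        [np.ones(len(samples)), variable.to_numpy(), extra.to_numpy()]
        if not extra.empty
        else [np.ones(len(samples)), variable.to_numpy()]
    )
    names = ["intercept", coef_name, *extra.columns]
    _check_full_rank(design, names)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"{n} samples cannot support {p} design columns")

    y = values.to_numpy().T  # samples x genes
    pinv = np.linalg.pinv(design)
    beta = pinv @ y
    residuals = y - design @ beta
    dof = n - p
    sigma2 = (residuals**2).sum(axis=0) / dof
    var_coef = np.linalg.inv(design.T @ design)[1, 1]
    se = np.sqrt(sigma2 * var_coef)

    zero_var = values.to_numpy().var(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * scipy.stats.t.sf(np.abs(stat), dof)
    stat = np.where(zero_var, 0.0, stat)
    pvalue = np.where(zero_var, 1.0, pvalue)

    base_mean = expr.to_linear().mean(axis=1).to_numpy()
    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": beta[1],
            "stat": stat,
            "pvalue": pvalue,
            "flag": np.where(zero_var, "zero_variance", ""),
        },
        index=values.index,
    )
    result.loc[zero_var, "log2FC"] = 0.0
    result["padj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    return result[["baseMean", "log2FC", "stat", "pvalue", "padj", "flag"]]


def fit_de(
    expr: Expression,
    condition: pd.Series,
    covariates: CovariateSet | pd.DataFrame | None = None,
    reference: str = "control",
    test_group: str = "AT",
) -> pd.DataFrame:
    """Per-gene linear-model differential expression between two conditions.

    ``log2FC`` is the test-minus-reference difference of log2 means after
    covariate adjustment; ``stat`` the t statistic of that coefficient.
    Genes with zero variance are reported with p = 1 and flagged.
    """
    condition = condition.reindex(expr.samples)
    levels = set(condition.dropna())
    if not {reference, test_group} <= levels:
        raise ValueError(
            f"both conditions must be present; found {sorted(levels)}"
        )
    coded = condition.map({reference: 0.0, test_group: 1.0})
    return _fit_lm(expr, coded, covariates, "condition")


def age_association(
    expr: Expression,
    age: pd.Series,
    covariates: CovariateSet | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene regression of log2 expression on age (slope per year)."""
    age = age.reindex(expr.samples).astype(float)
    distinct = age.dropna().nunique()
    if distinct < 2:
        raise ValueError("age is constant; association undefined")
    if len(age.dropna()) < 4:
        raise ValueError("need >= 4 samples with ages")
    return _fit_lm(expr, age, covariates, "age").rename(
        columns={"log2FC": "slope_per_year"}
    )


def de_specificity_frequency(
    de_results: dict[str, pd.DataFrame],
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Distribution of each cell type's DEGs by how many types share them.

    For every cell type, its significant genes (``padj < threshold``) are
    binned by the number of cell types in which they are significant; genes
    significant in exactly one type are that type's "specific" DEGs.
    """
    if len(de_results) < 2:
        raise ValueError("need DE results for >= 2 cell types")
    significant = {
        cell_type: set(table.index[table["padj"] < padj_threshold])
        for cell_type, table in de_results.items()
    }
    counts: dict[str, int] = {}
    for genes in significant.values():
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    n_types = len(de_results)
    rows = []
    for cell_type, genes in significant.items():
        dist = dict.fromkeys(range(1, n_types + 1), 0)
        for gene in genes:
            dist[counts[gene]] += 1
        total = len(genes)
        rows.append(
            dict(
                cell_type=cell_type,
                n_significant=total,
                frac_specific=(dist[1] / total if total else np.nan),
                **{f"shared_by_{k}": v for k, v in dist.items()},
            )
        )
    return pd.DataFrame(rows).set_index("cell_type")


def write_rnk(de_result: pd.DataFrame, path, stat_column: str = "stat") -> None:
    """Write a GSEA-convention .rnk file (gene TAB stat, descending)."""
    ranked = de_result[stat_column].sort_values(ascending=False)
    ranked.to_csv(path, sep="\t", header=False)
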