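"""Signature-based deconvolution of unsorted bulk-nuclei samples.

Two modes, both least-squares fits against sorted reference signatures:

* **global** — one simplex of fractions per sample against the full
  gene-by-cell-type signature matrix: ``f = argmin ||x - S f||`` subject to
  ``f >= 0`` and ``sum(f) = 1``.
* **comparative** — one two-column panel per target cell type (the target's
  signature vs the unweighted mean of all other signatures); the fitted
  target weight is the sample's "fraction of similarity" to that type.
  Restricting each panel to the target's own specific genes makes the
  fraction linear in the target's true mixing weight: at those genes every
  other cell type shares the same baseline, so composition shifts among the
  remaining types cancel out of the fit.

Genes can be weighted by the inverse of their mean signature expression
(the default), which stops highly expressed transcripts from dominating
the objective under multiplicative noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from netsdecon.io import Expression
from netsdecon.simulate import GroundTruthReference

__all__ = [
    "ComparativePanel",
    "build_signature_matrix",
    "signature_from_reference",
    "solve_simplex_lsq",
    "deconvolve_global",
    "build_comparative_panels",
    "deconvolve_comparative",
    "contrast_conditions",
    "compare_flow_proportions",
]


@dataclass
class ComparativePanel:
    """Two-column reference panel: target signature vs mean of the rest."""

    target: str
    matrix: pd.DataFrame  # genes x ["target", "rest"]


# ---------------------------------------------------------------------------
# Signature construction


def build_signature_matrix(
    expr: Expression,
    metadata: pd.DataFrame,
    genes: list[str] | None = None,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell-type mean linear per-million expression of sorted samples.

    ``metadata`` must map every sample to a cell type; ``genes`` restricts
    the signature to a marker universe (default: all genes).
    """
    if expr.scale != "linear_pm":
        raise ValueError("build_signature_matrix expects linear_pm expression")
    meta = metadata.set_index("sample_id")
    missing = [s for s in expr.samples if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing sample(s): {missing[:5]}")
    labels = meta.loc[list(expr.samples), "cell_type"]
    wanted = cell_types or sorted(set(labels) - {"unsorted"})
    absent = [c for c in wanted if c not in set(labels)]
    if absent:
        raise ValueError(f"no sorted samples for cell type(s): {absent}")
    values = expr.values if genes is None else expr.values.loc[genes]
    columns = {
        cell_type: values[labels.index[labels == cell_type]].mean(axis=1)
        for cell_type in wanted
    }
    signature = pd.DataFrame(columns)
    if (signature.sum(axis=0) <= 0).any():
        bad = signature.columns[signature.sum(axis=0) <= 0].tolist()
        raise ValueError(f"all-zero signature column(s): {bad}")
    return signature


def signature_from_reference(
    ref: GroundTruthReference, genes: list[str] | None = None
) -> pd.DataFrame:
    """Noise-free signature matrix taken from ground-truth profiles (CPM scale)."""
    sig = ref.profiles_pm()
    return sig if genes is None else sig.loc[genes]


# ---------------------------------------------------------------------------
# Simplex-constrained least squares


def _solve_equality_ls(ata: np.ndarray, atb: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ||Af-b|| s.t. sum(f)=1 over the free coordinates (KKT system)."""
    k = free.sum()
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * ata[np.ix_(free, free)]
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * atb[free], [1.0]])
    solution = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    return solution[:k], solution[k]


def solve_simplex_lsq(
    A: np.ndarray, b: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> tuple[np.ndarray, float, bool]:
    """Exact simplex-constrained least squares via primal active set.

    Minimizes ``||A f - b||_2`` subject to ``f >= 0`` and ``sum(f) = 1``.
    The convex QP is solved by iterating equality-constrained KKT solves,
    clamping negative coordinates and re-freeing coordinates whose KKT
    multiplier turns negative; an SLSQP polish is used as fallback if the
    active set fails to settle.

    Returns ``(f, residual_norm, converged)``.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    # condition the system on a common scale; argmin is unchanged
    scale = np.abs(A).mean() or 1.0
    A, b = A / scale, b / scale
    ata = A.T @ A
    atb = A.T @ b

    free = np.ones(n, dtype=bool)
    converged = False
    for _ in range(max_iter):
        f_free, lam = _solve_equality_ls(ata, atb, free)
        if (f_free < -tol).any():
            drop = np.flatnonzero(free)[np.argmin(f_free)]
            free[drop] = False
            if not free.any():
                break
            continue
        f = np.zeros(n)
        f[free] = np.clip(f_free, 0.0, None)
        f /= f.sum()
        # KKT check for clamped coordinates: multiplier mu_i >= 0
        grad = 2.0 * (ata @ f - atb)
        mu = grad + lam
        violated = np.flatnonzero(~free & (mu < -tol * max(1.0, np.abs(grad).max())))
        if violated.size:
            free[violated[np.argmin(mu[violated])]] = True
            continue
        converged = True
        break

    if not converged:
        # fallback: SLSQP polish from the uniform point
        result = scipy.optimize.minimize(
            lambda x: float(np.sum((A @ x - b) ** 2)),
            x0=np.full(n, 1.0 / n),
            jac=lambda x: 2.0 * (ata @ x - atb),
            bounds=[(0.0, 1.0)] * n,
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        f = np.clip(result.x, 0.0, None)
        f /= f.sum()
        converged = bool(result.success)
    residual = float(np.linalg.norm(A @ f - b) * scale)
    return f, residual, converged


def _gene_weights(signature: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "none":
        return np.ones(signature.shape[0])
    if mode == "mean":
        row_mean = signature.mean(axis=1).to_numpy()
        floor = 1e-6 * max(row_mean.mean(), 1e-300)
        return 1.0 / np.maximum(row_mean, floor)
    raise ValueError(f"unknown gene_weighting {mode!r}; use 'mean' or 'none'")


def _as_linear_values(x, genes: pd.Index) -> pd.DataFrame:
    """Align input expression to the signature's gene universe (linear scale)."""
    if isinstance(x, Expression):
        values = x.to_linear()
    elif isinstance(x, pd.DataFrame):
        values = x
    elif isinstance(x, pd.Series):
        values = x.to_frame()
    else:
        raise TypeError("expected Expression, DataFrame or Series")
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"signature gene(s) absent from sample expression: {missing[:5]}")
    return values.loc[list(genes)]


def deconvolve_global(
    x,
    signature: pd.DataFrame,
    gene_weighting: str = "model",
    irls_iter: int = 3,
) -> pd.DataFrame:
    """Estimate per-sample cell-type fractions on the simplex.

    Parameters
    ----------
    x
        Sample expression: an :class:`Expression` (per-million scale; log
        values are inverted), or a genes-by-samples DataFrame already on
        the signature's scale.
    signature
        Genes-by-cell-types reference matrix (linear per-million scale).
    gene_weighting
        ``"model"`` (default) iteratively reweights each gene by the
        inverse of its fitted mixture expression — the efficient weighting
        when noise scales with expression, and unbiased because the
        weights come from the model prediction, not the noisy observation.
        ``"mean"`` weights once by the inverse mean signature expression;
        ``"none"`` fits the raw objective.
    irls_iter
        Reweighting rounds for ``"model"`` (the first round uses
        ``"mean"`` weights).

    Returns
    -------
    DataFrame with one row per sample: the cell-type fractions (summing to
    1), the weighted residual norm, and a convergence flag.
    """
    values = _as_linear_values(x, signature.index)
    start = _gene_weights(signature, "mean" if gene_weighting == "model" else gene_weighting)
    S = signature.to_numpy()
    rows = {}
    for sample in values.columns:
        raw = values[sample].to_numpy()
        weights = start
        f, residual, converged = solve_simplex_lsq(S * weights[:, None], raw * weights)
        if gene_weighting == "model":
            for _ in range(max(0, irls_iter - 1)):
                fitted = S @ f
                weights = 1.0 / (fitted + 0.01 * fitted.mean())
                f, residual, converged = solve_simplex_lsq(
                    S * weights[:, None], raw * weights
                )
        if not converged:
            warnings.warn(f"deconvolution did not converge for sample {sample}")
        rows[sample] = np.concatenate([f, [residual, float(converged)]])
    out = pd.DataFrame(
        rows, index=[*signature.columns, "residual", "converged"]
    ).T
    out["converged"] = out["converged"].astype(bool)
    return out


# ---------------------------------------------------------------------------
# Comparative (target-vs-rest) deconvolution


def build_comparative_panels(
    signature: pd.DataFrame,
    panel_genes: dict[str, list[str]] | None = None,
) -> list[ComparativePanel]:
    """One target-vs-rest panel per cell type.

    Column 2 is the unweighted mean of all other cell types' signatures.
    ``panel_genes`` optionally restricts each panel to a per-target gene
    list (e.g. that type's specific genes from the specificity index); the
    default uses the signature's full gene universe for every panel.
    """
    if signature.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    panels = []
    for target in signature.columns:
        rest = signature.drop(columns=target).mean(axis=1)
        matrix = pd.DataFrame({"target": signature[target], "rest": rest})
        if panel_genes is not None:
            genes = panel_genes[target]
            missing = [g for g in genes if g not in matrix.index]
            if missing:
                raise KeyError(f"{target}: panel gene(s) missing: {missing[:5]}")
            matrix = matrix.loc[genes]
        if np.allclose(matrix["target"], matrix["rest"]):
            raise ValueError(f"{target}: target and rest signatures are identical")
        panels.append(ComparativePanel(target=target, matrix=matrix))
    return panels


def deconvolve_comparative(
    x,
    panel: ComparativePanel,
    gene_weighting: str = "mean",
) -> pd.DataFrame:
    """Fraction of similarity of each sample to the panel's target type.

    The two-component simplex fit has a closed form: the unconstrained
    weight of the target column, clipped to [0, 1] (exact optimum of the
    1-D convex problem).
    """
    matrix = panel.matrix
    values = _as_linear_values(x, matrix.index)
    weights = _gene_weights(matrix, gene_weighting)
    target = matrix["target"].to_numpy() * weights
    rest = matrix["rest"].to_numpy() * weights
    d = target - rest
    denom = float(d @ d)
    rows = {}
    for sample in values.columns:
        b = values[sample].to_numpy() * weights
        f = float(np.clip((b - rest) @ d / denom, 0.0, 1.0))
        residual = float(np.linalg.norm(b - (f * target + (1 - f) * rest)))
        rows[sample] = (f, residual)
    return pd.DataFrame(rows, index=["fraction", "residual"]).T.assign(
        cell_type=panel.target
    )


# ---------------------------------------------------------------------------
# Condition contrasts


def contrast_conditions(
    fractions: pd.DataFrame,
    labels: pd.Series,
    reference: str = "control",
    test_group: str = "AT",
) -> pd.DataFrame:
    """Welch t-test of per-sample fractions between two conditions.

    ``fractions`` is samples by cell types (e.g. stacked comparative
    fractions).  The fold change is the ratio of group means, always
    reported > 1 with an explicit direction: ``mean(reference)/mean(test)``
    for decreases, the inverse for increases.  BH correction runs across
    the cell types of this contrast.
    """
    labels = labels.reindex(fractions.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    ref_rows = fractions[labels == reference]
    test_rows = fractions[labels == test_group]
    if len(ref_rows) < 2 or len(test_rows) < 2:
        raise ValueError("each condition needs >= 2 samples")
    records = []
    for cell_type in fractions.columns:
        a, b = ref_rows[cell_type].to_numpy(), test_rows[cell_type].to_numpy()
        t_stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(p):  # zero variance in both groups
            t_stat, p = 0.0, 1.0
        mean_ref, mean_test = float(a.mean()), float(b.mean())
        if mean_test == 0 or mean_ref == 0:
            fold, direction = np.inf, ("decrease" if mean_test == 0 else "increase")
        elif mean_ref >= mean_test:
            fold, direction = mean_ref / mean_test, "decrease"
        else:
            fold, direction = mean_test / mean_ref, "increase"
        records.append(
            dict(
                cell_type=cell_type,
                mean_control=mean_ref,
                mean_test=mean_test,
                fold=fold,
                direction=direction,
                t=float(t_stat),
                pvalue=float(p),
            )
        )
    result = pd.DataFrame(records).set_index("cell_type")
    result["padj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    return result


def compare_flow_proportions(
    percent_table: pd.DataFrame,
    labels: pd.Series,
    reference: str = "control",
    test_group: str = "AT",
) -> pd.DataFrame:
    """Mann-Whitney U comparison of percentage composition per cell type.

    Exact null distribution when the pooled sample size is <= 20 and there
    are no ties; normal approximation with tie correction otherwise.
    """
    labels = labels.reindex(percent_table.index)
    records = []
    for cell_type in percent_table.columns:
        a = percent_table.loc[labels == reference, cell_type].to_numpy()
        b = percent_table.loc[labels == test_group, cell_type].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"{cell_type}: empty group")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{cell_type}: each group needs >= 2 values")
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            warnings.warn(f"{cell_type}: all values tied; p = 1")
            records.append(
                dict(cell_type=cell_type, U=len(a) * len(b) / 2.0, pvalue=1.0)
            )
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        u_stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        records.append(dict(cell_type=cell_type, U=float(u_stat), pvalue=float(p)))
    result = pd.DataFrame(records).set_index("cell_type")
    result["padj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    return result
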