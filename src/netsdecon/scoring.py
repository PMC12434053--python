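"""Preranked GSEA, gene-set scoring, signature panels and the aging axis.

The GSEA enrichment score is the classic weighted Kolmogorov-Smirnov
running sum: walking down the ranked list, genes in the set add
``|stat|**weight`` (normalized so the hits sum to 1) and genes outside
subtract ``1/(N - n)``; the ES is the running sum's maximum deviation from
zero.  Significance comes from gene-label permutations (random same-size
sets), NES from sign-matched normalization, and FDR from the standard
NES-based pooling across sets.

The gene-set score of a sample is the mean log2 expression over the set's
genes; the group contrast Δ is the difference of mean scores — a log2 fold
change of geometric-mean expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from netsdecon.io import Expression, GeneSetCollection, pca

logger = logging.getLogger(__name__)

__all__ = [
    "build_rank_list",
    "gsea_preranked",
    "build_sets_from_de",
    "gene_set_score",
    "signature_panel_test",
    "AgeAxis",
    "transcriptomic_age_axis",
]


def build_rank_list(de_result: pd.DataFrame, basemean_min: float = 10.0) -> pd.Series:
    """Ranked gene list from a DE table: stat descending, low-expression filtered.

    Genes with ``baseMean`` strictly below ``basemean_min`` are removed to
    reduce noise; ties in the statistic are broken by gene identifier.
    """
    if de_result.empty:
        raise ValueError("empty DE table")
    if de_result.index.has_duplicates:
        dup = de_result.index[de_result.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifier(s): {dup[:5]}")
    kept = de_result[de_result["baseMean"] >= basemean_min]
    if kept.empty:
        raise ValueError(f"all genes filtered at baseMean >= {basemean_min}")
    frame = kept[["stat"]].copy()
    frame["gene"] = frame.index
    frame = frame.sort_values(["stat", "gene"], ascending=[False, True])
    return frame["stat"]


def _step_sizes(stats: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    n_total = stats.size
    n_hits = int(hit_mask.sum())
    hit_weights = np.abs(stats) ** weight
    denom = hit_weights[hit_mask].sum()
    if denom == 0:  # all hit stats zero: fall back to unweighted steps
        hit_weights = np.ones(n_total)
        denom = float(n_hits)
    return np.where(hit_mask, hit_weights / denom, -1.0 / (n_total - n_hits))


def _enrichment_score(
    stats: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """ES of one set on a ranked list; returns (ES, index of the extremum).

    Sequential accumulation (not a vectorized prefix sum) so the score is
    bit-identical to the canonical walk down the list.
    """
    steps = _step_sizes(stats, hit_mask, weight)
    run, best, peak = 0.0, 0.0, 0
    for i, step in enumerate(steps.tolist()):
        run += step
        if abs(run) > abs(best):
            best, peak = run, i
    return best, peak


def _null_es(
    stats: np.ndarray, set_size: int, weight: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n_total = stats.size
    out = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n_total, dtype=bool)
        mask[rng.choice(n_total, set_size, replace=False)] = True
        running = np.cumsum(_step_sizes(stats, mask, weight))
        out[i] = running[np.abs(running).argmax()]
    return out


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Parameters
    ----------
    ranked
        gene -> statistic, ordered descending (see :func:`build_rank_list`).
    sets
        collection to test; sets with fewer than ``min_size`` genes in the
        ranked universe (or covering the whole universe) are skipped with a
        log entry.

    Returns one row per tested set: ES, NES, nominal p, FDR q, set sizes,
    and the leading-edge genes (hits up to the ES extremum).
    """
    genes = list(ranked.index)
    stats = ranked.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_total = len(genes)
    rng = np.random.default_rng(seed)

    records = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        positions = sorted(gene_pos[g] for g in members if g in gene_pos)
        if len(positions) < min_size:
            logger.info("set %s skipped: %d genes in universe < %d", name, len(positions), min_size)
            continue
        if len(positions) >= n_total:
            logger.info("set %s skipped: covers the entire ranked universe", name)
            continue
        mask = np.zeros(n_total, dtype=bool)
        mask[positions] = True
        es, peak = _enrichment_score(stats, mask, weight)
        if len(positions) not in null_by_size:
            null_by_size[len(positions)] = _null_es(
                stats, len(positions), weight, n_perm, rng
            )
        null = null_by_size[len(positions)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            pval, nes = 1.0, 0.0
        else:
            pval = float((np.abs(same_sign) >= abs(es)).mean())
            nes = float(es / np.abs(same_sign).mean())
        if es >= 0:
            leading = [genes[i] for i in positions if i <= peak]
        else:
            leading = [genes[i] for i in positions if i >= peak]
        records.append(
            dict(
                set=name,
                size=len(positions),
                es=es,
                nes=nes,
                pvalue=pval,
                leading_edge=",".join(leading),
                n_perm=n_perm,
                seed=seed,
            )
        )
    result = pd.DataFrame(records)
    if result.empty:
        return result
    result = result.set_index("set")

    # NES-based FDR: pool normalized null scores across all tested sets
    null_nes = []
    for size, null in null_by_size.items():
        pos, neg = null[null >= 0], null[null < 0]
        if pos.size:
            null_nes.append(pos / pos.mean())
        if neg.size:
            null_nes.append(neg / np.abs(neg).mean())
    null_nes = np.concatenate(null_nes)
    obs = result["nes"].to_numpy()
    fdr = np.empty(len(result))
    for i, nes in enumerate(obs):
        if nes >= 0:
            frac_null = (null_nes >= nes).mean() / max((null_nes >= 0).mean(), 1e-12)
            frac_obs = (obs >= nes).mean() / max((obs >= 0).mean(), 1e-12)
        else:
            frac_null = (null_nes <= nes).mean() / max((null_nes < 0).mean(), 1e-12)
            frac_obs = (obs <= nes).mean() / max((obs < 0).mean(), 1e-12)
        fdr[i] = min(1.0, frac_null / max(frac_obs, 1e-12))
    result["fdr"] = fdr
    return result


def build_sets_from_de(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    min_frac: float = 0.25,
    direction: str = "up",
    cluster_column: str | None = None,
) -> GeneSetCollection:
    """Gene sets from an external differential-expression table.

    Keeps genes with ``padj < padj_max`` (strict), ``frac_expressing >=
    min_frac`` (inclusive) and a fold change in the requested direction;
    one set per cluster when ``cluster_column`` is given, a single set
    otherwise.  Required columns: ``gene``, ``padj``, ``frac_expressing``,
    ``log2FC`` (plus the cluster column if named).
    """
    required = ["gene", "padj", "frac_expressing", "log2FC"]
    if cluster_column:
        required.append(cluster_column)
    for column in required:
        if column not in table.columns:
            raise KeyError(f"missing required column: {column!r}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    keep = (
        (table["padj"] < padj_max)
        & (table["frac_expressing"] >= min_frac)
        & ((table["log2FC"] > 0) if direction == "up" else (table["log2FC"] < 0))
    )
    passed = table[keep]
    sets: dict[str, list[str]] = {}
    if cluster_column:
        for cluster, group in passed.groupby(cluster_column):
            genes = list(dict.fromkeys(group["gene"]))
            if genes:
                sets[f"{cluster}_{direction}"] = genes
    else:
        sets[direction] = list(dict.fromkeys(passed["gene"]))
    return GeneSetCollection(sets)


def _sample_scores(expr: Expression, genes: list[str], zscore: bool) -> pd.Series:
    present = [g for g in genes if g in expr.values.index]
    if len(present) < 3:
        raise ValueError(f"only {len(present)} set genes present; need >= 3")
    block = expr.values.loc[present]
    if zscore:
        sd = block.std(axis=1, ddof=1).replace(0.0, 1.0)
        block = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    return block.mean(axis=0)


def gene_set_score(
    expr: Expression,
    sets: GeneSetCollection | dict[str, list[str]],
    groups: pd.Series,
    reference: str = "control",
    test_group: str = "AT",
    zscore: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample gene-set scores and the group contrast per set.

    The score of sample *j* is the mean log2 expression of the set's genes;
    Δ is mean score(test) - mean score(reference), i.e. the log2 fold
    change of the geometric-mean expression.  Welch's t-test per set, BH
    across sets.  ``zscore=True`` standardizes each gene across samples
    before averaging (off by default).

    Returns ``(scores, contrasts)``: samples-by-sets scores and a per-set
    table with delta, t, p and padj.
    """
    if expr.scale != "log2_pm":
        raise ValueError("gene_set_score expects log2_pm expression")
    if isinstance(sets, dict):
        sets = GeneSetCollection(sets)
    groups = groups.reindex(expr.samples)
    ref_samples = groups.index[groups == reference]
    test_samples = groups.index[groups == test_group]
    if len(ref_samples) < 2 or len(test_samples) < 2:
        raise ValueError("each group needs >= 2 samples")

    scores = pd.DataFrame(
        {name: _sample_scores(expr, genes, zscore) for name, genes in sets.items()}
    )
    records = []
    for name in scores.columns:
        a = scores.loc[ref_samples, name].to_numpy()
        b = scores.loc[test_samples, name].to_numpy()
        t_stat, p = scipy.stats.ttest_ind(b, a, equal_var=False)
        if np.isnan(p):
            t_stat, p = 0.0, 1.0
        records.append(
            dict(set=name, delta=float(b.mean() - a.mean()), t=float(t_stat), pvalue=float(p))
        )
    contrasts = pd.DataFrame(records).set_index("set")
    contrasts["padj"] = multipletests(contrasts["pvalue"], method="fdr_bh")[1]
    return scores, contrasts


def signature_panel_test(
    expr: Expression,
    panels: GeneSetCollection | dict[str, list[str]],
    groups: pd.Series,
    reference: str = "control",
    test_group: str = "AT",
) -> pd.DataFrame:
    """Aggregate group comparison of published signature panels (A1/A2/PAN...).

    Per panel, each gene contributes its reference-group and test-group
    mean; the two pooled per-gene mean vectors are compared by a paired
    t-test across genes, alongside the per-sample gene-set-score contrast.
    BH runs across panels.
    """
    if isinstance(panels, dict):
        panels = GeneSetCollection(panels)
    scores, score_contrasts = gene_set_score(
        expr, panels, groups, reference=reference, test_group=test_group
    )
    groups = groups.reindex(expr.samples)
    ref_samples = groups.index[groups == reference]
    test_samples = groups.index[groups == test_group]
    records = []
    for name, genes in panels.items():
        present = [g for g in genes if g in expr.values.index]
        ref_means = expr.values.loc[present, ref_samples].mean(axis=1)
        test_means = expr.values.loc[present, test_samples].mean(axis=1)
        t_stat, p = scipy.stats.ttest_rel(test_means, ref_means)
        if np.isnan(p):
            t_stat, p = 0.0, 1.0
        records.append(
            dict(
                panel=name,
                n_genes=len(present),
                delta=score_contrasts.at[name, "delta"],
                t_score=score_contrasts.at[name, "t"],
                t_paired=float(t_stat),
                pvalue=float(p),
            )
        )
    result = pd.DataFrame(records).set_index("panel")
    result["padj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    return result


@dataclass
class AgeAxis:
    """PC1 of age-associated genes as a transcriptomic age coordinate.

    The axis is oriented so the control-donor regression of PC1 on age has
    a positive slope.  ``acceleration_years`` maps the mean disease-group
    PC1 position onto the control age line and subtracts the group's mean
    chronological age: how many years "older" the disease samples look.
    """

    genes: list[str]
    pc1: pd.Series  # per sample
    control_slope: float
    control_intercept: float
    control_r: float
    condition_fits: pd.DataFrame  # per condition: slope, intercept, r, n
    acceleration_years: float  # nan when flagged
    flagged: bool


def transcriptomic_age_axis(
    expr: Expression,
    age_table: pd.DataFrame,
    age: pd.Series,
    condition: pd.Series,
    padj_max: float = 0.05,
    reference: str = "control",
    test_group: str = "AT",
) -> AgeAxis:
    """Build the aging axis from significant age-associated genes.

    ``age_table`` is an :func:`netsdecon.diffexpr.age_association` result
    (fit on control donors); genes with ``padj < padj_max`` define the
    axis.  PCA runs over *all* samples; the control fit and the
    acceleration summary follow the orientation rule, which makes the
    result invariant to loading sign flips.  If the control correlation is
    weak (|r| < 0.3) the acceleration is undefined and flagged.
    """
    significant = sorted(age_table.index[age_table["padj"] < padj_max])
    if len(significant) < 5:
        raise ValueError(f"only {len(significant)} significant age genes; need >= 5")
    age = age.reindex(expr.samples).astype(float)
    condition = condition.reindex(expr.samples)
    control_ages = age[condition == reference]
    if control_ages.max() - control_ages.min() < 20:
        raise ValueError("control donors must span >= 20 years of age")

    result = pca(expr, genes=significant, n_components=1)
    pc1 = result.scores["PC1"]

    ctrl = condition == reference
    fit = scipy.stats.linregress(age[ctrl], pc1[ctrl])
    slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    if slope < 0:  # orient the axis so control PC1 increases with age
        pc1 = -pc1
        slope, intercept, r = -slope, -intercept, -r

    fits = []
    for level in (reference, test_group):
        mask = condition == level
        if mask.sum() >= 3:
            f = scipy.stats.linregress(age[mask], pc1[mask])
            fits.append(
                dict(condition=level, slope=float(f.slope), intercept=float(f.intercept),
                     r=float(f.rvalue), n=int(mask.sum()))
            )
    condition_fits = pd.DataFrame(fits).set_index("condition")

    flagged = abs(r) < 0.3
    if flagged:
        logger.warning("control PC1-age correlation weak (r=%.2f); acceleration undefined", r)
        acceleration = float("nan")
    else:
        at_mask = condition == test_group
        apparent_age = (pc1[at_mask].mean() - intercept) / slope
        acceleration = float(apparent_age - age[at_mask].mean())
    return AgeAxis(
        genes=significant,
        pc1=pc1,
        control_slope=slope,
        control_intercept=intercept,
        control_r=r,
        condition_fits=condition_fits,
        acceleration_years=acceleration,
        flagged=flagged,
    )
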