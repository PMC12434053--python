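import numpy as np
import pandas as pd
import pytest

from netsdecon import (
    age_association,
    build_rank_list,
    build_sets_from_de,
    gene_set_score,
    gsea_preranked,
    make_reference,
    normalize,
    signature_panel_test,
    simulate_age_cohort,
    transcriptomic_age_axis,
)
from netsdecon.io import Expression, GeneSetCollection

from conftest import log_expression


def brute_force_es(ranked: pd.Series, members, weight: float = 1.0) -> float:
    """Independent O(N*|S|) running-sum enrichment score (test oracle).

    The hit normalizer is the numpy sum of the hit weights in list order —
    the canonical arithmetic — so agreement with the implementation can be
    checked for exact equality.
    """
    in_set = set(members) & set(ranked.index)
    nr = float(
        np.array([abs(s) ** weight for g, s in ranked.items() if g in in_set]).sum()
    )
    n, N = len(in_set), len(ranked)
    run, best = 0.0, 0.0
    for gene, stat in ranked.items():
        if gene in in_set:
            run += (abs(stat) ** weight / nr) if nr > 0 else 1.0 / n
        else:
            run -= 1.0 / (N - n)
        if abs(run) > abs(best):
            best = run
    return best


def _random_ranked(rng, n):
    stats = np.sort(rng.normal(size=n))[::-1]
    return pd.Series(stats, index=[f"g{i:04d}" for i in range(n)])


class TestBuildRankList:
    def test_strict_basemean_filter(self):
        table = pd.DataFrame(
            {"baseMean": [12.0, 9.0, 10.0, 3.0, 100.0],
             "stat": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=["g1", "g2", "g3", "g4", "g5"],
        )
        ranked = build_rank_list(table)
        assert set(ranked.index) == {"g1", "g3", "g5"}  # strict < 10 removes g2, g4
        assert list(ranked.index) == ["g5", "g3", "g1"]  # stat descending

    def test_no_filter_pure_stat_sort_with_gene_ties(self):
        table = pd.DataFrame(
            {"baseMean": [20.0] * 4, "stat": [1.0, 3.0, 1.0, 2.0]},
            index=["gd", "ga", "gb", "gc"],
        )
        ranked = build_rank_list(table)
        assert list(ranked.index) == ["ga", "gc", "gb", "gd"]  # tie gb<gd by ID

    def test_duplicate_genes_rejected(self):
        table = pd.DataFrame({"baseMean": [20.0, 20.0], "stat": [1.0, 2.0]},
                             index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate"):
            build_rank_list(table)

    def test_everything_filtered_rejected(self):
        table = pd.DataFrame({"baseMean": [1.0], "stat": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="filtered"):
            build_rank_list(table)


class TestGseaPreranked:
    def test_top_two_genes_hand_enumerable(self):
        # 10 genes, equal |stat|; set = top 2: running sum peaks at 1.0
        ranked = pd.Series(np.ones(10), index=[f"g{i}" for i in range(10)])
        sets = GeneSetCollection({"top": ["g0", "g1", "g2", "g3", "g4"]})
        result = gsea_preranked(ranked, sets, n_perm=50, seed=1)
        assert result.loc["top", "es"] == pytest.approx(1.0)
        assert result.loc["top", "es"] == pytest.approx(
            brute_force_es(ranked, sets["top"])
        )

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(20, 300))
            ranked = _random_ranked(rng, n)
            size = int(rng.integers(5, max(6, n // 3)))
            members = list(rng.choice(ranked.index, size, replace=False))
            result = gsea_preranked(ranked, GeneSetCollection({"s": members}),
                                    n_perm=2, seed=0)
            assert result.loc["s", "es"] == pytest.approx(
                brute_force_es(ranked, members), abs=1e-12
            )

    def test_whole_universe_set_skipped(self):
        ranked = _random_ranked(np.random.default_rng(1), 20)
        sets = GeneSetCollection({"all": list(ranked.index), "ok": list(ranked.index[:6])})
        result = gsea_preranked(ranked, sets, n_perm=20, seed=0)
        assert "all" not in result.index and "ok" in result.index

    def test_small_set_skipped(self):
        ranked = _random_ranked(np.random.default_rng(2), 50)
        sets = GeneSetCollection({"tiny": list(ranked.index[:2])})
        result = gsea_preranked(ranked, sets, n_perm=20, seed=0)
        assert result.empty

    def test_leading_edge_subset_of_hits(self):
        rng = np.random.default_rng(3)
        ranked = _random_ranked(rng, 100)
        members = list(rng.choice(ranked.index, 15, replace=False))
        result = gsea_preranked(ranked, GeneSetCollection({"s": members}),
                                n_perm=20, seed=0)
        leading = result.loc["s", "leading_edge"].split(",")
        assert set(leading) <= set(members)
        assert len(leading) >= 1

    def test_seeded_reproducibility_and_q_stability(self):
        rng = np.random.default_rng(4)
        ranked = _random_ranked(rng, 300)
        members = list(ranked.index[:20])  # planted at the very top
        sets = GeneSetCollection({"planted": members})
        a = gsea_preranked(ranked, sets, n_perm=500, seed=9)
        b = gsea_preranked(ranked, sets, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = gsea_preranked(ranked, sets, n_perm=1000, seed=9)
        assert abs(a.loc["planted", "fdr"] - c.loc["planted", "fdr"]) < 0.02


class TestBuildSetsFromDe:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene", "padj", "frac_expressing", "log2FC"])

    def test_boundary_rows(self):
        table = self._table(
            [("gA", 0.04, 0.25, 1.0),   # in: frac >= 0.25 inclusive
             ("gB", 0.05, 0.90, 1.0),   # out: padj strict < 0.05
             ("gC", 0.01, 0.24, 1.0),   # out: frac below
             ("gD", 0.01, 0.50, -1.0)]  # out: wrong direction
        )
        sets = build_sets_from_de(table, direction="up")
        assert sets["up"] == ["gA"]

    def test_ten_row_manual_filter_oracle(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"g{i}", float(rng.choice([0.01, 0.04, 0.05, 0.2])),
             float(rng.choice([0.1, 0.25, 0.6])), float(rng.choice([-2.0, 1.5])))
            for i in range(10)
        ]
        table = self._table(rows)
        expected = [g for g, padj, frac, fc in rows
                    if padj < 0.05 and frac >= 0.25 and fc > 0]
        assert build_sets_from_de(table, direction="up")["up"] == expected

    def test_cluster_column_one_set_per_cluster(self):
        table = self._table(
            [("g1", 0.01, 0.5, 1.0), ("g2", 0.01, 0.5, 1.0), ("g3", 0.01, 0.5, 1.0)]
        ).assign(state=["MG00", "MG01", "MG00"])
        sets = build_sets_from_de(table, direction="up", cluster_column="state")
        assert sets["MG00_up"] == ["g1", "g3"] and sets["MG01_up"] == ["g2"]

    def test_missing_column_named(self):
        table = self._table([("g1", 0.01, 0.5, 1.0)]).drop(columns="frac_expressing")
        with pytest.raises(KeyError, match="frac_expressing"):
            build_sets_from_de(table)


class TestGeneSetScore:
    @staticmethod
    def _groups(n_ref, n_test):
        idx = [f"s{i}" for i in range(n_ref + n_test)]
        return pd.Series(["control"] * n_ref + ["AT"] * n_test, index=idx), idx

    def test_identical_groups_delta_zero(self):
        groups, idx = self._groups(3, 3)
        values = pd.DataFrame(np.tile([[1.0], [2.0], [3.0]], (1, 6)),
                              index=["g1", "g2", "g3"], columns=idx)
        scores, contrasts = gene_set_score(log_expression(values),
                                           {"s": ["g1", "g2", "g3"]}, groups)
        assert contrasts.loc["s", "delta"] == 0.0
        assert contrasts.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_doubling_linear_scale_gives_delta_one(self):
        groups, idx = self._groups(3, 3)
        rng = np.random.default_rng(6)
        base = rng.normal(5, 1, (4, 3))
        values = pd.DataFrame(np.hstack([base, base + 1.0]),  # +1 log2 = x2 linear
                              index=["g1", "g2", "g3", "g4"], columns=idx)
        _, contrasts = gene_set_score(log_expression(values),
                                      {"s": ["g1", "g2", "g3", "g4"]}, groups)
        assert contrasts.loc["s", "delta"] == pytest.approx(1.0, abs=1e-12)

    def test_printed_toy_matches_hand_arithmetic(self):
        # 3-gene set, 2+2 samples; scores are plain means, Welch t by formula
        groups, idx = self._groups(2, 2)
        values = pd.DataFrame(
            [[1.0, 2.0, 4.0, 5.0], [3.0, 4.0, 6.0, 7.0], [2.0, 3.0, 5.0, 6.0]],
            index=["g1", "g2", "g3"], columns=idx,
        )
        scores, contrasts = gene_set_score(log_expression(values),
                                           {"s": ["g1", "g2", "g3"]}, groups)
        np.testing.assert_allclose(scores["s"], [2.0, 3.0, 5.0, 6.0])
        assert contrasts.loc["s", "delta"] == pytest.approx(3.0)
        # groups (2,3) vs (5,6): pooled se = sqrt(0.5/2+0.5/2)
        assert contrasts.loc["s", "t"] == pytest.approx(3.0 / np.sqrt(0.5))

    def test_invariant_to_per_gene_constant(self):
        groups, idx = self._groups(3, 3)
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(5, 1, (5, 6)),
                              index=[f"g{i}" for i in range(5)], columns=idx)
        shifted = values.add(pd.Series(rng.normal(0, 3, 5), index=values.index), axis=0)
        _, a = gene_set_score(log_expression(values), {"s": list(values.index)}, groups)
        _, b = gene_set_score(log_expression(shifted), {"s": list(values.index)}, groups)
        assert a.loc["s", "delta"] == pytest.approx(b.loc["s", "delta"], abs=1e-12)

    def test_too_few_present_genes_rejected(self):
        groups, idx = self._groups(2, 2)
        values = pd.DataFrame(np.ones((5, 4)), index=[f"g{i}" for i in range(5)],
                              columns=idx)
        with pytest.raises(ValueError, match=">= 3"):
            gene_set_score(log_expression(values), {"s": ["g0", "g1", "nope"]}, groups)


class TestSignaturePanelTest:
    def test_planted_panels_signs_and_significance(self):
        rng = np.random.default_rng(8)
        n_ref, n_test = 10, 10
        idx = [f"s{i}" for i in range(n_ref + n_test)]
        groups = pd.Series(["control"] * n_ref + ["AT"] * n_test, index=idx)
        genes = [f"g{i}" for i in range(60)]
        base = rng.normal(5, 0.5, (60, 20))
        values = pd.DataFrame(base, index=genes, columns=idx)
        up = np.log2(1.5)
        values.iloc[:20, n_ref:] += up    # panel A1-like: x1.5 in AT
        values.iloc[40:, n_ref:] += up    # third panel also up
        panels = {"A1": genes[:20], "PAN": genes[20:40], "A2": genes[40:]}
        result = signature_panel_test(log_expression(values), panels, groups)
        assert result.loc["A1", "delta"] > 0 and result.loc["A1", "padj"] < 0.01
        assert abs(result.loc["PAN", "delta"]) < 0.2
        assert result.loc["A2", "delta"] > 0
        assert len(result) == 3  # BH family is the three panels


class TestTranscriptomicAgeAxis:
    @staticmethod
    def _cohort(offset, seed=30):
        ref = make_reference(n_genes=800, markers_per_type=5, seed=seed)
        counts, meta, truth = simulate_age_cohort(
            ref, n_control=20, n_at=10, n_age_genes=100, slope_per_year=0.05,
            at_transcriptomic_offset=offset, seed=seed + 1,
        )
        expr = normalize(counts, log=True)
        indexed = meta.set_index("sample_id")
        controls = indexed.index[indexed["condition"] == "control"]
        control_expr = normalize(counts[list(controls)], log=True)
        table = age_association(control_expr, indexed.loc[controls, "age"])
        axis = transcriptomic_age_axis(expr, table, indexed["age"],
                                       indexed["condition"])
        return axis, expr, table, indexed

    def test_accelerated_cohort_recovers_offset(self):
        axis, *_ = self._cohort(offset=50.0)
        assert not axis.flagged
        assert axis.acceleration_years == pytest.approx(50.0, abs=10.0)

    def test_on_line_cohort_acceleration_near_zero(self):
        axis, *_ = self._cohort(offset=0.0, seed=60)
        assert abs(axis.acceleration_years) < 10.0

    def test_loading_sign_flip_leaves_acceleration_unchanged(self):
        axis, expr, table, indexed = self._cohort(offset=50.0)
        mirrored = Expression(-expr.values, "log2_pm")
        flipped = transcriptomic_age_axis(mirrored, table, indexed["age"],
                                          indexed["condition"])
        assert flipped.acceleration_years == pytest.approx(
            axis.acceleration_years, abs=1e-6
        )

    def test_too_few_significant_genes_rejected(self):
        axis, expr, table, indexed = self._cohort(offset=50.0)
        dead = table.copy()
        dead["padj"] = 1.0
        with pytest.raises(ValueError, match="significant age genes"):
            transcriptomic_age_axis(expr, dead, indexed["age"], indexed["condition"])
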