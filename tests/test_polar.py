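import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from operonpolar import (
    GeneAnnotation,
    OperonStructure,
    classify_operon_effects,
    concordance,
    distance_correlation,
    downstream_gene_test,
    operon_median_correction,
    position_fold_changes,
    summarize_classes,
)


def fc_table(rows):
    """rows: (gene_id, mutant_id, log2fc)"""
    df = pd.DataFrame(rows, columns=["gene_id", "mutant_id", "log2fc"])
    df["condition"] = "cassette"
    df["datatype"] = "protein"
    df["n_replicates"] = 1
    return df


def positioned(rows, datatype="protein"):
    """rows: (mutant_id, position, log2fc[, corrected, distance])"""
    full = [(r + (np.nan,) * (5 - len(r))) for r in rows]
    df = pd.DataFrame(full, columns=["mutant_id", "position", "log2fc",
                                     "corrected_log2fc", "intergenic_distance"])
    df["gene_id"] = [f"g{i}" for i in range(len(df))]
    df["condition"] = "cassette"
    df["datatype"] = datatype
    return df


class TestPositionFoldChanges:
    def test_positions_and_distance(self, abc_annotations, abc_operons):
        fc = fc_table([("geneA", "dB", 0.1), ("geneC", "dB", -0.5)])
        pos, ctrl = position_fold_changes(
            fc, abc_operons, {"dB": "geneB"}, abc_annotations
        )
        by_gene = pos.set_index("gene_id")
        assert by_gene.loc["geneA", "position"] == -1
        assert by_gene.loc["geneC", "position"] == 1
        # distance geneB end=2149 -> geneC start=2200: 50 nt
        assert by_gene.loc["geneC", "intergenic_distance"] == 50
        assert np.isnan(by_gene.loc["geneA", "intergenic_distance"])
        assert ctrl.empty

    def test_single_gene_operon_routed_to_controls(self, abc_annotations, abc_operons):
        fc = fc_table([("geneX", "dX", 0.2), ("geneA", "dX", 0.0)])
        pos, ctrl = position_fold_changes(
            fc, abc_operons, {"dX": "geneX"}, abc_annotations
        )
        assert pos.empty
        assert set(ctrl["gene_id"]) == {"geneX", "geneA"}

    def test_position_zero_row_absent(self):
        genes = {
            f"g{i}": GeneAnnotation(f"g{i}", "c", 1 + 1000 * i, 900 + 1000 * i, "+")
            for i in range(6)
        }
        ops = {"op": OperonStructure("op", tuple(f"g{i}" for i in range(6)))}
        fc = fc_table([(f"g{i}", "dC", 0.1 * i) for i in range(6)])
        pos, _ = position_fold_changes(fc, ops, {"dC": "g2"}, genes)
        assert sorted(pos["position"]) == [-2, -1, 1, 2, 3]
        assert 0 not in set(pos["position"])

    def test_unknown_deleted_gene_is_error(self, abc_annotations, abc_operons):
        fc = fc_table([("geneA", "dZ", 0.0)])
        with pytest.raises(ValueError, match="dZ"):
            position_fold_changes(fc, abc_operons, {"dZ": "ghost"}, abc_annotations)

    def test_exclusion_list_drops_mutant(self, abc_annotations, abc_operons):
        fc = fc_table([("geneA", "dB", 0.1), ("geneC", "dB", -0.5)])
        pos, ctrl = position_fold_changes(
            fc, abc_operons, {"dB": "geneB"}, abc_annotations,
            exclude_mutants={"dB"},
        )
        assert pos.empty and ctrl.empty


class TestMedianCorrection:
    def test_downstream_median_subtracted(self):
        t = positioned([("m", 1, -1.5), ("m", 2, -0.4), ("m", 3, -0.6)])
        out = operon_median_correction(t).set_index("position")
        assert out.loc[1, "corrected_log2fc"] == pytest.approx(-0.9)
        assert out.loc[2, "corrected_log2fc"] == pytest.approx(0.2)
        assert out.loc[3, "corrected_log2fc"] == pytest.approx(0.0)

    def test_single_downstream_gene_not_corrected(self):
        t = positioned([("m", 1, -1.5)])
        out = operon_median_correction(t, min_genes=2)
        assert out["corrected_log2fc"].isna().all()

    def test_corrected_side_median_is_zero(self):
        rng = np.random.default_rng(0)
        rows = [("m", p, v) for p, v in zip([-3, -2, -1, 1, 2, 3, 4],
                                            rng.normal(size=7))]
        out = operon_median_correction(positioned(rows))
        up = out[out["position"] < 0]["corrected_log2fc"]
        down = out[out["position"] > 0]["corrected_log2fc"]
        assert np.median(up) == pytest.approx(0.0, abs=1e-15)
        assert np.median(down) == pytest.approx(0.0, abs=1e-15)

    def test_upstream_and_downstream_corrected_independently(self):
        t = positioned([("m", -2, 1.0), ("m", -1, 3.0), ("m", 1, -1.0), ("m", 2, -2.0)])
        out = operon_median_correction(t).set_index("position")
        assert out.loc[-2, "corrected_log2fc"] == pytest.approx(-1.0)
        assert out.loc[-1, "corrected_log2fc"] == pytest.approx(1.0)
        assert out.loc[1, "corrected_log2fc"] == pytest.approx(0.5)

    def test_exclude_p1_from_downstream_median(self):
        t = positioned([("m", 1, -2.0), ("m", 2, -0.4), ("m", 3, -0.6)])
        out = operon_median_correction(
            t, include_p1_in_downstream_median=False
        ).set_index("position")
        # reference median over positions >= 2 only: -0.5
        assert out.loc[1, "corrected_log2fc"] == pytest.approx(-1.5)
        assert out.loc[2, "corrected_log2fc"] == pytest.approx(0.1)


class TestClassification:
    def test_up_classification(self):
        t = positioned([("m", 1, 0.0), ("m", 2, 1.4), ("m", 3, 1.2)])
        cls = classify_operon_effects(t)
        row = cls.iloc[0]
        assert row["class"] == "up"
        assert row["median_downstream_excl_p1"] == pytest.approx(1.3)

    def test_small_effect_is_none(self):
        t = positioned([("m", 2, -0.5)])
        assert classify_operon_effects(t).iloc[0]["class"] == "none"

    def test_no_genes_beyond_p1_not_evaluable(self):
        t = positioned([("m", 1, -3.0)])
        assert classify_operon_effects(t).iloc[0]["class"] == "not_evaluable"

    def test_invariant_to_p1_value(self):
        base = [("m", 2, 1.4), ("m", 3, 1.2)]
        for p1 in (-5.0, 0.0, 5.0):
            t = positioned([("m", 1, p1)] + base)
            assert classify_operon_effects(t).iloc[0]["class"] == "up"

    def test_threshold_is_strict(self):
        t = positioned([("m", 2, 1.0), ("m", 3, 1.0)])
        assert classify_operon_effects(t, threshold_log2=1.0).iloc[0]["class"] == "none"

    def test_summary_fractions(self):
        t = positioned([("m1", 2, 1.4), ("m2", 2, -1.7), ("m3", 2, 0.1), ("m4", 1, 0.0)])
        s = summarize_classes(classify_operon_effects(t))
        assert s["n_evaluable"] == 3
        assert s["fraction_up"] == pytest.approx(1 / 3)
        assert s["fraction_down"] == pytest.approx(1 / 3)


class TestDownstreamGeneTest:
    def test_one_sided_exact_p_for_separated_groups(self):
        rows = [("m1", 1, 1.0), ("m2", 1, 2.0), ("m3", 1, 3.0),
                ("m4", 2, 4.0), ("m5", 2, 5.0), ("m6", 2, 6.0)]
        res = downstream_gene_test(positioned(rows), alternative="less")
        # all 3 "+1" values below all 3 others: 1 of C(6,3)=20 assignments
        assert res.p_value == pytest.approx(1 / 20)
        assert res.method == "wilcoxon_rank_sum_exact"

    def test_equal_groups_give_p_near_one(self):
        rows = [("m1", 1, 0.5), ("m2", 1, 0.7), ("m3", 2, 0.5), ("m4", 2, 0.7)]
        res = downstream_gene_test(positioned(rows))
        assert res.p_value > 0.9

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=4), rng.normal(size=5)
        rows = [("m%d" % i, 1, v) for i, v in enumerate(x)]
        rows += [("n%d" % i, 2, v) for i, v in enumerate(y)]
        res = downstream_gene_test(positioned(rows))
        # brute force: enumerate all label assignments of the pooled values
        pooled = np.concatenate([x, y])
        u_obs = sum((xi > yj) for xi in x for yj in y)
        us = [
            sum((pooled[i] > pooled[j]) for i in comb
                for j in range(9) if j not in comb)
            for comb in itertools.combinations(range(9), 4)
        ]
        mu = len(x) * len(y) / 2
        p_brute = np.mean([abs(u - mu) >= abs(u_obs - mu) for u in us])
        assert res.p_value == pytest.approx(p_brute, abs=1e-12)

    def test_exact_and_asymptotic_agree_for_n6(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y = rng.normal(size=6), rng.normal(size=6)
            pe = stats.mannwhitneyu(x, y, method="exact").pvalue
            pa = stats.mannwhitneyu(x, y, method="asymptotic",
                                    use_continuity=True).pvalue
            assert abs(pe - pa) <= 0.02

    def test_median_linear_fold_change_reported(self):
        rows = [("m1", 1, -1.0), ("m2", 1, -1.0), ("m3", 2, 0.0), ("m4", 2, 0.0)]
        res = downstream_gene_test(positioned(rows))
        assert res.extra["median_linear_fc_p1"] == pytest.approx(0.5)

    def test_signed_rank_variant(self):
        rows = [("m%d" % i, 1, v) for i, v in enumerate([-0.5, -0.8, -0.3, -0.9, -0.2])]
        rows += [("x", 2, 0.0)]
        res = downstream_gene_test(positioned(rows), method="signed_rank")
        assert res.method == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(1 / 16)  # all-negative exact one... two-sided: 2/32

    def test_corrected_mode_uses_corrected_column(self):
        rows = [("m1", 1, -9.0, -1.0), ("m2", 1, -9.0, -1.2),
                ("m3", 2, -9.0, 0.1), ("m4", 2, -9.0, 0.0), ("m5", 3, -9.0, -0.1)]
        res = downstream_gene_test(positioned(rows), use_corrected=True)
        assert res.n1 == 2 and res.n2 == 3
        assert res.extra["median_linear_fc_p1"] == pytest.approx(2.0 ** -1.1)

    def test_empty_comparison_group_is_error(self):
        with pytest.raises(ValueError, match=">= \\+2"):
            downstream_gene_test(positioned([("m", 1, -1.0)]))


class TestDistanceCorrelation:
    @staticmethod
    def _pairs(corr_dist):
        return positioned([
            ("m%d" % i, 1, np.nan, c, d) for i, (c, d) in enumerate(corr_dist)
        ])

    def test_perfectly_monotone_is_one(self):
        t = self._pairs([(-2.0, 0), (-1.0, 10), (-0.5, 50), (-0.1, 200)])
        assert distance_correlation(t).statistic == pytest.approx(1.0)

    def test_reversed_order_is_minus_one(self):
        t = self._pairs([(-0.1, 0), (-0.5, 10), (-1.0, 50), (-2.0, 200)])
        assert distance_correlation(t).statistic == pytest.approx(-1.0)

    def test_ties_match_brute_force_average_ranks(self):
        pairs = [(-1.0, 5), (-1.0, 12), (-0.4, 12), (0.2, 40), (-0.2, 90)]
        t = self._pairs(pairs)
        rho = distance_correlation(t).statistic

        def avg_ranks(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx = avg_ranks([c for c, _ in pairs])
        ry = avg_ranks([d for _, d in pairs])
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="at least 4"):
            distance_correlation(self._pairs([(-1.0, 5), (-0.5, 10), (0.0, 20)]))


class TestConcordance:
    @staticmethod
    def _fc(values, datatype="protein"):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(values))],
            "mutant_id": ["m"] * len(values),
            "condition": "cassette",
            "datatype": datatype,
            "log2fc": values,
        })

    def test_identical_tables_r_one(self):
        a = self._fc([0.1, -0.5, 1.2, 0.7])
        assert concordance(a, self._fc([0.1, -0.5, 1.2, 0.7], "rna")).statistic == pytest.approx(1.0)

    def test_negated_table_r_minus_one(self):
        a = self._fc([0.1, -0.5, 1.2, 0.7])
        b = self._fc([-0.1, 0.5, -1.2, -0.7], "rna")
        assert concordance(a, b).statistic == pytest.approx(-1.0)

    def test_too_few_pairs_is_error(self):
        a = self._fc([0.1, 0.2])
        with pytest.raises(ValueError, match="at least 3"):
            concordance(a, self._fc([0.3, 0.4], "rna"))

    def test_recovers_latent_correlation_at_large_n(self):
        rng = np.random.default_rng(123)
        n = 10_000
        z = rng.normal(size=n)
        a_vals = 0.7 * z + np.sqrt(1 - 0.49) * rng.normal(size=n)
        df_a = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)], "mutant_id": "m",
            "log2fc": a_vals,
        })
        df_b = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)], "mutant_id": "m",
            "log2fc": z,
        })
        r = concordance(df_a, df_b).statistic
        assert abs(r - 0.7) < 0.02


def test_spearman_pearson_match_brute_force_small_inputs():
    """Library correlations equal the rank/moment formulas on all sizes <= 8."""
    rng = np.random.default_rng(9)
    for n in range(4, 9):
        for _ in range(20):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r_lib = stats.pearsonr(x, y)[0]
            r_brute = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert r_lib == pytest.approx(r_brute, abs=1e-12)
            rho_lib = stats.spearmanr(x, y)[0]
            rx = np.argsort(np.argsort(x))
            ry = np.argsort(np.argsort(y))
            rho_brute = np.corrcoef(rx, ry)[0, 1]
            assert rho_lib == pytest.approx(rho_brute, abs=1e-12)
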