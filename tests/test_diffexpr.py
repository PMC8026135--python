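"""Normalization and DE: size-factor identities, BH step-up against a
brute-force oracle, Wald-test degenerate cases, strict filters, top-N
ranking, QC boundaries, and rank-sum exactness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regiosig.containers import ConfigError, CountMatrix, DEResult
from regiosig.diffexpr import (
    bh_adjust,
    deg_filter,
    log_normalize,
    nb_wald_test,
    sc_qc_filter,
    size_factors_median_of_ratios,
    top_n_enriched,
    wilcoxon_de,
)
from conftest import make_matrix


class TestSizeFactors:
    def test_identical_columns_are_unit(self):
        m = make_matrix([[10, 10], [30, 30], [7, 7]])
        np.testing.assert_allclose(size_factors_median_of_ratios(m).factors, 1.0)

    def test_hand_computed_two_by_two(self):
        # geometric means sqrt(200), sqrt(1800); within-sample ratios constant
        m = make_matrix([[10, 20], [30, 60]])
        np.testing.assert_allclose(
            size_factors_median_of_ratios(m).factors,
            [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12,
        )

    def test_doubling_one_column_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 500, size=(50, 6))
        base = size_factors_median_of_ratios(make_matrix(counts)).factors
        doubled = counts.copy()
        doubled[:, 3] *= 2
        new = size_factors_median_of_ratios(make_matrix(doubled)).factors

        # brute-force recomputation of the expected factors
        logref = np.mean(np.log(doubled), axis=1)
        expect = np.exp(np.median(np.log(doubled) - logref[:, None], axis=0))
        np.testing.assert_allclose(new, expect, rtol=1e-12)
        # the scaled column doubles relative to the (rescaled) others
        np.testing.assert_allclose(new[3] / new[0], 2 * base[3] / base[0], rtol=1e-9)

    def test_no_reference_gene_is_an_error(self):
        m = make_matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="no reference genes"):
            size_factors_median_of_ratios(m)

    def test_matches_pydeseq2_on_fixture(self):
        """Independent oracle: DESeq2's median-of-ratios implementation."""
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 1000, size=(40, 5))
        ours = size_factors_median_of_ratios(make_matrix(counts)).factors
        _, theirs = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))
        np.testing.assert_allclose(ours, np.asarray(theirs), rtol=1e-9)

    def test_depth_rescaled_clone_normalizes_back(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(10, 400, size=(60, 4))
        scaled = counts.copy()
        scaled[:, 2] = counts[:, 2] * 3
        m = make_matrix(scaled)
        s = size_factors_median_of_ratios(m)
        norm = scaled / s.factors[None, :]
        base = counts / size_factors_median_of_ratios(make_matrix(counts)).factors
        np.testing.assert_allclose(norm[:, 2] / norm[:, 0], base[:, 2] / base[:, 0],
                                   rtol=1e-9)


class TestLogNormalize:
    def test_closed_forms(self):
        m = make_matrix([[0], [7]])
        out = log_normalize(m)
        assert out.iloc[0, 0] == pytest.approx(0.0)
        assert out.iloc[1, 0] == pytest.approx(3.0)

    def test_monotone_in_counts(self):
        a = log_normalize(make_matrix([[5], [10]]))
        b = log_normalize(make_matrix([[6], [10]]))
        assert b.iloc[0, 0] > a.iloc[0, 0]

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ConfigError, match="pseudocount"):
            log_normalize(make_matrix([[1]]), pseudocount=0.0)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_constant_vectors_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_matches_brute_force_step_up(self):
        def brute(p):
            p = np.asarray(p, dtype=float)
            n = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(2024)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNBWald:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(3)
        block = rng.integers(1, 300, size=(30, 3))
        counts = np.concatenate([block, block], axis=1)
        m = make_matrix(counts)
        res = nb_wald_test(m, [f"s{i}" for i in range(3)],
                           [f"s{i}" for i in range(3, 6)])
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p_raw"], 1.0)

    def test_group_overlap_and_size_errors(self):
        m = make_matrix(np.ones((5, 4), dtype=int))
        with pytest.raises(ConfigError, match="overlap"):
            nb_wald_test(m, ["s0", "s1"], ["s1", "s2"])
        with pytest.raises(ConfigError, match="at least 2"):
            nb_wald_test(m, ["s0"], ["s1", "s2"])

    def test_padj_is_bh_of_praw(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 500, size=(100, 8))
        m = make_matrix(counts)
        res = nb_wald_test(m, [f"s{i}" for i in range(4)],
                           [f"s{i}" for i in range(4, 8)])
        np.testing.assert_allclose(
            res.table["p_adj"], bh_adjust(res.table["p_raw"]), rtol=1e-12
        )


def _result_from(p_adj, log2fc):
    n = len(p_adj)
    table = pd.DataFrame(
        {
            "log2fc": log2fc, "mean_a": 1.0, "mean_b": 1.0, "dispersion": 0.0,
            "stat": 0.0, "p_raw": p_adj, "p_adj": p_adj,
            "pct_a": np.nan, "pct_b": np.nan,
        },
        index=[f"g{i}" for i in range(n)],
    )
    return DEResult(table=table, group_a=("a1", "a2"), group_b=("b1", "b2"),
                    method="nb_wald")


class TestDegFilter:
    def test_boundary_padj_exactly_alpha_excluded(self):
        res = _result_from([0.1, 0.0999999, 0.05], [1.0, 1.0, -1.0])
        up, down = deg_filter(res, alpha=0.1)
        assert "g0" not in up.genes and "g0" not in down.genes
        assert up.genes == ["g1"] and down.genes == ["g2"]

    def test_boundary_lfc_exactly_cutoff_excluded(self):
        res = _result_from([0.01, 0.01, 0.01], [0.322, 0.323, -0.322])
        up, down = deg_filter(res, alpha=0.1, min_abs_lfc=0.322)
        assert up.genes == ["g1"]
        assert down.genes == []

    def test_zero_cutoff_excludes_exact_zero_lfc(self):
        res = _result_from([0.01, 0.01], [0.0, 0.5])
        up, down = deg_filter(res, alpha=0.1, min_abs_lfc=0.0)
        assert up.genes == ["g1"] and down.genes == []


class TestTopN:
    def test_permuted_columns_are_degenerate_ties(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 100, size=(10, 4))
        mA = make_matrix(counts)
        mB = make_matrix(counts[:, [2, 3, 0, 1]])
        top_a, top_b = top_n_enriched(mA, mB, n=3)
        assert top_a.provenance["degenerate_ties"]
        assert top_a.genes == ["g0", "g1", "g2"]  # lexicographic tie-break

    def test_spiked_gene_ranks_first(self):
        counts = np.full((10, 4), 50)
        spiked = counts.copy()
        spiked[4] = 400
        top_a, _ = top_n_enriched(make_matrix(spiked), make_matrix(counts), n=2)
        assert top_a.genes[0] == "g4"

    def test_n_larger_than_universe_rejected(self):
        m = make_matrix(np.ones((5, 2), dtype=int))
        with pytest.raises(ConfigError, match="universe"):
            top_n_enriched(m, m, n=6)

    def test_recovery_of_true_enriched_genes(self):
        """>=95% of the top-N are truly A-enriched when 500 genes carry a
        2-log2 effect in dataset A."""
        from regiosig.synthdata import ExpressionSimConfig, simulate_bulk_counts

        cfg = ExpressionSimConfig(
            n_genes=2000, n_regions=2, n_celltypes=1, samples_per_group=4,
            frac_region_genes=0.5, frac_celltype_genes=0.0, region_lfc=2.0,
            astro_attenuation=1.0, dispersion=0.05, seed=11,
        )
        m, truth = simulate_bulk_counts(cfg)
        th = m.subset_samples([s for s in m.sample_ids if s.startswith("Th")])
        ctx = m.subset_samples([s for s in m.sample_ids if s.startswith("Ctx")])
        top_th, _ = top_n_enriched(th, ctx, n=400)
        frac_true = len(set(top_th.genes) & set(truth.region_genes["Th"])) / 400
        assert frac_true >= 0.95


class TestScQC:
    def _matrix(self, totals, mitos):
        n = len(totals)
        counts = np.zeros((3, n), dtype=int)
        counts[0] = totals
        meta = pd.DataFrame(
            {"total_umis": totals, "mito_fraction": mitos},
            index=[f"c{i}" for i in range(n)],
        )
        return make_matrix(counts, meta)

    def test_exactly_600_umis_removed(self):
        m = self._matrix([600, 601], [0.0, 0.0])
        kept = sc_qc_filter(m)
        assert list(kept.sample_ids) == ["c1"]

    def test_mito_boundary(self):
        m = self._matrix([700, 700, 700], [0.049, 0.05, 0.051])
        kept = sc_qc_filter(m)
        assert list(kept.sample_ids) == ["c0"]

    def test_all_pass_is_identity(self):
        m = self._matrix([1000, 2000], [0.01, 0.02])
        kept = sc_qc_filter(m)
        np.testing.assert_array_equal(kept.counts, m.counts)

    def test_missing_mito_information_is_error(self):
        counts = np.ones((3, 2), dtype=int) * 500
        meta = pd.DataFrame({"total_umis": [1500, 1500]}, index=["c0", "c1"])
        with pytest.raises(ConfigError, match="mito"):
            sc_qc_filter(make_matrix(counts, meta))


def _exact_two_sided_oracle(values_a, values_b):
    """Brute-force permutation distribution of the rank-sum statistic."""
    from itertools import combinations
    from scipy.stats import rankdata

    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    na, n = len(values_a), len(pooled)
    w_obs = ranks[:na].sum()
    lo = hi = total = 0
    for idx in combinations(range(n), na):
        w = ranks[list(idx)].sum()
        total += 1
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestWilcoxon:
    def _matrix_from_rows(self, rows):
        counts = np.asarray(rows)
        return make_matrix(counts)

    def test_complete_separation_5v5(self):
        m = self._matrix_from_rows(
            [[10, 11, 12, 13, 14, 1, 2, 3, 4, 5], [5] * 10]
        )
        res = wilcoxon_de(m, [f"s{i}" for i in range(5)],
                          [f"s{i}" for i in range(5, 10)], logfc_threshold=0.0)
        assert res.table.loc["g0", "p_raw"] == pytest.approx(2 / 252)

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6), (2, 6)])
    def test_matches_brute_force_enumeration_with_ties(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        counts = rng.integers(0, 4, size=(6, na + nb))  # heavy ties
        m = self._matrix_from_rows(counts)
        ga = [f"s{i}" for i in range(na)]
        gb = [f"s{i}" for i in range(na, na + nb)]
        res = wilcoxon_de(m, ga, gb, logfc_threshold=0.0, target_sum=100.0)
        # the documented contract ranks normalized values rounded to 6 decimals
        norm = np.round(counts / np.maximum(counts.sum(axis=0), 1) * 100.0, 6)
        for gi in range(6):
            if not res.table["tested"].iloc[gi]:
                continue
            expect = _exact_two_sided_oracle(norm[gi, :na], norm[gi, na:])
            assert res.table["p_raw"].iloc[gi] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 50, size=(5, 12))
        m = self._matrix_from_rows(counts)
        ga = [f"s{i}" for i in range(6)]
        gb = [f"s{i}" for i in range(6, 12)]
        r1 = wilcoxon_de(m, ga, gb, logfc_threshold=0.0)
        r2 = wilcoxon_de(m, gb, ga, logfc_threshold=0.0)
        np.testing.assert_allclose(r1.table["p_raw"], r2.table["p_raw"], rtol=1e-12)
        np.testing.assert_allclose(r1.table["logfc"], -r2.table["logfc"], atol=1e-12)

    def test_min_pct_zero_excludes_nothing_by_detection(self):
        counts = np.zeros((4, 8), dtype=int)
        counts[0] = [3, 0, 0, 0, 0, 0, 0, 0]  # detected in 1 cell only
        counts[1:] = 10
        m = self._matrix_from_rows(counts)
        res = wilcoxon_de(m, [f"s{i}" for i in range(4)],
                          [f"s{i}" for i in range(4, 8)],
                          logfc_threshold=0.0, min_pct=0.0)
        assert bool(res.table["tested"].iloc[0])

    def test_empty_group_rejected(self):
        m = self._matrix_from_rows(np.ones((2, 4), dtype=int))
        with pytest.raises(ConfigError, match="nonempty"):
            wilcoxon_de(m, [], [f"s{i}" for i in range(4)])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_adjust_is_monotone_and_bounded(p):
    adj = bh_adjust(p)
    assert np.all(adj + 1e-12 >= np.asarray(p))
    assert np.all((adj >= 0) & (adj <= 1))
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)
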