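"""Normalization, DE testing, module scores, and mode classification."""

import numpy as np
import pandas as pd
import pytest

from crisprai_screen import perturbseq_modes as pm


class TestLogNormalize:
    def test_closed_form(self):
        counts = pd.DataFrame([{"a": 10, "b": 9990}])
        norm = pm.log_normalize(counts, scale=1e4)
        assert norm.iloc[0, 0] == pytest.approx(np.log(11.0))

    def test_zero_stays_zero_and_scale_invariance(self):
        counts = pd.DataFrame([{"a": 0, "b": 5, "c": 15}])
        norm = pm.log_normalize(counts)
        assert norm.iloc[0, 0] == 0.0
        pd.testing.assert_frame_equal(norm, pm.log_normalize(counts * 2))

    def test_zero_total_cell_raises(self):
        with pytest.raises(ValueError, match="zero total"):
            pm.log_normalize(pd.DataFrame([{"a": 0, "b": 0}]))


class TestDETest:
    def test_identical_groups_zero_lfc(self, small_norm):
        cells = small_norm.index[:30]
        res = pm.de_test_lr(small_norm, cells, cells)
        assert (res.log2fc == 0).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        n = 250
        counts = pd.DataFrame(
            rng.negative_binomial(8, 0.4, size=(2 * n, 40)) + 1,
            index=[f"c{i}" for i in range(2 * n)],
            columns=[f"g{j}" for j in range(40)],
        )
        counts.iloc[:n, 0] *= 2  # two-fold shift in group A for gene g0
        norm = pm.log_normalize(counts)
        res = pm.de_test_lr(norm, norm.index[:n], norm.index[n:])
        row = res.set_index("gene").loc["g0"]
        assert row.p_adj < 0.05
        assert abs(row.log2fc - 1.0) < 0.35  # CPM renormalization shrinks it

    def test_batch_covariate_absorbs_batch_effect(self):
        """A pure batch effect confounded with nothing should not inflate
        significance when batch is included."""
        rng = np.random.default_rng(5)
        n = 150
        counts = pd.DataFrame(
            rng.negative_binomial(8, 0.4, size=(2 * n, 30)) + 1,
            index=[f"c{i}" for i in range(2 * n)],
        )
        counts.columns = [f"g{j}" for j in range(30)]
        norm = pm.log_normalize(counts)
        batch = pd.Series(
            ["b1"] * (n // 2) + ["b2"] * (n // 2) + ["b1"] * (n // 2) + ["b2"] * (n // 2),
            index=norm.index,
        )
        res = pm.de_test_lr(norm, norm.index[:n], norm.index[n:], batch=batch)
        assert (res.p_value < 0.05).mean() < 0.15

    def test_empty_group_rejected(self, small_norm):
        with pytest.raises(ValueError, match="nonempty"):
            pm.de_test_lr(small_norm, [], small_norm.index[:5])

    def test_bh_adjustment_monotone_and_dominates_p(self, small_norm):
        res = pm.de_test_lr(small_norm, small_norm.index[:40], small_norm.index[40:])
        assert (res.p_adj >= res.p_value - 1e-12).all()
        order = res.sort_values("p_value")
        assert order.p_adj.is_monotonic_increasing


class TestSignificantDE:
    def test_strict_boundaries(self):
        res = pd.DataFrame(
            {
                "gene": ["at_lfc", "at_p", "in_", "out"],
                "log2fc": [0.5, -0.8, -0.8, 0.3],
                "p_adj": [0.01, 0.05, 0.04, 0.01],
            }
        )
        assert pm.significant_de(res) == {"in_"}

    def test_empty(self):
        assert pm.significant_de(pd.DataFrame(columns=["gene", "log2fc", "p_adj"])) == set()


class TestClassifyMode:
    @pytest.mark.parametrize(
        "obs, exp, mode",
        [
            (1.0, 1.0, "additive"),  # observed equals expected
            (-0.5, 0.4, "synergy"),  # opposite sign, |d| = 0.9 > 0.1
            (0.1, 1.0, "buffer"),  # |d| = 0.9 > 0.7, lower magnitude
            (0.5, 1.0, "additive"),  # |d| = 0.5 <= 0.7 though lower magnitude
            (1.4, 0.7, "synergy"),  # greater magnitude, |d| > 0.1
            (-2.0, -0.9, "synergy"),  # greater magnitude, negative side
            (0.0, 0.0, "additive"),
        ],
    )
    def test_examples(self, obs, exp, mode):
        assert pm.classify_mode(obs, exp) == mode

    def test_truth_table_on_grid(self):
        """Exact agreement with a brute-force evaluation of the printed rule
        over (observed, expected) in [-2, 2]^2 at step 0.05."""

        def oracle(obs, exp, thr_syn=0.1, thr_buf=0.7):
            d = obs - exp
            opposite = (obs < 0 < exp) or (exp < 0 < obs)
            if abs(d) > thr_syn and (abs(obs) > abs(exp) or opposite):
                return "synergy"
            if abs(d) > thr_buf and abs(obs) < abs(exp):
                return "buffer"
            return "additive"

        grid = np.round(np.arange(-2.0, 2.0001, 0.05), 10)
        mismatches = [
            (o, e)
            for o in grid
            for e in grid
            if pm.classify_mode(o, e) != oracle(o, e)
        ]
        assert mismatches == []

    def test_bad_threshold_order_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            pm.classify_mode(1.0, 1.0, thr_syn=0.8, thr_buf=0.7)


class TestClassifyModes:
    def _de(self, genes, lfcs, padj=1e-6):
        return pd.DataFrame({"gene": genes, "log2fc": lfcs,
                             "p_value": padj, "p_adj": padj})

    def test_records_and_ratio(self):
        genes = ["syn", "buf", "add"]
        de_a = self._de(genes, [0.5, 1.0, 0.8])
        de_i = self._de(genes, [0.2, 1.0, -0.6])
        de_d = self._de(genes, [1.4, 0.9, 0.2])
        out = pm.classify_modes(de_a, de_i, de_d)
        rec = out.records.set_index("gene")
        assert (rec["lfc_double_expected"]
                == rec["lfc_single_a"] + rec["lfc_single_i"]).all()
        assert rec.loc["syn", "mode"] == "synergy"
        assert rec.loc["buf", "mode"] == "buffer"
        assert rec.loc["add", "mode"] == "additive"
        assert out.synergy_buffer_ratio == 1.0

    def test_ratio_nan_without_buffer_genes(self):
        de = self._de(["g"], [1.0])
        out = pm.classify_modes(de, de, self._de(["g"], [2.0]))
        assert np.isnan(out.synergy_buffer_ratio)

    def test_nonsignificant_genes_excluded(self):
        de_weak = self._de(["g"], [0.1], padj=0.9)
        out = pm.classify_modes(de_weak, de_weak, de_weak)
        assert len(out.records) == 0


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        norm = pd.DataFrame(1.7, index=[f"c{i}" for i in range(10)],
                            columns=[f"g{j}" for j in range(20)])
        score = pm.module_score(norm, ["g0", "g1"], n_bins=4, seed=0)
        assert np.allclose(score, 0.0)

    def test_exhaustive_controls_match_direct_computation(self, small_norm):
        """With one bin and enough controls the score reduces to
        mean(set) - mean(complement)."""
        gene_set = list(small_norm.columns[:10])
        score = pm.module_score(
            small_norm, gene_set, n_bins=1, n_controls=10_000, seed=1
        )
        rest = [g for g in small_norm.columns if g not in gene_set]
        direct = small_norm[gene_set].mean(axis=1) - small_norm[rest].mean(axis=1)
        assert np.allclose(score, direct)

    def test_deterministic_under_seed(self, small_norm):
        s1 = pm.module_score(small_norm, list(small_norm.columns[:5]), seed=9,
                             n_bins=5)
        s2 = pm.module_score(small_norm, list(small_norm.columns[:5]), seed=9,
                             n_bins=5)
        pd.testing.assert_series_equal(s1, s2)

    def test_random_sets_center_on_zero(self, small_norm):
        rng = np.random.default_rng(0)
        means = []
        for k in range(50):
            genes = list(rng.choice(small_norm.columns, size=8, replace=False))
            means.append(pm.module_score(small_norm, genes, n_bins=5, seed=k).mean())
        assert abs(np.mean(means)) < 0.05

    def test_empty_set_rejected(self, small_norm):
        with pytest.raises(ValueError, match="empty"):
            pm.module_score(small_norm, [])


class TestOverlapAndSelection:
    def test_disjoint_and_identical(self):
        out = pm.overlap_de_sets({"a", "b"}, {"c", "d", "e"}, {"f", "g", "h", "i"})
        assert (out["a_only"], out["i_only"], out["double_only"]) == (2, 3, 4)
        assert out["all_three"] == 0
        same = {"x", "y", "z", "w", "v"}
        out2 = pm.overlap_de_sets(same, same, same)
        assert out2["all_three"] == 5 and out2["a_only"] == 0

    def test_double_specific(self):
        out = pm.overlap_de_sets({"a", "b"}, {"b", "c"}, {"b", "d"})
        assert out["all_three"] == 1 and out["double_specific"] == {"d"}

    def test_top_additive_ordering_and_ties(self):
        rec = pd.DataFrame(
            {"gene": ["g3", "g1", "g2", "g4"], "difference": [0.9, 0.2, 0.0, -0.2]}
        )
        top, _ = pm.select_comparison_sets(
            rec, detected_genes=[f"x{i}" for i in range(10)], excluded_sets=[],
            n_top_additive=3, n_random=5, seed=0,
        )
        assert top == ["g2", "g1", "g4"]  # |0.2| tie broken by gene id

    def test_random_set_seeded_and_excludes(self):
        rec = pd.DataFrame({"gene": ["a", "b"], "difference": [0.0, 0.1]})
        detected = [f"x{i}" for i in range(50)] + ["bad1", "bad2"]
        r1 = pm.select_comparison_sets(rec, detected, [{"bad1"}, {"bad2"}],
                                       n_top_additive=2, n_random=20, seed=4)[1]
        r2 = pm.select_comparison_sets(rec, detected, [{"bad1"}, {"bad2"}],
                                       n_top_additive=2, n_random=20, seed=4)[1]
        assert r1 == r2
        assert not {"bad1", "bad2"} & set(r1)

    def test_insufficient_candidates_reported(self):
        rec = pd.DataFrame({"gene": ["a"], "difference": [0.0]})
        with pytest.raises(ValueError, match="candidate genes"):
            pm.select_comparison_sets(rec, ["x"], [], n_top_additive=1, n_random=5)
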