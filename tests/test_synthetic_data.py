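"""Simulator ground-truth checks: determinism, count moments, gating model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crisprai_screen import synthetic_data as sd


class TestPerturbSeq:
    def test_same_seed_bit_identical(self):
        truth = sd.example_perturb_truth(seed=3)
        a1, g1, m1, _ = sd.simulate_perturbseq(truth, 20)
        a2, g2, m2, _ = sd.simulate_perturbseq(truth, 20)
        np.testing.assert_array_equal(np.asarray(a1.X), np.asarray(a2.X))
        np.testing.assert_array_equal(np.asarray(g1.X), np.asarray(g2.X))
        pd.testing.assert_frame_equal(m1, m2)

    def test_null_truth_gives_near_zero_lfc(self):
        """With all effects 0, mean estimated log2FC across genes is ~0."""
        from crisprai_screen import perturbseq_modes as pm

        genes = [f"g{j}" for j in range(40)]
        truth = sd.PerturbTruth(
            genotypes=["A.a1", "B.i1"],
            gene_effects={},
            baseline_means=pd.Series(10.0, index=genes),
            library=sd.make_guide_library(["A", "B"]),
            seed=11,
        )
        adata, _, meta, _ = sd.simulate_perturbseq(truth, 500)
        counts = pd.DataFrame(np.asarray(adata.X), index=adata.obs_names,
                              columns=adata.var_names)
        norm = pm.log_normalize(counts)
        a = meta.index[meta.genotype == "A.a1"]
        b = meta.index[meta.genotype == "B.i1"]
        xa = np.expm1(norm.loc[a]).mean(axis=0) + 1
        xb = np.expm1(norm.loc[b]).mean(axis=0) + 1
        assert abs(np.log2(xa / xb).mean()) < 0.05

    def test_planted_lfc_recovered(self):
        """A planted 2-fold effect is estimated within +/-0.2 at 500 cells."""
        genes = [f"g{j}" for j in range(30)]
        truth = sd.PerturbTruth(
            genotypes=["NTC.1", "A.a1"],
            gene_effects={("A.a1", "g0"): 1.0},
            baseline_means=pd.Series(20.0, index=genes),
            library=sd.make_guide_library(["A"], n_ntc=1),
            seed=5,
        )
        adata, _, meta, _ = sd.simulate_perturbseq(truth, 500)
        counts = pd.DataFrame(np.asarray(adata.X), index=adata.obs_names,
                              columns=adata.var_names)
        from crisprai_screen import perturbseq_modes as pm

        norm = pm.log_normalize(counts)
        pert = meta.index[meta.genotype == "A.a1"]
        ntc = meta.index[meta.genotype == "NTC.1"]
        est = np.log2(
            (np.expm1(norm.loc[pert, "g0"]).mean() + 1)
            / (np.expm1(norm.loc[ntc, "g0"]).mean() + 1)
        )
        assert abs(est - 1.0) < 0.2

    def test_negative_binomial_moments(self):
        """Mean and variance match mu and mu + mu^2 * disp within 5% at 10k cells."""
        genes = ["g0", "g1"]
        truth = sd.PerturbTruth(
            genotypes=["A.a1"],
            gene_effects={},
            baseline_means=pd.Series([20.0, 50.0], index=genes),
            dispersion=0.3,
            libsize_sd=0.0,  # isolate the NB component
            library=sd.make_guide_library(["A"], n_ntc=0),
            seed=2,
        )
        adata, _, _, _ = sd.simulate_perturbseq(truth, 10_000)
        x = np.asarray(adata.X, dtype=float)
        for j, mu in enumerate([20.0, 50.0]):
            assert x[:, j].mean() == pytest.approx(mu, rel=0.05)
            assert x[:, j].var() == pytest.approx(mu + mu**2 * 0.3, rel=0.05)

    def test_unknown_genotype_guide_rejected(self):
        with pytest.raises(ValueError, match="absent from the library"):
            sd.PerturbTruth(
                genotypes=["NOPE.a1"],
                gene_effects={},
                baseline_means=pd.Series([1.0], index=["g0"]),
                library=sd.make_guide_library(["A"]),
            )

    def test_nonpositive_depth_rejected(self):
        truth = sd.example_perturb_truth()
        with pytest.raises(ValueError, match="depth"):
            sd.simulate_perturbseq(truth, 5, guide_noise=sd.GuideNoise(depth=0))


class TestSortScreen:
    def test_determinism(self):
        truth = sd.example_screen_truth(seed=9)
        c1, _ = sd.simulate_sort_screen(truth)
        c2, _ = sd.simulate_sort_screen(truth)
        pd.testing.assert_frame_equal(c1, c2)

    def test_additivity_echo_and_interaction(self):
        """Latent mean of a double equals the sum of singles when eps = 0."""
        beta = {("TSS", "a"): 1.5, ("E1", "i"): -0.7}
        truth = sd.example_screen_truth(n_elements=3, element_effects=beta)
        mus = sd.latent_means(truth)
        pairs = truth.pairs
        mu_of = lambda pid: mus[pairs.index[pairs.pair_id == pid][0]]
        assert mu_of("TSS.a|E1.i") == mu_of("TSS.a|NTC") + mu_of("E1.i|NTC")
        # epsilon shifts only the double
        truth2 = sd.example_screen_truth(
            n_elements=3,
            element_effects=beta,
            interaction_effects={frozenset({("TSS", "a"), ("E1", "i")}): 0.4},
        )
        mus2 = sd.latent_means(truth2)
        assert mus2[pairs.index[pairs.pair_id == "TSS.a|E1.i"][0]] == pytest.approx(
            mu_of("TSS.a|E1.i") + 0.4
        )

    def test_sorting_monotonic_in_beta(self):
        """Raising an activating beta never lowers the positive-gate share."""
        qs = []
        for b in (0.0, 0.5, 1.0, 2.0):
            truth = sd.example_screen_truth(
                n_elements=3, element_effects={("TSS", "a"): b} if b else None
            )
            mus = sd.latent_means(truth)
            idx = truth.pairs.index[truth.pairs.pair_id == "TSS.a|NTC"][0]
            qs.append(stats.norm.sf(truth.sort_threshold - mus[idx]))
        assert all(q2 > q1 for q1, q2 in zip(qs, qs[1:]))

    def test_planted_activator_enriches_in_all_replicates(self):
        from crisprai_screen import screen_scoring as ss

        truth = sd.example_screen_truth(seed=4, element_effects={("TSS", "a"): 2.0})
        counts, _ = sd.simulate_sort_screen(truth)
        scored = ss.score_screen(counts)
        single = scored[
            (scored.pair_type == "single")
            & (scored.element1 == "TSS")
            & (scored.direction1 == "a")
        ]
        assert len(single) == 3 and (single.z > 0).all()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sd.ScreenTruth(pairs=pd.DataFrame(columns=["element1"]))


class TestSignalTracks:
    def test_planted_levels_exact_without_noise(self):
        elements = sd.example_signal_layout(n_genes=3)
        bound = {("TF", elements["name"].iloc[0])}
        tracks = sd.simulate_signal_tracks(
            sd.SignalTruth(bound_elements=bound, bound_level=40, unbound_level=0.5),
            elements,
        )
        track = tracks["TF"]
        first = elements.iloc[0]
        inside = track[(track.start >= first.start) & (track.end <= first.end)]
        assert (inside.value == 40).all()
        outside = track[track.start >= first.end]
        assert (outside.value == 0.5).all()

    def test_bedgraph_roundtrip(self, tmp_path):
        from crisprai_screen import io

        elements = sd.example_signal_layout(n_genes=2)
        tracks = sd.simulate_signal_tracks(
            sd.SignalTruth(bound_elements={("TF", elements["name"].iloc[1])}),
            elements,
        )
        path = str(tmp_path / "t.bedGraph")
        io.write_bedgraph(tracks["TF"], path)
        back = io.read_bedgraph(path)
        pd.testing.assert_frame_equal(back, tracks["TF"].reset_index(drop=True))

    def test_zero_elements_empty_track(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        tracks = sd.simulate_signal_tracks(
            sd.SignalTruth(bound_elements={("TF", "x")}), empty
        )
        assert len(tracks["TF"]) == 0

    def test_negative_bin_size_rejected(self):
        with pytest.raises(ValueError, match="bin size"):
            sd.SignalTruth(bound_elements=set(), track_bin_size=-1)


class TestGuideDropout:
    def test_rates_outside_unit_interval_rejected(self):
        truth = sd.example_perturb_truth()
        _, gd, _, _ = sd.simulate_perturbseq(truth, 5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            sd.simulate_guide_dropout(gd, 1.5, 0.0)

    def test_zero_rates_estimate_zero(self):
        from crisprai_screen import guide_assignment as ga

        truth = sd.example_perturb_truth(seed=8)
        _, gd, meta, _ = sd.simulate_perturbseq(truth, 100)
        deg = sd.simulate_guide_dropout(gd, 0.0, 0.0, seed=1)
        counts = pd.DataFrame(np.asarray(deg.X), index=deg.obs_names,
                              columns=deg.var_names)
        asg = ga.assign_guides(counts, meta["capture_multiplicity"])
        est = ga.estimate_misassignment(asg, meta["capture_multiplicity"])
        assert est.fnr == 0.0 and est.fpr == 0.0

    def test_estimates_cover_truth_across_seeds(self):
        """Normal-approx 95% CIs on estimated FNR/FPR cover the planted
        rates in >= 90% of seeds."""
        from crisprai_screen import guide_assignment as ga

        truth = sd.example_perturb_truth(seed=0, n_background_genes=5)
        _, gd, meta, _ = sd.simulate_perturbseq(truth, 200)
        fnr_true, fpr_true = 0.4, 0.25
        cover_fnr = cover_fpr = 0
        n_seeds = 30
        for seed in range(n_seeds):
            deg = sd.simulate_guide_dropout(gd, fnr_true, fpr_true, seed=seed)
            counts = pd.DataFrame(np.asarray(deg.X), index=deg.obs_names,
                                  columns=deg.var_names)
            asg = ga.assign_guides(counts, meta["capture_multiplicity"])
            est = ga.estimate_misassignment(asg, meta["capture_multiplicity"])
            for rate, truth_v, n, bump in (
                (est.fnr, fnr_true, est.n_double_capture, "fnr"),
                (est.fpr, fpr_true, est.n_single_capture, "fpr"),
            ):
                half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-6) / n)
                covered = abs(rate - truth_v) <= half
                if bump == "fnr":
                    cover_fnr += covered
                else:
                    cover_fpr += covered
        assert cover_fnr / n_seeds >= 0.9
        assert cover_fpr / n_seeds >= 0.9

    def test_child_seed_arithmetic(self):
        assert sd.child_seed(0, 0) == 0
        assert sd.child_seed(1, 2) == 1_000_005
        assert 0 <= sd.child_seed(2**40, 123) < 2**31
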