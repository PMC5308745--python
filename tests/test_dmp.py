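import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from methmark.dmp import (
    adjust_bh,
    call_dmps,
    cluster_samples,
    filter_probes,
    paired_wilcoxon,
    summarize_regions,
)
from methmark.io import SampleDesign

from conftest import make_annotation, make_beta
from oracles import average_linkage_bruteforce, bh_adjust_quadratic, signed_rank_p_bruteforce


class TestPairedWilcoxon:
    def test_six_concordant_pairs_give_exact_floor(self):
        res = paired_wilcoxon([0.5, 0.6, 0.7, 0.8, 0.9, 0.95], [0.1] * 6)
        assert res.p_value == pytest.approx(2 / 64)

    def test_antisymmetric_differences_center_the_statistic(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = paired_wilcoxon(d, np.zeros(6))
        assert res.p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        res = paired_wilcoxon([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert res.degenerate and res.p_value == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">=3 complete pairs"):
            paired_wilcoxon([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError, match=">=3 complete pairs"):
            paired_wilcoxon([0.1, 0.2, np.nan], [0.3, 0.4, 0.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=3, max_size=10),
        st.sampled_from(["discard", "pratt"]),
    )
    def test_matches_exhaustive_enumeration(self, diffs, zero_method):
        """Exact p equals the 2^n sign-flip oracle, ties and zeros included."""
        diffs = np.array(diffs, dtype=float) / 2.0
        if not np.any(diffs != 0):
            return  # degenerate case covered separately
        res = paired_wilcoxon(diffs, np.zeros_like(diffs), zero_method=zero_method)
        assert res.p_value == pytest.approx(
            signed_rank_p_bruteforce(diffs, zero_method), abs=1e-12
        )

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        for n in (5, 8, 12, 20):
            x, y = rng.random(n), rng.random(n)
            ours = paired_wilcoxon(x, y).p_value
            ref = scipy_wilcoxon(x, y, zero_method="wilcox", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(40), rng.random(40)
        ours = paired_wilcoxon(x, y).p_value
        ref = scipy_wilcoxon(x, y, zero_method="wilcox", method="approx",
                             correction=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)


class TestAdjustBH:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_tied_inputs(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2] * 3)
        assert adjust_bh([]).size == 0

    def test_equals_quadratic_reference_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.random(60)
        ref = bh_adjust_quadratic(p)
        np.testing.assert_allclose(adjust_bh(p), ref, atol=1e-12)
        perm = rng.permutation(60)
        np.testing.assert_allclose(adjust_bh(p[perm]), ref[perm], atol=1e-12)


class TestFilterProbes:
    def _toy(self):
        # 10 probes: 2 on chrX, 1 SNP-flagged, 1 with a failed detection
        probes = [f"cg{i:04d}" for i in range(1, 11)]
        detp = np.zeros((10, 4))
        detp[3, 2] = 0.06
        beta = make_beta(np.full((10, 4), 0.5), probes=probes, detp=detp)
        rows = [{"probe_id": p} for p in probes]
        rows[0]["chromosome"] = "X"
        rows[1]["chromosome"] = "Y"
        rows[2]["snp_flag"] = True
        ann = make_annotation(rows)
        return beta, ann

    def test_hand_tally(self):
        beta, ann = self._toy()
        kept, report = filter_probes(beta, ann, 0.05)
        assert len(kept.probe_ids) == 6
        assert report == {"detection": 1, "sex_chromosome": 2, "snp": 1, "multimap": 0}
        assert "cg0004" not in kept.probe_ids  # detection p 0.06 in one sample
        assert "cg0005" in kept.probe_ids  # clean autosomal probe retained

    def test_threshold_validation(self):
        beta, ann = self._toy()
        with pytest.raises(ValueError, match="threshold"):
            filter_probes(beta, ann, 1.5)


class TestCallDmps:
    def test_gates_and_directions(self, toy_design):
        # probe 1: clear hypermethylation; probe 2: strong p but small delta
        rng = np.random.default_rng(0)
        n = 4
        tumor1, normal1 = 0.6 + rng.normal(0, 0.01, n), 0.2 + rng.normal(0, 0.01, n)
        tumor2, normal2 = 0.35 + rng.normal(0, 0.001, n), 0.2 + rng.normal(0, 0.001, n)
        vals = np.vstack([np.concatenate([tumor1, normal1]),
                          np.concatenate([tumor2, normal2])])
        beta = make_beta(vals, probes=["cgA", "cgB"],
                         samples=["s1T", "s2T", "s3T", "s4T", "s1N", "s2N", "s3N", "s4N"])
        res = call_dmps(beta, toy_design, delta_threshold=0.2, alpha=0.2, gate="raw_p")
        assert res.loc["cgA", "direction"] == "hyper"
        assert res.loc["cgB", "direction"] == "none"  # fails the delta-beta gate
        assert res["delta_beta"].equals(res["mean_beta_cancer"] - res["mean_beta_normal"])

    def test_equals_bruteforce_recomputation(self, small_cohort):
        beta, ann, expr, design, truth = small_cohort
        res = call_dmps(beta, design, gate="raw_p")
        pairs = design.pairs()
        sub = res.sample(n=40, random_state=0)
        for probe in sub.index:
            t = beta.beta.loc[probe, [a for a, _ in pairs]].to_numpy()
            n_ = beta.beta.loc[probe, [b for _, b in pairs]].to_numpy()
            assert res.loc[probe, "p_value"] == pytest.approx(
                signed_rank_p_bruteforce(t - n_), abs=1e-12)
            called = (abs(res.loc[probe, "delta_beta"]) > 0.2
                      and res.loc[probe, "p_value"] < 0.05)
            assert (res.loc[probe, "direction"] != "none") == called

    def test_requires_paired_design(self):
        beta = make_beta(np.full((2, 2), 0.5), samples=["a", "b"])
        design = SampleDesign(pd.DataFrame({
            "sample_id": ["a", "b"], "subject_id": ["p1", "p2"],
            "tissue": ["tumor", "normal"]}))
        with pytest.raises(ValueError, match="no paired subjects"):
            call_dmps(beta, design)


class TestSummarizeRegions:
    def _dmps(self, directions):
        return pd.DataFrame({
            "direction": directions,
            "mean_beta_normal": 0.2, "mean_beta_cancer": 0.5, "delta_beta": 0.3,
            "p_value": 0.01, "fdr": 0.05,
        }, index=pd.Index([f"cg{i:04d}" for i in range(1, len(directions) + 1)],
                          name="probe_id"))

    def test_all_promoter_island(self):
        dmps = self._dmps(["hyper"] * 3)
        ann = make_annotation([
            {"probe_id": p, "gene_symbols": ("G1",), "region_classes": ("TSS200",),
             "cgi_class": "Island"} for p in dmps.index])
        s = summarize_regions(dmps, ann)
        assert s.promoter_fraction["hyper"] == 1.0
        assert s.cgi_related_fraction["hyper"] == 1.0
        assert s.region_fractions.loc["hyper"].sum() == pytest.approx(1.0)

    def test_hand_tally_mixed(self):
        # 10 DMPs: 6 hyper (4 TSS200/Island, 2 Body/OpenSea), 4 hypo (1
        # 5UTR/Shore, 3 Intergenic/OpenSea)
        dirs = ["hyper"] * 6 + ["hypo"] * 4
        dmps = self._dmps(dirs)
        rows = []
        for i, p in enumerate(dmps.index):
            if i < 4:
                rows.append({"probe_id": p, "gene_symbols": ("G1",),
                             "region_classes": ("TSS200",), "cgi_class": "Island"})
            elif i < 6:
                rows.append({"probe_id": p, "gene_symbols": ("G2",),
                             "region_classes": ("Body",), "cgi_class": "OpenSea"})
            elif i < 7:
                rows.append({"probe_id": p, "gene_symbols": ("G3",),
                             "region_classes": ("5UTR",), "cgi_class": "Shore"})
            else:
                rows.append({"probe_id": p, "cgi_class": "OpenSea"})
        s = summarize_regions(dmps, make_annotation(rows))
        assert s.promoter_fraction["hyper"] == pytest.approx(4 / 6)
        assert s.promoter_fraction["hypo"] == pytest.approx(1 / 4)
        assert s.region_counts.loc["hypo", "Intergenic"] == 3
        assert s.cgi_fractions.loc["hyper", "Island"] == pytest.approx(4 / 6)
        for d in ("hyper", "hypo"):
            assert s.region_fractions.loc[d].sum() == pytest.approx(1.0)
            assert s.cgi_fractions.loc[d].sum() == pytest.approx(1.0)

    def test_empty_dmp_list_flags_undefined_fractions(self):
        dmps = self._dmps([]).iloc[0:0]
        ann = make_annotation([{"probe_id": "cg0001"}])
        s = summarize_regions(dmps, ann)
        assert s.region_counts.to_numpy().sum() == 0
        assert s.promoter_fraction.isna().all()


class TestClusterSamples:
    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(2)
        vals = rng.random((30, 6))
        vals[:, 3] = vals[:, 0]  # S4 duplicates S1
        beta = make_beta(vals)
        tree = cluster_samples(beta)
        first = tree.merges[0]
        merged = {tree.sample_ids[int(first[0])], tree.sample_ids[int(first[1])]}
        assert merged == {"S1", "S4"}
        assert first[2] == pytest.approx(0.0)

    def test_merge_heights_match_bruteforce_upgma(self):
        rng = np.random.default_rng(5)
        beta = make_beta(rng.random((40, 4)))
        tree = cluster_samples(beta)
        corr = beta.beta.corr().to_numpy()
        ref = average_linkage_bruteforce(1 - corr)
        np.testing.assert_allclose(sorted(tree.merges[:, 2]), sorted(ref), atol=1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        vals = rng.random((25, 5))
        beta = make_beta(vals)
        shuffled = make_beta(vals[:, [3, 1, 4, 0, 2]],
                             samples=["S4", "S2", "S5", "S1", "S3"])
        a, b = cluster_samples(beta), cluster_samples(shuffled)
        assert a.leaf_order == b.leaf_order
        np.testing.assert_allclose(a.merges, b.merges, atol=1e-12)

    def test_needs_two_samples(self):
        beta = make_beta(np.full((5, 1), 0.5))
        with pytest.raises(ValueError, match=">=2 samples"):
            cluster_samples(beta)
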