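"""Tests for ortholog pairing, DRI/DBEI, correlations, overlaps and motifs."""

import numpy as np
import pandas as pd
import pytest

from driseq import compstats, simgen


def de_table(ids, fc, padj=None):
    fc = np.asarray(fc, dtype=float)
    padj = np.full(len(ids), 0.01) if padj is None else np.asarray(padj, float)
    return pd.DataFrame(
        {"fold_change": fc, "log2fc": np.log2(fc), "padj": padj},
        index=pd.Index(ids, name="gene_id"),
    )


class TestPairFilter:
    def _tables(self, values_a, values_b):
        ta = pd.DataFrame({"s1": values_a, "s2": values_a}, index=["ga1", "ga2"])
        tb = pd.DataFrame({"s1": values_b, "s2": values_b}, index=["gb1", "gb2"])
        return {"prepA": ta}, {"prepB": tb}

    def test_pair_above_threshold_everywhere_is_retained(self):
        ta, tb = self._tables([1.0, 1.0], [1.0, 1.0])
        m = pd.DataFrame({"gene_a": ["ga1"], "gene_b": ["gb1"]})
        pairs, dropped = compstats.pair_orthologs_and_filter(ta, tb, m, 0.5)
        assert len(pairs) == 1 and dropped == 0

    def test_pair_exactly_at_threshold_is_dropped(self):
        ta, tb = self._tables([0.5, 1.0], [1.0, 1.0])
        m = pd.DataFrame({"gene_a": ["ga1", "ga2"], "gene_b": ["gb1", "gb2"]})
        pairs, _ = compstats.pair_orthologs_and_filter(ta, tb, m, 0.5)
        assert list(pairs["gene_a"]) == ["ga2"]

    def test_empty_map_gives_empty_result(self):
        ta, tb = self._tables([1.0, 1.0], [1.0, 1.0])
        m = pd.DataFrame({"gene_a": [], "gene_b": []})
        pairs, _ = compstats.pair_orthologs_and_filter(ta, tb, m, 0.5)
        assert pairs.empty

    def test_non_bijective_rows_dropped_and_counted(self):
        ta, tb = self._tables([1.0, 1.0], [1.0, 1.0])
        m = pd.DataFrame(
            {"gene_a": ["ga1", "ga1", "ga2"], "gene_b": ["gb1", "gb2", "gb2"]}
        )
        pairs, dropped = compstats.pair_orthologs_and_filter(ta, tb, m, 0.5)
        assert dropped == 3 and pairs.empty


class TestDriTable:
    def _inputs(self):
        pairs = pd.DataFrame({"gene_a": ["m1"], "gene_b": ["h1"]})
        de_h = de_table(["h1"], [4.0])
        de_m = de_table(["m1"], [2.0])
        basal_h = pd.Series({"h1": 3.0})
        basal_m = pd.Series({"m1": 6.0})
        return pairs, de_h, de_m, basal_h, basal_m

    def test_worked_example(self):
        dri, skipped = compstats.compute_dri_table(*self._inputs())
        row = dri.iloc[0]
        assert row["dri"] == pytest.approx(2.0)
        assert row["log2_dri"] == pytest.approx(1.0)
        assert row["dbei"] == pytest.approx(0.5)
        assert row["log2_dbei"] == pytest.approx(-1.0)
        assert skipped == 0

    def test_swapping_species_inputs_negates_log2_dri(self):
        rng = np.random.default_rng(2)
        ids = [f"g{i}" for i in range(30)]
        pairs = pd.DataFrame({"gene_a": ids, "gene_b": ids})
        fc1, fc2 = rng.lognormal(0, 1, 30), rng.lognormal(0, 1, 30)
        basal = pd.Series(rng.lognormal(2, 1, 30), index=ids)
        fwd, _ = compstats.compute_dri_table(
            pairs, de_table(ids, fc1), de_table(ids, fc2), basal, basal
        )
        rev, _ = compstats.compute_dri_table(
            pairs, de_table(ids, fc2), de_table(ids, fc1), basal, basal
        )
        assert np.allclose(fwd["log2_dri"], -rev["log2_dri"])

    def test_missing_gene_skipped_and_tallied(self):
        pairs = pd.DataFrame({"gene_a": ["m1", "m2"], "gene_b": ["h1", "h2"]})
        dri, skipped = compstats.compute_dri_table(
            pairs,
            de_table(["h1"], [4.0]),
            de_table(["m1", "m2"], [2.0, 2.0]),
            pd.Series({"h1": 1.0}),
            pd.Series({"m1": 1.0, "m2": 1.0}),
        )
        assert len(dri) == 1 and skipped == 1


class TestDistributionSummary:
    def test_constant_vector_has_zero_sd(self):
        s = compstats.summarize_log2_distribution([1.5, 1.5, 1.5])
        assert s.sd == 0.0 and s.n == 3

    def test_two_point_example(self):
        s = compstats.summarize_log2_distribution([-1.0, 1.0])
        assert s.mean == pytest.approx(0.0)
        assert s.sd == pytest.approx(np.sqrt(2))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compstats.summarize_log2_distribution([1.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = compstats.pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_fisher_interval_reproduces_published_bound(self):
        lo, hi = compstats.fisher_ci(0.480, 11302)
        assert round(hi, 3) == 0.494

    def test_r_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = compstats.pearson_with_ci(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.r == pytest.approx(num / den, rel=1e-12)

    def test_interval_contains_r_and_narrows_with_n(self):
        widths = []
        for n in (10, 100, 1000):
            lo, hi = compstats.fisher_ci(0.4, n)
            assert lo < 0.4 < hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compstats.pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestCohortAndOverlap:
    def test_induced_cohort_thresholds_are_strict(self):
        pairs = pd.DataFrame(
            {"gene_a": ["m1", "m2", "m3"], "gene_b": ["h1", "h2", "h3"]}
        )
        de_h = de_table(["h1", "h2", "h3"], [6, 6, 6], [0.01, 0.01, 0.01])
        de_m = de_table(["m1", "m2", "m3"], [6, 4.9, 6], [0.01, 0.01, 0.06])
        cohort = compstats.induced_cohort(de_h, de_m, pairs, fc_min=5, padj_max=0.05)
        assert list(cohort["gene_a"]) == ["m1"]

    def test_overlap_with_identical_comparison_is_total(self):
        ids = [f"p{i}" for i in range(40)]
        ref = de_table(ids, np.linspace(4, 50, 40))
        res = compstats.conserved_induction_overlap(
            ref, {"same": ref}, top_n=20, ref_fc_min=3.5
        )
        assert res["overlaps"]["same"] == 20 and res["union_overlap"] == 20

    def test_overlap_with_flat_comparison_is_zero(self):
        ids = [f"p{i}" for i in range(40)]
        ref = de_table(ids, np.linspace(4, 50, 40))
        flat = de_table(ids, np.ones(40))
        res = compstats.conserved_induction_overlap(
            ref, {"flat": flat}, top_n=20, ref_fc_min=3.5
        )
        assert res["overlaps"]["flat"] == 0

    def test_known_conserved_fraction_recovered(self):
        # 300 qualifying reference genes; each conserved with p=0.8
        rng = np.random.default_rng(23)
        ids = [f"p{i:03d}" for i in range(300)]
        ref = de_table(ids, rng.uniform(5, 60, 300))
        conserved = rng.random(300) < 0.8
        cmp_fc = np.where(conserved, 3.0, 1.0)
        cmp = de_table(ids, cmp_fc)
        res = compstats.conserved_induction_overlap(
            ref, {"cmp": cmp}, top_n=200, ref_fc_min=3.5, cmp_fc_min=1.5
        )
        frac = res["overlaps"]["cmp"] / 200
        # binomial 99% interval around 0.8 at n=200
        assert abs(frac - 0.8) < 2.576 * np.sqrt(0.8 * 0.2 / 200)

    def test_reference_set_deterministic_under_permutation(self):
        ids = [f"p{i}" for i in range(30)]
        fc = np.concatenate([np.full(15, 10.0), np.linspace(4, 9, 15)])
        ref = de_table(ids, fc)
        perm = ref.sample(frac=1, random_state=4)
        a = compstats.conserved_induction_overlap(ref, {}, top_n=10, ref_fc_min=3.5)
        b = compstats.conserved_induction_overlap(perm, {}, top_n=10, ref_fc_min=3.5)
        assert a["reference_ids"] == b["reference_ids"]

    def test_insufficient_qualifying_genes_rejected(self):
        ref = de_table(["p1", "p2"], [10, 10])
        with pytest.raises(ValueError, match="qualify"):
            compstats.conserved_induction_overlap(ref, {}, top_n=5)


class TestConnectionMap:
    def test_duplicated_replicate_has_unit_weight(self):
        v = np.random.default_rng(1).normal(size=100)
        g = compstats.connection_map({"a": v, "b": v.copy(), "c": v + 1e3 * np.arange(100)})
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_weights_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        vecs = {k: rng.normal(size=50) for k in "abcd"}
        g = compstats.connection_map(vecs)
        for u, v, d in g.edges(data=True):
            assert 0.0 <= d["weight"] <= 1.0
            assert g[u][v]["weight"] == g[v][u]["weight"]

    def test_shared_program_clusters_separate_from_independent_one(self):
        vectors, cluster_of = simgen.simulate_induction_programs(
            cluster_sizes=(3, 1), n_reps=3, n_genes=2000, seed=10
        )
        g = compstats.connection_map(vectors)
        within = [
            d["weight"] for u, v, d in g.edges(data=True) if cluster_of[u] == cluster_of[v]
        ]
        cross = [
            d["weight"] for u, v, d in g.edges(data=True) if cluster_of[u] != cluster_of[v]
        ]
        assert min(within) > max(cross)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compstats.connection_map({"a": np.zeros(5), "b": np.zeros(6)})

    def test_export_round_trips_through_graphml(self, tmp_path):
        import networkx as nx

        rng = np.random.default_rng(3)
        g = compstats.connection_map({k: rng.normal(size=30) for k in "abc"})
        compstats.write_connection_map(
            g, str(tmp_path / "g.graphml"), str(tmp_path / "g.tsv")
        )
        back = nx.read_graphml(str(tmp_path / "g.graphml"))
        for u, v, d in g.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(d["weight"])


class TestTc1Concordance:
    def _inputs(self, n=8, totals_value=500):
        ids_m = [f"m{i}" for i in range(n)]
        ids_h = [f"h{i}" for i in range(n)]
        rng = np.random.default_rng(5)
        fc_m = rng.lognormal(0, 0.5, n)
        dri = rng.normal(0, 0.7, n)
        fc_h = fc_m * np.exp2(dri)
        pairs = pd.DataFrame({"gene_a": ids_m, "gene_b": ids_h})
        sep = pd.DataFrame(
            {"gene_a": ids_m, "gene_b": ids_h, "log2_dri": dri}
        )
        totals = pd.Series(totals_value, index=ids_h, dtype=float)
        return pairs, de_table(ids_h, fc_h), de_table(ids_m, fc_m), sep, totals

    def test_identical_fold_changes_give_perfect_correlation(self):
        pairs, de_h, de_m, sep, totals = self._inputs()
        table, corr = compstats.tc1_concordance(de_h, de_m, sep, pairs, totals)
        assert corr.r == pytest.approx(1.0)
        assert len(table) == len(pairs)

    def test_read_cutoff_is_strict(self):
        pairs, de_h, de_m, sep, totals = self._inputs()
        totals.iloc[0] = 100  # exactly at the cut-off: excluded
        table, _ = compstats.tc1_concordance(de_h, de_m, sep, pairs, totals)
        assert len(table) == len(pairs) - 1

    def test_sequence_driven_effects_recovered_across_measurements(self):
        # two independent noisy measurements of the same sequence-encoded
        # regulation: correlation should be strong at n=72
        truth, _ = simgen.simulate_count_experiment(72, sigma_dri=0.68, seed=6)
        rng = np.random.default_rng(7)
        dri = truth["true_log2_dri"].to_numpy()
        sep_dri = dri + rng.normal(0, 0.1, 72)
        tc1_dri = dri + rng.normal(0, 0.1, 72)
        ids = list(truth.index)
        pairs = pd.DataFrame({"gene_a": ids, "gene_b": ids})
        sep = pd.DataFrame({"gene_a": ids, "gene_b": ids, "log2_dri": sep_dri})
        de_h = de_table(ids, np.exp2(tc1_dri))
        de_m = de_table(ids, np.ones(72))
        totals = pd.Series(1000.0, index=ids)
        _, corr = compstats.tc1_concordance(de_h, de_m, sep, pairs, totals)
        assert corr.r > 0.9

    def test_too_few_pairs_rejected(self):
        pairs, de_h, de_m, sep, totals = self._inputs(n=8, totals_value=10)
        with pytest.raises(ValueError, match="cut-off"):
            compstats.tc1_concordance(de_h, de_m, sep, pairs, totals)


class TestMotifs:
    def test_identical_sequences_have_no_specific_hits(self):
        seq, _ = simgen.make_promoter_pair(length=400, n_sites=2, divergence=0.0, seed=9)
        h1, h2 = compstats.compare_promoter_motifs(seq, seq)
        assert not any(h.species_specific for h in h1 + h2)
        assert len(h1) > 0  # the planted sites are found in both

    def test_planted_single_substitution_site_is_specific(self):
        rng = np.random.default_rng(12)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        s1 = base[:150] + "TGACTCA" + base[150:]
        s2 = base[:150] + "TGAATCA" + base[150:]  # S position broken
        h1, h2 = compstats.compare_promoter_motifs(s1, s2, motif="TGASTCA")
        specific_positions = {h.position for h in h1 if h.species_specific}
        assert specific_positions == {150}
        assert not any(h.species_specific for h in h2)

    def test_reverse_complementing_both_preserves_specific_count(self):
        p1, p2 = simgen.make_promoter_pair(length=500, n_sites=3, seed=14)
        h1, _ = compstats.compare_promoter_motifs(p1, p2, motif="TGASTCA")
        r1, _ = compstats.compare_promoter_motifs(
            simgen.revcomp(p1), simgen.revcomp(p2), motif="TGASTCA"
        )
        n = len({h.position for h in h1 if h.species_specific})
        m = len({h.position for h in r1 if h.species_specific})
        assert n == m == 3

    def test_invalid_iupac_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            compstats.compare_promoter_motifs("ACGT", "ACGT", motif="TGAXTCA")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compstats.compare_promoter_motifs("", "ACGT")


def test_dri_dbei_independence_recovered_from_generator():
    truth, _ = simgen.simulate_count_experiment(10_000, seed=15)
    r = np.corrcoef(truth["true_log2_dri"], truth["log2_dbei"])[0, 1]
    assert abs(r) < 2.5758 / np.sqrt(10_000)
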