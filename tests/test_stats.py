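"""Repertoire statistics: frequencies, Jk usage, activity, ratios, halves."""

import numpy as np
import pandas as pd
import pytest

from kappaseq.locus import JK_NAMES, assign_halves
from kappaseq.stats import (
    RepertoireTable,
    classify_active,
    frequencies,
    half_bias,
    jk_repertoire_correlations,
    jk_usage,
    pseudo_count_ratio,
    ratio_analysis,
)


def make_table(count_rows, sample_meta=None, genes=None):
    counts = pd.DataFrame(count_rows, columns=["sample", "v_gene", "jk", "count"])
    if sample_meta is None:
        ids = counts["sample"].unique()
        sample_meta = pd.DataFrame(
            {"stage": "preB", "genotype": "WT", "molecule": "gdna",
             "replicate": range(1, len(ids) + 1), "pairing": range(len(ids))},
            index=pd.Index(ids, name="sample"),
        )
    return RepertoireTable(counts=counts, samples=sample_meta, genes=genes or [])


class TestFrequencies:
    def test_single_gene_frequency_one(self):
        t = make_table([("s1", "g1", "Jk1", 10.0)])
        assert frequencies(t).loc["g1"] == 1.0

    def test_pooled_replicate_definition(self):
        """Pooled frequency is summed reads over replicates divided by the
        pooled total: (10+20+70)/300."""
        rows = []
        for i, n in enumerate([10.0, 20.0, 70.0]):
            rows.append((f"s{i}", "g", "Jk1", n))
            rows.append((f"s{i}", "other", "Jk1", 100.0 - n))
        t = make_table(rows)
        assert frequencies(t).loc["g"] == pytest.approx(100.0 / 300.0)

    def test_view_sums_to_one_and_decomposes(self):
        rng = np.random.default_rng(0)
        rows = [(f"s{i}", f"g{j}", jk, float(rng.integers(1, 50)))
                for i in range(2) for j in range(5) for jk in JK_NAMES]
        t = make_table(rows)
        fall = frequencies(t)
        assert fall.sum() == pytest.approx(1.0)
        per_jk = {jk: t.matrix(view=jk).sum(axis=1) for jk in JK_NAMES}
        total = t.matrix().values.sum()
        recon = sum(per_jk.values()) / total
        pd.testing.assert_series_equal(fall, recon, check_names=False)

    def test_zero_total_rejected(self):
        t = make_table([("s1", "g1", "Jk1", 0.0)])
        with pytest.raises(ValueError, match="zero total"):
            frequencies(t)


class TestJkUsage:
    def test_profile_pure_jk1_gene(self):
        rows = [("s1", "g1", "Jk1", 10.0), ("s2", "g1", "Jk1", 9.0),
                ("s1", "g2", "Jk2", 30.0), ("s2", "g2", "Jk2", 30.0)]
        _, prof = jk_usage(make_table(rows))
        assert prof.loc["g1"].tolist() == [100.0, 0.0, 0.0, 0.0]

    def test_gene_below_5_reads_in_one_replicate_excluded(self):
        rows = [("s1", "g1", "Jk1", 4.0), ("s2", "g1", "Jk1", 50.0),
                ("s1", "g2", "Jk1", 6.0), ("s2", "g2", "Jk1", 6.0)]
        _, prof = jk_usage(make_table(rows))
        assert "g1" not in prof.index
        assert "g2" in prof.index

    def test_global_usage_recovered_from_simulation(self, pairless_ref):
        from kappaseq.simulate import simulate_repertoire
        from conftest import clean_config

        weights = (0.5, 0.2, 0.2, 0.1)
        cfg = clean_config(n_molecules=20000, jk_weights=weights)
        truth = simulate_repertoire(pairless_ref, cfg, seed=3)
        counts = truth.molecules.groupby(["gene", "jk"]).size()
        rows = [("s1", g, jk, float(n)) for (g, jk), n in counts.items()]
        pct, _ = jk_usage(make_table(rows))
        for jk, w in zip(JK_NAMES, weights):
            assert abs(pct[jk] / 100.0 - w) < 0.02


class TestJkCorrelations:
    def test_identical_vectors_r_one(self):
        rows = [("s1", g, jk, c) for g, c in [("g1", 10.0), ("g2", 30.0)]
                for jk in JK_NAMES]
        corr = jk_repertoire_correlations(make_table(rows))
        assert np.allclose(corr.values, 1.0)

    def test_orthogonal_two_gene_toy_r_minus_one(self):
        rows = [("s1", "g1", "Jk1", 10.0), ("s1", "g2", "Jk2", 10.0)]
        corr = jk_repertoire_correlations(make_table(rows, genes=["g1", "g2"]))
        assert corr.loc["Jk1", "Jk2"] == pytest.approx(-1.0)

    def test_shared_weights_correlate_with_depth(self, pairless_ref):
        """When Jk4 and Jk5 share per-gene weights, their repertoires
        correlate toward 1 as depth grows."""
        rng = np.random.default_rng(5)
        w = rng.dirichlet(np.ones(len(pairless_ref.v_names)))
        f = pd.DataFrame(
            {jk: w * x for jk, x in zip(JK_NAMES, (0.4, 0.2, 0.2, 0.2))},
            index=pairless_ref.v_names)
        from kappaseq.simulate import simulate_repertoire
        from conftest import clean_config

        cfg = clean_config(n_molecules=50000)
        truth = simulate_repertoire(pairless_ref, cfg, seed=6, freq=f)
        counts = truth.molecules.groupby(["gene", "jk"]).size()
        rows = [("s1", g, jk, float(n)) for (g, jk), n in counts.items()]
        corr = jk_repertoire_correlations(
            make_table(rows, genes=pairless_ref.v_names))
        assert corr.loc["Jk4", "Jk5"] > 0.98


class TestClassifyActive:
    def _table(self, gene_count, total=1_000_000):
        rows = [("s1", "g", "Jk1", float(gene_count)),
                ("s1", "rest", "Jk1", float(total - gene_count))]
        return make_table(rows)

    def test_preB_threshold_boundary_15_per_million(self):
        assert classify_active(self._table(15), mode="preB").loc["g"] == "active"
        assert classify_active(self._table(14), mode="preB").loc["g"] == "inactive"

    def test_proB_one_read_cutoff(self):
        t = make_table([("s1", "g", "Jk1", 1.0), ("s1", "z", "Jk1", 0.0),
                        ("s1", "rest", "Jk1", 99.0)])
        out = classify_active(t, mode="proB")
        assert out.loc["g"] == "active"
        assert out.loc["z"] == "inactive"

    def test_zero_frequency_genes_inactive_at_any_threshold(self, pairless_ref):
        from kappaseq.simulate import simulate_repertoire
        from conftest import clean_config

        cfg = clean_config(n_molecules=5000, inactive_frac=0.25)
        truth = simulate_repertoire(pairless_ref, cfg, seed=7)
        counts = truth.molecules.groupby(["gene", "jk"]).size()
        rows = [("s1", g, jk, float(n)) for (g, jk), n in counts.items()]
        t = make_table(rows, genes=pairless_ref.v_names)
        zero_genes = truth.freq.index[truth.freq.sum(axis=1) == 0]
        for thr in (1.0, 15.0, 100.0):
            out = classify_active(t, mode="preB", threshold_per_million=thr)
            assert (out.loc[zero_genes] == "inactive").all()

    def test_monotone_in_threshold(self):
        t = self._table(40, total=100_000)
        lo = classify_active(t, mode="preB", threshold_per_million=15.0)
        hi = classify_active(t, mode="preB", threshold_per_million=500.0)
        flips = (lo == "inactive") & (hi == "active")
        assert not flips.any()


def _paired_tables(freqs_a, freqs_b, n_rep=3, depth=10000):
    rows_a, rows_b = [], []
    for r in range(n_rep):
        for g, (fa, fb) in enumerate(zip(freqs_a, freqs_b)):
            rows_a.append((f"a{r}", f"g{g}", "Jk1", fa * depth))
            rows_b.append((f"b{r}", f"g{g}", "Jk1", fb * depth))
    return make_table(rows_a), make_table(rows_b)


class TestRatioAnalysis:
    def test_identical_tables_no_flags(self):
        ta, tb = _paired_tables([0.5, 0.5], [0.5, 0.5])
        rep = ratio_analysis(ta, tb, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert (rep.flags == "").all()

    def test_one_replicate_below_1_5_not_flagged(self):
        """Mean fold 2.0 but one replicate at 1.4: the every-replicate rule
        rejects the gene."""
        rows_a, rows_b = [], []
        ratios = [2.5, 2.1, 1.4]
        for r, ratio in enumerate(ratios):
            rows_a.append((f"a{r}", "g", "Jk1", ratio * 100))
            rows_a.append((f"a{r}", "h", "Jk1", 1000 - ratio * 100))
            rows_b.append((f"b{r}", "g", "Jk1", 100.0))
            rows_b.append((f"b{r}", "h", "Jk1", 900.0))
        ta, tb = make_table(rows_a), make_table(rows_b)
        rep = ratio_analysis(ta, tb, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert rep.mean_ratio.loc["g"] >= 2.0 * (100 / 1000) / (100 / 1000) - 1e-6
        assert rep.flags.loc["g"] == ""

    def test_direction_symmetry(self):
        ta, tb = _paired_tables([0.8, 0.2], [0.4, 0.6])
        fwd = ratio_analysis(ta, tb, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        rev = ratio_analysis(tb, ta, ["b0", "b1", "b2"], ["a0", "a1", "a2"])
        remap = {"A": "B", "B": "A", "": ""}
        assert fwd.flags.map(remap).to_dict() == rev.flags.to_dict()

    def test_gene_missing_reads_in_a_replicate_excluded(self):
        rows_a = [("a0", "g", "Jk1", 10.0), ("a1", "g", "Jk1", 0.0),
                  ("a0", "h", "Jk1", 10.0), ("a1", "h", "Jk1", 10.0)]
        rows_b = [("b0", "g", "Jk1", 10.0), ("b1", "g", "Jk1", 10.0),
                  ("b0", "h", "Jk1", 10.0), ("b1", "h", "Jk1", 10.0)]
        rep = ratio_analysis(make_table(rows_a), make_table(rows_b),
                             ["a0", "a1"], ["b0", "b1"])
        assert "g" in rep.excluded and "h" not in rep.excluded

    def test_replicate_pairing_mismatch_rejected(self):
        ta, tb = _paired_tables([1.0], [1.0])
        with pytest.raises(ValueError, match="pairing"):
            ratio_analysis(ta, tb, ["a0", "a1"], ["b0"])

    def test_promoter_strength_flags_rna_high_gene(self, pairless_ref,
                                                   pairless_aligner):
        """A gene with 3x promoter strength in an otherwise unbiased RNA
        library is flagged divergent toward RNA against gDNA."""
        import pandas as pd
        from kappaseq.pipeline import run_library
        from kappaseq.simulate import simulate_repertoire
        from conftest import clean_config

        genes = pairless_ref.v_names
        f = pd.DataFrame(0.0, index=genes, columns=list(JK_NAMES))
        f.loc[:, "Jk1"] = 1.0
        f /= f.values.sum()
        boosted = genes[2]
        rows_g, rows_r = [], []
        for rep in range(3):
            cfg = clean_config(n_molecules=4000, nmd_survival=1.0)
            truth = simulate_repertoire(pairless_ref, cfg, seed=100 + rep, freq=f)
            truth.promoter_strength[:] = 1.0
            truth.promoter_strength[boosted] = 3.0
            g_res = run_library(pairless_ref, cfg, "gdna", seed=200 + rep,
                                truth=truth, aligner=pairless_aligner)
            r_res = run_library(pairless_ref, cfg, "rna", seed=300 + rep,
                                truth=truth, aligner=pairless_aligner)
            rows_g += [(f"g{rep}", g, jk, n)
                       for (g, jk), n in g_res.gene_jk_counts().items()]
            rows_r += [(f"r{rep}", g, jk, n)
                       for (g, jk), n in r_res.gene_jk_counts().items()]
        tg = make_table(rows_g, genes=genes)
        tr = make_table(rows_r, genes=genes)
        rep = ratio_analysis(tr, tg, ["r0", "r1", "r2"], ["g0", "g1", "g2"])
        assert rep.flags.loc[boosted] == "A"  # RNA-high


class TestPseudoCountRatio:
    def test_zero_replaced_by_one_read_equivalent(self):
        fa = pd.Series({"g": 0.01})
        fb = pd.Series({"g": 0.0})
        out = pseudo_count_ratio(fa, fb, total_a=1e4, total_b=1e4)
        assert out.loc["g", "ratio"] == pytest.approx(0.01 / 1e-4)
        assert bool(out.loc["g", "underrepresented"])

    def test_no_zero_identical_to_plain_ratio(self):
        fa = pd.Series({"g": 0.02})
        fb = pd.Series({"g": 0.01})
        out = pseudo_count_ratio(fa, fb, 1e4, 1e4)
        assert out.loc["g", "ratio"] == pytest.approx(2.0)
        assert not bool(out.loc["g", "underrepresented"])

    def test_double_zero_skipped(self):
        fa = pd.Series({"g": 0.0})
        fb = pd.Series({"g": 0.0})
        out = pseudo_count_ratio(fa, fb, 1e4, 1e4)
        assert out.empty


class TestHalfBias:
    def test_all_proximal_reads(self, pairless_ref):
        assign_halves(pairless_ref)
        prox = [g.name for g in pairless_ref.v_genes if g.half == "proximal"]
        rows = [("s1", g, "Jk1", 10.0) for g in prox]
        hb = half_bias(make_table(rows, genes=pairless_ref.v_names),
                       pairless_ref)
        assert hb.loc["s1", "proximal"] == pytest.approx(1.0)
        assert hb.loc["s1", "distal"] == pytest.approx(0.0)

    def test_rows_sum_to_one(self, pairless_ref):
        assign_halves(pairless_ref)
        rng = np.random.default_rng(1)
        rows = [(f"s{i}", g, "Jk1", float(rng.integers(1, 50)))
                for i in range(3) for g in pairless_ref.v_names]
        hb = half_bias(make_table(rows, genes=pairless_ref.v_names),
                       pairless_ref)
        assert np.allclose(hb.sum(axis=1).values, 1.0)

    def test_planted_distal_shift_recovered(self, pairless_ref):
        """Pro-B truth with distal share 0.55 vs pre-B 0.40 yields a
        recovered difference of ~0.15."""
        from kappaseq.simulate import simulate_repertoire
        from conftest import clean_config

        assign_halves(pairless_ref)
        prox = [g.name for g in pairless_ref.v_genes if g.half == "proximal"]
        dist = [g.name for g in pairless_ref.v_genes if g.half == "distal"]
        rows = []
        for sample, d_share in (("proB", 0.55), ("preB", 0.40)):
            f = pd.DataFrame(0.0, index=pairless_ref.v_names,
                             columns=list(JK_NAMES))
            f.loc[prox, "Jk1"] = (1 - d_share) / len(prox)
            f.loc[dist, "Jk1"] = d_share / len(dist)
            cfg = clean_config(n_molecules=20000)
            truth = simulate_repertoire(pairless_ref, cfg, seed=13, freq=f)
            counts = truth.molecules.groupby(["gene", "jk"]).size()
            rows += [(sample, g, jk, float(n)) for (g, jk), n in counts.items()]
        hb = half_bias(make_table(rows, genes=pairless_ref.v_names),
                       pairless_ref)
        diff = hb.loc["proB", "distal"] - hb.loc["preB", "distal"]
        assert abs(diff - 0.15) < 0.02
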