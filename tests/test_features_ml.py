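"""Feature windows, track quantification and random-forest models."""

import numpy as np
import pandas as pd
import pytest

from kappaseq.features import assemble_matrix, build_windows, quantify_track
from kappaseq.ml import (
    correlate_feature,
    rf_classify,
    rf_regress,
    rfe_select,
)
from kappaseq.simulate import (
    SimConfig,
    make_synthetic_locus,
    simulate_repertoire,
    simulate_signal_tracks,
)

from conftest import clean_config


class TestWindows:
    def test_rss_window_is_coding_plus_500(self, toy_ref):
        g = toy_ref.v_genes[0]
        w = build_windows(g)
        assert (w.rss[1] - w.rss[0]) == g.coding_len + 500
        # 300 bp coding regions give the 800 bp RSS window
        assert w.rss[1] - w.rss[0] == 800

    def test_window_adjacency_and_sizes(self, toy_ref):
        for g in toy_ref.v_genes:
            w = build_windows(g)
            if g.orientation == "deletional":
                assert w.upstream[1] == w.promoter[0]
                assert w.rss[1] == w.downstream[0]
            else:
                assert w.promoter[1] == w.upstream[0]
                assert w.downstream[1] == w.rss[0]
            assert w.upstream[1] - w.upstream[0] == 2500
            assert w.downstream[1] - w.downstream[0] == 2500
            w.validate()  # windows never overlap

    def test_inversional_windows_mirror_deletional(self, toy_ref):
        dele = next(g for g in toy_ref.v_genes if g.orientation == "deletional")
        inv = next(g for g in toy_ref.v_genes if g.orientation == "inversional")
        wd, wi = build_windows(dele), build_windows(inv)
        for name in ("promoter", "rss", "upstream", "downstream"):
            ld = wd.as_dict()[name]
            li = wi.as_dict()[name]
            assert (ld[1] - ld[0]) == (li[1] - li[0])
        # upstream is 5' in each gene's own orientation
        assert wd.upstream[1] <= wd.promoter[0]
        assert wi.upstream[0] >= wi.promoter[1]


class TestQuantifyTrack:
    def _windows(self, toy_ref):
        return build_windows(toy_ref.v_genes[0])

    def test_uniform_coverage_counts_bases(self, toy_ref):
        w = self._windows(toy_ref)
        ws, we = w.promoter
        track = pd.DataFrame({"chrom": ["igk"], "start": [ws], "end": [we],
                              "value": [1.0]})
        sig = quantify_track(track, w, total_tags=1e7)
        assert sig["promoter"] == pytest.approx(we - ws)

    def test_inverse_scaling_with_total_tags(self, toy_ref):
        w = self._windows(toy_ref)
        ws, we = w.promoter
        track = pd.DataFrame({"chrom": ["igk"], "start": [ws], "end": [we],
                              "value": [1.0]})
        s1 = quantify_track(track, w, total_tags=1e7)["promoter"]
        s2 = quantify_track(track, w, total_tags=2e7)["promoter"]
        assert s2 == pytest.approx(s1 / 2)

    def test_linear_in_coverage(self, toy_ref):
        w = self._windows(toy_ref)
        ws, we = w.rss
        t1 = pd.DataFrame({"chrom": ["igk"], "start": [ws], "end": [we],
                           "value": [1.5]})
        t3 = t1.assign(value=4.5)
        s1 = quantify_track(t1, w, 1e7)["rss"]
        s3 = quantify_track(t3, w, 1e7)["rss"]
        assert s3 == pytest.approx(3 * s1)

    def test_empty_track_all_zero(self, toy_ref):
        w = self._windows(toy_ref)
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        sig = quantify_track(track, w, 1e7)
        assert all(v == 0.0 for v in sig.values())

    def test_partial_overlap_prorated(self, toy_ref):
        w = self._windows(toy_ref)
        ws, we = w.promoter
        half = (ws + we) // 2
        track = pd.DataFrame({"chrom": ["igk"], "start": [ws], "end": [half],
                              "value": [2.0]})
        sig = quantify_track(track, w, 1e7)
        assert sig["promoter"] == pytest.approx(2.0 * (half - ws))


class TestAssembleMatrix:
    def _setup(self, ref, seed=1, n_tracks=34, planted_b=0.3):
        cfg = clean_config(planted_b=planted_b, n_tracks=n_tracks)
        truth = simulate_repertoire(ref, cfg, seed=seed)
        tracks, manifest = simulate_signal_tracks(ref, truth, cfg, seed=seed + 1)
        return truth, tracks, manifest

    def test_preB_mode_134_plus_shape(self, pairless_ref):
        _, tracks, manifest = self._setup(pairless_ref)
        mat = assemble_matrix(pairless_ref, tracks, manifest, "preB")
        assert mat.shape == (len(pairless_ref.v_genes), 4 * 34 + 2)

    def test_proB_mode_restricts_tracks(self, pairless_ref):
        _, tracks, manifest = self._setup(pairless_ref)
        n_pro = int((manifest["stage"] == "proB").sum())
        mat = assemble_matrix(pairless_ref, tracks, manifest, "proB")
        assert mat.shape[1] == 4 * n_pro + 2

    def test_gene_order_matches_reference(self, pairless_ref):
        _, tracks, manifest = self._setup(pairless_ref)
        mat = assemble_matrix(pairless_ref, tracks, manifest, "preB")
        assert mat.index.tolist() == pairless_ref.v_names

    def test_mask_columns_dropped(self, pairless_ref):
        _, tracks, manifest = self._setup(pairless_ref)
        drop = ["noise_01:promoter", "noise_02:rss"]
        mat = assemble_matrix(pairless_ref, tracks, manifest, "preB",
                              mask_columns=drop)
        assert not set(drop) & set(mat.columns)
        assert mat.shape[1] == 4 * 34 + 2 - 2

    def test_full_scale_locus_162_observations(self, tmp_path):
        """A 162-gene annotation yields 162 observations for the ML stage,
        surviving an annotation round trip."""
        from kappaseq.locus import load_reference, write_annotation, \
            write_genome, write_pairs

        ref = make_synthetic_locus(n_genes=162, seed=2, n_identical_pairs=3)
        write_genome(ref, tmp_path / "g.fa")
        write_annotation(ref, tmp_path / "a.tsv")
        write_pairs(ref, tmp_path / "p.tsv")
        loaded = load_reference(tmp_path / "g.fa", tmp_path / "a.tsv",
                                tmp_path / "p.tsv")
        assert len(loaded.v_genes) == 162
        _, tracks, manifest = self._setup(loaded, n_tracks=3)
        mat = assemble_matrix(loaded, tracks, manifest, "preB")
        assert mat.shape[0] == 162


@pytest.fixture(scope="module")
def planted_setup():
    """60-gene locus with a strong planted log-linear effect of one track's
    RSS-window signal on rearrangement frequency."""
    ref = make_synthetic_locus(n_genes=60, seed=4, n_identical_pairs=0)
    cfg = SimConfig(n_molecules=500, planted_b=0.5, planted_noise_sd=0.5,
                    inactive_frac=0.2, jk_dirichlet_conc=None)
    truth = simulate_repertoire(ref, cfg, seed=7)
    tracks, manifest = simulate_signal_tracks(ref, truth, cfg, seed=8)
    mat = assemble_matrix(ref, tracks, manifest, "preB")
    active = truth.freq.index[truth.freq.sum(axis=1) > 0]
    resp = np.log(truth.freq.sum(axis=1).loc[active])
    return ref, truth, mat, active, resp


class TestClassification:
    def test_planted_feature_separates_classes(self, planted_setup):
        ref, truth, mat, active, _ = planted_setup
        # labels perfectly determined by one feature
        det = (mat["planted_mark:rss"] > mat["planted_mark:rss"].median())
        labels = det.map({True: "active", False: "inactive"})
        rep = rf_classify(mat, labels, n_trees=200, seed=1)
        assert rep.performance > 0.9
        assert rep.vi.index[0] == "planted_mark:rss"

    def test_random_labels_near_majority_rate(self, planted_setup):
        _, _, mat, _, _ = planted_setup
        rng = np.random.default_rng(3)
        labels = pd.Series(rng.permutation(["a"] * 40 + ["b"] * 20),
                           index=mat.index)
        rep = rf_classify(mat, labels, n_trees=200, seed=2, tune_mtry=False)
        assert abs(rep.performance - 2 / 3) < 0.2

    def test_constant_features_give_majority_rate(self):
        idx = [f"g{i}" for i in range(40)]
        mat = pd.DataFrame({"f1": 1.0, "f2": 2.0}, index=idx)
        labels = pd.Series(["a"] * 28 + ["b"] * 12, index=idx)
        rep = rf_classify(mat, labels, n_trees=50, seed=3, tune_mtry=False)
        assert rep.performance == pytest.approx(28 / 40)

    def test_single_class_rejected(self, planted_setup):
        _, _, mat, _, _ = planted_setup
        labels = pd.Series("a", index=mat.index)
        with pytest.raises(ValueError, match="both classes"):
            rf_classify(mat, labels)

    def test_cv_partition_every_gene_tested_once(self, planted_setup):
        _, _, mat, _, _ = planted_setup
        labels = (mat["planted_mark:rss"] > mat["planted_mark:rss"].median())
        labels = labels.map({True: "a", False: "b"})
        rep = rf_classify(mat, labels, n_trees=50, seed=4, tune_mtry=False)
        assert rep.predictions.notna().all()
        assert set(rep.predictions.index) == set(mat.index)


class TestRegression:
    def test_planted_effect_top_variable_importance(self, planted_setup):
        _, _, mat, active, resp = planted_setup
        rep = rf_regress(mat.loc[active], resp, n_trees=300, seed=1)
        assert rep.vi.index[0] == "planted_mark:rss"

    def test_constant_response_zero_rmse(self, planted_setup):
        _, _, mat, active, _ = planted_setup
        resp = pd.Series(2.5, index=active)
        rep = rf_regress(mat.loc[active], resp, n_trees=100, seed=2)
        assert rep.performance == pytest.approx(0.0, abs=1e-12)
        assert (rep.vi.abs() < 1e-12).all()

    def test_independent_response_rmse_near_sd(self, planted_setup):
        _, _, mat, active, _ = planted_setup
        rng = np.random.default_rng(5)
        resp = pd.Series(rng.normal(size=len(active)), index=active)
        rep = rf_regress(mat.loc[active], resp, n_trees=200, seed=3)
        assert abs(rep.performance - resp.std()) < 0.5 * resp.std()

    def test_too_few_observations_refused(self, planted_setup):
        _, _, mat, active, resp = planted_setup
        few = list(active[:10])
        with pytest.raises(ValueError, match="too few"):
            rf_regress(mat.loc[few], resp.loc[few])

    def test_shuffled_response_destroys_planted_rank(self, planted_setup):
        """Permuting the response demotes the planted feature out of the VI
        top 5 in nearly every rerun."""
        _, _, mat, active, resp = planted_setup
        rng = np.random.default_rng(11)
        demoted = 0
        n_runs = 15
        for i in range(n_runs):
            shuffled = pd.Series(rng.permutation(resp.values), index=resp.index)
            rep = rf_regress(mat.loc[active], shuffled, n_trees=60,
                             n_folds=5, seed=i)
            rank = rep.vi.index.get_loc("planted_mark:rss")
            demoted += rank >= 5
        assert demoted / n_runs >= 0.9


class TestRFE:
    def test_planted_single_feature_suffices(self, planted_setup):
        _, _, mat, active, resp = planted_setup
        rep = rf_regress(mat.loc[active], resp, n_trees=200, seed=1)
        curve, selected = rfe_select(mat.loc[active], resp, rep,
                                     sizes=[1, 2, 3, 5, 10, 20],
                                     n_trees=100, seed=1)
        assert "planted_mark:rss" in selected
        assert len(selected) <= 3

    def test_top_k_one_single_row_curve(self, planted_setup):
        _, _, mat, active, resp = planted_setup
        rep = rf_regress(mat.loc[active], resp, n_trees=100, seed=2)
        curve, selected = rfe_select(mat.loc[active], resp, rep, top_k=1,
                                     n_trees=50, seed=2)
        assert len(curve) == 1 and len(selected) == 1

    def test_top_k_clamped_to_feature_count(self, planted_setup):
        _, _, mat, active, resp = planted_setup
        small = mat.loc[active, mat.columns[:5]]
        rep = rf_regress(small, resp, n_trees=50, seed=3)
        curve, _ = rfe_select(small, resp, rep, top_k=20, n_trees=30, seed=3)
        assert curve["n_features"].max() == 5


class TestCorrelation:
    def test_exact_linear_relation(self, planted_setup):
        _, _, mat, active, _ = planted_setup
        resp = 2.0 * mat.loc[active, "planted_mark:rss"]
        r, p = correlate_feature(mat.loc[active], resp, "planted_mark:rss")
        assert r == pytest.approx(1.0)
        assert p < 1e-20

    def test_planted_log_linear_low_noise(self):
        ref = make_synthetic_locus(n_genes=40, seed=9, n_identical_pairs=0)
        cfg = SimConfig(n_molecules=100, planted_b=0.5, planted_noise_sd=1e-4,
                        inactive_frac=0.0, jk_dirichlet_conc=None)
        truth = simulate_repertoire(ref, cfg, seed=10)
        tracks, manifest = simulate_signal_tracks(ref, truth, cfg, seed=11)
        mat = assemble_matrix(ref, tracks, manifest, "preB")
        resp = np.log(truth.freq.sum(axis=1))
        r, _ = correlate_feature(mat, resp, "planted_mark:rss")
        assert r > 0.999

    def test_zero_variance_flagged(self, planted_setup):
        _, _, mat, active, resp = planted_setup
        m = mat.loc[active].copy()
        m["const"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            correlate_feature(m, resp, "const")

    def test_null_correlations_small(self, planted_setup):
        _, _, mat, active, _ = planted_setup
        rng = np.random.default_rng(17)
        pvals = []
        for i in range(30):
            resp = pd.Series(rng.normal(size=len(active)), index=active)
            r, p = correlate_feature(mat.loc[active], resp, "noise_05:rss")
            pvals.append(p)
        # p-values roughly uniform under the null
        assert 0.1 < np.mean(pvals) < 0.9
        assert min(pvals) > 1e-6
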