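#!/usr/bin/env python
"""Chromatin-feature random forests over the synthetic locus.

Plants a log-linear effect of one track's RSS-window signal on gene
rearrangement propensity, emits 34 coverage tracks (1 planted + 33
noise), quantifies the four windows per gene, and runs the supervised
stack: RF classification of active vs inactive genes, RF regression of
log recombination frequency with variable importance, RFE feature
selection, and the single-feature Pearson correlation.  Outputs under
results/ml/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kappaseq.features import assemble_matrix
from kappaseq.locus import load_reference
from kappaseq.ml import correlate_feature, rf_classify, rf_regress, rfe_select
from kappaseq.simulate import (
    SimConfig,
    simulate_repertoire,
    simulate_signal_tracks,
    write_bedgraph,
)
from kappaseq.stats import classify_active

ROOT = Path(__file__).resolve().parent.parent / "results"
REF = ROOT / "reference"
OUT = ROOT / "ml"

N_TREES = 500  # scaled-down forest for the driver; library default is 5000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = load_reference(REF / "locus.fa", REF / "annotation.tsv",
                         REF / "identical_pairs.tsv")
    cfg = SimConfig(n_molecules=50_000, planted_b=0.5, planted_noise_sd=0.5,
                    inactive_frac=0.2)
    truth = simulate_repertoire(ref, cfg, seed=30)
    tracks, manifest = simulate_signal_tracks(ref, truth, cfg, seed=31)
    (OUT / "tracks").mkdir(exist_ok=True)
    for name, df in tracks.items():
        write_bedgraph(df, OUT / "tracks" / f"{name}.bedGraph")
    manifest.to_csv(OUT / "tracks" / "manifest.tsv", sep="\t", index=False)

    matrix = assemble_matrix(ref, tracks, manifest, "preB")
    matrix.to_csv(OUT / "feature_matrix.tsv", sep="\t")
    print(f"feature matrix: {matrix.shape[0]} genes x {matrix.shape[1]} features")

    # observed activity from a sampled repertoire
    counts = truth.molecules.groupby(["gene", "jk"]).size()
    from kappaseq.stats import RepertoireTable
    table = RepertoireTable(
        counts=pd.DataFrame(
            [("s1", g, jk, float(n)) for (g, jk), n in counts.items()],
            columns=["sample", "v_gene", "jk", "count"]),
        samples=pd.DataFrame({"stage": ["preB"]},
                             index=pd.Index(["s1"], name="sample")),
        genes=ref.v_names)
    labels = classify_active(table, mode="preB")

    clf = rf_classify(matrix, labels, n_trees=N_TREES, seed=32)
    clf.vi.to_csv(OUT / "classification_vi.tsv", sep="\t")
    print(f"classification accuracy {clf.performance:.3f}; "
          f"top VI: {', '.join(clf.vi.index[:3])}")

    active = labels.index[labels == "active"]
    obs_freq = table.matrix().sum(axis=1) / cfg.n_molecules
    resp = np.log(obs_freq.loc[active])
    reg = rf_regress(matrix.loc[active], resp, n_trees=N_TREES, seed=33)
    reg.vi.to_csv(OUT / "regression_vi.tsv", sep="\t")
    print(f"regression RMSE {reg.performance:.3f} (response SD "
          f"{resp.std():.3f}); top VI: {', '.join(reg.vi.index[:3])}")

    curve, selected = rfe_select(matrix.loc[active], resp, reg,
                                 sizes=[1, 2, 3, 5, 10, 15, 20],
                                 n_trees=200, seed=34)
    curve.to_csv(OUT / "rfe_curve.tsv", sep="\t", index=False)
    print(f"RFE: best subset {selected} "
          f"(within one SE of the best of {len(curve)} sizes)")

    r, p = correlate_feature(matrix.loc[active], resp, "planted_mark:rss")
    pd.Series({"pearson_r": r, "p_value": p}) \
        .to_csv(OUT / "planted_feature_correlation.tsv", sep="\t")
    print(f"planted feature vs log frequency: r={r:.2f}, p={p:.2e}")


if __name__ == "__main__":
    main()
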