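#!/usr/bin/env python
"""Repertoire statistics over the called libraries.

Computes the figure-style analyses: pooled VkJkALL frequencies, global and
per-gene Jk usage, the per-Jk repertoire correlation matrix, active-gene
classification (15 reads/million pre-B rule; 1-read pro-B rule), the
gDNA-vs-RNA divergence filter (>=2-fold average, >=1.5-fold in every
replicate, functional genes only), and the proximal/distal half split.
Tables land under results/stats/.
"""

from pathlib import Path

import pandas as pd

from kappaseq.locus import assign_halves, load_reference
from kappaseq.stats import (
    RepertoireTable,
    classify_active,
    frequencies,
    half_bias,
    jk_repertoire_correlations,
    jk_usage,
    ratio_analysis,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
REF = ROOT / "reference"
OUT = ROOT / "stats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = load_reference(REF / "locus.fa", REF / "annotation.tsv",
                         REF / "identical_pairs.tsv")
    assign_halves(ref)
    counts = pd.read_csv(ROOT / "calls" / "counts.tsv", sep="\t")
    samples = pd.read_csv(ROOT / "libraries" / "samples.tsv", sep="\t") \
        .set_index("sample")
    table = RepertoireTable(counts=counts, samples=samples, genes=ref.v_names)

    pre_g = table.sample_ids(stage="preB", molecule="gdna")
    pre_r = table.sample_ids(stage="preB", molecule="rna")
    pro_r = table.sample_ids(stage="proB", molecule="rna")

    freq = frequencies(table, samples=pre_g)
    freq.rename("frequency").to_csv(OUT / "preB_gdna_vkjkall_freq.tsv", sep="\t")
    print(f"pre-B gDNA VkJkALL: {int((freq > 0).sum())} genes with reads; "
          f"top gene {freq.idxmax()} at {100 * freq.max():.2f}%")

    pct, prof = jk_usage(table, samples=pre_g)
    pct.to_csv(OUT / "preB_gdna_jk_usage.tsv", sep="\t")
    prof.to_csv(OUT / "preB_gdna_per_gene_jk_profile.tsv", sep="\t")
    print("global Jk usage (%):",
          {k: round(v, 1) for k, v in pct.items()})

    corr = jk_repertoire_correlations(table, samples=pre_g)
    corr.to_csv(OUT / "preB_gdna_jk_correlations.tsv", sep="\t")

    active_pre = classify_active(table, mode="preB", samples=pre_g)
    active_pro = classify_active(table, mode="proB", samples=pro_r)
    pd.DataFrame({"preB_gdna": active_pre, "proB_rna": active_pro}) \
        .to_csv(OUT / "active_genes.tsv", sep="\t")
    print(f"active genes: pre-B {int((active_pre == 'active').sum())}, "
          f"pro-B {int((active_pro == 'active').sum())} of {len(ref.v_genes)}")

    report = ratio_analysis(table, table, pre_g, pre_r,
                            functional_only=ref)
    flagged = report.flags[report.flags != ""]
    report.per_replicate.assign(mean=report.mean_ratio, flag=report.flags) \
        .to_csv(OUT / "gdna_rna_ratio_filter.tsv", sep="\t")
    print(f"divergence filter: {len(flagged)} functional genes "
          f"(gDNA-high {(report.flags == 'A').sum()}, "
          f"RNA-high {(report.flags == 'B').sum()}); "
          f"{len(report.excluded)} excluded")

    pro_g = table.sample_ids(stage="proB", molecule="gdna")
    hb = pd.concat([
        half_bias(table, ref, samples=pre_g),
        half_bias(table, ref, samples=pro_g),
    ])
    hb.to_csv(OUT / "half_bias.tsv", sep="\t")
    pro = hb.loc[pro_g, "distal"].mean()
    pre = hb.loc[pre_g, "distal"].mean()
    print(f"distal-half share: pro-B {100 * pro:.1f}% vs pre-B "
          f"{100 * pre:.1f}% (difference {100 * (pro - pre):+.1f} points)")


if __name__ == "__main__":
    main()
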