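#!/usr/bin/env python
"""Simulate the sequencing libraries behind the repertoire analyses.

One shared ground truth per sort batch; from each batch a gDNA and an RNA
library (paired, as in the study's design): 3 pre-B sorts plus 2 pro-B
sorts, with the pro-B truth skewed toward the Jk-distal half and elevated
Jk1 usage.  Writes FASTQ pairs plus truth tables under results/libraries/.
"""

from pathlib import Path

import pandas as pd

from kappaseq.locus import load_reference
from kappaseq.simulate import (
    SimConfig,
    gdna_read_pairs,
    rna_read_pairs,
    simulate_repertoire,
    write_fastq_pair,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
REF = ROOT / "reference"
OUT = ROOT / "libraries"

N_MOLECULES = 20_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = load_reference(REF / "locus.fa", REF / "annotation.tsv",
                         REF / "identical_pairs.tsv")
    from kappaseq.locus import assign_halves
    assign_halves(ref)

    sheet = []
    distal = [g.name for g in ref.v_genes if g.half == "distal"]
    d_pre = None
    for stage, n_rep, jk1 in (("preB", 3, 0.40), ("proB", 2, 0.50)):
        cfg = SimConfig(n_molecules=N_MOLECULES,
                        jk_weights=(jk1, *(((1 - jk1) / 3,) * 3)))
        # one biological truth per stage (frequencies, promoter strengths,
        # inactive genes); replicates differ only by sampling
        stage_truth = simulate_repertoire(
            ref, cfg, seed={"preB": 501, "proB": 502}[stage])
        if stage == "preB":
            d_pre = stage_truth.freq.loc[distal].values.sum()
            strengths = stage_truth.promoter_strength  # shared across stages
        else:
            # pro-B repertoires skew ~5 points toward the Jk-distal half
            # relative to the pre-B truth
            f = stage_truth.freq.copy()
            d0 = f.loc[distal].values.sum()
            target = min(d_pre + 0.05, 0.95)
            boost = target * (1 - d0) / (d0 * (1 - target))
            f.loc[distal] *= boost
            stage_truth.freq = f / f.values.sum()
        stage_truth.freq.to_csv(OUT / f"{stage}_truth.tsv", sep="\t")
        for rep in range(1, n_rep + 1):
            seed = 1000 * rep + (0 if stage == "preB" else 17)
            truth = simulate_repertoire(ref, cfg, seed=seed,
                                        freq=stage_truth.freq)
            truth.promoter_strength = strengths
            for chem in ("gdna", "rna"):
                sample = f"{stage}_{chem}_rep{rep}"
                if chem == "gdna":
                    reads = gdna_read_pairs(truth, ref, cfg, seed=seed + 1)
                else:
                    reads, _ = rna_read_pairs(truth, ref, cfg, seed=seed + 2)
                write_fastq_pair(reads, OUT / sample)
                sheet.append({
                    "sample": sample, "stage": stage, "genotype": "WT",
                    "molecule": chem, "replicate": rep,
                    "pairing": f"{stage}{rep}", "n_reads": len(reads),
                })
                print(f"{sample}: {len(reads)} read pairs")
    pd.DataFrame(sheet).to_csv(OUT / "samples.tsv", sep="\t", index=False)
    print(f"sample sheet -> {OUT / 'samples.tsv'}")


if __name__ == "__main__":
    main()
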