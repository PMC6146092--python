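# kappaseq

Analysis of the mouse immunoglobulin kappa light-chain (Igκ) repertoire:
which Vκ gene segments rearrange, how often, to which Jκ, and what
chromatin and sequence features predict those frequencies.

During B-cell development each Igκ allele joins one of ~160 Vκ gene
segments to one of 4 functional Jκ segments (Jκ1, Jκ2, Jκ4, Jκ5).
Deep-sequencing protocols read this repertoire either from genomic DNA
(sheared fragments captured at a Jκ primer; unbiased, since each cell
carries two alleles) or from RNA (5′ RACE; weighted by promoter strength
and depleted of non-productive messages by nonsense-mediated decay).
`kappaseq` implements the full computational side of such a study as a
tested Python package:

* **locus model** (`kappaseq.locus`) — Vκ/Jκ annotation with orientation
  (deletional vs inversional relative to the Jκ–Cκ cluster), RSS
  coordinates, RIC scores, functionality classes, reference corrections,
  the registry of 3′-identical Vκ gene pairs, and the proximal/distal
  locus-half split;
* **simulator** (`kappaseq.simulate`) — ground-truthed gDNA and RNA
  libraries (500–1,000 bp shear, 6N UMIs, PCR re-sampling, Jκ primer
  cross-amplification, promoter strengths, NMD) plus planted-effect
  coverage tracks, so every downstream stage is testable without any
  external download;
* **read prep** (`kappaseq.prep`) — 3′ quality trimming (Phred > 20 kept,
  pair dropped if either mate loses > 50 bases), UMI extraction, and
  overlap-consensus pair merging;
* **V/J caller** (`kappaseq.caller`) — end-anchored V assignment with the
  two step-function cutoffs (≥ 150 aligned bases, ≥ 95% identity), Jκ
  identification from the sequence upstream of the primer (excluding the
  1 or 6 most Vκ-proximal exon nucleotides, so junctional nibbling and
  cross-priming are handled), frame-based productivity, orientation class;
* **deduplication** (`kappaseq.dedup`) — one count per (6N UMI [+ V read
  start for gDNA], gene, Jκ) key, and tag-ratio reallocation of counts
  between 3′-identical gene pairs, conserving pair totals exactly;
* **repertoire statistics** (`kappaseq.stats`) — pooled-replicate
  frequencies (Σ reads / Σ total), VκJκALL and per-Jκ views, Jκ usage,
  active-gene classification (15 reads per million for pre-B; 1 read for
  low-depth pro-B), the gDNA/RNA divergence filter (≥ 2-fold mean and
  ≥ 1.5-fold in every replicate), one-read pseudo-count ratios, and the
  proximal/distal half bias;
* **feature/ML stage** (`kappaseq.features`, `kappaseq.ml`) — four
  windows per gene (promoter, RSS = coding + 500 bp, ± 2.5 kb flanks),
  10-million-tag normalisation of bedGraph coverage, and random forests
  (10-fold CV, every gene tested once, 5,000 trees per fold by default)
  with impurity variable importance (MDGI / MDNP) and recursive feature
  elimination over the top-20 features.

The numbered drivers under `analysis/` run the whole study on a
synthetic 162-gene locus: `01_build_reference.py`,
`02_simulate_libraries.py`, `03_call_repertoires.py`,
`04_repertoire_stats.py`, `05_feature_models.py`, writing their tables
under `results/`.

## Worked example

Simulate a library with PCR duplication and Jκ cross-priming, run the
pipeline, and compare against the generator's ground truth:

```python
from kappaseq.caller import VAligner
from kappaseq.pipeline import run_library
from kappaseq.simulate import SimConfig, make_synthetic_locus

ref = make_synthetic_locus(n_genes=20, seed=11, n_identical_pairs=2)
cfg = SimConfig(n_molecules=5000, pcr_dup_rate=0.5, cross_prime_rate=0.05)
res = run_library(ref, cfg, "gdna", seed=3, aligner=VAligner(ref))
print(len(res.calls), len(res.dedup_calls))
prod = sum(c.productive == "productive" for c in res.calls) / len(res.calls)
print(f"productive fraction {prod:.3f}")
```

prints (seed 3):

```
9864 5000
productive fraction 0.337
```

9,864 reads collapse back to exactly the 5,000 simulated molecules
(UMI + shear-start deduplication), and about one third of junctions are
productive — random junctional trimming/insertion makes the three
reading-frame offsets equiprobable, and only the in-frame third can
encode protein. Running the full driver stack prints, among other lines:

```
global Jk usage (%): {'Jk1': 42.4, 'Jk2': 19.9, 'Jk4': 18.5, 'Jk5': 19.2}
divergence filter: 21 functional genes (gDNA-high 17, RNA-high 4); 46 excluded
distal-half share: pro-B 62.7% vs pre-B 57.7% (difference +5.0 points)
regression RMSE 0.727 (response SD 1.349); top VI: planted_mark:rss, ...
```

i.e. Jκ1 dominates usage, a fifth of functional genes diverge ≥ 2-fold
between gDNA and RNA libraries (promoter-strength differences), the
planted pro-B distal-half skew is recovered at +5 points, and the
planted chromatin mark's RSS-window feature tops the regression variable
importance.

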