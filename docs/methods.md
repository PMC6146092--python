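# Methods

This note documents the models, numerical choices and limitations behind
`kappaseq`, in the order data flows through the package.

## Locus model

Coordinates are 0-based half-open genomic intervals internally, BED-like
TSV on disk; 1-based numbers appear only in human-readable messages.
Orientation is stored as *deletional* / *inversional* relative to the
Jκ–Cκ cluster rather than as +/− strand, so synthetic loci need no
chromosome context. Only the four functional Jκ segments are modelled
(Jκ3 is non-functional); reads matching no Jκ exon are counted as
unassigned-J in QC rather than forced onto a segment. RIC scores are an
input annotation column: the package consumes RSS quality, it does not
recompute it.

Reference corrections (orientation flips, RSS replacements,
reclassified pseudogenes) are expressed as a generic name-keyed override
table; `DEFAULT_CORRECTIONS` encodes the published fixes for the real
C57BL/6 locus (Vκ8-23-1 orientation, Vκ4-60 RSS, four genes reclassified
per IMGT). The discriminating tag strings for the three 3′-identical
gene pairs live in external supplementary data, so the registry is
user-supplied and is verified against the genome at load time: members
must share their 3′-most 150 coding bases and each tag must occur in
exactly one member.

Locus halves: the generic rule halves the genomic span from the most
Jκ-proximal to the most Jκ-distal Vκ gene at its midpoint (ties to the
proximal side, so an evenly spaced locus splits evenly); for the real
locus the named boundary (proximal through Vκ13-76, distal from Vκ4-77)
reproduces the published split and is available as an explicit argument.

## Synthetic data generator

The generator emulates the study's data-generating process; its defaults
are the study conditions, not tuning knobs:

* gDNA fragments 500–1,000 bp (uniform), ending at a Jκ PCR primer, 6N
  UMI on the shear-side adapter;
* PCR re-sampling: each molecule is re-emitted with probability
  `pcr_dup_rate` repeatedly (geometric; mean 1/(1−p) copies), copies
  sharing UMI and shear start; default 0.3;
* Jκ cross-priming: with probability 0.05 the *next downstream* Jκ's
  primer amplifies the product (the retained downstream exon makes this
  physically possible; only adjacent-Jκ cross-priming is modelled so
  fragments keep enough V sequence to be assignable);
* Jκ usage ~(40, 20, 20, 20)% globally, with per-gene Jκ profiles drawn
  from a Dirichlet around that base (concentration 6) to emulate the
  strongly gene-specific Jκ usage seen in real repertoires;
* gene propensities log-normal (σ = 1); 20% of genes inactive
  (zero frequency). When a track effect is planted
  (`planted_b ≠ 0`), per-gene log-propensity is `b·signal + ε`
  (signal ~ U(0,10), ε ~ N(0, 0.5)) and the inactive set is the
  lowest-propensity genes — activity follows chromatin state, which is
  what makes classification recovery meaningful;
* RNA libraries: transcript count ∝ frequency × promoter strength ×
  (1 for in-frame molecules, `nmd_survival` = 0.2 otherwise). Promoter
  strengths are log-normal with σ = 0.55, chosen so that roughly a fifth
  of genes sit ≥ 2-fold from parity — the scale of gDNA/RNA divergence
  the ratio filter is designed to detect. Transcripts retain the leader
  intron so a single V reference model serves both chemistries (a
  deliberate simplification; splicing is irrelevant to every statistic
  computed here);
* junctions: V-side trim U{0..4}, J-side trim U{0..1} (within the
  caller's junction-exclusion allowance), untemplated insertion sized so
  the three reading-frame classes are exactly equiprobable. For in-frame
  junctions the draw is repeated until no stop codon spans the junction;
  coding regions and Jκ exons are generated stop-free in frame. Stop
  codon injection exists as an option and is off by default, so
  productivity is exactly frame-determined and the expected
  non-productive fraction is 2/3;
* read qualities are constant Phred 35 unless substitution errors are
  injected (`seq_error_rate`, default 0 in oracle settings), decoupling
  trimming tests from assignment tests;
* read names encode (molecule, gene, Jκ, productivity, priming Jκ) as a
  test oracle; the pipeline never parses names.

Synthetic reads are 520 bp per mate so that every 500–1,000 bp fragment
merges from its two ends — long-read-like, which keeps the end-to-end
molecule accounting exact; shorter mates only remove the longest
fragments from the merged pool uniformly at random.

What the generator does **not** emulate: realistic Illumina error
profiles, indels, chimeric reads, allelic exclusion, receptor editing,
or real chromatin-feature correlation structure (noise tracks are
independent). Passing tests therefore demonstrate the pipeline's
correctness on its stated contracts, not its robustness to every
artefact of real libraries.

## Read preparation

Trailing bases with Phred ≤ 20 are removed from the 3′ end of each mate
("Phred > 20" read literally as a strict inequality); if either mate
loses more than 50 bases the pair is discarded. 5′ ends are never
touched. Merging is an in-house seed-and-extend overlap scan (exact
20-mer seed of the reverse-complemented mate-2 prefix, exhaustive offset
scan as fallback), accepting the longest overlap with ≤ 10% mismatches
and at least 20 bp; the higher-quality base wins at a mismatch.
Containment (fragment shorter than a read) merges to the union span.
Unmerged pairs are dropped from downstream analysis. The 6N UMI is taken
from the first six bases of R1 in both chemistries (shear-side adapter
for gDNA, bridge-adapter 3′ end for RNA).

## V/J calling

V assignment is a gapless end-anchored alignment of the read into
per-gene V references (leader through coding end plus 600 bp upstream
context — the context makes the shear start an informative dedup
coordinate). Exact 20-mer seeds (stride 30, dense fallback) fix a
diagonal; the diagonal is scored +1/match, −3/mismatch and the
maximal-scoring prefix defines the aligned segment; identity =
matches / aligned columns. Assignment requires ≥ 150 aligned bases and
≥ 95% identity — both thresholds are the contract and are
property-tested as step functions. Ties (identical pairs) break by
identity, then aligned length, then gene name, and are flagged
ambiguous rather than dropped, because the reallocation step corrects
them at the count level. The simulator produces substitutions only, so
no gap state is needed; with indel-bearing data the aligner would
undercall and the thresholds would act conservatively.

Jκ identification searches the read for each Jκ exon minus its 1
(primary primer set) or 6 (alternate set) most Vκ-proximal nucleotides,
choosing the most V-proximal match; this simultaneously tolerates
junctional nibbling of the exon edge and corrects primer
cross-amplification, since a cross-primed read still carries the true
(more V-proximal) exon upstream of the mis-priming Jκ's own exon. A
near-exact (≤ 1 mismatch) pass runs only when no exon matches exactly.

Productivity is frame-based: the V coding frame (anchored at the coding
start, known from the alignment) must continue into the Jκ exon — the
virtual exon start must sit a multiple of 3 from the coding start — with
no in-frame stop codon between the coding start and the exon end within
the sequenced region. Reads missing either assignment are
*indeterminate*.

## Deduplication and reallocation

The dedup key is (sample, UMI, V-read start, gene, Jκ) for gDNA and
(sample, UMI, gene, Jκ) for RNA; including (gene, Jκ) is a conservative
choice so molecules from different assignments can never collapse. UMI
matching is exact — no 1-mismatch clustering — mirroring exact 6N use.
The first record in stable input order is retained; the operation is
idempotent. With a 6N-only key, collisions follow the birthday estimate
K(1−(1−1/K)^n), K = 4096 per (gene, Jκ) cell; tests check this bound
rather than pretending collisions away. gDNA keys add ~500 shear
positions and make collisions negligible at the depths used.

Identical-pair reallocation: with pooled deduplicated pair count
T = n_A + n_B and tag hits (a, b) among tag-covering reads,
n_A′ = T·a/(a+b) and n_B′ = T − n_A′. Counts stay real-valued
downstream and the pair total is conserved exactly; a + b = 0 leaves the
pair unadjusted with a warning.

## Repertoire statistics

Pooled-replicate frequency is Σ reads over replicates / Σ totals (the
definition used for the regression response); per-replicate vectors are
available for the paired analyses. Per-gene Jκ-usage profiles require
≥ 5 reads in every replicate. Active/inactive: pooled count ≥ 15 reads
per million pooled reads (pre-B rule, applied to pooled counts for
consistency with the response definition) or ≥ 1 read (pro-B low-depth
rule); the classification is monotone in the threshold. The divergence
filter takes the arithmetic mean of per-replicate frequency ratios and
flags a gene only when the mean is ≥ 2-fold *and* every replicate is
≥ 1.5-fold in the same direction; genes lacking reads in any replicate
of either repertoire are excluded, and pseudogenes are excluded in
functional-only mode. Zero frequencies entering a published-style ratio
are replaced by the frequency equivalent of one read (1/total) and the
ratio is flagged as an underrepresentation. Half bias sums frequencies
over proximal vs distal genes per sample; the two shares sum to 1 by
construction.

## Feature windows and random forests

Windows per gene, in the gene's own orientation: promoter = 500 bp
upstream of the leader-1 start plus leader and intron; RSS = coding
region + 500 bp downstream (800 bp for a 300 bp coding region);
upstream/downstream = 2.5 kb immediately beyond those. Windows never
overlap and adjacency is asserted. Coverage is consumed as bedGraph plus
a declared mapped-tag total; window signal = per-base coverage sum ×
10⁷/total_tags, i.e. linear in coverage and inversely proportional to
library size. The matrix appends RIC score and distance to Jκ1; with 34
tracks that is 4·34 + 2 = 138 columns. The published feature set counts
134, implying a handful of masked window features the text does not
enumerate; the assembler therefore computes all windows and accepts a
manifest-level column mask.

Models: scikit-learn random forests, 10-fold CV (shuffled, seeded,
every gene tested exactly once — asserted), 5,000 trees per fold by
default. Classification tunes mtry over {√p/2, √p, 2√p} by out-of-bag
score on the training fold only; regression uses the p/3 default.
Variable importance is impurity-based (mean decrease in Gini index /
node purity) and averaged across folds — whether to fold-average or
refit on all data was an open choice; fold-averaging keeps VI strictly
cross-validated. RFE restricts to the top-20 VI features and evaluates
VI-ranked nested subsets by CV, reporting the curve and the smallest
subset within one standard error of the best score; exhaustive 2²⁰
search would be computationally disproportionate and nested-subset RFE
is what the standard routine does.

Scaled problem sizes: the test-suite and driver forests use 100–500
trees and coarse RFE size grids ({1,2,3,5,10,20}); these sizes were
chosen to keep planted-effect recovery unambiguous while making the
suite quick to run, and the 5,000-tree default remains the library
setting. Planted-effect recovery (effect b = 0.5 on a U(0,10) signal
with ε ~ N(0,0.5), 33 independent noise tracks, 60-gene locus) ranks the
planted RSS-window feature first in regression VI and plateaus the RFE
curve by subset size ≤ 3 across ten seeds; below roughly b = 0.1 at that
noise level the planted feature is no longer reliably top-ranked.

## Known limitations

* The aligner has no gap state; indel-bearing reads would be truncated
  at the indel.
* RNA deduplication by 6N alone saturates at deep per-gene coverage
  (birthday collisions), exactly as the key construction implies; very
  deep RNA libraries undercount true molecules.
* The published processed read tables are not redistributed; analyses
  that assert their printed values require the user to supply the TSV
  (see `kappaseq.published`).
* Statistical significance testing between groups is out of scope; the
  package reports paired values and correlations only.
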