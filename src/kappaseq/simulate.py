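"""Ground-truthed simulation of Igkappa repertoire libraries.

This module stands in for the wet-lab side of the study: it fabricates a
synthetic Igkappa locus, draws VkJk rearrangement events from a known
frequency matrix, and emits the two library chemistries the pipeline
consumes --

* gDNA libraries: sheared 500-1,000 bp fragments anchored at a Jk PCR
  primer, 6N UMI on the shear-side adapter, PCR re-sampling, and Jk primer
  cross-amplification (a Jk primer picking up a rearrangement to an
  upstream Jk whose downstream sequence is retained on the allele);
* RNA libraries: full-length V transcripts with a 5' bridge-adapter 6N UMI,
  per-gene promoter strength multipliers, and nonsense-mediated decay
  suppressing non-productive transcripts.

Junctions carry V-side trimming, untemplated insertion and (bounded)
J-side trimming such that the three reading-frame offsets are
equiprobable; a molecule is productive iff the frame is preserved.  Every
read name encodes its ground truth (molecule id, gene, Jk, productivity)
so downstream stages can be oracle-tested; the pipeline itself never parses
read names.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .locus import (
    JK_NAMES,
    IdenticalPair,
    JkGene,
    LocusReference,
    VkGene,
    revcomp,
)

#: upstream context (bp) included in the per-gene V alignment reference;
#: shear starts land inside this span so gDNA dedup start positions stay
#: informative
V_UPSTREAM_CONTEXT = 600

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype="S1")

LEADER_EXON_LEN = 30
LEADER_INTRON_LEN = 60
CODING_LEN = 300
RSS_LEN = 28
TAG_LEN = 20
JK_EXON_LEN = 39
JK_SPACING = 200


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _rand_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence with no stop codon in frame 0."""
    out = []
    while len(out) < n_codons:
        c = _rand_seq(rng, 3)
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


# --------------------------------------------------------------------------
# synthetic locus
# --------------------------------------------------------------------------

def make_synthetic_locus(
    n_genes: int = 20,
    seed: int = 0,
    gene_spacing: int = 7000,
    inversional_frac: float = 0.5,
    pseudogene_frac: float = 0.2,
    orf_frac: float = 0.05,
    n_identical_pairs: int = 2,
    chrom: str = "igk",
) -> LocusReference:
    """Fabricate a miniature Igkappa locus with the geometry the pipeline
    relies on: Vk genes (leader exon + intron + 300 bp coding + RSS) spread
    upstream of the four functional Jk exons, each Jk with a primary and an
    alternate PCR primer site, and a Ck stub.

    ``n_identical_pairs`` adjacent gene pairs are made sequence-identical
    except for a 20 bp discriminating tag at the start of leader 1,
    mimicking the three 3'-identical Vk pairs of the real locus.
    """
    rng = np.random.default_rng(seed)
    left_margin = 4000
    v_span = n_genes * gene_spacing
    j_gap = 3000
    j_span = 4 * JK_SPACING + 600
    genome_len = left_margin + v_span + j_gap + j_span + 2000
    genome = np.array(list(_rand_seq(rng, genome_len)))

    gene_len = LEADER_EXON_LEN + LEADER_INTRON_LEN + CODING_LEN  # 390

    # gene-oriented sequences; identical pairs share everything but the tag
    pair_indices = set()
    for p in range(n_identical_pairs):
        i = 2 * p + 3  # adjacent genes (i, i+1), away from the locus edges
        if i + 1 < n_genes:
            pair_indices.add((i, i + 1))

    oriented: list[str] = []
    tags: list[str] = []
    for i in range(n_genes):
        partner = next((a for (a, b) in pair_indices if b == i), None)
        tag = _rand_seq(rng, TAG_LEN)
        if partner is not None:
            body = oriented[partner][TAG_LEN:]
            while tag == tags[partner]:
                tag = _rand_seq(rng, TAG_LEN)
            seq = tag + body
        else:
            seq = (
                tag
                + _rand_seq(rng, LEADER_EXON_LEN - TAG_LEN)
                + _rand_seq(rng, LEADER_INTRON_LEN)
                + _rand_codons(rng, CODING_LEN // 3)
            )
        oriented.append(seq)
        tags.append(tag)

    v_genes: list[VkGene] = []
    for i in range(n_genes):
        # proximal rank i -> genomic position (proximal genes closest to Jk)
        slot_right = left_margin + v_span - i * gene_spacing
        inversional = rng.random() < inversional_frac
        r = rng.random()
        functionality = (
            "pseudogene" if r < pseudogene_frac
            else "ORF" if r < pseudogene_frac + orf_frac
            else "functional"
        )
        name = f"Vk{rng.integers(1, 21)}-{i + 1}"
        seq = oriented[i]
        if not inversional:
            lo = slot_right - gene_len
            genome[lo:slot_right] = list(seq)
            g = VkGene(
                name=name, family=int(name[2:].split("-")[0]), chrom=chrom,
                start=lo + LEADER_EXON_LEN + LEADER_INTRON_LEN, end=slot_right,
                leader1_start=lo,
                leader_intron_start=lo,
                leader_intron_end=lo + LEADER_EXON_LEN + LEADER_INTRON_LEN,
                rss_start=slot_right, rss_end=slot_right + RSS_LEN,
                orientation="deletional", functionality=functionality,
                ric_score=float(rng.normal()),
            )
        else:
            lo = slot_right - gene_len
            genome[lo:slot_right] = list(revcomp(seq))
            g = VkGene(
                name=name, family=int(name[2:].split("-")[0]), chrom=chrom,
                start=lo, end=lo + CODING_LEN,
                leader1_start=slot_right - 1,
                leader_intron_start=lo + CODING_LEN,
                leader_intron_end=slot_right,
                rss_start=lo - RSS_LEN, rss_end=lo,
                orientation="inversional", functionality=functionality,
                ric_score=float(rng.normal()),
            )
        v_genes.append(g)

    # Jk cluster (plus strand), Jk1 most V-proximal
    j_genes: list[JkGene] = []
    j0 = left_margin + v_span + j_gap
    for k, jname in enumerate(JK_NAMES):
        es = j0 + k * JK_SPACING
        ee = es + JK_EXON_LEN
        genome[es:ee] = list(_rand_codons(rng, JK_EXON_LEN // 3))
        j_genes.append(JkGene(
            name=jname, chrom=chrom, start=es, end=ee,
            primer_primary_start=ee + 15, primer_primary_end=ee + 35,
            primer_alt_start=ee + 45, primer_alt_end=ee + 65,
        ))
    c_start = j0 + j_span
    c_exon = (chrom, c_start, c_start + 60)

    ref = LocusReference(
        genome={chrom: "".join(genome)},
        v_genes=v_genes,
        j_genes=j_genes,
        identical_pairs=[
            IdenticalPair(v_genes[a].name, v_genes[b].name, tags[a], tags[b])
            for a, b in sorted(pair_indices)
        ],
        c_exon=c_exon,
    )
    ref.compute_distances()
    ref.validate()
    return ref


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    Defaults mirror the sequenced libraries being emulated: 500-1,000 bp
    sheared gDNA fragments, 6N UMIs, Jk1 at ~40% usage with ~20% for each
    other Jk, a ~20% inactive-gene fraction, and strong depletion of
    non-productive transcripts in RNA libraries.
    """

    n_molecules: int = 10_000
    fragment_len_range: tuple[int, int] = (500, 1000)
    umi_len: int = 6
    pcr_dup_rate: float = 0.3
    cross_prime_rate: float = 0.05
    seq_error_rate: float = 0.0
    nmd_survival: float = 0.2
    read_len: int = 520
    jk_weights: tuple[float, ...] = (0.40, 0.20, 0.20, 0.20)
    #: Dirichlet concentration for per-gene Jk usage around ``jk_weights``
    #: (None = every gene shares the global usage exactly)
    jk_dirichlet_conc: Optional[float] = 6.0
    gene_log_sd: float = 1.0
    promoter_log_sd: float = 0.55
    inactive_frac: float = 0.2
    max_v_trim: int = 4
    max_j_trim: int = 1
    inject_stop_codons: bool = False
    planted_b: float = 0.0
    planted_noise_sd: float = 0.5
    n_tracks: int = 34

    def validate(self) -> None:
        for p in (self.pcr_dup_rate, self.cross_prime_rate, self.seq_error_rate,
                  self.nmd_survival, self.inactive_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.umi_len != 6:
            raise ValueError("deduplication chemistry uses 6N UMIs")
        lo, hi = self.fragment_len_range
        if not (0 < lo <= hi):
            raise ValueError("fragment length range must be positive")
        if abs(sum(self.jk_weights) - 1.0) > 1e-9:
            raise ValueError("jk_weights must sum to 1")


@dataclass
class GroundTruth:
    """True rearrangement process behind one simulated repertoire."""

    freq: pd.DataFrame                 # genes x Jk, sums to 1
    promoter_strength: pd.Series       # positive, RNA libraries only
    molecules: pd.DataFrame            # one row per gDNA molecule
    planted_effect: float = 0.0
    signal: Optional[pd.Series] = None  # designated-track window signal

    def validate(self) -> None:
        if abs(float(self.freq.values.sum()) - 1.0) > 1e-9:
            raise ValueError("true frequencies must sum to 1")
        if (self.promoter_strength <= 0).any():
            raise ValueError("promoter strengths must be positive")


def _sample_junction(
    rng: np.random.Generator,
    coding: str,
    exon: str,
    config: SimConfig,
) -> tuple[int, int, str, int]:
    """Draw (del_v, del_j, insert, frame_class) with the frame class uniform
    over {0,1,2}.  For in-frame junctions the draw is repeated until no stop
    codon spans the junction (stop-codon injection is off by default), so
    productivity is exactly frame-determined."""
    frame = int(rng.integers(3))
    while True:
        del_v = int(rng.integers(config.max_v_trim + 1))
        del_j = int(rng.integers(config.max_j_trim + 1))
        ins_len = (frame + del_v + del_j) % 3 + 3 * int(rng.integers(2))
        ins = _rand_seq(rng, ins_len)
        if frame != 0 or config.inject_stop_codons:
            return del_v, del_j, ins, frame
        # check codons spanning the junction (V coding start is frame 0)
        keep = len(coding) - del_v
        start = max((keep - 1) // 3 * 3 - 3, 0)
        window = coding[start:keep] + ins + exon[del_j:del_j + 9]
        clean = all(
            window[i:i + 3] not in STOP_CODONS
            for i in range(0, len(window) - 2, 3)
        )
        if clean:
            return del_v, del_j, ins, frame


def simulate_repertoire(
    ref: LocusReference,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    freq: Optional[pd.DataFrame] = None,
) -> GroundTruth:
    """Draw the true per-gene x per-Jk frequency matrix and one gDNA
    molecule table of ``n_molecules`` rearrangement events.

    ``freq`` overrides the generated frequency matrix (rows genes, columns
    Jk names; normalised internally).  When ``config.planted_b`` is nonzero
    the per-gene log-propensity is a linear function of a planted track
    signal (plus noise), enabling parameter-recovery tests of the ML stage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config.validate()
    genes = ref.v_names
    n = len(genes)

    signal = None
    if freq is None:
        n_inactive = int(round(config.inactive_frac * n))
        if config.planted_b != 0.0:
            sig = rng.uniform(0.0, 10.0, size=n)
            signal = pd.Series(sig, index=genes, name="planted_signal")
            logw = config.planted_b * sig + rng.normal(
                0.0, config.planted_noise_sd, size=n)
            # activity follows the planted mark: the lowest-propensity
            # genes are the inactive ones
            inactive = set(np.argsort(logw)[:n_inactive].tolist())
        else:
            logw = rng.normal(0.0, config.gene_log_sd, size=n)
            inactive = set(rng.choice(n, size=n_inactive,
                                      replace=False).tolist())
        w = np.exp(logw)
        w[list(inactive)] = 0.0
        if w.sum() == 0:
            raise ValueError("degenerate frequency matrix: all genes inactive")
        base = np.asarray(config.jk_weights, dtype=float)
        if config.jk_dirichlet_conc is None:
            jk_profile = np.tile(base, (n, 1))
        else:
            jk_profile = rng.dirichlet(base * config.jk_dirichlet_conc, size=n)
        fmat = (w[:, None] * jk_profile)
        fmat /= fmat.sum()
        freq = pd.DataFrame(fmat, index=genes, columns=list(JK_NAMES))
    else:
        freq = freq.reindex(index=genes, columns=list(JK_NAMES)).fillna(0.0)
        total = float(freq.values.sum())
        if total <= 0:
            raise ValueError("degenerate frequency matrix: all zero")
        freq = freq / total

    strength = pd.Series(
        np.exp(rng.normal(0.0, config.promoter_log_sd, size=n)),
        index=genes, name="promoter_strength",
    )

    flat = freq.values.ravel()
    draws = rng.choice(flat.size, size=config.n_molecules, p=flat)
    gi, ji = np.unravel_index(draws, freq.shape)

    coding = {g.name: ref.coding_seq(g) for g in ref.v_genes}
    exon = {j.name: ref.jk_exon_seq(j) for j in ref.j_genes}
    rows = []
    for m in range(config.n_molecules):
        gname = genes[gi[m]]
        jname = JK_NAMES[ji[m]]
        del_v, del_j, ins, frame = _sample_junction(
            rng, coding[gname], exon[jname], config)
        rows.append((m, gname, jname, del_v, del_j, ins, frame, frame == 0))
    molecules = pd.DataFrame(
        rows, columns=["mol_id", "gene", "jk", "del_v", "del_j", "ins",
                       "frame", "productive"],
    )
    truth = GroundTruth(
        freq=freq, promoter_strength=strength, molecules=molecules,
        planted_effect=config.planted_b, signal=signal,
    )
    truth.validate()
    return truth


# --------------------------------------------------------------------------
# read emission
# --------------------------------------------------------------------------

@dataclass
class SimRead:
    """One emitted read pair, name-encoding its ground truth."""

    name: str
    r1: str
    r2: str
    qual_char: str = "D"  # Phred 35
    clipped: bool = False
    umi: str = ""         # ground truth, for oracle tests only
    v_start: int = -1     # true shear position in V-reference space

    @property
    def q1(self) -> str:
        return self.qual_char * len(self.r1)

    @property
    def q2(self) -> str:
        return self.qual_char * len(self.r2)


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


def _emit_pairs(
    rng: np.random.Generator,
    name: str,
    fragment: str,
    umi: str,
    config: SimConfig,
    umi_on_r1: bool,
    clipped: bool,
    v_start: int = -1,
) -> Iterable[SimRead]:
    """Emit 1 + Geometric(pcr_dup_rate) identical copies of a fragment
    (independent sequencing errors per copy)."""
    copies = 1
    while rng.random() < config.pcr_dup_rate:
        copies += 1
    L = config.read_len
    for c in range(copies):
        r1 = fragment[:L]
        r2 = revcomp(fragment)[:L]
        if umi_on_r1:
            r1 = umi + r1
        else:
            r2 = umi + r2
        r1 = _inject_errors(rng, r1, config.seq_error_rate)
        r2 = _inject_errors(rng, r2, config.seq_error_rate)
        yield SimRead(name=f"{name}:c{c}", r1=r1, r2=r2, clipped=clipped,
                      umi=umi, v_start=v_start)


def gdna_read_pairs(
    truth: GroundTruth,
    ref: LocusReference,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    primer_set: str = "primary",
) -> list[SimRead]:
    """Emit the gDNA library for ``truth.molecules``.

    Each molecule becomes a sheared fragment ending at a Jk primer; with
    probability ``cross_prime_rate`` the *next downstream* Jk's primer
    amplifies the product instead (the true Jk exon is still present
    upstream in the read).  The 6N UMI sits on the shear-side adapter (R1).
    Read names encode ``molecule|gene|jk|productive|primedjk``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = ref.j_genes[0].chrom
    vext = {g.name: ref.gene_oriented_seq(g, V_UPSTREAM_CONTEXT) for g in ref.v_genes}
    jk_by_name = {j.name: j for j in ref.j_genes}
    j_order = [j.name for j in ref.j_genes]
    lo, hi = config.fragment_len_range
    out: list[SimRead] = []
    for row in truth.molecules.itertuples(index=False):
        jkt = jk_by_name[row.jk]
        prime_name = row.jk
        k = j_order.index(row.jk)
        if k + 1 < len(j_order) and rng.random() < config.cross_prime_rate:
            prime_name = j_order[k + 1]
        primer_end = jk_by_name[prime_name].primer_interval(primer_set)[1]
        jside = ref.slice(chrom, jkt.start + row.del_j, primer_end)
        v = vext[row.gene]
        template = v[: len(v) - row.del_v] + row.ins + jside
        frag_len = int(rng.integers(lo, hi + 1))
        clipped = frag_len >= len(template)
        fragment = template[-frag_len:] if not clipped else template
        # true shear position in V-reference coordinates (gDNA dedup key)
        v_portion = len(fragment) - len(row.ins) - len(jside)
        v_start = max((len(v) - row.del_v) - v_portion, 0)
        umi = _rand_seq(rng, config.umi_len)
        name = (
            f"m{row.mol_id}|{row.gene}|{row.jk}|"
            f"{'P' if row.productive else 'N'}|{prime_name}"
        )
        out.extend(_emit_pairs(rng, name, fragment, umi, config,
                               umi_on_r1=True, clipped=clipped,
                               v_start=v_start))
    return out


def rna_read_pairs(
    truth: GroundTruth,
    ref: LocusReference,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    n_molecules: Optional[int] = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Emit an RNA (5' RACE) library.

    Transcript abundance is proportional to rearrangement frequency times
    promoter strength, with non-productive transcripts surviving
    nonsense-mediated decay with probability ``nmd_survival``.  Transcripts
    cover the full V gene (leader through coding; the leader intron is
    retained so one V reference model serves both chemistries) plus the Jk
    exon and a Ck stub; the 6N bridge-adapter UMI leads R1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config.validate()
    n = config.n_molecules if n_molecules is None else n_molecules
    genes = ref.v_names
    strength = truth.promoter_strength.reindex(genes).values
    base = truth.freq.reindex(index=genes, columns=list(JK_NAMES)).values
    # joint weight over (gene, jk, frame): frame uniform, NMD on frames 1,2
    nmd = np.array([1.0, config.nmd_survival, config.nmd_survival]) / 3.0
    w = base[:, :, None] * strength[:, None, None] * nmd[None, None, :]
    flat = w.ravel()
    flat = flat / flat.sum()
    draws = rng.choice(flat.size, size=n, p=flat)
    gi, ji, fi = np.unravel_index(draws, w.shape)

    coding = {g.name: ref.coding_seq(g) for g in ref.v_genes}
    vgene = {g.name: ref.gene_oriented_seq(g, 0) for g in ref.v_genes}
    exon = {j.name: ref.jk_exon_seq(j) for j in ref.j_genes}
    c_stub = ref.c_seq()
    out: list[SimRead] = []
    rows = []
    for m in range(n):
        gname, jname = genes[gi[m]], JK_NAMES[ji[m]]
        frame = int(fi[m])
        # resample junction details at this frame class
        while True:
            del_v, del_j, ins, f = _sample_junction(
                rng, coding[gname], exon[jname], config)
            if f == frame:
                break
        v = vgene[gname]
        transcript = v[: len(v) - del_v] + ins + exon[jname][del_j:] + c_stub
        umi = _rand_seq(rng, config.umi_len)
        name = f"r{m}|{gname}|{jname}|{'P' if frame == 0 else 'N'}|{jname}"
        clipped = len(transcript) < config.read_len
        out.extend(_emit_pairs(rng, name, transcript, umi, config,
                               umi_on_r1=True, clipped=clipped))
        rows.append((m, gname, jname, del_v, del_j, ins, frame, frame == 0))
    mols = pd.DataFrame(
        rows, columns=["mol_id", "gene", "jk", "del_v", "del_j", "ins",
                       "frame", "productive"],
    )
    return out, mols


def write_fastq_pair(reads: Iterable[SimRead], prefix: str | Path) -> tuple[Path, Path]:
    """Write R1/R2 gzip FASTQ files; byte-identical for identical input."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq.gz")
    p2 = prefix.with_name(prefix.name + "_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for r in reads:
            f1.write(f"@{r.name}\n{r.r1}\n+\n{r.q1}\n")
            f2.write(f"@{r.name}\n{r.r2}\n+\n{r.q2}\n")
    return p1, p2


def parse_truth_name(name: str) -> dict:
    """Decode the ground truth embedded in a simulated read name (test use
    only; the pipeline never calls this)."""
    core, _, copy_idx = name.rpartition(":c")
    mol, gene, jk, prod, primed = core.split("|")
    return {
        "mol_id": mol, "gene": gene, "jk": jk,
        "productive": prod == "P", "primed_jk": primed,
        "copy": int(copy_idx),
    }


# --------------------------------------------------------------------------
# signal tracks
# --------------------------------------------------------------------------

def simulate_signal_tracks(
    ref: LocusReference,
    truth: GroundTruth,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    total_tags: int = 10_000_000,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit ``config.n_tracks`` coverage tracks (bedGraph frames) over every
    gene window plus a manifest (name, stage, assay, total_tags, strand).

    Track 0 (``planted_mark``) carries the planted signal in each gene's RSS
    window: after 10M-tag normalisation its window quantification equals
    ``truth.signal`` exactly; all other windows and all other tracks are
    lognormal noise.
    """
    from .features import build_windows  # local import to avoid cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    windows = {g.name: build_windows(g) for g in ref.v_genes}
    chrom = ref.v_genes[0].chrom
    scale = total_tags / 1e7

    names = ["planted_mark"] + [f"noise_{i:02d}" for i in range(1, config.n_tracks)]
    tracks: dict[str, pd.DataFrame] = {}
    for t, tname in enumerate(names):
        rows = []
        for g in ref.v_genes:
            for wname, (ws, we) in windows[g.name].as_dict().items():
                wlen = we - ws
                if t == 0 and wname == "rss" and truth.signal is not None:
                    sig = float(truth.signal[g.name])
                else:
                    sig = float(np.exp(rng.normal(0.0, 1.0)))
                value = sig * scale / wlen  # per-base coverage
                rows.append((chrom, ws, we, value))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        tracks[tname] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    manifest = pd.DataFrame({
        "name": names,
        "stage": ["preB" if i % 2 == 0 else "proB" for i in range(len(names))],
        "assay": ["ChIP"] * 29 + ["RNA"] * (len(names) - 29)
        if len(names) >= 29 else ["ChIP"] * len(names),
        "total_tags": total_tags,
        "strand": ".",
    })
    return tracks, manifest


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
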