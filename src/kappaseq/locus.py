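"""Annotated Igkappa locus model.

The mouse Igkappa light-chain locus carries ~160 Vkappa gene segments spread
over several megabases upstream of a compact cluster of four functional
Jkappa segments (Jk1, Jk2, Jk4, Jk5; Jk3 is non-functional and is not
modelled) followed by the constant-region exon Ckappa.  Every downstream
stage of the pipeline -- simulation, V/J calling, deduplication, repertoire
statistics and the feature/ML stage -- consumes the locus model built here.

Coordinates are 0-based half-open genomic intervals throughout; orientation
is encoded as ``deletional`` (same transcriptional orientation as the
Jk--Ck cluster) or ``inversional`` (opposite), so synthetic loci need no
chromosome context.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pyfaidx import Fasta

ORIENTATIONS = ("deletional", "inversional")
FUNCTIONALITY_CLASSES = ("functional", "ORF", "pseudogene")
JK_NAMES = ("Jk1", "Jk2", "Jk4", "Jk5")

#: junction-proximal Jk exon nucleotides excluded from Jk identification,
#: to allow for junctional nibbling of the exon (1 for the original primer
#: set, 6 for the alternate set located further from the junction)
JUNCTION_EXCLUSION = {"primary": 1, "alternate": 6}

#: length of the shared 3'-terminal stretch of the identical Vk gene pairs
IDENTICAL_PAIR_SHARED_BP = 150

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class LocusError(ValueError):
    """Raised for schema or validation failures while building a locus."""


@dataclass
class VkGene:
    """One Vkappa gene segment.

    ``start``/``end`` delimit the coding region.  ``leader1_start`` is the
    genomic position of the first transcribed base of leader exon 1 *in the
    gene's own orientation* (for inversional genes it is therefore the
    highest coordinate of the leader region).  ``leader_intron_start/end``
    span leader exon(s) plus intron as a plain genomic interval.
    """

    name: str
    family: int
    chrom: str
    start: int
    end: int
    leader1_start: int
    leader_intron_start: int
    leader_intron_end: int
    rss_start: int
    rss_end: int
    orientation: str
    functionality: str
    ric_score: float
    distance_to_jk1: int = -1
    half: str = ""

    @property
    def coding_len(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def validate(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise LocusError(f"{self.name}: bad orientation {self.orientation!r}")
        if self.functionality not in FUNCTIONALITY_CLASSES:
            raise LocusError(f"{self.name}: bad functionality {self.functionality!r}")
        if not (self.ric_score == self.ric_score and abs(self.ric_score) != float("inf")):
            raise LocusError(f"{self.name}: non-finite RIC score")
        if self.end <= self.start:
            raise LocusError(f"{self.name}: empty coding interval")
        # leader 1 must lie upstream of the coding region in the gene's own
        # orientation
        if self.orientation == "deletional" and self.leader1_start >= self.start:
            raise LocusError(f"{self.name}: leader1 not upstream of coding region")
        if self.orientation == "inversional" and self.leader1_start < self.end:
            raise LocusError(f"{self.name}: leader1 not upstream of coding region")


@dataclass
class JkGene:
    """One functional Jkappa segment with its two PCR primer locations."""

    name: str
    chrom: str
    start: int  # exon interval
    end: int
    primer_primary_start: int
    primer_primary_end: int
    primer_alt_start: int
    primer_alt_end: int

    def primer_interval(self, primer_set: str) -> tuple[int, int]:
        if primer_set == "primary":
            return (self.primer_primary_start, self.primer_primary_end)
        if primer_set == "alternate":
            return (self.primer_alt_start, self.primer_alt_end)
        raise LocusError(f"unknown primer set {primer_set!r}")


@dataclass
class IdenticalPair:
    """Two Vk genes sharing their 3'-most 150 bp, plus discriminating tags.

    ``tag_a``/``tag_b`` are short sequence strings found far upstream in the
    respective gene (user-supplied; the published discriminating strings live
    in external supplementary data).
    """

    member_a: str
    member_b: str
    tag_a: str
    tag_b: str


@dataclass
class LocusReference:
    genome: dict[str, str]
    v_genes: list[VkGene] = field(default_factory=list)
    j_genes: list[JkGene] = field(default_factory=list)
    identical_pairs: list[IdenticalPair] = field(default_factory=list)
    c_exon: Optional[tuple[str, int, int]] = None  # (chrom, start, end)

    # ------------------------------------------------------------------ access
    def vk(self, name: str) -> VkGene:
        for g in self.v_genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def jk(self, name: str) -> JkGene:
        for j in self.j_genes:
            if j.name == name:
                return j
        raise KeyError(name)

    @property
    def v_names(self) -> list[str]:
        return [g.name for g in self.v_genes]

    def jk1(self) -> JkGene:
        return self.j_genes[0]

    # ----------------------------------------------------------------- slices
    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.genome[chrom][max(start, 0):end]

    def gene_oriented_seq(self, gene: VkGene, upstream_context: int = 0) -> str:
        """Sequence from (leader1 start - context) through the coding end,
        read in the gene's own orientation (the V reference used for read
        alignment and simulation)."""
        if gene.orientation == "deletional":
            lo = gene.leader1_start - upstream_context
            return self.slice(gene.chrom, lo, gene.end)
        hi = gene.leader1_start + 1 + upstream_context
        return revcomp(self.slice(gene.chrom, gene.start, hi))

    def coding_seq(self, gene: VkGene) -> str:
        s = self.slice(gene.chrom, gene.start, gene.end)
        return s if gene.orientation == "deletional" else revcomp(s)

    def jk_exon_seq(self, j: JkGene) -> str:
        return self.slice(j.chrom, j.start, j.end)

    def primer_seq(self, j: JkGene, primer_set: str) -> str:
        s, e = j.primer_interval(primer_set)
        return self.slice(j.chrom, s, e)

    def c_seq(self) -> str:
        if self.c_exon is None:
            return ""
        chrom, s, e = self.c_exon
        return self.slice(chrom, s, e)

    def pair_of(self, gene_name: str) -> Optional[IdenticalPair]:
        for p in self.identical_pairs:
            if gene_name in (p.member_a, p.member_b):
                return p
        return None

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        names = [g.name for g in self.v_genes]
        if len(set(names)) != len(names):
            raise LocusError("duplicate Vk gene names")
        if [j.name for j in self.j_genes] != list(JK_NAMES):
            raise LocusError(f"expected exactly the four functional Jk genes {JK_NAMES}")
        for g in self.v_genes:
            g.validate()
            if g.end > len(self.genome[g.chrom]) or g.start < 0:
                raise LocusError(f"{g.name}: interval outside genome slice")
        for p in self.identical_pairs:
            a = self.vk(p.member_a)
            b = self.vk(p.member_b)
            tail_a = self.coding_seq(a)[-IDENTICAL_PAIR_SHARED_BP:]
            tail_b = self.coding_seq(b)[-IDENTICAL_PAIR_SHARED_BP:]
            if tail_a != tail_b:
                raise LocusError(
                    f"pair ({p.member_a},{p.member_b}): 3'-most "
                    f"{IDENTICAL_PAIR_SHARED_BP} bp differ"
                )
            if p.tag_a == p.tag_b:
                raise LocusError(
                    f"pair ({p.member_a},{p.member_b}): discriminating tags equal"
                )
            up_a = self.gene_oriented_seq(a)
            up_b = self.gene_oriented_seq(b)
            if not ((p.tag_a in up_a) ^ (p.tag_a in up_b)):
                raise LocusError(
                    f"pair tag {p.tag_a!r} does not discriminate "
                    f"{p.member_a}/{p.member_b}"
                )
            if not ((p.tag_b in up_b) ^ (p.tag_b in up_a)):
                raise LocusError(
                    f"pair tag {p.tag_b!r} does not discriminate "
                    f"{p.member_a}/{p.member_b}"
                )

    # ------------------------------------------------------------- derived cols
    def compute_distances(self) -> None:
        jk1 = self.jk1()
        for g in self.v_genes:
            # gap between the coding region and the Jk1 exon
            if g.end <= jk1.start:
                g.distance_to_jk1 = jk1.start - g.end
            else:
                g.distance_to_jk1 = g.start - jk1.end
            if g.distance_to_jk1 < 0:
                raise LocusError(f"{g.name}: overlaps the Jk cluster")
        self.v_genes.sort(key=lambda g: g.distance_to_jk1)


_V_COLUMNS = [
    "chrom", "start", "end", "name", "record_type", "family", "orientation",
    "functionality", "ric_score", "leader1_start", "leader_intron_start",
    "leader_intron_end", "rss_start", "rss_end",
    "primer_primary_start", "primer_primary_end",
    "primer_alt_start", "primer_alt_end",
]


def load_reference(
    genome_fasta: str | Path,
    annotation: str | Path,
    pairs: Optional[str | Path] = None,
) -> LocusReference:
    """Load and validate a locus model from FASTA + BED-like annotation.

    The annotation is tab-separated with a header; V rows use start/end as
    the coding interval, J rows as the exon interval, and the single C row
    as the constant exon.  ``pairs`` is an optional TSV registry of the
    3'-identical gene pairs and their discriminating tag strings.
    """
    fa = Fasta(str(genome_fasta), as_raw=True)
    genome = {name: str(fa[name][:]) for name in fa.keys()}
    ann = pd.read_csv(annotation, sep="\t", dtype=str)
    missing = set(_V_COLUMNS) - set(ann.columns)
    if missing:
        raise LocusError(f"annotation missing columns: {sorted(missing)}")

    def _int(row, col):
        v = row[col]
        if v in (".", "", None) or pd.isna(v):
            raise LocusError(f"row {row['name']}: missing required field {col}")
        return int(v)

    ref = LocusReference(genome=genome)
    for _, row in ann.iterrows():
        kind = row["record_type"]
        if kind == "V":
            ref.v_genes.append(VkGene(
                name=row["name"], family=_int(row, "family"), chrom=row["chrom"],
                start=_int(row, "start"), end=_int(row, "end"),
                leader1_start=_int(row, "leader1_start"),
                leader_intron_start=_int(row, "leader_intron_start"),
                leader_intron_end=_int(row, "leader_intron_end"),
                rss_start=_int(row, "rss_start"), rss_end=_int(row, "rss_end"),
                orientation=row["orientation"], functionality=row["functionality"],
                ric_score=float(row["ric_score"]),
            ))
        elif kind == "J":
            ref.j_genes.append(JkGene(
                name=row["name"], chrom=row["chrom"],
                start=_int(row, "start"), end=_int(row, "end"),
                primer_primary_start=_int(row, "primer_primary_start"),
                primer_primary_end=_int(row, "primer_primary_end"),
                primer_alt_start=_int(row, "primer_alt_start"),
                primer_alt_end=_int(row, "primer_alt_end"),
            ))
        elif kind == "C":
            ref.c_exon = (row["chrom"], _int(row, "start"), _int(row, "end"))
        else:
            raise LocusError(f"unknown record_type {kind!r}")
    ref.j_genes.sort(key=lambda j: JK_NAMES.index(j.name) if j.name in JK_NAMES else 99)
    if pairs is not None:
        pdf = pd.read_csv(pairs, sep="\t", dtype=str)
        for _, row in pdf.iterrows():
            ref.identical_pairs.append(IdenticalPair(
                row["member_a"], row["member_b"], row["tag_a"], row["tag_b"]))
    ref.compute_distances()
    ref.validate()
    return ref


def annotation_frame(ref: LocusReference) -> pd.DataFrame:
    """The annotation table (inverse of :func:`load_reference`)."""
    rows = []
    for g in ref.v_genes:
        rows.append({
            "chrom": g.chrom, "start": g.start, "end": g.end, "name": g.name,
            "record_type": "V", "family": g.family, "orientation": g.orientation,
            "functionality": g.functionality, "ric_score": g.ric_score,
            "leader1_start": g.leader1_start,
            "leader_intron_start": g.leader_intron_start,
            "leader_intron_end": g.leader_intron_end,
            "rss_start": g.rss_start, "rss_end": g.rss_end,
            "primer_primary_start": ".", "primer_primary_end": ".",
            "primer_alt_start": ".", "primer_alt_end": ".",
        })
    for j in ref.j_genes:
        rows.append({
            "chrom": j.chrom, "start": j.start, "end": j.end, "name": j.name,
            "record_type": "J", "family": ".", "orientation": ".",
            "functionality": ".", "ric_score": ".",
            "leader1_start": ".", "leader_intron_start": ".",
            "leader_intron_end": ".", "rss_start": ".", "rss_end": ".",
            "primer_primary_start": j.primer_primary_start,
            "primer_primary_end": j.primer_primary_end,
            "primer_alt_start": j.primer_alt_start,
            "primer_alt_end": j.primer_alt_end,
        })
    if ref.c_exon is not None:
        chrom, s, e = ref.c_exon
        rows.append({
            "chrom": chrom, "start": s, "end": e, "name": "Ck",
            "record_type": "C", "family": ".", "orientation": ".",
            "functionality": ".", "ric_score": ".",
            "leader1_start": ".", "leader_intron_start": ".",
            "leader_intron_end": ".", "rss_start": ".", "rss_end": ".",
            "primer_primary_start": ".", "primer_primary_end": ".",
            "primer_alt_start": ".", "primer_alt_end": ".",
        })
    return pd.DataFrame(rows, columns=_V_COLUMNS)


def write_annotation(ref: LocusReference, path: str | Path) -> None:
    annotation_frame(ref).to_csv(path, sep="\t", index=False)


def write_genome(ref: LocusReference, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_pairs(ref: LocusReference, path: str | Path) -> None:
    pd.DataFrame(
        [{"member_a": p.member_a, "member_b": p.member_b,
          "tag_a": p.tag_a, "tag_b": p.tag_b} for p in ref.identical_pairs]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- fixes

#: published reference fixes for the real C57BL/6 locus: orientation of
#: Vk8-23-1, the Vk4-60 RSS, and four genes reclassified as non-pseudogenes
#: following IMGT (Vk8-18, Vk1-35, Vk14-126, Vk1-131).
DEFAULT_CORRECTIONS = pd.DataFrame(
    [
        {"gene": "Vk8-23-1", "field": "orientation", "value": "flip"},
        {"gene": "Vk4-60", "field": "rss", "value": None},
        {"gene": "Vk8-18", "field": "functionality", "value": "functional"},
        {"gene": "Vk1-35", "field": "functionality", "value": "functional"},
        {"gene": "Vk14-126", "field": "functionality", "value": "functional"},
        {"gene": "Vk1-131", "field": "functionality", "value": "ORF"},
    ]
)


def apply_corrections(ref: LocusReference, overrides: pd.DataFrame) -> LocusReference:
    """Apply a reference-correction override table and return a new locus.

    Override rows carry ``gene``, ``field`` in {orientation, functionality,
    rss} and ``value``; for ``orientation`` the value ``flip`` toggles the
    class, otherwise it is set verbatim; for ``rss`` the value is
    ``start:end`` (genomic, 0-based half-open).
    """
    new = copy.deepcopy(ref)
    known = {g.name for g in new.v_genes}
    for _, row in overrides.iterrows():
        name = row["gene"]
        if name not in known:
            raise LocusError(f"correction names unknown gene {name!r}")
        g = new.vk(name)
        fld, value = row["field"], row["value"]
        if fld == "orientation":
            if value == "flip":
                g.orientation = (
                    "inversional" if g.orientation == "deletional" else "deletional"
                )
            else:
                g.orientation = value
        elif fld == "functionality":
            g.functionality = value
        elif fld == "rss":
            if value is None or value == ".":
                continue
            s, e = (int(x) for x in str(value).split(":"))
            g.rss_start, g.rss_end = s, e
        else:
            raise LocusError(f"unknown correction field {fld!r}")
    return new


# ---------------------------------------------------------------- locus halves

# Named boundary of the real locus: Vk3-1..Vk13-76 proximal,
# Vk4-77..Vk2-137 distal.
REAL_PROXIMAL_LAST = "Vk13-76"
REAL_DISTAL_FIRST = "Vk4-77"


def assign_halves(
    ref: LocusReference,
    proximal_last: Optional[str] = None,
) -> LocusReference:
    """Label every Vk gene proximal/distal relative to the Jk cluster.

    Generic rule: the genomic span from the most Jk-proximal to the most
    Jk-distal Vk gene is halved at its midpoint; genes on the Jk side of the
    midpoint are proximal.  For the real locus the named boundary
    (``proximal_last="Vk13-76"``) reproduces the published split.
    """
    genes = ref.v_genes  # already ordered proximal -> distal
    if not genes:
        return ref
    if proximal_last is not None:
        idx = ref.v_names.index(proximal_last)
        for i, g in enumerate(genes):
            g.half = "proximal" if i <= idx else "distal"
        return ref
    d_first = genes[0].distance_to_jk1
    d_last = genes[-1].distance_to_jk1
    mid = 0.5 * (d_first + d_last)
    for g in genes:
        g.half = "proximal" if g.distance_to_jk1 <= mid else "distal"
    return ref
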