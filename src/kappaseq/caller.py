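"""V/J assignment, productivity and orientation calling for merged reads.

V assignment is a gapless, end-anchored alignment of the read's 5' portion
into a per-gene V reference (leader through coding end plus upstream
context): exact k-mer seeds propose a diagonal, the diagonal is scored
with +1/match, -3/mismatch, and the maximal-scoring prefix defines the
aligned segment.  A gene is assigned only when the aligned length is at
least 150 bp and identity (matches / aligned columns) is at least 95%;
ties are broken by identity, then aligned length, then gene name, and are
flagged ambiguous (this is how reads covering only the shared 3' 150 bp of
an identical gene pair land deterministically on one member, to be
corrected later by reallocation).

Jk calling searches the read for each Jk exon with its most V-proximal
nucleotide(s) excluded -- 1 for the primary primer set, 6 for the
alternate -- so junctional nibbling of the exon does not defeat the match;
the most V-proximal matching exon wins, which also corrects Jk primer
cross-amplification (the true Jk exon lies upstream of the mis-priming
Jk's own exon in the read).

Productivity is frame-based: the V coding frame must be preserved into the
Jk exon across the junction, with no in-frame stop codon between the
start of the V coding region and the end of the Jk exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .locus import JUNCTION_EXCLUSION, LocusReference
from .simulate import V_UPSTREAM_CONTEXT, STOP_CODONS

MIN_V_ALIGNED_LEN = 150
MIN_V_IDENTITY = 95.0
_MISMATCH_PENALTY = 3


@dataclass
class VAssignment:
    gene: str
    identity_pct: float
    aligned_len: int
    v_start: int          # 5'-most aligned base in V-reference space
    v_read_start: int     # read coordinate where the V alignment begins
    v_read_end: int       # read coordinate one past the last aligned V base
    ambiguous: bool = False


@dataclass
class JAssignment:
    jk: str
    exon_read_start: int  # read coordinate of the (virtual) exon start


@dataclass
class VJCall:
    """One read's assignment record."""

    read_id: str
    umi: str
    sample_id: str
    v_gene: Optional[str]
    identity_pct: float
    v_aligned_len: int
    v_start: int
    jk: Optional[str]
    junction_seq: str
    productive: str       # productive | non-productive | indeterminate
    orientation_class: Optional[str]
    ambiguous: bool = False


class VAligner:
    """Seeded diagonal aligner over all Vk references of a locus."""

    def __init__(self, ref: LocusReference, context: int = V_UPSTREAM_CONTEXT,
                 k: int = 20, seed_stride: int = 30):
        self.ref = ref
        self.context = context
        self.k = k
        self.seed_stride = seed_stride
        self.names: list[str] = []
        self.arrs: list[np.ndarray] = []
        self.coding_offset: list[int] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for gi, g in enumerate(ref.v_genes):
            seq = ref.gene_oriented_seq(g, context)
            self.names.append(g.name)
            self.arrs.append(np.frombuffer(seq.encode(), dtype="S1"))
            self.coding_offset.append(len(seq) - g.coding_len)
            for p in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[p:p + k], []).append((gi, p))

    def assign_v(
        self,
        read_seq: str,
        min_len: int = MIN_V_ALIGNED_LEN,
        min_identity: float = MIN_V_IDENTITY,
    ) -> Optional[VAssignment]:
        k = self.k
        if len(read_seq) < k:
            return None
        rarr = np.frombuffer(read_seq.encode(), dtype="S1")
        candidates: set[tuple[int, int]] = set()
        hit_seeds = 0
        for s in range(0, len(read_seq) - k + 1, self.seed_stride):
            hits = self.index.get(read_seq[s:s + k])
            if hits:
                for gi, p in hits:
                    candidates.add((gi, p - s))
                hit_seeds += 1
                # one extra confirming seed guards against a sequencing
                # error inside the first seed's k-mer
                if hit_seeds >= 2:
                    break
        if not candidates:
            # dense pass for reads whose strided seeds all straddle a
            # mismatch; dictionary lookups are cheap
            for s in range(0, len(read_seq) - k + 1):
                hits = self.index.get(read_seq[s:s + k])
                if hits:
                    for gi, p in hits:
                        candidates.add((gi, p - s))
                    break
        results = {}
        for gi, diag in candidates:
            varr = self.arrs[gi]
            v0 = max(diag, 0)        # V coordinate where the overlap starts
            r0 = v0 - diag           # corresponding read coordinate
            span = min(len(varr) - v0, len(rarr) - r0)
            if span <= 0:
                continue
            eq = (varr[v0:v0 + span] == rarr[r0:r0 + span])
            score = np.where(eq, 1, -_MISMATCH_PENALTY).cumsum()
            end = int(score.argmax()) + 1
            if score[end - 1] <= 0:
                continue
            matches = int(eq[:end].sum())
            identity = 100.0 * matches / end
            key = (identity, end)
            prev = results.get(gi)
            if prev is None or key > (prev[0], prev[1]):
                results[gi] = (identity, end, v0, r0)
        # best = max identity, then longer alignment, then lexicographically
        # smallest name
        best = None
        for ident, alen, gi, v0, r0 in results_sorted(results, self.names):
            best = (ident, alen, gi, v0, r0)
            break
        if best is None:
            return None
        ident, alen, gi, v0, r0 = best
        if alen < min_len or ident < min_identity:
            return None
        ambiguous = sum(
            1 for t in results.values()
            if t[0] == ident and t[1] == alen
        ) > 1
        return VAssignment(
            gene=self.names[gi], identity_pct=ident, aligned_len=alen,
            v_start=v0, v_read_start=r0, v_read_end=r0 + alen,
            ambiguous=ambiguous,
        )


def results_sorted(results: dict, names: list[str]):
    """Candidates ranked by identity desc, aligned length desc, name asc."""
    return sorted(
        ((ident, alen, gi, v0, r0)
         for gi, (ident, alen, v0, r0) in results.items()),
        key=lambda t: (-t[0], -t[1], names[t[2]]),
    )


def _find_approx(haystack: str, needle: str, max_mismatch: int) -> int:
    """Leftmost position of needle in haystack allowing substitutions."""
    pos = haystack.find(needle)
    if pos >= 0 or max_mismatch == 0:
        return pos
    h = np.frombuffer(haystack.encode(), dtype="S1")
    nd = np.frombuffer(needle.encode(), dtype="S1")
    L = len(nd)
    if len(h) < L:
        return -1
    windows = np.lib.stride_tricks.sliding_window_view(h, L)
    mism = (windows != nd).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return int(hits[0]) if hits.size else -1


def assign_j(
    read_seq: str,
    ref: LocusReference,
    primer_set: str = "primary",
    max_mismatch: int = 1,
) -> Optional[JAssignment]:
    """Identify the rearranged Jk from the sequence upstream of the primer.

    Each Jk exon, minus its ``junction_exclusion`` most V-proximal
    nucleotides, is searched in the read; the most V-proximal (5'-most)
    match is the rearranged Jk.  Returns None (unassigned-J) when no exon
    matches.
    """
    excl = JUNCTION_EXCLUSION[primer_set]
    best: Optional[tuple[int, str]] = None
    for j in ref.j_genes:
        pat = ref.jk_exon_seq(j)[excl:]
        pos = read_seq.find(pat)
        if pos >= 0 and (best is None or pos < best[0]):
            best = (pos, j.name)
    if best is None and max_mismatch > 0:
        # near-exact pass only when no exon matched exactly (sequencing
        # errors in the exon stretch)
        for j in ref.j_genes:
            pat = ref.jk_exon_seq(j)[excl:]
            pos = _find_approx(read_seq, pat, max_mismatch)
            if pos >= 0 and (best is None or pos < best[0]):
                best = (pos, j.name)
    if best is None:
        return None
    return JAssignment(jk=best[1], exon_read_start=best[0] - excl)


# re-assignment of gDNA Jk calls is the same upstream-sequence search; the
# name documents intent at call sites
reassign_j = assign_j


def call_productive(
    read_seq: str,
    v: Optional[VAssignment],
    j: Optional[JAssignment],
    ref: LocusReference,
    aligner: VAligner,
) -> str:
    """Frame-based productivity: the V coding frame must continue into the
    Jk exon and no in-frame stop codon may occur from the start of the V
    coding region through the end of the Jk exon."""
    if v is None or j is None:
        return "indeterminate"
    gi = aligner.names.index(v.gene)
    coding_start_read = v.v_read_start + (aligner.coding_offset[gi] - v.v_start)
    exon_len = len(ref.jk_exon_seq(ref.jk(j.jk)))
    offset = j.exon_read_start - coding_start_read
    if offset <= 0:
        return "indeterminate"
    if offset % 3 != 0:
        return "non-productive"
    scan_start = coding_start_read
    while scan_start < 0:
        scan_start += 3
    scan_end = min(j.exon_read_start + exon_len, len(read_seq))
    for i in range(scan_start, scan_end - 2, 3):
        if read_seq[i:i + 3] in STOP_CODONS:
            return "non-productive"
    return "productive"


def classify_orientation(v_gene: Optional[str], ref: LocusReference) -> Optional[str]:
    """Deletional vs inversional, copied from the assigned gene."""
    if v_gene is None:
        return None
    return ref.vk(v_gene).orientation


def process_read(
    read_id: str,
    seq: str,
    umi: str,
    ref: LocusReference,
    aligner: VAligner,
    chemistry: str,
    primer_set: str = "primary",
    sample_id: str = "sample",
) -> VJCall:
    """Full per-read assignment: V, Jk (re-assigned for gDNA), frame,
    orientation."""
    v = aligner.assign_v(seq)
    j = assign_j(seq, ref, primer_set=primer_set)
    junction = ""
    if v is not None and j is not None and j.exon_read_start > v.v_read_end:
        junction = seq[v.v_read_end:j.exon_read_start]
    productive = call_productive(seq, v, j, ref, aligner)
    return VJCall(
        read_id=read_id, umi=umi, sample_id=sample_id,
        v_gene=None if v is None else v.gene,
        identity_pct=0.0 if v is None else v.identity_pct,
        v_aligned_len=0 if v is None else v.aligned_len,
        v_start=-1 if v is None else v.v_start,
        jk=None if j is None else j.jk,
        junction_seq=junction,
        productive=productive,
        orientation_class=classify_orientation(None if v is None else v.gene, ref),
        ambiguous=False if v is None else v.ambiguous,
    )


def calls_to_frame(calls: list[VJCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def process_merged_reads(
    merged,
    ref: LocusReference,
    chemistry: str,
    primer_set: str = "primary",
    sample_id: str = "sample",
    aligner: Optional[VAligner] = None,
) -> list[VJCall]:
    aligner = aligner or VAligner(ref)
    return [
        process_read(m.id, m.seq, m.umi, ref, aligner, chemistry,
                     primer_set=primer_set, sample_id=sample_id)
        for m in merged
    ]
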