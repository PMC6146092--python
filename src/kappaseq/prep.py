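"""Read preparation: quality trimming, UMI extraction, pair merging.

Contracts ahead of V/J calling: trailing bases at Phred <= 20 are trimmed
from the 3' end of each mate; a pair losing more than 50 bases from either
mate is discarded outright.  Mates are then merged by overlap consensus
(seeded overlap scan; the higher-quality base wins at a mismatch) and
unmerged pairs are dropped from downstream analysis.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .locus import revcomp

DEFAULT_PHRED_FLOOR = 20
DEFAULT_MAX_TRIM = 50
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.1


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]
    umi: str = ""

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: list[int]
    umi: str = ""


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream paired FASTQ (gzip or plain) into ReadPair records."""

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            rid = t1.split()[0]
            if rid != t2.split()[0]:
                raise ValueError(f"unsynchronised mates: {t1!r} vs {t2!r}")
            yield ReadPair(
                id=rid,
                seq1=s1, qual1=[ord(c) - 33 for c in q1],
                seq2=s2, qual2=[ord(c) - 33 for c in q2],
            )


def _trailing_low_quality(qual: list[int], floor: int) -> int:
    n = 0
    for q in reversed(qual):
        if q <= floor:
            n += 1
        else:
            break
    return n


def trim_filter(
    pair: ReadPair,
    max_trim: int = DEFAULT_MAX_TRIM,
    phred_floor: int = DEFAULT_PHRED_FLOOR,
) -> Optional[ReadPair]:
    """Trim trailing bases with Phred <= ``phred_floor`` from both mates;
    return None (pair discarded) if either mate loses more than
    ``max_trim`` bases.  5' ends are never altered."""
    t1 = _trailing_low_quality(pair.qual1, phred_floor)
    t2 = _trailing_low_quality(pair.qual2, phred_floor)
    if t1 > max_trim or t2 > max_trim:
        return None
    return ReadPair(
        id=pair.id,
        seq1=pair.seq1[: len(pair.seq1) - t1],
        qual1=pair.qual1[: len(pair.qual1) - t1],
        seq2=pair.seq2[: len(pair.seq2) - t2],
        qual2=pair.qual2[: len(pair.qual2) - t2],
        umi=pair.umi,
    )


def extract_umi(pair: ReadPair, chemistry: str, umi_len: int = 6) -> ReadPair:
    """Move the 6N UMI off the read into ``pair.umi``.

    Both library chemistries place the 6N at the start of R1 (gDNA: the
    shear-side adapter; RNA: the 3' end of the 5' bridge adapter).
    """
    if chemistry not in ("gdna", "rna"):
        raise ValueError(f"unknown chemistry {chemistry!r}")
    if len(pair.seq1) < umi_len:
        raise ValueError(f"{pair.id}: read shorter than UMI")
    return ReadPair(
        id=pair.id,
        seq1=pair.seq1[umi_len:], qual1=pair.qual1[umi_len:],
        seq2=pair.seq2, qual2=pair.qual2,
        umi=pair.seq1[:umi_len],
    )


def _overlap_candidates(seq1: str, r2rc: str, min_overlap: int, k: int = 20) -> list[int]:
    """Candidate offsets of r2rc within seq1, seeded by exact k-mer hits of
    the r2rc prefix (offset s means r2rc starts at seq1 position s)."""
    offsets = []
    if len(r2rc) >= k:
        seed = r2rc[:k]
        start = 0
        while True:
            i = seq1.find(seed, start)
            if i < 0:
                break
            offsets.append(i)
            start = i + 1
    return offsets


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> Optional[MergedRead]:
    """Overlap-consensus merge of a trimmed pair; None when no acceptable
    overlap exists.  At overlap mismatches the higher-quality base wins."""
    seq1, q1 = pair.seq1, pair.qual1
    r2rc = revcomp(pair.seq2)
    q2r = pair.qual2[::-1]
    n1, n2 = len(seq1), len(r2rc)
    if min(n1, n2) < min_overlap:
        return None

    a1 = np.frombuffer(seq1.encode(), dtype="S1")
    a2 = np.frombuffer(r2rc.encode(), dtype="S1")

    def evaluate(s: int) -> Optional[tuple[int, int]]:
        ov = min(n1 - s, n2)
        if ov < min_overlap:
            return None
        mism = int((a1[s:s + ov] != a2[:ov]).sum())
        if mism > max_mismatch_frac * ov:
            return None
        return ov, mism

    candidates = _overlap_candidates(seq1, r2rc, min_overlap)
    best: Optional[tuple[int, int, int]] = None  # (ov, -mism, -s)
    best_s = None
    for s in candidates or range(0, n1 - min_overlap + 1):
        res = evaluate(s)
        if res is None:
            continue
        key = (res[0], -res[1], -s)
        if best is None or key > best:
            best, best_s = key, s
    if best_s is None and candidates:
        # seeds existed but none validated (e.g. sequencing error in the
        # seed); fall back to the exhaustive scan
        for s in range(0, n1 - min_overlap + 1):
            res = evaluate(s)
            if res is None:
                continue
            key = (res[0], -res[1], -s)
            if best is None or key > best:
                best, best_s = key, s
    if best_s is None:
        return None

    s = best_s
    ov = min(n1 - s, n2)
    merged_seq = list(seq1[:s])
    merged_q = list(q1[:s])
    for i in range(ov):
        b1, b2 = seq1[s + i], r2rc[i]
        if b1 == b2:
            merged_seq.append(b1)
            merged_q.append(max(q1[s + i], q2r[i]))
        elif q1[s + i] >= q2r[i]:
            merged_seq.append(b1)
            merged_q.append(q1[s + i])
        else:
            merged_seq.append(b2)
            merged_q.append(q2r[i])
    if s + n2 > n1:
        merged_seq.extend(r2rc[ov:])
        merged_q.extend(q2r[ov:])
    else:  # r2 contained within r1
        merged_seq.extend(seq1[s + ov:])
        merged_q.extend(q1[s + ov:])
    return MergedRead(id=pair.id, seq="".join(merged_seq), qual=merged_q, umi=pair.umi)


@dataclass
class PrepStats:
    total: int = 0
    discarded_trim: int = 0
    unmerged: int = 0
    merged: int = 0
    reasons: dict = field(default_factory=dict)


def prepare_pairs(
    pairs,
    chemistry: str,
    max_trim: int = DEFAULT_MAX_TRIM,
    phred_floor: int = DEFAULT_PHRED_FLOOR,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[MergedRead], PrepStats]:
    """UMI-extract, trim and merge an iterable of ReadPairs."""
    stats = PrepStats()
    out: list[MergedRead] = []
    for pair in pairs:
        stats.total += 1
        pair = extract_umi(pair, chemistry)
        trimmed = trim_filter(pair, max_trim=max_trim, phred_floor=phred_floor)
        if trimmed is None:
            stats.discarded_trim += 1
            continue
        merged = merge_pair(trimmed, min_overlap=min_overlap,
                            max_mismatch_frac=max_mismatch_frac)
        if merged is None:
            stats.unmerged += 1
            continue
        stats.merged += 1
        out.append(merged)
    return out, stats


def sim_reads_to_pairs(reads) -> Iterator[ReadPair]:
    """Adapt simulator SimRead records to ReadPairs (no FASTQ round trip)."""
    for r in reads:
        yield ReadPair(
            id=r.name,
            seq1=r.r1, qual1=[ord(r.qual_char) - 33] * len(r.r1),
            seq2=r.r2, qual2=[ord(r.qual_char) - 33] * len(r.r2),
        )
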