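"""PCR-duplicate collapsing and identical-pair reallocation.

Reads sharing the random adapter 6N (and, for gDNA, the same V read start
position -- shear starts are random, so identity of both marks a PCR
duplicate) are presumed to come from one molecule and counted once.  The
dedup key additionally includes the (V gene, Jk) assignment so molecules
from different genes can never collapse.

Three Vk gene pairs of the real locus are 100% identical over their
3'-most 150 bp; reads covering only that stretch are assigned to one
member arbitrarily (deterministically, by the caller's tie-break).  Counts
are corrected afterwards: among the pair's reads long enough to contain a
discriminating upstream tag, the tag-hit ratio a:b re-divides the pooled
total T into T*a/(a+b) and T*b/(a+b) (real-valued counts, conserving T
exactly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .caller import VJCall
from .locus import IdenticalPair, LocusReference

log = logging.getLogger(__name__)


def dedup_key(call: VJCall, chemistry: str) -> tuple:
    if chemistry == "gdna":
        return (call.sample_id, call.umi, call.v_start, call.v_gene, call.jk)
    if chemistry == "rna":
        return (call.sample_id, call.umi, call.v_gene, call.jk)
    raise ValueError(f"unknown chemistry {chemistry!r}")


def dedup(calls: Iterable[VJCall], chemistry: str) -> list[VJCall]:
    """Keep exactly one representative per duplicate key (first in stable
    input order).  Idempotent."""
    seen: set[tuple] = set()
    out: list[VJCall] = []
    for c in calls:
        k = dedup_key(c, chemistry)
        if k in seen:
            continue
        seen.add(k)
        out.append(c)
    return out


@dataclass
class PairAdjustment:
    member_a: str
    member_b: str
    total: float
    tag_hits_a: int
    tag_hits_b: int
    adjusted_a: float
    adjusted_b: float
    applied: bool


def count_tag_hits(
    reads_by_gene: Mapping[str, Iterable[str]],
    pairs: Iterable[IdenticalPair],
) -> dict[tuple[str, str], tuple[int, int]]:
    """Count discriminating-tag occurrences among the reads assigned to
    either member of each identical pair.

    ``reads_by_gene`` maps an assigned gene name to the read sequences
    assigned to it; only reads long enough to actually cover the far
    upstream tag can contribute a hit.
    """
    out = {}
    for p in pairs:
        a = b = 0
        for gene in (p.member_a, p.member_b):
            for seq in reads_by_gene.get(gene, ()):
                if p.tag_a in seq:
                    a += 1
                elif p.tag_b in seq:
                    b += 1
        out[(p.member_a, p.member_b)] = (a, b)
    return out


def reallocate_identical_pairs(
    counts: Mapping[str, float],
    tag_hits: Mapping[tuple[str, str], tuple[int, int]],
) -> tuple[dict[str, float], list[PairAdjustment]]:
    """Re-divide each identical pair's pooled count by its tag-hit ratio.

    For pooled count T = n_a + n_b and tag hits (a, b):
    n_a' = T*a/(a+b), n_b' = T*b/(a+b).  When a+b == 0 the pair is left
    unadjusted with a warning.  Conservation n_a' + n_b' == T is exact.
    """
    adjusted = dict(counts)
    audit: list[PairAdjustment] = []
    for (ga, gb), (a, b) in tag_hits.items():
        na = adjusted.get(ga, 0.0)
        nb = adjusted.get(gb, 0.0)
        total = na + nb
        if a + b == 0:
            log.warning("pair (%s,%s): no tag-covering reads; left unadjusted",
                        ga, gb)
            audit.append(PairAdjustment(ga, gb, total, a, b, na, nb, False))
            continue
        new_a = total * a / (a + b)
        new_b = total - new_a
        adjusted[ga] = new_a
        adjusted[gb] = new_b
        audit.append(PairAdjustment(ga, gb, total, a, b, new_a, new_b, True))
    return adjusted, audit


def adjustment_audit_frame(audit: list[PairAdjustment]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in audit])


def dedup_and_reallocate(
    calls: list[VJCall],
    chemistry: str,
    ref: Optional[LocusReference] = None,
    read_seqs: Optional[Mapping[str, str]] = None,
) -> tuple[list[VJCall], dict[str, float], list[PairAdjustment]]:
    """Convenience wrapper: dedup, tally per-gene counts, then reallocate
    identical pairs using ``read_seqs`` (read_id -> merged sequence) for
    the tag search.  Returns (deduplicated calls, adjusted per-gene counts,
    audit)."""
    kept = dedup(calls, chemistry)
    counts: dict[str, float] = {}
    for c in kept:
        if c.v_gene is not None:
            counts[c.v_gene] = counts.get(c.v_gene, 0.0) + 1.0
    audit: list[PairAdjustment] = []
    if ref is not None and ref.identical_pairs and read_seqs is not None:
        by_gene: dict[str, list[str]] = {}
        for c in kept:
            if c.v_gene is not None and c.read_id in read_seqs:
                by_gene.setdefault(c.v_gene, []).append(read_seqs[c.read_id])
        hits = count_tag_hits(by_gene, ref.identical_pairs)
        counts, audit = reallocate_identical_pairs(counts, hits)
    return kept, counts, audit
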