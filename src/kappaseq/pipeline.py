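"""End-to-end orchestration: simulate -> prep -> call -> dedup -> counts.

Thin glue used by the analysis drivers, the test-suite oracles and the
acceptance script; each stage lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .caller import VAligner, VJCall, process_merged_reads
from .dedup import PairAdjustment, dedup_and_reallocate
from .locus import LocusReference
from .prep import MergedRead, PrepStats, prepare_pairs, sim_reads_to_pairs
from .simulate import (
    GroundTruth,
    SimConfig,
    gdna_read_pairs,
    rna_read_pairs,
)


@dataclass
class PipelineResult:
    truth: GroundTruth
    merged: list[MergedRead]
    prep_stats: PrepStats
    calls: list[VJCall]
    dedup_calls: list[VJCall]
    gene_counts: dict[str, float]
    pair_audit: list[PairAdjustment] = field(default_factory=list)
    molecules: Optional[pd.DataFrame] = None  # RNA molecule table

    def gene_jk_counts(self) -> dict[tuple[str, str], float]:
        """Deduplicated (gene, jk) counts with identical-pair adjustment
        spread proportionally over the member's Jk usage."""
        raw: dict[tuple[str, str], float] = {}
        for c in self.dedup_calls:
            if c.v_gene is None or c.jk is None:
                continue
            raw[(c.v_gene, c.jk)] = raw.get((c.v_gene, c.jk), 0.0) + 1.0
        per_gene: dict[str, float] = {}
        for (g, _), n in raw.items():
            per_gene[g] = per_gene.get(g, 0.0) + n
        out: dict[tuple[str, str], float] = {}
        for (g, jk), n in raw.items():
            adj = self.gene_counts.get(g, per_gene[g])
            out[(g, jk)] = n * (adj / per_gene[g]) if per_gene[g] else 0.0
        # pair members that lost all raw reads to their partner keep their
        # reallocated total on the partner's Jk profile
        for g, adj in self.gene_counts.items():
            if adj > 0 and per_gene.get(g, 0.0) == 0.0:
                out[(g, "Jk1")] = adj
        return out


def run_library(
    ref: LocusReference,
    config: SimConfig,
    chemistry: str = "gdna",
    seed: int = 0,
    primer_set: str = "primary",
    sample_id: str = "sample",
    truth: Optional[GroundTruth] = None,
    aligner: Optional[VAligner] = None,
) -> PipelineResult:
    """Simulate one library and run it through the full pipeline."""
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = simulate_truth(ref, config, rng)
    molecules = None
    if chemistry == "gdna":
        reads = gdna_read_pairs(truth, ref, config, rng, primer_set=primer_set)
    else:
        reads, molecules = rna_read_pairs(truth, ref, config, rng)
    merged, prep_stats = prepare_pairs(sim_reads_to_pairs(reads), chemistry)
    calls = process_merged_reads(
        merged, ref, chemistry, primer_set=primer_set,
        sample_id=sample_id, aligner=aligner,
    )
    read_seqs = {m.id: m.seq for m in merged}
    kept, counts, audit = dedup_and_reallocate(
        calls, chemistry, ref=ref, read_seqs=read_seqs)
    return PipelineResult(
        truth=truth, merged=merged, prep_stats=prep_stats, calls=calls,
        dedup_calls=kept, gene_counts=counts, pair_audit=audit,
        molecules=molecules,
    )


def simulate_truth(ref, config, seed) -> GroundTruth:
    from .simulate import simulate_repertoire

    return simulate_repertoire(ref, config, seed)


def nonproductive_junction_percentage(
    seed: int,
    n_molecules: int = 100_000,
    n_genes: int = 20,
) -> tuple[float, int]:
    """Percentage of non-productive VkJk junctions in a simulated gDNA
    repertoire with equiprobable reading-frame offsets, as classified by
    the frame-based productivity caller on fully processed reads.

    Returns (percentage, number of frame-resolved reads).  The underlying
    expectation is the two-thirds non-productive frequency of random
    junctions.
    """
    from .simulate import make_synthetic_locus

    ref = make_synthetic_locus(n_genes=n_genes, seed=seed,
                               n_identical_pairs=0)
    config = SimConfig(
        n_molecules=n_molecules, pcr_dup_rate=0.0, cross_prime_rate=0.0,
        seq_error_rate=0.0,
    )
    res = run_library(ref, config, "gdna", seed=seed + 1)
    statuses = [c.productive for c in res.calls
                if c.productive in ("productive", "non-productive")]
    n = len(statuses)
    pct = 100.0 * sum(s == "non-productive" for s in statuses) / n
    return pct, n
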