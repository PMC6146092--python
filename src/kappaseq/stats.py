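"""Repertoire statistics over deduplicated VkJk counts.

The central container is a long-format count table (sample x Vk gene x Jk)
plus a sample sheet carrying cell stage (pro-B/pre-B), genotype, molecule
type (gDNA/RNA), replicate number and a pairing key linking libraries made
from the same sorted cells.  Frequency views follow the study's
conventions: ``VkJkALL`` pools all Jk genes per Vk gene; ``VkJk1`` (etc.)
restricts to one Jk.  Pooled-replicate frequencies are the sum of reads
over all biological replicates divided by the pooled total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .locus import JK_NAMES, LocusReference

log = logging.getLogger(__name__)

VIEW_ALL = "ALL"


@dataclass
class RepertoireTable:
    """Per sample x Vk x Jk deduplicated counts (real-valued after
    identical-pair reallocation) plus sample metadata."""

    counts: pd.DataFrame   # columns: sample, v_gene, jk, count
    samples: pd.DataFrame  # index: sample id; stage, genotype, molecule,
                           # replicate, pairing
    genes: list[str] = field(default_factory=list)  # gene universe, locus order

    def __post_init__(self):
        required = {"sample", "v_gene", "jk", "count"}
        if not required.issubset(self.counts.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        if not self.genes:
            self.genes = sorted(self.counts["v_gene"].unique().tolist())

    @classmethod
    def from_calls(
        cls,
        per_sample_counts: dict[str, dict],
        samples: pd.DataFrame,
        genes: Optional[Sequence[str]] = None,
    ) -> "RepertoireTable":
        """Build from {sample: {(gene, jk): count}} mappings."""
        rows = []
        for sample, cc in per_sample_counts.items():
            for (gene, jk), n in cc.items():
                rows.append((sample, gene, jk, float(n)))
        counts = pd.DataFrame(rows, columns=["sample", "v_gene", "jk", "count"])
        return cls(counts=counts, samples=samples,
                   genes=list(genes) if genes is not None else [])

    # -------------------------------------------------------------- helpers
    def sample_ids(self, **criteria) -> list[str]:
        df = self.samples
        for k, v in criteria.items():
            df = df[df[k] == v]
        return df.index.tolist()

    def matrix(self, view: str = VIEW_ALL,
               samples: Optional[Iterable[str]] = None) -> pd.DataFrame:
        """Gene x sample count matrix for one repertoire view."""
        df = self.counts
        if samples is not None:
            df = df[df["sample"].isin(list(samples))]
        if view != VIEW_ALL:
            df = df[df["jk"] == view]
        mat = (df.pivot_table(index="v_gene", columns="sample",
                              values="count", aggfunc="sum", fill_value=0.0)
                 .reindex(self.genes, fill_value=0.0))
        if samples is not None:
            mat = mat.reindex(columns=list(samples), fill_value=0.0)
        return mat


def frequencies(
    table: RepertoireTable,
    view: str = VIEW_ALL,
    samples: Optional[Iterable[str]] = None,
    pooled: bool = True,
) -> pd.Series | pd.DataFrame:
    """Per-gene frequency vector(s) for one view.

    Pooled mode divides the replicate-summed count of each gene by the
    pooled total (the study's definition of recombination frequency);
    otherwise one frequency column per sample is returned.
    """
    mat = table.matrix(view=view, samples=samples)
    if pooled:
        total = mat.values.sum()
        if total <= 0:
            raise ValueError(f"zero total count for view {view!r}")
        return mat.sum(axis=1) / total
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample has zero total count")
    return mat / totals


def jk_usage(
    table: RepertoireTable,
    samples: Optional[Iterable[str]] = None,
    min_reads_per_replicate: float = 5.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Global percent Jk usage and per-gene Jk-usage profiles.

    Per-gene profiles (rows summing to 100) are reported only for genes
    with at least ``min_reads_per_replicate`` reads in *every* replicate.
    """
    samples = list(samples) if samples is not None else table.samples.index.tolist()
    per_jk = {jk: table.matrix(view=jk, samples=samples) for jk in JK_NAMES}
    global_counts = pd.Series(
        {jk: m.values.sum() for jk, m in per_jk.items()}, name="percent")
    global_pct = 100.0 * global_counts / global_counts.sum()

    gene_totals_per_sample = sum(per_jk.values())  # genes x samples, all Jk
    eligible = (gene_totals_per_sample >= min_reads_per_replicate).all(axis=1)
    prof = pd.DataFrame(
        {jk: per_jk[jk].sum(axis=1) for jk in JK_NAMES})
    prof = prof.loc[eligible[eligible].index.intersection(prof.index)]
    prof = prof.loc[[g for g in table.genes if g in prof.index and eligible[g]]]
    row_tot = prof.sum(axis=1)
    prof = 100.0 * prof.div(row_tot.replace(0, np.nan), axis=0).fillna(0.0)
    return global_pct, prof


def jk_repertoire_correlations(
    table: RepertoireTable,
    samples: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Pearson correlation matrix across genes between the pooled per-Jk
    repertoire frequency vectors (VkJk1, VkJk2, VkJk4, VkJk5)."""
    vecs = {}
    for jk in JK_NAMES:
        mat = table.matrix(view=jk, samples=samples)
        tot = mat.values.sum()
        vecs[jk] = mat.sum(axis=1) / tot if tot > 0 else mat.sum(axis=1)
    df = pd.DataFrame(vecs)
    return df.corr(method="pearson")


def classify_active(
    table: RepertoireTable,
    mode: str = "preB",
    samples: Optional[Iterable[str]] = None,
    threshold_per_million: float = 15.0,
    min_reads: float = 1.0,
) -> pd.Series:
    """Active/inactive classification of Vk genes from pooled counts.

    pre-B mode: active iff pooled count >= threshold_per_million reads per
    million pooled reads.  pro-B mode: active iff pooled count >=
    ``min_reads`` (the low-depth rule).
    """
    mat = table.matrix(view=VIEW_ALL, samples=samples)
    pooled = mat.sum(axis=1)
    total = pooled.sum()
    if mode == "preB":
        cutoff = threshold_per_million * total / 1e6
        active = pooled >= cutoff
    elif mode == "proB":
        active = pooled >= min_reads
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return active.map({True: "active", False: "inactive"})


@dataclass
class RatioReport:
    """Per-gene divergence between two repertoires (e.g. gDNA vs RNA)."""

    per_replicate: pd.DataFrame   # genes x replicate-pair ratios (A/B)
    mean_ratio: pd.Series         # arithmetic mean of replicate ratios
    flags: pd.Series              # 'A' | 'B' | '' per gene
    excluded: list[str]           # genes lacking reads in some replicate
    direction_labels: tuple[str, str] = ("A", "B")


def ratio_analysis(
    table_a: RepertoireTable,
    table_b: RepertoireTable,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    view: str = VIEW_ALL,
    min_fold_avg: float = 2.0,
    min_fold_each: float = 1.5,
    functional_only: Optional[LocusReference] = None,
) -> RatioReport:
    """Replicate-paired frequency-ratio filter between two repertoires.

    ``samples_a``/``samples_b`` are aligned replicate lists (same sort).
    A gene is flagged divergent toward A when its mean A/B frequency ratio
    is >= ``min_fold_avg`` and every per-replicate ratio is >=
    ``min_fold_each`` (and symmetrically toward B on the reciprocal).
    Genes lacking reads in any replicate of either repertoire are excluded,
    as are pseudogenes when ``functional_only`` provides the locus.
    """
    if len(samples_a) != len(samples_b):
        raise ValueError("replicate pairing mismatch between the two tables")
    fa = frequencies(table_a, view=view, samples=samples_a, pooled=False)
    fb = frequencies(table_b, view=view, samples=samples_b, pooled=False)
    genes = [g for g in table_a.genes if g in fb.index]
    fa = fa.reindex(genes, fill_value=0.0)
    fb = fb.reindex(genes, fill_value=0.0)

    has_all = (fa.gt(0).all(axis=1)) & (fb.gt(0).all(axis=1))
    excluded = [g for g in genes if not has_all[g]]
    if functional_only is not None:
        for g in genes:
            if g not in excluded and functional_only.vk(g).functionality == "pseudogene":
                excluded.append(g)
    keep = [g for g in genes if g not in excluded]

    ratios = pd.DataFrame(
        fa.loc[keep].values / fb.loc[keep].values,
        index=keep,
        columns=[f"rep{i + 1}" for i in range(len(samples_a))],
    )
    mean_ratio = ratios.mean(axis=1)
    flag_a = (mean_ratio >= min_fold_avg) & (ratios >= min_fold_each).all(axis=1)
    recip = 1.0 / ratios
    flag_b = (recip.mean(axis=1) >= min_fold_avg) & (recip >= min_fold_each).all(axis=1)
    flags = pd.Series("", index=keep, dtype=object)
    flags[flag_a] = "A"
    flags[flag_b] = "B"
    return RatioReport(per_replicate=ratios, mean_ratio=mean_ratio,
                       flags=flags, excluded=excluded)


def pseudo_count_ratio(
    freq_a: pd.Series,
    freq_b: pd.Series,
    total_a: float,
    total_b: float,
    min_partner_freq: float = 0.0,
) -> pd.DataFrame:
    """Per-gene frequency ratio A/B with the one-read zero-replacement rule.

    A zero frequency paired with a nonzero partner (at or above
    ``min_partner_freq``) is replaced by the frequency equivalent of one
    read (1/total); such ratios are flagged ``underrepresented`` since the
    true disparity is at least as large.  Genes zero on both sides are
    skipped with a log entry.
    """
    rows = {}
    for g in freq_a.index.union(freq_b.index):
        a = float(freq_a.get(g, 0.0))
        b = float(freq_b.get(g, 0.0))
        if a == 0.0 and b == 0.0:
            log.info("gene %s: zero in both repertoires; ratio undefined", g)
            continue
        replaced = False
        if a == 0.0 and b >= min_partner_freq:
            a = 1.0 / total_a
            replaced = True
        if b == 0.0 and a >= min_partner_freq:
            b = 1.0 / total_b
            replaced = True
        if a == 0.0 or b == 0.0:
            log.info("gene %s: zero below partner threshold; skipped", g)
            continue
        rows[g] = {"ratio": a / b, "underrepresented": replaced}
    return pd.DataFrame.from_dict(rows, orient="index")


def half_bias(
    table: RepertoireTable,
    ref: LocusReference,
    view: str = VIEW_ALL,
    samples: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Summed proximal vs distal frequency per sample (rows sum to 1)."""
    halves = {g.name: g.half for g in ref.v_genes}
    missing = [g for g, h in halves.items() if h not in ("proximal", "distal")]
    if missing:
        raise ValueError("assign_halves must run before half_bias")
    freq = frequencies(table, view=view, samples=samples, pooled=False)
    prox_genes = [g for g in freq.index if halves.get(g) == "proximal"]
    dist_genes = [g for g in freq.index if halves.get(g) == "distal"]
    return pd.DataFrame({
        "proximal": freq.loc[prox_genes].sum(axis=0),
        "distal": freq.loc[dist_genes].sum(axis=0),
    })
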