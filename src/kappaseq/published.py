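"""Loader for externally distributed processed per-gene read tables.

The study's processed read data (per sample x Vk gene deduplicated read
counts) is distributed as supplementary material and is not bundled with
this package.  When a user supplies it as a TSV it can be fed straight
into the repertoire statistics, e.g. to reproduce the active-gene counts
and the gDNA/RNA divergence filter on the real data.

Expected TSV layout: one row per (sample, v_gene, jk) with columns
``sample``, ``v_gene``, ``jk`` (``ALL`` allowed when only pooled counts
are available), ``count``, plus a sample sheet TSV with columns
``sample``, ``stage``, ``genotype``, ``molecule``, ``replicate``,
``pairing``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .stats import RepertoireTable

#: default location where a user may drop the supplementary table
DEFAULT_TABLE_PATH = Path("data/published/processed_per_gene_reads.tsv")
DEFAULT_SAMPLES_PATH = Path("data/published/processed_samples.tsv")


class MissingPublishedData(FileNotFoundError):
    pass


def load_per_gene_read_table(
    table_path: str | Path = DEFAULT_TABLE_PATH,
    samples_path: str | Path = DEFAULT_SAMPLES_PATH,
    genes: Optional[Sequence[str]] = None,
) -> RepertoireTable:
    table_path = Path(table_path)
    samples_path = Path(samples_path)
    if not table_path.exists() or not samples_path.exists():
        raise MissingPublishedData(
            f"processed per-gene read tables not found at {table_path} / "
            f"{samples_path}; they are distributed as the study's "
            "supplementary material and must be supplied by the user"
        )
    counts = pd.read_csv(table_path, sep="\t")
    counts["count"] = counts["count"].astype(float)
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample")
    return RepertoireTable(counts=counts, samples=samples,
                           genes=list(genes) if genes else [])
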