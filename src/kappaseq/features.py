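"""Window quantification of chromatin / RNA coverage around Vk genes.

Each Vk gene gets four non-overlapping windows defined in its own
orientation: promoter (500 bp upstream of the leader-1 start plus leader
and its intron), RSS (coding region plus 500 bp downstream), upstream
(2.5 kb immediately upstream of the promoter window) and downstream
(2.5 kb immediately downstream of the RSS window).  Coverage tracks are
consumed as bedGraph intervals with a declared mapped-tag total; window
signal is the per-base coverage sum scaled to a 10-million-tag library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .locus import LocusReference, VkGene

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 500
RSS_DOWNSTREAM = 500
FLANK = 2500
WINDOW_NAMES = ("promoter", "rss", "upstream", "downstream")
TAG_NORM = 1e7


@dataclass
class GeneWindows:
    promoter: tuple[int, int]
    rss: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            "promoter": self.promoter, "rss": self.rss,
            "upstream": self.upstream, "downstream": self.downstream,
        }

    def validate(self) -> None:
        ivs = sorted(self.as_dict().values())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError("gene windows overlap")


def build_windows(gene: VkGene) -> GeneWindows:
    """The four genomic windows for one gene, orientation-aware (upstream
    means 5' of the gene's own transcription)."""
    if gene.leader1_start < 0:
        raise ValueError(f"{gene.name}: missing leader annotation")
    if gene.orientation == "deletional":
        promoter = (gene.leader1_start - PROMOTER_UPSTREAM, gene.start)
        rss = (gene.start, gene.end + RSS_DOWNSTREAM)
        upstream = (promoter[0] - FLANK, promoter[0])
        downstream = (rss[1], rss[1] + FLANK)
    else:
        promoter = (gene.end, gene.leader1_start + 1 + PROMOTER_UPSTREAM)
        rss = (gene.start - RSS_DOWNSTREAM, gene.end)
        upstream = (promoter[1], promoter[1] + FLANK)
        downstream = (rss[0] - FLANK, rss[0])
    gw = GeneWindows(promoter=promoter, rss=rss,
                     upstream=upstream, downstream=downstream)
    gw.validate()
    return gw


def quantify_track(
    track: pd.DataFrame,
    windows: GeneWindows,
    total_tags: float,
    chrom: Optional[str] = None,
) -> dict[str, float]:
    """Per-window signal: sum of per-base coverage inside the window,
    scaled by 10^7 / total_tags.  Linear in coverage and inversely
    proportional to the tag total."""
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    if chrom is not None and "chrom" in track.columns:
        track = track[track["chrom"] == chrom]
    starts = track["start"].to_numpy(dtype=float)
    ends = track["end"].to_numpy(dtype=float)
    values = track["value"].to_numpy(dtype=float)
    out = {}
    scale = TAG_NORM / total_tags
    for name, (ws, we) in windows.as_dict().items():
        ov = np.minimum(ends, we) - np.maximum(starts, ws)
        ov = np.clip(ov, 0, None)
        sig = float((ov * values).sum()) * scale
        if sig == 0.0 and len(starts) and (we <= starts.min() or ws >= ends.max()):
            log.warning("window %s [%d,%d) outside track span; signal 0",
                        name, ws, we)
        out[name] = sig
    return out


def assemble_matrix(
    ref: LocusReference,
    tracks: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    stage_mode: str = "preB",
    mask_columns: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Genes x features matrix: {track x window} signals plus the two
    genetic features (RIC score and distance to Jk1).

    ``stage_mode='preB'`` uses both pre-B and pro-B tracks; ``'proB'``
    restricts to pro-B tracks.  ``mask_columns`` drops named feature
    columns after assembly (the published feature set masks a handful of
    window features; which ones is a manifest-level choice).
    """
    required = {"name", "stage", "total_tags"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"track manifest needs columns {sorted(required)}")
    if stage_mode == "preB":
        chosen = manifest
    elif stage_mode == "proB":
        chosen = manifest[manifest["stage"] == "proB"]
    else:
        raise ValueError(f"unknown stage_mode {stage_mode!r}")

    windows = {g.name: build_windows(g) for g in ref.v_genes}
    cols: dict[str, list[float]] = {}
    for row in chosen.itertuples(index=False):
        if row.name not in tracks:
            raise ValueError(f"manifest names unknown track {row.name!r}")
        track = tracks[row.name]
        per_gene = [
            quantify_track(track, windows[g.name], float(row.total_tags))
            for g in ref.v_genes
        ]
        for w in WINDOW_NAMES:
            cols[f"{row.name}:{w}"] = [pg[w] for pg in per_gene]
    mat = pd.DataFrame(cols, index=ref.v_names)
    mat["ric_score"] = [g.ric_score for g in ref.v_genes]
    mat["distance_to_jk1"] = [g.distance_to_jk1 for g in ref.v_genes]
    if mask_columns:
        mat = mat.drop(columns=[c for c in mask_columns if c in mat.columns])
    if mat.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return mat
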