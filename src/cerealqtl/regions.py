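"""Homologous-locus interval inference from filtered hits.

Marker or transcript hits that survive filtering nominate a chromosomal
segment per genome.  Borders snap to the extreme hit positions — evidence,
not annotation; gene-aware trimming happens downstream.  When a low
identity threshold lets stray hits through (the rice case), the
continuity filter keeps only the dominant spatial cluster of hits on a
chromosome, operationalizing the requirement that retained matches form
one continuous interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .io import AlignmentHit, write_bed6

#: Default single-linkage gap limits (bp).  Transcript projections are
#: dense, so a tighter limit suffices; sparse marker panels need slack.
DEFAULT_MAX_GAP_TRANSCRIPT = 2_000_000
DEFAULT_MAX_GAP_MARKER = 5_000_000
DEFAULT_MIN_SUPPORT = 3


@dataclass(frozen=True)
class LocusInterval:
    """An inferred homologous chromosomal segment (1-based inclusive)."""

    genome: str
    chrom: str
    start: int
    end: int
    support: int  # distinct supporting queries
    method: str   # marker | transcript_projection

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def jaccard(self, other: "LocusInterval | tuple[int, int]") -> float:
        """Jaccard overlap of the two intervals (same chromosome assumed)."""
        o_start, o_end = (other.start, other.end) if isinstance(other, LocusInterval) else other
        inter = min(self.end, o_end) - max(self.start, o_start) + 1
        if inter <= 0:
            return 0.0
        union = max(self.end, o_end) - min(self.start, o_start) + 1
        return inter / union


def infer_interval(
    hits: Sequence[AlignmentHit],
    min_support: int = DEFAULT_MIN_SUPPORT,
    genome: str = "",
    method: str = "marker",
) -> list[LocusInterval]:
    """Nominate one interval per chromosome carrying enough distinct queries.

    Hits are grouped by subject chromosome; a chromosome with at least
    ``min_support`` distinct query ids yields the interval spanning the
    strand-normalized extremes of its hits.  A single stray hit can never
    nominate a region.  Empty input yields an empty list.
    """
    by_chrom: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.sid, []).append(h)

    intervals: list[LocusInterval] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        queries = {h.qid for h in group}
        if len(queries) < min_support:
            continue
        lo = min(h.subject_span[0] for h in group)
        hi = max(h.subject_span[1] for h in group)
        intervals.append(
            LocusInterval(
                genome=genome, chrom=chrom, start=lo, end=hi,
                support=len(queries), method=method,
            )
        )
    return intervals


def continuity_filter(
    hits: Sequence[AlignmentHit],
    max_gap: int = DEFAULT_MAX_GAP_TRANSCRIPT,
) -> list[AlignmentHit]:
    """Keep only the dominant spatial cluster of hits on one chromosome.

    Hits (all on one chromosome) are clustered by single linkage with
    inter-hit gap <= ``max_gap``; the cluster supported by the most
    distinct queries wins, ties broken by higher summed bitscore.  Output
    preserves input order; the operation is idempotent.
    """
    if not hits:
        return []
    chroms = {h.sid for h in hits}
    if len(chroms) > 1:
        raise ValueError(
            f"continuity_filter expects hits on one chromosome, got {sorted(chroms)}"
        )
    order = sorted(range(len(hits)), key=lambda i: hits[i].subject_span[0])
    clusters: list[list[int]] = [[order[0]]]
    cluster_hi = hits[order[0]].subject_span[1]
    for idx in order[1:]:
        lo, hi = hits[idx].subject_span
        if lo - cluster_hi <= max_gap:
            clusters[-1].append(idx)
            cluster_hi = max(cluster_hi, hi)
        else:
            clusters.append([idx])
            cluster_hi = hi

    def cluster_key(c: list[int]) -> tuple[int, float]:
        return (len({hits[i].qid for i in c}), sum(hits[i].bitscore for i in c))

    best = max(clusters, key=cluster_key)
    keep = set(best)
    return [h for i, h in enumerate(hits) if i in keep]


def export_intervals(
    intervals: Iterable[LocusInterval],
    bed_path: str | Path | None = None,
    json_path: str | Path | None = None,
    parameters: dict | None = None,
) -> None:
    """Write BED6 and/or JSON reports of inferred intervals."""
    ivs = list(intervals)
    if bed_path is not None:
        write_bed6(
            (
                (iv.chrom, iv.start, iv.end, f"{iv.genome}:{iv.method}", iv.support, "+")
                for iv in ivs
            ),
            bed_path,
        )
    if json_path is not None:
        payload = {
            "intervals": [asdict(iv) for iv in ivs],
            "parameters": parameters or {},
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
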