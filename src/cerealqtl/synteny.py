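"""Cross-genome gene-order comparison against a reference genotype.

Each locus gene set is compared to the reference genotype's set by CDS
homology; every query gene receives at most one reference homolog (best
hit), mirroring a coloring scheme in which each gene carries at most one
reference color and unmatched genes stay uncolored.  Maximal descending
runs of reference ranks are then reported as candidate inversions — an
explicit, reproducible operationalization of calling inversions by eye
from the ordered diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genes import GeneRecord
from .homology import FilterPreset, filter_hits
from .io import AlignmentHit


@dataclass(frozen=True)
class InversionCall:
    genome: str
    #: 1-based query gene ranks covered by the call (inclusive)
    rank_start: int
    rank_end: int

    @property
    def length(self) -> int:
        return self.rank_end - self.rank_start + 1


@dataclass
class SyntenyMap:
    """Ordered per-genome gene lists with reference-homolog assignments."""

    reference_genome: str
    #: genome -> ordered list of (query gene rank, reference gene id or None)
    orders: dict[str, list[tuple[int, str | None]]] = field(default_factory=dict)
    #: reference gene id -> reference rank
    ref_ranks: dict[str, int] = field(default_factory=dict)
    inversion_calls: list[InversionCall] = field(default_factory=list)


def assign_homologs(
    query_genes: Sequence[GeneRecord],
    ref_genes: Sequence[GeneRecord],
    hits: Sequence[AlignmentHit],
    preset: FilterPreset | str,
) -> dict[str, str | None]:
    """Map each query gene to its best reference homolog, or None.

    ``hits`` are query-CDS vs reference-CDS alignments keyed by transcript
    id.  After preset filtering, the best reference gene per query is
    chosen by bitscore, then percent identity, then proximity of the
    reference rank to the assignments of the query's neighbors (keeps
    collinear choices among tandem duplicates), then reference gene id for
    full determinism.
    """
    passing = filter_hits(hits, preset)

    tid_to_query = {g.chosen_isoform: g for g in query_genes}
    tid_to_ref = {g.chosen_isoform: g for g in ref_genes}
    ref_rank = {g.gene_id: g.rank for g in ref_genes}

    # candidates per query gene id: list of (bitscore, pident, ref gene id)
    candidates: dict[str, list[tuple[float, float, str]]] = {}
    for h in passing:
        qg = tid_to_query.get(h.qid)
        rg = tid_to_ref.get(h.sid)
        if qg is None or rg is None:
            continue
        candidates.setdefault(qg.gene_id, []).append((h.bitscore, h.pident, rg.gene_id))

    mapping: dict[str, str | None] = {g.gene_id: None for g in query_genes}
    # first pass: unambiguous best-by-(bitscore, pident)
    tied: dict[str, list[str]] = {}
    for gid, cands in candidates.items():
        best_score = max((b, p) for b, p, _ in cands)
        best_refs = sorted({r for b, p, r in cands if (b, p) == best_score})
        if len(best_refs) == 1:
            mapping[gid] = best_refs[0]
        else:
            tied[gid] = best_refs

    # second pass: break score ties by reference-rank proximity to the
    # nearest assigned neighbors along the query order
    ordered = sorted(query_genes, key=lambda g: g.rank)
    pos = {g.gene_id: i for i, g in enumerate(ordered)}
    for gid, refs in sorted(tied.items(), key=lambda kv: pos[kv[0]]):
        i = pos[gid]
        neighbor_ranks = []
        for j in range(i - 1, -1, -1):
            m = mapping[ordered[j].gene_id]
            if m is not None:
                neighbor_ranks.append(ref_rank[m])
                break
        for j in range(i + 1, len(ordered)):
            m = mapping[ordered[j].gene_id]
            if m is not None:
                neighbor_ranks.append(ref_rank[m])
                break
        if neighbor_ranks:
            expected = sum(neighbor_ranks) / len(neighbor_ranks)
            mapping[gid] = min(refs, key=lambda r: (abs(ref_rank[r] - expected), r))
        else:
            mapping[gid] = min(refs)
    return mapping


def build_synteny_map(
    reference_genome: str,
    ref_genes: Sequence[GeneRecord],
    per_genome: dict[str, tuple[Sequence[GeneRecord], dict[str, str | None]]],
    min_run: int = 4,
) -> SyntenyMap:
    """Assemble per-genome ordered assignments and call inversions.

    ``per_genome`` maps genome name -> (its ordered gene records, its
    homolog mapping from :func:`assign_homologs`).  The reference genome
    itself is included with the identity mapping.
    """
    smap = SyntenyMap(reference_genome=reference_genome)
    smap.ref_ranks = {g.gene_id: g.rank for g in ref_genes}
    smap.orders[reference_genome] = [(g.rank, g.gene_id) for g in sorted(ref_genes, key=lambda g: g.rank)]
    for genome, (genes, mapping) in per_genome.items():
        smap.orders[genome] = [
            (g.rank, mapping.get(g.gene_id)) for g in sorted(genes, key=lambda g: g.rank)
        ]
    for genome in smap.orders:
        if genome == reference_genome:
            continue
        smap.inversion_calls.extend(call_inversions(smap, genome, min_run=min_run))
    return smap


def call_inversions(
    smap: SyntenyMap,
    genome: str,
    min_run: int = 4,
) -> list[InversionCall]:
    """Report maximal runs of >= ``min_run`` consecutive mapped genes whose
    reference ranks are strictly decreasing.

    Unmapped genes are skipped over: the run is taken over the subsequence
    of genes with a reference assignment, but the reported rank span covers
    the query ranks from the first to the last gene of the run.
    """
    mapped = [
        (rank, smap.ref_ranks[ref])
        for rank, ref in smap.orders[genome]
        if ref is not None and ref in smap.ref_ranks
    ]
    calls: list[InversionCall] = []
    i = 0
    while i < len(mapped):
        j = i
        while j + 1 < len(mapped) and mapped[j + 1][1] < mapped[j][1]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_run:
            calls.append(InversionCall(genome, mapped[i][0], mapped[j][0]))
        i = j + 1 if j > i else i + 1
    return calls


def export_synteny_plot_data(
    smap: SyntenyMap,
    highlighted: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Flatten a synteny map into a plot table.

    One row per gene per genome: rank, reference homolog (the color key;
    reference rows color by themselves), and a highlight flag for causal or
    candidate genes supplied per genome.  Segment lengths on a rendered
    figure are proportional to gene counts, which this table carries
    implicitly as rows per genome.
    """
    highlighted = highlighted or {}
    rows = []
    for genome, order in smap.orders.items():
        is_ref = genome == smap.reference_genome
        marks = highlighted.get(genome, set())
        for rank, ref in order:
            ref_rank = smap.ref_ranks.get(ref) if ref is not None else None
            rows.append(
                {
                    "genome": genome,
                    "rank": rank,
                    "reference_homolog": ref,
                    "reference_rank": ref_rank,
                    "is_reference": is_ref,
                    "highlighted": (ref in marks) if ref is not None else False,
                }
            )
    return pd.DataFrame(rows)


def render_synteny_figure(table: pd.DataFrame, path: str | Path) -> None:
    """Render the plot table as stacked per-genome gene tracks (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genomes = list(dict.fromkeys(table["genome"]))
    n_ref = table["reference_rank"].max()
    cmap = plt.get_cmap("viridis")
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(genomes) + 1))
    for yi, genome in enumerate(genomes):
        sub = table[table["genome"] == genome]
        n = len(sub)
        for _, row in sub.iterrows():
            x = (row["rank"] - 1) / max(n - 1, 1)
            if pd.notna(row["reference_rank"]) and n_ref:
                color = cmap((row["reference_rank"] - 1) / max(n_ref - 1, 1))
            else:
                color = "0.85"
            marker = "*" if row["highlighted"] else "o"
            ax.plot(x, yi, marker, color=color, markersize=9 if row["highlighted"] else 5)
        ax.text(-0.02, yi, genome, ha="right", va="center", fontsize=8)
    ax.set_ylim(-0.5, len(genomes) - 0.5)
    ax.set_xlim(-0.25, 1.02)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
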