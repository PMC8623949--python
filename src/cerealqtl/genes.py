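"""Gene complement of a locus interval and longest-isoform selection.

Each gene intersecting the interval contributes one representative
transcript: the isoform with the maximal total CDS length (lexicographic
transcript-id tie-break).  Genes with no protein-coding isoform are
excluded from the transcript set but counted in a side report, since
per-locus transcript counts are CDS-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io import GffGene, SequenceRecord, write_fasta
from .regions import LocusInterval


class LocusGenesError(KeyError):
    """A chosen isoform's CDS sequence could not be resolved."""


@dataclass
class GeneRecord:
    """A locus gene with its chosen longest isoform and CDS sequence."""

    gene: GffGene
    chosen_isoform: str
    cds_seq: SequenceRecord
    rank: int  # 1-based position index along the chromosome, by start

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


def extract_locus_genes(
    genes: Sequence[GffGene],
    interval: LocusInterval,
    cds: Sequence[SequenceRecord],
    containment: str = "overlap",
) -> list[GeneRecord]:
    """Extract genes of an interval, ordered by start, with longest isoforms.

    Parameters
    ----------
    genes:
        Annotated genes (any chromosome; filtered to the interval's).
    interval:
        The locus to extract.
    cds:
        CDS sequences; ids must resolve the chosen transcript ids.
    containment:
        ``overlap`` (default) keeps any gene intersecting the interval, so
        border genes supported by markers are not silently dropped;
        ``strict`` requires full containment.

    Raises
    ------
    LocusGenesError
        If a chosen isoform's CDS sequence is absent from ``cds``.
    """
    if containment not in ("overlap", "strict"):
        raise ValueError("containment must be 'overlap' or 'strict'")
    cds_by_id = {r.id: r for r in cds}

    selected: list[GffGene] = []
    for g in genes:
        if g.chrom != interval.chrom or not g.isoforms:
            continue
        if containment == "overlap":
            hit = g.start <= interval.end and g.end >= interval.start
        else:
            hit = g.start >= interval.start and g.end <= interval.end
        if hit:
            selected.append(g)

    selected.sort(key=lambda g: (g.start, g.end, g.gene_id))
    records: list[GeneRecord] = []
    for rank, g in enumerate(selected, start=1):
        tid, _cds_len = g.longest_isoform()
        if tid not in cds_by_id:
            raise LocusGenesError(
                f"CDS sequence for transcript {tid!r} (gene {g.gene_id}) "
                "missing from the CDS FASTA"
            )
        records.append(GeneRecord(gene=g, chosen_isoform=tid, cds_seq=cds_by_id[tid], rank=rank))
    return records


def noncoding_gene_count(genes: Sequence[GffGene], interval: LocusInterval) -> int:
    """Genes intersecting the interval that lack any protein-coding isoform."""
    return sum(
        1
        for g in genes
        if g.chrom == interval.chrom
        and not g.isoforms
        and g.start <= interval.end
        and g.end >= interval.start
    )


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    """TSV gene table: id, coordinates, chosen isoform, CDS length, rank."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tchosen_isoform\tcds_length\trank\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.gene.chrom}\t{r.gene.start}\t{r.gene.end}\t"
                f"{r.gene.strand}\t{r.chosen_isoform}\t{len(r.cds_seq.seq)}\t{r.rank}\n"
            )


def write_locus_cds(records: Sequence[GeneRecord], path: str | Path) -> None:
    write_fasta([r.cds_seq for r in records], path)
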