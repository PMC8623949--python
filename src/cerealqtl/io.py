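"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates in this package are 1-based inclusive (the GFF and
BLAST tabular convention).  The single place where 0-based half-open BED
coordinates are produced is :func:`to_bed_interval`.  Minus-strand alignment
hits keep the raw tabular convention ``sstart > send`` and are normalized
only when intervals are built (see :mod:`cerealqtl.regions`).

Sequences are uppercased on read and, for DNA alphabets, U is normalized to
T; the miRNA stage re-maps T back to U internally.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = set("ACGTNRYSWKMBDHV")
RNA_ALPHABET = set("ACGUNRYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_ALPHABETS = {
    "dna": DNA_ALPHABET,
    "rna": RNA_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}

#: Column names of the 14-column tabular hit format: the 12 standard columns
#: of ``blastn -outfmt 6`` plus query length and subject length.
HIT_TABLE_COLUMNS = [
    "qid", "sid", "pident", "aln_len", "mismatches", "gap_opens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


class FormatError(ValueError):
    """A file violated its declared format."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        rc = str(Seq(self.seq).reverse_complement())
        return SequenceRecord(self.id, rc, self.description)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 14-column tabular homology hit.

    ``sstart > send`` encodes a minus-strand hit and is preserved as parsed.
    """

    qid: str
    sid: str
    pident: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int

    @property
    def qcov(self) -> float:
        """Query coverage from aligned query span (gaps inflate aln_len)."""
        return (self.qend - self.qstart + 1) / self.qlen

    @property
    def strand(self) -> str:
        return "+" if self.sstart <= self.send else "-"

    @property
    def subject_span(self) -> tuple[int, int]:
        """Strand-normalized (low, high) subject coordinates, 1-based."""
        return (min(self.sstart, self.send), max(self.sstart, self.send))

    def validate(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise FormatError(
                f"hit {self.qid}->{self.sid}: query coords "
                f"{self.qstart}..{self.qend} violate 1 <= qstart <= qend <= qlen={self.qlen}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise FormatError(f"hit {self.qid}->{self.sid}: pident {self.pident} outside [0,100]")
        if self.aln_len < 1:
            raise FormatError(f"hit {self.qid}->{self.sid}: aln_len {self.aln_len} < 1")


@dataclass
class GffGene:
    """A gene feature with its mRNA isoforms and their total CDS lengths."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    #: (transcript_id, total CDS length in nt) per isoform
    isoforms: list[tuple[str, int]] = field(default_factory=list)

    def longest_isoform(self) -> tuple[str, int]:
        """Maximal-CDS isoform; ties broken by lexicographically smaller id."""
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id} has no isoforms")
        return max(self.isoforms, key=lambda it: (it[1], _NegStr(it[0])))


class _NegStr(str):
    """Inverts string comparison so max() picks the lexicographic minimum."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _validate_seq(rec_id: str, seq: str, alphabet: str) -> None:
    allowed = _ALPHABETS[alphabet]
    bad = set(seq) - allowed
    if bad:
        raise FormatError(
            f"record {rec_id!r}: characters {sorted(bad)} not in {alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        ``dna``, ``rna`` or ``protein``.  DNA reads normalize U->T so RNA
        and DNA sources interoperate; RNA reads normalize T->U.

    Raises
    ------
    FormatError
        On duplicate ids or characters outside the declared alphabet.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}; choose from {sorted(_ALPHABETS)}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
        elif alphabet == "rna":
            seq = seq.replace("T", "U")
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        _validate_seq(rec.id, seq, alphabet)
        records.append(SequenceRecord(rec.id, seq, rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 14-column tab-separated hit table (``-outfmt "6 std qlen slen"``).

    Minus-strand hits (``sstart > send``) are preserved unmodified.  Rows
    with the wrong column count raise :class:`FormatError` naming the row.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 14:
                raise FormatError(
                    f"{path}: row {i + 1} has {len(parts)} columns, expected 14"
                )
            try:
                hit = AlignmentHit(
                    qid=parts[0], sid=parts[1],
                    pident=float(parts[2]), aln_len=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    qstart=int(parts[6]), qend=int(parts[7]),
                    sstart=int(parts[8]), send=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                    qlen=int(parts[12]), slen=int(parts[13]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {i + 1}: {exc}") from exc
            hit.validate()
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.qid, h.sid, h.pident, h.aln_len, h.mismatches,
                        h.gap_opens, h.qstart, h.qend, h.sstart, h.send,
                        h.evalue, h.bitscore, h.qlen, h.slen,
                    )
                )
                + "\n"
            )


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits], columns=HIT_TABLE_COLUMNS)


def read_gff_genes(
    path: str | Path,
    chrom_filter: set[str] | None = None,
) -> list[GffGene]:
    """Read gene models from a GFF3 file.

    Per gene, each mRNA isoform is recorded with its total CDS length (sum
    of CDS segment lengths, ``end - start + 1`` per segment).  Genes without
    mRNA/CDS children (e.g. ncRNA genes) are kept with zero isoforms; the
    transcript-extraction stage excludes them.  CDS features whose parent
    cannot be resolved to a gene are skipped.

    Parameters
    ----------
    chrom_filter:
        If given, only genes on these chromosomes are returned.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GffGene] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        if chrom_filter is not None and gf.seqid not in chrom_filter:
            continue
        isoforms: list[tuple[str, int]] = []
        for mrna in db.children(gf, featuretype="mRNA", order_by="start"):
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
            )
            if cds_len > 0:
                isoforms.append((mrna.id, cds_len))
        isoforms.sort()
        genes.append(
            GffGene(
                gene_id=gf.id,
                chrom=gf.seqid,
                start=gf.start,
                end=gf.end,
                strand=gf.strand if gf.strand in "+-" else "+",
                isoforms=isoforms,
            )
        )
    return genes


def to_bed_interval(chrom: str, start_1based: int, end_1based: int) -> tuple[str, int, int]:
    """Convert a 1-based inclusive interval to BED's 0-based half-open.

    This is the only coordinate-convention conversion in the package.
    """
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError(f"bad interval {chrom}:{start_1based}-{end_1based}")
    return (chrom, start_1based - 1, end_1based)


def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, float | int, str]],
    path: str | Path,
) -> None:
    """Write BED6 rows given 1-based inclusive inputs.

    Each input tuple is (chrom, start_1based, end_1based, name, score, strand).
    """
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in intervals:
            c, bs, be = to_bed_interval(chrom, s, e)
            fh.write(f"{c}\t{bs}\t{be}\t{name}\t{score}\t{strand}\n")
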