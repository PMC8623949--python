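"""Sequence-homology hit generation and filtering.

Hits come from two sources: externally produced 14-column tabular files
(any BLAST-like aligner) read through :mod:`cerealqtl.io`, or the built-in
ungapped <=k-mismatch scanner :func:`internal_scan`, which is exact and
sufficient for desk-scale inputs and for the miRNA mature-sequence stage.
Gapped transcript-level homology on full genomes remains the job of an
external aligner consumed through the hit-table interface.

The filter presets encode the species-scaled retention thresholds used to
project wheat QTL markers and transcripts onto related cereal genomes:
divergence from wheat increases from the wheat genotypes themselves through
barley/rye and oat to rice, so the identity threshold is relaxed along that
series while coverage stays high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .io import AlignmentHit, SequenceRecord


@dataclass(frozen=True)
class FilterPreset:
    """Coverage/identity retention thresholds for one species class.

    ``min_qcov`` is a fraction of the query length covered by the aligned
    query span; ``min_pident`` a percent identity.  ``context`` records
    which pipeline stage the preset belongs to.
    """

    name: str
    min_qcov: float
    min_pident: float
    context: str  # marker | transcript | oat_contig | protein

    def __post_init__(self):
        if not (0 < self.min_qcov <= 1):
            raise ValueError(f"min_qcov {self.min_qcov} outside (0,1]")
        if not (0 < self.min_pident <= 100):
            raise ValueError(f"min_pident {self.min_pident} outside (0,100]")


#: Marker-projection presets: 90% marker coverage, identity scaled by
#: evolutionary distance from wheat.
#: Transcript-projection presets: used when markers are too sparse and
#: transcripts anchor the homologous region instead.
PRESETS: dict[str, FilterPreset] = {
    "wheat-marker": FilterPreset("wheat-marker", 0.90, 95.0, "marker"),
    "barley_rye-marker": FilterPreset("barley_rye-marker", 0.90, 90.0, "marker"),
    "oat-marker": FilterPreset("oat-marker", 0.90, 85.0, "marker"),
    "rice-marker": FilterPreset("rice-marker", 0.90, 80.0, "marker"),
    "wheat-transcript": FilterPreset("wheat-transcript", 0.80, 95.0, "transcript"),
    "barley_rye-transcript": FilterPreset("barley_rye-transcript", 0.80, 90.0, "transcript"),
    "rice-transcript": FilterPreset("rice-transcript", 0.50, 80.0, "transcript"),
    # rice CDS vs combined locus transcripts (region identification)
    "rice-cds": FilterPreset("rice-cds", 0.50, 80.0, "transcript"),
    # barley CDS vs combined locus transcripts
    "barley-cds": FilterPreset("barley-cds", 0.80, 90.0, "transcript"),
    # cross-genome transcript ordering against the reference genotype
    "wheat-synteny": FilterPreset("wheat-synteny", 0.80, 95.0, "transcript"),
    "barley_rye-synteny": FilterPreset("barley_rye-synteny", 0.80, 90.0, "transcript"),
    "rice-synteny": FilterPreset("rice-synteny", 0.80, 80.0, "transcript"),
}


def get_preset(name: str) -> FilterPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def internal_scan(
    query: SequenceRecord,
    subject: SequenceRecord,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """Report every ungapped full-length placement of ``query`` on ``subject``
    with at most ``max_mismatch`` substitutions.

    Both orientations are scanned when ``both_strands``; minus-strand hits
    use the ``sstart > send`` tabular convention.  ``pident`` is
    ``100 * (1 - mismatches / qlen)`` and query coverage is always 1.
    Positions containing ``N`` never count as matches.
    """
    if not query.seq:
        raise ValueError("empty query sequence")
    q = query.seq.upper()
    s = subject.seq.upper()
    qlen, slen = len(q), len(s)
    if qlen > slen:
        return []

    s_arr = _encode(s)
    # windows[i, j] = subject base at position i+j (0-based)
    windows = np.lib.stride_tricks.sliding_window_view(s_arr, qlen)
    n_mask = windows == ord("N")

    hits: list[AlignmentHit] = []

    def scan_one(q_str: str, minus: bool) -> None:
        q_arr = _encode(q_str)
        mm = ((windows != q_arr) | n_mask | (q_arr == ord("N"))).sum(axis=1)
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            n_mm = int(mm[pos])
            lo = int(pos) + 1  # 1-based subject start of the window
            hi = lo + qlen - 1
            sstart, send = (hi, lo) if minus else (lo, hi)
            hits.append(
                AlignmentHit(
                    qid=query.id, sid=subject.id,
                    pident=round(100.0 * (1 - n_mm / qlen), 3),
                    aln_len=qlen, mismatches=n_mm, gap_opens=0,
                    qstart=1, qend=qlen,
                    sstart=sstart, send=send,
                    evalue=0.0, bitscore=float(2 * (qlen - n_mm)),
                    qlen=qlen, slen=slen,
                )
            )

    scan_one(q, minus=False)
    if both_strands:
        rc = str(Seq(q).reverse_complement())
        scan_one(rc, minus=True)
    hits.sort(key=lambda h: (min(h.sstart, h.send), h.strand))
    return hits


def filter_hits(hits: Iterable[AlignmentHit], preset: FilterPreset | str) -> list[AlignmentHit]:
    """Retain hits meeting the preset's coverage and identity thresholds.

    Coverage is the aligned query span ``(qend - qstart + 1) / qlen``; both
    thresholds are inclusive ("at least").
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    return [
        h for h in hits
        if h.qcov >= preset.min_qcov and h.pident >= preset.min_pident
    ]


def _distinct_locations(a: AlignmentHit, b: AlignmentHit, min_separation: int = 10_000) -> bool:
    """Two hits count as distinct locations if on different chromosomes or
    on the same chromosome with non-overlapping spans >= ``min_separation``
    bp apart.  Tandem split hits therefore do not discard a marker."""
    if a.sid != b.sid:
        return True
    a_lo, a_hi = a.subject_span
    b_lo, b_hi = b.subject_span
    if a_lo > b_hi:
        return a_lo - b_hi >= min_separation
    if b_lo > a_hi:
        return b_lo - a_hi >= min_separation
    return False  # overlapping spans: same location


def drop_ambiguous_markers(
    hits: Sequence[AlignmentHit],
    min_separation: int = 10_000,
) -> list[AlignmentHit]:
    """Resolve each marker to a single placement or drop it as ambiguous.

    A marker whose two or more best hits (maximal coverage and identity)
    fall at distinct subject locations with identical (qcov, pident) is
    discarded entirely — it cannot be placed.  Otherwise only the single
    best hit (max qcov, then pident, then bitscore) is kept.  Idempotent.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    order: list[str] = []
    for h in hits:
        if h.qid not in by_query:
            order.append(h.qid)
        by_query.setdefault(h.qid, []).append(h)

    kept: list[AlignmentHit] = []
    for qid in order:
        group = by_query[qid]
        best_key = max((round(h.qcov, 9), h.pident) for h in group)
        best = [h for h in group if (round(h.qcov, 9), h.pident) == best_key]
        ambiguous = any(
            _distinct_locations(a, b, min_separation)
            for i, a in enumerate(best)
            for b in best[i + 1:]
        )
        if ambiguous:
            continue
        winner = max(group, key=lambda h: (round(h.qcov, 9), h.pident, h.bitscore))
        kept.append(winner)
    return kept


def match_oat_contigs(hits: Iterable[AlignmentHit]) -> set[str]:
    """Contig ids with at least one hit above 85% identity (strict) over at
    least 300 aligned nucleotides.  Intron-containing genomic contigs make
    query-coverage thresholds inappropriate, hence the aligned-length rule.
    """
    return {h.sid for h in hits if h.pident > 85.0 and h.aln_len >= 300}


@dataclass(frozen=True)
class ProteinMatch:
    """A protein-to-database match used for functional annotation filtering."""

    qid: str
    sid: str
    similarity: float  # percent
    qcov: float        # fraction of the query protein covered
    db: str            # uniprot_viridiplantae | brachypodium

    def __post_init__(self):
        if not (0 <= self.similarity <= 100):
            raise ValueError(f"similarity {self.similarity} outside [0,100]")
        if not (0 <= self.qcov <= 1):
            raise ValueError(f"qcov {self.qcov} outside [0,1]")


_PROTEIN_THRESHOLDS = {
    # db -> (min similarity %, min query coverage fraction)
    "uniprot_viridiplantae": (50.0, 0.5),
    "brachypodium": (75.0, 0.5),
}


def filter_protein_matches(matches: Iterable[ProteinMatch]) -> list[ProteinMatch]:
    """Annotation filter: 50% similarity + 50% coverage against Uniprot
    Viridiplantae, 75% + 50% against the Brachypodium proteome (the closer
    relative warrants the stricter similarity floor)."""
    out = []
    for m in matches:
        try:
            min_sim, min_cov = _PROTEIN_THRESHOLDS[m.db]
        except KeyError:
            raise KeyError(
                f"unknown protein db {m.db!r}; valid: {sorted(_PROTEIN_THRESHOLDS)}"
            ) from None
        if m.similarity >= min_sim and m.qcov >= min_cov:
            out.append(m)
    return out
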