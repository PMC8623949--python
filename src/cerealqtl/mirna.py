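"""Homology-based miRNA discovery inside locus intervals.

The stages follow the classic homology-first plant miRNA workflow:

1. scan the locus (both strands) for windows within Hamming distance 1 of
   any mature miRNA in the reference set;
2. extract candidate precursor windows around each hit, with the mature
   anchored to either hairpin arm, over several window lengths;
3. fold each window (thermodynamic MFE folding via ViennaRNA) and test the
   hairpin against four structural criteria:

   1. *Dicer cut sites*: the terminal 2 bases at each end of the mature
      must be paired in the miR/miR* duplex;
   2. *no multibranch*: the hairpin carrying the mature contains no
      multi-branched loop;
   3. *not in head*: the mature must not overlap the terminal loop;
   4. *duplex mismatches*: at most 4 unpaired bases within the mature and
      at most 6 within the star (inferred from structure with the
      canonical 2-nt 3' overhang);

4. collapse overlapping same-family survivors, summarize families per
   genome and their sharing partition, and score mature-vs-CDS target
   sites with a seed-weighted penalty ("expectation"), retaining sites
   with expectation <= 3.

Target-site accessibility (UPE) is not computed; the configuration records
the filter as disabled.  Expectation is the operative cutoff.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import RNA

from .homology import internal_scan
from .io import SequenceRecord

DEFAULT_WINDOW_LENGTHS = (100, 150, 200, 250)
DEFAULT_MAX_MISMATCH = 1
DEFAULT_DICER_SITE_BP = 2
MAX_MATURE_UNPAIRED = 4
MAX_STAR_UNPAIRED = 6
DEFAULT_MAX_EXPECTATION = 3.0
SEED_RANGE = (2, 13)  # 1-based mature positions with doubled penalty

_FAMILY_RE = re.compile(r"(miR|MIR|mir|let|lin)-?(\d+)")


def family_name(mature_id: str) -> str:
    """Normalize a miRBase-style id to its family (``tae-miR1122b-3p`` ->
    ``miR1122``); ids without a recognizable family keep their own name."""
    m = _FAMILY_RE.search(mature_id)
    if not m:
        return mature_id
    stem = m.group(1)
    prefix = "let" if stem.lower() == "let" else ("lin" if stem.lower() == "lin" else "miR")
    return f"{prefix}{m.group(2)}"


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MatureHit:
    """A <=1-mismatch placement of a mature miRNA on the locus."""

    mature_id: str
    family: str
    chrom: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str
    mismatches: int


def scan_matures(
    locus_seq: SequenceRecord,
    matures: Sequence[SequenceRecord],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[MatureHit]:
    """All windows on both strands of the locus within Hamming distance
    ``max_mismatch`` of any mature sequence.

    Matures are RNA; the locus is DNA and the comparison runs in DNA
    space.  Matures shorter than 18 nt are unusual and scanned anyway.
    """
    hits: list[MatureHit] = []
    for mat in matures:
        query = SequenceRecord(mat.id, rna_to_dna(mat.seq))
        fam = family_name(mat.id)
        for h in internal_scan(query, locus_seq, max_mismatch=max_mismatch, both_strands=True):
            lo, hi = h.subject_span
            hits.append(
                MatureHit(
                    mature_id=mat.id, family=fam, chrom=locus_seq.id,
                    start=lo, end=hi, strand=h.strand, mismatches=h.mismatches,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand, h.mature_id))
    return hits


@dataclass
class PrecursorCandidate:
    """A putative pre-miRNA window with structure and per-criterion verdicts."""

    chrom: str
    start: int   # 1-based inclusive window on the forward strand
    end: int
    strand: str
    seq: str     # RNA, 5'->3' in the strand carrying the mature
    mature_id: str
    family: str
    mature_span: tuple[int, int]  # 0-based inclusive offsets within seq
    clipped: bool = False
    structure: str | None = None
    mfe: float | None = None
    star_span: tuple[int, int] | None = None
    criteria: dict[str, bool] = field(default_factory=dict)
    accepted: bool = False

    @property
    def window_span(self) -> tuple[int, int]:
        return (self.start, self.end)


def extract_candidates(
    hit: MatureHit,
    locus_seq: SequenceRecord,
    window_lens: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
) -> list[PrecursorCandidate]:
    """Candidate precursor windows for one mature hit.

    For each window length L two geometries are produced: the mature on
    the 5' arm (window extends downstream of the mature's 5' end, in the
    hit's orientation) and on the 3' arm (window extends upstream of the
    mature's 3' end).  Windows clipped at the locus edges are flagged.
    """
    n = len(locus_seq.seq)
    out: list[PrecursorCandidate] = []
    for L in window_lens:
        if hit.strand == "+":
            spans = [
                (hit.start, hit.start + L - 1),  # mature at 5' arm
                (hit.end - L + 1, hit.end),      # mature at 3' arm
            ]
        else:
            # downstream in the minus orientation = decreasing forward coords
            spans = [
                (hit.end - L + 1, hit.end),
                (hit.start, hit.start + L - 1),
            ]
        for w_start, w_end in spans:
            clipped = w_start < 1 or w_end > n
            w_start_c = max(1, w_start)
            w_end_c = min(n, w_end)
            if w_end_c - w_start_c + 1 < hit.end - hit.start + 1:
                continue
            window_dna = locus_seq.seq[w_start_c - 1 : w_end_c]
            if hit.strand == "+":
                oriented = window_dna
                m_lo = hit.start - w_start_c
            else:
                from Bio.Seq import Seq

                oriented = str(Seq(window_dna).reverse_complement())
                m_lo = w_end_c - hit.end
            m_hi = m_lo + (hit.end - hit.start)
            out.append(
                PrecursorCandidate(
                    chrom=hit.chrom, start=w_start_c, end=w_end_c,
                    strand=hit.strand, seq=dna_to_rna(oriented),
                    mature_id=hit.mature_id, family=hit.family,
                    mature_span=(m_lo, m_hi), clipped=clipped,
                )
            )
    return out


def fold(seq: str) -> tuple[str, float]:
    """MFE secondary structure (dot-bracket, nested) and free energy in
    kcal/mol, via the ViennaRNA fold engine.  Deterministic for a fixed
    input and engine version."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq.upper()) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    structure, mfe = RNA.fold(seq.upper())
    return structure, float(mfe)


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 for unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def hairpin_loops(pt: Sequence[int]) -> list[tuple[int, int]]:
    """Terminal (hairpin) loops as 0-based inclusive (start, end) regions:
    unpaired stretches directly enclosed by a base pair with nothing
    paired in between."""
    loops = []
    for i, j in ((i, pt[i]) for i in range(len(pt)) if pt[i] > i):
        if j - i >= 2 and all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


def evaluate_criteria(
    cand: PrecursorCandidate,
    dicer_site_bp: int = DEFAULT_DICER_SITE_BP,
    max_mature_unpaired: int = MAX_MATURE_UNPAIRED,
    max_star_unpaired: int = MAX_STAR_UNPAIRED,
) -> PrecursorCandidate:
    """Fill the four criterion verdicts and the acceptance flag.

    The candidate must be folded (or is folded here).  The star span is
    derived from structure as the positions pairing with the mature plus a
    2-nt 3' overhang.  ``accepted`` is the conjunction of all four flags.
    """
    if cand.structure is None:
        cand.structure, cand.mfe = fold(cand.seq)
    n = len(cand.seq)
    m_lo, m_hi = cand.mature_span
    if not (0 <= m_lo <= m_hi < n):
        raise ValueError(f"mature span {cand.mature_span} outside sequence of length {n}")
    pt = pair_table(cand.structure)

    mature_idx = range(m_lo, m_hi + 1)
    partners = [pt[i] for i in mature_idx if pt[i] >= 0]

    # criterion 1: no mismatches at the Dicer cut sites — the terminal
    # dicer_site_bp bases at each mature end must be paired
    k = dicer_site_bp
    dicer_ok = bool(partners) and all(
        pt[i] >= 0 for i in list(range(m_lo, min(m_lo + k, m_hi + 1)))
        + list(range(max(m_hi - k + 1, m_lo), m_hi + 1))
    )

    if partners:
        s_lo_raw, s_hi_raw = min(partners), max(partners)
        star_span = (s_lo_raw, min(s_hi_raw + 2, n - 1))  # 2-nt 3' overhang
    else:
        star_span = None
    cand.star_span = star_span

    # criterion 4: unpaired bases within mature <= 4, within star <= 6
    mature_unpaired = sum(1 for i in mature_idx if pt[i] == -1)
    if star_span is not None:
        star_unpaired = sum(1 for i in range(star_span[0], star_span[1] + 1) if pt[i] == -1)
    else:
        star_unpaired = max_star_unpaired + 1
    duplex_mismatch_ok = (
        mature_unpaired <= max_mature_unpaired and star_unpaired <= max_star_unpaired
    )

    loops = hairpin_loops(pt)

    # criterion 3: mature must not sit on the head (terminal loop)
    not_in_head = not any(l_lo <= m_hi and l_hi >= m_lo for l_lo, l_hi in loops)

    # criterion 2: no multibranched loop within the hairpin carrying the
    # mature — the duplex region must enclose exactly one terminal loop
    if partners:
        r_lo = min(m_lo, s_lo_raw)
        r_hi = max(m_hi, s_hi_raw)
        n_loops = sum(1 for l_lo, l_hi in loops if l_lo >= r_lo and l_hi <= r_hi)
        no_multibranch = n_loops <= 1
    else:
        no_multibranch = True

    cand.criteria = {
        "dicer_ok": dicer_ok,
        "no_multibranch": no_multibranch,
        "not_in_head": not_in_head,
        "duplex_mismatch_ok": duplex_mismatch_ok,
    }
    cand.accepted = all(cand.criteria.values())
    return cand


def dedupe_precursors(cands: Sequence[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Collapse accepted candidates whose genomic windows overlap by at
    least 50% (of the shorter window) and share a family, keeping the one
    with the lowest folding free energy."""
    groups: list[list[PrecursorCandidate]] = []
    for cand in sorted(cands, key=lambda c: (c.chrom, c.start, c.end, c.mature_id)):
        placed = False
        for grp in groups:
            rep = grp[0]
            if rep.family != cand.family or rep.chrom != cand.chrom:
                continue
            if any(_window_overlap_frac(g, cand) >= 0.5 for g in grp):
                grp.append(cand)
                placed = True
                break
        if not placed:
            groups.append([cand])
    survivors = [
        min(grp, key=lambda c: (c.mfe if c.mfe is not None else 0.0, c.start, c.end))
        for grp in groups
    ]
    survivors.sort(key=lambda c: (c.chrom, c.start, c.end))
    return survivors


def _window_overlap_frac(a: PrecursorCandidate, b: PrecursorCandidate) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start + 1, b.end - b.start + 1)


@dataclass
class FamilySummary:
    """Per-genome miRNA family sets and per-family precursor counts."""

    families_by_genome: dict[str, set[str]]
    precursor_counts: dict[str, int]  # family -> total precursor count
    #: exclusive Venn region -> family count, keyed by the frozenset of
    #: genomes whose sets contain exactly those families
    partition: dict[frozenset, int]

    @property
    def total_precursors(self) -> int:
        return sum(self.precursor_counts.values())

    @property
    def all_families(self) -> set[str]:
        out: set[str] = set()
        for s in self.families_by_genome.values():
            out |= s
        return out


def summarize_families(
    per_genome: dict[str, Sequence[PrecursorCandidate]],
    merge_wheat: Sequence[str] | None = None,
) -> FamilySummary:
    """Family sets per genome plus the exclusive sharing partition.

    ``merge_wheat`` optionally lists genome names to pool into a single
    ``wheat`` set before partitioning, as in figures that group the wheat
    genotypes together.
    """
    sets: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for genome, cands in per_genome.items():
        sets[genome] = {c.family for c in cands}
        for c in cands:
            counts[c.family] = counts.get(c.family, 0) + 1
    if merge_wheat:
        merged: set[str] = set()
        for g in merge_wheat:
            merged |= sets.pop(g, set())
        sets["wheat"] = merged
    partition = family_partition(sets)
    return FamilySummary(families_by_genome=sets, precursor_counts=counts, partition=partition)


def family_partition(sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Exclusive Venn-region counts over the genome family sets: for each
    family, the exact set of genomes containing it defines its region."""
    partition: dict[frozenset, int] = {}
    union: set[str] = set()
    for s in sets.values():
        union |= s
    for fam in union:
        region = frozenset(g for g, s in sets.items() if fam in s)
        partition[region] = partition.get(region, 0) + 1
    return partition


@dataclass(frozen=True)
class TargetPrediction:
    """A scored mature-vs-transcript complementarity site."""

    mature_id: str
    transcript_id: str
    site_start: int  # 1-based on the transcript, 5'->3'
    site_end: int
    alignment: str   # per mature position: '|' pair, 'o' G:U wobble, 'x' mismatch
    expectation: float
    retained: bool


_WOBBLE = {("G", "U"), ("U", "G")}
_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def score_target(
    mature: SequenceRecord,
    transcript: SequenceRecord,
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    report_all: bool = False,
) -> list[TargetPrediction]:
    """Score every ungapped complementarity site of a mature on a CDS.

    The mature binds the transcript antiparallel; per mature position the
    penalty is 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a
    mismatch (a gap would cost 2; ungapped enumeration produces none), and
    penalties are doubled within the seed (mature positions 2-13).  The
    site's expectation is the summed penalty; sites with expectation <=
    ``max_expectation`` are retained.  Sites are reported 5'->3' along the
    transcript.
    """
    m = dna_to_rna(mature.seq)
    t = dna_to_rna(transcript.seq)
    L, n = len(m), len(t)
    out: list[TargetPrediction] = []
    if L == 0 or L > n:
        return out
    seed_lo, seed_hi = SEED_RANGE
    for w in range(n - L + 1):
        expectation = 0.0
        symbols = []
        for i in range(L):  # i: 0-based mature position from its 5' end
            mb = m[i]
            tb = t[w + L - 1 - i]  # antiparallel partner
            if (mb, tb) in _PAIR:
                pen, sym = 0.0, "|"
            elif (mb, tb) in _WOBBLE:
                pen, sym = 0.5, "o"
            else:
                pen, sym = 1.0, "x"
            if seed_lo <= i + 1 <= seed_hi:
                pen *= 2
            expectation += pen
            symbols.append(sym)
        retained = expectation <= max_expectation
        if retained or report_all:
            out.append(
                TargetPrediction(
                    mature_id=mature.id, transcript_id=transcript.id,
                    site_start=w + 1, site_end=w + L,
                    alignment="".join(symbols),
                    expectation=expectation, retained=retained,
                )
            )
    out.sort(key=lambda p: p.site_start)
    return out


def predict_targets(
    matures: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
) -> list[TargetPrediction]:
    """Retained target sites for every mature against every transcript."""
    preds: list[TargetPrediction] = []
    for mat in matures:
        for tr in transcripts:
            preds.extend(score_target(mat, tr, max_expectation=max_expectation))
    return preds


def discover_mirnas(
    locus_seq: SequenceRecord,
    matures: Sequence[SequenceRecord],
    window_lens: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[PrecursorCandidate], list[PrecursorCandidate]]:
    """Run scan -> extract -> fold -> criteria -> dedupe on one locus.

    Returns (deduped accepted precursors, all evaluated candidates).
    """
    evaluated: list[PrecursorCandidate] = []
    for hit in scan_matures(locus_seq, matures, max_mismatch=max_mismatch):
        for cand in extract_candidates(hit, locus_seq, window_lens):
            evaluated.append(evaluate_criteria(cand))
    accepted = dedupe_precursors([c for c in evaluated if c.accepted])
    return accepted, evaluated
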