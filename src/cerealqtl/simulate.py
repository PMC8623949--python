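"""Synthetic multi-genome locus sets with full ground truth.

The generator emulates the input structure of a multi-genome QTL
comparison: an ancestral locus of protein-coding genes (with isoforms and
introns) separated by intergenic spacers is copied into each genome with
i.i.d. substitutions (transition bias 2:1), configurable structural events
(inversions, translocations, gene losses), molecular markers embedded at
known positions, and pre-miRNA hairpins engineered to pass all four
structural acceptance criteria or to violate exactly one.  Hairpin parts
are exempt from substitution so the intended verdict of each planting is
exact.  All randomness flows from one seeded generator; the same seed
yields byte-identical fixtures.

Divergence defaults mirror the evolutionary series of the real analysis:
wheat genotypes are nearly identical to each other, barley and rye are
moderately diverged, and rice is distant enough that only relaxed identity
thresholds recover its homologs.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .io import GffGene, SequenceRecord, write_fasta

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"
#: transitions under a 2:1 transition:transversion bias
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

CRITERIA = ("dicer", "multibranch", "head", "duplex")
_CRITERION_FLAG = {
    "dicer": "dicer_ok",
    "multibranch": "no_multibranch",
    "head": "not_in_head",
    "duplex": "duplex_mismatch_ok",
}


def rc_rna(seq: str) -> str:
    return str(Seq(seq.replace("U", "T")).reverse_complement()).replace("T", "U")


def rc_dna(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# hairpin construction


def make_head_mature(rng: np.random.Generator) -> str:
    """A 21-nt mature of the form x + loop + revcomp(x): the only mature
    geometry that can overlap a terminal loop while keeping the other
    three criteria intact (its own ends pair with each other)."""
    x = "".join(rng.choice(list("GC"), size=9))
    loop = "".join(rng.choice(list("AC"), size=3))
    return x + loop + rc_rna(x)


def _head_compatible(mature: str) -> bool:
    return len(mature) == 21 and mature[:9] == rc_rna(mature[12:])


def make_hairpin(
    mature: str,
    violate: str | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Construct an RNA precursor containing ``mature`` on one arm.

    With ``violate=None`` the hairpin is a perfect inverted repeat that
    satisfies all four structural criteria; otherwise the construction
    breaks exactly the named criterion (``dicer``, ``multibranch``,
    ``head`` or ``duplex``):

    - ``dicer``: the star bases opposite the mature's last two nt are
      mismatched, unpairing the Dicer cut site at one end only (2 unpaired
      mature positions, so the duplex-mismatch criterion still holds); the
      broken pair sits between two intact helices, locking the register;
    - ``multibranch``: two GC-stem subhairpins replace the terminal loop,
      putting a multiloop inside the mature's hairpin;
    - ``head``: the mature straddles the terminal loop (requires the
      self-complementary mature from :func:`make_head_mature`, which is
      its own minimal hairpin);
    - ``duplex``: five spaced star positions opposite the mature interior
      are mismatched (5 > 4 unpaired mature bases), leaving the cut-site
      pairs intact.

    The mature always sits at the precursor's 5' end (offset 0).

    Folding is thermodynamic, so a pathological mature sequence (e.g. one
    that is strongly self-complementary) can fold away from the intended
    verdict; :func:`design_hairpin` resamples matures until the construct
    verifies under folding.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mature = mature.upper().replace("T", "U")
    if not (20 <= len(mature) <= 22):
        raise ValueError(f"mature length {len(mature)} outside 20-22 nt")
    if set(mature) - set(RNA_BASES):
        raise ValueError("mature must be ACGU only")
    if violate is not None and violate not in CRITERIA:
        raise ValueError(f"unknown criterion {violate!r}; choose from {CRITERIA}")

    if violate == "head":
        if not _head_compatible(mature):
            raise ValueError(
                "impossible construction: a head-violating hairpin needs a "
                "self-complementary mature from make_head_mature()"
            )
        # the mature is its own hairpin with the terminal loop inside it
        return mature

    if violate == "multibranch":
        s1 = "".join(rng.choice(list("GC"), size=8))
        s2 = "".join(rng.choice(list("GC"), size=8))
        sub1 = s1 + "GAAA" + rc_rna(s1)
        sub2 = s2 + "GAAA" + rc_rna(s2)
        return mature + "A" + sub1 + "AA" + sub2 + "A" + rc_rna(mature)

    ext = "".join(rng.choice(list(RNA_BASES), size=12, p=[0.2, 0.3, 0.3, 0.2]))
    loop = "".join(rng.choice(list("AC"), size=7))
    pre = list(mature + ext + loop + rc_rna(ext) + rc_rna(mature))
    n = len(pre)
    if violate == "dicer":
        # partner of mature position i is n-1-i in the perfect repeat;
        # break the mature's 3'-terminal 2 bp (interior of the arm)
        for i in (len(mature) - 1, len(mature) - 2):
            pre[n - 1 - i] = mature[i]
    elif violate == "duplex":
        for i in (4, 7, 10, 13, 16):
            pre[n - 1 - i] = mature[i]
    return "".join(pre)


def hairpin_mature_offset(violate: str | None) -> int:
    """Offset of the mature within the constructed precursor (always 0)."""
    return 0


@dataclass(frozen=True)
class HairpinDesign:
    """A verified hairpin construct with its intended criterion verdicts."""

    family: str
    mature: str      # RNA
    precursor: str   # RNA, mature at offset 0
    violate: str | None

    @property
    def intended_flag(self) -> str | None:
        return _CRITERION_FLAG[self.violate] if self.violate else None


def _evaluate_construct(mature: str, seq: str):
    from .mirna import PrecursorCandidate, evaluate_criteria

    cand = PrecursorCandidate(
        chrom="check", start=1, end=len(seq), strand="+", seq=seq,
        mature_id="check", family="check",
        mature_span=(0, len(mature) - 1),
    )
    return evaluate_criteria(cand)


def _verify_construct(mature: str, precursor: str, violate: str | None,
                      rng: np.random.Generator) -> bool:
    """Two-tier verification under folding: the bare construct must show
    exactly the intended verdict pattern (all criteria true, or only the
    targeted flag false), and the construct must keep its accept/reject
    outcome in random downstream sequence contexts (flag attribution in an
    arbitrary context is not required: distant sequence can always fold
    into the hairpin's neighborhood)."""
    flag = _CRITERION_FLAG[violate] if violate else None
    bare = _evaluate_construct(mature, precursor)
    if violate is None:
        if not bare.accepted:
            return False
    elif bare.criteria[flag] or not all(
        v for k, v in bare.criteria.items() if k != flag
    ):
        return False
    for _ in range(3):
        junk = "".join(rng.choice(list(RNA_BASES), size=30))
        ctx = _evaluate_construct(mature, precursor + junk)
        if ctx.accepted != (violate is None):
            return False
    return True


def design_hairpin(
    rng: np.random.Generator,
    family: str,
    violate: str | None = None,
    max_attempts: int = 30,
) -> HairpinDesign:
    """Sample matures and pads until the folded construct carries exactly
    the intended verdict pattern (all criteria true, or only the targeted
    one false) in random sequence contexts."""
    for _ in range(max_attempts):
        if violate == "head":
            mature = make_head_mature(rng)
        else:
            mature = "".join(rng.choice(list(RNA_BASES), size=21))
        precursor = make_hairpin(mature, violate, rng)
        if _verify_construct(mature, precursor, violate, rng):
            return HairpinDesign(family=family, mature=mature,
                                 precursor=precursor, violate=violate)
    raise RuntimeError(
        f"could not verify a {violate or 'passing'} hairpin for {family} "
        f"in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GenomeSpec:
    """One simulated genome: its name, the species class that chooses the
    filter preset, and its substitution divergence from the ancestor."""

    name: str
    species_class: str = "wheat"  # wheat | barley_rye | oat | rice
    divergence: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError(f"divergence {self.divergence} outside [0, 0.3]")


@dataclass(frozen=True)
class StructuralEvent:
    """A planted rearrangement on one genome, in ancestral gene indices."""

    genome: str
    kind: str  # inversion | translocation | gene_loss
    gene_start: int  # 0-based ancestral gene index
    n_genes: int
    #: translocation target: re-insert after this ancestral gene index
    insert_after: int | None = None


@dataclass(frozen=True)
class MirnaPlanting:
    """One hairpin planting: family, the criterion it violates (None for a
    passing hairpin), and the genomes carrying it (None = all)."""

    family: str
    violate: str | None = None
    genomes: tuple[str, ...] | None = None


def default_genomes() -> list[GenomeSpec]:
    return [
        GenomeSpec("svevo", "wheat", 0.0),
        GenomeSpec("zavitan", "wheat", 0.01),
        GenomeSpec("chinese_spring", "wheat", 0.01),
        GenomeSpec("barley", "barley_rye", 0.05),
        GenomeSpec("rye", "barley_rye", 0.05),
        GenomeSpec("rice", "rice", 0.12),
    ]


@dataclass
class SimulationConfig:
    seed: int
    genomes: list[GenomeSpec] = field(default_factory=default_genomes)
    genes_per_locus: int = 20
    gene_length: tuple[int, int] = (600, 1800)
    intergenic_length: tuple[int, int] = (1000, 3000)
    max_isoforms: int = 3
    n_markers: int = 15
    marker_length: tuple[int, int] = (100, 200)
    structural_events: list[StructuralEvent] = field(default_factory=list)
    mirna_plantings: list[MirnaPlanting] = field(default_factory=list)
    flank_length: int = 3000

    def validate(self) -> None:
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genome names")
        if self.genes_per_locus < 2:
            raise ValueError("need at least 2 genes per locus")
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        for ev in self.structural_events:
            if ev.genome not in names:
                raise ValueError(f"event genome {ev.genome!r} not simulated")
            if ev.kind not in ("inversion", "translocation", "gene_loss"):
                raise ValueError(f"unknown event kind {ev.kind!r}")
            if ev.gene_start < 0 or ev.gene_start + ev.n_genes > self.genes_per_locus:
                raise ValueError(
                    f"event span {ev.gene_start}+{ev.n_genes} exceeds locus of "
                    f"{self.genes_per_locus} genes"
                )
            if ev.kind == "translocation":
                if ev.insert_after is None:
                    raise ValueError("translocation needs insert_after")
                if ev.gene_start <= ev.insert_after < ev.gene_start + ev.n_genes:
                    raise ValueError("translocation target inside moved block")
        for pl in self.mirna_plantings:
            if pl.violate is not None and pl.violate not in CRITERIA:
                raise ValueError(f"unknown criterion {pl.violate!r}")
            if pl.genomes is not None:
                for g in pl.genomes:
                    if g not in names:
                        raise ValueError(f"planting genome {g!r} not simulated")
        if len(self.mirna_plantings) > self.genes_per_locus - 1:
            raise ValueError("more hairpin plantings than interior spacers")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class PlantedHairpin:
    family: str
    mature_id: str
    violate: str | None
    chrom: str
    start: int  # 1-based inclusive precursor coordinates
    end: int
    strand: str
    mature_start: int
    mature_end: int

    @property
    def intended_flag(self) -> str | None:
        return _CRITERION_FLAG[self.violate] if self.violate else None


@dataclass
class GroundTruth:
    reference: str
    #: genome -> (chrom, locus start, locus end), 1-based inclusive
    locus_span: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    #: genome -> (min marker start, max marker end): the recoverable borders
    marker_span: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: genome -> marker id -> (start, end, strand)
    markers: dict[str, dict[str, tuple[int, int, str]]] = field(default_factory=dict)
    #: genome -> gene id -> reference-genome gene id
    orthologs: dict[str, dict[str, str]] = field(default_factory=dict)
    #: genome -> gene ids in genomic order
    gene_order: dict[str, list[str]] = field(default_factory=dict)
    events: list[StructuralEvent] = field(default_factory=list)
    #: genome -> planted hairpins
    hairpins: dict[str, list[PlantedHairpin]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "reference": self.reference,
            "locus_span": self.locus_span,
            "marker_span": self.marker_span,
            "markers": self.markers,
            "orthologs": self.orthologs,
            "gene_order": self.gene_order,
            "events": [asdict(e) for e in self.events],
            "hairpins": {g: [asdict(h) for h in hs] for g, hs in self.hairpins.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimulatedGenome:
    name: str
    spec: GenomeSpec
    chrom: SequenceRecord
    genes: list[GffGene]
    cds: list[SequenceRecord]

    def gff3_text(self) -> str:
        return self._gff3

    _gff3: str = ""


@dataclass
class LocusSimulation:
    config: SimulationConfig
    genomes: dict[str, SimulatedGenome]
    markers: list[SequenceRecord]   # ancestral marker panel
    matures: list[SequenceRecord]   # synthetic mature miRNA reference set
    truth: GroundTruth

    def write_fixture(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, g in self.genomes.items():
            write_fasta([g.chrom], outdir / f"{name}.genome.fasta")
            write_fasta(g.cds, outdir / f"{name}.cds.fasta")
            (outdir / f"{name}.gff3").write_text(g.gff3_text())
        write_fasta(self.markers, outdir / "markers.fasta")
        write_fasta(self.matures, outdir / "matures.fasta")
        (outdir / "ground_truth.json").write_text(self.truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# internal part model


@dataclass
class _Part:
    kind: str  # spacer | gene | hairpin
    sense_seq: str
    strand: str = "+"
    anc_index: int = -1          # ancestral gene index for gene parts
    exons: list[tuple[int, int]] = field(default_factory=list)  # sense offsets
    isoforms: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)
    markers: list[tuple[str, int, int]] = field(default_factory=list)  # (id, sense lo, sense hi)
    hairpin: dict | None = None  # planting payload

    def emitted_seq(self) -> str:
        return self.sense_seq if self.strand == "+" else rc_dna(self.sense_seq)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions with transitions twice as likely as each
    transversion class combined (kappa = 2)."""
    if rate <= 0 or not seq:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        base = arr[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < 0.5:
            arr[i] = _TRANSITION[base]
        else:
            arr[i] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(arr)


def _place_marker(part: _Part, mlen: int, anchor: str,
                  rng: np.random.Generator) -> int | None:
    """Find a non-overlapping sense offset for a marker of length ``mlen``
    in a spacer part; ``anchor`` pulls it to the spacer start, end, or a
    random position.  Returns None if the spacer cannot host it."""
    n = len(part.sense_seq)
    if mlen > n - 2:
        return None

    def free(off: int) -> bool:
        return 0 <= off <= n - mlen and not any(
            lo <= off + mlen - 1 and hi >= off for _, lo, hi in part.markers
        )

    if anchor == "start":
        candidates = range(1, n - mlen + 1)
    elif anchor == "end":
        candidates = range(n - mlen - 1, -1, -1)
    else:
        for _ in range(20):
            off = int(rng.integers(0, n - mlen + 1))
            if free(off):
                return off
        candidates = range(0, n - mlen + 1)
    for off in candidates:
        if free(off):
            return off
    return None


def _build_gene(rng: np.random.Generator, cfg: SimulationConfig) -> _Part:
    gene_len = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
    n_exons = int(rng.integers(1, 4))
    intron_lens = [int(rng.integers(80, 151)) for _ in range(n_exons - 1)]
    while gene_len - sum(intron_lens) < 120 * n_exons and n_exons > 1:
        n_exons -= 1
        intron_lens.pop()
    exon_total = gene_len - sum(intron_lens)
    cuts = sorted(rng.choice(np.arange(1, exon_total // 60), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0] + [int(c) * 60 for c in cuts] + [exon_total]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    exons: list[tuple[int, int]] = []
    pos = 0
    for k, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if k < len(intron_lens):
            pos += intron_lens[k]
    n_iso = int(rng.integers(1, min(cfg.max_isoforms, n_exons) + 1))
    isoforms = [("1", tuple(range(n_exons)))]
    for j in range(2, n_iso + 1):
        isoforms.append((str(j), tuple(range(n_exons - (j - 1)))))
    return _Part(
        kind="gene",
        sense_seq=_random_dna(rng, pos),
        exons=exons,
        isoforms=isoforms,
    )


def _apply_events(parts: list[_Part], events: Sequence[StructuralEvent]) -> list[_Part]:
    def gene_part_pos(anc_idx: int) -> int:
        for i, p in enumerate(parts):
            if p.kind == "gene" and p.anc_index == anc_idx:
                return i
        raise ValueError(f"gene index {anc_idx} already removed by an earlier event")

    for ev in events:
        if ev.kind == "gene_loss":
            for idx in range(ev.gene_start, ev.gene_start + ev.n_genes):
                parts.pop(gene_part_pos(idx))
            continue
        i0 = gene_part_pos(ev.gene_start)
        i1 = gene_part_pos(ev.gene_start + ev.n_genes - 1)
        block = parts[i0 : i1 + 1]
        if ev.kind == "inversion":
            for p in block:
                p.strand = "-" if p.strand == "+" else "+"
            parts[i0 : i1 + 1] = block[::-1]
        elif ev.kind == "translocation":
            del parts[i0 : i1 + 1]
            dest = gene_part_pos(ev.insert_after) + 1
            parts[dest:dest] = block
    return parts


def simulate_locus_set(cfg: SimulationConfig) -> LocusSimulation:
    """Generate the full fixture set for one configuration.

    Returns per-genome chromosome FASTA records, gene annotations, CDS
    sets, the ancestral marker panel, the synthetic mature miRNA reference
    set, and the ground truth of everything planted.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- ancestral locus ---------------------------------------------------
    parts: list[_Part] = []
    for gi in range(cfg.genes_per_locus):
        parts.append(
            _Part(kind="spacer", sense_seq=_random_dna(rng, int(rng.integers(*cfg.intergenic_length))))
        )
        gene = _build_gene(rng, cfg)
        gene.anc_index = gi
        parts.append(gene)
    parts.append(
        _Part(kind="spacer", sense_seq=_random_dna(rng, int(rng.integers(*cfg.intergenic_length))))
    )

    # --- markers: substrings of ancestral spacers at known offsets --------
    # Each locus border is anchored by a pair of markers (QTL panels
    # saturate the flanks), so a single filtered-out edge marker does not
    # move the recoverable border; the rest are spread over the interior.
    spacer_ids = [i for i, p in enumerate(parts) if p.kind == "spacer"]
    interior = spacer_ids[1:-1]
    n_border_pairs = 2 if cfg.n_markers >= 6 else 1
    placements: list[tuple[int, str]] = (
        [(spacer_ids[0], "start")] * n_border_pairs
        + [(spacer_ids[-1], "end")] * n_border_pairs
    )
    n_extra = min(cfg.n_markers - 2 * n_border_pairs, len(interior))
    extra = rng.choice(interior, size=n_extra, replace=False)
    placements += [(int(i), "random") for i in sorted(int(i) for i in extra)]

    markers: list[SequenceRecord] = []
    for mi, (sp, anchor) in enumerate(sorted(placements)):
        part = parts[sp]
        mlen = int(rng.integers(cfg.marker_length[0], cfg.marker_length[1] + 1))
        off = _place_marker(part, mlen, anchor, rng)
        if off is None:
            continue
        mid = f"marker_{mi:03d}"
        part.markers.append((mid, off, off + mlen - 1))
        markers.append(SequenceRecord(mid, part.sense_seq[off : off + mlen]))

    # --- hairpin plantings -------------------------------------------------
    matures: list[SequenceRecord] = []
    family_mature: dict[str, str] = {}
    planting_parts: list[tuple[int, _Part]] = []
    # hairpins prefer marker-free interior spacers, spilling over to
    # markered ones when the locus is small
    free = [i for i in interior if not parts[i].markers]
    used = [i for i in interior if parts[i].markers]
    n_plant = len(cfg.mirna_plantings)
    k = min(len(free), n_plant)
    host_choice = (
        [int(x) for x in rng.choice(free, size=k, replace=False)]
        + [int(x) for x in rng.choice(used, size=n_plant - k, replace=False)]
    ) if n_plant else []
    for pi, planting in enumerate(cfg.mirna_plantings):
        if planting.family in family_mature:
            mature = family_mature[planting.family]
            precursor = make_hairpin(mature, planting.violate, rng)
        else:
            design = design_hairpin(rng, planting.family, planting.violate)
            mature, precursor = design.mature, design.precursor
            family_mature[planting.family] = mature
            matures.append(SequenceRecord(f"syn-{planting.family}-5p", mature))
        part = _Part(
            kind="hairpin",
            sense_seq=precursor.replace("U", "T"),
            hairpin={
                "family": planting.family,
                "mature_id": f"syn-{planting.family}-5p",
                "violate": planting.violate,
                "mature_offset": hairpin_mature_offset(planting.violate),
                "mature_len": len(mature),
                "genomes": planting.genomes,
            },
        )
        planting_parts.append((int(host_choice[pi]), part))

    # insert hairpin parts after their host spacers (descending index so
    # earlier insertions do not shift later hosts)
    for host, part in sorted(planting_parts, key=lambda t: -t[0]):
        parts.insert(host + 1, part)

    # --- per-genome realization --------------------------------------------
    truth = GroundTruth(reference=cfg.genomes[0].name)
    truth.events = list(cfg.structural_events)
    genomes: dict[str, SimulatedGenome] = {}

    for spec in cfg.genomes:
        grng = np.random.default_rng(rng.integers(0, 2**31))
        gparts = copy.deepcopy(parts)
        # drop hairpins not planted in this genome
        gparts = [
            p for p in gparts
            if p.kind != "hairpin"
            or p.hairpin["genomes"] is None
            or spec.name in p.hairpin["genomes"]
        ]
        for p in gparts:
            if p.kind != "hairpin":
                p.sense_seq = _mutate(p.sense_seq, spec.divergence, grng)
        events = [e for e in cfg.structural_events if e.genome == spec.name]
        gparts = _apply_events(gparts, events)

        chrom_name = f"{spec.name}_chr1"
        flank5 = _random_dna(grng, cfg.flank_length)
        flank3 = _random_dna(grng, cfg.flank_length)

        seq_chunks = [flank5]
        pos = len(flank5)  # 0-based genomic offset of the next part
        genes: list[GffGene] = []
        cds: list[SequenceRecord] = []
        g_markers: dict[str, tuple[int, int, str]] = {}
        g_hairpins: list[PlantedHairpin] = []
        order: list[str] = []
        locus_start = pos + 1

        for p in gparts:
            emitted = p.emitted_seq()
            p_start = pos + 1  # 1-based
            p_end = pos + len(emitted)
            if p.kind == "gene":
                gid = f"{spec.name}_G{p.anc_index:03d}"
                order.append(gid)
                L = len(p.sense_seq)
                iso_list: list[tuple[str, int]] = []
                for suffix, exon_idx in p.isoforms:
                    tid = f"{gid}.{suffix}"
                    cds_seq = "".join(
                        p.sense_seq[a : b + 1] for a, b in (p.exons[k] for k in exon_idx)
                    )
                    iso_list.append((tid, len(cds_seq)))
                    cds.append(SequenceRecord(tid, cds_seq))
                genes.append(
                    GffGene(
                        gene_id=gid, chrom=chrom_name,
                        start=p_start, end=p_end, strand=p.strand,
                        isoforms=sorted(iso_list),
                    )
                )
                p._gff_cache = _gene_gff_rows(  # type: ignore[attr-defined]
                    chrom_name, gid, p, p_start
                )
            elif p.kind == "spacer":
                for mid, lo, hi in p.markers:
                    if p.strand == "+":
                        g_markers[mid] = (p_start + lo, p_start + hi, "+")
                    else:
                        L = len(p.sense_seq)
                        g_markers[mid] = (p_start + (L - 1 - hi), p_start + (L - 1 - lo), "-")
            elif p.kind == "hairpin":
                h = p.hairpin
                mlen = h["mature_len"]
                off = h["mature_offset"]
                L = len(p.sense_seq)
                if p.strand == "+":
                    m_start, m_end = p_start + off, p_start + off + mlen - 1
                else:
                    m_start = p_start + (L - 1 - (off + mlen - 1))
                    m_end = p_start + (L - 1 - off)
                g_hairpins.append(
                    PlantedHairpin(
                        family=h["family"], mature_id=h["mature_id"],
                        violate=h["violate"], chrom=chrom_name,
                        start=p_start, end=p_end, strand=p.strand,
                        mature_start=m_start, mature_end=m_end,
                    )
                )
            seq_chunks.append(emitted)
            pos = p_end
        locus_end = pos
        seq_chunks.append(flank3)
        chrom_seq = "".join(seq_chunks)

        gff_lines = ["##gff-version 3"]
        for p in gparts:
            rows = getattr(p, "_gff_cache", None)
            if rows:
                gff_lines.extend(rows)
        gff_text = "\n".join(gff_lines) + "\n"

        sim = SimulatedGenome(
            name=spec.name, spec=spec,
            chrom=SequenceRecord(chrom_name, chrom_seq),
            genes=genes, cds=cds,
        )
        sim._gff3 = gff_text
        genomes[spec.name] = sim

        truth.locus_span[spec.name] = (chrom_name, locus_start, locus_end)
        if g_markers:
            truth.marker_span[spec.name] = (
                min(v[0] for v in g_markers.values()),
                max(v[1] for v in g_markers.values()),
            )
        truth.markers[spec.name] = g_markers
        truth.gene_order[spec.name] = order
        truth.hairpins[spec.name] = g_hairpins

    ref = cfg.genomes[0].name
    for spec in cfg.genomes:
        ref_ids = {g.split("_G")[1]: g for g in truth.gene_order[ref]}
        truth.orthologs[spec.name] = {
            gid: ref_ids[gid.split("_G")[1]]
            for gid in truth.gene_order[spec.name]
            if gid.split("_G")[1] in ref_ids
        }

    return LocusSimulation(
        config=cfg, genomes=genomes,
        markers=markers, matures=matures, truth=truth,
    )


def _gene_gff_rows(chrom: str, gid: str, part: _Part, p_start: int) -> list[str]:
    """GFF3 rows (gene, mRNA, CDS) for one gene part at its genomic start."""
    L = len(part.sense_seq)
    rows = [
        f"{chrom}\tsim\tgene\t{p_start}\t{p_start + L - 1}\t.\t{part.strand}\t.\tID={gid}"
    ]

    def genomic(a: int, b: int) -> tuple[int, int]:
        if part.strand == "+":
            return p_start + a, p_start + b
        return p_start + (L - 1 - b), p_start + (L - 1 - a)

    for suffix, exon_idx in part.isoforms:
        tid = f"{gid}.{suffix}"
        spans = [genomic(*part.exons[k]) for k in exon_idx]
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        rows.append(
            f"{chrom}\tsim\tmRNA\t{lo}\t{hi}\t.\t{part.strand}\t.\tID={tid};Parent={gid}"
        )
        for s, e in sorted(spans):
            rows.append(
                f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{part.strand}\t0\tID={tid}.cds;Parent={tid}"
            )
    return rows
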