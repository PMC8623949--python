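"""End-to-end per-locus workflow tying the stages together.

Stage order mirrors the analysis it automates: map markers onto each
genome and filter them by the species-scaled preset; infer the homologous
interval per genome (continuity-filtered); extract the interval's genes
with longest isoforms; order them against the reference genotype and flag
candidate inversions; discover miRNA precursors inside the interval; score
miRNA targets against the locus CDS set.  Every threshold used is recorded
in the run report, which alone suffices to reproduce the run.

Homology hits are produced with the built-in ungapped scanner, which is
exact at desk scale; externally generated 14-column hit tables can be
substituted at the module level for full-genome inputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import genes as genes_mod
from . import homology, mirna, regions, synteny
from .io import SequenceRecord, read_fasta, read_gff_genes

log = logging.getLogger("cerealqtl")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class GenomeInputs:
    name: str
    genome_fasta: str
    gff3: str
    cds_fasta: str
    species_class: str = "wheat"


@dataclass
class RunConfig:
    locus_name: str
    genomes: list[GenomeInputs]
    reference: str
    markers_fasta: str
    matures_fasta: str
    outdir: str
    seed: int = 0
    min_support: int = regions.DEFAULT_MIN_SUPPORT
    max_gap: int = regions.DEFAULT_MAX_GAP_MARKER
    min_run: int = 4
    window_lengths: tuple[int, ...] = mirna.DEFAULT_WINDOW_LENGTHS
    max_expectation: float = mirna.DEFAULT_MAX_EXPECTATION
    scan_divergence_budget: float = 0.25  # mismatch budget fraction for the scanner

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        genomes = [GenomeInputs(**g) for g in d.pop("genomes")]
        if "window_lengths" in d:
            d["window_lengths"] = tuple(d["window_lengths"])
        return RunConfig(genomes=genomes, **d)

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return RunConfig.from_dict(yaml.safe_load(text))
        return RunConfig.from_dict(json.loads(text))

    def validate(self) -> None:
        names = [g.name for g in self.genomes]
        if self.reference not in names:
            raise ValueError(f"reference {self.reference!r} not among genomes {names}")
        for g in self.genomes:
            for p in (g.genome_fasta, g.gff3, g.cds_fasta):
                if not Path(p).exists():
                    raise ValueError(f"missing input file {p}")
        for p in (self.markers_fasta, self.matures_fasta):
            if not Path(p).exists():
                raise ValueError(f"missing input file {p}")


def _marker_preset(species_class: str) -> homology.FilterPreset:
    return homology.get_preset(f"{species_class}-marker")


def _synteny_preset(species_class: str) -> homology.FilterPreset:
    key = f"{species_class}-synteny"
    if key not in homology.PRESETS:
        key = "rice-synteny" if species_class == "rice" else "barley_rye-synteny"
    return homology.get_preset(key)


def _scan_queries(queries, subject, budget: float):
    hits = []
    for q in queries:
        mm = int(math.floor(len(q.seq) * budget))
        hits.extend(homology.internal_scan(q, subject, max_mismatch=mm, both_strands=True))
    return hits


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "locus": cfg.locus_name,
        "reference": cfg.reference,
        "seed": cfg.seed,
        "parameters": {
            "min_support": cfg.min_support,
            "max_gap": cfg.max_gap,
            "min_run": cfg.min_run,
            "window_lengths": list(cfg.window_lengths),
            "max_expectation": cfg.max_expectation,
            "scan_divergence_budget": cfg.scan_divergence_budget,
            "upe_filter": "disabled",
            "presets": {
                g.name: {
                    "marker": _marker_preset(g.species_class).__dict__,
                    "synteny": _synteny_preset(g.species_class).__dict__,
                }
                for g in cfg.genomes
            },
        },
        "genomes": {},
    }

    markers = read_fasta(cfg.markers_fasta, "dna")
    matures = read_fasta(cfg.matures_fasta, "rna")
    if not markers:
        raise StageError("map-markers", f"marker panel {cfg.markers_fasta} is empty")

    per_genome_records: dict[str, list] = {}
    per_genome_interval: dict[str, regions.LocusInterval] = {}
    per_genome_accepted: dict[str, list] = {}

    for g in cfg.genomes:
        greport: dict = {}
        chrom_records = read_fasta(g.genome_fasta, "dna")

        # --- stage: marker mapping and filtering -------------------------
        preset = _marker_preset(g.species_class)
        raw_hits = []
        for chrom in chrom_records:
            raw_hits.extend(_scan_queries(markers, chrom, cfg.scan_divergence_budget))
        filtered = homology.filter_hits(raw_hits, preset)
        placed = homology.drop_ambiguous_markers(filtered)
        log.info(
            "%s: markers raw=%d filtered=%d placed=%d",
            g.name, len(raw_hits), len(filtered), len(placed),
        )
        greport["markers"] = {
            "raw_hits": len(raw_hits),
            "passing_hits": len(filtered),
            "placed_markers": len(placed),
        }

        # --- stage: region inference -------------------------------------
        by_chrom: dict[str, list] = {}
        for h in placed:
            by_chrom.setdefault(h.sid, []).append(h)
        continuous = []
        for chrom_hits in by_chrom.values():
            continuous.extend(regions.continuity_filter(chrom_hits, cfg.max_gap))
        intervals = regions.infer_interval(
            continuous, min_support=cfg.min_support, genome=g.name, method="marker"
        )
        if not intervals:
            raise StageError(
                "infer-region",
                f"no homologous interval for genome {g.name!r}: "
                f"{len(placed)} placed markers, min_support={cfg.min_support}",
            )
        interval = max(intervals, key=lambda iv: iv.support)
        per_genome_interval[g.name] = interval
        greport["interval"] = {
            "chrom": interval.chrom, "start": interval.start,
            "end": interval.end, "support": interval.support,
        }

        # --- stage: gene extraction --------------------------------------
        gff_genes = read_gff_genes(g.gff3)
        cds = read_fasta(g.cds_fasta, "dna")
        records = genes_mod.extract_locus_genes(gff_genes, interval, cds)
        per_genome_records[g.name] = records
        genes_mod.write_gene_table(records, outdir / f"{g.name}.genes.tsv")
        log.info("%s: %d locus genes (longest isoforms)", g.name, len(records))
        greport["genes"] = {"count": len(records)}

        # --- stage: miRNA discovery --------------------------------------
        chrom_seq = next(c for c in chrom_records if c.id == interval.chrom)
        locus_seq = SequenceRecord(
            interval.chrom, chrom_seq.seq[interval.start - 1 : interval.end]
        )
        accepted, evaluated = mirna.discover_mirnas(
            locus_seq, matures, window_lens=cfg.window_lengths
        )
        # shift windows to genome coordinates
        for c in accepted:
            c.start += interval.start - 1
            c.end += interval.start - 1
        per_genome_accepted[g.name] = accepted
        greport["mirna"] = {
            "candidates_evaluated": len(evaluated),
            "precursors_accepted": len(accepted),
            "families": sorted({c.family for c in accepted}),
        }

        # --- stage: target scoring ---------------------------------------
        fam_ok = {c.family for c in accepted}
        active_matures = [m for m in matures if mirna.family_name(m.id) in fam_ok]
        preds = mirna.predict_targets(
            active_matures, [r.cds_seq for r in records],
            max_expectation=cfg.max_expectation,
        )
        greport["targets"] = {
            "retained_sites": len(preds),
            "pairs": [list(t) for t in sorted({(p.mature_id, p.transcript_id) for p in preds})],
        }
        report["genomes"][g.name] = greport

    # --- stage: synteny -----------------------------------------------------
    ref_records = per_genome_records[cfg.reference]
    per_genome_maps = {}
    for g in cfg.genomes:
        if g.name == cfg.reference:
            continue
        q_records = per_genome_records[g.name]
        hits = []
        for qr in q_records:
            for rr in ref_records:
                if len(qr.cds_seq.seq) <= len(rr.cds_seq.seq):
                    hits.extend(
                        homology.internal_scan(
                            qr.cds_seq, rr.cds_seq,
                            max_mismatch=int(len(qr.cds_seq.seq) * cfg.scan_divergence_budget),
                            both_strands=True,
                        )
                    )
        mapping = synteny.assign_homologs(
            q_records, ref_records, hits, _synteny_preset(g.species_class)
        )
        per_genome_maps[g.name] = (q_records, mapping)
        report["genomes"][g.name]["synteny"] = {
            "mapped": sum(1 for v in mapping.values() if v is not None),
            "unmapped": sum(1 for v in mapping.values() if v is None),
        }
    smap = synteny.build_synteny_map(
        cfg.reference, ref_records, per_genome_maps, min_run=cfg.min_run
    )
    report["inversions"] = [
        {"genome": c.genome, "rank_start": c.rank_start, "rank_end": c.rank_end}
        for c in smap.inversion_calls
    ]
    plot_table = synteny.export_synteny_plot_data(smap)
    plot_table.to_csv(outdir / "synteny.tsv", sep="\t", index=False)

    # --- family summary -----------------------------------------------------
    summary = mirna.summarize_families(per_genome_accepted)
    report["families"] = {
        "per_genome": {g: sorted(s) for g, s in summary.families_by_genome.items()},
        "precursor_counts": dict(sorted(summary.precursor_counts.items())),
        "total_precursors": summary.total_precursors,
        "partition": {
            "+".join(sorted(k)): v for k, v in sorted(summary.partition.items(), key=lambda kv: sorted(kv[0]))
        },
    }

    report_text = json.dumps(report, indent=2, sort_keys=True) + "\n"
    (outdir / "report.json").write_text(report_text)
    return report
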