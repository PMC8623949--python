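import numpy as np
import pytest

from cerealqtl.homology import filter_hits, internal_scan
from cerealqtl.io import read_fasta, read_gff_genes
from cerealqtl.mirna import discover_mirnas
from cerealqtl.simulate import (
    GenomeSpec,
    MirnaPlanting,
    SimulationConfig,
    StructuralEvent,
    simulate_locus_set,
)

from conftest import small_config


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = small_config(3, mirna_plantings=[MirnaPlanting("miR9001")])
        a = simulate_locus_set(cfg)
        b = simulate_locus_set(cfg)
        assert a.truth.to_json() == b.truth.to_json()
        for name in a.genomes:
            assert a.genomes[name].chrom.seq == b.genomes[name].chrom.seq
            assert a.genomes[name].gff3_text() == b.genomes[name].gff3_text()
        d1, d2 = tmp_path / "f1", tmp_path / "f2"
        a.write_fixture(d1)
        b.write_fixture(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_different_seed_differs(self):
        a = simulate_locus_set(small_config(1))
        b = simulate_locus_set(small_config(2))
        assert a.genomes["svevo"].chrom.seq != b.genomes["svevo"].chrom.seq


class TestEmittedFilesCrossValidate(object):
    def test_gff_and_cds_agree(self, small_sim, tmp_path):
        small_sim.write_fixture(tmp_path)
        for name, g in small_sim.genomes.items():
            genes = read_gff_genes(tmp_path / f"{name}.gff3")
            cds = {c.id: c for c in read_fasta(tmp_path / f"{name}.cds.fasta")}
            chrom = read_fasta(tmp_path / f"{name}.genome.fasta")[0]
            assert {x.gene_id for x in genes} == set(small_sim.truth.gene_order[name])
            for gene in genes:
                assert 1 <= gene.start <= gene.end <= len(chrom.seq)
                for tid, cds_len in gene.isoforms:
                    assert tid in cds
                    assert len(cds[tid].seq) == cds_len

    def test_cds_sequence_matches_genome_slice(self, small_sim, tmp_path):
        """Plus-strand single-isoform CDS content equals the concatenated
        exon slices of the emitted chromosome."""
        small_sim.write_fixture(tmp_path)
        name = "svevo"
        gff = (tmp_path / f"{name}.gff3").read_text().splitlines()
        chrom = read_fasta(tmp_path / f"{name}.genome.fasta")[0].seq
        cds = {c.id: c.seq for c in read_fasta(tmp_path / f"{name}.cds.fasta")}
        by_tid: dict[str, list[tuple[int, int, str]]] = {}
        for line in gff:
            parts = line.split("\t")
            if len(parts) == 9 and parts[2] == "CDS":
                tid = parts[8].split("Parent=")[1].split(";")[0]
                by_tid.setdefault(tid, []).append((int(parts[3]), int(parts[4]), parts[6]))
        checked = 0
        for tid, segs in by_tid.items():
            if any(s[2] == "-" for s in segs):
                continue
            seq = "".join(chrom[a - 1 : b] for a, b, _ in sorted(segs))
            assert seq == cds[tid]
            checked += 1
        assert checked > 0

    def test_marker_sequences_found_at_recorded_positions(self, small_sim):
        panel = {m.id: m.seq for m in small_sim.markers}
        name = "svevo"  # zero divergence: planted markers are exact
        chrom = small_sim.genomes[name].chrom.seq
        for mid, (lo, hi, strand) in small_sim.truth.markers[name].items():
            segment = chrom[lo - 1 : hi]
            if strand == "-":
                from cerealqtl.simulate import rc_dna

                segment = rc_dna(segment)
            assert segment == panel[mid]


class TestNullModel:
    def test_zero_divergence_no_events(self):
        cfg = small_config(
            5,
            genomes=[GenomeSpec("a", "wheat", 0.0), GenomeSpec("b", "wheat", 0.0)],
        )
        sim = simulate_locus_set(cfg)
        # flanks outside the locus are genome-specific; the locus is shared
        spans = {
            n: sim.genomes[n].chrom.seq[
                sim.truth.locus_span[n][1] - 1 : sim.truth.locus_span[n][2]
            ]
            for n in ("a", "b")
        }
        assert spans["a"] == spans["b"]
        assert sim.truth.gene_order["a"] == [
            g.replace("b_", "a_") for g in sim.truth.gene_order["b"]
        ]


class TestDivergenceThresholds:
    """The species-scaled identity thresholds separate close from distant
    genomes: at 2% divergence markers pass the wheat preset; at 10% they
    fail it but pass the rice preset."""

    def _marker_hits(self, divergence, seed=17):
        cfg = small_config(
            seed,
            genomes=[GenomeSpec("ref", "wheat", 0.0),
                     GenomeSpec("query", "wheat", divergence)],
        )
        sim = simulate_locus_set(cfg)
        hits = []
        for m in sim.markers:
            hits.extend(
                internal_scan(m, sim.genomes["query"].chrom,
                              max_mismatch=int(len(m.seq) * 0.35))
            )
        best = {}
        for h in hits:
            if h.qid not in best or h.mismatches < best[h.qid].mismatches:
                best[h.qid] = h
        return list(best.values()), len(sim.markers)

    def test_low_divergence_passes_wheat_preset(self):
        hits, n = self._marker_hits(0.02)
        assert len(filter_hits(hits, "wheat-marker")) == n

    def test_high_divergence_fails_wheat_passes_rice(self):
        hits, n = self._marker_hits(0.10)
        assert len(filter_hits(hits, "wheat-marker")) < n / 2
        assert len(filter_hits(hits, "rice-marker")) == n


class TestValidation:
    def test_event_span_exceeding_locus(self):
        with pytest.raises(ValueError, match="exceeds locus"):
            small_config(1, structural_events=[
                StructuralEvent("svevo", "inversion", 6, 5)
            ]).validate()

    def test_unknown_event_genome(self):
        with pytest.raises(ValueError, match="not simulated"):
            small_config(1, structural_events=[
                StructuralEvent("nope", "inversion", 0, 2)
            ]).validate()

    def test_translocation_target_inside_block(self):
        with pytest.raises(ValueError, match="inside moved block"):
            small_config(1, structural_events=[
                StructuralEvent("svevo", "translocation", 2, 3, insert_after=3)
            ]).validate()

    def test_divergence_bounds(self):
        with pytest.raises(ValueError, match="divergence"):
            GenomeSpec("x", "wheat", 0.5)

    def test_duplicate_genome_names(self):
        with pytest.raises(ValueError, match="duplicate"):
            small_config(1, genomes=[GenomeSpec("a"), GenomeSpec("a")]).validate()


class TestGeneLoss:
    def test_lost_genes_absent_from_annotation_and_orthology(self):
        cfg = small_config(
            21,
            genomes=[GenomeSpec("ref", "wheat", 0.0), GenomeSpec("q", "wheat", 0.01)],
            structural_events=[StructuralEvent("q", "gene_loss", 3, 2)],
        )
        sim = simulate_locus_set(cfg)
        lost = {"q_G003", "q_G004"}
        assert lost.isdisjoint(sim.truth.gene_order["q"])
        assert len(sim.truth.gene_order["q"]) == cfg.genes_per_locus - 2
        assert lost.isdisjoint(sim.truth.orthologs["q"])


class TestPlantedMirnaRecovery:
    def test_end_to_end_accept_and_reject(self, small_sim):
        """The passing planting is discovered; the duplex decoy yields no
        accepted precursor anywhere near its window."""
        name = "svevo"
        genome = small_sim.genomes[name]
        chrom, lo, hi = small_sim.truth.locus_span[name]
        from cerealqtl.io import SequenceRecord

        locus = SequenceRecord(chrom, genome.chrom.seq[lo - 1 : hi])
        accepted, _ = discover_mirnas(locus, small_sim.matures)
        planted = {h.family: h for h in small_sim.truth.hairpins[name]}
        good = planted["miR9101"]
        decoy = planted["miR9102"]
        hits_good = [
            c for c in accepted
            if c.family == "miR9101"
            and c.start + lo - 1 <= good.end and c.end + lo - 1 >= good.start
        ]
        assert hits_good, "planted passing hairpin was not recovered"
        assert not any(c.family == "miR9102" for c in accepted), (
            "criterion-violating decoy was accepted"
        )
        assert len(accepted) == 1  # dedupe leaves one survivor per planting
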