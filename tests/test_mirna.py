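import numpy as np
import pytest

from cerealqtl.io import SequenceRecord
from cerealqtl.mirna import (
    PrecursorCandidate,
    dedupe_precursors,
    evaluate_criteria,
    extract_candidates,
    family_name,
    family_partition,
    fold,
    hairpin_loops,
    pair_table,
    scan_matures,
    score_target,
    summarize_families,
)
from cerealqtl.simulate import design_hairpin, make_hairpin, make_head_mature, rc_rna


@pytest.mark.parametrize(
    "mid,family",
    [
        ("tae-miR1122b-3p", "miR1122"),
        ("hvu-miR5049a", "miR5049"),
        ("osa-MIR1130-5p", "miR1130"),
        ("ath-let-7c", "let7"),
        ("weird_id", "weird_id"),
    ],
)
def test_family_normalization(mid, family):
    assert family_name(mid) == family


class TestScanMatures:
    LOCUS = None

    def _locus_with(self, mature_dna, nmut, rng):
        s = "".join(rng.choice(list("ACGT"), size=400))
        m = list(mature_dna)
        for i in rng.choice(len(m), size=nmut, replace=False):
            m[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[m[i]]
        return SequenceRecord("loc", s[:200] + "".join(m) + s[200:])

    def test_exact_planting_found_with_zero_mismatches(self):
        rng = np.random.default_rng(1)
        mseq = "".join(rng.choice(list("ACGU"), size=21))
        mature = SequenceRecord("syn-miR1-5p", mseq)
        locus = self._locus_with(mseq.replace("U", "T"), 0, rng)
        hits = [h for h in scan_matures(locus, [mature]) if h.strand == "+"]
        assert any(h.start == 201 and h.mismatches == 0 for h in hits)

    def test_two_mismatches_not_found(self):
        rng = np.random.default_rng(2)
        mseq = "".join(rng.choice(list("ACGU"), size=21))
        mature = SequenceRecord("syn-miR1-5p", mseq)
        locus = self._locus_with(mseq.replace("U", "T"), 2, rng)
        assert scan_matures(locus, [mature]) == []

    def test_strand_symmetry(self):
        """Scanning the reverse complement of the locus mirrors the hit set."""
        rng = np.random.default_rng(3)
        matures = [
            SequenceRecord(f"syn-miR{i}-5p",
                           "".join(rng.choice(list("ACGU"), size=21)))
            for i in range(3)
        ]
        locus = SequenceRecord("loc", "".join(rng.choice(list("ACGT"), size=800)))
        # plant one mature exactly
        locus.seq = locus.seq[:100] + matures[0].seq.replace("U", "T") + locus.seq[100:]
        rc = locus.reverse_complement()
        n = len(locus.seq)
        fwd = {(h.start, h.end, h.strand, h.mature_id, h.mismatches)
               for h in scan_matures(locus, matures)}
        mirrored = {
            (n - h.end + 1, n - h.start + 1, "+" if h.strand == "-" else "-",
             h.mature_id, h.mismatches)
            for h in scan_matures(rc, matures)
        }
        assert fwd == mirrored


class TestExtractCandidates:
    def test_window_arithmetic_plus_strand(self):
        from cerealqtl.mirna import MatureHit

        locus = SequenceRecord("loc", "A" * 6000)
        hit = MatureHit("m", "miR1", "loc", 5000, 5020, "+", 0)
        cands = extract_candidates(hit, locus, window_lens=(150,))
        spans = {(c.start, c.end) for c in cands}
        assert spans == {(5000, 5149), (4871, 5020)}
        five_prime = next(c for c in cands if c.start == 5000)
        assert five_prime.mature_span == (0, 20)
        three_prime = next(c for c in cands if c.start == 4871)
        assert three_prime.mature_span == (129, 149)

    def test_clipping_near_locus_start_is_flagged(self):
        from cerealqtl.mirna import MatureHit

        locus = SequenceRecord("loc", "A" * 300)
        hit = MatureHit("m", "miR1", "loc", 10, 30, "+", 0)
        cands = extract_candidates(hit, locus, window_lens=(100,))
        clipped = [c for c in cands if c.clipped]
        assert clipped and all(c.start >= 1 for c in cands)

    def test_minus_strand_orientation(self):
        from cerealqtl.mirna import MatureHit

        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        locus = SequenceRecord("loc", seq)
        hit = MatureHit("m", "miR1", "loc", 200, 220, "-", 0)
        cands = extract_candidates(hit, locus, window_lens=(100,))
        for c in cands:
            m_lo, m_hi = c.mature_span
            window_mature = c.seq[m_lo : m_hi + 1]
            genomic = seq[hit.start - 1 : hit.end]
            assert window_mature == rc_rna(genomic.replace("T", "U"))


class TestFold:
    def test_canonical_hairpin(self):
        structure, mfe = fold("GGGGGAAAACCCCC")
        assert "(" in structure and ")" in structure
        assert mfe < 0

    def test_poly_a_has_no_pairing(self):
        structure, mfe = fold("A" * 20)
        assert structure == "." * 20
        assert mfe >= -0.5

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTX")

    def test_bracket_balance_and_loop_length_invariants(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(30, 120))))
            structure, _ = fold(seq)
            pt = pair_table(structure)  # raises on imbalance
            for i, j in enumerate(pt):
                if j > i:
                    assert j - i - 1 >= 3  # minimum hairpin loop length


class TestStructureParsing:
    def test_pair_table_roundtrip(self):
        pt = pair_table("((..))")
        assert pt == [5, 4, -1, -1, 1, 0]

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            pair_table("((.)")

    def test_hairpin_loops_found(self):
        # two hairpins side by side
        pt = pair_table("((...))((...))")
        assert hairpin_loops(pt) == [(2, 4), (9, 11)]


def _candidate(mature, precursor, junk=""):
    seq = precursor + junk
    return PrecursorCandidate(
        chrom="c", start=1, end=len(seq), strand="+", seq=seq,
        mature_id="m", family="miR1", mature_span=(0, len(mature) - 1),
    )


class TestCriteria:
    """Each engineered construct flips exactly its targeted verdict."""

    def test_perfect_inverted_repeat_accepted(self):
        rng = np.random.default_rng(10)
        d = design_hairpin(rng, "miR1", None)
        cand = evaluate_criteria(_candidate(d.mature, d.precursor))
        assert cand.accepted and all(cand.criteria.values())

    @pytest.mark.parametrize("violate,flag", [
        ("dicer", "dicer_ok"),
        ("multibranch", "no_multibranch"),
        ("head", "not_in_head"),
        ("duplex", "duplex_mismatch_ok"),
    ])
    def test_single_violation_flips_only_target_flag(self, violate, flag):
        rng = np.random.default_rng(20)
        d = design_hairpin(rng, "miR1", violate)
        cand = evaluate_criteria(_candidate(d.mature, d.precursor))
        assert not cand.accepted
        assert cand.criteria[flag] is False
        others = {k: v for k, v in cand.criteria.items() if k != flag}
        assert all(others.values())

    def test_duplex_violation_has_at_least_five_unpaired(self):
        rng = np.random.default_rng(30)
        d = design_hairpin(rng, "miR1", "duplex")
        cand = evaluate_criteria(_candidate(d.mature, d.precursor))
        pt = pair_table(cand.structure)
        lo, hi = cand.mature_span
        assert sum(1 for i in range(lo, hi + 1) if pt[i] == -1) >= 5

    def test_mature_span_outside_sequence_is_error(self):
        cand = PrecursorCandidate("c", 1, 4, "+", "ACGU", "m", "miR1", (2, 10))
        with pytest.raises(ValueError):
            evaluate_criteria(cand)

    def test_accepted_iff_all_flags(self):
        rng = np.random.default_rng(40)
        for violate in (None, "dicer", "head"):
            d = design_hairpin(rng, "miR1", violate)
            cand = evaluate_criteria(_candidate(d.mature, d.precursor))
            assert cand.accepted == all(cand.criteria.values())


class TestMakeHairpin:
    def test_mature_length_validated(self):
        with pytest.raises(ValueError):
            make_hairpin("ACGU" * 3)

    def test_head_requires_compatible_mature(self):
        with pytest.raises(ValueError, match="impossible construction"):
            make_hairpin("ACGUACGUACGUACGUACGUA", "head")

    def test_head_mature_is_self_complementary(self):
        m = make_head_mature(np.random.default_rng(0))
        assert len(m) == 21 and m[:9] == rc_rna(m[12:])

    def test_unknown_criterion(self):
        with pytest.raises(ValueError, match="unknown criterion"):
            make_hairpin("A" * 21, "frobnicate")


class TestDedupe:
    def _acc(self, start, end, family="miR1", mfe=-30.0):
        c = PrecursorCandidate("c", start, end, "+", "A", "m", family, (0, 0))
        c.mfe = mfe
        c.accepted = True
        return c

    def test_same_hairpin_two_window_lengths_collapse(self):
        a = self._acc(1000, 1149, mfe=-40.0)
        b = self._acc(1000, 1199, mfe=-35.0)
        out = dedupe_precursors([a, b])
        assert out == [a]  # lower mfe wins

    def test_non_overlapping_same_family_kept(self):
        a = self._acc(1000, 1100)
        b = self._acc(5000, 5100)
        assert len(dedupe_precursors([a, b])) == 2

    def test_overlapping_different_family_kept(self):
        a = self._acc(1000, 1100, family="miR1")
        b = self._acc(1010, 1110, family="miR2")
        assert len(dedupe_precursors([a, b])) == 2


class TestFamilies:
    def test_forced_partition(self):
        a = self._cands("A", ["f1", "f2"])
        b = self._cands("B", ["f2"])
        summary = summarize_families({"A": a, "B": b})
        assert summary.partition == {
            frozenset({"A"}): 1,
            frozenset({"A", "B"}): 1,
        }

    def test_identical_sets_all_in_full_intersection(self):
        per = {g: self._cands(g, ["f1", "f2", "f3"]) for g in ("A", "B", "C")}
        summary = summarize_families(per)
        assert summary.partition == {frozenset({"A", "B", "C"}): 3}

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(9)
        fams = [f"f{i}" for i in range(12)]
        sets = {
            g: set(rng.choice(fams, size=int(rng.integers(0, 10)), replace=False))
            for g in "ABCD"
        }
        part = family_partition(sets)
        union = set().union(*sets.values())
        assert sum(part.values()) == len(union)

    def test_wheat_merge(self):
        per = {
            "svevo": self._cands("s", ["f1"]),
            "zavitan": self._cands("z", ["f2"]),
            "barley": self._cands("b", ["f1"]),
        }
        summary = summarize_families(per, merge_wheat=("svevo", "zavitan"))
        assert summary.families_by_genome["wheat"] == {"f1", "f2"}

    @staticmethod
    def _cands(genome, families):
        return [
            PrecursorCandidate(genome, i * 1000, i * 1000 + 100, "+", "A", "m", f, (0, 0))
            for i, f in enumerate(families)
        ]


class TestTargetScoring:
    def _mature(self, seq="ACGUACGUACGUACGUACGUA"):
        return SequenceRecord("syn-miR1-5p", seq)

    def test_perfect_complement_scores_zero(self):
        m = self._mature()
        site = rc_rna(m.seq).replace("U", "T")
        t = SequenceRecord("t1", "AAAA" + site + "CCCC")
        preds = [p for p in score_target(m, t) if p.expectation == 0]
        assert preds and preds[0].site_start == 5
        assert preds[0].retained

    def test_forced_arithmetic(self):
        m = self._mature("ACGUACGUACGUACGUACGUA")
        site = list(rc_rna(m.seq))
        L = len(site)
        # one G:U wobble in the seed: mature position 5 (seed doubles 0.5 -> 1.0)
        # mature position i pairs site index L-1-i
        gu = site.copy()
        i = 5 - 1
        assert m.seq[i] == "A"  # A pairs U; make target G for a U:G? need mature G or U
        # use mature position 7 (G): complement C -> U gives G:U wobble
        i = 7 - 1
        assert m.seq[i] == "G"
        gu[L - 1 - i] = "U"
        t = SequenceRecord("t", "".join(gu).replace("U", "T"))
        (p,) = [p for p in score_target(self._mature(), t) if p.site_start == 1]
        assert p.expectation == 1.0

        # one mismatch outside the seed: mature position 15
        mm = site.copy()
        i = 15 - 1
        mm[L - 1 - i] = m.seq[i]  # same base cannot pair
        t2 = SequenceRecord("t", "".join(mm).replace("U", "T"))
        (p2,) = [p for p in score_target(self._mature(), t2) if p.site_start == 1]
        assert p2.expectation == 1.0

        # both together
        both = site.copy()
        both[L - 1 - 6] = "U"
        both[L - 1 - 14] = m.seq[14]
        t3 = SequenceRecord("t", "".join(both).replace("U", "T"))
        (p3,) = [p for p in score_target(self._mature(), t3) if p.site_start == 1]
        assert p3.expectation == 2.0 and p3.retained

    def test_brute_force_site_scoring(self):
        """Every ungapped site scored by an independent position-loop oracle."""
        rng = np.random.default_rng(11)
        m = SequenceRecord("syn-miR7-5p",
                           "".join(rng.choice(list("ACGU"), size=21)))
        t = SequenceRecord("t", "".join(rng.choice(list("ACGT"), size=300)))
        preds = {p.site_start: p.expectation
                 for p in score_target(m, t, max_expectation=1e9, report_all=True)}
        pair = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        wobble = {("G", "U"), ("U", "G")}
        trna = t.seq.replace("T", "U")
        for w in range(len(trna) - 21 + 1):
            e = 0.0
            for i in range(21):
                mb, tb = m.seq[i], trna[w + 21 - 1 - i]
                pen = 0.0 if (mb, tb) in pair else (0.5 if (mb, tb) in wobble else 1.0)
                if 2 <= i + 1 <= 13:
                    pen *= 2
                e += pen
            assert preds[w + 1] == e

    def test_retention_cutoff(self):
        m = self._mature()
        t = SequenceRecord("t", "G" * 60)
        assert all(p.expectation <= 3 for p in score_target(m, t))
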