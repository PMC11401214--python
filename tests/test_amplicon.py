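import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanomatch import amplicon as amp
from nanomatch.amplicon import (
    Hinge,
    MergeFailure,
    NoHit,
    PrimerDef,
    RejectReason,
    VhhSequence,
    reverse_complement,
)
from nanomatch.seqio import IUPAC_DNA, SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def rec(seq, qual=None, id="r"):
    return SequenceRecord(id=id, seq=seq, qual=qual or tuple([30] * len(seq)))


# ---------------------------------------------------------------------------
# merge_read_pair

def brute_force_best_overlap(s1, s2rc, min_overlap, frac):
    """Independent oracle: scan every ungapped suffix/prefix overlap."""
    for L in range(min(len(s1), len(s2rc)), min_overlap - 1, -1):
        mism = sum(a != b for a, b in zip(s1[-L:], s2rc[:L]))
        if mism <= frac * L:
            return L
    return None


class TestMergeReadPair:
    def test_partial_overlap_length_identity(self):
        # r1 of length 8; rc(r2) starts with r1's last 4 bases
        r1 = rec("ACGTTGCA")
        s2rc = "TGCAGGTT"
        r2 = rec(reverse_complement(s2rc))
        m = amp.merge_read_pair(r1, r2, min_overlap=4)
        assert m.overlap_len == 4
        assert len(m.seq) == 8 + 8 - 4
        assert m.seq == "ACGTTGCAGGTT"

    def test_identical_full_length_reads(self):
        r1 = rec("ACGTACGTACGTACGTACGT")
        r2 = rec(reverse_complement(r1.seq))
        m = amp.merge_read_pair(r1, r2, min_overlap=5)
        assert m.seq == r1.seq
        assert m.overlap_len == len(r1.seq)
        assert m.conflict_count == 0

    def test_conflict_resolved_by_higher_quality(self):
        s1 = "ACGTACGTACGT"
        s2rc = "ACGTACGTACGA"  # last base differs
        q_low = tuple([20] * 12)
        q_high = tuple([38] * 12)
        r1 = rec(s1, qual=q_low)
        r2 = SequenceRecord(id="r", seq=reverse_complement(s2rc), qual=q_high[::-1])
        m = amp.merge_read_pair(r1, r2, min_overlap=12, max_overlap_mismatch_frac=0.2)
        assert m.conflict_count == 1
        assert m.seq[-1] == "A"  # r2's higher-quality base wins

    def test_quality_tie_keeps_r1_base(self):
        s1 = "ACGTACGTACGT"
        s2rc = "ACGTACGTACGA"
        r1 = rec(s1)
        r2 = rec(reverse_complement(s2rc))
        m = amp.merge_read_pair(r1, r2, min_overlap=12, max_overlap_mismatch_frac=0.2)
        assert m.seq[-1] == "T"

    def test_no_overlap_is_failure_value(self):
        r1 = rec("AAAAAAAAAA")
        r2 = rec("AAAAAAAAAA")  # rc = TTTTTTTTTT, no overlap matches
        out = amp.merge_read_pair(r1, r2, min_overlap=4)
        assert isinstance(out, MergeFailure)

    def test_matches_brute_force_offset_scan(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(150):
            n1 = int(rng.integers(10, 60))
            n2 = int(rng.integers(10, 60))
            s1 = "".join(rng.choice(bases, n1))
            # embed a true overlap most of the time
            L = int(rng.integers(0, min(n1, n2) + 1))
            tail = "".join(rng.choice(bases, n2 - L))
            s2rc = s1[n1 - L:] + tail if L else "".join(rng.choice(bases, n2))
            r1, r2 = rec(s1), rec(reverse_complement(s2rc))
            got = amp.merge_read_pair(r1, r2, min_overlap=5, max_overlap_mismatch_frac=0.1)
            expect = brute_force_best_overlap(s1, s2rc, 5, 0.1)
            if expect is None:
                assert isinstance(got, MergeFailure)
            else:
                assert got.overlap_len == expect
                assert len(got.seq) == n1 + n2 - expect


# ---------------------------------------------------------------------------
# find_primer

def oracle_find_primer(target, primer, frac):
    """Exhaustive position scan with IUPAC set membership (independent
    of the vectorized implementation)."""
    import math
    p = primer.annealing_seq
    budget = math.ceil(frac * len(p))
    search = target if primer.orientation == "forward" else reverse_complement(target)
    best = None
    for pos in range(len(search) - len(p) + 1):
        m = sum(1 for c, t in zip(p, search[pos:pos + len(p)]) if t not in IUPAC_DNA[c])
        if m > budget:
            continue
        plus = pos if primer.orientation == "forward" else len(target) - pos - len(p)
        key = (m, plus)
        if best is None or key < best:
            best = key
    return best


class TestFindPrimer:
    def test_budget_is_ceiling_of_fraction(self):
        p23 = PrimerDef(name="p", annealing_seq="A" * 23, orientation="forward")
        assert amp.allowed_mismatches(p23, 0.2) == 5

    def test_exact_substring(self):
        p = PrimerDef(name="p", annealing_seq="ACGT", orientation="forward")
        hit = amp.find_primer("TTACGTTT", p, 0.0)
        assert (hit.position, hit.mismatches) == (2, 0)

    def test_degenerate_code_matches_both_bases(self):
        p = PrimerDef(name="p", annealing_seq="AYGT", orientation="forward")
        for base in "CT":
            hit = amp.find_primer(f"GGA{base}GTGG", p, 0.0)
            assert hit.mismatches == 0

    def test_reverse_orientation_reports_plus_strand(self):
        p = PrimerDef(name="p", annealing_seq="ACGT", orientation="reverse")
        target = "TT" + reverse_complement("ACGT") + "GGG"
        hit = amp.find_primer(target, p, 0.0)
        assert hit.strand == "-"
        assert (hit.position, hit.end) == (2, 6)

    def test_no_hit_is_falsy_value(self):
        p = PrimerDef(name="p", annealing_seq="AAAAAAAA", orientation="forward")
        assert isinstance(amp.find_primer("CCCCCCCCCC", p, 0.0), NoHit)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        target=st.text(alphabet="ACGT", min_size=8, max_size=200),
        primer_seq=st.text(alphabet="ACGTYRN", min_size=4, max_size=25),
        orientation=st.sampled_from(["forward", "reverse"]),
        frac=st.sampled_from([0.0, 0.1, 0.2, 0.3]),
    )
    def test_equals_exhaustive_scan_oracle(self, target, primer_seq, orientation, frac):
        primer = PrimerDef(name="p", annealing_seq=primer_seq, orientation=orientation)
        got = amp.find_primer(target, primer, frac)
        expect = oracle_find_primer(target, primer, frac)
        if expect is None:
            assert isinstance(got, NoHit)
        else:
            assert (got.mismatches, got.position) == expect


# ---------------------------------------------------------------------------
# extract_and_translate

FWD = PrimerDef(name="fwd", annealing_seq="AAACCCGGGTTT", orientation="forward")
REV = PrimerDef(name="rev-lh", annealing_seq="CCGGAAGGTTCC", orientation="reverse",
                hinge=Hinge.LONG_IGG2)


def make_amplicon(coding):
    seq = FWD.annealing_seq + coding + reverse_complement(REV.annealing_seq)
    return amp.MergedAmplicon(id="m", seq=seq, overlap_len=0, conflict_count=0)


class TestExtractAndTranslate:
    def run(self, coding, **kw):
        kw.setdefault("translated_len_range", (1, 500))
        return amp.extract_and_translate(make_amplicon(coding), [FWD], [REV], **kw)

    def test_atg_frame_zero(self):
        out = self.run("ATGGCT")
        assert out.protein == "MA"

    def test_standard_code_translation(self):
        out = self.run("GTGCAGCTGCAGGAG")
        assert out.protein == "VQLQE"

    def test_hinge_from_reverse_primer_identity(self):
        out = self.run("ATGGCTGCA")
        assert out.hinge == Hinge.LONG_IGG2

    def test_internal_stop_rejected(self):
        out = self.run("ATGTAAGCT")
        assert out is RejectReason.INTERNAL_STOP

    def test_partial_codon_truncated(self):
        out = self.run("ATGGCTGC")  # 8 bases -> 2 codons
        assert out.protein == "MA"

    def test_length_window_enforced(self):
        out = self.run("ATGGCT", translated_len_range=(90, 180))
        assert out is RejectReason.BAD_LENGTH

    def test_no_forward_primer(self):
        m = amp.MergedAmplicon(id="m", seq="T" * 60, overlap_len=0, conflict_count=0)
        out = amp.extract_and_translate(m, [FWD], [REV], translated_len_range=(1, 500))
        assert out is RejectReason.NO_FORWARD

    def test_fallback_reverse_gives_unknown_hinge(self):
        fallback = PrimerDef(name="fb", annealing_seq="TTGGCCTTGGCC", orientation="reverse")
        seq = FWD.annealing_seq + "ATGGCTGCA" + reverse_complement(fallback.annealing_seq)
        m = amp.MergedAmplicon(id="m", seq=seq, overlap_len=0, conflict_count=0)
        out = amp.extract_and_translate(
            m, [FWD], [REV], fallback_rev=fallback, translated_len_range=(1, 500)
        )
        assert out.hinge == Hinge.UNKNOWN

    def test_retranslation_identity(self):
        out = self.run("GTGCAGCTGCAGGAGATGGCT")
        from Bio.Seq import Seq
        assert str(Seq(out.dna).translate()) == out.protein


# ---------------------------------------------------------------------------
# dedup_and_count

def draft(protein, dna, hinge=Hinge.LONG_IGG2):
    return VhhSequence(id="d", protein=protein, dna=dna, count=1, hinge=hinge)


class TestDedupAndCount:
    def test_counts_summed_and_conserved(self):
        drafts = [draft("PEPTIDE", "CCT")] * 3 + [draft("PROTEIN", "CCA")]
        out = amp.dedup_and_count(drafts)
        assert [(v.protein, v.count) for v in out] == [("PEPTIDE", 3), ("PROTEIN", 1)]
        assert sum(v.count for v in out) == len(drafts)

    def test_all_distinct(self):
        out = amp.dedup_and_count([draft("AB", "X"), draft("CD", "Y")])
        assert all(v.count == 1 for v in out)

    def test_representative_dna_is_majority_variant(self):
        drafts = [draft("PEP", "CCTGAACCT"), draft("PEP", "CCTGAACCT"),
                  draft("PEP", "CCAGAGCCA")]
        (v,) = amp.dedup_and_count(drafts)
        assert v.dna == "CCTGAACCT"

    def test_dna_tie_breaks_lexicographically(self):
        drafts = [draft("PEP", "CCT"), draft("PEP", "CCA")]
        (v,) = amp.dedup_and_count(drafts)
        assert v.dna == "CCA"

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(["AA", "AB", "BA", "BB"]), min_size=1, max_size=30))
    def test_total_support_conserved(self, proteins):
        drafts = [draft(p, p) for p in proteins]
        out = amp.dedup_and_count(drafts)
        assert sum(v.count for v in out) == len(proteins)
        assert len({v.protein for v in out}) == len(out)


# ---------------------------------------------------------------------------
# primer_coverage_survey & flanking diversity

PROBE = PrimerDef(name="probe", annealing_seq="ACGTACGTAC", orientation="forward")


def target_with_site(site, prefix="TTTT", suffix="GGGG"):
    return prefix + site + suffix


class TestSurvey:
    def test_nine_of_ten_with_distant_variant(self):
        common = "ACGTACGTAC"
        far = "ACGAACGAAA"  # 3 mismatches from common
        targets = [target_with_site(common)] * 9 + [target_with_site(far)]
        res = amp.primer_coverage_survey(targets, PROBE, 0.3, top_n=1, merge_radius=1)
        assert res.coverage == pytest.approx(9 / 10)
        assert res.coverage_pct == pytest.approx(90.0)

    def test_all_identical_full_coverage(self):
        targets = [target_with_site("ACGTACGTAC")] * 5
        res = amp.primer_coverage_survey(targets, PROBE, 0.2, top_n=1, merge_radius=1)
        assert res.coverage == pytest.approx(1.0)
        assert len(res.variants) == 1

    def test_one_mismatch_variant_merged(self):
        common = "ACGTACGTAC"
        near = "ACGTACGTAA"  # 1 mismatch
        targets = [target_with_site(common)] * 6 + [target_with_site(near)] * 2
        res = amp.primer_coverage_survey(targets, PROBE, 0.2, top_n=1, merge_radius=1)
        assert res.coverage == pytest.approx(1.0)
        assert res.variants[0].abundance == 8

    def test_no_sites_flagged_undefined(self):
        res = amp.primer_coverage_survey(["TTTTTTTTTTTT"], PROBE, 0.0, 1, 1)
        assert res.coverage is None
        assert res.n_with_site == 0

    def test_coverage_monotone_in_top_n_and_radius(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        site = "ACGTACGTAC"
        targets = []
        for _ in range(120):
            s = list(site)
            for pos in rng.choice(10, size=int(rng.integers(0, 3)), replace=False):
                s[pos] = str(rng.choice(bases))
            targets.append(target_with_site("".join(s)))
        prev = -1.0
        for top_n in (1, 2, 4, 8):
            res = amp.primer_coverage_survey(targets, PROBE, 0.4, top_n, 1)
            assert res.coverage >= prev
            prev = res.coverage
        prev = -1.0
        for radius in (0, 1, 2, 3):
            res = amp.primer_coverage_survey(targets, PROBE, 0.4, 3, radius)
            assert res.coverage >= prev
            prev = res.coverage


class TestFlankingDiversity:
    def test_identical_targets_one_flank(self):
        targets = ["AAACCCGGGTTTACGT"] * 3
        hits = [amp.PrimerHit("p", 3, "+", 0, 0, 6)] * 3
        flanks, skipped = amp.flanking_region_diversity(targets, hits, 3, "upstream")
        assert dict(flanks) == {"AAA": 3}
        assert skipped == 0

    def test_window_zero_degenerate(self):
        targets = ["AAACCC"]
        hits = [amp.PrimerHit("p", 3, "+", 0, 0, 3)]
        flanks, _ = amp.flanking_region_diversity(targets, hits, 0, "downstream")
        assert dict(flanks) == {"": 1}

    def test_out_of_bounds_skipped_and_tallied(self):
        targets = ["AAACCC"]
        hits = [amp.PrimerHit("p", 1, "+", 0, 0, 3)]
        flanks, skipped = amp.flanking_region_diversity(targets, hits, 5, "upstream")
        assert skipped == 1 and not flanks

    def test_two_primer_sets_diversity_is_set_intersection(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        targets = []
        for _ in range(40):
            flank = "".join(rng.choice(bases, 4))
            targets.append("GGGG" + flank + "ACGTACGTAC" + "TT")
        hits_a = [amp.PrimerHit("a", 8, "+", 0, 0, 10)] * len(targets)
        hits_b = [amp.PrimerHit("b", 8, "+", 0, 0, 10)] * len(targets)
        fa, _ = amp.flanking_region_diversity(targets, hits_a, 4, "upstream")
        fb, _ = amp.flanking_region_diversity(targets, hits_b, 4, "upstream")
        expected = {t[4:8] for t in targets}
        assert set(fa) == expected
        assert set(fa) & set(fb) == expected  # identical anchors -> same sets
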