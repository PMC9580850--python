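import numpy as np
import pytest

from bsjprimer.primer_design import PrimerPair
from bsjprimer.reference_io import Transcriptome
from bsjprimer.seq import revcomp
from bsjprimer.specificity import (
    HitClass,
    PrimerAlignment,
    SpecificityPolicy,
    classify_hit,
    pair_offtargets,
    search_primer,
    specificity_verdict,
)

from oracles import hamming_scan_oracle

STRICT = SpecificityPolicy("strict")
LOOSE = SpecificityPolicy("loose")

# the 11 printed rows of the mismatch-tolerance matrix:
# (m1, m2, strict tolerated?, loose tolerated?)
MATRIX_ROWS = [
    (0, 0, False, False),
    (0, 1, False, False),
    (1, 1, False, False),
    (2, 0, False, False),
    (2, 1, False, False),
    (3, 0, False, True),
    (3, 1, False, True),
    (2, 2, False, True),
    (4, 0, True, True),
    (2, 3, True, True),
    (3, 3, True, True),
]


class TestMismatchMatrix:
    @pytest.mark.parametrize("m1,m2,strict_ok,loose_ok", MATRIX_ROWS)
    def test_printed_rows_reproduce(self, m1, m2, strict_ok, loose_ok):
        for a, b in ((m1, m2), (m2, m1)):  # labels are unordered
            assert (classify_hit(a, b, STRICT) is HitClass.TOLERATED) == strict_ok
            assert (classify_hit(a, b, LOOSE) is HitClass.TOLERATED) == loose_ok

    def test_closed_form_thresholds(self):
        for m1 in range(7):
            for m2 in range(7):
                strict = classify_hit(m1, m2, STRICT) is HitClass.TOLERATED
                loose = classify_hit(m1, m2, LOOSE) is HitClass.TOLERATED
                assert strict == (max(m1, m2) >= 4 or m1 + m2 >= 5)
                assert loose == (max(m1, m2) >= 3 or m1 + m2 >= 4)

    def test_policy_nesting(self):
        """Everything strict tolerates, loose tolerates too."""
        for m1 in range(7):
            for m2 in range(7):
                if classify_hit(m1, m2, STRICT) is HitClass.TOLERATED:
                    assert classify_hit(m1, m2, LOOSE) is HitClass.TOLERATED

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_hit(-1, 0, STRICT)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            SpecificityPolicy("medium")


def _random_tx(rng, n=2000):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSearchPrimer:
    def test_planted_exact_match(self):
        rng = np.random.default_rng(0)
        primer = "ACGTTGCAACGGTTCCAAGG"
        tx = _random_tx(rng, 500)
        t = Transcriptome({"t1": tx[:100] + primer + tx[100:]})
        hits = [h for h in search_primer(primer, t) if h.mismatches == 0]
        assert any(h.position == 100 and h.strand == "+" for h in hits)

    def test_planted_two_substitutions(self):
        from bsjprimer.fixtures import mutate_with_mismatches
        primer = "ACGTTGCAACGGTTCCAAGG"
        site = mutate_with_mismatches(primer, 2)
        t = Transcriptome({"t1": "A" * 50 + site + "A" * 50})
        hits = search_primer(primer, t)
        assert any(h.position == 50 and h.mismatches == 2 and h.strand == "+"
                   for h in hits)

    def test_reverse_strand_match(self):
        primer = "ACGTTGCAACGGTTCCAAGG"
        t = Transcriptome({"t1": "C" * 40 + revcomp(primer) + "C" * 40})
        hits = search_primer(primer, t)
        assert any(h.position == 40 and h.strand == "-" and h.mismatches == 0
                   for h in hits)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_hamming_scan(self, seed):
        rng = np.random.default_rng(seed)
        primer = "".join(rng.choice(list("ACGT"), size=12))
        records = {"a": _random_tx(rng, 1500), "b": _random_tx(rng, 800)}
        got = [(h.transcript_id, h.position, h.strand, h.mismatches)
               for h in search_primer(primer, Transcriptome(records))]
        assert sorted(got) == sorted(hamming_scan_oracle(primer, records))

    def test_absent_primer_yields_nothing(self):
        # G/T-only primer against an A/C-only transcript: the + strand
        # never matches; the reverse complement is A/C-only and *does*
        # match, so use a transcript alphabet disjoint from both
        primer = "GTGTGGTTGGTTGTGG"
        t = Transcriptome({"t1": "AG" * 400})
        assert search_primer(primer, t) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            search_primer("ACGT", Transcriptome({"t": "ACGT" * 10}))


def _aln(tid, pos, strand, mm, length=20):
    return PrimerAlignment(tid, pos, strand, mm, length)


class TestPairOfftargets:
    def test_convergent_geometry_product_size(self):
        fwd = [_aln("t1", 100, "+", 0)]
        rev = [_aln("t1", 280, "-", 1)]
        (hit,) = pair_offtargets(fwd, rev)
        assert hit.product_size == 280 + 20 - 100  # includes both primers
        assert (hit.m1, hit.m2) == (0, 1)

    def test_swapped_strand_roles_also_amplify(self):
        fwd = [_aln("t1", 300, "-", 0)]
        rev = [_aln("t1", 100, "+", 2)]
        (hit,) = pair_offtargets(fwd, rev)
        assert hit.product_size == 220

    def test_divergent_orientation_no_hit(self):
        # minus-strand alignment upstream of the plus one: the host-gene
        # situation for BSJ primers
        fwd = [_aln("t1", 300, "+", 0)]
        rev = [_aln("t1", 100, "-", 0)]
        assert pair_offtargets(fwd, rev) == []

    def test_same_strand_no_hit(self):
        assert pair_offtargets([_aln("t1", 100, "+", 0)],
                               [_aln("t1", 300, "+", 0)]) == []

    def test_different_transcripts_no_hit(self):
        assert pair_offtargets([_aln("t1", 100, "+", 0)],
                               [_aln("t2", 300, "-", 0)]) == []

    def test_max_product_bound(self):
        fwd = [_aln("t1", 0, "+", 0)]
        rev = [_aln("t1", 2000, "-", 0)]
        assert pair_offtargets(fwd, rev, max_product=1000) == []
        assert len(pair_offtargets(fwd, rev, max_product=2020)) == 1


def make_pair(fwd_seq, rev_seq):
    amp = fwd_seq + "A" * 60 + revcomp(rev_seq)
    return PrimerPair(
        fwd_seq=fwd_seq, rev_seq=rev_seq, fwd_start=0, rev_end=len(amp),
        fwd_tm=59.0, rev_tm=59.0, fwd_gc=50.0, rev_gc=50.0,
        amplicon_seq=amp, penalty=0.0,
    )


class TestSpecificityVerdict:
    FWD = "ACGTTGCAACGGTTCCAAGG"
    REV = "TTGGCCAATTGGCCTTCTGT"

    def _tx_with_site(self, m1, m2, spacing=160):
        from bsjprimer.fixtures import plant_offtarget
        records, _ = plant_offtarget({}, self.FWD, self.REV, (m1, m2), spacing)
        return Transcriptome(records)

    def test_perfect_convergent_hit_fails(self):
        v = specificity_verdict(make_pair(self.FWD, self.REV),
                                self._tx_with_site(0, 0))
        assert not v.passed
        assert v.worst.m1 + v.worst.m2 == 0

    def test_tolerated_hit_passes_strict(self):
        v = specificity_verdict(make_pair(self.FWD, self.REV),
                                self._tx_with_site(2, 3))
        assert v.passed
        assert len(v.hits) == 1  # seen but tolerated

    def test_no_hits_passes(self):
        t = Transcriptome({"t1": "AC" * 500})
        assert specificity_verdict(make_pair(self.FWD, self.REV), t).passed

    def test_self_hit_on_host_transcript_is_divergent(self, genome, transcriptome):
        """A BSJ pair designed on a spliced template targets its host
        transcript with the reverse primer upstream of the forward one
        (divergent), which can never amplify linear RNA: the pair passes."""
        tx1 = transcriptome["TX1"]
        fwd = tx1[700:720]          # donor-side segment (downstream)
        rev = revcomp(tx1[400:420])  # acceptor-side segment (upstream)
        v = specificity_verdict(make_pair(fwd, rev), transcriptome)
        assert v.passed
        # both primers do align on the host transcript, divergently
        fwd_hits = search_primer(fwd, transcriptome)
        rev_hits = search_primer(rev, transcriptome)
        assert any(h.transcript_id == "TX1" and h.strand == "+" for h in fwd_hits)
        assert any(h.transcript_id == "TX1" and h.strand == "-" for h in rev_hits)
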