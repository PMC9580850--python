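import pytest

from bsjprimer.filtering import (
    AmpliconDecision,
    DesignOutcome,
    DesignResources,
    DesignStatus,
    FilterSettings,
    amplicon_structure_verdict,
    run_design,
    select_final,
    summarize,
)
from bsjprimer.fixtures import FixtureSpec, make_reference_bundle
from bsjprimer.folding import StructureResult
from bsjprimer.masking import flag_snps, flag_structure
from bsjprimer.primer_design import PrimerPair, enumerate_candidates
from bsjprimer.reference_io import (
    load_genome,
    load_snp_track,
    load_transcriptome,
    parse_circ_list,
    parse_exon_annotation,
)
from bsjprimer.seq import revcomp
from bsjprimer.specificity import specificity_verdict
from bsjprimer.template_builder import build_template, classify_ends


class StubEngine:
    def __init__(self, result):
        self.result = result

    def fold(self, seq, temperature=60.0):
        return self.result


def pair_on(amplicon, fwd_len=16, rev_len=16):
    return PrimerPair(
        fwd_seq=amplicon[:fwd_len], rev_seq=revcomp(amplicon[-rev_len:]),
        fwd_start=0, rev_end=len(amplicon),
        fwd_tm=59.0, rev_tm=59.0, fwd_gc=50.0, rev_gc=50.0,
        amplicon_seq=amplicon, penalty=0.0,
    )


def hairpin(stem_arm, loop=4):
    return stem_arm + "A" * loop + revcomp(stem_arm)


class TestAmpliconVerdict:
    def test_strong_fold_rejects_outright(self):
        amp = "AC" * 12 + hairpin("GCGGCCGGCGCC") + "CA" * 12
        v = amplicon_structure_verdict(pair_on(amp))
        assert v.delta_g < -15
        assert v.decision is AmpliconDecision.REJECT_HARD

    def test_band_fold_outside_primers_passes(self):
        amp = "AC" * 12 + hairpin("GCGGCC") + "CA" * 12
        v = amplicon_structure_verdict(pair_on(amp))
        assert -15 <= v.delta_g <= -5
        assert v.decision is AmpliconDecision.PASS

    def test_weak_fold_inside_primer_passes(self):
        # 3-pair helix (-1.9 kcal/mol) right at the 5' end: pairs sit in
        # the forward primer but the fold is weaker than -5
        amp = "AC" + hairpin("GGG") + "AC" * 25
        v = amplicon_structure_verdict(pair_on(amp))
        assert -5 < v.delta_g < 0
        assert v.decision is AmpliconDecision.PASS

    def test_band_fold_inside_forward_primer_rejects(self):
        amp = "AC" + hairpin("GCGGCC") + "CA" * 25
        v = amplicon_structure_verdict(pair_on(amp))
        assert -15 <= v.delta_g <= -5
        assert v.decision is AmpliconDecision.REJECT_PRIMER_OVERLAP
        assert v.overlapping_primer == "fwd"

    def test_band_fold_inside_reverse_primer_rejects(self):
        amp = "AC" * 25 + hairpin("GCGGCC") + "CA"
        v = amplicon_structure_verdict(pair_on(amp))
        assert v.decision is AmpliconDecision.REJECT_PRIMER_OVERLAP
        assert v.overlapping_primer == "rev"

    @pytest.mark.parametrize(
        "dg,paired_in_primer,expected",
        [
            (-20.0, False, AmpliconDecision.REJECT_HARD),
            (-15.001, False, AmpliconDecision.REJECT_HARD),
            (-15.0, False, AmpliconDecision.PASS),      # boundary: conditional band
            (-15.0, True, AmpliconDecision.REJECT_PRIMER_OVERLAP),
            (-5.0, True, AmpliconDecision.REJECT_PRIMER_OVERLAP),  # band inclusive
            (-4.999, True, AmpliconDecision.PASS),      # weaker than -5: always pass
            (0.0, False, AmpliconDecision.PASS),
        ],
    )
    def test_boundary_semantics(self, dg, paired_in_primer, expected):
        amp = "AC" * 40
        pairs = ((2, 30),) if paired_in_primer else ((30, 50),)
        pairing = "".join(
            "(" if any(i == a for a, b in pairs) else
            ")" if any(i == b for a, b in pairs) else "."
            for i in range(len(amp))
        )
        result = StructureResult(dg, pairing, pairs if dg < 0 else ())
        v = amplicon_structure_verdict(pair_on(amp), engine=StubEngine(result))
        assert v.decision is expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterSettings(dg_hard=-5, dg_soft=-15)


class TestSelectFinal:
    def _pair(self, size, penalty=0.0, fwd_start=0):
        return PrimerPair(
            fwd_seq="A" * 16, rev_seq="T" * 16, fwd_start=fwd_start,
            rev_end=fwd_start + size, fwd_tm=59, rev_tm=59, fwd_gc=50,
            rev_gc=50, amplicon_seq="A" * size, penalty=penalty,
        )

    def test_smallest_amplicon_wins(self):
        pairs = [self._pair(120), self._pair(80), self._pair(200)]
        assert select_final(pairs).amplicon_len == 80

    def test_single_pair(self):
        p = self._pair(100)
        assert select_final([p]) is p

    def test_tie_broken_by_penalty(self):
        a, b = self._pair(100, penalty=0.4), self._pair(100, penalty=0.1)
        assert select_final([a, b]) is b

    def test_empty_input(self):
        assert select_final([]) is None

    def test_selection_minimality(self):
        pairs = [self._pair(s) for s in (99, 51, 77, 51, 200)]
        best = select_final(pairs)
        assert all(best.amplicon_len <= p.amplicon_len for p in pairs)


def _load_resources(paths):
    return DesignResources(
        load_genome(paths["genome"]),
        parse_exon_annotation(paths["gtf"]),
        load_snp_track(paths["snps"]),
        load_transcriptome(paths["transcriptome"]),
    )


def _run_unspliced(spec, tmp_path):
    paths = make_reference_bundle(spec, tmp_path)
    res = _load_resources(paths)
    circs = {c.id: c for c in parse_circ_list(paths["circs"])}
    return run_design(circs["circ_unspliced"], res)


class TestRunDesign:
    def test_permissive_circle_is_designed(self, circs, resources):
        o = run_design(circs["circ_unspliced"], resources)
        assert o.status is DesignStatus.DESIGNED
        assert o.selected in o.passing
        assert all(o.selected.amplicon_len <= p.amplicon_len for p in o.passing)

    def test_planted_template_offtarget_fails_specificity(self, tmp_path):
        o = _run_unspliced(FixtureSpec(seed=3, template_offtarget=True), tmp_path)
        assert o.status is DesignStatus.FAIL_SPECIFICITY
        assert "0+0 mismatches" in o.failure_detail

    def test_saturating_hairpin_leaves_no_candidates(self, tmp_path):
        o = _run_unspliced(FixtureSpec(seed=3, saturating_hairpin=True), tmp_path)
        assert o.status is DesignStatus.FAIL_NO_CANDIDATES
        assert "masked region overlap" in o.failure_detail

    def test_junction_hairpin_fails_amplicon_filter(self, tmp_path):
        o = _run_unspliced(FixtureSpec(seed=3, junction_hairpin_stem=12), tmp_path)
        assert o.status is DesignStatus.FAIL_AMPLICON_STRUCTURE

    def test_missing_chromosome_is_resource_failure(self, resources):
        from bsjprimer.reference_io import CircCoordinate
        o = run_design(CircCoordinate("chrMISSING", 0, 400, id="bad"), resources)
        assert o.status is DesignStatus.FAIL_RESOURCE
        assert "chrMISSING" in o.failure_detail

    def test_filter_order_invariance(self, circs, resources):
        """Specificity and amplicon filters are independent predicates:
        applying them in either order yields the same passing set."""
        circ = circs["circ_unspliced"]
        t = build_template(circ, resources.genome,
                           classify_ends(circ, resources.transcripts), 150,
                           resources.transcripts)
        flag_snps(t, resources.snps)
        flag_structure(t)
        cands = list(enumerate_candidates(t))

        def spec_ok(p):
            return specificity_verdict(p, resources.transcriptome).passed

        def amp_ok(p):
            v = amplicon_structure_verdict(p)
            return v.decision is AmpliconDecision.PASS

        spec_then_amp = [p for p in cands if spec_ok(p) and amp_ok(p)]
        amp_then_spec = [p for p in cands if amp_ok(p) and spec_ok(p)]
        assert spec_then_amp == amp_then_spec


class TestOutcomeAndReport:
    def _designed(self, cid="c"):
        p = PrimerPair("A" * 16, "T" * 16, 0, 80, 59, 59, 50, 50, "A" * 80, 0.0)
        return DesignOutcome(cid, DesignStatus.DESIGNED, selected=p, passing=[p])

    def test_designed_requires_selected(self):
        with pytest.raises(ValueError):
            DesignOutcome("c", DesignStatus.DESIGNED)
        with pytest.raises(ValueError):
            DesignOutcome("c", DesignStatus.FAIL_SPECIFICITY,
                          selected=self._designed().selected,
                          passing=[self._designed().selected])

    def test_success_rate_arithmetic(self):
        outcomes = [self._designed(f"c{i}") for i in range(9)]
        outcomes.append(DesignOutcome("c9", DesignStatus.FAIL_SPECIFICITY))
        report = summarize(outcomes)
        assert report.success_rate == pytest.approx(90.0)
        assert report.total == 10

    def test_all_failed(self):
        outcomes = [DesignOutcome(f"c{i}", DesignStatus.FAIL_NO_CANDIDATES)
                    for i in range(4)]
        report = summarize(outcomes)
        assert report.success_rate == 0.0
        assert report.counts["FAIL_NO_CANDIDATES"] == 4

    def test_counts_conserve_total(self):
        outcomes = ([self._designed(f"c{i}") for i in range(3)]
                    + [DesignOutcome("x", DesignStatus.FAIL_SPECIFICITY),
                       DesignOutcome("y", DesignStatus.FAIL_AMPLICON_STRUCTURE)])
        report = summarize(outcomes)
        assert sum(report.counts.values()) == report.total == len(outcomes)
        # zero categories present in the totals table
        assert report.counts["FAIL_RESOURCE"] == 0
        assert "FAIL_RESOURCE" in report.render()

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
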