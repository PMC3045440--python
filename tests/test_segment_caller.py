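import numpy as np
import pytest

from conftest import random_dna
from igloci.rss_scan import default_spec, pair_d_type_rss, scan_rss
from igloci.segment_caller import (
    FRAMESHIFT,
    IN_FRAME_STOP,
    MISSING_LEADER,
    PARTIAL_SEQUENCE,
    CallerConfig,
    GeneSegment,
    call_d_segments,
    call_j_segments,
    call_v_segments,
    classify_functionality,
    name_segments,
    suppress_j_over_v,
)
from igloci.seqio import GenomicSequence, Interval, reverse_complement
from igloci.synthetic_locus import (
    SimConfig,
    generate_locus,
    evaluate_against_truth,
)


def _sim_v(seed=0, **kw):
    base = dict(n_v=8, n_d=0, n_j=0, c_isotypes=(), include_delta_remnant=False)
    base.update(kw)
    return generate_locus(SimConfig(seed=seed, **base))


def _call_v(seq):
    hits = scan_rss(seq, default_spec("IGH", "V"), "both")
    return call_v_segments(seq, hits, "IGH")


class TestVCalling:
    def test_intact_planted_v_is_functional_with_exact_boundaries(self):
        seq, truth = _sim_v()
        segs = _call_v(seq)
        rep = evaluate_against_truth(segs, truth)["V"]
        assert rep["recall"] == 1.0
        assert rep["boundary_exact"] == 1.0
        assert all(s.status == "functional" and s.defects == [] for s in segs)
        assert all(s.leader is not None for s in segs)

    def test_single_base_deletion_flags_frameshift(self):
        seq, truth = _sim_v(
            seed=1,
            pseudogene_fraction=0.5,
            pseudogene_lesion_mix=(FRAMESHIFT,),
        )
        segs = _call_v(seq)
        planted = {
            (t.interval.start, t.interval.end) for t in truth if t.status == "pseudogene"
        }
        assert planted  # 4 of 8
        for s in segs:
            if (s.coding.start, s.coding.end) in planted:
                assert s.status == "pseudogene"
                assert FRAMESHIFT in s.defects

    def test_truncated_fragment_is_called_truncated(self):
        seq, truth = _sim_v(seed=2, truncated_fraction=0.25)
        segs = _call_v(seq)
        planted_trunc = [t for t in truth if t.status == "truncated"]
        assert len(planted_trunc) == 2
        called_trunc = [s for s in segs if s.status == "truncated"]
        assert len(called_trunc) == len(planted_trunc)
        for s in called_trunc:
            assert s.defects == [PARTIAL_SEQUENCE]

    def test_minus_strand_v_called_with_flipped_strand(self):
        seq, truth = _sim_v(seed=3, minus_strand_v_fraction=0.5)
        segs = _call_v(seq)
        want = {(t.interval.start, t.interval.end): t.strand for t in truth}
        got = {(s.coding.start, s.coding.end): s.strand for s in segs}
        assert got == want

    def test_homology_gate_drops_unsupported_rss_noise(self, rng):
        # a lone V-type RSS in random DNA must not become a segment
        residues = (
            random_dna(rng, 3000)
            + "CACAGTG" + random_dna(rng, 23) + "ACAAAAACC"
            + random_dna(rng, 3000)
        )
        seq = GenomicSequence("noise", residues)
        assert _call_v(seq) == []


class TestClassify:
    CFG = CallerConfig()

    def test_clean_exon_is_functional(self):
        aa = "A" * 20 + "C" + "A" * 14 + "W" + "A" * 59 + "C" + "A" * 4  # landmarks at 21,36,96
        status, defects = classify_functionality(300, aa, True, self.CFG)
        assert (status, defects) == ("functional", [])

    def test_all_triggered_defects_are_recorded(self):
        aa = "A" * 21 + "C" + "A" * 14 + "W" + "A" * 10 + "*" + "A" * 48 + "C" + "A" * 3
        status, defects = classify_functionality(300, aa, False, self.CFG)
        assert status == "pseudogene"
        assert IN_FRAME_STOP in defects and MISSING_LEADER in defects

    def test_short_fragment_is_truncated(self):
        status, defects = classify_functionality(200, "A" * 66, True, self.CFG)
        assert (status, defects) == ("truncated", [PARTIAL_SEQUENCE])


class TestDCalling:
    def test_planted_cores_with_bounds(self, rng):
        seq, truth = generate_locus(
            SimConfig(seed=4, n_v=0, n_d=6, n_j=0, c_isotypes=(), include_delta_remnant=False)
        )
        hits = scan_rss(seq, default_spec("IGH", "D"), "both")
        segs = call_d_segments(pair_d_type_rss(hits, 40), seq)
        assert {(s.coding.start, s.coding.end) for s in segs} == {
            (t.interval.start, t.interval.end) for t in truth
        }
        assert all(len(s.rss) == 2 for s in segs)

    def test_overlong_core_rejected_by_bounds(self, rng):
        from igloci.rss_scan import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS

        up = (
            reverse_complement(NONAMER_CONSENSUS)
            + random_dna(rng, 12)
            + reverse_complement(HEPTAMER_CONSENSUS)
        )
        dn = HEPTAMER_CONSENSUS + random_dna(rng, 12) + NONAMER_CONSENSUS
        seq = GenomicSequence("s", "TT" + up + random_dna(rng, 50) + dn + "TT")
        hits = scan_rss(
            seq,
            default_spec("IGH", "D"),
            "both",
        )
        segs = call_d_segments(pair_d_type_rss(hits, 60), seq)
        assert segs == []

    def test_three_frame_translations_match_hand_translation(self, rng):
        from igloci.rss_scan import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS

        core = "GGTACAACTGGAACGAC"
        up = (
            reverse_complement(NONAMER_CONSENSUS)
            + random_dna(rng, 12)
            + reverse_complement(HEPTAMER_CONSENSUS)
        )
        dn = HEPTAMER_CONSENSUS + random_dna(rng, 12) + NONAMER_CONSENSUS
        seq = GenomicSequence("s", "AA" + up + core + dn + "AA")
        hits = scan_rss(seq, default_spec("IGH", "D"), "both")
        (seg,) = call_d_segments(pair_d_type_rss(hits, 40), seq)
        # hand translation of GGTACAACTGGAACGAC in frames 0/1/2
        assert seg.core_translations == ("GTTGT", "VQLER", "YNWND")


class TestJCalling:
    def _sim_j(self, seed=5, **kw):
        base = dict(n_v=0, n_d=0, n_j=4, c_isotypes=(), include_delta_remnant=False)
        base.update(kw)
        return generate_locus(SimConfig(seed=seed, **base))

    def test_intact_j_with_motif_is_functional(self):
        seq, truth = self._sim_j()
        hits = scan_rss(seq, default_spec("IGH", "J"), "both")
        segs = call_j_segments(seq, hits, "IGH")
        assert {(s.coding.start, s.coding.end) for s in segs} == {
            (t.interval.start, t.interval.end) for t in truth
        }
        assert all(s.status == "functional" for s in segs)

    def test_trp_to_stop_lesion_gives_pseudogene(self):
        # the classic J pseudogenization: the conserved Trp codon becomes a stop
        seq, truth = self._sim_j(seed=6, j_pseudo_indices=(1,))
        hits = scan_rss(seq, default_spec("IGH", "J"), "both")
        segs = call_j_segments(seq, hits, "IGH")
        by_start = {s.coding.start: s for s in segs}
        for t in truth:
            s = by_start[t.interval.start]
            assert s.status == t.status
            if t.status == "pseudogene":
                assert s.defects == [IN_FRAME_STOP]

    def test_candidate_without_motif_is_not_called(self, rng):
        from igloci.rss_scan import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS

        rss = (
            reverse_complement(NONAMER_CONSENSUS)
            + random_dna(rng, 23)
            + reverse_complement(HEPTAMER_CONSENSUS)
        )
        # downstream of the RSS: pure A/C (no Trp/Phe codon, no GT donor)
        seq = GenomicSequence("s", "TT" + rss + "ACCACCACCACCACCACCACCACC" * 3)
        hits = scan_rss(seq, default_spec("IGH", "J"), "both")
        assert call_j_segments(seq, hits, "IGH") == []

    def test_j_overlapping_v_is_suppressed(self):
        seq, _ = _sim_v(seed=7, n_v=3)
        v_segs = _call_v(seq)
        j_hits = scan_rss(seq, default_spec("IGH", "J"), "both")
        j_segs = call_j_segments(seq, j_hits, "IGH")
        kept = suppress_j_over_v(v_segs, j_segs)
        assert kept == []  # every J candidate here reads a V backwards


class TestInvariantsAndNaming:
    def test_status_partition_is_exhaustive(self):
        seq, _ = _sim_v(seed=8, n_v=12, pseudogene_fraction=0.3, truncated_fraction=0.1)
        segs = _call_v(seq)
        statuses = {"functional", "pseudogene", "truncated"}
        assert all(s.status in statuses for s in segs)
        counts = {st: sum(1 for s in segs if s.status == st) for st in statuses}
        assert sum(counts.values()) == len(segs)

    def test_naming_requires_families(self):
        seg = GeneSegment(
            kind="V",
            locus="IGH",
            coding=Interval("s", 0, 300, "+"),
            strand="+",
            rss=(_dummy_hit(),),
            status="functional",
        )
        with pytest.raises(ValueError):
            name_segments([seg])

    def test_position_numbering_from_constant_proximal_end(self):
        # three V segments left->right; constant region at the right end,
        # so the rightmost (most proximal) is position 1
        segs = []
        for k, start in enumerate((100, 700, 1300)):
            segs.append(
                GeneSegment(
                    kind="V",
                    locus="IGH",
                    coding=Interval("s", start, start + 300, "+"),
                    strand="+" if k != 1 else "-",
                    rss=(_dummy_hit(start + 300),),
                    status="pseudogene" if k == 0 else "functional",
                    defects=[IN_FRAME_STOP] if k == 0 else [],
                    family=2,
                )
            )
        name_segments(segs, c_proximal_end="right")
        assert [s.name for s in segs] == ["V2-3p", "V2-2", "V2-1"]

    def test_j_named_in_positional_order(self):
        segs = [
            GeneSegment(
                kind="J",
                locus="IGH",
                coding=Interval("s", start, start + 48, "+"),
                strand="+",
                rss=(_dummy_hit(start - 39),),
                status="functional",
            )
            for start in (500, 100)
        ]
        name_segments(segs)
        assert {s.coding.start: s.name for s in segs} == {100: "J1", 500: "J2"}

    def test_calls_are_deterministic(self):
        seq, _ = _sim_v(seed=9)
        a = [(s.coding, s.status, tuple(s.defects)) for s in _call_v(seq)]
        b = [(s.coding, s.status, tuple(s.defects)) for s in _call_v(seq)]
        assert a == b


def _dummy_hit(start: int = 300):
    from igloci.rss_scan import RssHit

    return RssHit(
        location=Interval("s", start, start + 39, "+"),
        orientation="heptamer_first",
        heptamer_mismatches=0,
        nonamer_mismatches=0,
        spacer_length=23,
        heptamer_interval=Interval("s", start, start + 7, "+"),
        nonamer_interval=Interval("s", start + 30, start + 39, "+"),
    )
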