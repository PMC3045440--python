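import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import oracle_scan
from conftest import random_dna
from igloci.rss_scan import (
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    RssHit,
    RssSpec,
    coding_span,
    default_spec,
    hamming,
    pair_d_type_rss,
    scan_rss,
)
from igloci.seqio import GenomicSequence, extract, reverse_complement

STRICT = RssSpec(
    spacer_lengths=frozenset({12}),
    max_total_mismatch=0,
    max_heptamer_mismatch=0,
    max_nonamer_mismatch=0,
)


def _keys(hits):
    return {
        (h.location.start, h.location.end, h.orientation, h.spacer_length,
         h.heptamer_mismatches, h.nonamer_mismatches)
        for h in hits
    }


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("CACAGTG", "CACAGTG", 0),
            # the two heptamer consensi differ at a single position (4th)
            ("CACAGTG", "CACTGTG", 1),
            ("NNN", "AAA", 3),  # N always mismatches
            ("NNN", "NNN", 3),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_unequal_lengths_is_usage_error(self):
        with pytest.raises(ValueError):
            hamming("ACGT", "ACG")

    @given(st.text("ACGT", min_size=1, max_size=30))
    def test_self_distance_zero(self, s):
        assert hamming(s, s) == 0


class TestSpecValidation:
    def test_spacer_bounds(self):
        with pytest.raises(ValueError):
            RssSpec(spacer_lengths=frozenset({7}))

    def test_total_budget_bounded_by_elements(self):
        with pytest.raises(ValueError):
            RssSpec(max_total_mismatch=9, max_heptamer_mismatch=2, max_nonamer_mismatch=4)

    def test_twelve_twentythree_rule_defaults(self):
        assert default_spec("IGH", "V").spacer_lengths == frozenset({23})
        assert default_spec("IGH", "D").spacer_lengths == frozenset({12})
        assert default_spec("IGK", "V").spacer_lengths == frozenset({12})
        assert default_spec("IGL", "J").spacer_lengths == frozenset({12})
        assert default_spec("IGH", "D", relaxed_d=True) == default_spec(
            "IGH", "D"
        ).relaxed_spacers(1) or default_spec("IGH", "D", relaxed_d=True).spacer_lengths == frozenset(
            {10, 11, 12, 13}
        )


class TestScan:
    def test_planted_exact_motif(self):
        seq = GenomicSequence(
            "s", HEPTAMER_CONSENSUS + "T" * 12 + NONAMER_CONSENSUS
        )
        hits = scan_rss(seq, STRICT, "both")
        assert len(hits) == 1
        h = hits[0]
        assert h.orientation == "heptamer_first"
        assert h.spacer_length == 12
        assert (h.location.start, h.location.end) == (0, 28)

    def test_ten_bp_spacer_needs_configured_spacer_set(self, rng):
        # a 10-spacer RSS (the DH76-style deviation) is invisible to a
        # {12}-only spec but found once 10 is allowed
        core = HEPTAMER_CONSENSUS + random_dna(rng, 10) + NONAMER_CONSENSUS
        seq = GenomicSequence("s", "TTTT" + core + "TTTT")
        only12 = STRICT
        with10 = RssSpec(
            spacer_lengths=frozenset({10, 12}),
            max_total_mismatch=0,
            max_heptamer_mismatch=0,
            max_nonamer_mismatch=0,
        )
        assert all(h.spacer_length != 10 for h in scan_rss(seq, only12, "both"))
        assert any(h.spacer_length == 10 for h in scan_rss(seq, with10, "both"))

    def test_minus_strand_rss_appears_nonamer_first(self):
        plus_unit = HEPTAMER_CONSENSUS + "T" * 12 + NONAMER_CONSENSUS
        seq = GenomicSequence("s", reverse_complement(plus_unit))
        hits = scan_rss(seq, STRICT, "both")
        assert [h.orientation for h in hits] == ["nonamer_first"]

    def test_short_sequence_returns_empty(self):
        assert scan_rss(GenomicSequence("s", "ACGT"), STRICT, "both") == []

    @pytest.mark.parametrize("spec_seed", range(3))
    def test_oracle_equivalence_on_random_sequences(self, spec_seed, rng):
        spec = _random_spec(np.random.default_rng(500 + spec_seed))
        for _ in range(5):
            seq = GenomicSequence("r", random_dna(rng, 3000))
            assert _keys(scan_rss(seq, spec, "both")) == oracle_scan(seq.residues, spec)

    def test_strand_symmetry(self, rng):
        spec = default_spec("IGH", "V")
        seq = GenomicSequence("r", random_dna(rng, 8000))
        rc = GenomicSequence("r", reverse_complement(seq.residues))
        fwd = _keys(scan_rss(seq, spec, "both"))
        n = seq.length
        mirrored = {
            (n - e, n - s, "nonamer_first" if o == "heptamer_first" else "heptamer_first",
             sp, hm, nm)
            for (s, e, o, sp, hm, nm) in _keys(scan_rss(rc, spec, "both"))
        }
        assert fwd == mirrored

    def test_monotone_in_budgets_and_spacers(self, rng):
        seq = GenomicSequence("r", random_dna(rng, 6000))
        tight = RssSpec(
            spacer_lengths=frozenset({12}),
            max_total_mismatch=2,
            max_heptamer_mismatch=1,
            max_nonamer_mismatch=2,
        )
        relaxed = RssSpec(
            spacer_lengths=frozenset({11, 12, 13}),
            max_total_mismatch=5,
            max_heptamer_mismatch=2,
            max_nonamer_mismatch=4,
        )
        assert _keys(scan_rss(seq, tight, "both")) <= _keys(scan_rss(seq, relaxed, "both"))

    def test_every_hit_reverifies_with_hamming(self, random_scaffold):
        spec = default_spec("IGH", "V")
        for h in scan_rss(random_scaffold, spec, "both"):
            hept = random_scaffold.residues[
                h.heptamer_interval.start : h.heptamer_interval.end
            ]
            non = random_scaffold.residues[
                h.nonamer_interval.start : h.nonamer_interval.end
            ]
            if h.orientation == "heptamer_first":
                assert hamming(hept, spec.heptamer_consensus) == h.heptamer_mismatches
                assert hamming(non, spec.nonamer_consensus) == h.nonamer_mismatches
            else:
                assert (
                    hamming(hept, reverse_complement(spec.heptamer_consensus))
                    == h.heptamer_mismatches
                )
                assert (
                    hamming(non, reverse_complement(spec.nonamer_consensus))
                    == h.nonamer_mismatches
                )

    def test_hits_sorted_deterministically(self, random_scaffold):
        spec = default_spec("IGH", "V").relaxed_spacers(1)
        hits = scan_rss(random_scaffold, spec, "both")
        keys = [(h.location.start, h.orientation, h.spacer_length) for h in hits]
        assert keys == sorted(keys)


def _random_spec(rng: np.random.Generator) -> RssSpec:
    hm = int(rng.integers(0, 3))
    nm = int(rng.integers(0, 5))
    spacers = frozenset(
        int(s) for s in rng.choice([10, 11, 12, 22, 23, 24], size=rng.integers(1, 3), replace=False)
    )
    required = frozenset({0, 1, 2}) if rng.random() < 0.7 else frozenset()
    return RssSpec(
        spacer_lengths=spacers,
        max_total_mismatch=min(hm + nm, int(rng.integers(0, hm + nm + 1)) + 1),
        max_heptamer_mismatch=hm,
        max_nonamer_mismatch=nm,
        required_exact_positions=required,
    )


class TestDPairing:
    def _facing(self, rng, core_len):
        up = (
            reverse_complement(NONAMER_CONSENSUS)
            + random_dna(rng, 12)
            + reverse_complement(HEPTAMER_CONSENSUS)
        )
        dn = HEPTAMER_CONSENSUS + random_dna(rng, 12) + NONAMER_CONSENSUS
        return up + random_dna(rng, core_len) + dn

    def test_facing_pair_around_core(self, rng):
        seq = GenomicSequence("s", "T" * 10 + self._facing(rng, 20) + "T" * 10)
        hits = scan_rss(seq, STRICT, "both")
        pairs = pair_d_type_rss(hits, max_coding_gap=40)
        assert len(pairs) == 1
        s, e = coding_span(pairs[0])
        assert e - s == 20

    def test_gap_bound_excludes_distant_pair(self, rng):
        seq = GenomicSequence("s", "T" * 10 + self._facing(rng, 60) + "T" * 10)
        hits = scan_rss(seq, STRICT, "both")
        assert pair_d_type_rss(hits, max_coding_gap=40) == []

    def test_simulated_cluster_recovered_with_exact_spans(self, rng):
        parts, expected = [], []
        pos = 0
        for _ in range(10):
            filler = random_dna(rng, int(rng.integers(60, 120)))
            core_len = int(rng.integers(10, 38))
            unit = self._facing(rng, core_len)
            parts += [filler, unit]
            start = pos + len(filler) + 28
            expected.append((start, start + core_len))
            pos += len(filler) + len(unit)
        seq = GenomicSequence("s", "".join(parts))
        hits = scan_rss(seq, STRICT, "both")
        pairs = pair_d_type_rss(hits, max_coding_gap=40)
        assert [coding_span(p) for p in pairs] == expected
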