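"""Fuzzy scanning for recombination signal sequences (RSSs).

An RSS is a conserved heptamer, a spacer of roughly 12 or 23 bp, and a
nonamer. V(D)J recombination joins a 12-spacer RSS to a 23-spacer RSS
(the 12/23 rule), so each segment kind in each locus carries a
characteristic spacer. Real RSSs diverge from the consensus, so matching
is by Hamming distance under per-element and total mismatch budgets, with
a handful of heptamer positions (the CAC adjacent to the coding region)
required to match exactly by default.

The scanner is a pure detector: it reports every hit, including
overlapping ones; suppression and interpretation belong to the segment
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import GenomicSequence, Interval, reverse_complement

HEPTAMER_CONSENSUS = "CACAGTG"  # coding-proximal reading
NONAMER_CONSENSUS = "ACAAAAACC"  # coding-proximal reading

HEPTAMER_FIRST = "heptamer_first"
NONAMER_FIRST = "nonamer_first"


@dataclass(frozen=True)
class RssSpec:
    """Consensus motifs, allowed spacers and mismatch budgets for one scan."""

    heptamer_consensus: str = HEPTAMER_CONSENSUS
    nonamer_consensus: str = NONAMER_CONSENSUS
    spacer_lengths: frozenset[int] = frozenset({23})
    max_total_mismatch: int = 5
    max_heptamer_mismatch: int = 2
    max_nonamer_mismatch: int = 4
    required_exact_positions: frozenset[int] = frozenset({0, 1, 2})

    def __post_init__(self) -> None:
        if len(self.heptamer_consensus) != 7 or len(self.nonamer_consensus) != 9:
            raise ValueError("heptamer must be 7 bp and nonamer 9 bp")
        if not self.spacer_lengths:
            raise ValueError("spacer_lengths must be non-empty")
        if any(not (8 <= s <= 30) for s in self.spacer_lengths):
            raise ValueError("spacer lengths must lie in [8, 30]")
        if not (0 <= self.max_heptamer_mismatch <= 7):
            raise ValueError("max_heptamer_mismatch must be in [0, 7]")
        if not (0 <= self.max_nonamer_mismatch <= 9):
            raise ValueError("max_nonamer_mismatch must be in [0, 9]")
        if self.max_total_mismatch > self.max_heptamer_mismatch + self.max_nonamer_mismatch:
            raise ValueError("max_total_mismatch exceeds the sum of element budgets")
        if any(not (0 <= p <= 6) for p in self.required_exact_positions):
            raise ValueError("required_exact_positions must be heptamer positions 0..6")

    def relaxed_spacers(self, tolerance: int = 1) -> "RssSpec":
        """Widen every allowed spacer by +/- tolerance (clipped to [8, 30])."""
        widened = {
            t
            for s in self.spacer_lengths
            for t in range(s - tolerance, s + tolerance + 1)
            if 8 <= t <= 30
        }
        return replace(self, spacer_lengths=frozenset(widened))


#: 12/23-rule defaults per (locus, segment kind).
DEFAULT_SPACERS: dict[tuple[str, str], frozenset[int]] = {
    ("IGH", "V"): frozenset({23}),
    ("IGH", "D"): frozenset({12}),
    ("IGH", "J"): frozenset({23}),
    ("IGK", "V"): frozenset({12}),
    ("IGK", "J"): frozenset({23}),
    ("IGL", "V"): frozenset({23}),
    ("IGL", "J"): frozenset({12}),
}

#: Relaxed D spacer set acknowledging real deviations (e.g. 10-bp D spacers).
RELAXED_D_SPACERS = frozenset({10, 11, 12, 13})


def default_spec(locus: str, kind: str, *, relaxed_d: bool = False) -> RssSpec:
    """The default RSS spec for a segment kind in a locus (12/23 rule)."""
    try:
        spacers = DEFAULT_SPACERS[(locus, kind)]
    except KeyError:
        raise ValueError(f"no default RSS spec for locus {locus!r}, kind {kind!r}") from None
    if relaxed_d and (locus, kind) == ("IGH", "D"):
        spacers = RELAXED_D_SPACERS
    return RssSpec(spacer_lengths=spacers)


@dataclass(frozen=True)
class RssHit:
    """One located heptamer-spacer-nonamer match (plus-strand coordinates).

    ``heptamer_first`` hits read heptamer->nonamer left to right (a
    plus-strand RSS); ``nonamer_first`` hits are the reverse-complement
    pattern (a minus-strand RSS as seen in plus coordinates).
    """

    location: Interval
    orientation: str
    heptamer_mismatches: int
    nonamer_mismatches: int
    spacer_length: int
    heptamer_interval: Interval
    nonamer_interval: Interval

    @property
    def total_mismatches(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches

    def key(self) -> tuple:
        """Identity tuple used for set comparisons against oracles."""
        return (
            self.location.seq_id,
            self.location.start,
            self.location.end,
            self.orientation,
            self.spacer_length,
            self.heptamer_mismatches,
            self.nonamer_mismatches,
        )

    def reflect(self, seq_length: int) -> "RssHit":
        """Mirror through the sequence end (orientation flips)."""
        return RssHit(
            location=self.location.reflect(seq_length),
            orientation=NONAMER_FIRST if self.orientation == HEPTAMER_FIRST else HEPTAMER_FIRST,
            heptamer_mismatches=self.heptamer_mismatches,
            nonamer_mismatches=self.nonamer_mismatches,
            spacer_length=self.spacer_length,
            heptamer_interval=self.heptamer_interval.reflect(seq_length),
            nonamer_interval=self.nonamer_interval.reflect(seq_length),
        )


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths ({len(a)} != {len(b)})")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _mismatch_profile(arr: np.ndarray, motif: str) -> np.ndarray:
    """Hamming distance of every window of len(motif) against the motif."""
    m = len(motif)
    n = arr.size - m + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    nbyte = ord("N")
    for k, ch in enumerate(motif.encode()):
        win = arr[k : k + n]
        mm += (win != ch) | (win == nbyte)
    return mm


def _exact_mask(arr: np.ndarray, motif: str, positions: frozenset[int], width: int) -> np.ndarray:
    n = arr.size - width + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n, dtype=bool)
    for p in positions:
        ok &= arr[p : p + n] == ord(motif[p])
    return ok


def scan_rss(
    seq: GenomicSequence,
    spec: RssSpec,
    strand: str = "both",
) -> list[RssHit]:
    """Find every RSS matching the spec on the requested strand(s).

    ``strand='+'`` reports heptamer_first hits, ``'-'`` the nonamer_first
    (reverse-complement pattern) hits, ``'both'`` both. Hits come back
    sorted by start coordinate, ties broken by (orientation, spacer).
    """
    if strand not in ("+", "-", "both"):
        raise ValueError(f"strand must be '+', '-' or 'both', got {strand!r}")
    arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    hits: list[RssHit] = []
    if strand in ("+", "both"):
        hits.extend(_scan_oriented(seq.id, arr, spec, HEPTAMER_FIRST))
    if strand in ("-", "both"):
        hits.extend(_scan_oriented(seq.id, arr, spec, NONAMER_FIRST))
    hits.sort(key=lambda h: (h.location.start, h.orientation, h.spacer_length))
    return hits


def _scan_oriented(seq_id: str, arr: np.ndarray, spec: RssSpec, orientation: str) -> list[RssHit]:
    if orientation == HEPTAMER_FIRST:
        first_motif, second_motif = spec.heptamer_consensus, spec.nonamer_consensus
        first_is_hept = True
        exact_motif, exact_positions = first_motif, spec.required_exact_positions
    else:
        # plus-strand reading of a minus-strand RSS: rc(nonamer) .. rc(heptamer)
        first_motif = reverse_complement(spec.nonamer_consensus)
        second_motif = reverse_complement(spec.heptamer_consensus)
        first_is_hept = False
        exact_motif = second_motif
        exact_positions = frozenset(6 - p for p in spec.required_exact_positions)

    len1, len2 = len(first_motif), len(second_motif)
    mm1 = _mismatch_profile(arr, first_motif)
    mm2 = _mismatch_profile(arr, second_motif)
    if first_is_hept:
        hept_mm, non_mm = mm1, mm2
        exact_ok = _exact_mask(arr, exact_motif, exact_positions, len1)
    else:
        non_mm, hept_mm = mm1, mm2
        exact_ok = _exact_mask(arr, exact_motif, exact_positions, len2)

    hits: list[RssHit] = []
    for spacer in sorted(spec.spacer_lengths):
        span = len1 + spacer + len2
        n = arr.size - span + 1
        if n <= 0:
            continue
        a = mm1[:n]
        b = mm2[len1 + spacer : len1 + spacer + n]
        if first_is_hept:
            hm, nm = a, b
            ok = exact_ok[:n]
        else:
            nm, hm = a, b
            ok = exact_ok[len1 + spacer : len1 + spacer + n]
        valid = (
            (hm <= spec.max_heptamer_mismatch)
            & (nm <= spec.max_nonamer_mismatch)
            & (hm + nm <= spec.max_total_mismatch)
            & ok
        )
        for i in np.nonzero(valid)[0]:
            i = int(i)
            if first_is_hept:
                hept_iv = Interval(seq_id, i, i + 7, "+")
                non_iv = Interval(seq_id, i + 7 + spacer, i + 7 + spacer + 9, "+")
                loc_strand = "+"
            else:
                non_iv = Interval(seq_id, i, i + 9, "-")
                hept_iv = Interval(seq_id, i + 9 + spacer, i + 9 + spacer + 7, "-")
                loc_strand = "-"
            hits.append(
                RssHit(
                    location=Interval(seq_id, i, i + span, loc_strand),
                    orientation=HEPTAMER_FIRST if first_is_hept else NONAMER_FIRST,
                    heptamer_mismatches=int(hm[i]),
                    nonamer_mismatches=int(nm[i]),
                    spacer_length=spacer,
                    heptamer_interval=hept_iv,
                    nonamer_interval=non_iv,
                )
            )
    return hits


def pair_d_type_rss(
    hits: list[RssHit], max_coding_gap: int = 40
) -> list[tuple[RssHit, RssHit]]:
    """Pair facing RSSs that could flank a D coding core.

    A D segment sits between an upstream nonamer_first RSS (heptamer on
    its right, facing the core) and a downstream heptamer_first RSS
    (heptamer on its left). Returns every pair whose enclosed span is at
    most ``max_coding_gap`` bp, sorted by coding-region start; one hit may
    appear in several pairs (the segment caller resolves sharing).
    """
    ups = sorted(
        (h for h in hits if h.orientation == NONAMER_FIRST),
        key=lambda h: h.heptamer_interval.end,
    )
    downs = sorted(
        (h for h in hits if h.orientation == HEPTAMER_FIRST),
        key=lambda h: h.heptamer_interval.start,
    )
    pairs: list[tuple[RssHit, RssHit]] = []
    for up in ups:
        core_start = up.heptamer_interval.end
        for dn in downs:
            gap = dn.heptamer_interval.start - core_start
            if gap < 0:
                continue
            if gap > max_coding_gap:
                break
            pairs.append((up, dn))
    pairs.sort(key=lambda p: (p[0].heptamer_interval.end, p[1].heptamer_interval.start))
    return pairs


def coding_span(pair: tuple[RssHit, RssHit]) -> tuple[int, int]:
    """The candidate D coding span (0-based half-open) enclosed by a pair."""
    up, dn = pair
    return up.heptamer_interval.end, dn.heptamer_interval.start
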