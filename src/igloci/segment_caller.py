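"""Calling and classifying V, D and J gene segments from RSS evidence.

A V segment is a leader exon (ATG-initiated, spliced with a GT donor),
an intron ending in an AG acceptor, a ~300 bp V exon carrying the
conserved framework landmarks (first Cys, FR2 Trp, second Cys), and a
downstream RSS whose heptamer abuts the exon 3' end. A D segment is a
short core flanked on both sides by RSSs whose heptamers face the core.
A J segment is an RSS-anchored coding region containing the J motif
(W-G-x-G for heavy chains, F-G-x-G for light) followed by a GT splice
donor.

Each called segment is classified as functional, pseudogene (in-frame
stop, frameshift, missing leader, missing conserved residue) or truncated
(an RSS-anchored fragment of roughly 200 bp). Because permissive RSS
budgets produce chance hits in background DNA, a candidate that is not
functional-grade on its own evidence must additionally be supported by
homology (>= ``homology_gate`` percent global identity) to another called
V segment — mirroring how pseudogenes are recognized in practice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .family_cluster import AlignParams, _aligner, global_percent_identity
from .rss_scan import HEPTAMER_FIRST, NONAMER_FIRST, RssHit, coding_span
from .seqio import GenomicSequence, Interval, reverse_complement, translate

logger = logging.getLogger(__name__)

FUNCTIONAL = "functional"
PSEUDOGENE = "pseudogene"
TRUNCATED = "truncated"

IN_FRAME_STOP = "in_frame_stop"
FRAMESHIFT = "frameshift"
MISSING_LEADER = "missing_leader"
MISSING_CONSERVED_RESIDUE = "missing_conserved_residue"
PARTIAL_SEQUENCE = "partial_sequence"

_J_MOTIFS = {"heavy": r"[W\*]G.G", "light": r"[F\*]G.G"}


@dataclass
class CallerConfig:
    """Geometry and thresholds for segment calling (all config-exposed).

    No standard reference fixes this geometry, so the defaults encode
    typical mammalian Ig gene architecture.
    """

    v_exon_bounds: tuple[int, int] = (270, 320)
    leader_window: int = 400  # bp upstream of the V exon searched for a leader
    leader_orf_bounds: tuple[int, int] = (30, 90)  # leader coding nt, ATG..donor
    min_intron: int = 60
    truncation_bound: int | None = None  # default 0.8 * lower V exon bound
    truncated_len: int = 200  # assumed length of an RSS-anchored fragment
    truncated_max_rss_mismatch: int = 2
    homology_gate: float = 65.0  # percent identity support for non-functional calls
    cys1_window: tuple[int, int] = (15, 30)  # 1-based aa windows for landmarks
    trp_window: tuple[int, int] = (30, 48)
    cys2_window: tuple[int, int] = (80, 108)
    d_len_bounds: tuple[int, int] = (8, 40)
    j_len_bounds: tuple[int, int] = (30, 70)
    j_donor_window: int = 30

    @property
    def truncation_cutoff(self) -> int:
        if self.truncation_bound is not None:
            return self.truncation_bound
        return int(0.8 * self.v_exon_bounds[0])


@dataclass
class GeneSegment:
    """A called V, D or J germline gene segment."""

    kind: str  # V, D, J
    locus: str  # IGH, IGK, IGL
    coding: Interval
    strand: str
    rss: tuple[RssHit, ...]
    status: str
    defects: list[str] = field(default_factory=list)
    leader: Interval | None = None
    name: str = ""
    family: int | None = None
    core_translations: tuple[str, str, str] | None = None  # D only

    def __post_init__(self) -> None:
        expected_rss = 2 if self.kind == "D" else 1
        if len(self.rss) != expected_rss:
            raise ValueError(
                f"{self.kind} segment must reference {expected_rss} RSS hit(s), "
                f"got {len(self.rss)}"
            )
        if self.status == PSEUDOGENE and not self.defects:
            raise ValueError("pseudogene status requires at least one defect")
        if self.status == FUNCTIONAL and self.defects:
            raise ValueError("functional status requires an empty defect list")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _landmarks_ok(aa: str, cfg: CallerConfig) -> bool:
    def present(residue: str, window: tuple[int, int]) -> bool:
        lo, hi = window
        return residue in aa[lo - 1 : hi]

    return (
        present("C", cfg.cys1_window)
        and present("W", cfg.trp_window)
        and present("C", cfg.cys2_window)
    )


def _prototype_frameshift(exon: str, prototype: str, params: AlignParams | None = None) -> bool:
    """True when aligning exon to a family prototype needs a gap of length % 3 != 0."""
    aligner = _aligner(params or AlignParams())
    alignment = aligner.align(exon, prototype)[0]
    for row in (str(alignment[0]), str(alignment[1])):
        inner = row.strip("-")
        for m in re.finditer(r"-+", inner):
            if (m.end() - m.start()) % 3 != 0:
                return True
    return False


def classify_functionality(
    coding_length: int,
    translated_exon: str,
    leader_found: bool,
    cfg: CallerConfig,
    exon_seq: str | None = None,
    prototype: str | None = None,
) -> tuple[str, list[str]]:
    """Assign (status, defects) to a V exon candidate.

    Truncated if the RSS-anchored coding region is shorter than the
    truncation cutoff; else pseudogene on any of in-frame stop, frameshift
    (length mod 3, plus optional gapped comparison to a family prototype),
    missing leader, or missing conserved landmark; else functional. All
    triggered defects are recorded.
    """
    if coding_length < cfg.truncation_cutoff:
        return TRUNCATED, [PARTIAL_SEQUENCE]
    defects: list[str] = []
    if "*" in translated_exon:
        defects.append(IN_FRAME_STOP)
    frameshift = coding_length % 3 != 0
    if not frameshift and prototype is not None and exon_seq is not None:
        frameshift = _prototype_frameshift(exon_seq, prototype)
    if frameshift:
        defects.append(FRAMESHIFT)
    if not leader_found:
        defects.append(MISSING_LEADER)
    if not _landmarks_ok(translated_exon, cfg):
        defects.append(MISSING_CONSERVED_RESIDUE)
    return (PSEUDOGENE, defects) if defects else (FUNCTIONAL, [])


# ---------------------------------------------------------------------------
# V segments
# ---------------------------------------------------------------------------

@dataclass
class _VDraft:
    coding: Interval  # plus-strand coordinates on the original scaffold
    strand: str
    hit: RssHit
    exon_seq: str  # reading direction
    status: str
    defects: list[str]
    leader: Interval | None
    orf_len: int


def find_leader(residues: str, exon_start: int, cfg: CallerConfig) -> tuple[int, int] | None:
    """Locate a leader exon upstream of a V exon start (local coordinates).

    Looks for an ATG-initiated stop-free stretch of a configurable length
    ending at a GT splice donor, with at least ``min_intron`` bp of intron
    before the exon's AG acceptor. Returns (start, end) of the leader
    coding stretch, or None. The rightmost viable ATG wins (ties broken by
    the shortest leader), which keeps the search deterministic.
    """
    lo = max(0, exon_start - cfg.leader_window)
    c_min, c_max = cfg.leader_orf_bounds
    for a in range(exon_start - cfg.min_intron - c_min - 2, lo - 1, -1):
        if residues[a : a + 3] != "ATG":
            continue
        for c in range(c_min, c_max + 1, 3):
            donor = a + c
            if donor + 2 + cfg.min_intron > exon_start:
                break
            if residues[donor : donor + 2] != "GT":
                continue
            if "*" in translate(residues[a : a + c]):
                continue
            return (a, donor)
    return None


def _orf_len(aa: str) -> int:
    stop = aa.find("*")
    return 3 * (len(aa) if stop == -1 else stop)


def _build_v_drafts_oriented(
    seq_id: str,
    residues: str,
    hits: list[RssHit],
    cfg: CallerConfig,
) -> list[tuple[RssHit, int, int, str, str, list[str], tuple[int, int] | None, int]]:
    """Drafts in local coordinates: (hit, start, end, exon, status, defects, leader, orf)."""
    v_min, v_max = cfg.v_exon_bounds
    out = []
    for hit in hits:
        end = hit.heptamer_interval.start
        exon_start = None
        for length in range(v_max, v_min - 1, -1):
            s = end - length
            if s >= 2 and residues[s - 2 : s] == "AG":
                exon_start = s
                break
        if exon_start is not None:
            exon = residues[exon_start:end]
            leader = find_leader(residues, exon_start, cfg)
            aa = translate(exon)
            status, defects = classify_functionality(
                len(exon), aa, leader is not None, cfg
            )
            out.append((hit, exon_start, end, exon, status, defects, leader, _orf_len(aa)))
        else:
            # RSS-anchored fragment with no acceptor in range: truncated
            # candidate, admitted only on a near-perfect RSS.
            if hit.total_mismatches > cfg.truncated_max_rss_mismatch:
                logger.debug("dropped V candidate at %d: no acceptor, weak RSS", end)
                continue
            s = end - cfg.truncated_len
            if s < 0:
                continue
            exon = residues[s:end]
            out.append(
                (hit, s, end, exon, TRUNCATED, [PARTIAL_SEQUENCE], None, _orf_len(translate(exon)))
            )
    return out


def call_v_segments(
    seq: GenomicSequence,
    hits: list[RssHit],
    locus: str,
    cfg: CallerConfig | None = None,
) -> list[GeneSegment]:
    """Call V segments on both strands from V-type RSS hits.

    Plus-strand V segments anchor at heptamer_first hits; minus-strand
    ones at nonamer_first hits (the scan is repeated on the reverse
    complement and coordinates mapped back, so the two strands are treated
    identically).
    """
    cfg = cfg or CallerConfig()
    n = seq.length
    residues = seq.residues
    drafts: list[_VDraft] = []

    plus_hits = [h for h in hits if h.orientation == HEPTAMER_FIRST]
    for hit, s, e, exon, status, defects, leader, orf in _build_v_drafts_oriented(
        seq.id, residues, plus_hits, cfg
    ):
        leader_iv = Interval(seq.id, leader[0], leader[1], "+") if leader else None
        drafts.append(
            _VDraft(Interval(seq.id, s, e, "+"), "+", hit, exon, status, defects, leader_iv, orf)
        )

    rc = reverse_complement(residues)
    minus_hits = [h.reflect(n) for h in hits if h.orientation == NONAMER_FIRST]
    for hit_rc, s, e, exon, status, defects, leader, orf in _build_v_drafts_oriented(
        seq.id, rc, minus_hits, cfg
    ):
        coding = Interval(seq.id, n - e, n - s, "-")
        leader_iv = (
            Interval(seq.id, n - leader[1], n - leader[0], "-") if leader else None
        )
        drafts.append(
            _VDraft(coding, "-", hit_rc.reflect(n), exon, status, defects, leader_iv, orf)
        )

    accepted = _gate_and_resolve(drafts, cfg)
    segments = [
        GeneSegment(
            kind="V",
            locus=locus,
            coding=d.coding,
            strand=d.strand,
            rss=(d.hit,),
            status=d.status,
            defects=list(d.defects),
            leader=d.leader,
        )
        for d in accepted
    ]
    segments.sort(key=lambda g: g.coding.start)
    return segments


def _gate_and_resolve(drafts: list[_VDraft], cfg: CallerConfig) -> list[_VDraft]:
    """Homology gate for non-functional drafts, then overlap suppression."""
    tier_a = [d for d in drafts if d.status == FUNCTIONAL]
    pending = [d for d in drafts if d.status != FUNCTIONAL]
    supported: list[_VDraft] = []
    for d in pending:
        # support must come from a *different* locus position: an
        # overlapping draft of the same region is trivially identical
        others = [
            e
            for e in tier_a + pending
            if e is not d and d.coding.intersection_length(e.coding) == 0
        ]
        for e in others:
            try:
                pid = global_percent_identity(d.exon_seq, e.exon_seq)
            except ValueError:
                continue
            if pid >= cfg.homology_gate:
                supported.append(d)
                break
        else:
            logger.debug(
                "dropped %s V candidate at %d: no homology support",
                d.status,
                d.coding.start,
            )
    candidates = tier_a + supported
    candidates.sort(
        key=lambda d: (d.hit.total_mismatches, -d.orf_len, d.coding.start)
    )
    kept: list[_VDraft] = []
    for d in candidates:
        if not any(d.coding.intersection_length(k.coding) > 0 for k in kept):
            kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# D segments
# ---------------------------------------------------------------------------

def call_d_segments(
    pairs: list[tuple[RssHit, RssHit]],
    seq: GenomicSequence,
    locus: str = "IGH",
    cfg: CallerConfig | None = None,
) -> list[GeneSegment]:
    """Turn facing-RSS pairs into D segments.

    Pairs whose coding span lies outside the configured length bounds are
    rejected; pairs sharing an RSS hit are resolved by fewest total
    mismatches, then shorter span, then leftmost. D cores are read in all
    three frames, so ORF-based functional/pseudogene classification does
    not apply: a D is functional unless its core contains an N (then
    truncated). Strand is reported '+' by convention: a facing-RSS unit is
    its own reverse complement at motif level, so strand is unknowable
    from RSS evidence.
    """
    cfg = cfg or CallerConfig()
    lo, hi = cfg.d_len_bounds
    candidates = []
    for up, dn in pairs:
        s, e = coding_span((up, dn))
        if lo <= e - s <= hi:
            candidates.append((up, dn, s, e))
    candidates.sort(
        key=lambda c: (c[0].total_mismatches + c[1].total_mismatches, c[3] - c[2], c[2])
    )
    used: set[tuple] = set()
    segments: list[GeneSegment] = []
    for up, dn, s, e in candidates:
        if up.key() in used or dn.key() in used:
            continue
        used.add(up.key())
        used.add(dn.key())
        core = seq.residues[s:e]
        status = TRUNCATED if "N" in core else FUNCTIONAL
        segments.append(
            GeneSegment(
                kind="D",
                locus=locus,
                coding=Interval(seq.id, s, e, "+"),
                strand="+",
                rss=(up, dn),
                status=status,
                defects=[PARTIAL_SEQUENCE] if status == TRUNCATED else [],
                core_translations=tuple(translate(core, f) for f in (0, 1, 2)),
            )
        )
    segments.sort(key=lambda g: g.coding.start)
    return segments


# ---------------------------------------------------------------------------
# J segments
# ---------------------------------------------------------------------------

def _call_j_oriented(
    residues: str, hits: list[RssHit], chain: str, cfg: CallerConfig
) -> list[tuple[RssHit, int, int, bool]]:
    """J candidates in local coordinates: (hit, start, end, stop_lesion)."""
    pattern = re.compile(_J_MOTIFS[chain])
    j_min, j_max = cfg.j_len_bounds
    out = []
    for hit in hits:
        start = hit.heptamer_interval.end
        window = residues[start : start + j_max]
        best: tuple[int, bool] | None = None
        for f in (0, 1, 2):
            aa = translate(window[f:])
            for m in pattern.finditer(aa):
                motif_nt_end = f + 3 * m.end()
                donor_region = residues[
                    start + motif_nt_end : start + motif_nt_end + cfg.j_donor_window
                ]
                g = donor_region.find("GT")
                if g == -1:
                    continue
                coding_len = motif_nt_end + g
                if not (j_min <= coding_len <= j_max):
                    continue
                is_stop = aa[m.start()] == "*"
                # the J motif sits near the coding 3' end: rightmost wins
                if best is None or motif_nt_end > best[0]:
                    best = (coding_len, is_stop)
        if best is not None:
            out.append((hit, start, start + best[0], best[1]))
    return out


def call_j_segments(
    seq: GenomicSequence,
    hits: list[RssHit],
    locus: str,
    cfg: CallerConfig | None = None,
) -> list[GeneSegment]:
    """Call J segments on both strands from J-type RSS hits.

    Plus-strand J segments anchor at nonamer_first hits (heptamer abutting
    the coding 5' end); the translated candidate must contain the J motif
    (or the motif with its first residue replaced by a stop, which marks
    the pseudogenizing Trp->stop lesion) followed by a GT splice donor.
    """
    cfg = cfg or CallerConfig()
    chain = "heavy" if locus == "IGH" else "light"
    n = seq.length
    segments: list[GeneSegment] = []

    plus_hits = [h for h in hits if h.orientation == NONAMER_FIRST]
    for hit, s, e, stop in _call_j_oriented(seq.residues, plus_hits, chain, cfg):
        segments.append(_make_j(seq.id, locus, hit, s, e, "+", stop))

    rc = reverse_complement(seq.residues)
    minus_hits = [h.reflect(n) for h in hits if h.orientation == HEPTAMER_FIRST]
    for hit_rc, s, e, stop in _call_j_oriented(rc, minus_hits, chain, cfg):
        segments.append(
            _make_j(seq.id, locus, hit_rc.reflect(n), n - e, n - s, "-", stop)
        )
    segments.sort(key=lambda g: g.coding.start)
    return segments


def _make_j(
    seq_id: str, locus: str, hit: RssHit, s: int, e: int, strand: str, stop: bool
) -> GeneSegment:
    return GeneSegment(
        kind="J",
        locus=locus,
        coding=Interval(seq_id, s, e, strand),
        strand=strand,
        rss=(hit,),
        status=PSEUDOGENE if stop else FUNCTIONAL,
        defects=[IN_FRAME_STOP] if stop else [],
    )


def suppress_j_over_v(
    v_segments: list[GeneSegment], j_segments: list[GeneSegment]
) -> list[GeneSegment]:
    """Drop J calls that overlap a called V segment or its RSS.

    An RSS motif pair is strand-symmetric (the reverse complement of
    heptamer-spacer-nonamer is again nonamer-spacer-heptamer), so every V
    RSS is also a perfect J-type anchor on the opposite strand, reading
    the V exon backwards. Where a V segment is called, that reading is
    spurious.
    """
    blocked = [g.coding for g in v_segments] + [
        h.location for g in v_segments for h in g.rss
    ]
    kept = []
    for j in j_segments:
        if any(j.coding.intersection_length(iv) > 0 for iv in blocked):
            logger.debug("suppressed J call at %d overlapping a V segment", j.coding.start)
            continue
        kept.append(j)
    return kept


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def name_segments(
    segments: list[GeneSegment], c_proximal_end: str = "right"
) -> list[GeneSegment]:
    """Assign locus-map names in place and return the segments.

    V and D are named ``<kind><family>-<position>`` with position counted
    1..n from the constant-region-proximal end of the locus; pseudogenes
    get suffix ``p`` and truncated segments ``t``. J segments are named
    ``J<index>`` in positional order. V and D require prior family
    assignment.
    """
    if c_proximal_end not in ("left", "right"):
        raise ValueError("c_proximal_end must be 'left' or 'right'")
    for kind in ("V", "D"):
        group = sorted(
            (g for g in segments if g.kind == kind), key=lambda g: g.coding.start
        )
        if any(g.family is None for g in group):
            raise ValueError(f"{kind} segments must have families before naming")
        m = len(group)
        for idx, g in enumerate(group):
            pos = m - idx if c_proximal_end == "right" else idx + 1
            suffix = {PSEUDOGENE: "p", TRUNCATED: "t"}.get(g.status, "")
            g.name = f"{kind}{g.family}-{pos}{suffix}"
    js = sorted((g for g in segments if g.kind == "J"), key=lambda g: g.coding.start)
    for idx, g in enumerate(js, start=1):
        g.name = f"J{idx}"
    return segments
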