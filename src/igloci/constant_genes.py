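"""Constant-region (C) gene discovery by translated homology.

Constant-region genes (mu, gamma, ..., C-kappa, C-lambda) are located by
Smith-Waterman alignment of reference domain proteins against all six
translation frames of the scaffold, the hits are chained into per-isotype
exon models (colinear on one strand, introns within bounds), and each
exon is screened for pseudogenizing defects: in-frame premature stops and
frameshifting indels, reported at exon-relative nucleotide positions.
A gene reduced to one surviving domain with no assembly-gap excuse for
the missing roster is a remnant (the decayed single-domain relic
pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GenomicSequence, Interval, extract, n_runs, translate
from .templates import IsotypeTemplate

logger = logging.getLogger(__name__)

INTACT = "intact"
PARTIAL = "partial"
PSEUDOEXON_CONTAINING = "pseudoexon-containing"
REMNANT = "remnant"

PREMATURE_STOP = "premature_stop"
FRAMESHIFT_INSERTION = "frameshift_insertion"
FRAMESHIFT_DELETION = "frameshift_deletion"
MISSING_DUE_TO_GAP = "missing_due_to_gap"


@dataclass(frozen=True)
class SearchParams:
    """Translated-search scoring (BLOSUM62, affine gaps)."""

    gap_open: float = -11.0
    gap_extend: float = -1.0
    min_score_per_residue: float = 2.0  # raw-score threshold = this * query length
    max_hits_per_frame: int = 8


@dataclass(frozen=True)
class TranslatedHit:
    """One local protein-vs-translated-DNA hit, codon-resolved."""

    interval: Interval  # genomic, plus coordinates; strand = reading direction
    frame: int  # 0..2 on the reading strand
    score: float
    percent_identity: float
    query_start: int  # aa coordinates on the query template
    query_end: int
    query_length: int


def _protein_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def translated_search(
    seq: GenomicSequence,
    query_protein: str,
    params: SearchParams | None = None,
) -> list[TranslatedHit]:
    """Smith-Waterman of a protein query against all six frames.

    Multiple occurrences per frame are found by iterative masking of
    already-reported regions; overlapping same-frame hits therefore
    resolve to the highest-scoring one. Queries shorter than 30 residues
    are refused (too little signal over six frames).
    """
    if len(query_protein) < 30:
        raise ValueError("translated_search requires a query of >= 30 residues")
    params = params or SearchParams()
    aligner = _protein_aligner(params)
    threshold = params.min_score_per_residue * len(query_protein)
    n = seq.length
    hits: list[TranslatedHit] = []
    for strand in ("+", "-"):
        for frame in (0, 1, 2):
            prot = translate(seq.residues, frame, strand).replace("*", "X")
            if len(prot) < 10:
                continue
            masked = list(prot)
            for _ in range(params.max_hits_per_frame):
                alignments = aligner.align("".join(masked), query_protein)
                if len(alignments) == 0:
                    break
                aln = alignments[0]
                if aln.score < threshold:
                    break
                p_blocks, q_blocks = aln.aligned
                p_start, p_end = int(p_blocks[0][0]), int(p_blocks[-1][1])
                q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
                matches = columns = 0
                for (ps, pe), (qs, qe) in zip(p_blocks, q_blocks):
                    for k in range(pe - ps):
                        columns += 1
                        if masked[ps + k] == query_protein[qs + k]:
                            matches += 1
                # internal gap columns count too
                gap_cols = (p_end - p_start) + (q_end - q_start) - 2 * columns
                denom = columns + gap_cols
                pid = 100.0 * matches / denom if denom else 0.0
                nt_lo = frame + 3 * p_start
                nt_hi = frame + 3 * p_end
                if strand == "+":
                    iv = Interval(seq.id, nt_lo, nt_hi, "+")
                else:
                    iv = Interval(seq.id, n - nt_hi, n - nt_lo, "-")
                hits.append(
                    TranslatedHit(
                        interval=iv,
                        frame=frame,
                        score=float(aln.score),
                        percent_identity=pid,
                        query_start=q_start,
                        query_end=q_end,
                        query_length=len(query_protein),
                    )
                )
                for k in range(p_start, p_end):
                    masked[k] = "X"
    hits.sort(key=lambda h: (-h.score, h.interval.start))
    return hits


# ---------------------------------------------------------------------------
# defect detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Defect:
    """A pseudogenizing lesion; positions are exon-relative, 1-based nt."""

    kind: str
    start: int
    end: int


@dataclass
class GeneConfig:
    intron_bounds: tuple[int, int] = (80, 10_000)
    premature_tail_frac: float = 0.05  # stops in the final 5% are not 'premature'
    frameshift_min_match: float = 0.9  # suffix identity confirming a frame switch
    gap_run_min: int = 20  # N-run length counted as an assembly gap


def _match_frac(a: str, b: str) -> float:
    m = min(len(a), len(b))
    if m == 0:
        return 0.0
    return sum(1 for x, y in zip(a[:m], b[:m]) if x == y) / m


def detect_exon_defects(
    seq: GenomicSequence,
    exon: Interval,
    template_protein: str,
    cfg: GeneConfig | None = None,
) -> list[Defect]:
    """Screen one anchored exon for premature stops and frameshifts.

    The exon interval must be template-anchored (reading frame 0 at its
    reading-direction start). A frameshift is recognized when the
    template's suffix re-aligns in a shifted frame: +1 for a single-base
    insertion, -1 for a deletion; the reported position is the first
    nucleotide of the disrupted codon.
    """
    cfg = cfg or GeneConfig()
    t = template_protein
    exp = 3 * len(t) + 4  # slack covers one inserted base

    def window_seq(shift: int) -> str:
        # shift < 0 extends the reading-direction start upstream
        if exon.strand == "+":
            lo = max(exon.start + shift, 0)
            return extract(seq, Interval(exon.seq_id, lo, min(lo + exp, seq.length), "+"))
        hi = min(exon.end - shift, seq.length)
        return extract(seq, Interval(exon.seq_id, max(hi - exp, 0), hi, "-"))

    # the anchoring alignment may have skipped an upstream indel; pick the
    # start shift whose initial translation actually matches the template
    best_shift, best_frac = 0, -1.0
    for shift in (0, -1, 1):
        frac = _match_frac(translate(window_seq(shift))[:12], t[:12])
        if frac > best_frac + 1e-9:
            best_shift, best_frac = shift, frac
    e = window_seq(best_shift)
    p0 = translate(e)[: len(t)]

    defects: list[Defect] = []
    fs_codon: int | None = None
    for i in range(min(len(p0), len(t))):
        if p0[i] == t[i] or p0[i] == "*":
            continue
        # a lone substitution leaves the frame-0 suffix largely intact
        if _match_frac(p0[i + 1 :], t[i + 1 :]) >= 0.5:
            continue
        ins = translate(e[3 * i + 1 :])[: len(t) - i]
        if len(ins) >= 5 and _match_frac(ins, t[i:]) >= cfg.frameshift_min_match:
            defects.append(Defect(FRAMESHIFT_INSERTION, 3 * i + 1, 3 * i + 1))
            fs_codon = i
            break
        dele = translate(e[3 * i + 2 :])[: len(t) - i - 1]
        if len(dele) >= 5 and _match_frac(dele, t[i + 1 :]) >= cfg.frameshift_min_match:
            defects.append(Defect(FRAMESHIFT_DELETION, 3 * i + 1, 3 * i + 1))
            fs_codon = i
            break
        break  # diverged without a recognizable frame switch

    premature_limit = int(len(t) * (1.0 - cfg.premature_tail_frac))
    stops = [
        Defect(PREMATURE_STOP, 3 * i + 1, 3 * i + 3)
        for i, aa in enumerate(p0)
        if aa == "*" and i < premature_limit and (fs_codon is None or i < fs_codon)
    ]
    return sorted(stops + defects, key=lambda d: d.start)


# ---------------------------------------------------------------------------
# exon chaining
# ---------------------------------------------------------------------------

@dataclass
class ConstantGeneModel:
    """An isotype gene as an ordered exon chain with defect annotations."""

    isotype: str
    exons: list[tuple[str, Interval]]  # (role, interval) in reading order
    strand: str
    status: str
    exon_defects: dict[str, list[Defect | str]] = field(default_factory=dict)
    name: str = ""

    @property
    def span(self) -> Interval:
        lo = min(iv.start for _, iv in self.exons)
        hi = max(iv.end for _, iv in self.exons)
        return Interval(self.exons[0][1].seq_id, lo, hi, self.strand)


def _anchor_plus(hit_iv: Interval, q_start: int, q_end: int, q_len: int, n: int) -> Interval:
    """Template-anchored exon interval in (possibly reflected) plus space."""
    start = max(0, hit_iv.start - 3 * q_start)
    end = min(n, hit_iv.end + 3 * (q_len - q_end))
    return Interval(hit_iv.seq_id, start, end, "+")


def chain_exons(
    hits_by_role: dict[str, list[TranslatedHit]],
    template: IsotypeTemplate,
    seq: GenomicSequence,
    cfg: GeneConfig | None = None,
) -> list[ConstantGeneModel]:
    """Chain per-role hits into one or more gene models for an isotype.

    Hits are grouped by strand, split into clusters wherever the gap
    exceeds the intron upper bound, and within each cluster the
    best-scoring colinear chain (one hit per roster role, introns within
    bounds) is selected by dynamic programming. Missing roster members
    whose expected location overlaps an N-run are annotated
    missing_due_to_gap (status partial); a single surviving exon with no
    gap excuse makes a remnant.
    """
    cfg = cfg or GeneConfig()
    n = seq.length
    roster = template.roles
    role_idx = {r: k for k, r in enumerate(roster)}
    gaps = n_runs(seq, min_len=cfg.gap_run_min)

    models: list[ConstantGeneModel] = []
    for strand in ("+", "-"):
        per_role: dict[str, list[tuple[Interval, float, int]]] = {}
        for role, hits in hits_by_role.items():
            for h in hits:
                if h.interval.strand != strand:
                    continue
                iv = h.interval if strand == "+" else h.interval.reflect(n)
                anchored = _anchor_plus(iv, h.query_start, h.query_end, h.query_length, n)
                per_role.setdefault(role, []).append((anchored, h.score, h.query_start))
        # a frameshifted exon aligns as two frame-split pieces: merge
        # overlapping same-role hits, anchoring on the piece that starts
        # earliest in the template (it fixes the exon's reading frame)
        cands = []
        for role, items in per_role.items():
            items.sort(key=lambda t: t[0].start)
            merged: list[list] = []
            for iv, score, q_start in items:
                if merged and iv.start < merged[-1][0].end:
                    prev_iv, prev_score, prev_q = merged[-1]
                    anchor = prev_iv if prev_q <= q_start else iv
                    merged[-1] = [
                        Interval(iv.seq_id, anchor.start, max(prev_iv.end, iv.end), "+"),
                        prev_score + score,
                        min(prev_q, q_start),
                    ]
                else:
                    merged.append([iv, score, q_start])
            cands.extend((role, iv, score) for iv, score, _ in merged)
        if not cands:
            continue
        cands.sort(key=lambda c: c[1].start)

        clusters: list[list[tuple[str, Interval, float]]] = []
        for c in cands:
            if clusters and c[1].start - max(iv.end for _, iv, _ in clusters[-1]) <= cfg.intron_bounds[1]:
                clusters[-1].append(c)
            else:
                clusters.append([c])

        for cluster in clusters:
            chain = _best_chain(cluster, role_idx, cfg)
            if not chain:
                continue
            models.append(
                _finalize_model(chain, template, seq, strand, n, gaps, cfg)
            )
    models.sort(key=lambda m: m.span.start)
    return models


def _best_chain(
    cluster: list[tuple[str, Interval, float]],
    role_idx: dict[str, int],
    cfg: GeneConfig,
) -> list[tuple[str, Interval]]:
    """Highest-total-score colinear chain (roster order, intron bounds)."""
    lo, hi = cfg.intron_bounds
    items = sorted(cluster, key=lambda c: (c[1].start, role_idx[c[0]]))
    best_score = [c[2] for c in items]
    prev = [-1] * len(items)
    for j in range(len(items)):
        rj, ivj, sj = items[j]
        for i in range(j):
            ri, ivi, _ = items[i]
            if role_idx[ri] >= role_idx[rj]:
                continue
            intron = ivj.start - ivi.end
            if not (lo <= intron <= hi):
                continue
            if best_score[i] + sj > best_score[j]:
                best_score[j] = best_score[i] + sj
                prev[j] = i
    j = max(range(len(items)), key=lambda k: best_score[k])
    chain: list[tuple[str, Interval]] = []
    while j != -1:
        chain.append((items[j][0], items[j][1]))
        j = prev[j]
    chain.reverse()
    # one hit per role: DP already enforces strictly increasing role indices
    return chain


def _finalize_model(
    chain: list[tuple[str, Interval]],
    template: IsotypeTemplate,
    seq: GenomicSequence,
    strand: str,
    n: int,
    gaps: list[Interval],
    cfg: GeneConfig,
) -> ConstantGeneModel:
    roster = template.roles
    found_roles = [r for r, _ in chain]
    exons: list[tuple[str, Interval]] = []
    exon_defects: dict[str, list[Defect | str]] = {}
    for role, iv_plusspace in chain:
        iv = iv_plusspace if strand == "+" else iv_plusspace.reflect(n)
        iv = Interval(iv.seq_id, iv.start, iv.end, strand)
        exons.append((role, iv))
        defects = detect_exon_defects(seq, iv, template.protein(role), cfg)
        if defects:
            exon_defects[role] = list(defects)

    missing = [r for r in roster if r not in found_roles]
    gap_excused: list[str] = []
    for role in missing:
        span = _expected_span(role, roster, chain, template, n)
        if span is not None and any(span.intersection_length(g) > 0 for g in gaps):
            exon_defects[role] = [MISSING_DUE_TO_GAP]
            gap_excused.append(role)

    has_defects = any(
        isinstance(d, Defect) for ds in exon_defects.values() for d in ds
    )
    if not missing:
        status = PSEUDOEXON_CONTAINING if has_defects else INTACT
    elif len(found_roles) == 1 and not gap_excused:
        status = REMNANT
    else:
        status = PARTIAL

    # report exons in reading order
    exons.sort(key=lambda e: e[1].start, reverse=(strand == "-"))
    return ConstantGeneModel(
        isotype=template.isotype,
        exons=exons,
        strand=strand,
        status=status,
        exon_defects=exon_defects,
    )


def _expected_span(
    role: str,
    roster: tuple[str, ...],
    chain: list[tuple[str, Interval]],
    template: IsotypeTemplate,
    n: int,
) -> Interval | None:
    """Rough genomic span where a missing exon was expected (plus space of the chain)."""
    idx = roster.index(role)
    found = {roster.index(r): iv for r, iv in chain}
    left = [i for i in found if i < idx]
    right = [i for i in found if i > idx]
    exon_len = 3 * len(template.protein(role))
    if left and right:
        lo = found[max(left)].end
        hi = found[min(right)].start
    elif right:
        hi = found[min(right)].start
        lo = max(0, hi - exon_len - 10_000)
    elif left:
        lo = found[max(left)].end
        hi = min(n, lo + exon_len + 10_000)
    else:
        return None
    if lo >= hi:
        return None
    seq_id = chain[0][1].seq_id
    return Interval(seq_id, lo, hi)


def find_constant_genes(
    seq: GenomicSequence,
    templates: dict[str, IsotypeTemplate],
    search_params: SearchParams | None = None,
    gene_cfg: GeneConfig | None = None,
) -> list[ConstantGeneModel]:
    """Search and chain all isotype templates against one scaffold."""
    models: list[ConstantGeneModel] = []
    for template in templates.values():
        hits_by_role = {
            role: translated_search(seq, protein, search_params)
            for role, protein in template.exons
        }
        if any(hits_by_role.values()):
            models.extend(chain_exons(hits_by_role, template, seq, gene_cfg))
    models.sort(key=lambda m: m.span.start)
    # number duplicate isotypes in genomic order (gamma1, gamma2, ...)
    counts: dict[str, int] = {}
    for m in models:
        counts[m.isotype] = counts.get(m.isotype, 0) + 1
    seen: dict[str, int] = {}
    for m in models:
        if counts[m.isotype] > 1:
            seen[m.isotype] = seen.get(m.isotype, 0) + 1
            m.name = f"{m.isotype}{seen[m.isotype]}"
        else:
            m.name = m.isotype
    return models
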