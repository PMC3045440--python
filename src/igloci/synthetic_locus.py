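"""Ground-truth immunoglobulin locus simulator.

Generates translocon-organized loci (V cluster -> D cluster -> J cluster
-> constant genes) with every feature the annotation pipeline must find:
leader exons with canonical splice sites, V exons carrying the conserved
framework landmarks, RSS flanks with the locus-correct spacers, D cores
flanked by facing 12-spacer RSSs, J segments with the J motif and splice
donor, pentamer-repeat switch arrays upstream of designated constant
genes, multi-exon constant genes reverse-translated from protein
templates, and planted lesions (in-frame stops, single-base indels,
leader ablation, ~200 bp 5' truncations, premature stops and single-A
insertions in constant exons). Every planted fact is recorded as a
TruthRecord so calls can be scored for precision/recall.

Ground-truth boundaries are kept well-defined by construction: intron 3'
ends are pyrimidine tracts (the polypyrimidine tract; no decoy AG
acceptors), truncated fragments sit behind an AG-free buffer, switch
arrays carry pentamer-free flanks, and J tails contain no GT or decoy J
motif before the true donor. Without these guarantees a planted boundary
would be ambiguous even to a perfect annotator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rss_scan import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS
from .seqio import GenomicSequence, Interval, reverse_complement
from .templates import IsotypeTemplate, default_templates

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = {"TAA", "TAG", "TGA"}

IN_FRAME_STOP = "in_frame_stop"
FRAMESHIFT = "frameshift"
MISSING_LEADER = "missing_leader"
PARTIAL_SEQUENCE = "partial_sequence"

#: most-used mammalian codon per amino acid (deterministic reverse translation)
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_V_LANDMARK_CODONS = {21: "TGC", 35: "TGG", 95: "TGT"}  # 0-based codon index
_J_MOTIF_NT = {"IGH": "TGGGGCCAAGGC", "IGK": "TTTGGCCAAGGC", "IGL": "TTTGGCCAAGGC"}
_J_TAIL = "ACCAACTCC"  # Thr-Asn-Ser; contains no GT before the true donor


class SimConfigError(ValueError):
    """Raised for contradictory simulator configuration."""


@dataclass
class SimConfig:
    """Composition of a simulated locus. Defaults are the study conditions."""

    seed: int = 0
    locus: str = "IGH"
    scaffold_id: str = "sim_scaffold"
    n_v: int = 40
    n_d: int = 20
    n_j: int = 6
    n_v_families: int = 4
    prototype_divergence: float = 0.6  # per-site rate separating family prototypes
    within_family_divergence: float = 0.08
    pseudogene_fraction: float = 0.0
    truncated_fraction: float = 0.0
    pseudogene_lesion_mix: tuple[str, ...] = (IN_FRAME_STOP, FRAMESHIFT)
    minus_strand_v_fraction: float = 0.0
    j_pseudo_indices: tuple[int, ...] = ()  # J segments given the Trp->stop lesion
    v_exon_codons: int = 100
    leader_codon_bounds: tuple[int, int] = (11, 20)  # codons after the ATG
    intron_bounds: tuple[int, int] = (90, 150)
    d_core_bounds: tuple[int, int] = (10, 37)
    truncated_len_bounds: tuple[int, int] = (180, 220)
    c_isotypes: tuple[str, ...] = ("mu", "gamma", "gamma")
    include_delta_remnant: bool = True
    remnant_offset: int = 10_000  # bp downstream of the mu gene
    c_exon_defects: tuple[tuple[int, str, str], ...] = ()  # (gene idx, role, kind)
    switch_before: tuple[int, ...] | None = None  # C-gene indices; None = all
    switch_len: int = 2000
    c_intron_bounds: tuple[int, int] = (150, 400)
    c_spacing_bounds: tuple[int, int] = (9000, 11_000)
    switch_gap_bounds: tuple[int, int] = (800, 1500)
    intergenic_bounds: tuple[int, int] = (400, 1200)

    def __post_init__(self) -> None:
        for name in ("pseudogene_fraction", "truncated_fraction", "minus_strand_v_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.pseudogene_fraction + self.truncated_fraction > 1.0:
            raise SimConfigError("lesion fractions sum above 1")
        if self.locus != "IGH" and self.n_d != 0:
            raise SimConfigError("n_d must be 0 unless locus is IGH")
        if self.locus not in ("IGH", "IGK", "IGL"):
            raise SimConfigError(f"unknown locus {self.locus!r}")
        if 3 * self.v_exon_codons < max(k * 3 + 3 for k in _V_LANDMARK_CODONS):
            raise SimConfigError("v_exon_codons too small for the conserved landmarks")
        if self.truncated_len_bounds[0] >= 3 * self.v_exon_codons:
            raise SimConfigError("truncated fragments must be shorter than the V exon")


@dataclass
class TruthRecord:
    """One planted feature with every fact needed to score a call."""

    kind: str  # V, D, J, C, switch
    interval: Interval
    strand: str
    status: str
    lesions: list[str] = field(default_factory=list)
    family: int | None = None
    name: str = ""
    isotype: str | None = None
    exons: list[tuple[str, Interval]] | None = None
    defect_positions: list[tuple[str, str, int]] | None = None  # (role, kind, nt pos)


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.integers(0, 4, n).astype(np.uint8).choose(BASES).tobytes().decode()


def _random_codons(rng: np.random.Generator, k: int) -> str:
    out = []
    while len(out) < k:
        c = _random_dna(rng, 3)
        if c not in STOPS:
            out.append(c)
    return "".join(out)


def _ag_free_dna(rng: np.random.Generator, n: int) -> str:
    s = _random_dna(rng, n)
    while "AG" in s:
        s = s.replace("AG", "AC")
    return s


def _pentamer_free(rng: np.random.Generator, n: int, pentamers: tuple[str, ...]) -> str:
    motifs = set(pentamers) | {reverse_complement(p) for p in pentamers}
    s = _random_dna(rng, n)
    changed = True
    while changed:
        changed = False
        for m in motifs:
            i = s.find(m)
            if i != -1:
                mid = i + len(m) // 2
                repl = "A" if s[mid] != "A" else "C"
                s = s[:mid] + repl + s[mid + 1 :]
                changed = True
    return s


def _j_motif_free(rng: np.random.Generator, n: int) -> str:
    """Random DNA with no J-motif decoy ([WF*]G.G in any frame)."""
    pattern = re.compile(r"[WF\*]G.G")
    from .seqio import translate

    s = _random_dna(rng, n)
    for _ in range(50):
        hit = None
        for f in (0, 1, 2):
            m = pattern.search(translate(s[f:]))
            if m:
                hit = (f, m.start())
                break
        if hit is None:
            return s
        f, a = hit
        pos = f + 3 * (a + 1)  # first base of the codon that must encode G
        repl = "C" if s[pos] != "C" else "T"
        s = s[:pos] + repl + s[pos + 1 :]
    return s


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation with the most-common codon per residue."""
    return "".join(PREFERRED_CODON[aa] for aa in protein)


def make_v_prototypes(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Family prototype exons: random codons with planted Cys/Trp/Cys landmarks."""
    raw = _random_codons(rng, cfg.v_exon_codons)
    base = [raw[i : i + 3] for i in range(0, len(raw), 3)]
    for idx, codon in _V_LANDMARK_CODONS.items():
        base[idx] = codon
    prototypes = ["".join(base)]
    for _ in range(cfg.n_v_families - 1):
        prototypes.append(
            _mutate_exon(rng, "".join(base), cfg.prototype_divergence)
        )
    return prototypes


def _mutate_exon(rng: np.random.Generator, exon: str, rate: float) -> str:
    """Per-site mutation preserving landmark codons and introducing no stops."""
    codons = [exon[i : i + 3] for i in range(0, len(exon), 3)]
    out = []
    for ci, codon in enumerate(codons):
        if ci in _V_LANDMARK_CODONS:
            out.append(codon)
            continue
        new = list(codon)
        for p in range(3):
            if rng.random() < rate:
                choices = [b for b in "ACGT" if b != new[p]]
                new[p] = choices[rng.integers(0, 3)]
        cand = "".join(new)
        out.append(codon if cand in STOPS else cand)
    return "".join(out)


def make_family_member(
    rng: np.random.Generator, prototype: str, divergence: float
) -> str:
    return _mutate_exon(rng, prototype, divergence)


# ---------------------------------------------------------------------------
# locus assembly
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, seq_id: str) -> None:
        self.seq_id = seq_id
        self.parts: list[str] = []
        self.pos = 0

    def emit(self, s: str) -> int:
        start = self.pos
        self.parts.append(s)
        self.pos += len(s)
        return start

    def sequence(self) -> GenomicSequence:
        return GenomicSequence(self.seq_id, "".join(self.parts))


def _plus_rss(rng: np.random.Generator, spacer: int) -> str:
    return HEPTAMER_CONSENSUS + _random_dna(rng, spacer) + NONAMER_CONSENSUS


def _minus_rss(rng: np.random.Generator, spacer: int) -> str:
    return (
        reverse_complement(NONAMER_CONSENSUS)
        + _random_dna(rng, spacer)
        + reverse_complement(HEPTAMER_CONSENSUS)
    )


def _v_spacer(locus: str) -> int:
    return 12 if locus == "IGK" else 23


def _j_spacer(locus: str) -> int:
    return 12 if locus == "IGL" else 23


def generate_locus(cfg: SimConfig) -> tuple[GenomicSequence, list[TruthRecord]]:
    """Build the scaffold and its truth table; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    b = _Builder(cfg.scaffold_id)
    truth: list[TruthRecord] = []

    def intergenic() -> None:
        b.emit(_random_dna(rng, int(rng.integers(*cfg.intergenic_bounds))))

    intergenic()

    # --- V cluster -------------------------------------------------------
    prototypes = make_v_prototypes(cfg, rng)
    n_pseudo = int(np.floor(cfg.pseudogene_fraction * cfg.n_v))
    n_trunc = int(np.floor(cfg.truncated_fraction * cfg.n_v))
    order = rng.permutation(cfg.n_v)
    pseudo_set = set(order[:n_pseudo].tolist())
    trunc_set = set(order[n_pseudo : n_pseudo + n_trunc].tolist())
    n_minus = int(np.floor(cfg.minus_strand_v_fraction * cfg.n_v))
    minus_set = set(rng.permutation(cfg.n_v)[:n_minus].tolist())

    lesion_cycle = 0
    for i in range(cfg.n_v):
        family = i % cfg.n_v_families + 1
        exon = make_family_member(rng, prototypes[family - 1], cfg.within_family_divergence)
        if i in trunc_set:
            frag_len = int(rng.integers(*cfg.truncated_len_bounds))
            unit, exon_off, exon_len = _truncated_v_unit(rng, cfg, exon, frag_len)
            status, lesions = "truncated", [PARTIAL_SEQUENCE]
            b.emit(_ag_free_dna(rng, 160))  # no decoy acceptors upstream
        else:
            lesions = []
            if i in pseudo_set:
                kind = cfg.pseudogene_lesion_mix[lesion_cycle % len(cfg.pseudogene_lesion_mix)]
                lesion_cycle += 1
                exon, extra = _apply_v_lesion(rng, exon, kind)
                lesions = [kind] + extra
            unit, exon_off, exon_len = _full_v_unit(
                rng, cfg, exon, ablate_leader=MISSING_LEADER in lesions
            )
            status = "pseudogene" if lesions else "functional"
        strand = "-" if i in minus_set else "+"
        if strand == "-":
            unit_start = b.emit(reverse_complement(unit))
            lo = unit_start + len(unit) - (exon_off + exon_len)
            hi = unit_start + len(unit) - exon_off
        else:
            unit_start = b.emit(unit)
            lo = unit_start + exon_off
            hi = unit_start + exon_off + exon_len
        truth.append(
            TruthRecord(
                kind="V",
                interval=Interval(cfg.scaffold_id, lo, hi, strand),
                strand=strand,
                status=status,
                lesions=lesions,
                family=family,
                name=f"simV{i + 1}",
            )
        )
        intergenic()

    # --- D cluster (heavy only) -----------------------------------------
    for i in range(cfg.n_d):
        core = _random_dna(rng, int(rng.integers(cfg.d_core_bounds[0], cfg.d_core_bounds[1] + 1)))
        up = _minus_rss(rng, 12)
        dn = _plus_rss(rng, 12)
        unit_start = b.emit(up + core + dn)
        lo = unit_start + len(up)
        truth.append(
            TruthRecord(
                kind="D",
                interval=Interval(cfg.scaffold_id, lo, lo + len(core), "+"),
                strand="+",
                status="functional",
                name=f"simD{i + 1}",
            )
        )
        intergenic()

    # --- J cluster --------------------------------------------------------
    motif = _J_MOTIF_NT[cfg.locus]
    for i in range(cfg.n_j):
        n_pre = int(rng.integers(3, 7))
        pre = _random_codons(rng, n_pre)
        this_motif = motif
        lesions = []
        status = "functional"
        if i in cfg.j_pseudo_indices:
            if not motif.startswith("TGG") and not motif.startswith("TTT"):
                raise SimConfigError("cannot plant a stop in this J motif")
            this_motif = "TGA" + motif[3:]
            lesions = [IN_FRAME_STOP]
            status = "pseudogene"
        coding = pre + this_motif + _J_TAIL
        unit = _minus_rss(rng, _j_spacer(cfg.locus)) + coding + "GT"
        unit_start = b.emit(unit)
        lo = unit_start + 16 + _j_spacer(cfg.locus)
        truth.append(
            TruthRecord(
                kind="J",
                interval=Interval(cfg.scaffold_id, lo, lo + len(coding), "+"),
                strand="+",
                status=status,
                lesions=lesions,
                name=f"simJ{i + 1}",
            )
        )
        b.emit(_j_motif_free(rng, 45))  # no decoy motif past the true donor
        intergenic()

    # --- constant region --------------------------------------------------
    templates = default_templates()
    switch_before = (
        set(range(len(cfg.c_isotypes))) if cfg.switch_before is None else set(cfg.switch_before)
    )
    if cfg.locus == "IGH":
        pentamers = ("GGGCT", "GAGCT")
        for gi, isotype in enumerate(cfg.c_isotypes):
            b.emit(_random_dna(rng, int(rng.integers(*cfg.c_spacing_bounds))))
            if gi in switch_before:
                # AAAAA junction buffers: no pentamer (or its reverse
                # complement) can span into or out of the array
                b.emit(_pentamer_free(rng, 55, pentamers) + "AAAAA")
                reps = cfg.switch_len // 5
                array = "".join(
                    np.asarray(pentamers, dtype=object)[rng.integers(0, 2, reps)]
                )
                a_start = b.emit(array)
                truth.append(
                    TruthRecord(
                        kind="switch",
                        interval=Interval(cfg.scaffold_id, a_start, a_start + len(array), "+"),
                        strand="+",
                        status="switch",
                        name=f"S{gi + 1}",
                        isotype=isotype,
                    )
                )
                b.emit("AAAAA" + _pentamer_free(rng, 55, pentamers))
                b.emit(_random_dna(rng, int(rng.integers(*cfg.switch_gap_bounds))))
            _emit_c_gene(b, rng, cfg, templates[isotype], gi, truth)
            if isotype == "mu" and cfg.include_delta_remnant:
                b.emit(_random_dna(rng, cfg.remnant_offset))
                remnant = reverse_translate(templates["delta"].protein("CH3"))
                r_start = b.emit(remnant)
                iv = Interval(cfg.scaffold_id, r_start, r_start + len(remnant), "+")
                truth.append(
                    TruthRecord(
                        kind="C",
                        interval=iv,
                        strand="+",
                        status="remnant",
                        name="delta_remnant",
                        isotype="delta",
                        exons=[("CH3", iv)],
                    )
                )
    else:
        iso = "c_kappa" if cfg.locus == "IGK" else "c_lambda"
        b.emit(_random_dna(rng, int(rng.integers(*cfg.c_spacing_bounds))))
        _emit_c_gene(b, rng, cfg, templates[iso], 0, truth)

    intergenic()
    return b.sequence(), truth


def _emit_c_gene(
    b: _Builder,
    rng: np.random.Generator,
    cfg: SimConfig,
    template: IsotypeTemplate,
    gene_index: int,
    truth: list[TruthRecord],
) -> None:
    defects_for_gene = [
        (role, kind) for gi, role, kind in cfg.c_exon_defects if gi == gene_index
    ]
    exon_ivs: list[tuple[str, Interval]] = []
    defect_positions: list[tuple[str, str, int]] = []
    for k, (role, protein) in enumerate(template.exons):
        dna = reverse_translate(protein)
        for d_role, d_kind in defects_for_gene:
            if d_role != role:
                continue
            n_codons = len(protein)
            if d_kind == "premature_stop":
                ci = int(rng.integers(int(0.2 * n_codons), int(0.6 * n_codons)))
                dna = dna[: 3 * ci] + "TAG" + dna[3 * ci + 3 :]
                defect_positions.append((role, "premature_stop", 3 * ci + 1))
            elif d_kind == "frameshift_insertion":
                # avoid Lys codons: A + AA re-encodes Lys, making the true
                # insertion point ambiguous even in principle
                while True:
                    ci = int(rng.integers(int(0.3 * n_codons), int(0.7 * n_codons)))
                    if protein[ci] != "K":
                        break
                dna = dna[: 3 * ci] + "A" + dna[3 * ci :]  # adenine at a codon start
                defect_positions.append((role, "frameshift_insertion", 3 * ci + 1))
            else:
                raise SimConfigError(f"unknown constant-exon defect {d_kind!r}")
        start = b.emit(dna)
        exon_ivs.append((role, Interval(cfg.scaffold_id, start, start + len(dna), "+")))
        if k < len(template.exons) - 1:
            b.emit(_random_dna(rng, int(rng.integers(*cfg.c_intron_bounds))))
    lo = exon_ivs[0][1].start
    hi = exon_ivs[-1][1].end
    truth.append(
        TruthRecord(
            kind="C",
            interval=Interval(cfg.scaffold_id, lo, hi, "+"),
            strand="+",
            status="pseudoexon-containing" if defect_positions else "intact",
            name=f"{template.isotype}{gene_index + 1}",
            isotype=template.isotype,
            exons=exon_ivs,
            defect_positions=defect_positions or None,
        )
    )


def _full_v_unit(
    rng: np.random.Generator, cfg: SimConfig, exon: str, ablate_leader: bool
) -> tuple[str, int, int]:
    """leader + GT + intron(+pyrimidine tract + AG) + exon + RSS."""
    k = int(rng.integers(*cfg.leader_codon_bounds))
    leader = "" if ablate_leader else "ATG" + _random_codons(rng, k) + "GT"
    intron_len = int(rng.integers(*cfg.intron_bounds))
    tract = "".join("CT"[rng.integers(0, 2)] for _ in range(50))
    intron = _random_dna(rng, max(intron_len - 52, 10)) + tract + "AG"
    rss = _plus_rss(rng, _v_spacer(cfg.locus))
    unit = leader + intron + exon + rss
    exon_off = len(leader) + len(intron)
    return unit, exon_off, len(exon)


def _truncated_v_unit(
    rng: np.random.Generator, cfg: SimConfig, exon: str, frag_len: int
) -> tuple[str, int, int]:
    frag = exon[-frag_len:]
    rss = _plus_rss(rng, _v_spacer(cfg.locus))
    return frag + rss, 0, len(frag)


def _apply_v_lesion(
    rng: np.random.Generator, exon: str, kind: str
) -> tuple[str, list[str]]:
    n_codons = len(exon) // 3
    if kind == IN_FRAME_STOP:
        while True:
            ci = int(rng.integers(5, n_codons - 5))
            if ci not in _V_LANDMARK_CODONS:
                break
        return exon[: 3 * ci] + "TAA" + exon[3 * ci + 3 :], []
    if kind == FRAMESHIFT:
        p = int(rng.integers(30, len(exon) - 30))
        return exon[:p] + exon[p + 1 :], []
    if kind == MISSING_LEADER:
        return exon, []
    raise SimConfigError(f"unknown V lesion kind {kind!r}")


# ---------------------------------------------------------------------------
# truth I/O and evaluation
# ---------------------------------------------------------------------------

def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "kind": t.kind,
                "seq_id": t.interval.seq_id,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.strand,
                "status": t.status,
                "lesions": ",".join(t.lesions),
                "family": "" if t.family is None else t.family,
                "name": t.name,
                "isotype": t.isotype or "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnnRecord:
    """A normalized annotation (call or truth) used for scoring."""

    kind: str
    interval: Interval
    strand: str
    status: str
    defects: list[str] = field(default_factory=list)
    name: str = ""


def normalize_calls(objs) -> list[AnnRecord]:
    """Coerce GeneSegments, ConstantGeneModels and SwitchRegions to AnnRecords."""
    from .constant_genes import ConstantGeneModel, Defect
    from .repeat_switch import SwitchRegion
    from .segment_caller import GeneSegment

    out: list[AnnRecord] = []
    for o in objs:
        if isinstance(o, GeneSegment):
            out.append(
                AnnRecord(o.kind, o.coding, o.strand, o.status, list(o.defects), o.name)
            )
        elif isinstance(o, ConstantGeneModel):
            defects = [
                d.kind if isinstance(d, Defect) else str(d)
                for ds in o.exon_defects.values()
                for d in ds
            ]
            out.append(AnnRecord("C", o.span, o.strand, o.status, defects, o.name))
        elif isinstance(o, SwitchRegion):
            out.append(
                AnnRecord("switch", o.location, o.location.strand, "switch", [], "")
            )
        elif isinstance(o, AnnRecord):
            out.append(o)
        else:
            raise TypeError(f"cannot normalize {type(o).__name__} for evaluation")
    return out


def truth_to_records(truth: list[TruthRecord]) -> list[AnnRecord]:
    return [
        AnnRecord(t.kind, t.interval, t.strand, t.status, list(t.lesions), t.name)
        for t in truth
    ]


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def evaluate_against_truth(
    calls,
    truth: list[TruthRecord],
    min_reciprocal_overlap: float = 0.8,
) -> dict[str, dict]:
    """Score calls against planted truth, per feature kind.

    A call matches a truth record when kinds agree and reciprocal overlap
    is at least the threshold; matching is one-to-one, greedy by highest
    overlap. Reports recall, precision, boundary-exact fraction among
    matches, a status-confusion table, and the fraction of matched
    records whose planted lesions all appear among the called defects.
    """
    call_recs = normalize_calls(calls)
    truth_recs = truth_to_records(truth)
    kinds = sorted({r.kind for r in truth_recs} | {r.kind for r in call_recs})
    report: dict[str, dict] = {}
    for kind in kinds:
        cs = [c for c in call_recs if c.kind == kind]
        ts = [t for t in truth_recs if t.kind == kind]
        pairs = []
        for ci, c in enumerate(cs):
            for ti, t in enumerate(ts):
                ov = _reciprocal_overlap(c.interval, t.interval)
                if ov >= min_reciprocal_overlap:
                    pairs.append((ov, ci, ti))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        used_c: set[int] = set()
        used_t: set[int] = set()
        matches: list[tuple[int, int]] = []
        for ov, ci, ti in pairs:
            if ci in used_c or ti in used_t:
                continue
            used_c.add(ci)
            used_t.add(ti)
            matches.append((ci, ti))

        boundary_exact = sum(
            1
            for ci, ti in matches
            if cs[ci].interval.start == ts[ti].interval.start
            and cs[ci].interval.end == ts[ti].interval.end
        )
        status_match = sum(1 for ci, ti in matches if cs[ci].status == ts[ti].status)
        lesions_ok = sum(
            1
            for ci, ti in matches
            if all(lesion in cs[ci].defects for lesion in ts[ti].defects)
        )
        confusion: dict[tuple[str, str], int] = {}
        for ci, ti in matches:
            key = (ts[ti].status, cs[ci].status)
            confusion[key] = confusion.get(key, 0) + 1
        for ti in range(len(ts)):
            if ti not in used_t:
                key = (ts[ti].status, "missed")
                confusion[key] = confusion.get(key, 0) + 1
        report[kind] = {
            "n_truth": len(ts),
            "n_calls": len(cs),
            "n_matched": len(matches),
            "recall": len(matches) / len(ts) if ts else 1.0,
            "precision": len(matches) / len(cs) if cs else 1.0,
            "boundary_exact": boundary_exact / len(matches) if matches else 1.0,
            "status_accuracy": status_match / len(matches) if matches else 1.0,
            "status_accuracy_over_truth": status_match / len(ts) if ts else 1.0,
            "lesion_recovery": lesions_ok / len(matches) if matches else 1.0,
            "confusion": confusion,
        }
    return report


def metrics_frame(report: dict[str, dict]) -> pd.DataFrame:
    rows = []
    for kind, m in sorted(report.items()):
        row = {"kind": kind}
        row.update({k: v for k, v in m.items() if k != "confusion"})
        rows.append(row)
    return pd.DataFrame(rows)
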