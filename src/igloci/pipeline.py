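"""End-to-end annotation: scan -> call -> classify -> families -> switch -> constants.

``annotate`` runs the whole pipeline over a FASTA of scaffolds and writes
the standard output set (GFF3, segment/family tables, switch BED,
constant-gene GFF3, a human-readable locus map, and a run log). All
stages are deterministic, so two runs on identical input produce
byte-identical outputs; the run log therefore carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .constant_genes import (
    ConstantGeneModel,
    Defect,
    GeneConfig,
    SearchParams,
    find_constant_genes,
)
from .family_cluster import Family, build_identity_matrix, cluster_families
from .repeat_switch import SwitchConfig, SwitchRegion, find_switch_regions
from .rss_scan import RssSpec, default_spec, pair_d_type_rss, scan_rss
from .segment_caller import (
    CallerConfig,
    GeneSegment,
    call_d_segments,
    call_j_segments,
    call_v_segments,
    name_segments,
    suppress_j_over_v,
)
from .seqio import (
    Feature,
    GenomicSequence,
    Interval,
    extract,
    n_runs,
    read_fasta,
    write_bed6,
    write_fasta,
    write_gff3,
)
from .templates import IsotypeTemplate, default_templates

logger = logging.getLogger(__name__)

_SEGMENT_FTYPE = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible annotation run (single TOML-able artifact)."""

    locus: str = "IGH"
    caller: CallerConfig = field(default_factory=CallerConfig)
    switch: SwitchConfig = field(default_factory=SwitchConfig)
    search: SearchParams = field(default_factory=SearchParams)
    gene: GeneConfig = field(default_factory=GeneConfig)
    family_threshold: float = 70.0
    relaxed_d_spacers: bool = False
    c_proximal_end: str = "right"
    gap_mark_min: int = 10_000  # N-runs above this get a locus-map gap mark
    seed: int = 0
    templates: dict[str, IsotypeTemplate] | None = None  # None = bundled synthetic

    def config_hash(self) -> str:
        payload = repr(
            {
                f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)
                if f.name != "templates"
            }
        )
        if self.templates:
            payload += repr(sorted((k, v.exons) for k, v in self.templates.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        sections = {
            "caller": CallerConfig,
            "switch": SwitchConfig,
            "search": SearchParams,
            "gene": GeneConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                fixed = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = sections[key](**fixed)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class AnnotationResult:
    segments: list[GeneSegment]
    families: list[Family]
    d_families: list[Family]
    switch_regions: list[SwitchRegion]
    constant_genes: list[ConstantGeneModel]
    scaffolds: list[GenomicSequence]
    stage_counts: dict[str, int] = field(default_factory=dict)


def annotate(
    fasta: str | Path | list[GenomicSequence],
    cfg: RunConfig | None = None,
    out_prefix: str | Path | None = None,
) -> AnnotationResult:
    """Annotate scaffolds; optionally write the full output set."""
    cfg = cfg or RunConfig()
    stage = "read"
    try:
        scaffolds = (
            fasta if isinstance(fasta, list) else read_fasta(fasta)
        )
        segments: list[GeneSegment] = []
        switch_regions: list[SwitchRegion] = []
        constant_genes: list[ConstantGeneModel] = []
        for seq in scaffolds:
            stage = "scan_rss"
            v_spec = default_spec(cfg.locus, "V")
            j_spec = default_spec(cfg.locus, "J")
            hits_by_spec: dict[RssSpec, list] = {}
            for spec in {v_spec, j_spec}:
                hits_by_spec[spec] = scan_rss(seq, spec, "both")

            stage = "call_v"
            scaffold_segments = call_v_segments(
                seq, hits_by_spec[v_spec], cfg.locus, cfg.caller
            )
            if cfg.locus == "IGH":
                stage = "call_d"
                d_spec = default_spec(cfg.locus, "D", relaxed_d=cfg.relaxed_d_spacers)
                d_hits = scan_rss(seq, d_spec, "both")
                pairs = pair_d_type_rss(d_hits, cfg.caller.d_len_bounds[1])
                scaffold_segments += call_d_segments(pairs, seq, cfg.locus, cfg.caller)
            stage = "call_j"
            j_segments = call_j_segments(seq, hits_by_spec[j_spec], cfg.locus, cfg.caller)
            v_here = [g for g in scaffold_segments if g.kind == "V"]
            scaffold_segments += suppress_j_over_v(v_here, j_segments)

            stage = "constant_genes"
            templates = cfg.templates if cfg.templates is not None else default_templates()
            constant_here = find_constant_genes(seq, templates, cfg.search, cfg.gene)
            constant_genes += constant_here

            if cfg.locus == "IGH":
                stage = "switch_regions"
                switch_regions += find_switch_regions(
                    seq,
                    cfg=cfg.switch,
                    constant_genes=[(m.name, m.span) for m in constant_here],
                )
            segments += scaffold_segments

        stage = "families"
        families = _assign_families(
            [g for g in segments if g.kind == "V"], scaffolds, cfg.family_threshold
        )
        d_families = _assign_families(
            [g for g in segments if g.kind == "D"], scaffolds, cfg.family_threshold
        )
        stage = "naming"
        name_segments(segments, cfg.c_proximal_end)

        counts = {
            "scaffolds": len(scaffolds),
            "V": sum(1 for g in segments if g.kind == "V"),
            "D": sum(1 for g in segments if g.kind == "D"),
            "J": sum(1 for g in segments if g.kind == "J"),
            "families": len(families),
            "switch_regions": len(switch_regions),
            "constant_genes": len(constant_genes),
        }
        result = AnnotationResult(
            segments=sorted(segments, key=lambda g: (g.coding.seq_id, g.coding.start)),
            families=families,
            d_families=d_families,
            switch_regions=switch_regions,
            constant_genes=constant_genes,
            scaffolds=scaffolds,
            stage_counts=counts,
        )
        if out_prefix is not None:
            stage = "write"
            write_outputs(result, cfg, out_prefix)
        return result
    except Exception as exc:
        if out_prefix is not None:
            _cleanup_outputs(out_prefix)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _assign_families(
    segments: list[GeneSegment],
    scaffolds: list[GenomicSequence],
    threshold: float,
) -> list[Family]:
    """Cluster segment coding sequences and write family ids onto segments."""
    if not segments:
        return []
    by_id = {s.id: s for s in scaffolds}
    keyed = {
        f"{g.coding.seq_id}:{g.coding.start}-{g.coding.end}{g.strand}": g
        for g in segments
    }
    ordered = sorted(keyed, key=lambda k: (keyed[k].coding.seq_id, keyed[k].coding.start))
    seqs = {k: extract(by_id[keyed[k].coding.seq_id], keyed[k].coding) for k in ordered}
    matrix = build_identity_matrix(seqs)
    families = cluster_families(matrix, threshold)
    for fam in families:
        for member in fam.members:
            keyed[member].family = fam.id
    return families


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

_OUTPUT_SUFFIXES = (
    ".gff3",
    ".segments.tsv",
    ".segments.fasta",
    ".families.tsv",
    ".switch.bed",
    ".constants.gff3",
    ".locus_map.txt",
    ".run.log",
    ".summary.tsv",
)


def _cleanup_outputs(out_prefix: str | Path) -> None:
    for suffix in _OUTPUT_SUFFIXES:
        p = Path(str(out_prefix) + suffix)
        if p.exists():
            p.unlink()


def segments_frame(segments: list[GeneSegment]) -> pd.DataFrame:
    rows = []
    for g in segments:
        rows.append(
            {
                "name": g.name,
                "kind": g.kind,
                "locus": g.locus,
                "seq_id": g.coding.seq_id,
                "start": g.coding.start,
                "end": g.coding.end,
                "strand": g.strand,
                "status": g.status,
                "defects": ",".join(g.defects),
                "family": "" if g.family is None else g.family,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "kind", "locus", "seq_id", "start", "end",
            "strand", "status", "defects", "family",
        ],
    )


def _segment_feature(g: GeneSegment) -> Feature:
    attrs = {
        "ID": f"{g.coding.seq_id}:{g.kind}:{g.coding.start}",
        "Name": g.name or f"{g.kind}@{g.coding.start}",
        "status": g.status,
    }
    if g.defects:
        attrs["defects"] = ",".join(g.defects)
    if g.family is not None:
        attrs["family"] = str(g.family)
    children = []
    for idx, hit in enumerate(g.rss):
        children.append(
            Feature(
                hit.location,
                "recombination_signal_sequence",
                {
                    "ID": f"{attrs['ID']}:rss{idx}",
                    "orientation": hit.orientation,
                    "spacer": str(hit.spacer_length),
                    "heptamer_mismatches": str(hit.heptamer_mismatches),
                    "nonamer_mismatches": str(hit.nonamer_mismatches),
                },
            )
        )
    if g.leader is not None:
        children.append(
            Feature(g.leader, "leader_exon", {"ID": f"{attrs['ID']}:leader"})
        )
    return Feature(
        Interval(g.coding.seq_id, g.coding.start, g.coding.end, g.strand),
        _SEGMENT_FTYPE[g.kind],
        attrs,
        children,
    )


def _constant_feature(m: ConstantGeneModel) -> Feature:
    gene_id = f"{m.span.seq_id}:C:{m.span.start}"
    defect_summary = ",".join(
        f"{role}:{d.kind if isinstance(d, Defect) else d}"
        for role, ds in sorted(m.exon_defects.items())
        for d in ds
    )
    attrs = {"ID": gene_id, "Name": m.name or m.isotype, "status": m.status}
    if defect_summary:
        attrs["defects"] = defect_summary
    children = []
    for role, iv in m.exons:
        c_attrs = {"ID": f"{gene_id}:{role}", "exon_role": role}
        ds = m.exon_defects.get(role, [])
        if ds:
            c_attrs["defects"] = ",".join(
                f"{d.kind}@{d.start}" if isinstance(d, Defect) else str(d) for d in ds
            )
        children.append(Feature(iv, "exon", c_attrs))
    return Feature(m.span, "C_gene", attrs, children)


def summarize(segments_df: pd.DataFrame) -> pd.DataFrame:
    """Per-(locus, kind) bookkeeping: totals and status/family breakdown."""
    cols = [
        "locus", "kind", "total", "functional", "pseudogene",
        "truncated", "families", "unassigned",
    ]
    if segments_df.empty:
        return pd.DataFrame([{c: 0 for c in cols}], columns=cols)
    rows = []
    for (locus, kind), grp in segments_df.groupby(["locus", "kind"], sort=True):
        fams = grp.loc[grp["family"] != "", "family"]
        fam_sizes = fams.value_counts()
        rows.append(
            {
                "locus": locus,
                "kind": kind,
                "total": len(grp),
                "functional": int((grp["status"] == "functional").sum()),
                "pseudogene": int((grp["status"] == "pseudogene").sum()),
                "truncated": int((grp["status"] == "truncated").sum()),
                "families": int(fams.nunique()),
                "unassigned": int((fam_sizes == 1).sum()),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def locus_map(result: AnnotationResult, cfg: RunConfig) -> str:
    """Human-readable locus map in genomic order.

    Pseudogene/truncated marks follow the locus-map convention (name
    suffixes p and t); V segments carry strand arrows; N-runs above
    ``gap_mark_min`` appear as double-slash gap marks.
    """
    lines: list[str] = []
    for seq in result.scaffolds:
        lines.append(f"scaffold {seq.id} ({seq.length:,} bp)")
        entries: list[tuple[int, str]] = []
        for g in result.segments:
            if g.coding.seq_id != seq.id:
                continue
            arrow = {"+": ">", "-": "<"}[g.strand] if g.kind == "V" else " "
            entries.append(
                (
                    g.coding.start,
                    f"  {g.name:<10s} {arrow} {g.coding.start + 1:>9,}..{g.coding.end:,} "
                    f"{g.status}",
                )
            )
        for r in result.switch_regions:
            if r.location.seq_id != seq.id:
                continue
            link = f" -> {r.constant_gene}" if r.constant_gene else ""
            entries.append(
                (
                    r.location.start,
                    f"  S-region    {r.location.start + 1:>9,}..{r.location.end:,} "
                    f"density={r.pentamer_density:.2f}{link}",
                )
            )
        for m in result.constant_genes:
            if m.span.seq_id != seq.id:
                continue
            entries.append(
                (
                    m.span.start,
                    f"  {m.name:<10s}   {m.span.start + 1:>9,}..{m.span.end:,} "
                    f"{m.status} ({len(m.exons)} exons)",
                )
            )
        for run in n_runs(seq, min_len=cfg.gap_mark_min):
            entries.append(
                (
                    run.start,
                    f"  //-- gap {run.length:,} bp "
                    f"({run.start + 1:,}..{run.end:,}) --//",
                )
            )
        entries.sort(key=lambda e: e[0])
        lines.extend(text for _, text in entries)
    return "\n".join(lines) + "\n"


def write_outputs(result: AnnotationResult, cfg: RunConfig, out_prefix: str | Path) -> None:
    prefix = str(out_prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    seq_lengths = {s.id: s.length for s in result.scaffolds}
    by_id = {s.id: s for s in result.scaffolds}

    write_gff3(
        [_segment_feature(g) for g in result.segments], prefix + ".gff3", seq_lengths
    )
    df = segments_frame(result.segments)
    df.to_csv(prefix + ".segments.tsv", sep="\t", index=False)
    write_fasta(
        (
            (g.name or f"{g.kind}@{g.coding.start}", extract(by_id[g.coding.seq_id], g.coding))
            for g in result.segments
        ),
        prefix + ".segments.fasta",
    )
    fam_rows = []
    for fam in result.families + result.d_families:
        for member in fam.members:
            fam_rows.append(
                {"segment": member, "family_id": fam.id, "unassigned": fam.unassigned}
            )
    pd.DataFrame(fam_rows, columns=["segment", "family_id", "unassigned"]).to_csv(
        prefix + ".families.tsv", sep="\t", index=False
    )
    write_bed6(
        (
            (r.location, f"S|{r.constant_gene or 'unlinked'}", r.pentamer_density)
            for r in result.switch_regions
        ),
        prefix + ".switch.bed",
    )
    write_gff3(
        [_constant_feature(m) for m in result.constant_genes],
        prefix + ".constants.gff3",
        seq_lengths,
    )
    Path(prefix + ".locus_map.txt").write_text(locus_map(result, cfg))
    summarize(df).to_csv(prefix + ".summary.tsv", sep="\t", index=False)

    log_lines = [
        f"igloci {__version__}",
        f"config_hash {cfg.config_hash()}",
        f"locus {cfg.locus}",
        f"seed {cfg.seed}",
    ]
    log_lines += [f"count {k} {v}" for k, v in result.stage_counts.items()]
    Path(prefix + ".run.log").write_text("\n".join(log_lines) + "\n")
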