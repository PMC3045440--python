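"""Sequence and annotation I/O, coordinate conventions, translation utilities.

Conventions used throughout the package:

* Internal coordinates are 0-based, half-open, always on the plus strand.
  Minus-strand features keep plus-strand coordinates; their sequence is
  reverse-complemented on extraction.
* GFF3 output (and any printed report) is 1-based inclusive; BED stays
  0-based half-open.
* DNA is uppercased on ingest; ``U`` becomes ``T`` and any other IUPAC
  ambiguity code collapses to ``N`` (so mismatch counting downstream is
  well defined: ``N`` never matches anything).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate ids)."""


@dataclass(frozen=True)
class GenomicSequence:
    """A named linear DNA sequence (scaffold) over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-normalized residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval on a named sequence.

    Minus-strand intervals store plus-strand coordinates; ``strand`` only
    records reading direction.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def intersection_length(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reflect(self, seq_length: int) -> "Interval":
        """Mirror through the end of a sequence of the given length."""
        return Interval(
            self.seq_id,
            seq_length - self.end,
            seq_length - self.start,
            "-" if self.strand == "+" else "+",
        )


def normalize_dna(raw: str, *, context: str = "") -> str:
    """Uppercase, map U->T, collapse every other IUPAC code to N."""
    s = raw.upper().replace("U", "T")
    bad = set(s) - _ALLOWED
    if bad:
        n_replaced = sum(s.count(c) for c in bad)
        logger.warning(
            "replaced %d ambiguous residue(s) %s with N%s",
            n_replaced,
            sorted(bad),
            f" in {context}" if context else "",
        )
        s = "".join(c if c in _ALLOWED else "N" for c in s)
    return s


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a multi-record DNA FASTA into normalized GenomicSequences.

    Record ids are the first whitespace-delimited header token. Raises
    :class:`FastaFormatError` on an empty file or duplicate ids.
    """
    records: list[GenomicSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomicSequence(rec.id, normalize_dna(str(rec.seq), context=rec.id)))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    return seq.translate(_RC_TABLE)[::-1]


def extract(seq: GenomicSequence | str, interval: Interval) -> str:
    """Extract interval sequence; minus-strand intervals come back reverse-complemented."""
    residues = seq if isinstance(seq, str) else seq.residues
    sub = residues[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


def translate(seq: str, frame: int = 0, strand: str = "+") -> str:
    """Translate one frame with the standard code; stops are '*'.

    A trailing partial codon is dropped; a sequence shorter than one codon
    in the requested frame gives an empty string.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = reverse_complement(seq) if strand == "-" else seq
    s = s[frame:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate())


def six_frame_translations(seq: str) -> dict[tuple[str, int], str]:
    """All six translations keyed by (strand, frame)."""
    return {
        (strand, frame): translate(seq, frame, strand)
        for strand in ("+", "-")
        for frame in (0, 1, 2)
    }


def n_runs(seq: GenomicSequence | str, min_len: int = 1, seq_id: str = "") -> list[Interval]:
    """Maximal runs of N of at least ``min_len`` bp (assembly-gap report)."""
    if isinstance(seq, GenomicSequence):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = seq, seq_id or "seq"
    runs: list[Interval] = []
    i = 0
    n = len(residues)
    while i < n:
        if residues[i] == "N":
            j = i
            while j < n and residues[j] == "N":
                j += 1
            if j - i >= min_len:
                runs.append(Interval(sid, i, j))
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """A GFF3-writable annotated interval with optional child features."""

    interval: Interval
    ftype: str
    attrs: dict[str, str] = field(default_factory=dict)
    children: list["Feature"] = field(default_factory=list)


def _esc(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def _gff3_line(f: Feature, source: str) -> str:
    iv = f.interval
    attrs = ";".join(f"{k}={_esc(v)}" for k, v in f.attrs.items())
    return "\t".join(
        [
            iv.seq_id,
            source,
            f.ftype,
            str(iv.start + 1),  # 1-based inclusive
            str(iv.end),
            ".",
            iv.strand,
            ".",
            attrs or ".",
        ]
    )


def write_gff3(
    features: Sequence[Feature],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
    source: str = "igloci",
) -> None:
    """Write features (children nested under parents) as GFF3.

    Raises ValueError naming the feature if it exceeds its sequence bounds.
    """
    lines = ["##gff-version 3"]

    def emit(f: Feature, parent_id: str | None) -> None:
        iv = f.interval
        if seq_lengths is not None and iv.seq_id in seq_lengths:
            if iv.end > seq_lengths[iv.seq_id]:
                name = f.attrs.get("ID", f.attrs.get("Name", f.ftype))
                raise ValueError(
                    f"feature {name!r} [{iv.start}, {iv.end}) exceeds length "
                    f"{seq_lengths[iv.seq_id]} of {iv.seq_id}"
                )
        attrs = dict(f.attrs)
        if parent_id is not None:
            attrs.setdefault("Parent", parent_id)
        lines.append(_gff3_line(Feature(iv, f.ftype, attrs), source))
        for child in f.children:
            emit(child, f.attrs.get("ID"))

    for f in features:
        emit(f, None)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[Feature]:
    """Read a GFF3 file back into flat Features (Parent kept as attribute).

    Coordinates are converted back to the internal 0-based half-open system.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    for rec in db.all_features(order_by=("seqid", "start")):
        attrs = {k: ",".join(v) for k, v in rec.attributes.items()}
        strand = rec.strand if rec.strand in ("+", "-") else "+"
        features.append(
            Feature(Interval(rec.seqid, rec.start - 1, rec.end, strand), rec.featuretype, attrs)
        )
    return features


def write_bed6(
    rows: Iterable[tuple[Interval, str, float]],
    path: str | Path,
) -> None:
    """Write (interval, name, score) rows as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
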