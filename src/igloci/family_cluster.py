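"""Percent-identity computation and gene-family clustering.

V (and D) gene segments are grouped into families by pairwise nucleotide
identity: segments sharing more than a threshold (default 70%) belong to
the same family, and family membership is transitive (single linkage), so
a family is a connected component of the >threshold similarity graph.
Segments below threshold to everything become unassigned singletons.

Identity is computed from a Needleman-Wunsch global alignment with affine
gaps (defaults: match +1, mismatch -1, gap open -5, gap extend -1) as
matches / aligned columns, where columns with an internal gap count in the
denominator and terminal-overhang columns are excluded. The denominator
convention changes results and is therefore part of the documented
contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_percent_identity(a: str, b: str, params: AlignParams | None = None) -> float:
    """Global-alignment percent identity in [0, 100].

    Internal gap columns count in the denominator; terminal overhangs do
    not. Symmetric up to co-optimal alignment choice.
    """
    if not a or not b:
        raise ValueError("global_percent_identity requires non-empty sequences")
    params = params or AlignParams()
    alignment = _aligner(params).align(a, b)[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    both = [i for i in range(len(s1)) if s1[i] != "-" and s2[i] != "-"]
    if not both:
        return 0.0
    i0, i1 = both[0], both[-1] + 1
    matches = sum(1 for i in range(i0, i1) if s1[i] == s2[i] and s1[i] != "-")
    return 100.0 * matches / (i1 - i0)


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix over named sequences."""

    members: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.members)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match member count")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("identity matrix diagonal must be exactly 100")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.members.index(a), self.members.index(b)])


def build_identity_matrix(
    sequences: dict[str, str], params: AlignParams | None = None
) -> IdentityMatrix:
    """All-vs-all global percent identity (upper triangle mirrored)."""
    names = list(sequences)
    n = len(names)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_percent_identity(sequences[names[i]], sequences[names[j]], params)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(names, values)


@dataclass
class Family:
    """One gene family; ``unassigned`` marks below-threshold singletons."""

    id: int
    members: list[str]
    unassigned: bool = False


def cluster_families(
    matrix: IdentityMatrix,
    threshold: float = 70.0,
    review_band: tuple[float, float] = (70.0, 80.0),
) -> list[Family]:
    """Single-linkage families: connected components of the >threshold graph.

    Family ids are dense 1..k, ordered by size descending with ties broken
    by the smallest member index in matrix order. Pairs falling inside
    ``review_band`` are logged for manual review (the historical 70-80%
    case-by-case band).
    """
    names = matrix.members
    n = len(names)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    has_edge = [False] * n
    lo, hi = review_band
    for i in range(n):
        for j in range(i + 1, n):
            pid = float(matrix.values[i, j])
            if lo < pid < hi:
                logger.info(
                    "identity %.1f%% between %s and %s falls in the %g-%g review band",
                    pid, names[i], names[j], lo, hi,
                )
            if pid > threshold:
                union(i, j)
                has_edge[i] = has_edge[j] = True

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    ordered = sorted(components.values(), key=lambda idxs: (-len(idxs), idxs[0]))
    return [
        Family(
            id=k + 1,
            members=[names[i] for i in idxs],
            unassigned=len(idxs) == 1 and not has_edge[idxs[0]],
        )
        for k, idxs in enumerate(ordered)
    ]


@dataclass
class ReferenceAssignment:
    label: str
    mean_identity: float
    margin: float
    ambiguous: bool


def assign_to_reference(
    family_members: dict[int, dict[str, str]],
    references: list[tuple[str, str]],
    params: AlignParams | None = None,
    margin: float = 2.0,
) -> dict[int, ReferenceAssignment]:
    """Label each family by its nearest reference group.

    ``references`` is a list of (label, sequence); several references may
    share a label (a reference group, e.g. one human V family or clan).
    Each family gets the label with the highest mean identity between its
    members and the group's references; assignments whose margin over the
    runner-up is below ``margin`` percentage points are flagged ambiguous.
    """
    if not references:
        raise ValueError("assign_to_reference requires a non-empty reference set")
    by_label: dict[str, list[str]] = {}
    for label, seq in references:
        by_label.setdefault(label, []).append(seq)

    out: dict[int, ReferenceAssignment] = {}
    for fam_id, members in family_members.items():
        scores: list[tuple[float, str]] = []
        for label, refs in by_label.items():
            idents = [
                global_percent_identity(m, r, params)
                for m in members.values()
                for r in refs
            ]
            scores.append((float(np.mean(idents)), label))
        scores.sort(key=lambda t: (-t[0], t[1]))
        best, runner = scores[0], (scores[1] if len(scores) > 1 else (float("-inf"), ""))
        gap = best[0] - runner[0]
        out[fam_id] = ReferenceAssignment(
            label=best[1],
            mean_identity=best[0],
            margin=gap if np.isfinite(gap) else float("inf"),
            ambiguous=gap < margin,
        )
    return out
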