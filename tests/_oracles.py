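"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain loops and string slices, no numpy, no shared
code with the scanners they verify.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def _ham(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def oracle_scan(seq: str, spec) -> set[tuple]:
    """Exhaustively test every (position, spacer, orientation) triple.

    Returns hit keys (start, end, orientation, spacer, heptamer_mm,
    nonamer_mm) for comparison with the production scanner.
    """
    hept = spec.heptamer_consensus
    non = spec.nonamer_consensus
    rc_hept = _rc(hept)
    rc_non = _rc(non)
    required = sorted(spec.required_exact_positions)
    n = len(seq)
    hits: set[tuple] = set()
    for spacer in spec.spacer_lengths:
        span = 16 + spacer
        for i in range(n - span + 1):
            # heptamer-first: heptamer .. spacer .. nonamer
            h = seq[i : i + 7]
            if all(h[p] == hept[p] for p in required):
                hm = _ham(h, hept)
                if hm <= spec.max_heptamer_mismatch:
                    m = seq[i + 7 + spacer : i + span]
                    nm = _ham(m, non)
                    if (
                        nm <= spec.max_nonamer_mismatch
                        and hm + nm <= spec.max_total_mismatch
                    ):
                        hits.add((i, i + span, "heptamer_first", spacer, hm, nm))
            # nonamer-first: rc(nonamer) .. spacer .. rc(heptamer)
            h2 = seq[i + 9 + spacer : i + span]
            if all(h2[6 - p] == rc_hept[6 - p] for p in required):
                hm = _ham(h2, rc_hept)
                if hm <= spec.max_heptamer_mismatch:
                    m2 = seq[i : i + 9]
                    nm = _ham(m2, rc_non)
                    if (
                        nm <= spec.max_nonamer_mismatch
                        and hm + nm <= spec.max_total_mismatch
                    ):
                        hits.add((i, i + span, "nonamer_first", spacer, hm, nm))
    return hits


def oracle_dot_matrix(a: str, b: str, window: int, max_mismatch: int) -> set[tuple]:
    """Naive double-loop windowed comparison."""
    dots = set()
    for i in range(len(a) - window + 1):
        wa = a[i : i + window]
        for j in range(len(b) - window + 1):
            if _ham(wa, b[j : j + window]) <= max_mismatch:
                dots.add((i, j))
    return dots


def oracle_single_linkage(names: list[str], values, threshold: float) -> list[frozenset]:
    """Connected components by explicit transitive closure (Floyd-Warshall style)."""
    n = len(names)
    linked = [[values[i][j] > threshold for j in range(n)] for i in range(n)]
    for i in range(n):
        linked[i][i] = True
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if linked[i][k] and linked[k][j]:
                    linked[i][j] = True
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(names[j] for j in range(n) if linked[i][j])
        seen.update(j for j in range(n) if linked[i][j])
        comps.append(comp)
    return comps
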