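# Methods

This note documents the models and procedures implemented in `igloci`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical/design choices
that were genuinely open.

## Coordinates and sequence handling

All internal coordinates are 0-based half-open on the plus strand;
minus-strand features keep plus-strand coordinates and are
reverse-complemented on extraction. Conversion to 1-based inclusive
happens only at the GFF3 boundary (BED stays 0-based). IUPAC ambiguity
codes other than N are collapsed to N on ingest rather than matched
permissively: this keeps Hamming mismatch counting well defined (N
mismatches everything, including another N).

## RSS scanning

An RSS is modeled as heptamer (7 bp) + spacer + nonamer (9 bp) with
consensi `CACAGTG` / `ACAAAAACC` read in the coding-proximal direction.
The nonamer consensus is a configuration default, not a measured value.
Matching is Hamming distance under three budgets — per-heptamer (default
≤ 2), per-nonamer (≤ 4), and pooled total (≤ 5) — plus a set of
heptamer positions required to match exactly (default the first three,
the `CAC` adjacent to the coding region). The historical description of
this kind of search ("five or more mismatches allowed") is unbounded if
read literally; the pooled ≤ 5 reading reproduces a permissive-but-finite
search, and whether separate or pooled budgets were historically used is
unknowable, so both are supported. The exact-CAC default prevents
pathological hit counts at the ≤ 5 budget and is overridable.

A minus-strand RSS appears in plus coordinates as the reverse-complement
pattern (nonamer first); the scanner reports both orientations. Note an
important symmetry: the reverse complement of heptamer-spacer-nonamer is
again nonamer-spacer-heptamer, so every plus-strand RSS is
simultaneously a perfect opposite-orientation anchor. Consequences are
handled downstream (see J-over-V suppression and the D strand
convention). Spacer sets follow the 12/23 rule per locus and segment
kind; a ±1 relaxation and an explicit {10,11,12,13} D mode exist because
real loci contain e.g. 10-bp D spacers. The scanner is a pure detector:
overlapping hits are all reported, and suppression is the caller's job.

The scanner is verified against an independent brute-force oracle
(exhaustive per-position, per-spacer, per-orientation testing) for exact
set equality on seeded random sequences.

## V segment calling and classification

For each V-type RSS the caller scans candidate exon lengths from the
upper bound down (default 270–320 bp), anchoring the exon 5' end at an
`AG` splice acceptor; the first (longest) acceptor-anchored candidate
wins, which is deterministic and, on the simulator's loci, boundary-exact
because intron 3' ends are pyrimidine tracts (see below). A leader is
sought within 400 bp upstream: an ATG-initiated stop-free stretch of
30–90 nt ending at a `GT` donor with at least 60 bp of intron. The
conserved framework landmarks are located by scanning the translation
for Cys in aa 15–30, Trp in aa 30–48 and Cys in aa 80–108 — positional
tolerance windows rather than a numbering scheme, so no external
numbering system is imported.

Classification: truncated if the RSS-anchored coding region is below 0.8
× the lower exon bound; otherwise pseudogene on any of in-frame stop,
frameshift (exon length mod 3; plus, when a family prototype is
supplied, a gapped comparison flagging gaps of length ≢ 0 mod 3),
missing leader, or missing conserved residue; otherwise functional. All
triggered defects are recorded, not just the first.

**Homology gate.** At the default budgets, ~150 kb of random DNA yields
on the order of ten spurious V-type RSS hits, and nearly every one has a
chance `AG` at an acceptor-compatible distance, which would flood the
pseudogene class. A candidate that is not functional-grade on its own
evidence is therefore only called if it shares ≥ 65% global identity
with another called V segment at a *different* position (overlapping
candidates are trivially identical and do not count). This mirrors how
pseudogenes are recognized in practice — by homology to intact
relatives — and drives false V calls to near zero while leaving planted
lesioned segments (which always have family relatives) untouched.
Truncated fragments carry no leader/ORF evidence at all, so they
additionally require a near-perfect RSS (≤ 2 total mismatches) and are
assigned a nominal 200 bp extent. Fragments with no RSS anchor are not
called at all; fragments findable only by homology are a documented
limitation.

Minus-strand V segments are called by running the identical plus-strand
procedure on the reverse complement and mapping coordinates back, which
makes strand symmetry exact by construction. Overlapping accepted
candidates are resolved by fewest RSS mismatches, then longest ORF, then
smallest start — an invented but deterministic order.

## D and J segments

D segments are spans of 8–40 bp (covering the observed 10–37 bp range)
between facing RSSs: an upstream nonamer-first hit and a downstream
heptamer-first hit whose heptamers point at the core. Pairs sharing a
hit resolve by fewest mismatches, then shorter span, then leftmost. D
cores are read in all three frames (reported with each call), so ORF
status is not meaningful; a D is functional unless its core contains N.
Because a facing-RSS unit is its own reverse complement at motif level,
D strand is not identifiable from RSS evidence; it is reported `+` by
convention and the strand-symmetry test compares D by coordinates and
status only.

J segments anchor at the heptamer 3' end of a J-type RSS. The candidate
(30–70 bp) must contain, in some frame, the J motif (`WGxG` heavy,
`FGxG` light) or the motif with its first residue replaced by a stop —
the classic Trp→stop pseudogenization — followed by a `GT` donor within
30 bp of the motif. The rightmost motif wins (the motif sits near the
coding 3' end). Because every V RSS is also a perfect J-type anchor in
the opposite orientation (reading the V exon backwards), J calls
overlapping a called V segment or its RSS are suppressed in the
pipeline.

**Naming.** V and D are `"<kind><family>-<position>"` with positions
counted 1..n from the constant-region-proximal end, suffix `p` for
pseudogenes and `t` for truncated segments; J are `J<index>` in
positional order. Naming requires prior family assignment.

## Families

Identity is computed from Needleman–Wunsch global alignment with affine
gaps (match +1, mismatch −1, open −5, extend −1 — invented defaults,
config-exposed) as matches / aligned columns, counting internal gap
columns in the denominator and excluding terminal overhangs. The
denominator convention materially changes values and is part of the
contract; the overhang exclusion means a clean fragment of a longer
sequence scores 100, which is the behavior wanted for truncated
segments.

Families are the connected components of the graph with an edge where
identity > 70% (strict), i.e. single linkage — chosen because family
membership is defined pairwise, without centroids, and "unassigned"
segments are precisely those below threshold to everything. Pairs in the
historical 70–80% case-by-case band are logged for review but the
operational rule (> 70% joins) is what is implemented. Identity is
computed over the full coding region (whether framework-only identity
was historically used is unknown; full-region is the documented
default). Reference assignment labels each family with the reference
group of highest mean member-to-reference identity, flagging margins
under 2 points as ambiguous.

## Switch regions and dot matrix

Pentamer coverage marks every base covered by `GGGCT`/`GAGCT` or their
reverse complements (switch repeats function on both strands — a
documented choice). Windows of 500 bp (step 50) with coverage ≥ 0.20
seed regions; qualifying windows merge across gaps ≤ 200 bp, and each
merged span is trimmed to maximal covered clusters (internal gaps ≤ 50
bp) of at least 200 bp. Trimming to the repeat array itself, rather than
the window grid, is what makes detected boundaries exact on planted
arrays. The density statistic exists to make detection testable — the
historical practice was visual identification in dot plots. Expected
pentamer coverage of uniform random DNA is ≈ 2% (4 motifs × 5 bp /
4^5), far below the 0.20 threshold, and the seeded 100-kb negative
control finds nothing. Regions are linked to the nearest downstream
constant gene within 10 kb.

The dot matrix is the classical exhaustive windowed comparison (default
window 30 bp, mismatch limit 9), verified against a naive double-loop
oracle, with plain-text PGM and PNG renderings.

## Constant genes

Domain template proteins are aligned locally (BLOSUM62, open −11,
extend −1) against all six frames; hits scoring at least 2.0 × query
length are kept (exact matches score ≈ 5 × length; random local maxima
on these scales sit near 0.5 ×, so the threshold separates cleanly —
config-exposed because no historical cutoff is stated). Multiple
occurrences per frame are found by iterative masking. Stops translate
to `X` for alignment so a single premature stop does not split a hit.

Hits chain into gene models per isotype: per-strand clustering at the
intron upper bound (default 80 bp – 10 kb), then a dynamic program picks
the highest-scoring colinear chain in roster order. A frameshifted exon
aligns as two frame-split pieces; overlapping same-role hits are merged
and anchored by the piece starting earliest in the template, and defect
detection additionally probes anchor shifts of ±1 nt and keeps the one
whose initial translation matches the template — this recovers the true
reading frame even when the in-frame prefix alone is too short to score.

Defect screening translates the anchored exon in frame: stops before
the final 5% of the exon are premature (the 5% tail separates true
terminators — an invented, config-exposed threshold); a frameshift is
recognized when the template suffix re-aligns in frame +1 (single-base
insertion) or −1 (deletion) at ≥ 90% identity, reported at the first
nucleotide of the disrupted codon. An insertion of A immediately before
a Lys codon (`AAG`) re-encodes Lys and shifts the apparent insertion
point — a genuine ambiguity of homopolymer runs; the simulator avoids
planting insertions at such sites so that truth positions are
well-defined.

Status: intact (full roster, no defects), pseudoexon-containing (full
roster with defects), partial (missing roster members; those whose
expected span overlaps an N-run ≥ 20 bp are annotated
`missing_due_to_gap`), remnant (exactly one surviving exon with no gap
excuse). The γ roster deliberately omits the hinge exon: hinges are
poorly conserved and not reliably identifiable by translated homology,
so modeling them would manufacture false defects. The bundled templates
are synthetic stand-ins (fixed random proteins with realistic lengths
and rosters) so tests need no downloads; real analyses supply real
domain proteins via `--templates`.

## The synthetic locus generator

The generator emulates a translocon-organized locus: V cluster → D
cluster (heavy only) → J cluster → constant region, with seeded random
intergenic DNA (default 400–1200 bp between segments), leader exons with
canonical splice sites, correct per-locus RSS spacers, V family
structure (prototypes separated by a per-site divergence of 0.6,
members at 0.08), planted lesions in configured fractions (counts are
floor(fraction × n) so tests get exact expectations), a configurable
fraction of V segments on the minus strand (the mixed transcriptional
orientations seen in κ loci), pentamer switch arrays (2 kb) upstream of
designated constant genes, constant genes reverse-translated from the
templates with the most-common mammalian codon per residue (determinism
beats codon realism for a fixture), and an optional single-domain
remnant 10 kb downstream of μ.

**Ground-truth well-definedness.** A planted boundary must be
recoverable by a perfect annotator, so the generator removes decoys that
would make truth ambiguous even in principle: intron 3' ends are 50-bp
pyrimidine tracts (a real feature — the polypyrimidine tract — which
also guarantees no spurious `AG` acceptor upstream of the true one);
truncated fragments sit behind a 160-bp AG-free buffer (a fragment is
*defined* by the absence of an acceptor at exon-compatible distances);
switch arrays carry 60-bp pentamer-free flanks with `AAAAA` junction
buffers; J tail codons contain no `GT` or decoy J motif before the true
donor; and constant-exon insertions avoid Lys codons. These choices were
made at design time as part of defining what the planted truth *is*.

**What the generator does not emulate**, and hence what passing tests do
not show about real genomes: phylogenetically realistic sequence
evolution (mutations are i.i.d. per site), codon-usage realism,
assembly gaps interleaved with features (N-runs are only planted
explicitly), repeat elements and segmental duplications, diverged RSSs
(planted RSSs are exact consensus — the mismatch budgets are exercised
by the oracle tests, not the round trip), hinge exons, and
gene-conversion structure among pseudogenes. Perfect round-trip scores
on simulated loci therefore validate the machinery and its bookkeeping,
not performance on diverged real sequence.

## Evaluation

A call matches a truth record when kinds agree and reciprocal overlap ≥
0.8; matching is one-to-one, greedy by highest overlap. Reported per
kind: recall, precision, boundary-exact fraction, status accuracy (and
the same denominated over truth), a status confusion table, and the
fraction of matched records whose planted lesions all appear among
called defects.

## Problem sizes

The shipped verification runs use a 40 V / 20 D / 6 J / 1 μ + 2 γ /
3-switch locus (~140 kb) for the round trip, 10 × 40 V loci for lesion
classification, 20 seeds × 30 sequences for family recovery, 10
scaffolds for constant-gene recovery, and 100 × 10 kb × 5 specs for
scanner/oracle equality — sizes chosen so the full suite completes in
about two minutes while every feature class appears many times per
replicate.

## Known limitations

* Truncated fragments are only called when RSS-anchored with ≤ 2 total
  mismatches; badly decayed fragments with degraded RSSs are invisible.
* D segment strand is conventional (see above).
* The leader search returns the rightmost viable ATG; leader boundaries
  are therefore approximate and are not scored.
* Assembly gaps are reported (N-run report, locus-map gap marks ">10 kb"
  style) but no inference is made across them.
* Identity-based reference labeling is a nearest-neighbor heuristic, not
  phylogenetics; credibility values and tree inference are out of scope.
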