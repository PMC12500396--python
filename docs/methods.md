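# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Data model and coordinates

Internally every interval is 0-based half-open; GenBank and GFF3 1-based
inclusive coordinates are converted exactly once, at the I/O boundary.
Circular chromosomes are stored linearly in their deposited rotation;
modules that must see origin-spanning structure (repeat discovery, the
dnaA–dnaN interval) operate on a virtually doubled sequence and report
coordinates modulo the length, so deposited coordinates are never mutated.
IUPAC ambiguity codes other than N are coerced to N with a warning rather
than rejected, because draft assemblies in scope contain them. Identity is
everywhere matches / alignment columns, gaps counted as columns — the
convention that makes a statement like "1,044 of 1,407 bp" well defined.

## Insertion-sequence discovery

The discovery problem is: find every pair of chromosomal regions longer
than `min_length` (default 500 bp) sharing more than `min_identity`
(default 0.99) nucleotide identity, on either strand, and group them into
repeat families. All-pairs alignment is quadratic in genome length, so the
implementation anchors on exact 21-mers: positions sharing a 21-mer are
grouped by diagonal (forward) or anti-diagonal (reverse-complement),
chained when successive anchors are within `max_gap` = 100 bp, extended
base-by-base while the two regions stay identical, and finally verified by
a full pairwise alignment (edlib). Only verified pairs enter the copy
graph; families are its connected components, copy orientation is
propagated by BFS over pair strands, and the consensus is the per-column
majority over oriented copies. k = 21 makes chance anchors in a ~2.7 Mb
genome negligible while tolerating ~1 substitution per 50 bp
(0.99^21 ≈ 0.81 of 21-mers survive 1 % divergence, so chains bridge
mismatches comfortably within the gap bound). K-mers occurring more than
100 times are skipped as hyper-repetitive. The `window` parameter is
retained as a memory bound for very large inputs; results do not depend on
it provided it exceeds the longest repeat.

Characterisation steps:

* **Transposase check.** CDS products overlapping any copy are matched
  case-insensitively against {"transposase", "insertion element",
  "IS family"}. Families with a hit are IS; families overlapping only
  other products (e.g. rRNA operons) are flagged non-IS but still
  reported; with no annotation at all the family is "unevaluated".
* **Terminal IRs.** The first 60 consensus bases are aligned, ungapped,
  against the reverse complement of the last 60, anchored within 5 bases
  of each terminus. The score is +1 per match, −3 per mismatch, with a
  floor of 10 aligned bases and at most 25 % mismatches; the penalty keeps
  chance flank pairings from inflating a perfect IR (a pure
  identical-count objective would happily report 22/29 over a planted
  16/16).
* **TSDs.** Per copy, the longest k ∈ [2, 12] with the k bases left of the
  copy equal to the k bases right of it. A family-level TSD requires ≥ 2
  copies with equal-length TSDs whose sequences differ between copies;
  identical flanks at every copy are rejected and flagged, because they
  belong to the element or a target preference, not to duplication. This
  "distinct between copies" rule is deliberately hard: distinct TSDs are
  the evidence for independent insertion events.
* **Extent refinement.** Boundaries extend outward column-by-column while
  all copies agree and the trailing 20-column window stays ≥ 0.99 in
  agreement (at that default any disagreeing column stops extension);
  trailing disagreements are trimmed, one side is committed before the
  other is grown so adjacent copies can never come to overlap, and the
  conserved extent is the refined consensus length. When all copies share
  identical terminal ≤ 10-mers after refinement the extent is flagged as
  possibly including the target site — that ambiguity is experimental, not
  computational, and is surfaced rather than resolved.
* **Homolog recruitment.** The consensus is aligned infix-style against
  the (copy-masked) genome on both strands; locations at ≥ 0.70 identity
  over ≥ 0.70 of the consensus length are reported, best-identity first,
  ties to the lower coordinate. Up to 20 relatives per strand are
  recruited before the scan stops.
* **Empty sites.** Each copy's 200 bp flanks are placed in a second
  genome at ≥ 0.95 identity. The two flank placements delimit the site;
  because one TSD copy remains at a naïve site, adjacency is accepted when
  the placement offset is within one TSD length (±2 bp slack). A flank
  that cannot be placed makes the copy "untraceable", not an error.

## CRISPR arrays

Detection is CRT-like and deterministic: every exact 8-mer whose
occurrence list contains runs with successive spacings inside
[repeat_min + spacer_min, repeat_max + spacer_max] (defaults
[21+18, 48+60]) nominates a chain; the longest chain wins, and chains
inside an already-claimed span are dropped. Repeat boundaries grow from
the seed while ≥ 80 % of units agree on the majority base, bounded by the
repeat-length bounds. Terminal repeats beyond the chain are picked up by
scanning every admissible spacer length and accepting ≥ 60 % identity to
the consensus (degenerate terminal repeats are common in real arrays, and
retaining them is what makes a count like "99 repeats, 98 spacers"
well-defined); internal units must stay ≥ 85 % identical. Spacer-length
bounds are enforced between consecutive repeats, after which
repeats = spacers + 1 holds by construction and is asserted by the type.

"Downstream of the cas locus" depends on gene strand, so anchored search
takes seeds starting within ±5 kb of the annotated locus on either side —
but a seeded array is followed as far as it runs, since a ~100-unit array
is longer than the window itself. cas loci are maximal runs of
cas-annotated CDS separated by ≤ 2 intervening genes, labelled "type I-E"
when cas3 plus the cascade genes (cse1/cse2/cas7/cas5/cas6e) are present.
No PAM inference or leader-end orientation call is made; arrays are
reported as found on the forward strand.

## oriC prediction

The origin is taken as the dnaA–dnaN intergenic interval (the shorter arc
on a circular chromosome), which in actinobacteria hosts the functional
elements. Within it: DnaA boxes are all 9-mers within Hamming distance 1
of `TTGTCCACA` on either strand (the consensus and tolerance are
parameters, since box motifs vary across genera); box arrays are maximal
runs with inter-box gaps ≤ 100 bp; the DnaA-trio is the longest tandem run
of ≥ 3 `G[AT]T` units, longest-then-leftmost; and the unwinding element is
the 50 bp sliding window of maximal AT fraction, ties to the left — a
deliberately simple surrogate for a thermodynamic duplex-stability model,
adequate because the element is treated qualitatively. A prediction with
no boxes is returned with a low-confidence flag rather than suppressed.
Both the full intergenic interval and the box-spanned sub-interval are
available, since printed origin bounds in the literature are sometimes
motif-trimmed and sometimes not.

## Fragment ANI and taxonomy

ANI follows the ANIb convention: non-overlapping 1020 bp query fragments
(the trailing short fragment is dropped; fragments never span record
boundaries in draft assemblies), each mapped to its best reference
location by exact 16-mer seeding with diagonal voting, then aligned within
a ±120 bp band; both orientations are tried and fragments are kept at
≥ 0.70 identity over ≥ 0.70 coverage. ANI is 100 × the mean identity of
kept fragments. Two unrelated genomes share essentially no 16-mers, so
they yield zero mapped fragments and an *undefined* ANI — treated as "no
edge" in clustering, never as 0, which would corrupt identity ranges.
For clustering, the two directed values are symmetrised by their mean.
Species are union-find components of the ≥ threshold graph (default 95 %,
configurable — the boundary is a community convention, not a constant of
nature); QC keeps genomes with completeness ≥ 90 and contamination ≤ 5,
boundary values included, mirroring the strict inequalities of the usual
filter. Outlier detection flags genomes below threshold to their own
species' type strain; near-identical groups are components at ≥ 99 %.
The neighbour-joining tree on d = (100 − ANI)/100 (scikit-bio; negative
branch lengths clamped to 0) is deliberately plumbing — a quick clade
visual, not a substitute for a maximum-likelihood phylogeny, which is out
of scope.

## Pangenome classes

Two schemes coexist and are never mixed. The global scheme uses the
Panaroo-convention thresholds; as commonly printed they overlap at their
boundaries (core "99–100 %", soft core "95–99 %"), which is resolved here
with half-open upper bounds (core x ≥ 0.99, soft core [0.95, 0.99), shell
[0.15, 0.95), cloud (0, 0.15)) so the classes form a true partition. The
clade-aware scheme uses per-clade thresholds (core > 0.95, shell
(0.15, 0.95], cloud (0, 0.15], absent = 0). A gene is clade-specific when
non-absent in exactly one clade with *strict zero* presence elsewhere; a
tolerance parameter exists (counting ≤ tolerance presence as absence) but
defaults to 0, and strict absence is applied to specific shell and cloud
as well as core — an explicit interpretation, flagged as such. Genes
absent everywhere are dropped at parse time, so cloud excludes x = 0.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (arguments, seed) — one
`numpy.random.Generator` per call, no global state. Defaults emulate the
motivating organism: ~70.6 % GC, 1.2 kb IS elements with 16 bp IRs at two
to three chromosomal positions with 4 bp or no TSDs, a 28 bp-repeat /
33–34 bp-spacer CRISPR array of up to 99 repeats, an oriC with two
DnaA-box arrays, a trio run, and an AT ≥ 0.8 unwinding element. The
default fixture length is 200 kb, scaled down from the megabase range
because every algorithm is length-agnostic and fixture cost should stay
in seconds; the acceptance script states the sizes it used alongside each
number.

Substitutions pick uniformly among the three alternative bases — the
simplest model under which expected identity ≈ 1 − rate — and every event
is logged, so the *realised* substitution fraction is known exactly and
calibration never depends on rate expectations. Clade sets use a
star-within-star topology (founders at inter/2 from the ancestor, members
at intra/2 from their founder) rather than a coalescent, because pairwise
path divergences — hence expected identities — are then analytically
controlled, which is exactly what threshold-behaviour tests need.
Presence/absence matrices draw presence *counts* uniformly from the
integers whose frequency falls inside the requested class interval, so
planted classes are recovered exactly by construction at the resolution
the genome count allows.

Planted truth is made *well-defined* by construction: insertion sites are
chosen so the bases immediately flanking each copy differ pairwise across
copies (otherwise the maximal conserved interval genuinely extends into
the flanks and "exact boundary recovery" would be ill-posed); the bases
just inside a planted IR are pinned so they cannot base-pair (the planted
IR is the unique maximal inverted repeat); and the columns flanking CRISPR
repeats (spacer first/last bases plus the abutting genome bases) are never
unanimous. These constraints remove measure-zero-in-real-data ambiguities
from the synthetic truth; they do not make the detectors' task easier in
any other way.

What the generators do **not** emulate: codon structure and real gene
content, rearrangements and horizontal transfer, coalescent genealogies,
IS target-site preference, CRISPR repeat degeneracy gradients, and
real-assembly artefacts (contig breaks, collapsed repeats). Passing the
planted-truth suite therefore demonstrates algorithmic correctness under
controlled conditions, not end-to-end performance on arbitrary real
assemblies; the optional accession-based tests (fetched reference genomes)
cover one real chromosome end to end.

## Numerical choices and tie-breaks

All orderings are deterministic: families are named in chromosome order;
homolog ties break by (higher identity, lower start); trio and DUE ties go
to the lower coordinate; consensus ties to the lexicographically smallest
base; identical CLI invocations produce byte-identical report bundles.
Seeds derived inside multi-step simulations are drawn below 2^31 from the
caller's generator. The ANI seeding band (120 bp) bounds the alignment
window around the voted diagonal; indel drift beyond the band would lose
fragments, acceptable at the indel rates in scope (≤ 10⁻³ per site).

## Known limitations

* Repeat discovery requires exact 21-mer anchors; repeat pairs just above
  the identity threshold with unusually even mismatch spacing (< one
  anchor per `max_gap`) could fragment into sub-threshold chains. At the
  default 0.99 threshold this needs > 1 mismatch per ~50 bp sustained, in
  which case the pair is below threshold anyway.
* Empty-site detection assumes flanks are locally unique; flanks inside
  other repeats are reported untraceable rather than resolved.
* The CLI takes parameters from flags only; run manifests (JSON, with
  input checksums and all parameters) provide reproducibility instead of
  a config-file layer.
* The oriC stage requires dnaA/dnaN annotation; there is no GC-skew
  fallback (explicitly out of scope).
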