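"""Replication-origin prediction from the dnaA-dnaN intergenic region.

In actinobacteria oriC typically sits between dnaA and dnaN and carries
arrays of DnaA boxes (9-mer initiator binding sites), tandem DnaA-trio
trinucleotides that assist strand separation, and an AT-rich DNA unwinding
element (DUE). The box consensus (default TTGTCCACA, <=1 mismatch) and the
trio pattern (G[AT]T, >=3 tandem copies) are configurable parameters with
literature-standard defaults; the DUE is located as the maximal-AT sliding
window, a deliberately simple surrogate for a thermodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Feature, GenomeRecord, revcomp

DEFAULT_BOX = "TTGTCCACA"


@dataclass
class OriCRegion:
    """Predicted origin with its fine-scale features (genome coordinates)."""

    region: tuple[int, int]
    boxes: list[tuple[int, str, str, int]]  # (start, strand, sequence, mismatches)
    box_arrays: list[tuple[int, int]]  # index ranges over boxes
    trio: tuple[int, int, int] | None  # (start, end, copy count)
    due: tuple[int, int, float]  # (start, end, at fraction)
    low_confidence: bool = False
    notes: list[str] = field(default_factory=list)


def _find_named_cds(genome: GenomeRecord, gene: str, product: str) -> Feature:
    hits = [
        f
        for f in genome.features
        if f.kind in ("CDS", "gene")
        and (
            f.qualifiers.get("gene", "").lower() == gene.lower()
            or f.qualifiers.get("product", "") == product
        )
    ]
    # a gene + CDS pair for the same locus counts once
    uniq = {}
    for f in hits:
        uniq.setdefault((f.start, f.end), f)
    hits = list(uniq.values())
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one {gene} feature, found {len(hits)}: "
            + ", ".join(f"[{f.start},{f.end})" for f in hits)
        )
    return hits[0]


def intergenic_dnaA_dnaN(genome: GenomeRecord) -> tuple[int, int]:
    """The interval strictly between the dnaA and dnaN coding regions.

    On a circular chromosome the two candidate inter-feature gaps are
    resolved to the shorter one (dnaA and dnaN are adjacent in the organisms
    in scope); the returned interval may wrap, in which case end > genome
    length and callers read it modulo the length.
    """
    dnaA = _find_named_cds(
        genome, "dnaA", "chromosomal replication initiator protein DnaA"
    )
    dnaN = _find_named_cds(genome, "dnaN", "DNA polymerase III subunit beta")
    n = len(genome)
    a, b = sorted([dnaA, dnaN], key=lambda f: f.start)
    inner = (a.end, b.start)
    if inner[1] < inner[0]:
        raise ValueError("dnaA and dnaN features overlap")
    if not genome.is_circular:
        return inner
    outer = (b.end, a.start + n)  # wraps the origin
    return inner if inner[1] - inner[0] <= outer[1] - outer[0] else outer


def _region_seq(genome: GenomeRecord, region: tuple[int, int]) -> str:
    n = len(genome)
    s, e = region
    if e <= n:
        return genome.sequence[s:e]
    return genome.sequence[s:] + genome.sequence[: e - n]


def scan_dnaA_boxes(
    sequence: str,
    consensus: str = DEFAULT_BOX,
    max_mismatch: int = 1,
) -> list[tuple[int, str, str, int]]:
    """All box hits on both strands within Hamming distance ``max_mismatch``.

    Returns (start, strand, sequence, mismatches) sorted by position.
    """
    if len(consensus) != 9:
        raise ValueError("DnaA-box consensus must be a 9-mer")
    rc = revcomp(consensus)
    L = len(consensus)
    hits = []
    for i in range(len(sequence) - L + 1):
        word = sequence[i : i + L]
        mm = sum(1 for a, b in zip(word, consensus) if a != b)
        if mm <= max_mismatch:
            hits.append((i, "+", word, mm))
        mm_rc = sum(1 for a, b in zip(word, rc) if a != b)
        if mm_rc <= max_mismatch:
            hits.append((i, "-", word, mm_rc))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def group_box_arrays(
    boxes: list[tuple[int, str, str, int]], max_gap: int = 100
) -> list[tuple[int, int]]:
    """Maximal runs of boxes with inter-box gaps <= ``max_gap``.

    Returns half-open index ranges over the (sorted) box list; singleton
    arrays are allowed.
    """
    if not boxes:
        return []
    ranges = []
    start = 0
    for i in range(1, len(boxes)):
        gap = boxes[i][0] - (boxes[i - 1][0] + len(boxes[i - 1][2]))
        if gap > max_gap:
            ranges.append((start, i))
            start = i
    ranges.append((start, len(boxes)))
    return ranges


def find_dnaA_trios(
    sequence: str, min_copies: int = 3, pattern: str = "G[AT]T"
) -> tuple[int, int, int] | None:
    """Longest tandem run of >= ``min_copies`` trio units on either strand.

    The unit is the trinucleotide G-[A/T]-T. Ties go to the lower
    coordinate; the forward strand wins a cross-strand tie. Returns
    (start, end, copies) in the coordinates of ``sequence``.
    """

    def unit_ok(s: str) -> bool:
        return len(s) == 3 and s[0] == "G" and s[1] in "AT" and s[2] == "T"

    best = None  # (copies, start, end)
    for strand_seq, strand in ((sequence, "+"), (revcomp(sequence), "-")):
        n = len(strand_seq)
        i = 0
        while i < n - 2:
            if unit_ok(strand_seq[i : i + 3]):
                j = i
                while j + 3 <= n and unit_ok(strand_seq[j : j + 3]):
                    j += 3
                copies = (j - i) // 3
                if copies >= min_copies:
                    if strand == "+":
                        s, e = i, j
                    else:
                        s, e = n - j, n - i
                    cand = (copies, -s)
                    if best is None or cand > (best[0], -best[1]):
                        best = (copies, s, e)
                i = j
            else:
                i += 1
    if best is None:
        return None
    copies, s, e = best
    return (s, e, copies)


def find_due(sequence: str, window: int = 50) -> tuple[int, int, float]:
    """Maximal-AT sliding window of length ``window``; ties to the left."""
    n = len(sequence)
    if n < window:
        at = sum(1 for b in sequence if b in "AT") / max(n, 1)
        return (0, n, at)
    is_at = [1 if b in "AT" else 0 for b in sequence]
    cur = sum(is_at[:window])
    best = cur
    best_i = 0
    for i in range(1, n - window + 1):
        cur += is_at[i + window - 1] - is_at[i - 1]
        if cur > best:
            best = cur
            best_i = i
    return (best_i, best_i + window, best / window)


def predict_oric(
    genome: GenomeRecord,
    consensus: str = DEFAULT_BOX,
    max_mismatch: int = 1,
    box_array_gap: int = 100,
    due_window: int = 50,
) -> OriCRegion:
    """Compose the full origin prediction on the dnaA-dnaN intergenic region.

    Coordinates in the result are genome-absolute (0-based internally;
    exported formats are 1-based).
    """
    region = intergenic_dnaA_dnaN(genome)
    seq = _region_seq(genome, region)
    n = len(genome)
    off = region[0]

    def absolute(p: int) -> int:
        return (off + p) % n

    boxes = [
        (absolute(p), strand, word, mm)
        for p, strand, word, mm in scan_dnaA_boxes(seq, consensus, max_mismatch)
    ]
    arrays = group_box_arrays(
        sorted(boxes, key=lambda b: b[0]), max_gap=box_array_gap
    )
    trio_rel = find_dnaA_trios(seq)
    trio = (
        (absolute(trio_rel[0]), absolute(trio_rel[1]), trio_rel[2])
        if trio_rel
        else None
    )
    if len(seq) < due_window:
        d = find_due(seq, due_window)
        due = (absolute(d[0]), absolute(d[1]), d[2])
        notes = ["intergenic region shorter than the DUE window"]
    else:
        d = find_due(seq, due_window)
        due = (absolute(d[0]), absolute(d[1]), d[2])
        notes = []
    result = OriCRegion(
        region=region,
        boxes=sorted(boxes, key=lambda b: b[0]),
        box_arrays=arrays,
        trio=trio,
        due=due,
        low_confidence=not boxes,
        notes=notes,
    )
    return result


def oric_features(oric: OriCRegion) -> list[Feature]:
    """Origin features for GFF3 export (DnaA_box, DnaA_trio, DUE)."""
    feats = [
        Feature("misc_feature", oric.region[0], oric.region[1], "+",
                {"note": "oriC (dnaA-dnaN intergenic)"})
    ]
    for start, strand, word, mm in oric.boxes:
        feats.append(
            Feature("misc_feature", start, start + len(word), strand,
                    {"note": f"DnaA_box mismatches={mm}"})
        )
    if oric.trio:
        feats.append(
            Feature("misc_feature", oric.trio[0], oric.trio[1], "+",
                    {"note": f"DnaA_trio copies={oric.trio[2]}"})
        )
    s, e, at = oric.due
    feats.append(
        Feature("misc_feature", s, e, "+", {"note": f"DUE at={at:.2f}"})
    )
    return feats
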