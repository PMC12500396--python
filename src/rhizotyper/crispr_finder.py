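"""CRISPR repeat-spacer array detection anchored to cas loci.

A CRT-like heuristic: exact 8-mer seeds recurring at spacings compatible
with one repeat + one spacer nominate a candidate period; repeat boundaries
are then grown column-by-column across all units, the terminal repeat is
retained if it stays recognisable, and arrays are trimmed until the hard
invariant repeats = spacers + 1 holds. "Downstream of the cas genes" is
automated as a window on both sides of the annotated cas locus, since
downstream depends on gene strand.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .genome_io import Feature, GenomeRecord

logger = logging.getLogger(__name__)

_CAS_GENE = re.compile(r"\bcas\d+[a-z]?\b|\bcse\d\b|\bcsy\d\b", re.IGNORECASE)
_CAS_PRODUCT = re.compile(r"CRISPR-associated|\bCas\d+[a-z]?\b", re.IGNORECASE)
_TYPE_IE = {"cas3", "cse1", "cse2", "cas7", "cas5", "cas6e"}


@dataclass
class CrisprArray:
    """An ordered repeat-spacer array.

    Invariant: ``len(repeats) == len(spacers) + 1``; spacers lie strictly
    between consecutive repeats.
    """

    region: tuple[int, int]
    repeat_consensus: str
    repeats: list[tuple[int, str]]
    spacers: list[tuple[int, str]]
    cas_locus: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.repeats) != len(self.spacers) + 1:
            raise ValueError("repeats must equal spacers + 1")


def _cas_terms(feature: Feature) -> set[str]:
    terms = set()
    gene = feature.qualifiers.get("gene", "")
    product = feature.qualifiers.get("product", "")
    for m in _CAS_GENE.findall(gene):
        terms.add(m.lower())
    for m in re.findall(r"\b(Cas\d+[a-z]?|Cse\d|Cas6e)\b", product):
        terms.add(m.lower())
    return terms


def locate_cas_loci(features: list[Feature]) -> list[tuple[int, int, str]]:
    """Find runs of cas-annotated CDS and label the system when possible.

    CDS whose gene or product matches the cas vocabulary are grouped into
    maximal runs separated by at most two intervening genes; a locus gets
    the label "type I-E" when cas3 plus the cascade genes are present, else
    "cas (untyped)".
    """
    cds = sorted(
        (f for f in features if f.kind == "CDS"), key=lambda f: f.start
    )
    hits = []
    for idx, f in enumerate(cds):
        product = f.qualifiers.get("product", "")
        gene = f.qualifiers.get("gene", "")
        if _CAS_PRODUCT.search(product) or _CAS_GENE.search(gene):
            hits.append(idx)
    if not hits:
        return []
    loci = []
    run = [hits[0]]
    for idx in hits[1:]:
        if idx - run[-1] <= 3:  # <= 2 intervening genes
            run.append(idx)
        else:
            loci.append(run)
            run = [idx]
    loci.append(run)
    out = []
    for run in loci:
        terms: set[str] = set()
        for idx in run:
            terms |= _cas_terms(cds[idx])
        label = "type I-E" if _TYPE_IE.issubset(terms) else "cas (untyped)"
        out.append((cds[run[0]].start, cds[run[-1]].end, label))
    return out


def _grow_repeat(seq: str, anchors: list[int], seed_len: int,
                 repeat_bounds: tuple[int, int], min_agree: float = 0.8):
    """Extend seed anchors into full repeat intervals by column agreement."""
    n = len(seq)
    max_rep = repeat_bounds[1]
    left = 0
    while seed_len + left < max_rep:
        col = [seq[a - left - 1] for a in anchors if a - left - 1 >= 0]
        if len(col) < len(anchors):
            break
        most = Counter(col).most_common(1)[0][1]
        if most / len(col) < min_agree:
            break
        left += 1
    right = 0
    while seed_len + left + right < max_rep:
        col = [
            seq[a + seed_len + right]
            for a in anchors
            if a + seed_len + right < n
        ]
        if len(col) < len(anchors):
            break
        most = Counter(col).most_common(1)[0][1]
        if most / len(col) < min_agree:
            break
        right += 1
    return left, right


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    ln = min(len(a), len(b))
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / max(len(a), len(b)) if ln else 0.0


def find_crispr_array(
    genome: GenomeRecord,
    anchor: tuple[int, int] | None = None,
    repeat_bounds: tuple[int, int] = (21, 48),
    spacer_bounds: tuple[int, int] = (18, 60),
    min_repeats: int = 3,
    search_span: int = 5000,
    seed_len: int = 8,
) -> list[CrisprArray]:
    """Detect repeat-spacer arrays, optionally near a cas locus.

    With ``anchor`` the candidate seeds must start within ``search_span``
    bases of the locus on either side (both orientations, since downstream
    depends on strand), but a seeded array is followed as far as it runs;
    without an anchor the whole genome is scanned. Arrays are reported
    sorted by genomic start with a per-column majority consensus.
    """
    lo, hi = 0, len(genome)
    seq = genome.sequence[lo:hi]
    n = len(seq)
    if anchor is not None:
        seed_lo = max(0, anchor[0] - search_span)
        seed_hi = min(len(genome), anchor[1] + search_span)
    else:
        seed_lo, seed_hi = lo, hi
    period_lo = repeat_bounds[0] + spacer_bounds[0]
    period_hi = repeat_bounds[1] + spacer_bounds[1]

    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_len + 1):
        positions[seq[i : i + seed_len]].append(i)

    # candidate chains: runs of one seed recurring at period-compatible gaps
    chains = []
    for kmer, pos in positions.items():
        if len(pos) < min_repeats:
            continue
        run = [pos[0]]
        for p in pos[1:]:
            gap = p - run[-1]
            if period_lo <= gap <= period_hi:
                run.append(p)
            else:
                if len(run) >= min_repeats:
                    chains.append(run)
                run = [p]
        if len(run) >= min_repeats:
            chains.append(run)
    if not chains:
        return []

    # greedy selection: longest chain first, drop chains inside a taken span
    chains.sort(key=lambda r: (-len(r), r[0]))
    taken: list[tuple[int, int]] = []
    arrays = []
    for run in chains:
        if not (seed_lo <= run[0] < seed_hi or seed_lo <= run[-1] < seed_hi):
            continue
        span = (run[0], run[-1] + seed_len)
        if any(s < span[1] and span[0] < e for s, e in taken):
            continue
        arr = _build_array(seq, run, seed_len, repeat_bounds, spacer_bounds,
                           min_repeats)
        if arr is None:
            continue
        region, consensus, repeats, spacers = arr
        taken.append(region)
        arrays.append(
            CrisprArray(
                region=(region[0] + lo, region[1] + lo),
                repeat_consensus=consensus,
                repeats=[(p + lo, s) for p, s in repeats],
                spacers=[(p + lo, s) for p, s in spacers],
                cas_locus=anchor,
            )
        )
    arrays.sort(key=lambda a: a.region[0])
    return arrays


def _build_array(seq, run, seed_len, repeat_bounds, spacer_bounds, min_repeats):
    left, right = _grow_repeat(seq, run, seed_len, repeat_bounds)
    rep_len = seed_len + left + right
    if rep_len < repeat_bounds[0]:
        return None
    starts = [a - left for a in run]
    units = [seq[s : s + rep_len] for s in starts]
    # consensus over the internal units
    consensus = "".join(
        Counter(col).most_common(1)[0][0] for col in zip(*units)
    )

    # pick up (possibly degenerate) terminal repeats beyond the seed chain,
    # scanning every spacer length the bounds allow
    def best_terminal(candidates):
        scored = [
            (s, _identity(seq[s : s + rep_len], consensus))
            for s in candidates
            if 0 <= s and s + rep_len <= len(seq)
        ]
        scored = [(s, i) for s, i in scored if i >= 0.6]
        return max(scored, key=lambda t: (t[1], -t[0]))[0] if scored else None

    for _ in range(2):
        prev = best_terminal(
            starts[0] - sp - rep_len
            for sp in range(spacer_bounds[0], spacer_bounds[1] + 1)
        )
        if prev is None:
            break
        starts.insert(0, prev)
    for _ in range(2):
        nxt = best_terminal(
            starts[-1] + rep_len + sp
            for sp in range(spacer_bounds[0], spacer_bounds[1] + 1)
        )
        if nxt is None:
            break
        starts.append(nxt)

    # drop units that degrade below the identity floor (terminal exempt)
    kept = []
    for i, s in enumerate(starts):
        unit = seq[s : s + rep_len]
        ident = _identity(unit, consensus)
        terminal = i in (0, len(starts) - 1)
        if ident >= (0.6 if terminal else 0.85):
            kept.append(s)
    if len(kept) < min_repeats:
        return None
    # enforce spacer bounds between consecutive repeats
    good = [kept[0]]
    for s in kept[1:]:
        spacer_len = s - (good[-1] + rep_len)
        if spacer_bounds[0] <= spacer_len <= spacer_bounds[1]:
            good.append(s)
        else:
            if len(good) >= min_repeats:
                break
            good = [s]
    if len(good) < min_repeats:
        return None
    repeats = [(s, seq[s : s + rep_len]) for s in good]
    spacers = [
        (good[i] + rep_len, seq[good[i] + rep_len : good[i + 1]])
        for i in range(len(good) - 1)
    ]
    region = (good[0], good[-1] + rep_len)
    consensus = "".join(
        Counter(col).most_common(1)[0][0]
        for col in zip(*(u for _, u in repeats))
    )
    return region, consensus, repeats, spacers


def spacers_to_fasta(array: CrisprArray, prefix: str = "array") -> str:
    """Export spacers as multi-FASTA, ids ``{prefix}_spacer_{ordinal}``."""
    if not array.spacers:
        logger.warning("array has no spacers; emitting empty FASTA")
        return ""
    out = []
    for i, (_, sp) in enumerate(array.spacers, start=1):
        out.append(f">{prefix}_spacer_{i}\n{sp}")
    return "\n".join(out) + "\n"


def array_features(array: CrisprArray) -> list[Feature]:
    """Repeat units as repeat_region features for GFF3 export."""
    return [
        Feature("repeat_region", p, p + len(s), "+",
                {"note": "CRISPR repeat"})
        for p, s in array.repeats
    ]


def array_table(arrays: list[CrisprArray]) -> str:
    lines = ["start\tend\trepeat_length\tn_repeats\tn_spacers\tconsensus"]
    for a in arrays:
        lines.append(
            f"{a.region[0]}\t{a.region[1]}\t{len(a.repeat_consensus)}\t"
            f"{len(a.repeats)}\t{len(a.spacers)}\t{a.repeat_consensus}"
        )
    return "\n".join(lines) + "\n"
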