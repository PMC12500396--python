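"""De-novo insertion-sequence discovery by chromosome self-comparison.

Multi-copy repeat families are found by k-mer anchored self-alignment of the
chromosome against itself (both strands), chaining collinear anchors and
verifying every candidate copy pair with a full pairwise alignment. Families
are then characterised: transposase annotation check, terminal inverted
repeats (IRs), target-site duplications (TSDs), conserved-extent refinement,
divergent-homolog recruitment, and empty (naive) insertion sites in a second
genome.

The self-comparison is sub-quadratic: exact 21-mer anchors shared between
two chromosomal locations are chained when collinear within a gap bound,
extended base-by-base while the two locations stay identical, and the pair
is kept only if a full dynamic-programming alignment confirms
length > ``min_length`` and identity > ``min_identity``. Circular
chromosomes are scanned on a virtually doubled sequence with coordinates
reduced modulo the length; the trivial full-genome self-match is excluded.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .alignment import best_infix, global_identity
from .genome_io import Feature, GenomeRecord, revcomp

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

TRANSPOSASE_VOCAB = ("transposase", "insertion element", "is family")


@dataclass
class RepeatCopy:
    """One genomic copy of a repeat family."""

    start: int
    end: int
    strand: str = "+"
    identity_to_consensus: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ISFamily:
    """A multi-copy repeat family and its IS characterisation."""

    name: str
    consensus: str
    copies: list[RepeatCopy]
    transposase_products: list[str] = field(default_factory=list)
    transposase_status: str = "unevaluated"  # unevaluated | is | non_is
    ir: tuple[str, str, int, int] | None = None  # (left, right, identical, total)
    tsds: list[str | None] = field(default_factory=list)
    tsd_length: int | None = None
    refined_extent: int | None = None
    notes: list[str] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for b, c in _CODE.items():
        out[arr == ord(b)] = c
    return out


def _kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer integers and a validity mask (no N in window)."""
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    vals = np.zeros(m, dtype=np.uint64)
    for t in range(k):
        vals = (vals << np.uint64(2)) | codes[t : t + m].astype(np.uint64)
    bad = (codes == 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return vals, valid


def _dup_positions(vals: np.ndarray, valid: np.ndarray, max_occ: int):
    """Positions grouped by k-mer value, keeping values seen 2..max_occ times."""
    idx = np.nonzero(valid)[0]
    v = vals[idx]
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]
    pos_sorted = idx[order]
    groups = []
    boundaries = np.nonzero(np.diff(v_sorted))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [v_sorted.size]))
    for s, e in zip(starts, ends):
        if 2 <= e - s <= max_occ:
            groups.append((int(v_sorted[s]), pos_sorted[s:e]))
    return groups


def _chain(anchor_is: list[int], k: int, max_gap: int):
    """Split a sorted anchor list into runs with inter-anchor gaps <= max_gap."""
    runs = []
    start = prev = anchor_is[0]
    for i in anchor_is[1:]:
        if i - prev > k + max_gap:
            runs.append((start, prev + k))
            start = i
        prev = i
    runs.append((start, prev + k))
    return runs


def find_repeat_families(
    genome: GenomeRecord,
    window: int = 100_000,
    min_length: int = 500,
    min_identity: float = 0.99,
    k: int = 21,
    max_gap: int = 100,
    max_occ: int = 100,
    prefix: str = "REP",
) -> list[ISFamily]:
    """Find multi-copy repeat families by k-mer anchored self-comparison.

    Every maximal region pair (both strands) longer than ``min_length`` at
    identity above ``min_identity`` is represented; overlapping intervals are
    merged into copies and families are the connected components of the
    verified copy-pair graph. ``window`` bounds the chaining workspace and is
    kept for memory control; results do not depend on it as long as it
    exceeds the longest repeat.
    """
    n = len(genome)
    if n < min_length:
        raise ValueError("genome shorter than min_length")
    S = genome.sequence + genome.sequence if genome.is_circular else genome.sequence
    codes = _encode(S)
    vals, valid = _kmer_ints(codes, k)

    rc_seq = revcomp(S)
    rc_vals, rc_valid = _kmer_ints(_encode(rc_seq), k)

    # forward-forward anchors grouped by diagonal j - i
    fwd_groups: dict[int, list[int]] = defaultdict(list)
    value_groups = _dup_positions(vals, valid, max_occ)
    for _, positions in value_groups:
        ps = positions.tolist()
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                i, j = ps[a], ps[b]
                d = j - i
                if genome.is_circular and d % n == 0:
                    continue  # trivial doubled-sequence self-match
                fwd_groups[d].append(i)

    # forward-reverse anchors grouped by anti-diagonal i + j
    rc_groups: dict[int, list[int]] = defaultdict(list)
    if vals.size:
        fwd_map: dict[int, np.ndarray] = {v: p for v, p in value_groups}
        # also include unique k-mers: an inverted copy pair may share each
        # k-mer only once per strand, so match all valid k-mer values
        order = np.argsort(vals[valid], kind="stable")
        all_pos = np.nonzero(valid)[0][order]
        all_v = vals[valid][order]
        rc_pos_all = np.nonzero(rc_valid)[0]
        rc_v_all = rc_vals[rc_valid]
        rc_order = np.argsort(rc_v_all, kind="stable")
        rc_v_sorted = rc_v_all[rc_order]
        rc_pos_sorted = rc_pos_all[rc_order]
        # sort-merge join between forward and rc k-mer values
        left = np.searchsorted(rc_v_sorted, all_v, side="left")
        right = np.searchsorted(rc_v_sorted, all_v, side="right")
        hit = right > left
        L = len(S)
        for ai in np.nonzero(hit)[0]:
            i = int(all_pos[ai])
            for p in rc_pos_sorted[left[ai] : right[ai]]:
                j = L - k - int(p)  # S coordinate of the rc-matching window
                if j <= i:
                    continue
                rc_groups[i + j].append(i)

    candidates = []  # (a0, a1, b0, b1, strand)
    for d, ilist in fwd_groups.items():
        ilist = sorted(set(ilist))
        for a0, a1 in _chain(ilist, k, max_gap):
            if a1 - a0 <= min_length // 2:
                continue
            candidates.append((a0, a1, a0 + d, a1 + d, "+"))
    for c, ilist in rc_groups.items():
        ilist = sorted(set(ilist))
        for a0, a1 in _chain(ilist, k, max_gap):
            if a1 - a0 <= min_length // 2:
                continue
            b0, b1 = c - (a1 - k), c - a0 + k
            candidates.append((a0, a1, b0, b1, "-"))

    # base-by-base extension while the two locations remain identical
    Slen = len(S)
    verified = []  # (a0, a1, b0, b1, strand)
    for a0, a1, b0, b1, strand in candidates:
        if strand == "+":
            while a0 > 0 and b0 > 0 and b0 - 1 >= a1 and S[a0 - 1] == S[b0 - 1]:
                a0 -= 1
                b0 -= 1
            while a1 < Slen and b1 < Slen and a1 < b0 and S[a1] == S[b1]:
                a1 += 1
                b1 += 1
            sub_b = S[b0:b1]
        else:
            while a0 > 0 and b1 < Slen and S[a0 - 1] == _COMP[S[b1]]:
                a0 -= 1
                b1 += 1
            while a1 < Slen and b0 > 0 and a1 < b0 and S[a1] == _COMP[S[b0 - 1]]:
                a1 += 1
                b0 -= 1
            sub_b = revcomp(S[b0:b1])
        identity, _, columns = global_identity(S[a0:a1], sub_b)
        if columns > min_length and identity > min_identity:
            verified.append((a0, a1, b0, b1, strand, identity))

    if not verified:
        return []

    # merge overlapping intervals into copies
    intervals = []
    for a0, a1, b0, b1, strand, _ in verified:
        intervals.append((a0, a1))
        intervals.append((b0, b1))
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    def find_copy(s, e):
        for ci, (ms, me) in enumerate(merged):
            if s >= ms and e <= me:
                return ci
        raise AssertionError("interval not covered by merge")

    # connected components over verified pairs, tracking relative orientation
    parent = list(range(len(merged)))

    def root(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for a0, a1, b0, b1, strand, ident in verified:
        ca, cb = find_copy(a0, a1), find_copy(b0, b1)
        edges.append((ca, cb, strand))
        parent[root(ca)] = root(cb)

    comp_members: dict[int, list[int]] = defaultdict(list)
    for ci in range(len(merged)):
        comp_members[root(ci)].append(ci)

    adj: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for ca, cb, strand in edges:
        adj[ca].append((cb, strand))
        adj[cb].append((ca, strand))

    families: list[ISFamily] = []
    for members in comp_members.values():
        if len(members) < 2:
            continue
        # orientation by BFS from the left-most copy
        members.sort(key=lambda ci: merged[ci][0])
        strand_of = {members[0]: "+"}
        queue = [members[0]]
        while queue:
            cur = queue.pop(0)
            for nxt, s in adj[cur]:
                if nxt in strand_of:
                    continue
                strand_of[nxt] = strand_of[cur] if s == "+" else (
                    "-" if strand_of[cur] == "+" else "+"
                )
                queue.append(nxt)
        copies = []
        seqs = []
        seen_keys = set()
        for ci in members:
            ms, me = merged[ci]
            start, end = ms, me
            if genome.is_circular:
                if start >= n:
                    continue  # doubled-sequence duplicate
                key = (start % n, end - start)
                if key in seen_keys:
                    continue
                seen_keys.add(key)
            sub = S[ms:me]
            strand = strand_of.get(ci, "+")
            seqs.append(sub if strand == "+" else revcomp(sub))
            copies.append(RepeatCopy(start, end, strand))
        if len(copies) < 2:
            continue
        consensus = _consensus(seqs)
        for copy, s in zip(copies, seqs):
            copy.identity_to_consensus = global_identity(s, consensus)[0]
        families.append(ISFamily(name="", consensus=consensus, copies=copies))

    families.sort(key=lambda f: min(c.start for c in f.copies))
    for i, fam in enumerate(families):
        fam.name = f"{prefix}{i + 1}"
        fam.copies.sort(key=lambda c: c.start)
    return families


def _consensus(seqs: list[str]) -> str:
    """Per-column majority consensus; ties break to the lexicographic base."""
    ref = max(seqs, key=len)
    counts = [defaultdict(int) for _ in range(len(ref))]
    for s in seqs:
        if len(s) == len(ref):
            for i, b in enumerate(s):
                counts[i][b] += 1
            continue
        res = edlib.align(s, ref, mode="NW", task="path")
        qi = ri = 0
        for num, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
            ln = int(num)
            if op in "=X":
                for t in range(ln):
                    counts[ri + t][s[qi + t]] += 1
                qi += ln
                ri += ln
            elif op == "I":  # insertion relative to ref: skip query bases
                qi += ln
            else:  # deletion: ref bases unmatched
                ri += ln
    return "".join(
        max(sorted(c.items()), key=lambda kv: kv[1])[0] if c else "N"
        for c in counts
    )


def tag_transposase(
    families: list[ISFamily], features: list[Feature]
) -> list[ISFamily]:
    """Record transposase products of CDS overlapping family copies.

    Families with a matching product are tagged IS; families overlapping only
    non-transposase CDS (e.g. rRNA operons) are flagged non-IS repeats; with
    no annotation at all every family stays "unevaluated".
    """
    cds = [f for f in features if f.kind == "CDS" and "product" in f.qualifiers]
    for fam in families:
        if not cds:
            fam.transposase_status = "unevaluated"
            continue
        products = []
        overlapped = False
        for copy in fam.copies:
            for f in cds:
                if f.start < copy.end and copy.start < f.end:
                    overlapped = True
                    prod = f.qualifiers["product"]
                    if any(v in prod.lower() for v in TRANSPOSASE_VOCAB):
                        products.append(prod)
        fam.transposase_products = sorted(set(products))
        if products:
            fam.transposase_status = "is"
        elif overlapped:
            fam.transposase_status = "non_is"
        else:
            fam.transposase_status = "unevaluated"
    return families


def detect_terminal_irs(
    family: ISFamily,
    search_span: int = 60,
    min_ir: int = 10,
    max_mismatch_fraction: float = 0.25,
    anchor_slop: int = 5,
) -> ISFamily:
    """Detect terminal inverted repeats on the family consensus.

    The first ``search_span`` bases are compared, ungapped, against the
    reverse complement of the last ``search_span`` bases, anchored within
    ``anchor_slop`` bases of each terminus. The best alignment under a
    +1 match / -3 mismatch score is reported as
    (left seq, right seq, identical, total) when total >= ``min_ir`` and the
    mismatch fraction stays within bounds; the penalty stops chance flank
    matches from inflating the repeat beyond its real extent.
    """
    cons = family.consensus
    span = min(search_span, len(cons) // 2)
    left = cons[:span]
    right_rc = revcomp(cons[-span:])  # right_rc[0] pairs with the 3' terminus
    best = None
    for a in range(anchor_slop + 1):
        for b in range(anchor_slop + 1):
            limit = min(span - a, span - b)
            mism = 0
            for ln in range(1, limit + 1):
                if left[a + ln - 1] != right_rc[b + ln - 1]:
                    mism += 1
                if ln >= min_ir and mism / ln <= max_mismatch_fraction:
                    ident = ln - mism
                    score = ident - 3 * mism
                    cand = (score, ln, -a, -b, ident, mism)
                    if best is None or cand > best:
                        best = cand
    if best is None:
        family.ir = None
        return family
    score, ln, neg_a, neg_b, ident, _ = best
    a, b = -neg_a, -neg_b
    left_seq = cons[a : a + ln]
    right_seq = cons[len(cons) - b - ln : len(cons) - b]
    family.ir = (left_seq, right_seq, ident, ln)
    return family


def detect_tsds(
    genome: GenomeRecord, family: ISFamily, max_tsd: int = 12, min_tsd: int = 2
) -> ISFamily:
    """Call per-copy target-site duplications and the family-level TSD.

    A copy's TSD is the longest k in [min_tsd, max_tsd] with the k bases
    immediately left of the copy equal to the k bases immediately right of
    it. A family-level TSD is reported only when >= 2 copies carry
    equal-length TSDs whose sequences differ between copies — identical
    flanks at every copy belong to the element (or a target preference) and
    are flagged instead.
    """
    seq = genome.sequence
    n = len(seq)
    tsds: list[str | None] = []
    for copy in family.copies:
        found = None
        for klen in range(max_tsd, min_tsd - 1, -1):
            if copy.start - klen < 0 or copy.end + klen > n:
                continue
            left = seq[copy.start - klen : copy.start]
            right = seq[copy.end : copy.end + klen]
            if left == right:
                found = left
                break
        tsds.append(found)
    family.tsds = tsds
    present = [t for t in tsds if t is not None]
    family.tsd_length = None
    if len(present) >= 2:
        lengths = {len(t) for t in present}
        if len(lengths) == 1:
            if len(set(present)) == 1:
                family.notes.append(
                    "identical flanking sequence at every copy: rejected as "
                    "TSD (element terminus or target preference); review"
                )
            elif len(set(present)) == len(present):
                family.tsd_length = lengths.pop()
    return family


def refine_extent(
    genome: GenomeRecord,
    family: ISFamily,
    ext_identity: float = 0.99,
    agree_window: int = 20,
) -> ISFamily:
    """Extend family boundaries over the full conserved extent.

    Both boundaries move outward column by column while all copies carry the
    same base and the trailing ``agree_window`` columns stay >=
    ``ext_identity`` in agreement; extension also stops at genome bounds and
    before two copies would touch. Copy coordinates are updated and the
    conserved extent length recorded. When every copy shares an identical
    terminal short (<=10 bp) flank the extent is flagged as possibly
    including the target site.
    """
    if len(family.copies) < 2:
        logger.warning("family %s has one copy; extent not refined", family.name)
        return family
    seq = genome.sequence
    n = len(seq)
    copies = sorted(family.copies, key=lambda c: c.start)

    def genomic_limits(idx: int) -> tuple[int, int]:
        """Exclusive-of-neighbours genomic window a copy may grow into."""
        s, e = copies[idx].start, copies[idx].end
        lo = max([c.end for c in copies if c.end <= s], default=0)
        hi = min([c.start for c in copies if c.start >= e], default=n)
        return lo, hi

    ext = {"left": 0, "right": 0}  # element orientation, shared by all copies

    def apply_side(side: str) -> None:
        # commit one side's extension so the other side sees updated
        # neighbour limits (keeps adjacent copies from jointly overlapping)
        d = ext[side]
        if not d:
            return
        for copy in copies:
            if (side == "left") == (copy.strand == "+"):
                copy.start -= d
            else:
                copy.end += d

    for side in ("left", "right"):
        agreements: list[bool] = []
        while True:
            bases = []
            for i, copy in enumerate(copies):
                lo, hi = genomic_limits(i)
                grow_left = (side == "left") == (copy.strand == "+")
                if grow_left:
                    p = copy.start - ext[side] - 1
                    if p < lo:
                        bases = None
                        break
                    b = seq[p]
                else:
                    p = copy.end + ext[side]
                    if p >= hi:
                        bases = None
                        break
                    b = seq[p]
                bases.append(b if copy.strand == "+" else _COMP[b])
            if bases is None:
                break
            agree = len(set(bases)) == 1
            agreements.append(agree)
            win = agreements[-agree_window:]
            if sum(win) / len(win) < ext_identity:
                agreements.pop()
                break
            ext[side] += 1
        while agreements and not agreements[-1]:  # trim trailing disagreement
            agreements.pop()
            ext[side] -= 1
        apply_side(side)

    if ext["left"] or ext["right"]:
        oriented = [
            seq[c.start : c.end] if c.strand == "+"
            else revcomp(seq[c.start : c.end])
            for c in copies
        ]
        family.consensus = _consensus(oriented)
    family.refined_extent = len(family.consensus)
    family.copies = copies

    # identical terminal <=10-mers shared by all copies may be the target
    # site rather than the element; only experiments can resolve that
    for tlen in range(10, 0, -1):
        termini = set()
        for c in copies:
            el = seq[c.start : c.end] if c.strand == "+" else revcomp(
                seq[c.start : c.end]
            )
            termini.add(el[:tlen])
            termini.add(revcomp(el[-tlen:]))
        if len(termini) == 1:
            family.notes.append(
                f"refined extent shares identical terminal {tlen}-mers across "
                "all copies; may include the target site (<10 bp)"
            )
            break
    return family


def scan_homologs(
    genome: GenomeRecord,
    family: ISFamily,
    min_identity: float = 0.70,
    min_coverage: float = 0.70,
) -> list[RepeatCopy]:
    """Find divergent single-copy relatives of a family consensus.

    Genome locations outside the family's own copies that align to the
    consensus at >= ``min_identity`` over >= ``min_coverage`` of its length
    are reported, identity measured as matches / alignment columns. Ties are
    broken by (higher identity, lower start coordinate).
    """
    cons = family.consensus
    L = len(cons)
    max_ed = int(L * (1 - min_identity) * 1.5) + 1
    masked = list(genome.sequence)
    for c in family.copies:
        for p in range(c.start, c.end):
            masked[p] = "N"
    hits: list[RepeatCopy] = []
    for strand in "+-":
        target = "".join(masked)
        if strand == "-":
            target = revcomp(target)
        work = target
        for _ in range(20):  # cap recruited relatives per strand
            res = best_infix(cons, work, max_ed)
            if res is None:
                break
            s, e, ident, columns = res
            if ident < min_identity:
                break
            cov = min(1.0, (e - s) / L)
            if cov >= min_coverage:
                if strand == "+":
                    hits.append(RepeatCopy(s, e, "+", ident))
                else:
                    n = len(genome)
                    hits.append(RepeatCopy(n - e, n - s, "-", ident))
            work = work[:s] + "N" * (e - s) + work[e:]
    hits.sort(key=lambda h: (-h.identity_to_consensus, h.start))
    return hits


def find_empty_sites(
    family: ISFamily,
    donor: GenomeRecord,
    reference: GenomeRecord,
    flank: int = 200,
    min_flank_identity: float = 0.95,
) -> list[tuple[int | None, int, str]]:
    """Locate naive (element-free) insertion sites in a second genome.

    For each copy, the ``flank`` bases on either side are placed in
    ``reference``; an empty site is reported when they sit adjacent (offset
    within one TSD length) with no intervening element. Returns
    (reference position or None, copy index, status) where status is
    "empty", "occupied_or_distant" or "untraceable".
    """
    out = []
    tsd_len = family.tsd_length or 0
    ref_seq = reference.sequence
    max_ed = int(flank * (1 - min_flank_identity) * 1.5) + 1
    for ci, copy in enumerate(family.copies):
        ls = donor.sequence[max(0, copy.start - flank) : copy.start]
        rs = donor.sequence[copy.end : copy.end + flank]
        if len(ls) < flank // 2 or len(rs) < flank // 2:
            out.append((None, ci, "untraceable"))
            continue
        lhit = best_infix(ls, ref_seq, max_ed)
        rhit = best_infix(rs, ref_seq, max_ed)
        if (
            lhit is None
            or rhit is None
            or lhit[2] < min_flank_identity
            or rhit[2] < min_flank_identity
        ):
            out.append((None, ci, "untraceable"))
            continue
        gap = rhit[0] - lhit[1]
        if abs(gap) <= max(tsd_len, 2):
            out.append((lhit[1], ci, "empty"))
        else:
            out.append((None, ci, "occupied_or_distant"))
    return out


def family_table(families: list[ISFamily]) -> str:
    """TSV summary of discovered families."""
    lines = [
        "name\tn_copies\tcoordinates\tstrands\tir\ttsd_length\ttsds\t"
        "transposase\trefined_extent"
    ]
    for fam in families:
        coords = ",".join(f"{c.start}-{c.end}" for c in fam.copies)
        strands = ",".join(c.strand for c in fam.copies)
        ir = f"{fam.ir[2]}/{fam.ir[3]}" if fam.ir else "."
        tsds = ",".join(t or "." for t in fam.tsds) if fam.tsds else "."
        prods = ";".join(fam.transposase_products) or fam.transposase_status
        lines.append(
            f"{fam.name}\t{len(fam.copies)}\t{coords}\t{strands}\t{ir}\t"
            f"{fam.tsd_length if fam.tsd_length else '.'}\t{tsds}\t{prods}\t"
            f"{fam.refined_extent if fam.refined_extent else '.'}"
        )
    return "\n".join(lines) + "\n"
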