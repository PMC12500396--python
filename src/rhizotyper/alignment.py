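"""Thin pairwise-alignment helpers on top of edlib.

Identity is everywhere defined as matching columns / alignment columns, with
gap columns counted — the "1,044 of 1,407 bp" convention.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_stats(cigar: str) -> tuple[int, int]:
    """(matching columns, total columns) from an extended cigar string."""
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def global_identity(a: str, b: str) -> tuple[float, int, int]:
    """Global (NW) alignment identity of two sequences.

    Returns (identity, matching columns, total columns).
    """
    res = edlib.align(a, b, mode="NW", task="path")
    matches, columns = cigar_stats(res["cigar"])
    return matches / columns if columns else 0.0, matches, columns


def best_infix(query: str, target: str, max_ed: int = -1):
    """Best infix (HW) placement of ``query`` in ``target``.

    Returns (target_start, target_end_exclusive, identity, columns) or None
    when no alignment within ``max_ed`` exists.
    """
    res = edlib.align(query, target, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    end += 1
    identity, _, columns = global_identity(query, target[start:end])
    return start, end, identity, columns
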