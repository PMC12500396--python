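"""Fragment-based average nucleotide identity and species delineation.

The query genome is cut into non-overlapping fragments (default 1020 bp,
the ANIb convention); each fragment is placed at its best reference
location by exact k-mer seeding with diagonal voting followed by a
banded-window alignment, on both strands. Fragments are retained when they
align at >= 70 % identity over >= 70 % of their length, and ANI is 100x the
mean identity of retained fragments. Species are the connected components
of the >= threshold (default 95 %) graph; an undefined ANI (no mapped
fragments) is "no edge", never zero.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .alignment import best_infix
from .genome_io import GenomeRecord, QCRecord, revcomp

logger = logging.getLogger(__name__)

SEED_K = 16


@dataclass
class ANIResult:
    """One directed pairwise fragment-ANI measurement."""

    query_id: str
    ref_id: str
    ani: float | None  # percent; None when no fragment mapped
    fragments_total: int
    fragments_mapped: int

    @property
    def aligned_fraction(self) -> float:
        if self.fragments_total == 0:
            return 0.0
        return self.fragments_mapped / self.fragments_total


@dataclass
class SpeciesClustering:
    """Threshold-derived species components with identity summaries."""

    threshold: float
    components: list[set[str]]
    intra_range: tuple[float, float] | None
    inter_range: tuple[float, float] | None


def _as_records(genomes) -> list[GenomeRecord]:
    if isinstance(genomes, GenomeRecord):
        return [genomes]
    return list(genomes)


class _SeedIndex:
    """Exact k-mer index of a reference record set (both strands via query rc)."""

    def __init__(self, records: list[GenomeRecord], k: int = SEED_K):
        self.k = k
        self.seq = "".join(r.sequence for r in records)
        self.index: dict[str, list[int]] = defaultdict(list)
        step = 1
        for i in range(0, len(self.seq) - k + 1, step):
            word = self.seq[i : i + k]
            if "N" not in word:
                self.index[word].append(i)


def _map_fragment(frag: str, idx: _SeedIndex, band: int = 120):
    """Best placement of a fragment via seed diagonal voting + alignment.

    Returns identity (matches/columns) or None when no seed chains.
    """
    best = None
    for oriented in (frag, revcomp(frag)):
        votes: dict[int, int] = defaultdict(int)
        k = idx.k
        for off in range(0, len(oriented) - k + 1, k):
            word = oriented[off : off + k]
            for p in idx.index.get(word, ()):
                votes[(p - off) // band] += 1
        if not votes:
            continue
        diag_band = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        start = diag_band * band
        lo = max(0, start - band)
        hi = min(len(idx.seq), start + len(oriented) + 2 * band)
        window = idx.seq[lo:hi]
        hit = best_infix(oriented, window, max_ed=int(len(oriented) * 0.6))
        if hit is None:
            continue
        identity = hit[2]
        if best is None or identity > best:
            best = identity
    return best


def fragment_ani(
    query,
    reference,
    fragment_length: int = 1020,
    min_fragment_identity: float = 0.70,
    min_fragment_coverage: float = 0.70,
    _ref_index: _SeedIndex | None = None,
) -> ANIResult:
    """Directed fragment ANI of ``query`` against ``reference``.

    Fragments never span record boundaries; the trailing fragment shorter
    than ``fragment_length`` is dropped.
    """
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    q_records = _as_records(query)
    r_records = _as_records(reference)
    if not q_records or not r_records:
        raise ValueError("empty genome input")
    idx = _ref_index if _ref_index is not None else _SeedIndex(r_records)

    identities = []
    total = 0
    for rec in q_records:
        seq = rec.sequence
        for s in range(0, len(seq) - fragment_length + 1, fragment_length):
            frag = seq[s : s + fragment_length]
            total += 1
            ident = _map_fragment(frag, idx)
            if ident is not None and ident >= min_fragment_identity:
                identities.append(ident)
    mapped = len(identities)
    ani = 100.0 * float(np.mean(identities)) if mapped else None
    if ani is None:
        logger.info(
            "%s vs %s: no fragments mapped (unrelated)",
            q_records[0].id, r_records[0].id,
        )
    return ANIResult(
        query_id=q_records[0].id,
        ref_id=r_records[0].id,
        ani=ani,
        fragments_total=total,
        fragments_mapped=mapped,
    )


def ani_matrix(genomes: list, **kwargs) -> dict[tuple[str, str], ANIResult]:
    """All ordered pairwise fragment-ANI results, keyed by (query, ref) id."""
    records = [_as_records(g) for g in genomes]
    if len(records) < 2:
        raise ValueError("need >= 2 genomes")
    ids = [recs[0].id for recs in records]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    indexes = [_SeedIndex(recs) for recs in records]
    out = {}
    for qi, q in enumerate(records):
        for ri, r in enumerate(records):
            if qi == ri:
                continue
            out[(ids[qi], ids[ri])] = fragment_ani(
                q, r, _ref_index=indexes[ri], **kwargs
            )
    return out


def symmetrize(results: dict[tuple[str, str], ANIResult]) -> dict[frozenset, float]:
    """Mean of the two directions where both defined, else the defined one."""
    sym: dict[frozenset, float] = {}
    for (q, r), res in results.items():
        key = frozenset((q, r))
        if res.ani is None:
            continue
        if key in sym:
            sym[key] = (sym[key] + res.ani) / 2
        else:
            sym[key] = res.ani
    return sym


def genome_ids_of(sym: dict[frozenset, float]) -> list[str]:
    ids = set()
    for key in sym:
        ids |= set(key)
    return sorted(ids)


def qc_filter(
    records: list[QCRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Keep genomes with completeness >= min and contamination <= max.

    Boundary values are kept: the filter drops strictly-below-90 /
    strictly-above-5 genomes.
    """
    kept, dropped = [], []
    for r in records:
        reasons = []
        if r.completeness < min_completeness:
            reasons.append(f"completeness {r.completeness} < {min_completeness}")
        if r.contamination > max_contamination:
            reasons.append(f"contamination {r.contamination} > {max_contamination}")
        if reasons:
            dropped.append((r.genome_id, "; ".join(reasons)))
        else:
            kept.append(r.genome_id)
    return kept, dropped


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def _components(ids, sym, threshold):
    uf = _UnionFind(ids)
    for key, val in sym.items():
        if len(key) == 2 and val >= threshold:
            a, b = sorted(key)
            uf.union(a, b)
    comps: dict[str, set[str]] = defaultdict(set)
    for g in ids:
        comps[uf.find(g)].add(g)
    return sorted(comps.values(), key=lambda c: sorted(c)[0])


def cluster_species(
    sym: dict[frozenset, float],
    threshold: float = 95.0,
    genome_ids: list[str] | None = None,
) -> SpeciesClustering:
    """Union-find components of the >= threshold ANI graph.

    Intra ranges are computed over defined pairs within components, inter
    over defined pairs across components.
    """
    ids = genome_ids if genome_ids is not None else genome_ids_of(sym)
    comps = _components(ids, sym, threshold)
    comp_of = {}
    for i, c in enumerate(comps):
        for g in c:
            comp_of[g] = i
    intra, inter = [], []
    for key, val in sym.items():
        if len(key) != 2:
            continue
        a, b = sorted(key)
        if a not in comp_of or b not in comp_of:
            continue
        (intra if comp_of[a] == comp_of[b] else inter).append(val)
    return SpeciesClustering(
        threshold=threshold,
        components=comps,
        intra_range=(min(intra), max(intra)) if intra else None,
        inter_range=(min(inter), max(inter)) if inter else None,
    )


def clade_summary(
    sym: dict[frozenset, float], labels: dict[str, str]
) -> tuple[dict[str, tuple[float, float] | None], tuple[float, float] | None]:
    """Min/max ANI within each clade label and across labels."""
    ids = genome_ids_of(sym)
    missing = [g for g in ids if g not in labels]
    if missing:
        raise ValueError(f"unlabelled genomes: {missing}")
    intra: dict[str, list[float]] = defaultdict(list)
    inter: list[float] = []
    for key, val in sym.items():
        if len(key) != 2:
            continue
        a, b = sorted(key)
        if labels[a] == labels[b]:
            intra[labels[a]].append(val)
        else:
            inter.append(val)
    intra_ranges = {
        clade: ((min(v), max(v)) if v else None)
        for clade, v in (
            (c, intra.get(c, [])) for c in sorted(set(labels.values()))
        )
    }
    return intra_ranges, ((min(inter), max(inter)) if inter else None)


def flag_outliers(
    sym: dict[frozenset, float],
    species_labels: dict[str, str],
    type_strain_of: dict[str, str],
    threshold: float = 95.0,
) -> list[tuple[str, str, float]]:
    """Genomes below ``threshold`` ANI to their own species' type strain."""
    out = []
    for genome, species in sorted(species_labels.items()):
        ts = type_strain_of.get(species)
        if ts is None:
            logger.warning("species %s has no type strain; skipped", species)
            continue
        if genome == ts:
            continue
        val = sym.get(frozenset((genome, ts)))
        if val is not None and val < threshold:
            out.append((genome, species, val))
    return out


def near_identical_groups(
    sym: dict[frozenset, float], threshold: float = 99.0
) -> list[set[str]]:
    """Components (>= 2 members) of the >= threshold graph: likely clones."""
    ids = genome_ids_of(sym)
    return [c for c in _components(ids, sym, threshold) if len(c) >= 2]


def nj_tree(sym: dict[frozenset, float]) -> str:
    """Neighbour-joining newick tree from ANI distances d = (100 - ani)/100.

    Negative branch lengths are clamped to zero. Requires every pair
    defined.
    """
    ids = genome_ids_of(sym)
    if len(ids) < 2:
        raise ValueError("need >= 2 genomes for a tree")
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            val = sym.get(frozenset((ids[i], ids[j])))
            if val is None:
                raise ValueError(
                    f"ANI undefined for pair ({ids[i]}, {ids[j]}); genomes "
                    "may be unrelated — check thresholds before tree building"
                )
            dm[i, j] = dm[j, i] = (100.0 - val) / 100.0
    if n == 2:
        half = dm[0, 1] / 2
        return f"({ids[0]}:{half:.6f},{ids[1]}:{half:.6f});"
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(dm, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def matrix_tsv(sym: dict[frozenset, float]) -> str:
    """Symmetric ANI matrix as TSV (diagonal 100, undefined pairs 'NA')."""
    ids = genome_ids_of(sym)
    lines = ["\t".join(["genome"] + ids)]
    for a in ids:
        row = [a]
        for b in ids:
            if a == b:
                row.append("100.0")
            else:
                v = sym.get(frozenset((a, b)))
                row.append(f"{v:.4f}" if v is not None else "NA")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_matrix_tsv(source) -> dict[frozenset, float]:
    """Read a symmetric ANI matrix TSV back into the pairwise dict form."""
    import io
    import os

    import pandas as pd

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        df = pd.read_csv(source, sep="\t", index_col=0)
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t", index_col=0)
    sym: dict[frozenset, float] = {}
    ids = list(df.columns)
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            v = df.loc[a, b]
            if pd.notna(v):
                sym[frozenset((a, b))] = float(v)
    return sym


def pairs_tsv(results: dict[tuple[str, str], ANIResult]) -> str:
    """Long-format directed ANI table."""
    lines = ["query\tref\tani\tfragments_mapped\tfragments_total"]
    for (q, r), res in sorted(results.items()):
        ani = f"{res.ani:.4f}" if res.ani is not None else "NA"
        lines.append(
            f"{q}\t{r}\t{ani}\t{res.fragments_mapped}\t{res.fragments_total}"
        )
    return "\n".join(lines) + "\n"
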