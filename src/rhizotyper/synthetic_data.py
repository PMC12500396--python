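"""Synthetic genomes with planted, exactly-known features.

Every generator is a pure function of its arguments plus a single integer
seed (one ``numpy.random.Generator`` per call, no global state), and returns
the planted truth alongside the sequence so discovery modules can be tested
for exact recovery without any downloads.

Defaults emulate a high-GC actinobacterial chromosome: GC 0.706, multi-copy
IS elements with terminal inverted repeats and 2-12 bp target-site
duplications, a cas-anchored CRISPR array of 28 bp repeats and 33-34 bp
spacers, and a dnaA-dnaN intergenic oriC carrying DnaA-box arrays, a
DnaA-trio run and an AT-rich unwinding element. The default fixture length
is 200 kb — all downstream algorithms are length-agnostic, so fixtures are
scaled down from the megabase range for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Feature, GenomeRecord, revcomp

BASES = np.array(["A", "C", "G", "T"])
DEFAULT_GC = 0.706
DNAA_BOX = "TTGTCCACA"

GLOBAL_CLASSES = ("core", "soft_core", "shell", "cloud")
CLADE_CLASSES = ("core", "shell", "cloud")


@dataclass
class PlantTruth:
    """Ground truth for one planted feature set."""

    kind: str  # is_element | crispr | oric
    intervals: list[tuple[int, int, str]]
    payload: dict = field(default_factory=dict)


@dataclass
class CladeSimSpec:
    """Parameters for a two-clade star-within-star divergence simulation.

    ``inter_divergence`` is the total expected substitution proportion
    separating the two clade founders; ``intra_divergence`` the proportion
    separating two members of the same clade. Pairwise identities are then
    approximately 1 - (sum of path divergences), valid for rates <= 0.05.
    """

    n_per_clade: tuple[int, int]
    intra_divergence: float
    inter_divergence: float
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.intra_divergence, self.inter_divergence, self.indel_rate):
            if not (0 <= r < 0.5):
                raise ValueError("rates must lie in [0, 0.5)")
        if self.inter_divergence <= self.intra_divergence:
            raise ValueError("inter_divergence must exceed intra_divergence")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def random_genome(
    length: int, gc: float = DEFAULT_GC, seed: int = 0, id: str = "synthetic"
) -> GenomeRecord:
    """I.i.d. random genome with P(G)=P(C)=gc/2, reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc <= 1):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return GenomeRecord(id=id, sequence=_random_seq(rng, length, gc))


def plant_is_copies(
    genome: GenomeRecord,
    element_length: int = 1200,
    n_copies: int = 3,
    ir_length: int = 16,
    tsd_length: int = 0,
    seed: int = 0,
    sites: list[int] | None = None,
    site_range: tuple[int, int] | None = None,
    transposase_product: str | None = "IS30 family transposase",
) -> tuple[GenomeRecord, PlantTruth]:
    """Insert ``n_copies`` of one IS-like element, recording exact truth.

    The element carries perfect ``ir_length`` terminal inverted repeats; when
    ``tsd_length`` > 0 the bases immediately left of each insertion point are
    duplicated to flank the element, with distinct duplications across sites.
    The genome grows by ``n_copies * (element_length + tsd_length)``. Unless
    ``transposase_product`` is None, each copy gets a CDS stub feature
    carrying that product so annotation-dependent steps can be exercised.
    """
    if element_length < 2 * ir_length + 100:
        raise ValueError("element_length must be >= 2*ir_length + 100")
    rng = np.random.default_rng(seed)
    margin = 300 + tsd_length
    if sites is None:
        lo, hi = site_range or (margin, len(genome) - margin)
        lo = max(lo, margin)
        hi = min(hi, len(genome) - margin)
        if hi - lo < n_copies * 2 * element_length:
            raise ValueError("genome too short for requested placements")
        seq0 = genome.sequence
        for _ in range(2000):
            cand = np.sort(rng.integers(lo, hi, size=n_copies))
            if n_copies > 1 and np.diff(cand).min() < 2 * element_length:
                continue
            # the bases immediately flanking each insertion must be pairwise
            # distinct across copies, so the planted element is the unique
            # maximal conserved interval (otherwise boundary truth is
            # ill-defined, as conservation genuinely extends into the flanks)
            left = [seq0[s - tsd_length - 1] for s in cand]
            right = [seq0[s] for s in cand]
            if len(set(left)) < n_copies or len(set(right)) < n_copies:
                continue
            if tsd_length:
                # flank rule applies to the duplicated bases themselves
                tsds = [seq0[s - tsd_length : s] for s in cand]
                first = [t[0] for t in tsds]
                last = [t[-1] for t in tsds]
                if len(set(first)) < n_copies or len(set(last)) < n_copies:
                    continue
            sites = [int(s) for s in cand]
            break
        else:
            raise ValueError("could not place non-clashing insertion sites")
    sites = sorted(sites)

    ir = _random_seq(rng, ir_length, 0.5) if ir_length else ""
    core = _random_seq(rng, element_length - 2 * ir_length, DEFAULT_GC)
    if ir_length:
        # pin the bases just inside the IRs so they cannot base-pair: the
        # planted IR is then the unique maximal inverted repeat
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if core[0] == comp[core[-1]]:
            repl = "A" if core[0] != "A" else "C"
            core = repl + core[1:]
    element = ir + core + revcomp(ir)

    seq = genome.sequence
    pieces = []
    prev = 0
    intervals = []
    tsd_seqs = []
    shift = 0
    for s in sites:
        tsd = seq[s - tsd_length : s] if tsd_length else ""
        pieces.append(seq[prev:s])
        pieces.append(element + tsd)
        start = s + shift
        intervals.append((start, start + element_length, "+"))
        tsd_seqs.append(tsd)
        shift += element_length + tsd_length
        prev = s
    pieces.append(seq[prev:])
    new_seq = "".join(pieces)

    unit = element_length + tsd_length
    features = [
        Feature(
            f.kind,
            f.start + unit * sum(1 for s in sites if s <= f.start),
            f.end + unit * sum(1 for s in sites if s <= f.start),
            f.strand,
            dict(f.qualifiers),
        )
        for f in genome.features
    ]
    if transposase_product:
        for s, e, _ in intervals:
            features.append(
                Feature("CDS", s + ir_length + 10, e - ir_length - 10, "+",
                        {"product": transposase_product})
            )

    out = GenomeRecord(
        id=genome.id,
        sequence=new_seq,
        description=genome.description,
        is_circular=genome.is_circular,
        features=features,
    )
    truth = PlantTruth(
        kind="is_element",
        intervals=intervals,
        payload={
            "element": element,
            "ir_length": ir_length,
            "tsd_length": tsd_length,
            "tsds": tsd_seqs,
        },
    )
    return out, truth


def plant_crispr(
    genome: GenomeRecord,
    n_spacers: int = 98,
    repeat_length: int = 28,
    spacer_lengths: tuple[int, ...] = (33, 34),
    cas_stub: bool = True,
    seed: int = 0,
    at: int | None = None,
) -> tuple[GenomeRecord, PlantTruth]:
    """Insert a CRISPR array: repeat, then (spacer, repeat) x n_spacers.

    Yields ``n_spacers + 1`` identical repeat copies separated by mutually
    distinct random spacers. With ``cas_stub`` a type I-E cas operon of CDS
    features (cas3 + cascade + cas1/cas2) is placed immediately upstream.
    """
    if n_spacers < 2:
        raise ValueError("n_spacers must be >= 2")
    rng = np.random.default_rng(seed)
    repeat = _random_seq(rng, repeat_length, 0.5)

    cas_span = 9000 if cas_stub else 0
    approx_len = repeat_length + n_spacers * (max(spacer_lengths) + repeat_length)
    if at is None:
        lo = cas_span + 500
        hi = len(genome) - approx_len - 500
        if hi <= lo:
            raise ValueError("genome too short for CRISPR array")
        at = int(rng.integers(lo, hi))
    if at < cas_span:
        raise ValueError("insertion point leaves no room for cas stub")

    # spacers are mutually distinct, and the columns immediately flanking
    # the repeats (spacer first/last bases plus the genome bases abutting
    # the array) are not unanimous — otherwise the repeat unit would
    # genuinely extend into them and the planted length would be ambiguous
    left_flank = genome.sequence[at - 1] if at > 0 else "A"
    for _ in range(200):
        spacers: list[str] = []
        seen: set[str] = set()
        while len(spacers) < n_spacers:
            ln = int(rng.choice(list(spacer_lengths)))
            sp = _random_seq(rng, ln, DEFAULT_GC)
            if sp not in seen:
                seen.add(sp)
                spacers.append(sp)
        right_flank = genome.sequence[at] if at < len(genome) else "A"
        firsts = {sp[0] for sp in spacers} | {right_flank}
        lasts = {sp[-1] for sp in spacers} | {left_flank}
        if len(firsts) > 1 and len(lasts) > 1:
            break
    array = repeat + "".join(sp + repeat for sp in spacers)

    seq = genome.sequence[:at] + array + genome.sequence[at:]
    features = [
        Feature(f.kind, f.start + (len(array) if f.start >= at else 0),
                f.end + (len(array) if f.start >= at else 0), f.strand,
                dict(f.qualifiers))
        for f in genome.features
    ]

    repeats = []
    spacer_truth = []
    pos = at
    repeats.append((pos, repeat))
    pos += repeat_length
    for sp in spacers:
        spacer_truth.append((pos, sp))
        pos += len(sp)
        repeats.append((pos, repeat))
        pos += repeat_length

    if cas_stub:
        cas_products = [
            "CRISPR-associated endonuclease Cas3",
            "CRISPR-associated protein Cse1",
            "CRISPR-associated protein Cse2",
            "CRISPR-associated protein Cas7",
            "CRISPR-associated protein Cas5",
            "CRISPR-associated endoribonuclease Cas6e",
            "CRISPR-associated endonuclease Cas1",
            "CRISPR-associated protein Cas2",
        ]
        p = at - cas_span
        for prod in cas_products:
            ln = 900
            features.append(
                Feature("CDS", p, p + ln, "+", {"product": prod})
            )
            p += ln + 100

    out = GenomeRecord(
        id=genome.id, sequence=seq, description=genome.description,
        is_circular=genome.is_circular, features=features,
    )
    truth = PlantTruth(
        kind="crispr",
        intervals=[(at, at + len(array), "+")],
        payload={
            "repeat": repeat,
            "repeats": repeats,
            "spacers": spacer_truth,
        },
    )
    return out, truth


def plant_oric(
    genome: GenomeRecord,
    n_boxes_per_array: tuple[int, int] = (5, 4),
    seed: int = 0,
    dnaA_at: int | None = None,
    intergenic_length: int = 700,
) -> tuple[GenomeRecord, PlantTruth]:
    """Write an oriC into the dnaA-dnaN intergenic region (length preserved).

    If the genome lacks dnaA/dnaN features, CDS stubs are added with
    ``intergenic_length`` bases between them. The intergenic region is
    overwritten with: an AT-rich 50-base unwinding element, a >=3-copy
    tandem DnaA-trio run, and two clustered arrays of exact DnaA-box 9-mers.
    """
    rng = np.random.default_rng(seed)
    features = [
        Feature(f.kind, f.start, f.end, f.strand, dict(f.qualifiers))
        for f in genome.features
    ]
    named = {
        f.qualifiers.get("gene"): f for f in features if f.kind == "CDS"
    }
    if "dnaA" in named and "dnaN" in named:
        ig_start = named["dnaA"].end
        ig_end = named["dnaN"].start
    else:
        if dnaA_at is None:
            dnaA_at = 2000
        dnaA = Feature("CDS", dnaA_at, dnaA_at + 1350, "+", {
            "gene": "dnaA",
            "product": "chromosomal replication initiator protein DnaA",
        })
        ig_start = dnaA.end
        ig_end = ig_start + intergenic_length
        dnaN = Feature("CDS", ig_end, ig_end + 1100, "+", {
            "gene": "dnaN",
            "product": "DNA polymerase III subunit beta",
        })
        features.extend([dnaA, dnaN])
    ig_len = ig_end - ig_start
    n1, n2 = n_boxes_per_array
    trio_copies = 5
    needed = 50 + 20 + trio_copies * 3 + 20 + n1 * (9 + 6) + 150 + n2 * (9 + 6)
    if ig_len < needed:
        raise ValueError(
            f"intergenic region too short: {ig_len} < {needed} bases"
        )

    # layout left to right: DUE | trio | array 1 | 150 nt gap | array 2
    parts: list[str] = []
    pos = ig_start
    due = "".join(rng.choice(["A", "T"], size=45)) + _random_seq(rng, 5, 0.5)
    due_iv = (pos, pos + 50)
    parts.append(due)
    pos += 50
    parts.append(_random_seq(rng, 20, DEFAULT_GC))
    pos += 20
    trio = "".join(
        "G" + rng.choice(["A", "T"]) + "T" for _ in range(trio_copies)
    )
    trio_iv = (pos, pos + len(trio), trio_copies)
    parts.append(trio)
    pos += len(trio)
    parts.append(_random_seq(rng, 20, DEFAULT_GC))
    pos += 20
    boxes = []
    arrays = []
    for n_boxes, gap_after in ((n1, 150), (n2, 0)):
        arr_start = len(boxes)
        for _ in range(n_boxes):
            boxes.append((pos, "+", DNAA_BOX))
            parts.append(DNAA_BOX)
            pos += 9
            parts.append(_random_seq(rng, 6, DEFAULT_GC))
            pos += 6
        arrays.append((arr_start, len(boxes)))
        if gap_after:
            parts.append(_random_seq(rng, gap_after, DEFAULT_GC))
            pos += gap_after
    filler = ig_len - (pos - ig_start)
    parts.append(_random_seq(rng, filler, DEFAULT_GC))
    region = "".join(parts)
    assert len(region) == ig_len

    seq = genome.sequence
    if ig_end > len(seq):
        raise ValueError("dnaN stub extends past genome end; use longer genome")
    new_seq = seq[:ig_start] + region + seq[ig_end:]
    out = GenomeRecord(
        id=genome.id, sequence=new_seq, description=genome.description,
        is_circular=genome.is_circular, features=features,
    )
    truth = PlantTruth(
        kind="oric",
        intervals=[(ig_start, ig_end, "+")],
        payload={
            "boxes": boxes,
            "box_arrays": arrays,
            "trio": trio_iv,
            "due": due_iv,
        },
    )
    return out, truth


def diverge(
    genome: GenomeRecord,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenomeRecord, dict]:
    """Mutate each site independently; return the mutant plus an exact log.

    Substituted sites change to one of the three alternative bases chosen
    uniformly. Indels of length 1-10 are applied at ``indel_rate`` per site.
    The log records every event, so the realised per-site substitution
    proportion is ``log["n_substitutions"] / log["length"]`` exactly.
    """
    if not (0 <= sub_rate < 0.5):
        raise ValueError("sub_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    n = len(seq)
    sub_pos = np.nonzero(rng.random(n) < sub_rate)[0]
    base_idx = {b: i for i, b in enumerate(b"ACGT")}
    lut = np.frombuffer(b"ACGT", dtype="S1")
    for p in sub_pos:
        old = seq[p][0]
        if old not in base_idx:
            continue
        choices = [i for i in range(4) if i != base_idx[old]]
        seq[p] = lut[rng.choice(choices)]
    mutant = seq.tobytes().decode()

    indels = []
    if indel_rate > 0:
        ind_pos = np.nonzero(rng.random(n) < indel_rate)[0]
        for p in ind_pos[::-1]:  # right to left keeps earlier coords valid
            length = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                ins = _random_seq(rng, length, DEFAULT_GC)
                mutant = mutant[:p] + ins + mutant[p:]
                indels.append(("ins", int(p), length))
            else:
                mutant = mutant[:p] + mutant[p + length :]
                indels.append(("del", int(p), length))
    if not mutant:
        raise ValueError("divergence deleted the whole sequence")
    log = {
        "length": n,
        "n_substitutions": int(len(sub_pos)),
        "sub_positions": sub_pos,
        "indels": indels,
    }
    out = GenomeRecord(
        id=genome.id, sequence=mutant, description=genome.description,
        is_circular=genome.is_circular,
    )
    return out, log


def simulate_clades(
    ancestor: GenomeRecord, spec: CladeSimSpec
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Star-within-star two-clade simulation with controlled identities.

    Each clade founder diverges from the ancestor by ``inter_divergence/2``;
    each member diverges from its founder by ``intra_divergence/2``, so
    within-clade pairs differ by ~intra and between-clade pairs by
    ~inter + intra substitution proportion.
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[GenomeRecord] = []
    labels: dict[str, str] = {}
    for ci, (clade, n) in enumerate(zip("AB", spec.n_per_clade)):
        founder, _ = diverge(
            ancestor,
            spec.inter_divergence / 2,
            spec.indel_rate,
            seed=int(rng.integers(2**31)),
        )
        for m in range(n):
            member, _ = diverge(
                founder,
                spec.intra_divergence / 2,
                spec.indel_rate,
                seed=int(rng.integers(2**31)),
            )
            name = f"{clade}{m + 1}"
            member.id = name
            genomes.append(member)
            labels[name] = clade
    return genomes, labels


def _count_range(n: int, lo: float, hi: float, lo_open: bool, hi_open: bool):
    ks = []
    for k in range(1, n + 1):
        x = k / n
        ok_lo = x > lo if lo_open else x >= lo
        ok_hi = x < hi if hi_open else x <= hi
        if ok_lo and ok_hi:
            ks.append(k)
    return ks

# global (whole-matrix) class frequency intervals: half-open upper bounds
_GLOBAL_BOUNDS = {
    "core": (0.99, 1.0, False, False),
    "soft_core": (0.95, 0.99, False, True),
    "shell": (0.15, 0.95, False, True),
    "cloud": (0.0, 0.15, True, True),
}
# clade-aware intervals: core >95%, shell (15,95], cloud (0,15]
_CLADE_BOUNDS = {
    "core": (0.95, 1.0, True, False),
    "shell": (0.15, 0.95, True, False),
    "cloud": (0.0, 0.15, True, False),
}


def simulate_pa_matrix(
    n_per_clade: tuple[int, int],
    class_counts: dict[str, int],
    seed: int = 0,
):
    """Plant a presence/absence matrix with known per-gene classes.

    ``class_counts`` keys are global classes (``core``, ``soft_core``,
    ``shell``, ``cloud``) or clade-specific classes
    (``A-specific-core`` etc.; clade-specific genes get zero presence in the
    other clade). Presence counts are drawn uniformly from the integers whose
    frequency lies inside the class interval, so truth is exact by
    construction. Returns (PresenceMatrix, truth dict gene_id -> class).
    """
    import pandas as pd

    from .genome_io import PresenceMatrix

    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_clade
    n = n_a + n_b
    genome_ids = [f"A_{i + 1:02d}" for i in range(n_a)] + [
        f"B_{i + 1:02d}" for i in range(n_b)
    ]
    clade_of = {g: g[0] for g in genome_ids}
    clade_cols = {"A": list(range(n_a)), "B": list(range(n_a, n))}

    rows = []
    gene_ids = []
    truth = {}
    gi = 0
    for cls, count in class_counts.items():
        for _ in range(count):
            row = np.zeros(n, dtype="int8")
            if cls in _GLOBAL_BOUNDS:
                ks = _count_range(n, *_GLOBAL_BOUNDS[cls])
                if not ks:
                    raise ValueError(
                        f"class {cls!r} unattainable with {n} genomes"
                    )
                k = int(rng.choice(ks))
                cols = rng.choice(n, size=k, replace=False)
                row[cols] = 1
            else:
                parts = cls.split("-specific-")
                if len(parts) != 2 or parts[0] not in clade_cols or \
                        parts[1] not in _CLADE_BOUNDS:
                    raise ValueError(f"unknown class key {cls!r}")
                clade, ccls = parts
                nc = len(clade_cols[clade])
                ks = _count_range(nc, *_CLADE_BOUNDS[ccls])
                if not ks:
                    raise ValueError(
                        f"class {cls!r} unattainable with {nc} genomes in "
                        f"clade {clade}"
                    )
                k = int(rng.choice(ks))
                cols = rng.choice(clade_cols[clade], size=k, replace=False)
                row[cols] = 1
            gi += 1
            gene = f"gene_{gi:05d}"
            gene_ids.append(gene)
            truth[gene] = cls
            rows.append(row)
    df = pd.DataFrame(
        np.array(rows, dtype="int8"), index=gene_ids, columns=genome_ids
    )
    return PresenceMatrix(df, clade_of), truth


def make_characterization_fixture(
    seed: int = 0,
    length: int = 200_000,
    n_is_copies: int = 3,
    tsd_length: int = 4,
    n_spacers: int = 10,
    repeat_length: int = 28,
):
    """One genome with oriC + CRISPR + IS plants and all truths.

    Plants are ordered so earlier truths are never shifted: IS copies go in
    the middle of the genome first, the CRISPR array is inserted above them,
    and the oriC overwrite (length-preserving) happens last near the start.
    """
    if length < 50_000:
        raise ValueError("fixture needs >= 50 kb to hold all planted features")
    rng = np.random.default_rng(seed)
    g = random_genome(length, DEFAULT_GC, seed=int(rng.integers(2**31)))
    g, is_truth = plant_is_copies(
        g, element_length=1200, n_copies=n_is_copies, ir_length=16,
        tsd_length=tsd_length, seed=int(rng.integers(2**31)),
        site_range=(int(0.1 * length), int(0.55 * length)),
    )
    g, crispr_truth = plant_crispr(
        g, n_spacers=n_spacers, repeat_length=repeat_length, cas_stub=True,
        seed=int(rng.integers(2**31)), at=len(g) - int(0.24 * length),
    )
    g, oric_truth = plant_oric(g, seed=int(rng.integers(2**31)), dnaA_at=2000)
    return g, {"is": is_truth, "crispr": crispr_truth, "oric": oric_truth}


def write_fixture_dir(outdir, seed: int = 0, **kwargs) -> None:
    """Write a characterisation fixture as FASTA + GFF3 truth + TSV tables."""
    import os

    from .genome_io import write_fasta, write_features_gff3

    os.makedirs(outdir, exist_ok=True)
    g, truths = make_characterization_fixture(seed=seed, **kwargs)
    write_fasta(g, os.path.join(outdir, "genome.fasta"))
    extra = []
    for name, truth in truths.items():
        for s, e, strand in truth.intervals:
            extra.append(
                Feature("repeat_region" if name == "is" else "misc_feature",
                        s, e, strand, {"note": f"planted_{name}"})
            )
    write_features_gff3(g, extra, os.path.join(outdir, "truth.gff3"))
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("kind\tstart\tend\tstrand\tdetail\n")
        for name, truth in truths.items():
            for s, e, strand in truth.intervals:
                fh.write(f"{name}\t{s}\t{e}\t{strand}\t.\n")
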