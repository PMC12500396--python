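"""Genome I/O and the shared data model.

Internal coordinates are 0-based half-open throughout the package; GenBank and
GFF3 1-based inclusive coordinates are converted only at the I/O boundary.
Circular chromosomes are stored linearly in their deposited rotation; modules
that need to see origin-spanning structure work on a virtually doubled
sequence and report coordinates modulo the length.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
# IUPAC ambiguity codes other than N are coerced to N on parse
_AMBIG = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T (N excluded from the denominator)."""
    g = seq.count("G")
    c = seq.count("C")
    acgt = g + c + seq.count("A") + seq.count("T")
    if acgt == 0:
        return 0.0
    return (g + c) / acgt


@dataclass
class Feature:
    """A typed annotation interval (CDS, gene, tRNA, rRNA, repeat_region, ...).

    ``start``/``end`` are 0-based half-open on the forward strand; ``strand``
    is '+' or '-'. Qualifiers hold gene/product/locus_tag strings.
    """

    kind: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GenomeRecord:
    """A (possibly circular) nucleotide sequence with annotation features."""

    id: str
    sequence: str
    description: str = ""
    is_circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal characters {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature [{f.start}, {f.end}) outside genome of length "
                    f"{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    chars = set(seq)
    ambig = chars & _AMBIG
    if ambig:
        logger.warning(
            "record %s: coercing ambiguity codes %s to N",
            record_id,
            "".join(sorted(ambig)),
        )
        seq = re.sub(f"[{''.join(sorted(_AMBIG))}]", "N", seq)
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-IUPAC characters {sorted(bad)}"
        )
    return seq


def _detect_format(text: str) -> str:
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            return "fasta"
        if stripped.startswith("LOCUS"):
            return "genbank"
        raise ValueError(
            f"cannot auto-detect format from first line {stripped[:40]!r}"
        )
    raise ValueError("empty input")


_FEATURE_KINDS = {
    "CDS",
    "gene",
    "tRNA",
    "rRNA",
    "ncRNA",
    "tmRNA",
    "repeat_region",
    "misc_feature",
    "regulatory",
    "oriC",
}


def _features_from_seqrecord(rec) -> list[Feature]:
    out: list[Feature] = []
    for f in rec.features:
        if f.type not in _FEATURE_KINDS:
            continue
        quals = {
            k: v[0] if isinstance(v, list) else str(v)
            for k, v in f.qualifiers.items()
            if k in ("gene", "product", "locus_tag", "note")
        }
        start = int(f.location.start)
        end = int(f.location.end)
        if end <= start:  # origin-spanning join; keep the leading part
            end = len(rec.seq)
        strand = "-" if f.location.strand == -1 else "+"
        out.append(Feature(f.type, start, end, strand, quals))
    return out


def parse_genome(source, format: str = "auto") -> list[GenomeRecord]:
    """Parse FASTA or GenBank input into :class:`GenomeRecord` objects.

    ``source`` may be a path or raw text. Sequences are uppercased, U mapped
    to T and non-N ambiguity codes coerced to N with a warning. Circularity is
    read from the GenBank LOCUS topology; FASTA records default to linear.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        raise ValueError(f"unreadable source {source!r}")
    if format == "auto":
        format = _detect_format(text)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")

    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), format):
        seq = _clean_sequence(str(rec.seq), rec.id)
        circular = False
        if format == "genbank":
            circular = rec.annotations.get("topology", "linear") == "circular"
        features = _features_from_seqrecord(rec) if format == "genbank" else []
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description if rec.description != rec.id else "",
                is_circular=circular,
                features=features,
            )
        )
    if not records:
        raise ValueError("no records parsed from input")
    return records


def write_fasta(records, path=None, width: int = 60) -> str:
    """Write records as multi-FASTA (60-column wrap); returns the text."""
    if isinstance(records, GenomeRecord):
        records = [records]
    chunks = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        body = "\n".join(
            rec.sequence[i : i + width] for i in range(0, len(rec.sequence), width)
        )
        chunks.append(f"{header}\n{body}\n")
    text = "".join(chunks)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_features_gff3(genome: GenomeRecord, extra=(), path=None) -> str:
    """Emit the genome's features (plus ``extra``) as GFF3 text.

    Coordinates are converted to 1-based inclusive; rows are ordered by
    (start, end, kind) for determinism.
    """
    feats = list(genome.features) + list(extra)
    for f in feats:
        if f.end > len(genome):
            raise ValueError(
                f"feature [{f.start}, {f.end}) outside genome of length {len(genome)}"
            )
    lines = ["##gff-version 3"]
    for f in sorted(feats, key=lambda f: (f.start, f.end, f.kind)):
        attrs = ";".join(
            f"{k}={v}" for k, v in sorted(f.qualifiers.items())
        ) or "."
        lines.append(
            "\t".join(
                [
                    genome.id,
                    "rhizotyper",
                    f.kind,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@dataclass
class PresenceMatrix:
    """Binary gene x genome presence/absence matrix with optional clade labels."""

    data: pd.DataFrame  # genes as index, genomes as columns, values 0/1
    clade_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("presence matrix cells must be 0/1")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate genome ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.columns)


def read_presence_matrix(source, clade_of=None) -> PresenceMatrix:
    """Read an Rtab-dialect TSV (genes x genomes, 0/1 cells).

    All-zero gene rows are dropped with a logged count; any non-binary cell is
    an error naming its row and column.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        df = pd.read_csv(source, sep="\t", index_col=0, dtype=str)
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t", index_col=0, dtype=str)
    for col in df.columns:
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-binary cell {df.loc[row, col]!r} at gene {row!r}, "
                f"genome {col!r}"
            )
    mat = df.astype("int8")
    zero = mat.sum(axis=1) == 0
    if zero.any():
        logger.warning("dropping %d all-zero gene rows", int(zero.sum()))
        mat = mat.loc[~zero]
    return PresenceMatrix(mat, clade_of or {})


@dataclass
class QCRecord:
    """Completeness/contamination record for one genome assembly."""

    genome_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100):
            raise ValueError("completeness must be within [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")


def read_qc_table(source) -> list[QCRecord]:
    """Read a TSV with header ``genome_id completeness contamination``."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t")
    required = {"genome_id", "completeness", "contamination"}
    if not required.issubset(df.columns):
        raise ValueError(f"QC table must have columns {sorted(required)}")
    return [
        QCRecord(str(r.genome_id), float(r.completeness), float(r.contamination))
        for r in df.itertuples()
    ]


def read_label_table(source) -> dict[str, str]:
    """Read a two-column TSV mapping genome_id to clade/species label."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t")
    if df.shape[1] < 2:
        raise ValueError("label table needs two columns: genome_id, label")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
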