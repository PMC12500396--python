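"""Pangenome frequency classes, global and population-structure-aware.

Two classification schemes coexist and are never mixed:

* global (whole-matrix presence fraction x): core x >= 0.99, soft core
  0.95 <= x < 0.99, shell 0.15 <= x < 0.95, cloud 0 < x < 0.15 — the
  printed boundaries overlap at 0.95/0.99, resolved here as half-open upper
  bounds so the classes form a true partition;
* clade-aware (per-clade fraction x_c): core x_c > 0.95, shell
  0.15 < x_c <= 0.95, cloud 0 < x_c <= 0.15, absent x_c = 0. A gene is
  cladeX-specific-<class> when it is non-absent in exactly one clade
  (strict zero presence elsewhere, tolerance configurable but 0 by
  default), shared-<class> when every clade gives the same non-absent
  class, and mixed-<classA|classB> otherwise.

All-zero genes are dropped at parse time, so "cloud" excludes x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import PresenceMatrix

GLOBAL_ORDER = ("core", "soft_core", "shell", "cloud")
CLADE_ORDER = ("core", "shell", "cloud", "absent")


@dataclass
class PangenomePartition:
    """Per-gene global, per-clade and combined class assignments."""

    global_class: dict[str, str]
    clade_class: dict[str, dict[str, str]]  # gene -> clade -> class
    combined_class: dict[str, str]

    def __post_init__(self) -> None:
        genes = set(self.global_class)
        if set(self.combined_class) != genes:
            raise ValueError("combined and global classes cover different genes")


def _global_class(x: float) -> str:
    if x >= 0.99:
        return "core"
    if x >= 0.95:
        return "soft_core"
    if x >= 0.15:
        return "shell"
    return "cloud"


def _clade_class(x: float) -> str:
    if x == 0:
        return "absent"
    if x > 0.95:
        return "core"
    if x > 0.15:
        return "shell"
    return "cloud"


def global_partition(matrix: PresenceMatrix) -> dict[str, str]:
    """Assign each gene its global frequency class."""
    frac = matrix.data.mean(axis=1)
    return {gene: _global_class(x) for gene, x in frac.items()}


def clade_partition(
    matrix: PresenceMatrix, specific_tolerance: float = 0.0
) -> PangenomePartition:
    """Global, per-clade and combined classification of every gene.

    ``specific_tolerance`` relaxes the strict-absence requirement for
    clade-specific calls (a gene counts as absent from a clade when its
    presence fraction there is <= the tolerance); the default 0 keeps the
    strict definition — never present in the other clade.
    """
    if not matrix.clade_of:
        raise ValueError("matrix has no clade labels")
    clades = sorted(set(matrix.clade_of.values()))
    if len(clades) < 2:
        raise ValueError("need >= 2 clades")
    cols_of = {
        c: [g for g in matrix.genome_ids if matrix.clade_of.get(g) == c]
        for c in clades
    }
    for c, cols in cols_of.items():
        if not cols:
            raise ValueError(f"clade {c!r} has no genomes")
    unlabeled = [g for g in matrix.genome_ids if g not in matrix.clade_of]
    if unlabeled:
        raise ValueError(f"unlabelled genomes: {unlabeled}")

    global_class = global_partition(matrix)
    clade_frac = {c: matrix.data[cols_of[c]].mean(axis=1) for c in clades}

    clade_class: dict[str, dict[str, str]] = {}
    combined: dict[str, str] = {}
    for gene in matrix.gene_ids:
        per = {}
        for c in clades:
            x = float(clade_frac[c].loc[gene])
            if 0 < x <= specific_tolerance:
                x = 0.0
            per[c] = _clade_class(x)
        clade_class[gene] = per
        present = [c for c in clades if per[c] != "absent"]
        if len(present) == 1:
            combined[gene] = f"{present[0]}-specific-{per[present[0]]}"
        elif len({per[c] for c in present}) == 1:
            combined[gene] = f"shared-{per[present[0]]}"
        else:
            kinds = "|".join(per[c] for c in clades)
            combined[gene] = f"mixed-{kinds}"
    return PangenomePartition(global_class, clade_class, combined)


def summarize_partition(partition: PangenomePartition) -> pd.DataFrame:
    """Deterministic counts table over global and combined classes.

    Rows are (scheme, class, count); within each scheme the counts sum to
    the number of genes.
    """
    rows = []
    n = len(partition.global_class)
    counts = pd.Series(partition.global_class).value_counts()
    for cls in GLOBAL_ORDER:
        rows.append(("global", cls, int(counts.get(cls, 0))))
    comb = pd.Series(partition.combined_class).value_counts()
    for cls in sorted(comb.index):
        rows.append(("combined", cls, int(comb[cls])))
    df = pd.DataFrame(rows, columns=["scheme", "class", "count"])
    assert df[df.scheme == "global"]["count"].sum() == n
    assert df[df.scheme == "combined"]["count"].sum() == n
    return df


def per_gene_table(partition: PangenomePartition) -> pd.DataFrame:
    """Per-gene class assignments in gene order."""
    genes = sorted(partition.global_class)
    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g,
                "global_class": partition.global_class[g],
                "combined_class": partition.combined_class[g],
                **{
                    f"clade_{c}": cls
                    for c, cls in sorted(partition.clade_class[g].items())
                },
            }
        )
    return pd.DataFrame(rows)
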