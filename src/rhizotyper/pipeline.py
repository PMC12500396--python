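"""High-level report-bundle pipelines tying the analysis stages together.

Each run writes its outputs plus a JSON manifest (package version,
parameters, input checksums) sufficient to reproduce the command
bit-identically. Stages degrade gracefully: a genome without annotation
still gets IS discovery (transposase "unevaluated"), while cas- and
dnaA-dependent stages are skipped with a note.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

from . import __version__
from .ani_taxonomy import (
    ani_matrix,
    clade_summary,
    cluster_species,
    flag_outliers,
    matrix_tsv,
    near_identical_groups,
    nj_tree,
    pairs_tsv,
    qc_filter,
    symmetrize,
)
from .crispr_finder import array_table, find_crispr_array, locate_cas_loci, spacers_to_fasta
from .genome_io import GenomeRecord, write_features_gff3
from .is_discovery import (
    detect_terminal_irs,
    detect_tsds,
    family_table,
    find_repeat_families,
    refine_extent,
    tag_transposase,
)
from .oric_finder import oric_features, predict_oric

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_USAGE = 2
EXIT_INPUT = 3
EXIT_ALL_FAILED = 4


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir, command, params, inputs):
    manifest = {
        "tool": "rhizotyper",
        "version": __version__,
        "command": command,
        "parameters": params,
        "inputs": {p: _checksum(p) for p in inputs if os.path.exists(p)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_characterize(
    genome: GenomeRecord,
    outdir: str,
    genome_path: str | None = None,
    min_length: int = 500,
    min_identity: float = 0.99,
    window: int = 100_000,
) -> dict:
    """Run IS discovery, CRISPR and oriC stages and write a report bundle.

    Returns a stage-status dict; a stage that cannot run (e.g. oriC without
    dnaA/dnaN annotation) is reported as skipped, and the bundle is written
    for whichever stages succeeded.
    """
    os.makedirs(outdir, exist_ok=True)
    status: dict[str, str] = {}
    report: dict[str, object] = {}

    try:
        families = find_repeat_families(
            genome, window=window, min_length=min_length,
            min_identity=min_identity,
        )
        families = tag_transposase(families, genome.features)
        for fam in families:
            detect_terminal_irs(fam)
            detect_tsds(genome, fam)
            refine_extent(genome, fam)
        with open(os.path.join(outdir, "is_families.tsv"), "w") as fh:
            fh.write(family_table(families))
        report["is_families"] = families
        status["is"] = "ok"
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("IS stage failed: %s", exc)
        status["is"] = f"failed: {exc}"

    cas_loci = locate_cas_loci(genome.features)
    if genome.features:
        anchor = (cas_loci[0][0], cas_loci[0][1]) if cas_loci else None
        arrays = find_crispr_array(genome, anchor=anchor)
        with open(os.path.join(outdir, "crispr_arrays.tsv"), "w") as fh:
            fh.write(array_table(arrays))
        for i, arr in enumerate(arrays, 1):
            with open(
                os.path.join(outdir, f"crispr_{i}_spacers.fasta"), "w"
            ) as fh:
                fh.write(spacers_to_fasta(arr, prefix=f"{genome.id}_{i}"))
        report["crispr"] = arrays
        status["crispr"] = "ok"
    else:
        status["crispr"] = "skipped: no annotation for cas anchoring"

    try:
        oric = predict_oric(genome)
        write_features_gff3(
            genome, oric_features(oric), os.path.join(outdir, "oric.gff3")
        )
        report["oric"] = oric
        status["oric"] = "ok"
    except ValueError as exc:
        status["oric"] = f"skipped: {exc}"

    _write_manifest(
        outdir,
        "characterize",
        {
            "min_length": min_length,
            "min_identity": min_identity,
            "window": window,
        },
        [genome_path] if genome_path else [],
    )
    with open(os.path.join(outdir, "stages.json"), "w") as fh:
        json.dump(status, fh, indent=2, sort_keys=True)
    report["status"] = status
    return report


def run_taxonomy(
    genomes: list,
    outdir: str,
    qc_records=None,
    labels: dict[str, str] | None = None,
    type_strain_of: dict[str, str] | None = None,
    threshold: float = 95.0,
    input_paths: list[str] | None = None,
) -> dict:
    """QC filter -> ANI matrix -> clustering -> summaries -> tree bundle."""
    os.makedirs(outdir, exist_ok=True)
    report: dict[str, object] = {}
    if qc_records:
        kept, dropped = qc_filter(qc_records)
        keep_ids = set(kept)
        genomes = [
            g for g in genomes
            if (g[0].id if isinstance(g, list) else g.id) in keep_ids
        ]
        report["qc_dropped"] = dropped
    if len(genomes) < 2:
        raise ValueError("fewer than 2 genomes after QC")

    results = ani_matrix(genomes)
    sym = symmetrize(results)
    with open(os.path.join(outdir, "ani_pairs.tsv"), "w") as fh:
        fh.write(pairs_tsv(results))
    with open(os.path.join(outdir, "ani_matrix.tsv"), "w") as fh:
        fh.write(matrix_tsv(sym))

    ids = [g[0].id if isinstance(g, list) else g.id for g in genomes]
    clustering = cluster_species(sym, threshold=threshold, genome_ids=ids)
    report["clustering"] = clustering
    lines = ["component\tgenomes"]
    for i, comp in enumerate(clustering.components, 1):
        lines.append(f"{i}\t{','.join(sorted(comp))}")
    with open(os.path.join(outdir, "species_clusters.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if labels:
        report["clade_summary"] = clade_summary(sym, labels)
        if type_strain_of:
            report["outliers"] = flag_outliers(
                sym, labels, type_strain_of, threshold=threshold
            )
    else:
        report["clade_summary"] = None
        logger.info("no clade labels supplied; clade summary skipped")
    report["near_identical"] = near_identical_groups(sym)

    try:
        newick = nj_tree(sym)
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(newick + "\n")
        report["tree"] = newick
    except ValueError as exc:
        report["tree"] = None
        logger.warning("tree skipped: %s", exc)

    _write_manifest(
        outdir, "taxonomy", {"threshold": threshold}, input_paths or []
    )
    return report
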