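"""Planted-truth recovery and calibration benchmarks.

These routines regenerate synthetic study conditions from a seed, run the
discovery modules at default parameters, and score exact recovery against
the generators' truth records. They back both the regression suite and the
acceptance script; fixture sizes are 200 kb (all algorithms are
length-agnostic, so megabase chromosomes differ only in runtime).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .ani_taxonomy import (
    ani_matrix,
    cluster_species,
    fragment_ani,
    symmetrize,
)
from .crispr_finder import find_crispr_array, locate_cas_loci
from .is_discovery import (
    detect_terminal_irs,
    detect_tsds,
    find_repeat_families,
)
from .pangenome_partition import clade_partition, global_partition
from .synthetic_data import (
    CladeSimSpec,
    diverge,
    make_characterization_fixture,
    random_genome,
    simulate_clades,
    simulate_pa_matrix,
)

# CRISPR study conditions cycled across replicate seeds
CRISPR_GRID = [(2, 25), (10, 28), (98, 35), (98, 28), (10, 25), (2, 35)]


def characterization_trial(seed: int, length: int = 200_000) -> dict[str, bool]:
    """Run one seeded fixture through discovery; score exact recovery.

    Alternating replicates plant 4 bp TSDs / no TSDs, and cycle spacer
    counts {2, 10, 98} x repeat lengths {25, 28, 35}.
    """
    tsd_length = 4 if seed % 2 == 0 else 0
    n_spacers, repeat_length = CRISPR_GRID[seed % len(CRISPR_GRID)]
    genome, truths = make_characterization_fixture(
        seed=seed, length=length, tsd_length=tsd_length,
        n_spacers=n_spacers, repeat_length=repeat_length,
    )
    out: dict[str, bool] = {}

    families = find_repeat_families(genome)
    is_truth = truths["is"]
    out["is_copy_count"] = (
        len(families) == 1 and len(families[0].copies) == len(is_truth.intervals)
    )
    if out["is_copy_count"]:
        fam = families[0]
        found = sorted((c.start, c.end) for c in fam.copies)
        out["is_boundaries"] = found == sorted(
            (s, e) for s, e, _ in is_truth.intervals
        )
        detect_terminal_irs(fam)
        out["is_ir"] = fam.ir is not None and fam.ir[2:] == (16, 16)
        detect_tsds(genome, fam)
        if tsd_length:
            out["is_tsd"] = (
                fam.tsd_length == tsd_length
                and sorted(fam.tsds) == sorted(is_truth.payload["tsds"])
            )
        else:
            out["is_tsd"] = fam.tsd_length is None
    else:
        out["is_boundaries"] = out["is_ir"] = out["is_tsd"] = False

    loci = locate_cas_loci(genome.features)
    arrays = find_crispr_array(
        genome, anchor=(loci[0][0], loci[0][1]) if loci else None
    )
    ct = truths["crispr"]
    if len(arrays) == 1:
        arr = arrays[0]
        out["crispr_counts"] = (
            len(arr.repeats) == len(ct.payload["repeats"])
            and len(arr.spacers) == len(ct.payload["spacers"])
            and len(arr.repeats) == len(arr.spacers) + 1
        )
        out["crispr_consensus"] = arr.repeat_consensus == ct.payload["repeat"]
    else:
        out["crispr_counts"] = out["crispr_consensus"] = False

    from .oric_finder import predict_oric

    oric = predict_oric(genome)
    ot = truths["oric"].payload
    found_boxes = {(b[0], b[1]) for b in oric.boxes}
    out["oric_boxes"] = all(
        (p, s) in found_boxes for p, s, _ in ot["boxes"]
    )
    out["oric_trio"] = oric.trio is not None and oric.trio[0] == ot["trio"][0]
    out["oric_due"] = oric.due[:2] == tuple(ot["due"])
    return out


def recovery_rates(
    n_replicates: int = 20, base_seed: int = 0, length: int = 200_000
) -> dict[str, float]:
    """Fraction of replicates with exact recovery, per metric."""
    tallies: Counter = Counter()
    for i in range(n_replicates):
        trial = characterization_trial(base_seed + i, length=length)
        for key, ok in trial.items():
            tallies[key] += bool(ok)
    return {k: tallies[k] / n_replicates for k in sorted(tallies)}


def ani_calibration(
    seed: int,
    rates=(0.005, 0.025, 0.05),
    length: int = 200_000,
) -> dict[str, float]:
    """Self-ANI and |ANI - 100(1 - realised substitution rate)| per rate."""
    rng = np.random.default_rng(seed)
    ancestor = random_genome(length, seed=int(rng.integers(2**31)))
    out = {"self_ani": fragment_ani(ancestor, ancestor).ani}
    errors = []
    for rate in rates:
        mutant, log = diverge(
            ancestor, rate, 0.0, seed=int(rng.integers(2**31))
        )
        realised = 100.0 * (1 - log["n_substitutions"] / log["length"])
        ani = fragment_ani(ancestor, mutant).ani
        errors.append(abs(ani - realised))
        out[f"abs_error_rate_{rate}"] = abs(ani - realised)
    out["max_abs_error"] = max(errors)
    return out


def clade_clustering(
    seed: int, length: int = 100_000, n_per_clade=(3, 3)
) -> dict[str, int]:
    """Two-clade simulation: component counts at 95 and 85 % thresholds."""
    rng = np.random.default_rng(seed)
    ancestor = random_genome(length, seed=int(rng.integers(2**31)))
    spec = CladeSimSpec(
        n_per_clade=n_per_clade, intra_divergence=0.03,
        inter_divergence=0.10, seed=int(rng.integers(2**31)),
    )
    genomes, _ = simulate_clades(ancestor, spec)
    sym = symmetrize(ani_matrix(genomes))
    return {
        "components_at_95": len(cluster_species(sym, 95).components),
        "components_at_85": len(cluster_species(sym, 85).components),
        "n_genomes": len(genomes),
    }


def pangenome_recovery(seed: int) -> dict[str, int]:
    """Plant the headline class counts and recount them via the classifiers.

    Global classes over 51 genomes; clade-specific core over a 35 + 16
    split, in a separate matrix because a clade-specific-core gene's global
    frequency (34-35 of 51) lands in global shell and would distort the
    planted global counts.
    """
    planted_global = {
        "core": 1013, "soft_core": 711, "shell": 951, "cloud": 2275
    }
    m, _ = simulate_pa_matrix((35, 16), planted_global, seed=seed)
    counts = Counter(global_partition(m).values())

    m2, _ = simulate_pa_matrix(
        (35, 16), {"A-specific-core": 114, "B-specific-core": 90},
        seed=seed + 1,
    )
    combined = Counter(clade_partition(m2).combined_class.values())
    return {
        "global_core": counts["core"],
        "global_soft_core": counts["soft_core"],
        "global_shell": counts["shell"],
        "global_cloud": counts["cloud"],
        "clade_specific_core_A": combined["A-specific-core"],
        "clade_specific_core_B": combined["B-specific-core"],
        "n_genomes": len(m.genome_ids),
    }
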