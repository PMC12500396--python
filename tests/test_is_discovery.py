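import numpy as np
import pytest

from rhizotyper.genome_io import Feature, GenomeRecord, revcomp
from rhizotyper.is_discovery import (
    detect_terminal_irs,
    detect_tsds,
    find_empty_sites,
    find_repeat_families,
    refine_extent,
    scan_homologs,
    tag_transposase,
)
from rhizotyper.synthetic_data import diverge, plant_is_copies, random_genome


def levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit distance (row-vectorised)."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        sub = prev[:-1] + np.fromiter(
            (ca != cb for cb in b), dtype=int, count=len(b)
        )
        for j in range(1, len(b) + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, sub[j - 1])
        prev = cur
    return int(prev[-1])


class TestFindRepeatFamilies:
    def test_three_identical_copies_exact_boundaries(self):
        g, truth = plant_is_copies(
            random_genome(100_000, seed=1), element_length=1200, n_copies=3,
            ir_length=16, tsd_length=0, seed=2,
        )
        fams = find_repeat_families(g)
        assert len(fams) == 1
        found = sorted((c.start, c.end) for c in fams[0].copies)
        assert found == sorted((s, e) for s, e, _ in truth.intervals)
        # copy-pair identity re-verified by independent DP alignment
        seqs = [g.sequence[s:e] for s, e in found]
        assert levenshtein(seqs[0], seqs[1]) == 0
        assert levenshtein(seqs[0], seqs[2]) == 0

    def test_random_genome_has_no_families(self):
        g = random_genome(100_000, seed=3)
        assert find_repeat_families(g) == []

    def test_no_qualifying_repeat_oracle_small_scale(self):
        # >=500 bp at >99% identity allows <=4 mismatches, so by pigeonhole
        # an exact run >= 100 bp must exist; no duplicated 100-mer in a
        # random 10 kb sequence certifies the negative result
        g = random_genome(10_000, seed=4)
        seen = set()
        dup = False
        for i in range(len(g) - 100 + 1):
            w = g.sequence[i : i + 100]
            if w in seen:
                dup = True
                break
            seen.add(w)
        assert not dup
        assert find_repeat_families(g) == []

    def test_identity_threshold_behaviour(self):
        base = random_genome(120_000, seed=5)
        g, truth = plant_is_copies(
            base, element_length=1500, n_copies=2, ir_length=12,
            tsd_length=0, seed=6,
        )
        # add ~2% substitutions to the second copy only
        s, e, _ = truth.intervals[1]
        mutated, log = diverge(
            GenomeRecord(id="el", sequence=g.sequence[s:e]), 0.02, seed=7
        )
        seq = g.sequence[:s] + mutated.sequence + g.sequence[e:]
        g2 = GenomeRecord(id=g.id, sequence=seq)
        realised_identity = 1 - log["n_substitutions"] / log["length"]
        assert realised_identity < 0.99
        assert find_repeat_families(g2, min_identity=0.99) == []
        fams = find_repeat_families(g2, min_identity=0.97)
        assert len(fams) == 1 and len(fams[0].copies) == 2

    def test_inverted_copy_detected_with_strand(self):
        g = random_genome(60_000, seed=8)
        el = random_genome(900, seed=9).sequence
        seq = (
            g.sequence[:10_000] + el + g.sequence[10_000:40_000]
            + revcomp(el) + g.sequence[40_000:]
        )
        fams = find_repeat_families(GenomeRecord(id="g", sequence=seq))
        assert len(fams) == 1
        strands = sorted(c.strand for c in fams[0].copies)
        assert strands == ["+", "-"]

    def test_rotation_invariance_on_circular_genome(self):
        g, truth = plant_is_copies(
            random_genome(50_000, seed=10), element_length=800, n_copies=2,
            ir_length=10, tsd_length=0, seed=11,
        )
        g.is_circular = True
        n = len(g)
        rot = 17_000
        g2 = GenomeRecord(
            id="rot", sequence=g.sequence[rot:] + g.sequence[:rot],
            is_circular=True,
        )
        f1 = find_repeat_families(g)
        f2 = find_repeat_families(g2)
        assert len(f1) == len(f2) == 1
        shifted = sorted(
            ((c.start - rot) % n, (c.start - rot) % n + c.length)
            for c in f1[0].copies
        )
        assert shifted == sorted((c.start, c.end) for c in f2[0].copies)

    def test_family_count_monotone_in_thresholds(self):
        g, _ = plant_is_copies(
            random_genome(80_000, seed=12), element_length=700, n_copies=3,
            ir_length=10, tsd_length=0, seed=13,
        )
        n_strict = len(find_repeat_families(g, min_length=500))
        n_loose = len(find_repeat_families(g, min_length=300))
        assert n_loose >= n_strict


class TestTagTransposase:
    def _family(self, g):
        return find_repeat_families(g)[0]

    def test_transposase_product_recorded(self):
        g, _ = plant_is_copies(
            random_genome(60_000, seed=14), element_length=900, n_copies=2,
            ir_length=10, tsd_length=0, seed=15,
            transposase_product="IS30 family transposase",
        )
        fam = tag_transposase([self._family(g)], g.features)[0]
        assert fam.transposase_status == "is"
        assert fam.transposase_products == ["IS30 family transposase"]

    def test_rrna_overlap_flagged_non_is(self):
        g, truth = plant_is_copies(
            random_genome(60_000, seed=16), element_length=900, n_copies=2,
            ir_length=10, tsd_length=0, seed=17, transposase_product=None,
        )
        feats = [
            Feature("CDS", s + 10, e - 10, "+", {"product": "16S ribosomal RNA"})
            for s, e, _ in truth.intervals
        ]
        fam = tag_transposase([self._family(g)], feats)[0]
        assert fam.transposase_status == "non_is"

    def test_no_annotation_unevaluated(self):
        g, _ = plant_is_copies(
            random_genome(60_000, seed=18), element_length=900, n_copies=2,
            ir_length=10, tsd_length=0, seed=19, transposase_product=None,
        )
        fam = tag_transposase([self._family(g)], [])[0]
        assert fam.transposase_status == "unevaluated"


class TestTerminalIrs:
    def _fam_with_consensus(self, consensus):
        from rhizotyper.is_discovery import ISFamily, RepeatCopy

        return ISFamily(
            name="f", consensus=consensus,
            copies=[RepeatCopy(0, len(consensus))],
        )

    def test_perfect_ir_reported_full(self):
        ir = "GACTTGCCAGGTATCC"
        core = random_genome(800, seed=20).sequence
        # pin the core ends so they cannot base-pair and extend the IR
        core = "A" + core[1:-1] + "A"
        fam = self._fam_with_consensus(ir + core + revcomp(ir))
        detect_terminal_irs(fam)
        assert fam.ir[2:] == (16, 16)
        assert fam.ir[0] == ir

    def test_two_mismatches_counted(self):
        ir = "GACTTGCCAGGTATCC"
        right = list(revcomp(ir))
        # mismatches mid-IR so the full-length alignment stays optimal
        right[7] = "A" if right[7] != "A" else "C"
        right[11] = "A" if right[11] != "A" else "C"
        core = random_genome(700, seed=21).sequence
        core = "A" + core[1:-1] + "A"
        fam = self._fam_with_consensus(ir + core + "".join(right))
        detect_terminal_irs(fam)
        assert fam.ir[2:] == (14, 16)

    def test_random_ends_no_ir(self):
        # exhaustive check at small span: no anchored window satisfies the
        # mismatch bound, so the detector must stay silent
        cons = random_genome(600, seed=22).sequence
        span, min_ir, frac = 20, 10, 0.25
        left, rrc = cons[:span], revcomp(cons[-span:])
        qualifying = False
        for a in range(6):
            for b in range(6):
                limit = min(span - a, span - b)
                mism = 0
                for ln in range(1, limit + 1):
                    if left[a + ln - 1] != rrc[b + ln - 1]:
                        mism += 1
                    if ln >= min_ir and mism / ln <= frac:
                        qualifying = True
        fam = self._fam_with_consensus(cons)
        detect_terminal_irs(fam, search_span=span, min_ir=min_ir,
                            max_mismatch_fraction=frac)
        assert (fam.ir is not None) == qualifying


class TestTsds:
    def test_planted_distinct_tsds_called(self):
        g, truth = plant_is_copies(
            random_genome(80_000, seed=23), element_length=1000, n_copies=2,
            ir_length=12, tsd_length=4, seed=24,
        )
        fam = find_repeat_families(g)[0]
        detect_tsds(g, fam)
        assert fam.tsd_length == 4
        assert sorted(fam.tsds) == sorted(truth.payload["tsds"])

    def test_no_tsd_when_none_planted(self):
        g, _ = plant_is_copies(
            random_genome(80_000, seed=25), element_length=1000, n_copies=3,
            ir_length=12, tsd_length=0, seed=26,
        )
        fam = find_repeat_families(g)[0]
        detect_tsds(g, fam)
        assert fam.tsd_length is None

    def test_identical_flanks_rejected(self):
        # same 4-mer flanking every copy: element terminus or target
        # preference, not a duplication
        from rhizotyper.is_discovery import ISFamily, RepeatCopy

        el = random_genome(600, seed=27).sequence
        pad = random_genome(2_000, seed=28).sequence
        flank = "TGCA"
        seq = pad + flank + el + flank + pad + flank + el + flank + pad
        s1 = len(pad) + 4
        s2 = 2 * len(pad) + 2 * 4 + len(el) + 4
        g = GenomeRecord(id="g", sequence=seq)
        fam = ISFamily(
            name="f", consensus=el,
            copies=[RepeatCopy(s1, s1 + len(el)), RepeatCopy(s2, s2 + len(el))],
        )
        detect_tsds(g, fam)
        assert fam.tsd_length is None
        assert any("identical flanking" in n for n in fam.notes)


class TestRefineExtent:
    def test_conserved_extent_recovered(self):
        # copies identical over exactly 1,476 bases with divergent flanks
        el = random_genome(1476, seed=29).sequence
        pads = [random_genome(3_000, seed=s).sequence for s in (30, 31, 32, 33)]
        seq = pads[0] + el + pads[1] + el + pads[2] + el + pads[3]
        g = GenomeRecord(id="g", sequence=seq)
        from rhizotyper.is_discovery import ISFamily, RepeatCopy

        starts = [3_000, 3_000 + 1476 + 3_000, 3_000 + 2 * (1476 + 3_000)]
        # seed detection deliberately trimmed 100 bp on each side
        fam = ISFamily(
            name="f", consensus=el[100:-100],
            copies=[RepeatCopy(s + 100, s + 1476 - 100) for s in starts],
        )
        refine_extent(g, fam)
        assert fam.refined_extent == 1476
        assert [(c.start, c.end) for c in fam.copies] == [
            (s, s + 1476) for s in starts
        ]

    def test_single_copy_noop(self):
        from rhizotyper.is_discovery import ISFamily, RepeatCopy

        g = random_genome(5_000, seed=34)
        fam = ISFamily(name="f", consensus=g.sequence[100:600],
                       copies=[RepeatCopy(100, 600)])
        refine_extent(g, fam)
        assert fam.refined_extent is None

    def test_adjacent_tandem_copies_do_not_overlap(self):
        el = random_genome(800, seed=35).sequence
        pad = random_genome(2_000, seed=36).sequence
        seq = pad + el + el + pad
        g = GenomeRecord(id="g", sequence=seq)
        from rhizotyper.is_discovery import ISFamily, RepeatCopy

        fam = ISFamily(
            name="f", consensus=el[50:-50],
            copies=[
                RepeatCopy(2_000 + 50, 2_000 + 750),
                RepeatCopy(2_800 + 50, 2_800 + 750),
            ],
        )
        refine_extent(g, fam)
        c1, c2 = sorted(fam.copies, key=lambda c: c.start)
        assert c1.end <= c2.start


class TestScanHomologs:
    def _setup(self):
        g = random_genome(120_000, seed=37)
        g, truth = plant_is_copies(
            g, element_length=1407, n_copies=3, ir_length=12, tsd_length=0,
            seed=38, site_range=(5_000, 80_000),
        )
        el = truth.payload["element"]
        rel, _ = diverge(GenomeRecord(id="el", sequence=el), 0.26, seed=39)
        seq = g.sequence[:100_000] + rel.sequence + g.sequence[100_000:]
        return GenomeRecord(id="g", sequence=seq, features=g.features)

    def test_divergent_relative_found_at_070_not_099(self):
        g = self._setup()
        fam = find_repeat_families(g)[0]
        hits = scan_homologs(g, fam, min_identity=0.70)
        assert len(hits) == 1
        assert 100_000 - 20 <= hits[0].start <= 100_000 + 20
        assert scan_homologs(g, fam, min_identity=0.99) == []

    def test_identity_matches_independent_dp(self):
        g = self._setup()
        fam = find_repeat_families(g)[0]
        (hit,) = scan_homologs(g, fam, min_identity=0.70)
        a = fam.consensus
        b = g.sequence[hit.start : hit.end]
        ed = levenshtein(a, b)
        import edlib

        assert edlib.align(a, b)["editDistance"] == ed

    def test_no_relative_no_hits(self):
        g, _ = plant_is_copies(
            random_genome(60_000, seed=40), element_length=900, n_copies=2,
            ir_length=10, tsd_length=0, seed=41,
        )
        fam = find_repeat_families(g)[0]
        assert scan_homologs(g, fam) == []


class TestEmptySites:
    def _donor(self):
        g, truth = plant_is_copies(
            random_genome(80_000, seed=42), element_length=1200, n_copies=2,
            ir_length=16, tsd_length=4, seed=43,
        )
        fam = find_repeat_families(g)[0]
        detect_tsds(g, fam)
        return g, truth, fam

    def test_deletion_reference_yields_empty_site(self):
        g, truth, fam = self._donor()
        s, e, _ = truth.intervals[0]
        ref = GenomeRecord(id="ref", sequence=g.sequence[:s] + g.sequence[e + 4 :])
        res = find_empty_sites(fam, g, ref)
        by_copy = {ci: stat for _, ci, stat in res}
        assert by_copy[0] == "empty"
        assert by_copy[1] == "occupied_or_distant"

    def test_identical_reference_no_empty_sites(self):
        g, _, fam = self._donor()
        res = find_empty_sites(fam, g, g)
        assert all(stat == "occupied_or_distant" for _, _, stat in res)

    def test_scrambled_reference_untraceable(self):
        g, _, fam = self._donor()
        ref = random_genome(80_000, seed=44, id="scrambled")
        res = find_empty_sites(fam, g, ref)
        assert all(stat == "untraceable" for _, _, stat in res)
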