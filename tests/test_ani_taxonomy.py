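import numpy as np
import pytest

from rhizotyper.ani_taxonomy import (
    ani_matrix,
    clade_summary,
    cluster_species,
    flag_outliers,
    fragment_ani,
    near_identical_groups,
    nj_tree,
    qc_filter,
    symmetrize,
)
from rhizotyper.genome_io import GenomeRecord, QCRecord
from rhizotyper.synthetic_data import (
    CladeSimSpec,
    diverge,
    random_genome,
    simulate_clades,
)


def _sym(pairs):
    """Build a symmetrised matrix dict from (a, b, ani) triples."""
    return {frozenset((a, b)): v for a, b, v in pairs}


class TestFragmentAni:
    def test_self_identity(self):
        g = random_genome(60_000, seed=1)
        res = fragment_ani(g, g)
        assert res.ani == 100.0
        assert res.fragments_mapped == res.fragments_total
        assert res.aligned_fraction == 1.0

    def test_matches_mutation_log(self):
        g = random_genome(200_000, seed=2)
        mut, log = diverge(g, 0.025, 0.0, seed=3)
        res = fragment_ani(g, mut)
        realised = 100.0 * (1 - log["n_substitutions"] / log["length"])
        assert res.ani == pytest.approx(realised, abs=0.2)

    def test_unrelated_genomes_flagged(self):
        a = random_genome(50_000, seed=4, id="a")
        b = random_genome(50_000, seed=5, id="b")
        res = fragment_ani(a, b)
        assert res.ani is None
        assert res.fragments_mapped == 0

    def test_monotone_in_divergence(self):
        g = random_genome(100_000, seed=6)
        anis = []
        for rate in (0.005, 0.01, 0.025, 0.05, 0.1):
            mut, _ = diverge(g, rate, seed=7)
            anis.append(fragment_ani(g, mut).ani)
        assert all(a > b for a, b in zip(anis, anis[1:]))

    def test_short_fragment_length_rejected(self):
        g = random_genome(5_000, seed=8)
        with pytest.raises(ValueError):
            fragment_ani(g, g, fragment_length=50)


class TestAniMatrix:
    def test_identical_genomes_all_100(self):
        gs = [random_genome(30_000, seed=9, id=f"g{i}") for i in range(3)]
        for g in gs[1:]:
            g.sequence = gs[0].sequence
        sym = symmetrize(ani_matrix(gs))
        assert all(v == 100.0 for v in sym.values())

    def test_two_clade_block_structure(self):
        anc = random_genome(60_000, seed=10)
        spec = CladeSimSpec((2, 2), 0.03, 0.10, seed=11)
        genomes, labels = simulate_clades(anc, spec)
        sym = symmetrize(ani_matrix(genomes))
        intra, inter = clade_summary(sym, labels)
        within = min(r[0] for r in intra.values() if r)
        between = inter[1]
        assert within - between >= 5.0


class TestQcFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (89.9, 1.0, False),
            (90.0, 5.0, True),
            (99.0, 5.1, False),
            (100.0, 0.0, True),
        ],
    )
    def test_boundary_semantics(self, completeness, contamination, kept):
        recs = [QCRecord("g", completeness, contamination)]
        kept_ids, dropped = qc_filter(recs)
        assert (kept_ids == ["g"]) == kept
        if not kept:
            reason = dropped[0][1]
            if completeness < 90:
                assert "completeness" in reason
            else:
                assert "contamination" in reason


class TestClusterSpecies:
    def _two_block(self):
        pairs = []
        a = ["a1", "a2", "a3"]
        b = ["b1", "b2"]
        for grp in (a, b):
            for i, x in enumerate(grp):
                for y in grp[i + 1 :]:
                    pairs.append((x, y, 97.0))
        for x in a:
            for y in b:
                pairs.append((x, y, 90.0))
        return _sym(pairs)

    def test_threshold_95_gives_two_components(self):
        cl = cluster_species(self._two_block(), threshold=95)
        assert len(cl.components) == 2
        assert cl.intra_range == (97.0, 97.0)
        assert cl.inter_range == (90.0, 90.0)

    def test_threshold_85_gives_one(self):
        assert len(cluster_species(self._two_block(), threshold=85).components) == 1

    def test_component_count_monotone_in_threshold(self):
        sym = self._two_block()
        counts = [
            len(cluster_species(sym, threshold=t).components)
            for t in (100, 98, 95, 91, 85)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_duplicate_isolated_at_100(self):
        sym = _sym(
            [("a", "b", 100.0), ("a", "c", 97.0), ("b", "c", 97.0)]
        )
        cl = cluster_species(sym, threshold=100)
        assert {"a", "b"} in cl.components
        assert {"c"} in cl.components


class TestCladeSummary:
    def test_hand_built_matrix(self):
        sym = _sym(
            [
                ("a1", "a2", 98.0),
                ("b1", "b2", 96.0),
                ("a1", "b1", 90.0),
                ("a1", "b2", 89.0),
                ("a2", "b1", 91.0),
                ("a2", "b2", 90.5),
            ]
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        intra, inter = clade_summary(sym, labels)
        assert intra == {"A": (98.0, 98.0), "B": (96.0, 96.0)}
        assert inter == (89.0, 91.0)

    def test_single_member_clade_empty_range(self):
        sym = _sym([("a", "b", 97.0)])
        intra, inter = clade_summary(sym, {"a": "A", "b": "A"})
        assert intra == {"A": (97.0, 97.0)}
        assert inter is None

    def test_unlabelled_genome_is_error(self):
        sym = _sym([("a", "b", 97.0)])
        with pytest.raises(ValueError):
            clade_summary(sym, {"a": "A"})


class TestOutliers:
    def test_mislabelled_genome_flagged(self):
        sym = _sym(
            [("ts", "ok", 97.0), ("ts", "bad", 86.0), ("ok", "bad", 86.5)]
        )
        labels = {"ts": "sp", "ok": "sp", "bad": "sp"}
        out = flag_outliers(sym, labels, {"sp": "ts"})
        assert out == [("bad", "sp", 86.0)]

    def test_all_conforming_empty(self):
        sym = _sym([("ts", "ok", 97.0)])
        assert flag_outliers(sym, {"ts": "sp", "ok": "sp"}, {"sp": "ts"}) == []


class TestNearIdentical:
    def test_duplicate_grouped(self):
        sym = _sym([("a", "b", 100.0), ("a", "c", 95.0), ("b", "c", 95.0)])
        assert near_identical_groups(sym, threshold=99.9) == [{"a", "b"}]

    def test_nesting_across_thresholds(self):
        sym = _sym(
            [("a", "b", 99.95), ("a", "c", 99.2), ("b", "c", 99.2)]
        )
        tight = near_identical_groups(sym, threshold=99.9)
        loose = near_identical_groups(sym, threshold=99.0)
        for grp in tight:
            assert any(grp <= big for big in loose)


class TestNjTree:
    def test_two_taxa_total_length(self):
        sym = _sym([("a", "b", 90.0)])
        newick = nj_tree(sym)
        assert "a:0.050000" in newick and "b:0.050000" in newick

    def test_three_taxon_closed_form(self):
        import io

        from skbio import TreeNode

        sym = _sym([("a", "b", 98.0), ("a", "c", 94.0), ("b", "c", 92.0)])
        d_ab, d_ac, d_bc = 0.02, 0.06, 0.08
        tree = TreeNode.read(io.StringIO(nj_tree(sym)))
        dist = {t.name: t.accumulate_to_ancestor(tree.root()) for t in tree.tips()}
        assert dist["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert dist["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert dist["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_two_clade_simulation_bipartitions(self):
        import io

        from skbio import TreeNode

        anc = random_genome(40_000, seed=12)
        genomes, labels = simulate_clades(
            anc, CladeSimSpec((3, 3), 0.02, 0.10, seed=13)
        )
        sym = symmetrize(ani_matrix(genomes))
        tree = TreeNode.read(io.StringIO(nj_tree(sym)))
        tip_sets = [
            frozenset(t.name for t in clade.tips())
            for clade in tree.non_tips(include_self=False)
        ]
        a_tips = frozenset(g for g, c in labels.items() if c == "A")
        b_tips = frozenset(g for g, c in labels.items() if c == "B")
        assert a_tips in tip_sets or b_tips in tip_sets

    def test_undefined_pair_is_error(self):
        sym = _sym([("a", "b", 97.0), ("a", "c", 96.0)])  # b-c missing
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(sym)
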