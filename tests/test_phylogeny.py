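"""Maximum-parsimony trees, clade extraction and tabulation.

The exhaustive search is checked against an independent brute-force
enumerator (written here from scratch: dict-based Fitch over all rooted
topologies generated by sequential leaf insertion).
"""

import itertools

import numpy as np
import pytest

from spatialevo import phylogeny as P
from tests.conftest import make_presence


# ---------------------------------------------------------------------------
# independent oracle: enumerate all rooted topologies, score with set-Fitch

def _all_topologies(leaves):
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert_everywhere(left, leaf):
                yield (t, right)
            for t in insert_everywhere(right, leaf):
                yield (left, t)

    def build(tree, remaining):
        if not remaining:
            yield tree
            return
        for t in insert_everywhere(tree, remaining[0]):
            yield from build(t, remaining[1:])

    yield from build(first, list(rest))


def _fitch_changes(tree, char, root_state=0):
    def down(node):
        if not isinstance(node, tuple):
            return {char[node]}, 0
        (sl, cl), (sr, cr) = down(node[0]), down(node[1])
        inter = sl & sr
        if inter:
            return inter, cl + cr
        return sl | sr, cl + cr + 1

    s, c = down(tree)
    return c + (0 if root_state in s else 1)


def brute_force_score(patterns, weights, regions):
    best = None
    for topo in _all_topologies(list(regions)):
        total = 0
        for mask, w in zip(patterns, weights):
            char = {r: (mask >> i) & 1 for i, r in enumerate(regions)}
            total += w * _fitch_changes(topo, char)
        best = total if best is None else min(best, total)
    return best


# ---------------------------------------------------------------------------

class TestParsimonyTree:
    def test_perfectly_nested_caterpillar(self):
        pm = make_presence(
            {"m1": [1, 1, 1], "m2": [1, 0, 1], "m3": [1, 0, 0]},
            ["T1", "T2", "T5"],
        )
        t = P.build_parsimony_tree(pm)
        assert t.parsimony_score == 3  # each mutation arises exactly once
        clades = {frozenset(c.regions): c for c in P.map_mutations_to_clades(t)}
        assert frozenset({"T1", "T2", "T5"}) in clades
        assert frozenset({"T1", "T5"}) in clades
        assert frozenset({"T1"}) in clades

    def test_star_single_trunk(self):
        pm = make_presence({"m1": [1, 1, 1]}, ["T1", "T2", "T3"])
        t = P.build_parsimony_tree(pm)
        clades = P.map_mutations_to_clades(t)
        assert len(clades) == 1
        assert clades[0].cls == "trunk" and clades[0].n_mutations == 1

    def test_homoplasy_triple_matches_brute_force(self):
        pm = make_presence(
            {"m1": [1, 1, 0], "m2": [0, 1, 1], "m3": [1, 0, 1]},
            ["T1", "T2", "T3"],
        )
        t = P.build_parsimony_tree(pm)
        expected = brute_force_score([0b011, 0b110, 0b101], [1, 1, 1],
                                     ["T1", "T2", "T3"])
        assert t.parsimony_score == expected

    @pytest.mark.parametrize("n_regions", [3, 4, 5])
    def test_random_matrices_match_brute_force(self, n_regions, rng):
        regions = [f"T{i+1}" for i in range(n_regions)]
        for _ in range(15):
            n_mut = int(rng.integers(3, 10))
            mat = rng.random((n_mut, n_regions)) < 0.5
            mat[:, 0] |= ~mat.any(axis=1)
            pm = make_presence({f"m{i}": mat[i] for i in range(n_mut)}, regions)
            t = P.build_parsimony_tree(pm)
            masks, weights, _, regs = P._patterns(pm)
            assert t.parsimony_score == brute_force_score(masks, weights, regs)

    def test_empty_matrix_rejected(self):
        import pandas as pd
        pm = P.PresenceMatrix("PX", pd.DataFrame(columns=["T1", "T2"]).astype(bool),
                              3, 0.02)
        with pytest.raises(ValueError):
            P.build_parsimony_tree(pm)

    def test_deterministic_rerun(self, rng):
        mat = rng.random((12, 5)) < 0.4
        mat[:, 0] |= ~mat.any(axis=1)
        regions = ["T1", "T2", "T3", "T4", "T5"]
        pm = make_presence({f"m{i}": mat[i] for i in range(12)}, regions)
        t1 = P.build_parsimony_tree(pm)
        t2 = P.build_parsimony_tree(pm)
        assert t1.to_newick() == t2.to_newick()
        assert t1.parsimony_score == t2.parsimony_score


class TestClades:
    def test_homoplastic_flagged_and_excluded(self):
        pm = make_presence(
            {"m1": [1, 1, 0], "m2": [0, 1, 1], "m3": [1, 0, 1]},
            ["T1", "T2", "T3"],
        )
        t = P.build_parsimony_tree(pm)
        clades = P.map_mutations_to_clades(t)
        flagged = [c for c in clades if c.homoplastic]
        assert flagged  # the optimal tree cannot host all three cleanly
        ct = P.tabulate_clades({"PX": clades})
        assert not ct.df["homoplastic"].any()
        ct_incl = P.tabulate_clades({"PX": clades}, include_homoplastic=True)
        assert ct_incl.df["homoplastic"].any()

    def test_laminarity_after_exclusion(self, rng):
        # clean clades from one tree are nested or disjoint
        regions = ["T1", "T2", "T3", "T4", "T5"]
        for _ in range(20):
            mat = rng.random((15, 5)) < 0.45
            mat[:, 0] |= ~mat.any(axis=1)
            pm = make_presence({f"m{i}": mat[i] for i in range(15)}, regions)
            clades = [c for c in P.map_mutations_to_clades(P.build_parsimony_tree(pm))
                      if not c.homoplastic]
            for a, b in itertools.combinations(clades, 2):
                inter = a.regions & b.regions
                assert not inter or inter == a.regions or inter == b.regions

    def test_branched_size_tags(self):
        pm = make_presence(
            {"m1": [1, 1, 1, 1, 1], "m2": [1, 0, 0, 0, 1], "m3": [0, 1, 0, 0, 0]},
            ["T1", "T2", "T3", "T4", "T5"],
        )
        ct = P.tabulate_clades(
            {"PX": P.map_mutations_to_clades(P.build_parsimony_tree(pm))}
        )
        assert ct.class_counts == {"trunk": 1, "branched": 1, "private": 1}
        assert ct.branched_size_counts() == {"#2": 1, "#3": 0, "#4+": 0}

    def test_center_involvement_fraction(self):
        clades = {
            "P1": [
                P.Clade("P1", frozenset({"T5", "T1"}), 5, 3, ["a"]),
                P.Clade("P1", frozenset({"T5", "T3"}), 5, 2, ["b"]),
                P.Clade("P1", frozenset({"T2", "T3"}), 5, 1, ["c"]),
            ]
        }
        ct = P.tabulate_clades(clades)
        assert ct.center_involvement_fraction() == pytest.approx(2 / 3)

    def test_class_counts_sum_to_total(self, rng):
        regions = ["T1", "T2", "T3", "T4"]
        tables = {}
        for p in range(6):
            mat = rng.random((10, 4)) < 0.5
            mat[:, 0] |= ~mat.any(axis=1)
            pm = make_presence({f"m{i}": mat[i] for i in range(10)}, regions)
            pm.patient = f"P{p}"
            tables[f"P{p}"] = P.map_mutations_to_clades(P.build_parsimony_tree(pm))
        ct = P.tabulate_clades(tables)
        assert sum(ct.class_counts.values()) == len(ct.df)


class TestNewick:
    def test_newick_contains_all_leaves(self):
        pm = make_presence({"m1": [1, 1, 1], "m2": [1, 1, 0]}, ["T1", "T2", "T5"])
        nwk = P.build_parsimony_tree(pm).to_newick()
        for leaf in ("T1", "T2", "T5"):
            assert leaf in nwk
        assert nwk.endswith(";")

    def test_edge_map_covers_all_mutations(self):
        pm = make_presence({"m1": [1, 1, 1], "m2": [1, 0, 1], "m3": [0, 1, 0]},
                           ["T1", "T2", "T5"])
        t = P.build_parsimony_tree(pm)
        muts = [m for lst in t.edge_mutation_map().values() for m in lst]
        assert sorted(muts) == ["m1", "m2", "m3"]
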