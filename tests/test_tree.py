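"""Neighbor joining, rooting, newick I/O, and the clade assignment rules.

The clade rules are checked against an independent enumeration oracle
that works on clades-as-tip-sets (no tree traversal shared with the
implementation), over every rooted binary topology of a query plus three
references under three taxonomy scenarios.
"""

import io
import itertools

import numpy as np
import pytest
from skbio import TreeNode

from rootid.model import MarkerSequence
from rootid.simulate import SimParams, simulate_dataset
from rootid.tree import (
    TreeAssignParams,
    TreeIdentifier,
    assign_from_tree,
    import_newick,
    nj_tree,
    root_tree,
    total_branch_length,
)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_matrix(self):
        # AB|CD split, internal branch 1, pendants 1,2,3,4
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(mat, labels)
        # the AB|CD split exists
        tip_dist = {
            frozenset([a, b]): tree.find(a).distance(tree.find(b))
            for a, b in itertools.combinations(labels, 2)
        }
        for (a, b), expected in zip(
            itertools.combinations(labels, 2), [3, 5, 6, 6, 7, 7]
        ):
            assert tip_dist[frozenset([a, b])] == pytest.approx(expected)

    def test_three_taxon_closed_form(self):
        mat = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(mat, ["a", "b", "c"])
        # pendant lengths solve the three-point equations:
        # x = (dab + dac - dbc)/2 etc.
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5)
        assert lengths["b"] == pytest.approx(1.5)
        assert lengths["c"] == pytest.approx(2.5)

    def test_topology_invariant_under_matrix_permutation(self, rng):
        labels = ["A", "B", "C", "D", "E"]
        base = np.array(
            [
                [0.0, 0.2, 0.5, 0.6, 0.7],
                [0.2, 0.0, 0.5, 0.6, 0.7],
                [0.5, 0.5, 0.0, 0.3, 0.6],
                [0.6, 0.6, 0.3, 0.0, 0.6],
                [0.7, 0.7, 0.6, 0.6, 0.0],
            ]
        )

        def splits(tree):
            tips = frozenset(t.name for t in tree.tips())
            out = set()
            for node in tree.non_tips():
                under = frozenset(t.name for t in node.tips())
                out.add(min(under, tips - under, key=sorted))
            return out

        ref_splits = splits(nj_tree(base, labels))
        perm = rng.permutation(5)
        permuted = base[np.ix_(perm, perm)]
        plabels = [labels[i] for i in perm]
        assert splits(nj_tree(permuted, plabels)) == ref_splits

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(bad, ["a", "b", "c"])


class TestRooting:
    def test_midpoint_root_on_long_pendant(self):
        tree = TreeNode.read(io.StringIO("((A:0.1,B:0.1):0.1,(C:0.1,D:1.0):0.1);"))
        rooted = root_tree(tree)
        # midpoint lies on D's pendant edge: D's path to the root is
        # half the longest tip-to-tip path (D..A = 1.3 -> 0.65)
        assert rooted.find("D").distance(rooted.root()) == pytest.approx(0.65)

    def test_outgroup_rooting(self):
        tree = TreeNode.read(io.StringIO("((A:0.1,B:0.2):0.1,(C:0.1,OUT:0.9):0.3);"))
        rooted = root_tree(tree, outgroup_tips=["OUT"])
        children = {
            frozenset(t.name for t in c.tips()) or frozenset([c.name])
            for c in rooted.children
        }
        assert frozenset(["OUT"]) in children

    def test_missing_outgroup_rejected(self):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:1);"))
        with pytest.raises(ValueError, match="outgroup"):
            root_tree(tree, outgroup_tips=["NOPE"])

    def test_total_length_preserved_by_rooting(self):
        tree = TreeNode.read(io.StringIO("((A:0.1,B:0.2):0.15,(C:0.3,D:0.4):0.05);"))
        before = total_branch_length(tree.copy())
        assert total_branch_length(root_tree(tree.copy())) == pytest.approx(before)
        assert total_branch_length(
            root_tree(tree.copy(), outgroup_tips=["D"])
        ) == pytest.approx(before)


class TestNewickIO:
    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        nwk = "((A:0.12345,B:0.2):0.05,(C:0.3,D:0.41):0.07);"
        p = tmp_path / "t.nwk"
        p.write_text(nwk)
        tree = import_newick(p, known_tips={"A", "B", "C", "D"})
        out = tmp_path / "out.nwk"
        tree.write(str(out))
        back = import_newick(out, known_tips={"A", "B", "C", "D"})
        for a, b in itertools.combinations("ABCD", 2):
            assert back.find(a).distance(back.find(b)) == pytest.approx(
                tree.find(a).distance(tree.find(b)), abs=1e-9
            )

    def test_lengths_required(self, tmp_path):
        p = tmp_path / "nolen.nwk"
        p.write_text("((A,B),(C,D));")
        with pytest.raises(ValueError, match="branch lengths"):
            import_newick(p)

    def test_unknown_tips_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,X:1):1);")
        with pytest.raises(ValueError, match="X"):
            import_newick(p, known_tips={"A", "B", "C"})

    def test_hand_written_tree_parses_to_expected_splits(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,D:1):1);")
        tree = import_newick(p, known_tips=set("ABCD"))
        cherries = {
            frozenset(t.name for t in node.tips()) for node in tree.non_tips()
        }
        assert frozenset("AB") in cherries and frozenset("CD") in cherries


# --- enumeration oracle for the clade rules --------------------------------


def all_rooted_topologies(leaves):
    """Every rooted binary topology over the leaf set, as nested frozensets."""
    leaves = tuple(leaves)
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    seen = set()
    n = len(leaves)
    for r in range(1, n // 2 + 1):
        for left in itertools.combinations(leaves, r):
            right = tuple(x for x in leaves if x not in left)
            key = frozenset([frozenset(left), frozenset(right)])
            if key in seen or not right:
                continue
            seen.add(key)
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    out.append((lt, rt))
    return out


def to_newick(struct, bl):
    if isinstance(struct, str):
        return f"{struct}:{bl(struct)}"
    left, right = struct
    return f"({to_newick(left, bl)},{to_newick(right, bl)}):{bl(struct)}"


def struct_tips(struct):
    if isinstance(struct, str):
        return frozenset([struct])
    return struct_tips(struct[0]) | struct_tips(struct[1])


def oracle_assign(struct, bl, query, species_of, genus_of, family_of, eps=1e-8):
    """Clade rules evaluated purely on tip sets and path lengths."""
    clades = []

    def walk(node, depth):
        tips = struct_tips(node) if not isinstance(node, str) else frozenset([node])
        clades.append((tips, depth))
        if not isinstance(node, str):
            for child in node:
                walk(child, depth + bl(child))

    walk(struct, 0.0)
    depth_of = {tips: d for tips, d in clades if len(tips) == 1}

    def mrca_depth(x, y):
        return max(d for tips, d in clades if x in tips and y in tips)

    def patristic(x, y):
        return (
            depth_of[frozenset([x])]
            + depth_of[frozenset([y])]
            - 2 * mrca_depth(x, y)
        )

    refs = sorted(species_of)
    parent_clade = min(
        (tips for tips, _ in clades if query in tips and len(tips) >= 2), key=len
    )
    # rule 1: identical-sequence exception
    identical = [r for r in refs if patristic(query, r) <= eps]
    if identical and len({species_of[r] for r in identical}) == 1:
        target = species_of[identical[0]]
        for r in identical:
            mrca = min(
                (tips for tips, _ in clades if query in tips and r in tips), key=len
            )
            if {species_of[x] for x in mrca & set(refs)} == {target}:
                return ("species", target)
    candidates = [
        tips for tips, _ in clades if query in tips and tips > parent_clade
    ]
    # rule 2: species-specific clade with >= 2 reference tips
    for tips in candidates:
        inside = tips & set(refs)
        if len(inside) >= 2 and len({species_of[r] for r in inside}) == 1:
            return ("species", species_of[next(iter(inside))])
    # rules 3-4: genus then family, one node in, >= 1 reference tip
    for rank, rank_of in (("genus", genus_of), ("family", family_of)):
        for tips in candidates:
            inside = tips & set(refs)
            if inside and len({rank_of[species_of[r]] for r in inside}) == 1:
                return (rank, rank_of[species_of[next(iter(inside))]])
    return ("unidentified", "")


SCENARIOS = {
    "one_species": {"r1": "Alpha prima", "r2": "Alpha prima", "r3": "Alpha prima"},
    "two_species_one_genus": {
        "r1": "Alpha prima", "r2": "Alpha prima", "r3": "Alpha secunda",
    },
    "two_genera": {"r1": "Alpha prima", "r2": "Alpha prima", "r3": "Beta prima"},
}


class TestAssignFromTree:
    def _assign(self, newick, toy_taxonomy, species_of, **kw):
        tree = TreeNode.read(io.StringIO(newick))
        return assign_from_tree(tree, "q", species_of, toy_taxonomy, **kw)

    def test_sister_to_species_clade_not_species(self, toy_taxonomy):
        ident = self._assign(
            "((r1:0.1,r2:0.1):0.1,q:0.1):0.0;",
            toy_taxonomy,
            {"r1": "Alpha prima", "r2": "Alpha prima"},
        )
        assert ident.rank != "species"

    def test_one_node_into_species_clade(self, toy_taxonomy):
        ident = self._assign(
            "((r1:0.1,q:0.1):0.1,r2:0.1):0.0;",
            toy_taxonomy,
            {"r1": "Alpha prima", "r2": "Alpha prima"},
        )
        assert (ident.rank, ident.taxon) == ("species", "Alpha prima")
        assert ident.note == "species_clade"

    def test_identical_sequence_exception_fires_when_sister(self, toy_taxonomy):
        ident = self._assign(
            "((r1:0.0,q:0.0):0.1,r2:0.1):0.0;",
            toy_taxonomy,
            {"r1": "Alpha prima", "r2": "Alpha secunda"},
        )
        assert (ident.rank, ident.taxon) == ("species", "Alpha prima")
        assert ident.note == "identical_exception"

    def test_identical_to_two_species_falls_through(self, toy_taxonomy):
        # query at distance 0 from references of two species: the
        # exception must not fire; genus rule applies one node up
        ident = self._assign(
            "(((r1:0.0,q:0.0):0.0,r2:0.0):0.1,r3:0.1):0.0;",
            toy_taxonomy,
            {"r1": "Alpha prima", "r2": "Alpha secunda", "r3": "Alpha secunda"},
        )
        assert ident.rank == "genus"

    def test_unmapped_reference_tip_named_in_error(self, toy_taxonomy):
        tree = TreeNode.read(io.StringIO("((r1:1,q:1):1,mystery:1):0.0;"))
        with pytest.raises(ValueError, match="mystery"):
            assign_from_tree(
                tree, "q", {"r1": "Alpha prima"}, toy_taxonomy, query_tips={"q"}
            )

    def test_matches_enumeration_oracle_on_all_four_tip_topologies(self, toy_taxonomy):
        genus_of = {
            "Alpha prima": "Alpha", "Alpha secunda": "Alpha", "Beta prima": "Beta",
        }
        family_of = {
            "Alpha prima": "Alphaceae", "Alpha secunda": "Alphaceae",
            "Beta prima": "Alphaceae",
        }
        topologies = all_rooted_topologies(["q", "r1", "r2", "r3"])
        assert len(topologies) == 15
        checked = 0
        for struct in topologies:
            for lengths in ("unit", "zero"):
                bl = (lambda node: 1.0) if lengths == "unit" else (lambda node: 0.0)
                nwk = to_newick(struct, bl)[: -len(f":{bl(struct)}")] + ";"
                tree = TreeNode.read(io.StringIO(nwk))
                for name, species_of in SCENARIOS.items():
                    expected = oracle_assign(
                        struct, bl, "q", species_of, genus_of, family_of
                    )
                    got = assign_from_tree(
                        tree, "q", species_of, toy_taxonomy, query_tips={"q"}
                    )
                    assert (got.rank, got.taxon) == expected, (nwk, name, lengths)
                    checked += 1
        assert checked == 90

    def test_other_query_tips_ignored_in_uniformity(self, toy_taxonomy):
        tree = TreeNode.read(
            io.StringIO("(((r1:0.1,q2:0.1):0.1,q:0.1):0.1,(r2:0.1,r3:0.1):0.1):0.0;")
        )
        ident = assign_from_tree(
            tree,
            "q",
            {"r1": "Alpha prima", "r2": "Alpha prima", "r3": "Alpha secunda"},
            toy_taxonomy,
            query_tips={"q", "q2"},
        )
        # q is one node into a clade whose only reference is Alpha prima:
        # 1 ref < 2 so no species call, but the genus rule fires
        assert (ident.rank, ident.taxon) == ("genus", "Alpha")

    def test_removing_and_reattaching_query_is_stable(self, toy_taxonomy):
        nwk = "((r1:0.1,q:0.2):0.1,(r2:0.1,r3:0.3):0.2):0.0;"
        species_of = {"r1": "Alpha prima", "r2": "Alpha prima", "r3": "Alpha prima"}
        tree = TreeNode.read(io.StringIO(nwk))
        before = assign_from_tree(tree, "q", species_of, toy_taxonomy)
        q = tree.find("q")
        parent = q.parent
        parent.remove(q)
        parent.append(q)
        after = assign_from_tree(tree, "q", species_of, toy_taxonomy)
        assert (before.rank, before.taxon) == (after.rank, after.taxon)


def test_species_recovery_with_two_reference_populations(scorer):
    """Zero population offset and two reference tips per species: every
    clean query lands inside its conspecific clade on the NJ tree."""
    params = SimParams(
        seed=31, n_families=3, genera_per_family=2, species_per_genus=2,
        n_queries=20, intraspecific_depth=0.0, adulteration_prob=0.0,
    )
    ds = simulate_dataset(params)
    marker = "psbA-trnH"
    refdb = {
        marker: [
            MarkerSequence(
                sp.replace(" ", "_") + f"_p{i}", sp, marker,
                ds.sequences.variants[marker][sp][i], "reference",
            )
            for sp in sorted(v.species_name for v in ds.taxonomy)
            for i in (0, 1)
        ]
    }
    ident = TreeIdentifier().fit(refdb, ds.taxonomy, scorer=scorer)
    queries = [q.marker_seqs[marker] for q in ds.queries]
    truth = {t.sample_id: t.true_species for t in ds.truth}
    out = ident.predict(queries)
    assert all(
        o.rank == "species" and o.taxon == truth[q.owner_id]
        for q, o in zip(queries, out)
    )
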