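import pytest

from lgtree.core_io import ClassifierConfig, read_newick, write_newick
from lgtree.lgt_classify import (
    LgtCall,
    classify_and_infer,
    classify_gene,
    fitch_states,
    infer_direction,
    reconcile_methods,
    summarize_calls,
)
from lgtree.synthetic_data import random_tree
from lgtree.tree_build import root_tree
from oracles import brute_force_fitch, random_topology

CFG = ClassifierConfig()


def rooted(newick: str):
    return root_tree(read_newick(newick), "as-given")


def walk_oracle(tree, query, groups, cfg=CFG):
    """Independent enumeration of root-path nodes and their group sets."""
    leaf = tree.find_leaf(query)
    qs = groups.species_of(query) if query in groups else query
    node = leaf.parent
    while node is not None:
        if node.support is not None and not node.is_root and node.support > cfg.support_threshold:
            others = [l for l in node.leaves() if l is not leaf]
            if any(groups.species_of(l.label) != qs for l in others):
                g = {groups.group_of(l.label) for l in others}
                if g <= {cfg.focal_group}:
                    return "no_lgt", g
                if cfg.focal_group in g:
                    return "unresolved", g
                return "lgt", g
        node = node.parent
    return "unresolved", set()


class TestClassifyGene:
    def test_high_evalue_is_novel(self):
        tree = rooted("((Q:1,IV_1:1)98:1,(IV_2:1,IV_3:1)99:1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-3)
        assert call.status == "novel"
        assert call.support is None and not call.decision_groups

    def test_threshold_boundary_not_novel(self):
        # e-value exactly 1e-6 is NOT novel under the strict > gate
        tree = rooted("((Q:1,IV_1:1)98:1,(IV_2:1,IV_3:1)99:1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-6)
        assert call.status != "novel"

    def test_all_focal_descendants_no_lgt(self):
        tree = rooted("((Q:1,IV_1:1)98:1,(IV_2:1,IV_3:1)99:1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "no_lgt"
        assert call.decision_groups == frozenset({"cluster_IV"})
        assert call.support == 98.0

    def test_nested_in_supported_donor_clade_is_lgt(self):
        tree = rooted("(((Q:1,XIVa_1:1)95:1,XIVa_2:1)90:1,(IV_1:1,IV_2:1)99:1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "lgt"
        assert call.decision_groups == frozenset({"cluster_XIVa"})
        assert walk_oracle(tree, "Q", _gm()) == ("lgt", {"cluster_XIVa"})

    def test_unsupported_inner_then_mixed_node_unresolved(self):
        tree = rooted(
            "(((Q:1,XIVa_1:1)55:1,IV_3:1)80:1,(IV_1:1,IV_2:1)99:1);"
        )
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "unresolved"
        assert call.decision_groups == frozenset({"cluster_XIVa", "cluster_IV"})
        assert walk_oracle(tree, "Q", _gm()) == (
            "unresolved", {"cluster_XIVa", "cluster_IV"},
        )

    def test_no_gated_node_records_unresolved(self):
        tree = rooted("((Q:1,XIVa_1:1)40:1,(XIVa_2:1,XIVa_3:1)50:1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "unresolved"
        assert call.support is None
        assert "no_supported_node" in call.notes

    def test_absent_support_never_satisfies_gate(self):
        tree = rooted("((Q:1,XIVa_1:1):1,(XIVa_2:1,XIVa_3:1):1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "unresolved"

    def test_own_species_does_not_trigger_different_species_test(self):
        # decision node containing only the query's own species is skipped
        from lgtree.core_io import TaxonGroupMap

        gm = TaxonGroupMap(
            entries={
                "Q": ("sp1", "cluster_IV"),
                "same": ("sp1", "cluster_IV"),
                "IV_2": ("sp2", "cluster_IV"),
                "XIVa_1": ("sp3", "cluster_XIVa"),
            },
            focal_group="cluster_IV",
        )
        tree = rooted("((Q:1,same:1)99:1,(IV_2:1,XIVa_1:1)99:1);")
        call = classify_gene(tree, "Q", gm, top_evalue=1e-20)
        # first supported node has only sp1 -> walk continues to the root's
        # other side... root is ungated, so unresolved
        assert call.status == "unresolved"
        assert call.support is None

    def test_query_missing_raises(self):
        tree = rooted("((A:1,IV_1:1)98:1,(IV_2:1,IV_3:1)99:1);")
        with pytest.raises(KeyError):
            classify_gene(tree, "Q", _gm(), top_evalue=1e-20)

    def test_unmapped_leaf_raises(self):
        tree = rooted("((Q:1,mystery:1)98:1,(IV_2:1,IV_3:1)99:1);")
        with pytest.raises(ValueError, match="mystery"):
            classify_gene(tree, "Q", _gm(), top_evalue=1e-20)

    def test_rotation_and_reserialization_invariance(self, rng, toy_groups):
        for _ in range(50):
            tree, gm = _random_labelled_tree(rng)
            base = classify_gene(tree, "Q", gm, top_evalue=1e-20)
            rotated = tree.copy()
            for n in rotated.postorder():
                n.children.reverse()
            r1 = classify_gene(rotated, "Q", gm, top_evalue=1e-20)
            r2 = classify_gene(
                root_tree(read_newick(write_newick(tree)), "as-given"),
                "Q", gm, top_evalue=1e-20,
            )
            assert r1.status == base.status
            assert r2.status == base.status
            assert r1.decision_groups == base.decision_groups

    def test_focal_only_trees_never_lgt(self, rng):
        # if every non-query leaf is focal-group, status is never lgt
        from lgtree.core_io import TaxonGroupMap

        for _ in range(1000):
            n = int(rng.integers(4, 12))
            tree = random_tree(n, rng)
            labels = tree.leaf_labels()
            query = labels[int(rng.integers(n))]
            entries = {l: (l, "cluster_IV") for l in labels}
            gm = TaxonGroupMap(
                entries=entries,
                vocabulary=("cluster_IV", "cluster_XIVa"),
                focal_group="cluster_IV",
            )
            for node in tree.postorder():
                if not node.is_leaf and not node.is_root:
                    node.support = float(rng.uniform(0, 100))
            call = classify_gene(tree, query, gm, top_evalue=1e-20)
            assert call.status != "lgt"


def _gm():
    from lgtree.core_io import TaxonGroupMap

    entries = {"Q": ("Q", "cluster_IV")}
    for i in range(1, 6):
        entries[f"IV_{i}"] = (f"IV_{i}", "cluster_IV")
        entries[f"XIVa_{i}"] = (f"XIVa_{i}", "cluster_XIVa")
        entries[f"other_{i}"] = (f"other_{i}", "other")
    return TaxonGroupMap(
        entries=entries,
        vocabulary=("cluster_IV", "cluster_XIVa", "other"),
        focal_group="cluster_IV",
    )


def _random_labelled_tree(rng):
    n = int(rng.integers(4, 10))
    tree = random_tree(n, rng)
    leaves = tree.leaves()
    groups = ["cluster_IV", "cluster_XIVa", "other"]
    from lgtree.core_io import TaxonGroupMap

    entries = {}
    for i, leaf in enumerate(leaves):
        if i == 0:
            leaf.label = "Q"
            entries["Q"] = ("Q", "cluster_IV")
        else:
            g = groups[int(rng.integers(3))]
            entries[leaf.label] = (leaf.label, g)
    for node in tree.postorder():
        if not node.is_leaf and not node.is_root:
            node.support = float(rng.uniform(0, 100))
    gm = TaxonGroupMap(
        entries=entries, vocabulary=tuple(groups), focal_group="cluster_IV"
    )
    return tree, gm


class TestFitch:
    def test_uniform_leaves_zero_changes(self):
        tree = rooted("((a,b),(c,d));")
        res = fitch_states(tree, {l: "g" for l in "abcd"})
        assert res.changes == 0
        assert all(s == frozenset({"g"}) for s in res.state_sets.values())

    def test_three_one_split(self):
        # brute force over all 2^4 internal labelings confirms minimum = 1
        tree = rooted("((a,b),(c,d));")
        groups = {"a": "IV", "b": "XIVa", "c": "XIVa", "d": "XIVa"}
        res = fitch_states(tree, groups)
        assert res.changes == 1
        assert res.state_sets[tree.root] == frozenset({"XIVa"})
        topo = (("a", "b"), ("c", "d"))
        assert brute_force_fitch(topo, groups, ("IV", "XIVa")) == 1

    def test_two_two_alternating(self):
        tree = rooted("((a,b),(c,d));")
        groups = {"a": "IV", "b": "XIVa", "c": "IV", "d": "XIVa"}
        res = fitch_states(tree, groups)
        assert res.changes == 2
        assert res.state_sets[tree.root] == frozenset({"IV", "XIVa"})
        topo = (("a", "b"), ("c", "d"))
        assert brute_force_fitch(topo, groups, ("IV", "XIVa")) == 2

    def test_unlabeled_leaf_raises(self):
        tree = rooted("((a,b),(c,d));")
        with pytest.raises(ValueError, match="no group"):
            fitch_states(tree, {"a": "g", "b": "g", "c": "g"})

    def test_against_brute_force_oracle(self, rng):
        alphabet = ("A", "B", "C")
        for _ in range(300):
            n = int(rng.integers(2, 9))
            labels = [f"l{i}" for i in range(n)]
            topo = random_topology(labels, rng)
            groups = {l: alphabet[int(rng.integers(3))] for l in labels}
            tree = rooted(_topo_to_newick(topo) + ";")
            res = fitch_states(tree, groups)
            assert res.changes == brute_force_fitch(topo, groups, alphabet)

    def test_leaf_sets_are_singletons(self):
        tree = rooted("((a,b),(c,d));")
        res = fitch_states(tree, {"a": "x", "b": "y", "c": "x", "d": "x"})
        for leaf in tree.leaves():
            assert len(res.state_sets[leaf]) == 1


def _topo_to_newick(topo):
    if isinstance(topo, str):
        return topo
    return "(" + ",".join(_topo_to_newick(c) for c in topo) + ")"


class TestInferDirection:
    def test_resolved_donor(self):
        tree = rooted("(((Q:1,XIVa_1:1)95:1,XIVa_2:1)90:1,(IV_1:1,IV_2:1)99:1);")
        call = classify_and_infer(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "lgt"
        assert call.donor == "cluster_XIVa"
        assert call.direction == "from cluster_XIVa to cluster_IV"

    def test_mixed_donor_groups_unresolved(self):
        tree = rooted("((Q:1,XIVa_1:1,other_1:1)95:1,(IV_1:1,IV_2:1)99:1);")
        call = classify_and_infer(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "lgt"
        assert call.decision_groups == frozenset({"cluster_XIVa", "other"})
        assert call.donor is None
        assert call.direction == "unresolved"

    def test_root_ambiguous_toy_unresolved(self):
        # ((IV,XIVa),(IV,XIVa)) with the query as the first IV; both root
        # states attain the brute-force minimum of 2, so no direction
        tree = rooted("((Q:1,XIVa_1:1)100:1,(IV_1:1,XIVa_2:1)100:1);")
        groups = {"Q": "cluster_IV", "XIVa_1": "cluster_XIVa",
                  "IV_1": "cluster_IV", "XIVa_2": "cluster_XIVa"}
        topo = (("Q", "XIVa_1"), ("IV_1", "XIVa_2"))
        assert brute_force_fitch(topo, groups, ("cluster_IV", "cluster_XIVa")) == 2
        call = classify_and_infer(tree, "Q", _gm(), top_evalue=1e-20)
        assert call.status == "lgt"
        assert call.direction == "unresolved"
        assert call.donor is None

    def test_contract_error_on_non_lgt(self):
        tree = rooted("((Q:1,IV_1:1)98:1,(IV_2:1,IV_3:1)99:1);")
        call = classify_gene(tree, "Q", _gm(), top_evalue=1e-20)
        with pytest.raises(ValueError, match="lgt"):
            infer_direction(call, tree, "Q", _gm())


class TestReconcile:
    @staticmethod
    def _call(status, support=None, donor=None, notes=()):
        direction = "not_applicable"
        if status == "lgt" and donor:
            direction = f"from {donor} to cluster_IV"
        return LgtCall(
            gene_id="g1", status=status, support=support, donor=donor,
            direction=direction,
            decision_groups=frozenset({donor}) if donor else frozenset(),
            notes=notes,
        )

    def test_agreement_is_lgt(self):
        out = reconcile_methods(
            self._call("lgt", 95, "cluster_XIVa"),
            self._call("lgt", 90, "cluster_XIVa"),
        )
        assert out.status == "lgt"
        assert out.donor == "cluster_XIVa"
        assert not any(n.startswith("discordant") for n in out.notes)

    def test_unresolved_vs_no_is_no(self):
        out = reconcile_methods(self._call("unresolved"), self._call("no_lgt"))
        assert out.status == "no_lgt"
        assert any(n.startswith("discordant") for n in out.notes)

    def test_low_support_lgt_vs_no_is_no_and_flagged(self):
        nj = self._call("lgt", 61, "cluster_XIVa", notes=("low_support",))
        out = reconcile_methods(nj, self._call("no_lgt"))
        assert out.status == "no_lgt"
        assert "low_support:nj" in out.notes

    def test_lgt_vs_unresolved_is_unresolved(self):
        # the conservative headline count excludes single-method lgt calls
        out = reconcile_methods(
            self._call("unresolved"), self._call("lgt", 90, "cluster_XIVa")
        )
        assert out.status == "unresolved"

    def test_gene_id_mismatch(self):
        a = self._call("no_lgt")
        b = LgtCall(gene_id="other", status="no_lgt")
        with pytest.raises(ValueError, match="mismatch"):
            reconcile_methods(a, b)

    def test_commutative_status(self):
        statuses = ["novel", "no_lgt", "unresolved", "lgt"]
        for s1 in statuses:
            for s2 in statuses:
                a = self._call(s1, 90 if s1 != "novel" else None)
                b = self._call(s2, 85 if s2 != "novel" else None)
                assert (
                    reconcile_methods(a, b).status
                    == reconcile_methods(b, a).status
                )


class TestSummarize:
    def test_empty_input_all_zero(self):
        s = summarize_calls([])
        assert s.total == 0 and s.lgt == 0 and s.per_donor == ()

    def test_fixture_headline_counts(self, fixture_records):
        s = summarize_calls(fixture_records)
        assert s.total == 44
        assert s.lgt == 10
        assert s.donor_count("cluster_XIVa") == 7
        assert s.direction_resolved == 7
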