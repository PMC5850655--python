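import numpy as np
import pytest

from oracles import rf_distance
from substab import (
    MissingTaxonError,
    NewickParseError,
    Split,
    ValidationError,
    bipartitions,
    induced_subtree,
    parse_newick,
    random_rooted_tree,
    root_at,
    same_topology,
    unroot,
    write_newick,
)


def split(a, b):
    return Split.of(a, b)


class TestNewick:
    def test_parse_quartet(self):
        t = parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        assert t.leaf_names() == {"A", "B", "C", "D"}
        assert bipartitions(t) == {split("AB", "CD")}

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,B)),C;", ")A,B(;"])
    def test_parse_errors(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_round_trip_random_tree(self, rng):
        t = random_rooted_tree([f"leaf{i}" for i in range(10)], rng)
        back = parse_newick(write_newick(t))
        assert same_topology(t, back)
        orig = sorted(n.length for n in t.iter_nodes() if n.length is not None)
        got = sorted(n.length for n in back.iter_nodes() if n.length is not None)
        assert np.allclose(orig, got, atol=1e-9)

    def test_pb_ps_annotation_label(self):
        t = parse_newick("(((A,B),C),D,E);")
        s = split("AB", "CDE")
        text = write_newick(t, annotation="pb_ps", pb={s: 97.0}, ps={s: 100.0})
        assert "97|100" in text
        back = parse_newick(text)
        labels = [n.label for n in back.iter_nodes() if n.label]
        assert "97|100" in labels

    def test_ps_na_when_undefined(self):
        t = parse_newick("(((A,B),C),D,E);")
        text = write_newick(
            t, annotation="pb_ps",
            pb={split("AB", "CDE"): 100.0, split("ABC", "DE"): 80.0},
            ps={split("ABC", "DE"): 50.0},
        )
        assert "100|NA" in text and "80|50" in text

    def test_quoted_names_round_trip(self):
        t = parse_newick("('sp one':1,'sp(2)':1,(C:1,D:1):1);")
        assert "sp one" in t.leaf_names()
        assert same_topology(t, parse_newick(write_newick(t)))


class TestBipartitions:
    def test_caterpillar_splits(self):
        t = parse_newick("(((A,B),C),D,E);")
        assert bipartitions(t) == {split("AB", "CDE"), split("ABC", "DE")}

    def test_star_has_none(self):
        assert bipartitions(parse_newick("(A,B,C,D);")) == frozenset()

    def test_split_count_is_n_minus_3(self, rng):
        for n in (5, 8, 12, 20):
            t = random_rooted_tree([f"x{i}" for i in range(n)], rng)
            assert len(bipartitions(t)) == n - 3
            assert len(bipartitions(unroot(t))) == n - 3


class TestSameTopology:
    def test_ignores_branch_lengths(self):
        a = parse_newick("((A:1,B:2):3,(C:4,D:5):6);")
        b = parse_newick("((A:9,B:9):9,(C:9,D:9):9);")
        assert same_topology(a, b)

    def test_distinguishes_quartets(self):
        assert not same_topology(parse_newick("((A,B),(C,D));"),
                                 parse_newick("((A,C),(B,D));"))

    def test_leafset_mismatch_raises(self):
        with pytest.raises(ValidationError):
            same_topology(parse_newick("((A,B),(C,D));"),
                          parse_newick("((A,B),(C,E));"))

    def test_agrees_with_rf_oracle(self, rng):
        names = [f"t{i}" for i in range(8)]
        for _ in range(40):
            t1 = unroot(random_rooted_tree(names, rng))
            t2 = unroot(random_rooted_tree(names, rng))
            mine = same_topology(t1, t2)
            assert mine == (rf_distance(write_newick(t1),
                                        write_newick(t2)) == 0)


class TestRooting:
    def test_root_quartet_at_leaf(self):
        rooted = root_at(parse_newick("((A,B),(C,D));"), "D")
        assert rooted.rooted
        from substab import enumerate_clades
        clades = {rec.clade_taxa for rec in enumerate_clades(rooted)}
        assert clades == {frozenset("AB"), frozenset("ABC")}

    def test_root_unroot_involution(self, rng):
        t = unroot(random_rooted_tree([f"n{i}" for i in range(7)], rng))
        assert same_topology(t, unroot(root_at(t, "n3")))

    def test_root_choice_changes_clades(self):
        from substab import enumerate_clades
        t = parse_newick("((A,B),(C,D));")
        at_a = {r.clade_taxa for r in enumerate_clades(root_at(t, "A"))}
        at_b = {r.clade_taxa for r in enumerate_clades(root_at(t, "B"))}
        assert frozenset("CD") in at_a and frozenset("CD") in at_b
        assert at_a != at_b

    def test_unknown_outgroup(self):
        with pytest.raises(MissingTaxonError):
            root_at(parse_newick("((A,B),(C,D));"), "Z")


class TestInducedSubtree:
    def test_three_taxa_star(self):
        t = parse_newick("(((A,B),C),D,E);")
        sub = induced_subtree(t, {"A", "B", "C"})
        assert sub.leaf_names() == {"A", "B", "C"}
        assert bipartitions(sub) == frozenset()

    def test_full_set_identity(self):
        t = parse_newick("(((A,B),C),D,E);")
        assert same_topology(t, induced_subtree(t, t.leaf_names()))

    def test_manual_pruning(self):
        t = parse_newick("(((A,B),C),(D,E));")
        sub = induced_subtree(t, {"A", "C", "D", "E"})
        assert bipartitions(sub) == {split("AC", "DE")}

    def test_lengths_are_summed_on_suppressed_path(self):
        t = parse_newick("(((A:1,B:1):2,C:1):3,D:4,E:5);")
        sub = induced_subtree(t, {"A", "C", "D"})
        d = {n.name: n.length for n in sub.iter_leaves()}
        assert d["A"] == pytest.approx(3.0)  # pendant 1 + suppressed 2

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError):
            induced_subtree(parse_newick("((A,B),(C,D));"), {"A", "B"})
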