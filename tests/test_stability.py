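import pytest

from substab import (
    ValidationError,
    caterpillar_tree,
    closest_outgroups,
    distance_matrix,
    enumerate_clades,
    neighbor_joining,
    parse_newick,
    ps_averaged,
    ps_single_outgroup,
    random_rooted_tree,
    root_at,
    simulate_alignment,
    stability_profile,
)
from substab.stability import choose_root_outgroup


def _clades(tree_text):
    return enumerate_clades(parse_newick(tree_text))


class TestEnumeration:
    def test_caterpillar_five(self):
        recs = _clades("((((1,2),3),4),5);")
        assert [sorted(r.clade_taxa) for r in recs] == [
            ["1", "2"], ["1", "2", "3"], ["1", "2", "3", "4"],
        ]
        by_size = {len(r.clade_taxa): r for r in recs}
        assert by_size[2].sister_taxa == {"3"}
        assert by_size[3].sister_taxa == {"4"}
        # child of the root: its split is the root leaf's pendant edge,
        # no interior branch -> no outgroup pool
        assert by_size[4].sister_taxa == frozenset()
        assert [r.ps_eligible for r in recs] == [False, True, False]
        assert by_size[4].status == "NA:no-outgroup"
        assert by_size[2].status == "NA:two-taxa"

    def test_balanced_quartet_none_eligible(self):
        recs = _clades("((A,B),(C,D));")
        assert {frozenset(r.clade_taxa) for r in recs} == {
            frozenset("AB"), frozenset("CD")
        }
        assert not any(r.ps_eligible for r in recs)

    def test_eight_leaf_count(self, rng):
        t = random_rooted_tree([f"t{i}" for i in range(8)], rng)
        assert len(enumerate_clades(t)) == 6  # n - 2 non-root internal

    def test_caterpillar_six_eligible_set(self):
        recs = _clades("(((((1,2),3),4),5),6);")
        eligible = [sorted(r.clade_taxa) for r in recs if r.ps_eligible]
        assert eligible == [["1", "2", "3"], ["1", "2", "3", "4"]]

    def test_unrooted_input_rejected(self):
        with pytest.raises(ValidationError, match="root"):
            enumerate_clades(parse_newick("((A,B),C,(D,E));"))


class TestClosestOutgroups:
    def test_single_sister_leaf(self):
        recs = _clades("((((1,2),3),4),5);")
        rec = next(r for r in recs if len(r.clade_taxa) == 3)
        assert closest_outgroups(rec) == ["4"]

    def test_sister_subtree_pool(self):
        # clade 1-6 whose sister subtree holds 7-11; rooted at 12
        text = ("((((((s1,s2),s3),s4),s5),s6),"
                "((((s7,s8),s9),s10),s11)),s12);")
        recs = _clades("(" + text)
        rec = next(r for r in recs if len(r.clade_taxa) == 6
                   and "s1" in r.clade_taxa)
        assert set(closest_outgroups(rec)) == {"s7", "s8", "s9", "s10", "s11"}
        assert closest_outgroups(rec) == sorted(rec.sister_taxa)


@pytest.fixture(scope="module")
def high_signal():
    truth = caterpillar_tree(7, internal_len=0.08, terminal_len=0.05)
    aln = simulate_alignment(truth, 2000, seed=11)
    tree = neighbor_joining(distance_matrix(aln))
    rooted = root_at(tree, "t7")
    return aln, tree, rooted


class TestPs:
    def test_identity_bootstrap_s_equals_n(self, high_signal):
        aln, tree, rooted = high_signal
        rec = next(r for r in enumerate_clades(rooted) if r.ps_eligible)
        out = ps_single_outgroup(aln, tree, rec, closest_outgroups(rec)[0],
                                 replicates=25, seed=0,
                                 identity_bootstrap=True)
        assert (out.s, out.n, out.ps) == (25, 25, 100.0)

    def test_ps_is_exact_ratio(self, high_signal):
        aln, tree, rooted = high_signal
        rec = next(r for r in enumerate_clades(rooted) if r.ps_eligible)
        out = ps_single_outgroup(aln, tree, rec, closest_outgroups(rec)[0],
                                 replicates=40, seed=3)
        assert out.ps == 100.0 * out.s / out.n
        assert 0 <= out.s <= out.n == 40

    def test_mean_is_unweighted_average(self, high_signal):
        aln, tree, rooted = high_signal
        rec = next(r for r in enumerate_clades(rooted) if r.ps_eligible)
        res = ps_averaged(aln, tree, rec, replicates=30, seed=2)
        assert res.ps_mean == sum(r.ps for r in res.per_outgroup) / len(
            res.per_outgroup
        )

    def test_results_independent_of_evaluation_order(self, high_signal):
        aln, tree, rooted = high_signal
        recs = [r for r in enumerate_clades(rooted) if r.ps_eligible]
        forward = [
            ps_averaged(aln, tree, r, replicates=30, seed=6) for r in recs
        ]
        backward = [
            ps_averaged(aln, tree, r, replicates=30, seed=6)
            for r in reversed(recs)
        ]
        fwd = {frozenset(r.clade.clade_taxa):
               [(o.outgroup, o.s, o.n) for o in r.per_outgroup]
               for r in forward}
        bwd = {frozenset(r.clade.clade_taxa):
               [(o.outgroup, o.s, o.n) for o in r.per_outgroup]
               for r in backward}
        assert fwd == bwd

    def test_profile_identity_mode_all_100(self, high_signal):
        aln, tree, _ = high_signal
        results = stability_profile(aln, tree, replicates=20, seed=0,
                                    root_outgroup="t7",
                                    identity_bootstrap=True)
        assert results and all(r.ps_mean == 100.0 for r in results)

    def test_ineligible_clade_rejected(self, high_signal):
        aln, tree, rooted = high_signal
        rec = next(r for r in enumerate_clades(rooted)
                   if len(r.clade_taxa) == 2)
        with pytest.raises(ValidationError):
            ps_averaged(aln, tree, rec, replicates=10, seed=0)

    def test_wrong_outgroup_rejected(self, high_signal):
        aln, tree, rooted = high_signal
        rec = next(r for r in enumerate_clades(rooted) if r.ps_eligible)
        with pytest.raises(ValidationError):
            ps_single_outgroup(aln, tree, rec, "t1", replicates=10, seed=0)


def test_root_heuristic_picks_most_distant_leaf():
    import numpy as np

    from substab import DistanceMatrix

    d = np.array([
        [0.0, 0.1, 0.1, 0.4],
        [0.1, 0.0, 0.1, 0.4],
        [0.1, 0.1, 0.0, 0.5],
        [0.4, 0.4, 0.5, 0.0],
    ])
    assert choose_root_outgroup(DistanceMatrix(("a", "b", "c", "d"), d)) == "d"
    # tie between b and a breaks lexicographically
    tie = np.array([
        [0.0, 0.2, 0.3],
        [0.2, 0.0, 0.3],
        [0.3, 0.3, 0.0],
    ])
    assert choose_root_outgroup(DistanceMatrix(("b", "a", "c"), tie)) == "c"
    sym = np.ones((3, 3)) - np.eye(3)
    assert choose_root_outgroup(DistanceMatrix(("b", "a", "c"), sym)) == "a"
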