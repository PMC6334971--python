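import itertools

import pytest

from tomseek import assets
from tomseek import phyloprofile as pp
from tomseek import synthetic_data as sd


def all_rooted_binary_trees(labels):
    """Enumerate every rooted binary topology over the label set (newick)."""
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    first = labels[0]
    rest = labels[1:]
    for k in range(len(rest)):
        for left_rest in itertools.combinations(rest, k):
            left = [first, *left_rest]
            right = [l for l in rest if l not in left_rest]
            if not right:
                continue
            for lt in all_rooted_binary_trees(left):
                for rt in all_rooted_binary_trees(right):
                    yield f"({lt},{rt})"


def dollo_oracle(tree: "pp.dendropy.Tree", present: set, absent: set) -> int:
    """Minimal loss count over all single-gain scenarios, by brute force."""
    nodes = list(tree.preorder_node_iter())
    below = {id(n): pp._clade_leafset(n) for n in nodes}
    best = None
    for gain in nodes:
        if not present <= below[id(gain)]:
            continue
        sub_edges = [
            n for n in gain.preorder_iter() if n is not gain
        ]  # candidate loss edges strictly below the gain
        for r in range(len(sub_edges) + 1):
            if best is not None and r >= best:
                break
            for combo in itertools.combinations(sub_edges, r):
                lost = set().union(*(below[id(n)] for n in combo)) if combo else set()
                implied_present = below[id(gain)] - lost
                if present <= implied_present and not (absent & implied_present):
                    best = r if best is None else min(best, r)
                    break
            else:
                continue
            break
    return best


class TestNewick:
    def test_two_leaf_tree(self):
        tree = pp.read_newick("(A,B);")
        assert pp.leaf_labels(tree) == {"A", "B"}

    def test_four_leaves_three_internal(self):
        tree = pp.read_newick("((A,B),(C,D));")
        assert len(pp.leaf_labels(tree)) == 4
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 3

    def test_round_trip_topology(self):
        text = "((A,B),(C,(D,E)));"
        tree = pp.read_newick(text)
        again = pp.read_newick(pp.write_newick(tree))
        clades1 = {
            pp._clade_leafset(n) for n in tree.preorder_node_iter()
        }
        clades2 = {
            pp._clade_leafset(n) for n in again.preorder_node_iter()
        }
        assert clades1 == clades2

    def test_unbalanced_rejected(self):
        with pytest.raises(pp.NewickError):
            pp.read_newick("((A,B);")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(pp.NewickError, match="duplicate"):
            pp.read_newick("(A,(B,A));")


class TestDolloMap:
    def test_present_everywhere_no_losses(self):
        tree = pp.read_newick("((A,B),(C,D));")
        prof = pp.PhyloProfile.from_dict(
            {"X": {t: "1" for t in "ABCD"}}
        )
        entry = pp.dollo_map(tree, prof, "X")
        assert entry.gain_clade == frozenset("ABCD")
        assert entry.n_losses == 0

    def test_independent_losses_in_two_lineages(self):
        """Absence in two separate clades maps to two loss events."""
        tree = pp.read_newick("((Cme,(Tva,Gin)),((Egr,Sin),Tbr));")
        prof = pp.PhyloProfile.from_dict(
            {
                "Tom7": {
                    "Cme": "1", "Egr": "1", "Sin": "1",
                    "Tva": "0", "Gin": "0", "Tbr": "0",
                }
            }
        )
        entry = pp.dollo_map(tree, prof, "Tom7")
        assert entry.gain_clade == frozenset(
            {"Cme", "Tva", "Gin", "Egr", "Sin", "Tbr"}
        )
        assert set(entry.loss_clades) == {
            frozenset({"Tva", "Gin"}),
            frozenset({"Tbr"}),
        }

    def test_single_leaf_gain(self):
        tree = pp.read_newick("((A,B),(C,D));")
        prof = pp.PhyloProfile.from_dict(
            {"X": {"A": "1", "B": "0", "C": "0", "D": "0"}}
        )
        entry = pp.dollo_map(tree, prof, "X")
        assert entry.gain_clade == frozenset({"A"})
        assert entry.n_losses == 0

    def test_all_absent_zero_events(self):
        tree = pp.read_newick("(A,B);")
        prof = pp.PhyloProfile.from_dict({"X": {"A": "0", "B": "0"}})
        entry = pp.dollo_map(tree, prof, "X")
        assert entry.gain_clade is None and entry.n_losses == 0

    def test_uncertain_leaves_resolved_to_avoid_events(self):
        tree = pp.read_newick("((A,B),(C,D));")
        prof = pp.PhyloProfile.from_dict(
            {"X": {"A": "1", "B": "?", "C": "1", "D": "?"}}
        )
        entry = pp.dollo_map(tree, prof, "X")
        assert entry.n_losses == 0

    def test_implied_states_reproduce_profile(self):
        for seed in range(20):
            tree, prof, _ = sd.gen_tree_profile(
                sd.TreeProfileSpec(n_leaves=10, p_loss=0.3), seed
            )
            for comp in prof.components:
                entry = pp.dollo_map(tree, prof, comp)
                implied = pp.implied_leaf_states(tree, entry)
                for taxon in prof.taxa:
                    state = prof.frame.loc[comp, taxon]
                    if state != pp.UNCERTAIN:
                        assert implied[taxon] == state

    def test_adding_present_leaf_never_lowers_gain(self):
        tree = pp.read_newick("((A,(B,C)),((D,E),F));")
        prof1 = pp.PhyloProfile.from_dict(
            {"X": {"B": "1", "C": "1", "A": "0", "D": "0", "E": "0", "F": "0"}}
        )
        prof2 = pp.PhyloProfile.from_dict(
            {"X": {"B": "1", "C": "1", "D": "1", "A": "0", "E": "0", "F": "0"}}
        )
        g1 = pp.dollo_map(tree, prof1, "X").gain_clade
        g2 = pp.dollo_map(tree, prof2, "X").gain_clade
        assert g1 <= g2


class TestDolloOptimality:
    def test_exhaustive_small_trees_all_patterns(self):
        """Loss counts equal the brute-force minimum on every topology."""
        labels = list("ABCDE")
        for n in (2, 3, 4, 5):
            subset = labels[:n]
            for newick in all_rooted_binary_trees(subset):
                tree = pp.read_newick(newick + ";")
                for bits in itertools.product("01", repeat=n):
                    present = {t for t, b in zip(subset, bits) if b == "1"}
                    if not present:
                        continue
                    absent = set(subset) - present
                    prof = pp.PhyloProfile.from_dict(
                        {"X": dict(zip(subset, bits))}
                    )
                    entry = pp.dollo_map(tree, prof, "X")
                    assert entry.n_losses == dollo_oracle(tree, present, absent), (
                        newick,
                        bits,
                    )

    def test_sampled_larger_trees_all_patterns(self):
        import numpy as np

        labels = list("ABCDEFGH")
        rng = np.random.default_rng(23)
        for trial in range(6):
            n = int(rng.integers(6, 9))
            subset = labels[:n]
            order = list(subset)
            rng.shuffle(order)
            newick = sd._random_newick(order, rng)
            tree = pp.read_newick(newick + ";")
            for bits in itertools.product("01", repeat=n):
                present = {t for t, b in zip(subset, bits) if b == "1"}
                if not present:
                    continue
                absent = set(subset) - present
                prof = pp.PhyloProfile.from_dict({"X": dict(zip(subset, bits))})
                entry = pp.dollo_map(tree, prof, "X")
                assert entry.n_losses == dollo_oracle(tree, present, absent)


class TestProfileReport:
    def test_simulated_histories_recovered(self):
        for seed in range(20):
            tree, prof, truth = sd.gen_tree_profile(
                sd.TreeProfileSpec(n_leaves=12, p_loss=0.25), seed
            )
            entries, _ = pp.profile_report(tree, prof)
            for comp, entry in entries.items():
                assert entry.gain_clade == truth.gain_clades[comp]
                assert set(entry.loss_clades) == set(truth.loss_clades[comp])

    def test_empty_profile(self):
        tree = pp.read_newick("(A,B);")
        prof = pp.PhyloProfile.from_dict({})
        entries, table = pp.profile_report(tree, prof)
        assert entries == {} and len(table) == 0

    def test_uncertain_only_component_flagged(self):
        tree = pp.read_newick("(A,B);")
        prof = pp.PhyloProfile.from_dict({"X": {"A": "?", "B": "?"}})
        entries, table = pp.profile_report(tree, prof)
        assert entries["X"].n_gains == 0
        row = table[table.component == "X"].iloc[0]
        assert bool(row.uncertain_only)

    def test_packaged_example_tree_and_profile(self):
        tree = assets.lineage_consensus_tree()
        prof = assets.example_tom_profile()
        entries, table = pp.profile_report(tree, prof)
        # the pore-forming channel is ubiquitous: single gain, no loss
        assert entries["Tom40"].n_losses == 0
        # Tom7 absence maps to independent losses in separate lineages
        assert entries["Tom7"].n_losses >= 2
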