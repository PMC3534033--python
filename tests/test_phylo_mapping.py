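"""Sharing matrix and Dollo parsimony, with a brute-force single-gain
placement oracle."""
from itertools import combinations

import dendropy
import numpy as np
import pytest

from plastintron.phylo_mapping import (dollo_map, fitch_length, load_tree,
                                       sharing_matrix, _dollo_one)
from plastintron.site_mapping import AlignedSite, SiteGroup

TREE = "((((Egra,Elon)n1,Maen)n2,Evir)n3,Egym)root;"


def group(gene, tags, column=0, twintron=False):
    members = tuple(
        AlignedSite(site_id=f"{gene}.{t}.1", gene=gene, species_tag=t,
                    column=column, phase=0)
        for t in tags
    )
    return SiteGroup(gene=gene, members=members,
                     twintron_flags={m.site_id: twintron for m in members})


def brute_force_min_losses(tree, states):
    """Exhaustive search over all single-gain placements: for each candidate
    gain branch covering every present leaf, try loss-branch subsets of
    growing size until the observed pattern is reproduced."""
    present = {t for t, s in states.items() if s == "present"}
    nodes = list(tree.preorder_node_iter())
    leafsets = {
        id(nd): frozenset(l.taxon.label for l in nd.leaf_iter())
        for nd in nodes
    }
    best = None
    for gain in nodes:
        gl = leafsets[id(gain)]
        if not present <= gl:
            continue
        inside = [nd for nd in gain.preorder_iter() if nd is not gain]
        inside.append(gain)  # a loss on the gain branch itself is pointless
        candidates = [nd for nd in gain.preorder_iter()]
        for k in range(0, len(candidates) + 1):
            if best is not None and k >= best:
                break
            done = False
            for combo in combinations(candidates, k):
                lost = set()
                for nd in combo:
                    lost |= leafsets[id(nd)]
                carriers = gl - lost
                ok = all(
                    (t in carriers) == (states[t] == "present")
                    for t in gl if states[t] != "inapplicable"
                ) and all(
                    states[t] != "present" for t in set(states) - gl
                )
                if ok:
                    best = k if best is None else min(best, k)
                    done = True
                    break
            if done:
                break
    return best


def random_states(tree, rng):
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    while True:
        states = {
            t: rng.choice(["present", "absent", "inapplicable"],
                          p=[0.45, 0.45, 0.1])
            for t in leaves
        }
        if any(s == "present" for s in states.values()):
            return states


class TestSharingMatrix:
    def test_published_fixture_counts(self, fixture_groups):
        sm = sharing_matrix(fixture_groups, ["Maen", "Egra", "Evir", "Egym"])
        assert sm.entry("Maen", "Egra") == 40
        assert sm.entry("Maen", "Maen") == 53
        four_way = sum(
            1 for g in fixture_groups
            if {"Maen", "Egra", "Evir", "Egym"} <= g.species
        )
        assert four_way == 1

    def test_symmetry_and_diagonal_totals(self, fixture_groups):
        sm = sharing_matrix(fixture_groups,
                            ["Maen", "Egra", "Elon", "Evir", "Egym"])
        assert np.array_equal(sm.counts, sm.counts.T)
        for i, s in enumerate(sm.species):
            total = sum(1 for g in fixture_groups if s in g.species)
            assert sm.counts[i, i] == total
            assert all(sm.counts[i, j] <= total for j in range(len(sm.species)))

    def test_twintron_submatrix(self, fixture_groups):
        sm = sharing_matrix(fixture_groups, ["Maen", "Egra"])
        assert sm.entry("Maen", "Egra", twintrons=True) == 12

    def test_single_species_matrix(self):
        sm = sharing_matrix([group("psbC", ["Maen"])], ["Maen"])
        assert sm.counts.shape == (1, 1) and sm.counts[0, 0] == 1

    def test_siteless_species_warns_zero_row(self):
        with pytest.warns(UserWarning, match="no site group"):
            sm = sharing_matrix([group("psbC", ["Maen"])], ["Maen", "Ppar"])
        assert sm.entry("Ppar", "Ppar") == 0

    def test_added_empty_taxon_changes_no_entries(self, fixture_groups):
        import warnings

        a = sharing_matrix(fixture_groups, ["Maen", "Egra"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = sharing_matrix(fixture_groups, ["Maen", "Egra", "Zzz"])
        assert np.array_equal(a.counts, b.counts[:2, :2])


class TestDollo:
    def test_four_way_site_gains_at_photosynthetic_ancestor(self):
        tree = load_tree(TREE)
        g = group("psbC", ["Maen", "Egra", "Evir", "Egym"])
        gmap = dollo_map([g], tree)
        assert gmap.sites[0].gain_clade == frozenset(
            ["Egra", "Elon", "Maen", "Evir", "Egym"])
        # Elon lacks psbC entirely: inapplicable, so no loss is charged
        gmap2 = dollo_map([g], tree, inapplicable={"Elon": {"psbC"}})
        assert gmap2.sites[0].n_losses == 0
        # without masking, Elon's absence costs one loss
        assert gmap.sites[0].n_losses == 1

    def test_masked_taxon_constrains_nothing(self):
        tree = load_tree(TREE)
        g = group("rps3", ["Egra", "Maen"])
        gmap = dollo_map([g], tree, inapplicable={"Elon": {"rps3"}})
        (h,) = gmap.sites
        assert h.gain_clade == frozenset(["Egra", "Elon", "Maen"])
        assert h.n_losses == 0

    def test_root_gain_zero_losses_when_universal(self):
        tree = load_tree(TREE)
        g = group("tufA", ["Egra", "Elon", "Maen", "Evir", "Egym"])
        (h,) = dollo_map([g], tree).sites
        assert h.n_losses == 0

    def test_loss_counts_match_brute_force(self, rng):
        trees = [
            TREE,
            "(((A,B)x,(C,D)y)z,(E,F)w)root;",
            "((A,(B,(C,(D,E)p)q)r)s,F)root;",
            "((A,B)x,C)root;",
        ]
        for _ in range(500):
            tree = load_tree(trees[int(rng.integers(len(trees)))])
            states = random_states(tree, rng)
            gain, losses = _dollo_one(tree, states)
            assert len(losses) == brute_force_min_losses(tree, states)

    def test_unrooted_tree_rejected(self):
        with pytest.raises(ValueError, match="rooted"):
            load_tree("(A,B,C);")

    def test_species_outside_tree_rejected(self):
        tree = load_tree(TREE)
        with pytest.raises(ValueError, match="not in tree"):
            dollo_map([group("x", ["Maen", "Qqq"])], tree)

    def test_fitch_never_exceeds_dollo_changes(self, rng):
        tree = load_tree(TREE)
        for _ in range(50):
            states = random_states(tree, rng)
            _, losses = _dollo_one(tree, states)
            assert fitch_length(tree, states) <= 1 + len(losses)
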