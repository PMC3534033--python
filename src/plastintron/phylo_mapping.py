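"""Pairwise sharing matrix and Dollo-parsimony gain/loss mapping.

Cognate insertion-site homology implies a unique origin, so each site is
mapped under Dollo parsimony: exactly one gain (on the branch above the
most recent common ancestor of the taxa carrying the site) and as few
subsequent losses as explain the absences. Taxa that have lost the host
gene are *inapplicable* — they constrain nothing. A Fitch-style
unconstrained parsimony count is available for sensitivity checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .site_mapping import SiteGroup

__all__ = [
    "SharingMatrix",
    "SiteHistory",
    "GainLossMap",
    "load_tree",
    "sharing_matrix",
    "dollo_map",
    "fitch_length",
    "ascii_cladogram",
]

PRESENT, ABSENT, INAPPLICABLE = "present", "absent", "inapplicable"


@dataclass
class SharingMatrix:
    species: list[str]
    counts: np.ndarray  # symmetric; diagonal = per-species totals
    twintron_counts: np.ndarray  # same layout, twintron-flagged groups only

    def to_frame(self, twintrons: bool = False) -> pd.DataFrame:
        m = self.twintron_counts if twintrons else self.counts
        return pd.DataFrame(m, index=self.species, columns=self.species)

    def entry(self, a: str, b: str, twintrons: bool = False) -> int:
        m = self.twintron_counts if twintrons else self.counts
        return int(m[self.species.index(a), self.species.index(b)])


@dataclass
class SiteHistory:
    site_key: str
    gain_clade: frozenset[str]  # leaves under the gain branch
    loss_clades: tuple[frozenset[str], ...]
    states: dict  # taxon -> present/absent/inapplicable

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)


@dataclass
class GainLossMap:
    tree: dendropy.Tree
    sites: list[SiteHistory] = field(default_factory=list)

    def branch_gain_counts(self) -> dict[frozenset, int]:
        out: dict[frozenset, int] = {}
        for s in self.sites:
            out[s.gain_clade] = out.get(s.gain_clade, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "site": s.site_key,
                    "gain_branch": "|".join(sorted(s.gain_clade)),
                    "n_losses": s.n_losses,
                    "loss_branches": ";".join(
                        "|".join(sorted(c)) for c in s.loss_clades
                    ),
                }
            )
        return pd.DataFrame(rows)


def load_tree(source: str, from_path: bool = False) -> dendropy.Tree:
    """Load a rooted newick tree."""
    kwargs = {"path": source} if from_path else {"data": source}
    tree = dendropy.Tree.get(schema="newick", **kwargs)
    tree.is_rooted = True
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError("tree must be rooted (bifurcating at the root)")
    return tree


def _leaf_names(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def sharing_matrix(groups: Sequence[SiteGroup],
                   species: Sequence[str]) -> SharingMatrix:
    """Pairwise shared-site counts; diagonal holds per-species totals.

    The parallel twintron matrix counts only twintron-flagged groups
    (the bracketed counts of the published figure).
    """
    species = list(species)
    idx = {s: i for i, s in enumerate(species)}
    n = len(species)
    counts = np.zeros((n, n), dtype=int)
    twins = np.zeros((n, n), dtype=int)
    for g in groups:
        tags = [t for t in g.species if t in idx]
        for a in tags:
            counts[idx[a], idx[a]] += 1
            if g.twintron:
                twins[idx[a], idx[a]] += 1
        for i, a in enumerate(tags):
            for b in tags[i + 1:]:
                counts[idx[a], idx[b]] += 1
                counts[idx[b], idx[a]] += 1
                if g.twintron:
                    twins[idx[a], idx[b]] += 1
                    twins[idx[b], idx[a]] += 1
    for s in species:
        if counts[idx[s], idx[s]] == 0:
            import warnings

            warnings.warn(f"species {s} occurs in no site group", stacklevel=2)
    return SharingMatrix(species=species, counts=counts, twintron_counts=twins)


def _states_for_group(group: SiteGroup, taxa: Iterable[str],
                      inapplicable: Mapping[str, set] | None) -> dict:
    states = {}
    for t in taxa:
        if t in group.species:
            states[t] = PRESENT
        elif inapplicable and group.gene in inapplicable.get(t, set()):
            states[t] = INAPPLICABLE
        else:
            states[t] = ABSENT
    return states


def _dollo_one(tree: dendropy.Tree, states: Mapping[str, str]) -> tuple:
    """Gain clade and minimal loss clades for one presence pattern."""
    present = {t for t, s in states.items() if s == PRESENT}
    if not present:
        raise ValueError("site present in no taxon")
    mrca = tree.mrca(taxon_labels=sorted(present))
    losses: list[frozenset[str]] = []

    def walk(node) -> None:
        # place a loss at the root of each maximal subtree under the gain
        # clade containing no present taxon but at least one absent one
        leaves = _leaf_names(node)
        if leaves & present:
            for ch in node.child_nodes():
                walk(ch)
        elif any(states[t] == ABSENT for t in leaves):
            losses.append(leaves)
        # all-inapplicable subtree: nothing to explain

    walk(mrca)
    return _leaf_names(mrca), tuple(losses)


def dollo_map(groups: Sequence[SiteGroup], tree: dendropy.Tree,
              inapplicable: Optional[Mapping[str, set]] = None,
              site_keys: Optional[Sequence[str]] = None) -> GainLossMap:
    """Dollo reconstruction for every site group.

    ``inapplicable`` maps a taxon to the set of gene names it has lost;
    such taxa are masked out of the reconstruction for those genes. Groups
    whose members all fall outside the tree are skipped.
    """
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    out = GainLossMap(tree=tree)
    for k, g in enumerate(groups):
        if not (g.species & set(taxa)):
            continue
        states = _states_for_group(g, taxa, inapplicable)
        missing = g.species - set(taxa)
        if missing:
            raise ValueError(f"species {sorted(missing)} not in tree")
        gain, losses = _dollo_one(tree, states)
        key = site_keys[k] if site_keys else (
            g.members[0].site_id if g.members else f"group{k}"
        )
        out.sites.append(
            SiteHistory(site_key=key, gain_clade=gain,
                        loss_clades=losses, states=states)
        )
    return out


def fitch_length(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    """Unordered (Fitch) parsimony length of a binary presence/absence
    character; inapplicable taxa contribute the full state set."""

    def post(node) -> tuple[set, int]:
        if node.is_leaf():
            s = states[node.taxon.label]
            if s == INAPPLICABLE:
                return {PRESENT, ABSENT}, 0
            return {s}, 0
        sets, cost = [], 0
        for ch in node.child_nodes():
            cs, cc = post(ch)
            sets.append(cs)
            cost += cc
        inter = set.intersection(*sets)
        if inter:
            return inter, cost
        return set.union(*sets), cost + len(sets) - 1

    _, cost = post(tree.seed_node)
    return cost


def ascii_cladogram(gmap: GainLossMap) -> str:
    """Cladogram with per-branch gain counts, in the style of the published
    phylogenetic mapping figure."""
    counts = gmap.branch_gain_counts()
    tree = gmap.tree

    def label(node) -> str:
        leaves = _leaf_names(node)
        n = counts.get(leaves, 0)
        base = node.taxon.label if node.is_leaf() else ""
        return f"{base}[+{n}]" if n else base

    lines: list[str] = []

    def draw(node, prefix: str, is_last: bool) -> None:
        connector = "`-- " if is_last else "|-- "
        lines.append(prefix + connector + label(node))
        children = node.child_nodes()
        ext = "    " if is_last else "|   "
        for i, ch in enumerate(children):
            draw(ch, prefix + ext, i == len(children) - 1)

    lines.append(label(tree.seed_node) or "root")
    kids = tree.seed_node.child_nodes()
    for i, ch in enumerate(kids):
        draw(ch, "", i == len(kids) - 1)
    return "\n".join(lines)
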