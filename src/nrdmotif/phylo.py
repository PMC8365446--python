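"""Mapping discrete specificity states onto a phylogeny.

Implements the small-parsimony machinery behind single-origin claims:
Fitch change counting (with the multifurcating union/intersection
extension) and an unrooted monophyly test via edge bipartitions.  Tips
whose state is UNKNOWN are treated as missing data — pruned before
counting — not as a third character state.

Trees are ``dendropy.Tree`` objects; :func:`parse_newick` and
:func:`write_newick` convert to and from Newick text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "StateTree",
    "parse_newick",
    "write_newick",
    "fitch_count",
    "is_monophyletic",
    "MonophylyResult",
    "annotate_tree",
    "state_report",
]

DEFAULT_IGNORE = frozenset({"UNKNOWN"})


@dataclass(frozen=True)
class StateTree:
    """A phylogeny together with a tip → state map."""

    tree: dendropy.Tree
    tip_states: dict

    def __post_init__(self):
        labels = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        missing = set(self.tip_states) - labels
        if missing:
            raise ValueError(f"states given for tips absent from the tree: "
                             f"{sorted(missing)[:5]}")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse Newick text into a tree, rejecting duplicate tip labels.

    Polytomies are allowed; labels and branch lengths are preserved.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen, dups = set(), set()
    for lab in labels:
        (dups if lab in seen else seen).add(lab)
    if dups:
        raise ValueError(f"duplicate tip labels: {sorted(dups)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def _pruned_state_tree(tree: dendropy.Tree, tip_states: Mapping,
                       ignore_states: Iterable) -> tuple[dendropy.Tree, dict]:
    ignore = set(ignore_states)
    states = {t: s for t, s in tip_states.items() if s not in ignore}
    leaves = list(tree.leaf_node_iter())
    keep = [leaf.taxon for leaf in leaves if leaf.taxon.label in states]
    if len(keep) < 1:
        raise ValueError("no tips remain after dropping ignored states")
    if len(keep) == len(leaves):
        return tree, states  # nothing to prune; tree is never mutated
    pruned = tree.extract_tree_with_taxa(taxa=keep)
    return pruned, states


def fitch_count(st: StateTree,
                ignore_states: Iterable = DEFAULT_IGNORE) -> int:
    """Minimum number of state changes on the tree (Fitch parsimony).

    Tips with ignored states are pruned first.  Polytomies are handled by
    the multifurcating extension: at a node whose children carry state
    sets S1..Sk, the states attaining the maximum membership count m are
    kept and ``k - m`` changes are added — which reduces to the classic
    union/intersection rule on bifurcations.  The count is invariant to
    the (arbitrary) rooting.
    """
    pruned, states = _pruned_state_tree(st.tree, st.tip_states, ignore_states)
    tips_with_state = [l for l in pruned.leaf_node_iter()
                       if l.taxon.label in states]
    if len(tips_with_state) < 2:
        if not tips_with_state:
            raise ValueError("all tips ignored; nothing to count")
        return 0

    changes = 0
    node_sets: dict = {}
    for node in pruned.postorder_node_iter():
        if node.is_leaf():
            node_sets[node] = frozenset({states[node.taxon.label]})
            continue
        child_sets = [node_sets[c] for c in node.child_nodes()]
        if len(child_sets) == 1:
            node_sets[node] = child_sets[0]
            continue
        counts: dict = {}
        for cs in child_sets:
            for s in cs:
                counts[s] = counts.get(s, 0) + 1
        m = max(counts.values())
        node_sets[node] = frozenset(s for s, c in counts.items() if c == m)
        changes += len(child_sets) - m
    return changes


@dataclass(frozen=True)
class MonophylyResult:
    monophyletic: bool
    state: str
    state_tips: frozenset
    #: smallest edge-bipartition side containing every tip of the state
    smallest_containing_clade: frozenset


def is_monophyletic(st: StateTree, state,
                    ignore_states: Iterable = DEFAULT_IGNORE
                    ) -> MonophylyResult:
    """Test whether the tips carrying ``state`` form one unrooted clade.

    Monophyly is defined on the tree pruned to informative tips: the
    state's tips are monophyletic iff some edge bipartition separates
    exactly those tips from the rest.  The smallest bipartition side
    containing all of the state's tips is returned as witness (it equals
    the state tip set exactly when monophyletic).
    """
    pruned, states = _pruned_state_tree(st.tree, st.tip_states, ignore_states)
    target = frozenset(t for t, s in states.items() if s == state)
    if not target:
        raise ValueError(f"state {state!r} absent from informative tips")
    all_tips = frozenset(l.taxon.label for l in pruned.leaf_node_iter())

    best = all_tips
    for node in pruned.preorder_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        for side in (clade, all_tips - clade):
            if target <= side and len(side) < len(best):
                best = side
    return MonophylyResult(monophyletic=(best == target), state=str(state),
                           state_tips=target, smallest_containing_clade=best)


def annotate_tree(st: StateTree) -> dendropy.Tree:
    """Return a copy of the tree with each tip's state as a comment."""
    tree = st.tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        s = st.tip_states.get(leaf.taxon.label)
        if s is not None:
            leaf.annotations.add_new("state", str(s))
    return tree


def state_report(st: StateTree,
                 ignore_states: Iterable = DEFAULT_IGNORE) -> dict:
    """JSON-ready summary: change count and per-state monophyly."""
    pruned_states = {t: s for t, s in st.tip_states.items()
                     if s not in set(ignore_states)}
    observed = sorted(set(pruned_states.values()))
    changes = fitch_count(st, ignore_states)
    mono = {}
    for s in observed:
        r = is_monophyletic(st, s, ignore_states)
        mono[s] = {"monophyletic": r.monophyletic,
                   "witness_clade": sorted(r.smallest_containing_clade)}
    return {"changes": changes, "states": observed, "monophyly": mono}
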