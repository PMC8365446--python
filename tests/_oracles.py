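"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: alignment scores
come from exhaustive enumeration of every gapped alignment, parsimony
scores from exhaustive enumeration of every internal-node labeling.
"""

from __future__ import annotations

import itertools
import math

import dendropy


def brute_force_align_score(a: str, b: str, score_fn,
                            gap_open: float = 11.0,
                            gap_extend: float = 1.0) -> float:
    """Maximum score over every global alignment of a and b.

    A gap run of length L costs ``gap_open + (L-1)*gap_extend``; end
    gaps are penalized.  ``score_fn(x, y)`` scores a residue pair.
    Exponential enumeration — only for very short sequences.
    """
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if prev == "D" else gap_open),
                "D")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if prev == "I" else gap_open),
                "I")

    rec(0, 0, 0.0, None)
    return best


def enumeration_parsimony(tree: dendropy.Tree, states: dict) -> int:
    """Minimum change count by enumerating all internal labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    alphabet = sorted(set(states.values()))

    def node_state(node, labeling):
        if node.is_leaf():
            return states[node.taxon.label]
        return labeling[id(node)]

    best = math.inf
    for combo in itertools.product(alphabet, repeat=len(internals)):
        labeling = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        for node in internals:
            s_par = labeling[id(node)]
            for child in node.child_nodes():
                if node_state(child, labeling) != s_par:
                    cost += 1
        if cost < best:
            best = cost
    return int(best)


def all_rooted_binary_topologies(labels: list[str]):
    """Yield every rooted binary labeled topology as a Newick string.

    There are (2n-3)!! of them for n labels.
    """
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # left subtree always contains the first label: canonical, no dupes
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            left_labels = [first, *combo]
            right_labels = [l for l in rest if l not in combo]
            if not right_labels:
                continue
            for left in all_rooted_binary_topologies(left_labels):
                for right in all_rooted_binary_topologies(right_labels):
                    yield f"({left},{right})"


def random_binary_newick(labels: list[str], rng) -> str:
    """Random rooted binary topology (uniform-ish via random splits)."""
    labels = list(labels)
    rng.shuffle(labels)

    def build(ls):
        if len(ls) == 1:
            return ls[0]
        cut = int(rng.integers(1, len(ls)))
        return f"({build(ls[:cut])},{build(ls[cut:])})"

    return build(labels) + ";"
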