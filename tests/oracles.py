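"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and scipy's test functions)
they are used to check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def fisher_two_tailed_enumeration(table) -> float:
    """Two-tailed Fisher exact p by full enumeration with exact rationals.

    Enumerates every 2x2 table with the observed margins, computes exact
    hypergeometric point probabilities, and sums those not exceeding the
    observed table's probability (with the same 1+1e-7 relative gate scipy
    applies at ties).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x: int) -> Fraction:
        # P(X = x) for X ~ Hypergeom(n, r1, c1); x = top-left cell
        return Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    observed = point_prob(a)
    gate = observed * Fraction(10**7 + 1, 10**7)
    total = sum(point_prob(x) for x in range(lo, hi + 1) if point_prob(x) <= gate)
    return float(total)


def random_ultrametric_newick(
    rng: np.random.Generator, n_leaves: int
) -> tuple[str, list[str]]:
    """A random ultrametric tree in newick form (leaf labels L1..Ln, ages > 0)."""
    labels = [f"L{i + 1}" for i in range(n_leaves)]
    nodes = [(label, 0.0) for label in labels]  # (newick, age)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, age_j) = nodes.pop(j)
        (nwk_i, age_i) = nodes.pop(i)
        age = max(age_i, age_j) + float(rng.uniform(1.0, 5.0))
        merged = f"({nwk_i}:{age - age_i:.6f},{nwk_j}:{age - age_j:.6f})"
        nodes.append((merged, age))
    return nodes[0][0] + ";", labels


class SimpleTree:
    """Minimal parsed tree over a dendropy tree, for brute-force searches."""

    def __init__(self, dendropy_tree):
        self.nodes = list(dendropy_tree.preorder_node_iter())

    @staticmethod
    def leaves_of(node) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def dollo_min_losses_bruteforce(dendropy_tree, present: set[str]) -> int:
    """Minimum loss count over every admissible single origin.

    For each node whose clade contains all carriers, count the maximal
    carrier-free subtrees beneath it; return the minimum over origins.
    """
    best = None
    for node in dendropy_tree.preorder_node_iter():
        clade = SimpleTree.leaves_of(node)
        if not present <= clade:
            continue

        def count_losses(n) -> int:
            total = 0
            for child in n.child_nodes():
                if SimpleTree.leaves_of(child) & present:
                    total += count_losses(child)
                else:
                    total += 1
            return total

        losses = count_losses(node)
        if best is None or losses < best:
            best = losses
    assert best is not None
    return best
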