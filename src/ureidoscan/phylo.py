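"""Neighbor-joining trees and unrooted monophyly tests.

Trees are scikit-bio ``TreeNode`` objects; the NJ root is a trifurcation
and carries no meaning (the tree is unrooted). Monophyly of a leaf subset
is defined over bipartitions: the subset is monophyletic iff some edge
separates exactly that subset from the remaining leaves.
"""

from __future__ import annotations

import logging
from typing import Iterable

from skbio import DistanceMatrix, TreeNode

log = logging.getLogger(__name__)


def _pair_key(ka: tuple[str, ...], kb: tuple[str, ...]) -> tuple:
    """Deterministic ordering key for a candidate join.

    Each active node is keyed by the lexicographically smallest leaf label
    beneath it; a candidate pair is keyed by its sorted node keys.
    """
    return tuple(sorted((ka[0], kb[0])))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou–Nei) with deterministic tie handling.

    At each step the pair minimizing ``Q(i, j) = (n - 2) d(i, j) - r_i -
    r_j`` is joined; exact Q ties are broken by the smallest (i, j) id pair
    (ids of internal nodes are the smallest leaf label beneath them).
    Negative branch lengths are clamped to 0 and logged. Requires n >= 3.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"neighbor joining requires at least 3 taxa, got {n}")

    # active nodes keyed by smallest-leaf label; distances on frozen pairs
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    d: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((ids[i], ids[j]))] = float(dm[ids[i], ids[j]])

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    def clamp(x: float, what: str) -> float:
        if x < 0:
            log.info("negative NJ branch length %.6g at %s clamped to 0", x, what)
            return 0.0
        return x

    active = sorted(nodes)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = clamp(dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2)), f"join({a},{b})")
        lb = clamp(dab - la, f"join({a},{b})")
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        new_key = min(a, b)
        parent = TreeNode(children=[na, nb])
        nodes[new_key] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = (dist(a, c) + dist(b, c) - dab) / 2.0
            d[frozenset((new_key, c))] = duc
        active = sorted(nodes)

    # final three-node star: closed-form limb lengths
    a, b, c = active
    la = clamp((dist(a, b) + dist(a, c) - dist(b, c)) / 2.0, f"star({a})")
    lb = clamp((dist(a, b) + dist(b, c) - dist(a, c)) / 2.0, f"star({b})")
    lc = clamp((dist(a, c) + dist(b, c) - dist(a, b)) / 2.0, f"star({c})")
    for key, length in zip((a, b, c), (la, lb, lc)):
        nodes[key].length = length
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """All edge bipartitions of an unrooted tree in canonical form.

    Each split is represented by the side that does NOT contain the
    alphabetically smallest leaf, which is unique regardless of rooting.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        if 0 < len(clade) < len(leaves):
            splits.add(leaves - clade if anchor in clade else clade)
    return splits


def is_monophyletic(tree: TreeNode, leaf_subset: Iterable[str]) -> bool:
    """True iff some edge separates exactly ``leaf_subset`` from the rest."""
    subset = frozenset(leaf_subset)
    if not subset:
        raise ValueError("leaf subset must be nonempty")
    leaves = frozenset(t.name for t in tree.tips())
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if subset == leaves:
        return True
    complement = leaves - subset
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset({node.name})
        if clade == subset or clade == complement:
            return True
    return False
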