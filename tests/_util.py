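"""Independent oracles and helpers shared by the test modules.

Everything here is deliberately implemented by a different route than the
package code it checks: naive window scans, exhaustive alignment
enumeration, graph-based monophyly, random tree construction.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from ureidoscan.msa import _SYM_INDEX, blosum62_matrix
from ureidoscan.records import STANDARD_AA


def brute_force_core_scan(seq: str, relaxed: bool = False) -> list[tuple[int, bool]]:
    """Window-by-window check of the 4 fixed core positions."""
    out = []
    for i in range(len(seq) - 7):
        window = seq[i : i + 8]
        n = (
            (window[1] == "H")
            + (window[2] == "H")
            + (window[6] == "D")
            + (window[7] == "G")
        )
        if n == 4:
            out.append((i, False))
        elif relaxed and n == 3:
            out.append((i, True))
    return out


def enumerate_alignment_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Best score over ALL gapped global alignments, by exhaustive recursion.

    A gap run of length k costs gap_open + (k - 1) * gap_extend; a run is
    tracked by which sequence last consumed a gap.
    """
    S = blosum62_matrix()

    best = [-float("inf")]

    def rec(i: int, j: int, last: str | None, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = S[_SYM_INDEX[a[i]], _SYM_INDEX[b[j]]]
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            cost = gap_extend if last == "X" else gap_open
            rec(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = gap_extend if last == "Y" else gap_open
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, None, 0.0)
    return best[0]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(STANDARD_AA))[rng.integers(0, 20, size=length)])


def random_binary_tree(
    rng: np.random.Generator, leaves: list[str], min_len: float = 0.1, max_len: float = 1.0
) -> TreeNode:
    """A random rooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=l) for l in leaves]
    for node in nodes:
        node.length = float(rng.uniform(min_len, max_len))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(min_len, max_len))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root


def tip_distances(tree: TreeNode):
    """Tip-to-tip path-length distances as a skbio DistanceMatrix."""
    return tree.tip_tip_distances()


def graph_monophyly(tree: TreeNode, subset: set[str]) -> bool:
    """Monophyly oracle via explicit edge-removal on a networkx graph."""
    import networkx as nx

    G = nx.Graph()
    tips = {}
    for node in tree.traverse(include_self=True):
        G.add_node(id(node))
        if node.is_tip():
            tips[id(node)] = node.name
        if node.parent is not None:
            G.add_edge(id(node), id(node.parent))
    all_tips = set(tips.values())
    for u, v in list(G.edges):
        H = G.copy()
        H.remove_edge(u, v)
        for comp in nx.connected_components(H):
            names = {tips[n] for n in comp if n in tips}
            if names == subset or names == all_tips - subset:
                return True
    return False
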