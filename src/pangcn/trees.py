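"""Distance-based phylogenetics: JC69 distances, neighbor joining,
bootstrap split supports and Newick I/O.

Trees are :class:`skbio.TreeNode` objects rooted at a trifurcation, i.e.
unrooted topologies in the usual NJ sense.  The neighbor-joining
implementation is the classical Saitou–Nei algorithm with Q-matrix pair
selection; ties in Q break by lexicographic taxon-pair order so results are
deterministic, and negative branch-length estimates are clamped to zero.
"""

from __future__ import annotations

import math
from io import StringIO
from typing import Callable

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "jc_distance",
    "jc_matrix",
    "neighbor_joining",
    "tree_splits",
    "bootstrap_support",
    "annotate_supports",
    "write_newick",
    "read_newick",
]

_GAPLIKE = set("-.NnXx?")


def jc_distance(aligned_a: str, aligned_b: str) -> float:
    """Jukes–Cantor distance between two rows of an alignment.

    Columns with a gap or ambiguous base in either row are removed pairwise;
    saturation (p >= 0.75) raises ``ValueError`` because the correction is
    undefined there.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    total = diff = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        total += 1
        if x != y:
            diff += 1
    if total == 0:
        raise ValueError("no comparable columns")
    p = diff / total
    if p >= 0.75:
        raise ValueError(f"saturated distance (p = {p:.3f} >= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """All-pairs JC69 distance matrix from an aligned sequence dict."""
    ids = sorted(alignment)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(alignment[ids[i]], alignment[ids[j]])
    return DistanceMatrix(d, ids)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ tree from a symmetric distance matrix.

    Returns a :class:`TreeNode` whose root is the final trifurcation (or the
    single internal node for 3 taxa).  Negative branch lengths are clamped
    to zero.
    """
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    d = {a: {b: float(matrix[a, b]) for b in ids} for a in ids}
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in ids}
    active = sorted(ids)
    counter = 0

    def clamp(x: float) -> float:
        return max(0.0, x)

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best_pair = None
        best_q = math.inf
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * d[a][b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair
        la_raw = 0.5 * d[a][b] + (r[a] - r[b]) / (2.0 * (n - 2))
        la = clamp(la_raw)
        lb = clamp(d[a][b] - la_raw)
        new_name = f"__internal{counter}"
        counter += 1
        parent = TreeNode(name=None)
        nodes[a].length = la
        nodes[b].length = lb
        parent.extend([nodes[a], nodes[b]])
        nodes[new_name] = parent
        d[new_name] = {}
        for c in active:
            if c in (a, b):
                continue
            dist = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_name][c] = dist
            d[c][new_name] = dist
        active = sorted([c for c in active if c not in (a, b)] + [new_name],
                        key=lambda s: (s.startswith("__"), s))

    a, b, c = active
    root = TreeNode(name=None)
    nodes[a].length = clamp(0.5 * (d[a][b] + d[a][c] - d[b][c]))
    nodes[b].length = clamp(0.5 * (d[a][b] + d[b][c] - d[a][c]))
    nodes[c].length = clamp(0.5 * (d[a][c] + d[b][c] - d[a][b]))
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


# ---------------------------------------------------------------------------
# splits and bootstrap


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree, each canonicalized as
    the side not containing the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            splits.add(frozenset(side))
    return splits


def bootstrap_support(
    resampler: Callable[[np.random.Generator], object],
    builder: Callable[[object], TreeNode],
    n: int,
    seed: int,
) -> dict[frozenset[str], float]:
    """Split frequencies (percent) over ``n`` bootstrap replicates.

    ``resampler(rng)`` draws one pseudo-replicate of the underlying data and
    ``builder`` turns it into a tree; the composition is deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 211]))
    counts: dict[frozenset[str], int] = {}
    for _ in range(n):
        tree = builder(resampler(rng))
        for split in tree_splits(tree):
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * c / n for split, c in counts.items()}


def annotate_supports(tree: TreeNode, supports: dict[frozenset[str], float]) -> TreeNode:
    """Write split supports onto the internal-node labels of ``tree``."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            node.name = f"{supports.get(frozenset(side), 0.0):.0f}"
    return tree


# ---------------------------------------------------------------------------
# Newick


def _fmt_len(x: float | None) -> str:
    return "" if x is None else f":{x:.6g}"


def _quote(name: str) -> str:
    if any(ch in name for ch in "()[]':;,= \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode, path: str | None = None) -> str:
    """Serialize a tree (supports as internal labels, 6-significant-digit
    branch lengths); writes to ``path`` when given and returns the text."""

    def rec(node: TreeNode) -> str:
        if node.is_tip():
            return f"{_quote(node.name or '')}{_fmt_len(node.length)}"
        inner = ",".join(rec(c) for c in node.children)
        label = _quote(node.name) if node.name else ""
        return f"({inner}){label}{_fmt_len(node.length)}"

    text = rec(tree) + ";\n"
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source: str) -> TreeNode:
    """Parse Newick text (or a file path) into a :class:`TreeNode`;
    malformed input raises scikit-bio's parse error, which carries the
    offending position."""
    if "(" not in source and ";" not in source:
        return TreeNode.read(source, format="newick")
    return TreeNode.read(StringIO(source), format="newick")
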