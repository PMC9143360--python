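"""Neighbor-joining trees from p-distance matrices.

Classic agglomerative neighbor joining: at each step the pair (i, j)
minimising Q(i, j) = (n - 2) d(i, j) - r_i - r_j is joined (r_i = row sum),
branch lengths follow the standard formulas, and the new node's distances
are d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2. Ties in Q break to the
lowest (row, column) index pair, so the result is deterministic given the
input order. Negative branch lengths are clamped to zero and counted.

On an additive matrix NJ is exact: leaf-to-leaf path lengths through the
tree reproduce the input distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceMatrix


class MissingDistanceError(ValueError):
    """NJ needs a fully defined matrix; impute or drop the offending taxa."""


@dataclass
class TreeNode:
    """A node in an (un)rooted tree; ``length`` is the edge to the parent."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class Tree:
    """An unrooted NJ tree (root is the final three-way join for n >= 3)."""

    root: TreeNode
    n_negative_clamped: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf patristic distances (for additivity checks).

        Returned as a square DataFrame over sorted leaf names; patristic
        sums are unbounded, unlike p-distances.
        """
        # distances from every node to all leaves below it, then combine
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def down(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            groups = []
            for c in node.children:
                sub = {k: v + (c.length or 0.0) for k, v in down(c).items()}
                groups.append(sub)
                acc.update(sub)
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for la, va in groups[a].items():
                        for lb, vb in groups[b].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = va + vb
            return acc

        down(self.root)
        return pd.DataFrame(d, index=names, columns=names)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build an unrooted NJ tree from a fully defined distance matrix."""
    n = len(dm)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if np.isnan(dm.values).any():
        raise MissingDistanceError(
            "distance matrix has undefined entries; remove those taxa or "
            "impute before tree building"
        )
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(name=l) for l in dm.labels]
    clamped = 0

    def attach(child: TreeNode, length: float) -> None:
        nonlocal clamped
        if length < 0.0:
            clamped += 1
            length = 0.0
        child.length = float(length)

    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            attach(node, half)
            root.children.append(node)
        return Tree(root, clamped)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) on ties: argmin scans row-major
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = d[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        attach(nodes[i], li)
        attach(nodes[j], lj)
        parent.children = [nodes[i], nodes[j]]
        # new node reuses slot i
        for k in active:
            if k in (i, j):
                continue
            nd = (d[i, k] + d[j, k] - dij) / 2.0
            d[i, k] = d[k, i] = nd
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # final three-way join with the closed three-point formulas
    x, y, z = active
    dxy, dxz, dyz = d[x, y], d[x, z], d[y, z]
    root = TreeNode()
    attach(nodes[x], (dxy + dxz - dyz) / 2.0)
    attach(nodes[y], (dxy + dyz - dxz) / 2.0)
    attach(nodes[z], (dxz + dyz - dxy) / 2.0)
    root.children = [nodes[x], nodes[y], nodes[z]]
    return Tree(root, clamped)


_NEWICK_RESERVED = set("():;,[] '\t\n")


def _format_label(name: str) -> str:
    if set(name) & _NEWICK_RESERVED:
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Tree, decimals: int = 6) -> str:
    """Serialise a tree as a Newick string with branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = _format_label(node.name or "")
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                body += _format_label(node.name)
        if node.length is not None:
            body += f":{node.length:.{decimals}f}"
        return body

    return render(tree.root) + ";"


def write_newick(tree: Tree, path: str | Path, decimals: int = 6) -> None:
    Path(path).write_text(to_newick(tree, decimals) + "\n")


def root_on(newick: str, outgroup: str) -> str:
    """Re-root a Newick tree on an outgroup label (display-level only)."""
    import io

    from skbio import TreeNode as SkbioNode

    t = SkbioNode.read(io.StringIO(newick))
    t = t.root_at(t.find(outgroup), above=True, reset=True)
    out = io.StringIO()
    t.write(out)
    return out.getvalue().strip()
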