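"""Distance trees: p-distance, neighbor joining, column bootstrap.

Whole-plastome alignments of congeneric species are gap-sparse and
highly similar, so uncorrected p-distances with canonical Saitou–Nei
neighbor joining are sufficient to test the claim that matters for
super-barcoding: every species forms an exclusive, strongly supported
clade.  Support values come from a column-resampling bootstrap of the
alignment, counting how often each original bipartition recurs.

Numerical conventions: joins minimize the Q-criterion with ties broken
by the lexicographic pair of cluster names (a cluster is named after its
smallest leaf); negative branch lengths are clamped to zero with the
deficit transferred to the sister edge, so path lengths are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, _ACGT_CODES


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in [0, 1]."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("p-distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


class Node:
    """A tree node; leaves carry a name, internal nodes optional support."""

    __slots__ = ("name", "children", "support")

    def __init__(
        self,
        name: str | None = None,
        children: list[tuple["Node", float]] | None = None,
        support: float | None = None,
    ):
        self.name = name
        self.children = children or []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def _quote(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass
class Tree:
    """An unrooted tree rendered with a trifurcating root."""

    root: Node
    ids: tuple[str, ...] = field(default_factory=tuple)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        def render(node: Node, length: float | None) -> str:
            if node.is_leaf:
                body = _quote(node.name)
            else:
                inner = ",".join(render(c, l) for c, l in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.10g}"

        return render(self.root, None) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def _anchor(self) -> str:
        return min(self.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaves())
        anchor = self._anchor()
        splits: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset((node.name,))
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def branch_lengths(self) -> dict[frozenset[str] | str, float]:
        """Leaf-name -> pendant length; canonical split -> internal length."""
        all_leaves = frozenset(self.leaves())
        anchor = self._anchor()
        out: dict[frozenset[str] | str, float] = {}

        def walk(node: Node) -> frozenset[str]:
            below_all = []
            for child, length in node.children:
                below = walk(child)
                if child.is_leaf:
                    out[child.name] = length
                elif 1 < len(below) < len(all_leaves) - 1:
                    side = below if anchor not in below else all_leaves - below
                    out[side] = length
                below_all.append(below)
            if node.is_leaf:
                return frozenset((node.name,))
            return frozenset().union(*below_all)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for child, _ in node.children:
                    walk(child)

        walk(self.root)
        return out


def is_monophyletic(tree: Tree, leaf_names: Sequence[str]) -> bool:
    """True when the leaf set forms an exclusive group on the unrooted tree."""
    group = frozenset(leaf_names)
    all_leaves = frozenset(tree.leaves())
    if not group <= all_leaves:
        raise ValueError("leaf names not in tree")
    if len(group) in (1, len(all_leaves) - 1, len(all_leaves)):
        return True
    anchor = min(all_leaves)
    side = group if anchor not in group else all_leaves - group
    return side in tree.bipartitions()


# ---------------------------------------------------------------------------
# p-distance


def _pdist_pair(
    ri: np.ndarray, rj: np.ndarray, comp: np.ndarray, pair: tuple[str, str]
) -> float:
    n_comp = int(np.count_nonzero(comp))
    if n_comp == 0:
        raise ValueError(f"no comparable columns for pair {pair[0]!r} vs {pair[1]!r}")
    return float(np.count_nonzero((ri != rj) & comp)) / n_comp


def _pdist_from_matrix(
    M: np.ndarray, ids: Sequence[str], deletion: str
) -> np.ndarray:
    valid = np.isin(M, _ACGT_CODES)
    n = len(ids)
    d = np.zeros((n, n))
    complete_cols = valid.all(axis=0) if deletion == "complete" else None
    for i in range(n):
        for j in range(i + 1, n):
            comp = complete_cols if complete_cols is not None else valid[i] & valid[j]
            d[i, j] = d[j, i] = _pdist_pair(M[i], M[j], comp, (ids[i], ids[j]))
    return d


def p_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected pairwise p-distances.

    Gaps and non-ACGT symbols are excluded per pair (``pairwise``
    deletion, default) or globally (``complete``).  A pair with zero
    comparable columns raises an error naming the pair.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    if len(aln) < 3:
        raise ValueError("need at least 3 sequences for tree building")
    d = _pdist_from_matrix(aln.matrix, aln.ids, deletion)
    return DistanceMatrix(tuple(aln.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical Saitou–Nei neighbor joining (exact on additive inputs)."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    names: list[str] = list(dm.ids)  # cluster name = smallest leaf inside
    D = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best: tuple | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((names[i], names[j])))
                cand = (q, pair, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, preserving the path length through the join
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        joined = Node(children=[(nodes[i], li), (nodes[j], lj)])
        keep = [x for x in range(m) if x not in (i, j)]
        new_row = 0.5 * (D[i, keep] + D[j, keep] - dij)
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = new_row
        D2[: m - 2, m - 2] = new_row
        D2[m - 2, m - 2] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [joined]
        names = [names[x] for x in keep] + [min(names[i], names[j])]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max((d01 + d02 - d12) / 2, 0.0)
    l1 = max((d01 + d12 - d02) / 2, 0.0)
    l2 = max((d02 + d12 - d01) / 2, 0.0)
    root = Node(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return Tree(root, dm.ids)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> Tree:
    """NJ tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``replicates``
    times; support for each original bipartition is the percentage of
    replicate trees containing it.  Seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(p_distance_matrix(aln, deletion))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree.bipartitions()}

    rng = np.random.default_rng(seed)
    M = aln.matrix
    ids = aln.ids
    L = aln.length
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep_d = _pdist_from_matrix(M[:, cols], ids, deletion)
        rep_tree = nj_tree(DistanceMatrix(tuple(ids), rep_d))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    for node in tree.internal_nodes():
        below = frozenset(node.leaves())
        side = below if anchor not in below else all_leaves - below
        if side in counts:
            node.support = 100.0 * counts[side] / replicates
    return tree


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().rename_axis("sample").to_csv(path, sep="\t")
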