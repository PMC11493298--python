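"""Rooted, branch-length-annotated trees and shared-ancestry bookkeeping.

Trees here serve a single purpose: bookkeeping of shared evolutionary time.
The central quantity is the shared-path matrix, whose (i, j) entry is the
total branch length ancestral to *both* tips i and j (the root-to-MRCA path),
and whose diagonal holds root-to-tip path lengths.  Under a Brownian-motion
trait model this matrix, scaled by the diffusion rate, is the trait
variance-covariance among tips.

Dialect notes: branch lengths are required on every edge except the root
edge; internal node labels are ignored on read and omitted on write; labels
are unquoted.  A tree may carry a stem (root-edge) length — e.g., a Yule
process started from a single lineage at the origin — which is shared by all
tips and is included in shared-path matrices and in the total tree length.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import dendropy

__all__ = [
    "Tree",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "read_newick",
    "read_newick_list",
    "write_newick_list",
    "build_felsenstein_tree",
    "build_star_tree",
    "simulate_pure_birth",
    "shared_path_matrix",
    "prune_to_tips",
    "root_clades",
]

_ULTRAMETRIC_RTOL = 1e-9


class NewickParseError(ValueError):
    """Malformed or dialect-violating Newick input."""


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


class Tree:
    """A rooted tree stored as parallel parent/length/label arrays.

    Nodes are integer ids ``0..n_nodes-1``; the root is node 0 and has
    ``parent[0] == -1``.  ``length[i]`` is the branch length of the edge
    above node ``i`` (``root_length`` for the root's stem edge, 0.0 if the
    tree has no stem).  Tip labels are unique non-empty strings.
    """

    __slots__ = ("parent", "length", "labels", "children", "root_length")

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        labels: Sequence[str | None],
        root_length: float = 0.0,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        self.root_length = float(root_length)
        self._validate()
        self.children: list[list[int]] = [[] for _ in range(len(self.parent))]
        for node in range(1, len(self.parent)):
            self.children[self.parent[node]].append(node)

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0 or self.parent[0] != -1:
            raise TreeError("node 0 must be the root (parent -1)")
        if np.any(self.parent[1:] < 0) or np.any(self.parent[1:] >= n):
            raise TreeError("every non-root node needs exactly one valid parent")
        # parents must precede children: guarantees acyclicity
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be ordered with parents before children")
        if np.any(self.length[1:] < 0) or self.root_length < 0:
            raise TreeError("negative branch length")
        tips = [self.labels[i] for i in range(n) if self.labels[i]]
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in lexicographic order (the matrix ordering convention)."""
        return sorted(self.labels[i] for i in self.tip_ids)

    def depths(self) -> np.ndarray:
        """Root-to-node path length per node (stem excluded)."""
        d = np.zeros(self.n_nodes)
        for node in range(1, self.n_nodes):
            d[node] = d[self.parent[node]] + self.length[node]
        return d

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths, stem included."""
        return float(self.length[1:].sum() + self.root_length)

    @property
    def is_ultrametric(self) -> bool:
        d = self.depths()[self.tip_ids]
        span = d.max() - d.min()
        return bool(span <= _ULTRAMETRIC_RTOL * max(d.max(), 1.0))

    def without_stem(self) -> "Tree":
        """Copy of the tree with the stem (root-edge) length removed.

        Useful when a simulated tree should mimic an inferred phylogeny,
        which carries no branch above its root."""
        return Tree(self.parent, self.length, self.labels, root_length=0.0)

    # -- Newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if self.is_tip(node):
                body = self.labels[node]
            else:
                body = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == 0:
                if self.root_length > 0:
                    return f"{body}:{float(self.root_length)!r}"
                return body
            return f"{body}:{float(self.length[node])!r}"

        return render(0) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree(n_tips={self.n_tips}, total_length={self.total_length:.4g})"


def _from_dendropy(dtree: "dendropy.Tree") -> Tree:
    seed = dtree.seed_node
    parent: list[int] = []
    length: list[float] = []
    labels: list[str | None] = []
    ids: dict = {}
    for node in dtree.preorder_node_iter():
        ids[node] = len(parent)
        if node is seed:
            parent.append(-1)
            length.append(0.0)
        else:
            if node.edge.length is None:
                tok = node.taxon.label if node.taxon else "(internal node)"
                raise NewickParseError(f"missing branch length on edge above {tok!r}")
            parent.append(ids[node.parent_node])
            length.append(float(node.edge.length))
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickParseError("tip without a label")
            labels.append(node.taxon.label)
        else:
            labels.append(None)
    root_length = float(seed.edge.length) if seed.edge.length else 0.0
    try:
        return Tree(parent, length, labels, root_length=root_length)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick statement (";"-terminated).

    Raises :class:`NewickParseError` naming the offending token on malformed
    parentheses, duplicate tip labels, or a missing branch length.
    """
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_list(path) -> list[Tree]:
    """Read a newline-delimited multi-tree Newick file (gene-tree collections)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_list(trees: Iterable[Tree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")


# -- deterministic constructions ------------------------------------------


def build_star_tree(labels: Sequence[str], tip_length: float) -> Tree:
    if tip_length < 0:
        raise TreeError("tip_length must be >= 0")
    n = len(labels)
    parent = [-1] + [0] * n
    length = [0.0] + [float(tip_length)] * n
    return Tree(parent, length, [None] + list(labels))


def build_felsenstein_tree(
    n_per_clade: int, tip_length: float, internal_length: float
) -> Tree:
    """Two star clades of ``n_per_clade`` tips joined at the root.

    This is the "worst case" design for confounding: the only structure is
    the split between the two clades.  Tips are labelled ``c1_1..c1_n`` and
    ``c2_1..c2_n``; each clade's stem branch has length ``internal_length``
    and every tip branch has length ``tip_length``.  With zero internal
    length the result collapses to a single ``2 n``-tip star.
    """
    if n_per_clade < 2:
        raise ValueError("n_per_clade must be >= 2")
    if tip_length < 0 or internal_length < 0:
        raise ValueError("branch lengths must be >= 0")
    parent = [-1, 0, 0]
    length = [0.0, float(internal_length), float(internal_length)]
    labels: list[str | None] = [None, None, None]
    for clade, anc in ((1, 1), (2, 2)):
        for i in range(1, n_per_clade + 1):
            parent.append(anc)
            length.append(float(tip_length))
            labels.append(f"c{clade}_{i}")
    return Tree(parent, length, labels)


def simulate_pure_birth(n_tips: int, birth_rate: float, rng: np.random.Generator) -> Tree:
    """Simulate a Yule (pure-birth) tree with ``n_tips`` extant tips.

    The process starts from a single lineage at the origin; while k lineages
    exist the wait to the next split is Exponential(k * birth_rate), and the
    splitting lineage is uniform among the k.  Simulation stops the instant
    the n-th lineage is born, so the tree depth (stem included) is the time
    of the final split and the two youngest tips have zero-length terminal
    branches.  The wait while one lineage exists becomes the stem
    (``root_length``).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    # first split ends the single-lineage (stem) phase and creates the root
    t = rng.exponential(1.0 / birth_rate)
    parent = [-1, 0, 0]
    length = [0.0, 0.0, 0.0]
    birth = {1: t, 2: t}
    active = [1, 2]
    stem = t
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        split = active.pop(int(rng.integers(k)))
        length[split] = t - birth[split]
        for _ in range(2):
            node = len(parent)
            parent.append(split)
            length.append(0.0)
            birth[node] = t
            active.append(node)
    for node in active:  # extant lineages run to the stopping time
        length[node] = t - birth[node]
    labels: list[str | None] = [None] * len(parent)
    for i, node in enumerate(sorted(active)):
        labels[node] = f"t{i + 1}"
    return Tree(parent, length, labels, root_length=stem)


# -- shared-path matrix and pruning ----------------------------------------


def shared_path_matrix(tree: Tree):
    """Shared-ancestry matrix: (i, j) = root-to-MRCA path length (+ stem).

    Diagonal entries are root-to-tip path lengths; under Brownian motion
    this matrix times the diffusion rate is the trait covariance among tips.
    Tip order is lexicographic by label.  Returns a
    :class:`~structcorr.covariance.CovarianceMatrix`.
    """
    from .covariance import CovarianceMatrix

    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depths = tree.depths()
    mat = np.full((n, n), tree.root_length, dtype=float)
    # tipsets bottom-up; pairs in different child subtrees share this node
    tipset: dict[int, list[int]] = {}
    for node in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip(node):
            i = index[tree.labels[node]]
            tipset[node] = [i]
            mat[i, i] = depths[node] + tree.root_length
        else:
            kids = [tipset.pop(c) for c in tree.children[node]]
            d = depths[node] + tree.root_length
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.asarray(kids[a])
                    ib = np.asarray(kids[b])
                    mat[np.ix_(ia, ib)] = d
                    mat[np.ix_(ib, ia)] = d
            tipset[node] = [i for kid in kids for i in kid]
    return CovarianceMatrix(mat, labels)


def root_clades(tree: Tree) -> list[list[str]]:
    """Tip labels of each clade subtended by a child of the root, largest
    first (ties by label) — a convenient source of genuine clades for
    clade-shift confounders."""
    out = []
    for child in tree.children[0]:
        stack, tips = [child], []
        while stack:
            node = stack.pop()
            if tree.is_tip(node):
                tips.append(tree.labels[node])
            else:
                stack.extend(tree.children[node])
        out.append(sorted(tips))
    return sorted(out, key=lambda tips: (-len(tips), tips))


def prune_to_tips(tree: Tree, keep: Iterable[str]) -> Tree:
    """Induced subtree on ``keep``: unbranched internals are suppressed with
    branch lengths summed, so root-to-tip distances are preserved."""
    keep = set(keep)
    have = {tree.labels[i] for i in tree.tip_ids}
    missing = sorted(keep - have)
    if missing:
        raise TreeError(f"unknown tip labels: {missing}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to prune to")

    # count kept tips under each node
    counts = np.zeros(tree.n_nodes, dtype=int)
    for node in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip(node):
            counts[node] = 1 if tree.labels[node] in keep else 0
        else:
            counts[node] = sum(counts[c] for c in tree.children[node])

    # new root: deepest node with all kept tips below it
    new_root = 0
    extra_stem = tree.root_length
    node = 0
    while True:
        live = [c for c in tree.children[node] if counts[c] > 0]
        if len(live) == 1 and counts[live[0]] == len(keep):
            extra_stem += tree.length[live[0]]
            node = live[0]
        else:
            new_root = node
            break

    parent_out = [-1]
    length_out = [0.0]
    labels_out: list[str | None] = [None if not tree.is_tip(new_root) else tree.labels[new_root]]

    def build(old: int, new_parent: int, carried: float) -> None:
        live = [c for c in tree.children[old] if counts[c] > 0]
        for child in live:
            clen = carried + tree.length[child]
            sub = [c for c in tree.children[child] if counts[c] > 0]
            if tree.is_tip(child) or len(sub) >= 2:
                node_id = len(parent_out)
                parent_out.append(new_parent)
                length_out.append(clen)
                labels_out.append(tree.labels[child] if tree.is_tip(child) else None)
                if not tree.is_tip(child):
                    build(child, node_id, 0.0)
            else:  # suppress unbranched internal, sum lengths
                build(child, new_parent, clen)

    build(new_root, 0, 0.0)
    return Tree(parent_out, length_out, labels_out, root_length=extra_stem)
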