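"""Rooted phylogenies with substitutions/site branch lengths, and posterior tree sets.

Trees are parsed with :mod:`dendropy` (plain multi-tree newick or NEXUS with a
``translate`` block, e.g. BEAST output; bracketed ``[&...]`` annotations are
stripped) and converted to a light array-backed :class:`PhyloTree` container.
The container exists because downstream recovery and coverage experiments build
and query on the order of 10^5 trees; it supports exactly the queries the clock
needs — node heights (mean root-to-tip path below a node) and MRCA lookup by
taxon set — plus newick round-tripping.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "PosteriorTreeSet",
    "normalize_label",
    "read_trees",
    "write_trees",
    "node_height",
    "find_mrca",
    "is_monophyletic",
]

#: tolerance on max-min root-to-tip spread below a node before a
#: non-ultrametricity warning is logged
ULTRAMETRIC_TOL = 1e-6

_BEAST_COMMENT = re.compile(r"\[[^]]*\]")


def normalize_label(label: str) -> str:
    """Normalise a taxon label: underscores to spaces, collapsed whitespace.

    Tree files and calibration tables are matched on normalised labels, so
    ``"SFVmsp_MSP38"`` and ``"SFVmsp MSP38"`` name the same taxon.
    """
    return " ".join(label.replace("_", " ").split())


class PhyloTree:
    """A rooted tree with branch lengths, indexed for fast clade queries.

    Nodes are integers ``0..n_nodes-1`` with ``0`` the root. Tips carry labels;
    clades are represented as bitmasks over the tip order, so MRCA lookup and
    monophyly checks are O(depth) after a single preorder pass.
    """

    __slots__ = (
        "parent",
        "children",
        "length",
        "labels",
        "tip_order",
        "_tip_index",
        "_mask",
        "_n_tips_below",
        "_sum_tip_dist",
        "_min_tip_dist",
        "_max_tip_dist",
        "_postorder",
        "_warned_nonultrametric",
    )

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        length: Sequence[float],
        labels: Sequence[str | None],
    ):
        self.parent = list(parent)
        self.children = [list(c) for c in children]
        self.length = [float(x) for x in length]
        self.labels = list(labels)
        if self.parent and self.parent[0] != -1:
            raise ValueError("node 0 must be the root")
        for i in range(1, len(self.parent)):
            if not 0 <= self.parent[i] < i:
                raise ValueError("nodes must be indexed in preorder (parent < child)")
            if not math.isfinite(self.length[i]) or self.length[i] < 0:
                raise ValueError(f"branch length of node {i} must be finite and >= 0")
        self._warned_nonultrametric = False
        self._finalize()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        parent: list[int] = []
        children: list[list[int]] = []
        length: list[float] = []
        labels: list[str | None] = []
        index: dict[int, int] = {}
        for node in dtree.preorder_node_iter():
            i = len(parent)
            index[id(node)] = i
            parent.append(index[id(node.parent_node)] if node.parent_node else -1)
            children.append([])
            if node.parent_node is not None:
                parent_i = parent[i]
                children[parent_i].append(i)
            bl = node.edge.length
            length.append(0.0 if node.parent_node is None and bl is None else float(bl or 0.0))
            if node.is_leaf():
                lab = node.taxon.label if node.taxon is not None else node.label
                labels.append(lab)
            else:
                labels.append(None)
        return cls(parent, children, length, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=_BEAST_COMMENT.sub("", newick),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(dtree)

    def _finalize(self) -> None:
        n = len(self.parent)
        # postorder via reversed preorder (parents always precede children)
        order = list(range(n))
        self._postorder = order[::-1]
        self.tip_order = [i for i in order if not self.children[i]]
        self._tip_index = {}
        for rank, i in enumerate(self.tip_order):
            if self.labels[i] is None:
                raise ValueError(f"tip node {i} has no label")
            key = normalize_label(self.labels[i])
            if key in self._tip_index:
                raise ValueError(f"duplicate tip label {self.labels[i]!r}")
            self._tip_index[key] = i
        mask = [0] * n
        n_tips = [0] * n
        sum_d = [0.0] * n
        min_d = [0.0] * n
        max_d = [0.0] * n
        for rank, i in enumerate(self.tip_order):
            mask[i] = 1 << rank
            n_tips[i] = 1
        for i in self._postorder:
            if self.children[i]:
                lo, hi = math.inf, -math.inf
                for c in self.children[i]:
                    mask[i] |= mask[c]
                    n_tips[i] += n_tips[c]
                    sum_d[i] += sum_d[c] + n_tips[c] * self.length[c]
                    lo = min(lo, min_d[c] + self.length[c])
                    hi = max(hi, max_d[c] + self.length[c])
                min_d[i], max_d[i] = lo, hi
        self._mask = mask
        self._n_tips_below = n_tips
        self._sum_tip_dist = sum_d
        self._min_tip_dist = min_d
        self._max_tip_dist = max_d

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_order)

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_order]

    def tip_label_set(self) -> frozenset[str]:
        return frozenset(self._tip_index)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def _taxa_mask(self, taxa: Iterable[str]) -> int:
        mask = 0
        missing = []
        for t in taxa:
            i = self._tip_index.get(normalize_label(t))
            if i is None:
                missing.append(t)
            else:
                mask |= self._mask[i]
        if missing:
            raise KeyError(
                "taxa not found in tree: " + ", ".join(sorted(map(str, missing)))
            )
        return mask

    def mrca(self, taxa: Iterable[str]) -> int:
        """Most recent common ancestor of a set of >= 2 tip labels."""
        taxa = list(taxa)
        if len(set(normalize_label(t) for t in taxa)) < 2:
            raise ValueError("MRCA needs at least two distinct taxa")
        want = self._taxa_mask(taxa)
        node = self._tip_index[normalize_label(taxa[0])]
        while self._mask[node] & want != want:
            node = self.parent[node]
        return node

    def node_height(self, node: int) -> float:
        """Mean path length from ``node`` to its descendant tips (0 for a tip).

        Strict-clock trees are ultrametric up to numeric noise, in which case
        every descendant tip gives the same value; beyond ``ULTRAMETRIC_TOL``
        spread a warning is logged (once per tree) and the mean is used.
        """
        spread = self._max_tip_dist[node] - self._min_tip_dist[node]
        if spread > ULTRAMETRIC_TOL and not self._warned_nonultrametric:
            self._warned_nonultrametric = True
            logger.warning(
                "tree is not ultrametric below node %d (tip-path spread %.3g); "
                "using mean root-to-tip path as node height",
                node,
                spread,
            )
        return self._sum_tip_dist[node] / self._n_tips_below[node]

    def clade_height(self, taxa: Iterable[str]) -> float:
        return self.node_height(self.mrca(taxa))

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        want = self._taxa_mask(list(taxa))
        return self._mask[self.mrca(taxa)] == want

    def node_heights(self) -> list[float]:
        """Heights of all nodes (tips are exactly 0)."""
        return [
            0.0 if self.is_tip(i) else self.node_height(i) for i in range(self.n_nodes)
        ]

    # -- derived trees -------------------------------------------------

    def with_heights(self, heights: Sequence[float]) -> "PhyloTree":
        """New tree, same topology/labels, branch lengths from node heights.

        ``heights[i]`` is the desired height of node ``i`` (tips must be 0);
        each branch length becomes parent height minus child height, so the
        result is exactly ultrametric with the given internal-node heights.
        """
        length = [0.0] * self.n_nodes
        for i in range(1, self.n_nodes):
            bl = heights[self.parent[i]] - heights[i]
            if bl < 0:
                raise ValueError(
                    f"node {i} height {heights[i]!r} exceeds its parent's"
                )
            length[i] = bl
        return PhyloTree(self.parent, self.children, length, self.labels)

    # -- serialisation -------------------------------------------------

    def _newick_node(self, i: int, fmt: str) -> str:
        if self.is_tip(i):
            label = self.labels[i]
            if re.search(r"[\s(),:;\[\]']", label):
                label = "'" + label.replace("'", "''") + "'"
            body = label
        else:
            body = "(" + ",".join(self._newick_node(c, fmt) for c in self.children[i]) + ")"
        if i == 0:
            return body
        return body + ":" + format(self.length[i], fmt)

    def to_newick(self, float_format: str = ".10g") -> str:
        return self._newick_node(0, float_format) + ";"

    def to_dendropy(
        self, taxon_namespace: "dendropy.TaxonNamespace | None" = None
    ) -> "dendropy.Tree":
        return dendropy.Tree.get(
            data=self.to_newick(float_format=".17g"),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


@dataclass
class PosteriorTreeSet:
    """An ordered sample of rooted trees, one per posterior draw.

    All trees share one tip label set; the post-burn-in sample must contain at
    least two trees (a single tree cannot carry posterior uncertainty).
    """

    trees: list[PhyloTree]
    burn_in_fraction: float = 0.0
    source_path: str = ""
    tip_labels: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.trees) < 2:
            raise ValueError(
                f"posterior tree set needs >= 2 trees after burn-in, got {len(self.trees)}"
            )
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        ref = self.trees[0].tip_label_set()
        for k, tree in enumerate(self.trees[1:], start=1):
            if tree.tip_label_set() != ref:
                raise ValueError(
                    f"tree {k} has a different tip label set from tree 0"
                )
        self.tip_labels = ref

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]


def read_trees(
    path: str | Path,
    format: str = "newick",
    burn_in_fraction: float = 0.1,
) -> PosteriorTreeSet:
    """Read a multi-tree file and discard the initial burn-in fraction.

    Parameters
    ----------
    path
        Multi-tree newick (one tree per line) or NEXUS file. NEXUS
        ``translate`` tables are resolved to full labels; BEAST-style
        ``[&...]`` annotations are ignored.
    format
        ``"newick"`` or ``"nexus"``.
    burn_in_fraction
        Proportion of initial trees discarded, default 0.1 (the conventional
        10% MCMC burn-in). ``floor(burn_in_fraction * N)`` trees are dropped.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    text = path.read_text()
    if format == "newick":
        text = _BEAST_COMMENT.sub("", text)
    dtrees = dendropy.TreeList.get(
        data=text,
        schema=format,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    trees = []
    for k, dtree in enumerate(dtrees):
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise ValueError(
                    f"tree {k} in {path.name} has a branch with no length"
                )
        trees.append(PhyloTree.from_dendropy(dtree))
    n_burn = math.floor(burn_in_fraction * len(trees))
    kept = trees[n_burn:]
    if len(kept) < 2:
        raise ValueError(
            f"{path.name}: only {len(kept)} trees remain after discarding "
            f"{n_burn} burn-in trees; need >= 2"
        )
    return PosteriorTreeSet(kept, burn_in_fraction, str(path))


def write_trees(trees: Iterable[PhyloTree], path: str | Path) -> None:
    """Write trees as plain newick, one per line."""
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")


# functional forms mirroring the object API -----------------------------------

def node_height(tree: PhyloTree, node: int) -> float:
    """Mean path length (substitutions/site) from ``node`` down to its tips."""
    return 0.0 if tree.is_tip(node) else tree.node_height(node)


def find_mrca(tree: PhyloTree, taxa: Iterable[str]) -> int:
    """Most recent common ancestor node of ``taxa`` (>= 2 tip labels)."""
    return tree.mrca(taxa)


def is_monophyletic(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    """True iff the MRCA of ``taxa`` has exactly ``taxa`` below it."""
    return tree.is_monophyletic(taxa)
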