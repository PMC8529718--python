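"""Tree containers and newick I/O.

Two tree flavours move through the pipeline:

* :class:`PhylogramTree` — a rooted topology whose branch lengths are
  expected substitutions per site (the output of an ML tree search),
  together with the alignment length used to estimate it.
* :class:`Chronogram` — the same topology with node ages in MYA (extant
  tips at age 0) and per-branch substitution rates.

Internal nodes are always addressed by the most recent common ancestor
(MRCA) of a pair of tip taxa (:class:`NodeQuery`), never by an internal
index, so that re-reading a tree can never silently shift a calibration.

dendropy handles newick parsing/serialisation; computation happens on a
flat array representation (:class:`ArrayTree`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ArrayTree",
    "PhylogramTree",
    "Chronogram",
    "NodeQuery",
    "TreeError",
    "read_tree",
    "write_tree",
    "mrca",
]


class TreeError(ValueError):
    """Raised for malformed or unusable tree input."""


@dataclass(frozen=True)
class NodeQuery:
    """An internal node addressed as mrca(taxon_a, taxon_b)."""

    taxon_a: str
    taxon_b: str
    label: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = f"{self.label}: " if self.label else ""
        return f"{tag}mrca({self.taxon_a}, {self.taxon_b})"


class ArrayTree:
    """Flat, index-based view of a rooted tree.

    Node 0 is the root; children always have a higher index than their
    parent (preorder numbering), so iterating indices in reverse is a
    valid postorder sweep.
    """

    def __init__(self, parent, children, labels, blen):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.labels = list(labels)
        self.blen = np.asarray(blen, dtype=float)
        self.n_nodes = len(self.parent)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.tip_index = {
            self.labels[i]: i for i in range(self.n_nodes) if self.is_tip[i]
        }
        self.postorder = np.arange(self.n_nodes)[::-1]
        self.internal = np.flatnonzero(~self.is_tip)
        # branch j is identified with its child node j; root (0) has none
        self.branches = np.arange(1, self.n_nodes)

    # -- construction -------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "ArrayTree":
        root = tree.seed_node
        parent, children, labels, blen = [], [], [], []
        index = {}
        stack = [(root, -1)]
        while stack:
            node, pidx = stack.pop()
            idx = len(parent)
            index[node] = idx
            parent.append(pidx)
            children.append([])
            if pidx >= 0:
                children[pidx].append(idx)
            if node.is_leaf():
                labels.append(node.taxon.label if node.taxon else (node.label or ""))
            else:
                labels.append(node.label or "")
            blen.append(node.edge.length if node.edge.length is not None else np.nan)
            for ch in reversed(node.child_nodes()):
                stack.append((ch, idx))
        return cls(parent, children, labels, blen)

    def to_dendropy(self, blen=None) -> dendropy.Tree:
        blen = self.blen if blen is None else np.asarray(blen, dtype=float)
        taxa = dendropy.TaxonNamespace()
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                nodes[i].taxon = taxa.new_taxon(self.labels[i])
            if i > 0:
                nodes[self.parent[i]].add_child(nodes[i])
                nodes[i].edge.length = float(blen[i]) if np.isfinite(blen[i]) else None
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[0]
        tree.is_rooted = True
        return tree

    # -- queries ------------------------------------------------------
    def tip_labels(self):
        return [self.labels[i] for i in range(self.n_nodes) if self.is_tip[i]]

    def depth(self, i: int) -> int:
        d = 0
        while self.parent[i] >= 0:
            i = self.parent[i]
            d += 1
        return d

    def ancestors(self, i: int):
        """Indices from i's parent up to the root."""
        out = []
        while self.parent[i] >= 0:
            i = self.parent[i]
            out.append(i)
        return out

    def mrca_index(self, label_a: str, label_b: str) -> int:
        for lab in (label_a, label_b):
            if lab not in self.tip_index:
                raise TreeError(f"taxon {lab!r} not present in tree")
        a, b = self.tip_index[label_a], self.tip_index[label_b]
        if a == b:
            return a
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a, da = self.parent[a], da - 1
        while db > da:
            b, db = self.parent[b], db - 1
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return int(a)

    def tips_under(self, i: int):
        """Tip indices in the clade rooted at i."""
        out, stack = [], [i]
        while stack:
            j = stack.pop()
            if self.is_tip[j]:
                out.append(j)
            else:
                stack.extend(self.children[j])
        return out

    def clade_tip_sets(self):
        """Frozensets of tip labels, one per internal node."""
        sets = {}
        for i in self.postorder:
            if self.is_tip[i]:
                continue
            labs = set()
            for c in self.children[i]:
                if self.is_tip[c]:
                    labs.add(self.labels[c])
                else:
                    labs |= sets[c]
            sets[i] = labs
        return {i: frozenset(s) for i, s in sets.items()}


@dataclass
class PhylogramTree:
    """Rooted tree with branch lengths in expected substitutions/site."""

    tree: ArrayTree
    alignment_length: int

    def __post_init__(self):
        t = self.tree
        labs = t.tip_labels()
        if len(set(labs)) != len(labs):
            raise TreeError("tip labels are not unique")
        b = t.blen[1:]
        if not np.all(np.isfinite(b)):
            raise TreeError("tree has missing branch lengths")
        if np.any(b < 0):
            raise TreeError("tree has negative branch lengths")
        if self.alignment_length <= 0:
            raise TreeError("alignment_length must be positive")

    @property
    def n_tips(self) -> int:
        return int(self.tree.is_tip.sum())

    def expected_counts(self) -> np.ndarray:
        """Expected substitution counts per branch (length x sites).

        Real-valued by design: ML branch lengths are estimates, not
        integer counts, so the Poisson term generalises via
        x*log(mu) - mu.
        """
        x = self.tree.blen.copy() * self.alignment_length
        x[0] = 0.0
        return x


@dataclass
class Chronogram:
    """Tree with node ages in MYA (tips at 0) and per-branch rates.

    ``rates`` are substitutions/site/MY, indexed by child node like
    branch lengths; entry 0 (the root, which has no branch) is NaN.
    """

    tree: ArrayTree
    ages: np.ndarray
    rates: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        t = self.tree
        tips = t.is_tip
        if np.any(np.abs(self.ages[tips]) > 1e-9):
            raise TreeError("chronogram tips must have age 0")
        par = t.parent[1:]
        if np.any(self.ages[par] < self.ages[1:] - 1e-9 * max(1.0, self.root_age)):
            raise TreeError("parent node younger than child")

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    def durations(self) -> np.ndarray:
        """Branch durations in MY, indexed by child node (root NaN)."""
        d = np.full(self.tree.n_nodes, np.nan)
        d[1:] = self.ages[self.tree.parent[1:]] - self.ages[1:]
        return d

    def age_of(self, query: NodeQuery) -> float:
        return float(self.ages[self.tree.mrca_index(query.taxon_a, query.taxon_b)])

    def max_ultrametric_deviation(self) -> float:
        """max over tips of |root_age - path length to tip|."""
        t = self.tree
        dur = self.durations()
        depth = np.zeros(t.n_nodes)
        for i in range(1, t.n_nodes):
            depth[i] = depth[t.parent[i]] + dur[i]
        return float(np.max(np.abs(self.root_age - depth[t.is_tip])))

    def to_newick(self) -> str:
        """Newick with branch lengths in MY (ultrametric)."""
        dur = self.durations()
        dtree = self.tree.to_dendropy(blen=dur)
        return dtree.as_string(schema="newick", suppress_rooting=False).strip()

    def node_age_table(self, node_defs: dict[str, NodeQuery] | None = None) -> pd.DataFrame:
        """Sidecar table (node_label, taxonA, taxonB, age)."""
        t = self.tree
        rows = []
        if node_defs:
            for lab, q in node_defs.items():
                rows.append((lab, q.taxon_a, q.taxon_b, self.age_of(q)))
        else:
            sets = t.clade_tip_sets()
            for i in t.internal:
                labs = sorted(sets[i])
                rows.append((f"n{i}", labs[0], labs[-1], float(self.ages[i])))
        return pd.DataFrame(rows, columns=["node_label", "taxonA", "taxonB", "age"])


# ---------------------------------------------------------------------------
# I/O


def read_tree(path_or_str, alignment_length: int) -> PhylogramTree:
    """Read a rooted newick phylogram.

    Accepts a filesystem path or a raw newick string. The tree must be
    rooted (bifurcating at the base or flagged ``[&R]``) and every
    non-root branch must carry a length.
    """
    src = str(path_or_str)
    is_data = "(" in src and ";" in src
    try:
        if is_data:
            dtree = dendropy.Tree.get(
                data=src, schema="newick", preserve_underscores=True
            )
        else:
            dtree = dendropy.Tree.get(
                path=src, schema="newick", preserve_underscores=True
            )
    except TreeError:
        raise
    except Exception as err:  # dendropy parse errors -> uniform TreeError
        raise TreeError(f"could not parse newick input: {err}") from err
    nchild = len(dtree.seed_node.child_nodes())
    if nchild > 2 and not dtree.is_rooted:
        raise TreeError(
            f"input tree is unrooted (basal {nchild}-furcation); root it first"
        )
    at = ArrayTree.from_dendropy(dtree)
    return PhylogramTree(tree=at, alignment_length=alignment_length)


def write_tree(phylogram: PhylogramTree, path=None) -> str:
    """Serialise a phylogram back to newick; returns the string."""
    s = (
        phylogram.tree.to_dendropy()
        .as_string(schema="newick", suppress_rooting=False)
        .strip()
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def mrca(tree, query: NodeQuery) -> int:
    """Index of the MRCA of the query's taxon pair.

    Accepts an ArrayTree, PhylogramTree or Chronogram. Symmetric in the
    pair by construction.
    """
    at = tree if isinstance(tree, ArrayTree) else tree.tree
    return at.mrca_index(query.taxon_a, query.taxon_b)
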