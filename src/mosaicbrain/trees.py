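"""Phylogenetic trees: I/O, clade splicing, and Brownian-motion covariance.

The central objects are :class:`PhyloTree`, a light array-backed rooted tree
with branch lengths in millions of years (My), and :class:`PhyloCovariance`,
the tip-by-tip matrix of shared root-to-MRCA path lengths that a Brownian
motion (BM) model of trait evolution induces, optionally attenuated by
Pagel's lambda.

Parsing and serialization of Newick/Nexus delegate to :mod:`dendropy`;
everything numerical runs on flat numpy arrays indexed in preorder, which
keeps covariance construction a single sparse-style matrix product and makes
repeated evaluation (lambda profiling, branch-scalar MCMC) cheap.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "TreeError",
    "read_tree",
    "write_tree",
    "splice_clade",
    "phylo_vcv",
    "apply_lambda",
    "is_ultrametric",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


@dataclass
class PhyloTree:
    """Rooted, dated phylogeny stored as parent-pointer arrays.

    Nodes are indexed 0..n_nodes-1 in preorder (root first, every parent
    before its children).  ``lengths[i]`` is the branch above node ``i``
    (0 for the root).  Tips carry labels; internal nodes may be unlabelled.
    Edges are indexed by their child node, so edge ``i`` exists for every
    non-root node ``i``.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 for root
    lengths: np.ndarray         # (n_nodes,) float, branch above each node
    labels: list                # (n_nodes,) str or None

    _children: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.intp)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths[1:] < 0):
            raise TreeError("negative branch lengths are not allowed")
        if self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, len(self.parent))):
            raise TreeError("nodes must be in preorder with node 0 as the sole root")
        tips = [l for i, l in enumerate(self.labels) if self.is_tip(i)]
        if len(set(tips)) != len(tips):
            raise TreeError("tip labels must be unique")

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def children(self) -> list:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i in range(1, self.n_nodes):
                ch[self.parent[i]].append(i)
            self._children = ch
        return self._children

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if self.is_tip(i)], dtype=np.intp)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node (preorder recurrence)."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    @property
    def height(self) -> float:
        return float(self.node_depths()[self.tip_indices].max())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths.copy(), list(self.labels))

    # -- clades ------------------------------------------------------------
    def descendant_tips(self, node: int) -> list:
        """Tip indices in the clade rooted at ``node`` (including ``node`` if a tip)."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            ch = self.children[i]
            if ch:
                stack.extend(ch)
            else:
                out.append(i)
        return sorted(out)

    def mrca(self, taxa) -> int:
        """Most recent common ancestor (node index) of a set of tip labels."""
        taxa = set(taxa)
        idx = {self.labels[i] for i in self.tip_indices}
        missing = taxa - idx
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        if len(taxa) == 1:
            return next(i for i in self.tip_indices if self.labels[i] in taxa)
        # count, per node, how many target tips sit below it; walk up from tips
        count = np.zeros(self.n_nodes, dtype=int)
        for i in self.tip_indices:
            if self.labels[i] in taxa:
                count[i] = 1
        for i in range(self.n_nodes - 1, 0, -1):
            count[self.parent[i]] += count[i]
        # deepest node containing all targets = last preorder node with full count
        full = np.flatnonzero(count == len(taxa))
        return int(full.max())

    def is_monophyletic(self, taxa) -> bool:
        node = self.mrca(taxa)
        clade = {self.labels[i] for i in self.descendant_tips(node)}
        return clade == set(taxa)

    def clade_edges(self, node: int) -> np.ndarray:
        """Edge (child-node) indices inside the clade rooted at ``node``,
        including the stem edge of ``node`` itself (if not the root)."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if i != 0:
                out.append(i)
            stack.extend(self.children[i])
        return np.array(sorted(out), dtype=np.intp)

    # -- covariance machinery ---------------------------------------------
    def tip_membership(self, taxa_order=None) -> tuple:
        """Boolean-as-float matrix E (n_edges+1, n_tips): E[e, j] = 1 iff tip j
        lies below edge e (edge indexed by child node; row 0, the root, is zero).

        The BM covariance for branch-length weights w is ``E.T @ (w[:,None]*E)``.
        """
        order = self.tip_labels if taxa_order is None else list(taxa_order)
        col = {lab: j for j, lab in enumerate(order)}
        unknown = [l for l in self.tip_labels if l not in col]
        if len(order) != self.n_tips or unknown:
            missing = set(order) - set(self.tip_labels)
            if missing:
                raise TreeError(f"unknown taxon label(s): {sorted(missing)}")
            raise TreeError("taxa_order must be a permutation of the tip labels")
        E = np.zeros((self.n_nodes, len(order)))
        for i in self.tip_indices:
            E[i, col[self.labels[i]]] = 1.0
        for i in range(self.n_nodes - 1, 0, -1):
            E[self.parent[i]] += E[i]
        E[0] = 0.0
        return E, order

    def vcv(self, taxa_order=None) -> tuple:
        """BM expected covariance: V[i,j] = shared root-to-MRCA path length."""
        E, order = self.tip_membership(taxa_order)
        V = E.T @ (self.lengths[:, None] * E)
        return V, order

    # -- dendropy bridge ---------------------------------------------------
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_tip(i):
                nodes[i].taxon = taxa.require_taxon(label=self.labels[i])
            elif self.labels[i]:
                nodes[i].label = self.labels[i]
            nodes[i].edge.length = float(self.lengths[i]) if i else None
            if i:
                nodes[self.parent[i]].add_child(nodes[i])
        dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
        dtree.is_rooted = True
        return dtree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        order = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        parent = np.empty(len(order), dtype=np.intp)
        lengths = np.zeros(len(order))
        labels = []
        for i, nd in enumerate(order):
            parent[i] = index[id(nd.parent_node)] if nd.parent_node else -1
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else (nd.label or f"node {i}")
                    raise TreeError(f"missing branch length above {who!r}")
                lengths[i] = nd.edge.length
            labels.append(nd.taxon.label if nd.taxon else nd.label)
        return cls(parent, lengths, labels)


@dataclass
class PhyloCovariance:
    """Tip covariance under BM: V[i,j] is the shared path (My) from the root
    to MRCA(i, j); ``lam`` multiplies the off-diagonal (Pagel's lambda)."""

    matrix: np.ndarray
    taxa_order: list
    lam: float = 1.0

    def __post_init__(self):
        V = np.asarray(self.matrix, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] != len(self.taxa_order):
            raise TreeError("covariance must be square and match taxa_order")
        if not np.allclose(V, V.T, atol=1e-8):
            raise TreeError("covariance must be symmetric")
        self.matrix = V

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


# ---------------------------------------------------------------------------
# I/O


def _detect_schema(text: str) -> str:
    return "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"


def read_tree(source, schema: str | None = None) -> PhyloTree:
    """Read a rooted tree with branch lengths from Newick or Nexus.

    ``source`` may be a path or the tree text itself; the schema is detected
    from the content when not given.  Nexus TRANSLATE blocks are honoured.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    schema = schema or _detect_schema(text)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=schema, preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific error classes
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def write_tree(tree: PhyloTree, path=None, schema: str = "newick") -> str:
    """Serialize to Newick or Nexus; returns the text, optionally writing it."""
    text = tree.to_dendropy().as_string(schema=schema, unquoted_underscores=True,
                                        suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Splicing


def splice_clade(backbone: PhyloTree, donor: PhyloTree, anchor_taxa,
                 return_report: bool = False):
    """Replace a clade of ``backbone`` with the matching clade of ``donor``.

    The donor clade is the subtree below the MRCA of ``anchor_taxa`` in the
    donor (it may contain additional tips, e.g. a better-sampled species-level
    phylogeny grafted onto a backbone supertree).  All donor branch lengths are
    rescaled by the ratio of the clade's crown age in the backbone to its crown
    age in the donor, so node ages are continuous across the attachment point.

    Returns the spliced tree; with ``return_report=True`` also returns a dict
    with the rescale ratio and the (should-be-zero) attachment-age adjustment.
    """
    anchor_taxa = set(anchor_taxa)
    if not backbone.is_monophyletic(anchor_taxa):
        raise TreeError("anchor taxa are not monophyletic in the backbone")
    b_node = backbone.mrca(anchor_taxa)
    b_depth = backbone.node_depths()
    b_age = float(np.max(b_depth[backbone.descendant_tips(b_node)]) - b_depth[b_node])

    donor_present = anchor_taxa & set(donor.tip_labels)
    if not donor_present:
        raise TreeError("no anchor taxa present in the donor tree")
    d_node = donor.mrca(donor_present)
    d_depth = donor.node_depths()
    d_age = float(np.max(d_depth[donor.descendant_tips(d_node)]) - d_depth[d_node])
    if d_age <= 0:
        raise TreeError("donor clade has zero age; cannot rescale")
    ratio = b_age / d_age

    # Work on dendropy objects for the structural surgery.
    db = backbone.to_dendropy()
    dd = donor.to_dendropy()
    b_mrca = db.mrca(taxon_labels=sorted(anchor_taxa))
    d_mrca = dd.mrca(taxon_labels=sorted(donor_present))

    # Detach + rescale the donor clade (dd is a private copy, safe to mutate).
    if d_mrca.parent_node is not None:
        d_mrca.parent_node.remove_child(d_mrca)
    for nd in d_mrca.preorder_iter():
        if nd is not d_mrca and nd.edge.length is not None:
            nd.edge.length = nd.edge.length * ratio

    stem = b_mrca.edge.length  # backbone stem branch above the clade is kept
    parent = b_mrca.parent_node
    d_mrca.edge.length = stem
    if parent is None:
        db.seed_node = d_mrca
    else:
        parent.remove_child(b_mrca)
        parent.add_child(d_mrca)
    out = PhyloTree.from_dendropy(db)

    # Residual age mismatch at the attachment (0 when the rescale is exact).
    depths = out.node_depths()
    new_node = out.mrca(donor_present)
    adjustment = float(np.max(depths[out.descendant_tips(new_node)]) - depths[new_node] - b_age)
    if return_report:
        return out, {"ratio": ratio, "backbone_clade_age": b_age,
                     "donor_clade_age": d_age, "attachment_adjustment": adjustment}
    return out


# ---------------------------------------------------------------------------
# Covariance operations


def phylo_vcv(tree: PhyloTree, taxa_order=None) -> PhyloCovariance:
    """BM covariance matrix of the tips: V[i,j] = root-to-MRCA shared path."""
    V, order = tree.vcv(taxa_order)
    return PhyloCovariance(V, order, lam=1.0)


def apply_lambda(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: multiply off-diagonal covariances by ``lam``.

    lambda = 1 keeps the full BM structure; lambda = 0 removes all shared
    history, leaving independent tips with their original variances.
    """
    if not 0.0 <= lam <= 1.0:
        raise TreeError(f"lambda must lie in [0, 1], got {lam}")
    V = cov.matrix * lam
    np.fill_diagonal(V, np.diag(cov.matrix))
    return PhyloCovariance(V, list(cov.taxa_order), lam=cov.lam * lam)


def is_ultrametric(tree: PhyloTree, tol: float = 1e-6) -> bool:
    """True when all root-to-tip depths agree within ``tol`` (My)."""
    d = tree.node_depths()[tree.tip_indices]
    return bool(d.max() - d.min() <= tol)
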