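"""Phylogenetic trees and the covariance structures they imply.

A rooted tree with branch lengths defines, under Brownian trait evolution,
an among-tip variance-covariance matrix ``C`` whose entry ``C[i, j]`` is the
shared path length from the root to the most recent common ancestor of tips
``i`` and ``j`` (and ``C[i, i]`` the root-to-tip distance).  Pagel's lambda
rescales the off-diagonal of ``C``; multi-population data use the correlation
form of ``C`` expanded to one row per population (a "kinship" matrix).

Newick parsing and serialisation are delegated to :mod:`dendropy`; the tree
is then held in a flat array representation convenient for traversal and
vectorised computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickFormatError",
    "TreeValidationError",
    "PhyloTree",
    "PhyloCov",
    "KinshipMatrix",
    "read_newick",
    "write_newick",
    "vcv_from_tree",
    "lambda_transform",
    "population_kinship",
]

#: relative tolerance (x tree depth) used when deciding ultrametricity
ULTRAMETRIC_RTOL = 1e-6


class NewickFormatError(ValueError):
    """Raised when a Newick string/file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths, in flat-array form.

    Parameters
    ----------
    parent
        ``parent[i]`` is the index of node ``i``'s parent; ``-1`` for the root.
    length
        ``length[i]`` is the length of the branch subtending node ``i``
        (``0.0`` for the root).
    labels
        Per-node label; tips must carry unique non-empty labels, internal
        labels may be ``None``.
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        labels: Sequence[str | None],
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.length) == n and len(self.labels) == n):
            raise TreeValidationError("parent/length/labels must have equal length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.tips = [i for i in range(n) if not self.children[i]]
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise NewickFormatError(
                        "missing branch length on an edge; covariance is undefined "
                        "without branch lengths"
                    )
                length[i] = nd.edge.length
            elif nd.edge.length is not None:
                length[i] = nd.edge.length
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent, length, labels)

    @classmethod
    def from_newick_string(cls, newick: str) -> "PhyloTree":
        text = newick.strip()
        if not text:
            raise NewickFormatError("empty Newick input")
        if not text.endswith(";"):
            raise NewickFormatError(
                f"Newick string must terminate with ';' (ended at position {len(text)})"
            )
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            if "Duplicate taxon labels" in str(exc):
                raise TreeValidationError(f"tip labels must be unique: {exc}") from exc
            raise NewickFormatError(f"Newick parse failure: {exc}") from exc
        return cls.from_dendropy(dtree)

    # -- invariants ----------------------------------------------------

    def _validate(self) -> None:
        if self.n_tips < 3:
            raise TreeValidationError(
                f"tree has {self.n_tips} tips; at least 3 are required"
            )
        if np.any(self.length < 0):
            raise TreeValidationError("negative branch length")
        if np.any(self.length[np.arange(self.length.size) != self.root] == 0):
            warnings.warn("tree contains zero-length branches", stacklevel=3)
        tip_labels = [self.labels[i] for i in self.tips]
        if any(lbl is None or lbl == "" for lbl in tip_labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeValidationError("tip labels must be unique")

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def postorder(self) -> list[int]:
        """Node indices, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        order.reverse()
        return order

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        depth = np.zeros(self.n_nodes)
        stack = [self.root]
        while stack:
            nd = stack.pop()
            for ch in self.children[nd]:
                depth[ch] = depth[nd] + self.length[ch]
                stack.append(ch)
        return depth

    def is_bifurcating(self) -> bool:
        return all(len(self.children[i]) in (0, 2) for i in range(self.n_nodes))

    def bifurcating_copy(self) -> "PhyloTree":
        """Resolve polytomies into arbitrary zero-length bifurcations."""
        if self.is_bifurcating():
            return self
        warnings.warn(
            "polytomies resolved to zero-length bifurcations", stacklevel=2
        )
        parent = list(self.parent)
        length = list(self.length)
        labels = list(self.labels)
        children = [list(c) for c in self.children]
        i = 0
        while i < len(children):
            while len(children[i]) > 2:
                # collapse the first two children under a new zero-length node
                a, b = children[i][0], children[i][1]
                new = len(parent)
                parent.append(i)
                length.append(0.0)
                labels.append(None)
                children.append([a, b])
                parent[a] = parent[b] = new
                children[i] = [new] + children[i][2:]
            i += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-length warning already issued
            return PhyloTree(parent, length, labels)

    # -- serialisation -------------------------------------------------

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                body = self.labels[i]
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    body += self.labels[i]
            if i == self.root:
                return body
            return f"{body}:{float(self.length[i])!r}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree with {self.n_tips} tips>"


@dataclass
class PhyloCov:
    """Among-tip Brownian variance-covariance matrix of a tree."""

    C: np.ndarray
    tip_order: list[str]
    is_ultrametric: bool
    depth: float

    def index_of(self, label: str) -> int:
        return self.tip_order.index(label)

    def submatrix(self, keep: Sequence[int]) -> "PhyloCov":
        """Covariance restricted to a subset of tips (order preserved)."""
        keep = list(keep)
        C = self.C[np.ix_(keep, keep)]
        labels = [self.tip_order[i] for i in keep]
        diag = np.diag(C)
        depth = float(diag.max())
        ultra = bool(np.all(np.abs(diag - depth) <= ULTRAMETRIC_RTOL * max(depth, 1.0)))
        return PhyloCov(C=C, tip_order=labels, is_ultrametric=ultra, depth=depth)


@dataclass
class KinshipMatrix:
    """Population-level phylogenetic correlation matrix.

    ``A[p, q]`` is the correlation-scaled shared history of the species the
    two populations belong to; populations of the same species have
    correlation 1 on an ultrametric tree.
    """

    A: np.ndarray
    population_order: list[str]
    species_of: dict[str, str] = field(repr=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_newick(path) -> PhyloTree:
    """Read a strict Newick file (branch lengths mandatory, ';'-terminated)."""
    with open(path) as fh:
        return PhyloTree.from_newick_string(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def vcv_from_tree(tree: PhyloTree) -> PhyloCov:
    """Brownian variance-covariance matrix implied by the tree.

    ``C[i, j]`` = root-to-MRCA path length of tips i, j; ``C[i, i]`` =
    root-to-tip distance.  Polytomies are handled as-is.
    """
    if np.any(tree.length < 0):
        raise TreeValidationError("negative branch length; covariance undefined")
    depth = tree.depths()
    n = tree.n_tips
    tip_index = {node: k for k, node in enumerate(tree.tips)}
    C = np.zeros((n, n))
    # tip sets per node, built in postorder; pairs across distinct child
    # subtrees have their MRCA at the current node
    below: dict[int, list[int]] = {}
    for nd in tree.postorder():
        if not tree.children[nd]:
            k = tip_index[nd]
            C[k, k] = depth[nd]
            below[nd] = [k]
            continue
        kids = [below.pop(c) for c in tree.children[nd]]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    C[i, kids[b]] = depth[nd]
                    C[kids[b], i] = depth[nd]
        below[nd] = [i for kid in kids for i in kid]
    diag = np.diag(C)
    d = float(diag.max())
    ultra = bool(np.all(np.abs(diag - d) <= ULTRAMETRIC_RTOL * max(d, 1.0)))
    return PhyloCov(C=C, tip_order=tree.tip_labels, is_ultrametric=ultra, depth=d)


def lambda_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's lambda transform: off-diagonals scaled by ``lam`` in [0, 1]."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCov(
        C=C, tip_order=list(cov.tip_order),
        is_ultrametric=cov.is_ultrametric, depth=cov.depth,
    )


def population_kinship(
    cov: PhyloCov,
    species_of: Mapping[str, str] | Iterable[tuple[str, str]],
) -> KinshipMatrix:
    """Expand the correlation form of ``C`` to one row per population.

    ``A[p, q] = C[s(p), s(q)] / sqrt(C[s(p), s(p)] * C[s(q), s(q)])``.
    Population order follows the order of the supplied mapping.
    """
    if not isinstance(species_of, Mapping):
        species_of = dict(species_of)
    pops = list(species_of)
    unknown = sorted({sp for sp in species_of.values() if sp not in cov.tip_order})
    if unknown:
        raise KeyError(
            f"populations mapped to species absent from the tree: {unknown}"
        )
    if not cov.is_ultrametric:
        warnings.warn(
            "tree is not ultrametric: same-species populations still receive "
            "kinship 1 under the normalised form, but the Brownian "
            "interpretation is approximate",
            stacklevel=2,
        )
    idx = np.array([cov.index_of(species_of[p]) for p in pops])
    Csub = cov.C[np.ix_(idx, idx)]
    d = np.sqrt(np.diag(cov.C)[idx])
    A = Csub / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return KinshipMatrix(A=A, population_order=pops, species_of=dict(species_of))
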