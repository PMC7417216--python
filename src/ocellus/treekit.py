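"""Phylogeny handling: Newick I/O, replicate tips and Brownian covariance.

Comparative regressions across species need an error covariance derived
from shared evolutionary history.  Under Brownian motion the expected
trait covariance between two tips equals the depth (distance from the
root) of their most recent common ancestor, and the variance of a tip
equals its own depth.

When several conspecific specimens enter an analysis, each extra
specimen is represented by a *replicate tip* attached at the position of
the species' original tip with branch length zero.  Every specimen of a
species is then phylogenetically equidistant from all other species, so
well-sampled species do not distort between-species relationships.
Zero-length replicate branches make the Brownian covariance singular
(identical rows); a small ridge restores positive-definiteness while
leaving the replicate-tip semantics intact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "SingularCovarianceError",
    "Phylogeny",
    "TraitCovariance",
    "read_newick",
    "add_replicate_tips",
    "bm_covariance",
    "graft_tip",
]

#: Default ridge, relative to the mean tip depth, added to the diagonal
#: of the Brownian covariance so that replicate tips (zero-length
#: branches) leave the matrix invertible.
DEFAULT_RIDGE = 1e-8


class NewickError(ValueError):
    """The Newick input could not be parsed or violates tree invariants."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """The Brownian covariance is singular (duplicated tips, ridge = 0)."""


class Phylogeny:
    """A rooted tree with branch lengths, backed by a dendropy Tree.

    Tip labels must be unique.  Replicate tips produced by
    :func:`add_replicate_tips` are labelled ``<species>#k`` with k >= 2.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"could not parse Newick input: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "Phylogeny":
        text = Path(path).read_text(encoding="utf-8")
        if not text.strip():
            raise NewickError(f"{path}: empty Newick file")
        return cls.from_string(text)

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise NewickError(
                    f"missing branch length above node "
                    f"{node.taxon.label if node.taxon else '<internal>'}"
                )
            if node.edge.length < 0:
                raise NewickError("negative branch length")

    # -- basic queries -------------------------------------------------
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        depths = self._node_depths()
        return {leaf.taxon.label: depths[leaf] for leaf in self._tree.leaf_node_iter()}

    def _node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    # -- I/O -----------------------------------------------------------
    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n", encoding="utf-8")

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_string(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    return Phylogeny.from_file(path)


@dataclass(frozen=True)
class TraitCovariance:
    """Brownian-motion trait covariance over an ordered set of tips.

    ``matrix[i, j]`` is the depth of the most recent common ancestor of
    tips i and j (plus any ridge on the diagonal); units are branch-length
    time.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("covariance shape does not match label count")
        object.__setattr__(self, "matrix", m)

    def reorder(self, labels: list[str] | tuple[str, ...]) -> "TraitCovariance":
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = np.array([index[lab] for lab in labels])
        except KeyError as exc:
            raise KeyError(f"label not in covariance: {exc}") from exc
        return TraitCovariance(tuple(labels), self.matrix[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="tip")


def add_replicate_tips(tree: Phylogeny, counts: Mapping[str, int]) -> Phylogeny:
    """Attach zero-length replicate tips for multiply-sampled species.

    For a species with count m, m - 1 new tips labelled ``species#2`` ..
    ``species#m`` are attached at the position of the original tip with
    branch length zero, so all conspecific specimens keep exactly the
    original species' distances to every other species.  Counts of 1
    leave the tree unchanged.
    """
    out = tree.copy()
    leaves = {leaf.taxon.label: leaf for leaf in out.tree.leaf_node_iter()}
    unknown = sorted(set(counts) - set(leaves))
    if unknown:
        raise KeyError(f"species not in tree: {unknown}")
    for species, count in counts.items():
        if count < 1:
            raise ValueError(f"count for {species} must be >= 1, got {count}")
        if count == 1:
            continue
        leaf = leaves[species]
        taxon = leaf.taxon
        # The original leaf becomes an (unlabelled) anchor node carrying
        # the original branch length; the specimen tips hang off it with
        # zero-length branches.
        leaf.taxon = None
        first = leaf.new_child(edge_length=0.0)
        first.taxon = taxon
        namespace = out.tree.taxon_namespace
        for k in range(2, count + 1):
            rep = leaf.new_child(edge_length=0.0)
            rep.taxon = namespace.new_taxon(label=f"{species}#{k}")
    return Phylogeny(out.tree)


def bm_covariance(
    tree: Phylogeny, ridge: float = DEFAULT_RIDGE, *, allow_singular: bool = False
) -> TraitCovariance:
    """Brownian-motion covariance: MRCA depths, plus a diagonal ridge.

    ``ridge`` is relative to the mean tip depth; it is added to the
    diagonal to restore positive-definiteness when replicate tips at
    zero distance make rows identical.  With ``ridge = 0`` and duplicated
    rows a :class:`SingularCovarianceError` is raised unless
    ``allow_singular`` (callers that add their own variance component
    want the raw Brownian structure).
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    dtree = tree.tree
    depths = tree._node_depths()
    leaves = list(dtree.leaf_node_iter())
    labels = tuple(leaf.taxon.label for leaf in leaves)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))

    # Postorder sweep: tips below each child subtree share the focal
    # node's depth as their MRCA depth.
    tipsets: dict[dendropy.Node, np.ndarray] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = np.array([index[node]])
            continue
        child_sets = [tipsets.pop(c) for c in node.child_nodes()]
        depth = depths[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                V[np.ix_(child_sets[a], child_sets[b])] = depth
                V[np.ix_(child_sets[b], child_sets[a])] = depth
        tipsets[node] = np.concatenate(child_sets)
    diag = np.array([depths[leaf] for leaf in leaves])
    V[np.diag_indices(n)] = diag

    if ridge > 0:
        V = V + ridge * float(diag.mean()) * np.eye(n)
    elif not allow_singular:
        # Zero patristic distance between two distinct tips => identical
        # rows => singular matrix.
        d2 = diag[:, None] + diag[None, :] - 2 * V
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 <= 0):
            raise SingularCovarianceError(
                "tips at zero phylogenetic distance (replicate tips?) make the "
                "covariance singular; use ridge > 0"
            )
    return TraitCovariance(labels, V)


def graft_tip(
    tree: Phylogeny,
    label: str,
    anchor: str,
    attach_depth: float,
    tip_depth: float | None = None,
) -> Phylogeny:
    """Graft a named tip onto the branch above an existing tip.

    A new node is inserted on the path from the root to ``anchor`` at
    depth ``attach_depth`` and the new tip descends from it, ending at
    ``tip_depth`` (default: the anchor tip's depth, keeping an
    ultrametric tree ultrametric).  No taxonomic inference is performed;
    the placement is entirely user-specified.
    """
    out = tree.copy()
    leaves = {leaf.taxon.label: leaf for leaf in out.tree.leaf_node_iter()}
    if label in leaves:
        raise ValueError(f"tip {label!r} already present")
    if anchor not in leaves:
        raise KeyError(f"anchor tip {anchor!r} not in tree")
    depths = Phylogeny(out.tree)._node_depths()
    node = leaves[anchor]
    # Walk rootward to the edge spanning attach_depth.
    while node.parent_node is not None and depths[node.parent_node] > attach_depth:
        node = node.parent_node
    parent = node.parent_node
    if parent is None or not (depths[parent] <= attach_depth <= depths[node]):
        raise ValueError(
            f"attach_depth {attach_depth} does not intersect the root-to-"
            f"{anchor!r} path on a branch"
        )
    tip_depth = depths[leaves[anchor]] if tip_depth is None else tip_depth
    if tip_depth < attach_depth:
        raise ValueError("tip_depth must be at or below attach_depth")
    new_inner = dendropy.Node()
    parent.remove_child(node)
    parent.add_child(new_inner)
    new_inner.edge.length = attach_depth - depths[parent]
    new_inner.add_child(node)
    node.edge.length = depths[node] - attach_depth
    new_tip = new_inner.new_child(edge_length=tip_depth - attach_depth)
    new_tip.taxon = out.tree.taxon_namespace.new_taxon(label=label)
    return Phylogeny(out.tree)
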