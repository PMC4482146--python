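"""Phylogenies and the species-by-species matrices derived from them.

A :class:`Phylogeny` is a rooted tree (polytomies allowed) with unique tip
labels and non-negative branch lengths.  Two matrices drive every statistic
downstream:

* **patristic distances** — sums of branch lengths along tip-to-tip paths,
  the raw material of the phylogenetic eigenvector regression;
* **Abouheif proximities** — a topology-only closeness,
  ``a_ij = 1 / prod(ddf of internal nodes on the path i->j)`` where ``ddf``
  is a node's number of direct descendants, the weight matrix of the
  Abouheif/Moran's I phylogenetic-signal test.

Both are carried as :class:`WeightMatrix`, which records its species order,
its kind, and how (whether) it has been normalized.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "WeightMatrix",
    "read_newick",
    "patristic_distances",
    "abouheif_proximity",
    "normalize_weights",
    "NewickParseError",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or fails validation."""


@dataclass(frozen=True)
class WeightMatrix:
    """An n x n species proximity or distance matrix with fixed label order.

    Parameters
    ----------
    labels : tuple of str
        Species labels in the row/column order of ``values``.
    values : ndarray
        Square matrix aligned to ``labels``.
    kind : str
        ``"abouheif_proximity"``, ``"patristic_distance"``,
        ``"inverse_distance"`` or ``"custom"``.
    normalization : str
        ``"raw"``, ``"row_normalized"`` or ``"symmetrized_row_normalized"``.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str
    normalization: str = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"weight matrix must be square, got {values.shape}")
        if len(self.labels) != values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a {values.shape[0]}x"
                f"{values.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in weight matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def align(self, labels: list[str] | tuple[str, ...]) -> "WeightMatrix":
        """Reorder rows/columns to ``labels`` (a permutation of the current)."""
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) ^ set(self.labels))
            raise ValueError(f"label sets differ; symmetric difference: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return replace(self, labels=tuple(labels),
                       values=self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, kind: str = "custom",
                 normalization: str = "raw") -> "WeightMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("CSV row and column labels disagree")
        return cls(tuple(df.index), df.to_numpy(dtype=float), kind, normalization)


class Phylogeny:
    """A rooted phylogeny with unique tips; thin wrapper over a dendropy tree.

    Missing branch lengths default to 1 (with a warning): the Abouheif
    analyses are topology-only, but distance-based steps need lengths.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"cannot parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick_string(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(file=out, schema="newick", suppress_rooting=True,
                         unquoted_underscores=True)
        return out.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        labels = []
        filled = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else node.label
                if label is None or label == "":
                    raise NewickParseError("unlabeled tip in tree")
                labels.append(str(label))
            else:
                if node is not self._tree.seed_node and len(node.child_nodes()) < 2:
                    raise NewickParseError(
                        "internal node with a single child (unifurcation)"
                    )
            if node is not self._tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 1.0
                    filled += 1
                elif node.edge.length < 0:
                    raise NewickParseError(
                        f"negative branch length {node.edge.length}"
                    )
        root_children = self._tree.seed_node.child_nodes()
        if len(labels) > 1 and len(root_children) < 2:
            raise NewickParseError("root must have at least two children")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        if filled:
            warnings.warn(
                f"{filled} branch length(s) missing; defaulted to 1.0",
                stacklevel=3,
            )
        self._tips = labels

    # -- basic accessors ----------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in tree (Newick) order; the canonical species order."""
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def _leaf_map(self) -> dict:
        out = {}
        for leaf in self._tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            out[str(label)] = leaf
        return out

    def _ancestry(self):
        """Per tip: list of (node, depth-of-node) from parent up to root."""
        depth = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        leaf_map = self._leaf_map()
        paths = {}
        for label, leaf in leaf_map.items():
            chain = []
            node = leaf.parent_node
            while node is not None:
                chain.append(node)
                node = node.parent_node
            paths[label] = chain
        return depth, paths

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path lengths, in tip order."""
        depth, _ = self._ancestry()
        leaf_map = self._leaf_map()
        return pd.Series({t: depth[leaf_map[t]] for t in self._tips},
                         name="depth").loc[self._tips]

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.tip_depths().to_numpy()
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    # -- derived matrices ---------------------------------------------------

    def patristic_distances(self) -> WeightMatrix:
        return patristic_distances(self)

    def abouheif_proximity(self) -> WeightMatrix:
        return abouheif_proximity(self)

    def shared_path_lengths(self) -> WeightMatrix:
        """V_ij = root-to-MRCA(i,j) path length; V_ii = root-to-tip depth.

        This is the Brownian-motion trait covariance structure (up to the
        rate constant) and feeds the trait simulator.
        """
        depth, paths = self._ancestry()
        leaf_map = self._leaf_map()
        tips = self._tips
        n = len(tips)
        anc_sets = {t: set(paths[t]) for t in tips}
        V = np.zeros((n, n))
        for i, ti in enumerate(tips):
            V[i, i] = depth[leaf_map[ti]]
            for j in range(i + 1, n):
                tj = tips[j]
                common = anc_sets[ti] & anc_sets[tj]
                V[i, j] = V[j, i] = max(depth[node] for node in common)
        return WeightMatrix(tuple(tips), V, kind="custom")

    def collapse_clades(self, clades: dict[str, list[str]]) -> "Phylogeny":
        """Polytomize: replace each named clade's internal structure by a star.

        Used for robustness reruns where poorly supported subclade topology
        is collapsed into a single polytomous group.
        """
        newick_parts = []
        used = set()
        for name, members in clades.items():
            used.update(members)
        tree = dendropy.Tree(self._tree)  # deep copy
        phylo = Phylogeny(tree)
        for name, members in clades.items():
            leaf_map = phylo._leaf_map()
            nodes = [leaf_map[m] for m in members]
            mrca = tree.mrca(taxa=[nd.taxon for nd in nodes])
            # detach everything below the mrca, reattach tips directly
            for child in list(mrca.child_nodes()):
                mrca.remove_child(child)
            for nd in nodes:
                nd.parent_node = None
                nd.edge.length = 1.0
                mrca.add_child(nd)
        del newick_parts, used
        return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read a rooted phylogeny from a Newick file."""
    return Phylogeny.from_file(path)


def patristic_distances(tree: Phylogeny) -> WeightMatrix:
    """Tip-to-tip path-length (patristic) distance matrix.

    ``d_ij = depth_i + depth_j - 2 * depth(MRCA(i, j))``; symmetric with a
    zero diagonal by construction.
    """
    V = tree.shared_path_lengths().values
    d = np.diag(V)
    D = d[:, None] + d[None, :] - 2.0 * V
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return WeightMatrix(tuple(tree.tips), D, kind="patristic_distance")


def abouheif_proximity(tree: Phylogeny) -> WeightMatrix:
    """Topology-only Abouheif proximity matrix.

    For each pair of tips, multiply the direct-descendant counts (``ddf``)
    of every internal node on the connecting path — both tips' ancestors up
    to and including their MRCA — and invert.  Branch lengths are ignored;
    the diagonal is zero.
    """
    _, paths = tree._ancestry()
    tips = tree.tips
    n = len(tips)
    ddf = {}
    A = np.zeros((n, n))
    for i, ti in enumerate(tips):
        chain_i = paths[ti]
        set_i = set(chain_i)
        for j in range(i + 1, n):
            tj = tips[j]
            chain_j = paths[tj]
            # MRCA = first ancestor of j that is also an ancestor of i
            mrca = next(node for node in chain_j if node in set_i)
            prod = 1.0
            for node in chain_i:
                prod *= ddf.setdefault(node, len(node.child_nodes()))
                if node is mrca:
                    break
            for node in chain_j:
                if node is mrca:
                    break
                prod *= ddf.setdefault(node, len(node.child_nodes()))
            A[i, j] = A[j, i] = 1.0 / prod
    return WeightMatrix(tuple(tips), A, kind="abouheif_proximity")


def normalize_weights(w: WeightMatrix, mode: str) -> WeightMatrix:
    """Row-normalize a weight matrix, optionally symmetrizing afterwards.

    ``row_normalized`` divides each row by its sum (rows then sum to one);
    ``symmetrized_row_normalized`` takes ``(W + W.T) / 2`` of that, which is
    what the phylogenetic PCA decomposition requires to stay symmetric.
    """
    if mode == "raw":
        return w
    if mode not in ("row_normalized", "symmetrized_row_normalized"):
        raise ValueError(f"unknown normalization {mode!r}")
    sums = w.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [w.labels[i] for i in bad]
        raise ValueError(f"zero row sum for species: {names}")
    R = w.values / sums[:, None]
    if mode == "symmetrized_row_normalized":
        R = 0.5 * (R + R.T)
    return replace(w, values=R, normalization=mode)
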