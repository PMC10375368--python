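"""Dated-tree container, Newick I/O, and lineage-through-time extraction.

The time convention used throughout the package is *forward* time
``t in [0, T]`` with ``t = 0`` at the root (crown) and ``t = T`` at the
present.  A tree is "dated" when it is ultrametric to within a relative
tolerance of its root age.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["Phylogeny", "LTTCurve", "read_newick", "write_newick", "ltt"]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or validated."""


@dataclass
class LTTCurve:
    """Lineage-through-time step function of a reconstructed crown tree.

    ``times`` are the jump locations in forward time, starting at 0 (the
    crown, where 2 lineages exist) and ending at the present ``T``;
    ``counts[k]`` is the number of reconstructed lineages on
    ``[times[k], times[k+1])``.
    """

    times: np.ndarray
    counts: np.ndarray
    present: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("lineage counts must be nondecreasing")

    @property
    def n_events(self) -> int:
        return len(self.times)


class Phylogeny:
    """A rooted, bifurcating, dated phylogeny with unique tip labels.

    Thin wrapper around a :class:`dendropy.Tree` that caches node depths
    (distance from the root in time units) and exposes the quantities the
    rest of the package needs: the LTT, per-tip edge paths, and the
    Brownian-motion covariance (shared-path-length) matrix.
    """

    def __init__(self, tree: dendropy.Tree, dated: bool = True, rtol: float = 1e-6):
        self._tree = tree
        self.dated = dated
        self.rtol = rtol
        self._validate()

    # ------------------------------------------------------------------
    # construction / validation
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        t = self._tree
        leaves = t.leaf_nodes()
        if len(leaves) < 2:
            raise NewickParseError("tree must have at least 2 tips")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lb is None for lb in labels):
            raise NewickParseError("every tip must be labeled")
        if len(set(labels)) != len(labels):
            dups = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise NewickParseError(f"duplicate tip labels: {dups}")
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None:
                bl = nd.edge.length
                if bl is None:
                    raise NewickParseError("every edge must carry a branch length")
                if bl < 0:
                    raise NewickParseError(f"negative branch length {bl}")
            nchild = len(nd.child_nodes())
            if nchild not in (0, 2):
                raise NewickParseError(
                    f"tree is not strictly bifurcating (node with {nchild} children); "
                    "resolve polytomies or pass resolve_polytomies=True when reading"
                )
        # depths from the root, ignoring any root edge
        self._depth = {}
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                self._depth[nd] = 0.0
            else:
                self._depth[nd] = self._depth[nd.parent_node] + nd.edge.length
        tip_depths = np.array([self._depth[lf] for lf in leaves])
        self._root_age = float(tip_depths.max())
        if self.dated:
            if self._root_age <= 0:
                raise NewickParseError("dated tree must have positive depth")
            spread = tip_depths.max() - tip_depths.min()
            if spread > self.rtol * self._root_age:
                raise NewickParseError(
                    f"tree is not ultrametric: root-to-tip spread {spread:.6g} exceeds "
                    f"rtol*root_age = {self.rtol * self._root_age:.6g}"
                )

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def root_age(self) -> float:
        """Depth of the present below the root (crown age), in time units."""
        return self._root_age

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def node_depth(self, node) -> float:
        return self._depth[node]

    def internal_node_depths(self) -> np.ndarray:
        """Depths (forward time from the root) of all internal nodes, sorted.

        Includes the root itself at depth 0.
        """
        d = [self._depth[nd] for nd in self._tree.preorder_internal_node_iter()]
        return np.sort(np.asarray(d, dtype=float))

    def tip_path_lengths(self, label: str) -> list[float]:
        """Branch lengths on the path from tip *label* to the root, pendant first."""
        for lf in self._tree.leaf_node_iter():
            if lf.taxon.label == label:
                out = []
                nd = lf
                while nd.parent_node is not None:
                    out.append(float(nd.edge.length))
                    nd = nd.parent_node
                return out
        raise KeyError(f"tip {label!r} not in tree")

    def vcv(self, labels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion covariance matrix: shared root-to-MRCA path lengths.

        V[i, j] is the depth of the MRCA of tips i and j; V[i, i] is the depth
        of tip i.  Returns (matrix, labels in matrix order).
        """
        if labels is None:
            labels = self.tips
        idx = {lb: k for k, lb in enumerate(labels)}
        n = len(labels)
        V = np.zeros((n, n))
        # postorder: collect per-node tip index sets; at each internal node,
        # pairs drawn from different children share that node as MRCA
        below: dict = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                lb = nd.taxon.label
                below[nd] = [idx[lb]] if lb in idx else []
                if lb in idx:
                    V[idx[lb], idx[lb]] = self._depth[nd]
            else:
                kids = [below[c] for c in nd.child_nodes()]
                d = self._depth[nd]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                V[i, j] = V[j, i] = d
                below[nd] = [i for k in kids for i in k]
        return V, list(labels)

    def prune_to(self, labels: list[str]) -> "Phylogeny":
        """Return a new Phylogeny restricted to *labels* (unifurcations suppressed)."""
        keep = set(labels)
        missing = keep - set(self.tips)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to prune to")
        t = self._tree.clone(depth=1)
        taxa = [tx for tx in t.taxon_namespace if tx.label in keep]
        t.retain_taxa(taxa)
        return Phylogeny(t, dated=self.dated, rtol=self.rtol)

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def read_newick(
    path_or_string,
    dated: bool = True,
    rtol: float = 1e-6,
    resolve_polytomies: bool = False,
    seed: int | None = None,
) -> Phylogeny:
    """Read a Newick tree (file path or literal string) into a :class:`Phylogeny`.

    Polytomies are rejected by default; with ``resolve_polytomies=True`` they
    are randomly resolved with zero-length internal edges (seeded).
    """
    s = str(path_or_string)
    if "(" in s and ";" in s:
        src = {"data": s}
    else:
        with open(s) as fh:
            src = {"data": fh.read()}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            suppress_internal_node_taxa=True,
            **src,
        )
    except Exception as e:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {e}") from e
    if resolve_polytomies:
        rng = np.random.default_rng(seed)
        _resolve_polytomies(tree, rng)
    return Phylogeny(tree, dated=dated, rtol=rtol)


def _resolve_polytomies(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    for nd in list(tree.preorder_internal_node_iter()):
        while len(nd.child_nodes()) > 2:
            kids = nd.child_nodes()
            i, j = rng.choice(len(kids), size=2, replace=False)
            a, b = kids[int(i)], kids[int(j)]
            nd.remove_child(a)
            nd.remove_child(b)
            mid = dendropy.Node()
            mid.edge.length = 0.0
            mid.add_child(a)
            mid.add_child(b)
            nd.add_child(mid)


def write_newick(tree: Phylogeny, path) -> None:
    tree.write(path)


def ltt(tree: Phylogeny) -> LTTCurve:
    """Lineage-through-time curve of a dated ultrametric tree.

    The count starts at 2 at the crown (t = 0) and increases by one at each
    internal-node age; the final count equals the number of tips.
    """
    if not tree.dated:
        raise ValueError("LTT requires a dated (ultrametric) tree")
    depths = tree.internal_node_depths()  # includes root at 0
    counts = np.arange(2, 2 + len(depths))
    return LTTCurve(times=depths, counts=counts, present=tree.root_age)
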