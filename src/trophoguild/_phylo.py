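"""Array-based phylogeny utilities shared across the pipeline.

Wraps :mod:`dendropy` trees into flat parent/child arrays so that
likelihood recursions (Mk pruning, marginal ancestral states) and
Brownian-motion covariances run as plain numpy, independent of the
tree library's node objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloArrays",
    "read_tree",
    "read_trees",
    "prune_to",
    "tree_from_string",
]

_BLEN_FLOOR = 1e-8


def read_tree(path: str) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    _check_tree(tree)
    return tree


def read_trees(path: str) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (e.g. stochastically resolved trees)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick", preserve_underscores=True)
    out = list(trees)
    for t in out:
        _check_tree(t)
    return out


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    _check_tree(tree)
    return tree


def _check_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree tip labels are not unique")


def prune_to(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Prune a tree down to ``species``, preserving patristic distances.

    Raises if any requested species is missing from the tree.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(species) - tips)
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(labels=set(species))
    # suppress degree-2 nodes left by extraction so branch lengths add up
    pruned.suppress_unifurcations()
    return pruned


@dataclass
class PhyloArrays:
    """Flat representation of a rooted tree.

    Nodes are indexed ``0..n_nodes-1`` with tips first (``0..n_tips-1``,
    in the order of ``labels``) and internal nodes in postorder after
    them, the root last.
    """

    labels: list[str]
    parent: np.ndarray  # parent index per node; -1 for the root
    blen: np.ndarray  # branch length from node to its parent; 0 at root
    children: list[list[int]]
    postorder: np.ndarray  # all node indices in postorder (root last)
    n_tips: int
    depths: np.ndarray = field(init=False)  # root-to-node path length

    def __post_init__(self) -> None:
        depths = np.zeros(len(self.parent))
        for v in self.postorder[::-1]:  # preorder
            p = self.parent[v]
            depths[v] = self.blen[v] + (depths[p] if p >= 0 else 0.0)
        self.depths = depths

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def tree_height(self) -> float:
        return float(self.depths[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths[: self.n_tips]
        return bool((d.max() - d.min()) <= rel_tol * max(d.max(), 1.0))

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloArrays":
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        clamped = False
        for nd in tree.postorder_node_iter():
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                el = nd.edge.length if nd.edge.length is not None else 0.0
                if el <= 0:
                    el = _BLEN_FLOOR
                    clamped = True
                blen[v] = el
                children[parent[v]].append(v)
        if clamped:
            warnings.warn("non-positive branch lengths clamped to 1e-8", stacklevel=2)
        postorder = np.array(
            [index[id(nd)] for nd in tree.postorder_node_iter()], dtype=int
        )
        return cls(labels=labels, parent=parent, blen=blen, children=children,
                   postorder=postorder, n_tips=len(leaves))

    # ------------------------------------------------------------------
    # Brownian-motion covariance / correlation
    # ------------------------------------------------------------------
    def brownian_covariance(self) -> np.ndarray:
        """Tip covariance under Brownian motion: shared root-to-MRCA path."""
        n = self.n_tips
        V = np.zeros((n, n))
        # tip sets per node, assembled bottom-up
        tipsets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if v < n:
                tipsets[v] = np.array([v], dtype=int)
                V[v, v] = self.depths[v]
                continue
            kids = self.children[v]
            sets = [tipsets.pop(c) for c in kids]
            d = self.depths[v]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    V[np.ix_(sets[a], sets[b])] = d
                    V[np.ix_(sets[b], sets[a])] = d
            tipsets[v] = np.concatenate(sets)
        return V

    def brownian_correlation(self, warn_non_ultrametric: bool = True) -> np.ndarray:
        """Unit-diagonal phylogenetic correlation matrix (cov2cor of BM)."""
        if warn_non_ultrametric and not self.is_ultrametric(1e-3):
            warnings.warn("tree is not ultrametric; using correlation scaling",
                          stacklevel=2)
        V = self.brownian_covariance()
        s = np.sqrt(np.diag(V))
        return V / np.outer(s, s)

    def patristic_distances(self) -> np.ndarray:
        """Pairwise path lengths between tips."""
        V = self.brownian_covariance()
        d = np.diag(V)
        return d[:, None] + d[None, :] - 2.0 * V

    # ------------------------------------------------------------------
    # Equal-rates Mk machinery (closed-form transition probabilities)
    # ------------------------------------------------------------------
    def _er_decay(self, q: float, k: int) -> np.ndarray:
        """exp(-q*K/(K-1)*t) per node branch; q is the total leave rate."""
        return np.exp(-(q * k / (k - 1.0)) * self.blen)

    def mk_loglik(self, q: float, tip_states: np.ndarray, k: int) -> float:
        """Log-likelihood of a discrete trait under equal-rates Mk.

        ``q`` is the total rate of leaving a state (each of the other
        ``k-1`` states is entered at rate ``q/(k-1)``); uniform root prior.
        """
        part, logscale = self._mk_partials(q, tip_states, k)
        root = self.root
        lik = part[root].mean()  # uniform prior 1/k
        return float(np.log(lik) + logscale[root])

    def _mk_partials(self, q, tip_states, k):
        n = self.n_nodes
        part = np.zeros((n, k))
        part[np.arange(self.n_tips), tip_states] = 1.0
        logscale = np.zeros(n)
        decay = self._er_decay(q, k)
        for v in self.postorder:
            if v < self.n_tips:
                continue
            acc = np.ones(k)
            ls = 0.0
            for c in self.children[v]:
                e = decay[c]
                tot = part[c].sum()
                msg = (1.0 - e) * tot / k + e * part[c]
                acc *= msg
                ls += logscale[c]
            m = acc.max()
            part[v] = acc / m
            logscale[v] = ls + np.log(m)
        return part, logscale

    def mk_fit_rate(self, tip_states: np.ndarray, k: int,
                    bounds: tuple[float, float] = (1e-6, 1e4)) -> float:
        """Maximum-likelihood equal-rates Mk transition rate."""
        from scipy.optimize import minimize_scalar

        lo, hi = np.log(bounds[0]), np.log(bounds[1])

        def nll(logq: float) -> float:
            return -self.mk_loglik(np.exp(logq), tip_states, k)

        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        return float(np.exp(res.x))

    def mk_marginal_ancestral(self, q: float, tip_states: np.ndarray,
                              k: int) -> np.ndarray:
        """Marginal ancestral state probabilities at internal nodes.

        Returns an ``(n_internal, k)`` matrix, rows ordered as internal
        node indices ``n_tips..n_nodes-1``, each row summing to 1.
        """
        part, _ = self._mk_partials(q, tip_states, k)
        decay = self._er_decay(q, k)
        n = self.n_nodes
        up = np.zeros((n, k))
        up[self.root] = 1.0 / k
        # child messages toward the parent, reused for sibling products
        msg = np.zeros((n, k))
        for v in self.postorder:
            if self.parent[v] >= 0:
                e = decay[v]
                tot = part[v].sum()
                msg[v] = (1.0 - e) * tot / k + e * part[v]
        for v in self.postorder[::-1]:  # preorder: parents before children
            if v < self.n_tips:
                continue
            kids = self.children[v]
            for c in kids:
                sib = up[v].copy()
                for b in kids:
                    if b != c:
                        sib *= msg[b]
                # propagate through c's branch: sum_s P(s->s') * sib(s)
                e = decay[c]
                tot = sib.sum()
                up[c] = (1.0 - e) * tot / k + e * sib
                up[c] /= up[c].max()  # relative scale only
        marg = part[self.n_tips:] * up[self.n_tips:]
        marg /= marg.sum(axis=1, keepdims=True)
        return marg
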