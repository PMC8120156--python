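"""Hierarchy over concepts via meta-concepts and UPGMA.

The flat dictionary has no internal structure.  To relate concepts
topologically, the same inference machinery is re-run with the concept
archetypes themselves as the source collection, yielding *meta-concepts*.
Each concept is then a bag-of-meta-concepts count vector (how many times
each meta-concept appears in the optimal dissection of its archetype),
concepts are compared by cosine similarity, and the similarity matrix is
agglomerated with UPGMA (distance = 1 - similarity) into an ultrametric
tree exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import Dictionary
from .dissection import dissect
from .search import AnnealParams, anneal

__all__ = ["infer_meta", "feature_vectors", "cosine_similarity", "upgma",
           "to_newick", "TreeNode", "similarity_matrix"]


def infer_meta(C: Dictionary, params: AnnealParams | None = None) -> Dictionary:
    """Infer the dictionary of meta-concepts over the concept archetypes."""
    if len(C.concepts) < 2:
        raise ValueError("meta-concept inference needs at least 2 concepts")
    archetypes = [c.archetype for c in C.concepts]
    return anneal(archetypes, params, spec=C.spec)


def feature_vectors(C: Dictionary, meta: Dictionary) -> np.ndarray:
    """(len(C), len(meta)) matrix of meta-concept usage counts.

    Row k counts, per meta-concept, its usages in the optimal dissection of
    concept k's archetype; archetypes dissected all-null give zero rows.
    """
    if not meta.concepts:
        raise ValueError("meta dictionary is empty")
    index = {c.id: j for j, c in enumerate(meta.concepts)}
    out = np.zeros((len(C.concepts), len(meta.concepts)), dtype=int)
    for k, c in enumerate(C.concepts):
        d = dissect(c.archetype, meta)
        for r in d.regions:
            if not r.is_null:
                out[k, index[r.concept_id]] += 1
    return out


def cosine_similarity(u, v) -> float:
    """Cosine of two count vectors in [0, 1].

    Two zero vectors are indistinguishable (similarity 1); a zero against a
    nonzero vector shares nothing (similarity 0).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 and nv == 0.0:
        return 1.0
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))


def similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    m = len(vectors)
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            S[i, j] = S[j, i] = cosine_similarity(vectors[i], vectors[j])
    return S


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an ultrametric tree; ``height`` is distance-to-leaves / 2
    scale (leaves at height 0)."""

    name: str = ""
    height: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def upgma(similarity: np.ndarray, names=None) -> TreeNode:
    """Agglomerate a similarity matrix (unit diagonal, symmetric) by UPGMA.

    Distances are 1 - similarity; at each step the pair of clusters with
    the smallest average distance merges at height d/2, ties broken by the
    lowest pair of cluster indices.  Returns the root TreeNode.
    """
    S = np.asarray(similarity, dtype=float)
    m = S.shape[0]
    if S.shape != (m, m) or not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("similarity matrix must be square and symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-9):
        raise ValueError("similarity matrix must have a unit diagonal")
    names = list(names) if names is not None else [f"L{i}" for i in range(m)]
    if m == 0:
        raise ValueError("cannot cluster an empty matrix")
    D = 1.0 - S
    clusters = {i: (TreeNode(name=names[i]), 1) for i in range(m)}
    dist = {}
    for i in range(m):
        for j in range(i + 1, m):
            dist[(i, j)] = D[i, j]
    nxt = m
    while len(clusters) > 1:
        best_pair, bd = None, np.inf
        for (i, j), d in sorted(dist.items()):
            if d < bd - 1e-15:
                best_pair, bd = (i, j), d
        bi, bj = best_pair
        ni, si = clusters[bi]
        nj, sj = clusters[bj]
        node = TreeNode(height=bd / 2.0, children=[ni, nj])
        del clusters[bi], clusters[bj]
        # unweighted average: new distances weighted by cluster sizes
        new = {}
        for k, (nk, sk) in clusters.items():
            dik = dist[(min(bi, k), max(bi, k))]
            djk = dist[(min(bj, k), max(bj, k))]
            new[k] = (si * dik + sj * djk) / (si + sj)
        dist = {(i, j): d for (i, j), d in dist.items()
                if bi not in (i, j) and bj not in (i, j)}
        for k, d in new.items():
            dist[(min(nxt, k), max(nxt, k))] = d
        clusters[nxt] = (node, si + sj)
        nxt += 1
    (root, _), = clusters.values()
    return root


def to_newick(tree: TreeNode) -> str:
    """Newick text with branch lengths = parent height - child height."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(render(c, node.height)
                                  for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:g}"

    return render(tree, None) + ";"
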