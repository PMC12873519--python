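"""Phylogenetic tree ingestion, simulation, and trait covariance structures.

Trees are held as rooted :class:`dendropy.Tree` objects with branch
lengths in time-like units.  The functions here provide

* Newick reading/writing with validation (:func:`read_tree`,
  :func:`write_tree`),
* a seeded pure-birth (Yule) simulator producing ultrametric trees
  rescaled to unit root-to-tip depth (:func:`generate_tree`),
* random resolution of polytomies that preserves ultrametricity
  (:func:`resolve_polytomies`), and
* the species-by-species trait covariance (or correlation) matrices
  implied by white-noise, Brownian-motion, Ornstein-Uhlenbeck and
  Pagel-lambda models of trait evolution (:func:`covariance_matrix`),
  which are the residual structures used by the PGLS module.

Under Brownian motion the trait covariance of two species equals the
depth of their most recent common ancestor (shared evolutionary
history); under an OU process with rate ``alpha`` the correlation decays
as ``exp(-alpha * d_ij)`` with patristic distance ``d_ij``; Pagel's
lambda multiplies the BM off-diagonals by ``lambda`` (lambda = 0 is
white noise, lambda = 1 is BM).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "CorrelationStructure",
    "read_tree",
    "write_tree",
    "generate_tree",
    "tip_labels",
    "tip_depths",
    "is_ultrametric",
    "is_binary",
    "resolve_polytomies",
    "covariance_matrix",
]

_KINDS = ("WN", "BM", "OU", "PAGEL_LAMBDA")


@dataclass(frozen=True)
class CorrelationStructure:
    """A named residual correlation model for trait evolution.

    ``kind`` is one of ``"WN"`` (white noise / phylogenetic
    independence), ``"BM"`` (Brownian motion), ``"OU"``
    (Ornstein-Uhlenbeck, ``parameter`` = rate alpha > 0, default 1) or
    ``"PAGEL_LAMBDA"`` (``parameter`` = lambda in [0, 1]).
    """

    kind: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        if kind not in _KINDS:
            raise ValueError(f"unknown correlation structure {self.kind!r}; use one of {_KINDS}")
        object.__setattr__(self, "kind", kind)
        if kind == "OU":
            alpha = 1.0 if self.parameter is None else float(self.parameter)
            if not alpha > 0:
                raise ValueError(f"OU rate alpha must be > 0, got {alpha!r}")
            object.__setattr__(self, "parameter", alpha)
        elif kind == "PAGEL_LAMBDA":
            lam = float(self.parameter) if self.parameter is not None else 1.0
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"Pagel lambda must be in [0, 1], got {lam!r}")
            object.__setattr__(self, "parameter", lam)

    @property
    def label(self) -> str:
        if self.kind == "OU":
            return f"OU(alpha={self.parameter:g})"
        if self.kind == "PAGEL_LAMBDA":
            return f"PAGEL_LAMBDA(lambda={self.parameter:g})"
        return self.kind


def read_tree(source: str) -> dendropy.Tree:
    """Parse a rooted Newick tree from a string or file path.

    Branch lengths are required on all non-root edges; duplicate tip
    labels are rejected.
    """
    text = source
    if "(" not in source:  # looks like a path, not newick
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as err:
        raise ValueError(f"malformed newick: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            raise ValueError(
                f"edge above node {edge.head_node} has no branch length"
            )
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length!r}")
    return tree


def write_tree(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize a tree to Newick; write to ``path`` if given."""
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip."""
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depth[node]
    return out


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True when all root-to-tip depths agree to ``rel_tol`` (relative)."""
    depths = np.array(list(tip_depths(tree).values()))
    span = depths.max() - depths.min()
    return bool(span <= rel_tol * max(depths.max(), 1e-300))


def is_binary(tree: dendropy.Tree) -> bool:
    """True when every internal node has exactly two children."""
    return all(
        len(node.child_nodes()) == 2
        for node in tree.preorder_internal_node_iter()
    )


def generate_tree(n: int, seed: int) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) ultrametric tree with ``n`` tips.

    Speciation events occur at unit rate; the process is stopped an
    Exponential(n)-distributed time after the n-th lineage appears (the
    waiting time to the next, uncounted, event), so tip edges are never
    degenerate.  The tree is rescaled to unit root-to-tip depth and tips
    are labelled ``sp001 ... sp<n>`` in a seed-determined order.
    """
    if n < 2:
        raise ValueError(f"need at least 2 tips, got {n!r}")
    from dendropy.simulate import treesim

    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=rng
    )
    tree.is_rooted = True
    # observe the n-tip tree partway to the (n+1)-th speciation
    extra = rng.expovariate(float(n))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # rescale to unit depth
    depth = max(tip_depths(tree).values())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
    return tree


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Randomly resolve polytomies, preserving tip depths.

    The input must be ultrametric.  Each multifurcation is replaced by a
    random sequence of bifurcations; the new internal edges are given
    length ``1e-8 x tree depth`` and pendant edges are then adjusted so
    every root-to-tip depth is exactly its original value.  Deterministic
    for a given ``seed``.  Already-binary trees are returned unchanged
    (same object).
    """
    if not is_ultrametric(tree):
        raise ValueError("polytomy resolution requires an ultrametric tree")
    if is_binary(tree):
        return tree
    target = tip_depths(tree)
    depth = max(target.values())
    eps = 1e-8 * depth
    resolved = dendropy.Tree(tree)  # deep copy sharing the taxon namespace
    resolved.is_rooted = True
    resolved.resolve_polytomies(limit=2, update_bipartitions=False, rng=random.Random(int(seed)))
    for edge in resolved.preorder_edge_iter():
        if edge.head_node is resolved.seed_node:
            continue
        if edge.length is None or (edge.length == 0.0 and not edge.head_node.is_leaf()):
            edge.length = eps
    # restore exact ultrametricity on pendant edges
    depths = tip_depths(resolved)
    for leaf in resolved.leaf_node_iter():
        lbl = leaf.taxon.label
        leaf.edge.length += target[lbl] - depths[lbl]
        if leaf.edge.length < 0:
            raise RuntimeError(
                f"cannot preserve depth of tip {lbl!r}: pendant edge would be negative"
            )
    return resolved


def _depth_and_mrca(tree: dendropy.Tree, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Vector of tip depths and matrix of MRCA depths, ordered as ``taxa``."""
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    node_depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    below: dict[dendropy.Node, list[int]] = {}
    mrca = np.zeros((n, n))
    tipd = np.zeros(n)
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            if lbl not in index:
                continue
            i = index[lbl]
            tipd[i] = node_depth[node]
            mrca[i, i] = node_depth[node]
            below[node] = [i]
        else:
            groups = [below.get(ch, []) for ch in node.child_nodes()]
            merged: list[int] = []
            for gi, g in enumerate(groups):
                for h in groups[gi + 1:]:
                    for a in g:
                        for b in h:
                            mrca[a, b] = mrca[b, a] = node_depth[node]
                merged.extend(g)
            below[node] = merged
    covered = below.get(tree.seed_node, [])
    if len(covered) != n:
        missing = sorted(set(taxa) - {taxa[i] for i in covered})
        raise ValueError(f"taxa not found in tree: {missing}")
    return tipd, mrca


def covariance_matrix(
    tree: dendropy.Tree,
    structure: CorrelationStructure,
    taxa: list[str] | None = None,
) -> np.ndarray:
    """Residual covariance/correlation matrix implied by a trait model.

    Rows/columns follow ``taxa`` (default: the tree's tip order).  WN
    gives the identity; BM gives MRCA depths (diagonal = tip depth); OU
    gives correlations ``exp(-alpha * d_ij)`` with unit diagonal;
    PAGEL_LAMBDA multiplies BM off-diagonals by lambda.  The overall
    scale is irrelevant downstream because PGLS profiles the residual
    variance.
    """
    if taxa is None:
        taxa = tip_labels(tree)
    missing = set(taxa) - set(tip_labels(tree))
    if missing:
        raise ValueError(f"taxa not found in tree: {sorted(missing)}")
    n = len(taxa)
    if structure.kind == "WN":
        return np.eye(n)
    tipd, mrca = _depth_and_mrca(tree, list(taxa))
    if structure.kind == "BM":
        return mrca
    if structure.kind == "PAGEL_LAMBDA":
        lam = structure.parameter
        C = lam * mrca
        np.fill_diagonal(C, np.diag(mrca))
        return C
    # OU: patristic distance d_ij = depth_i + depth_j - 2 * mrca_ij
    dist = tipd[:, None] + tipd[None, :] - 2.0 * mrca
    np.fill_diagonal(dist, 0.0)
    return np.exp(-structure.parameter * dist)
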