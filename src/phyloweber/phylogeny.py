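"""Time-calibrated phylogenies and the species correlation structure they imply.

A rooted ultrametric tree over the analysis species defines a correlation
matrix ``V`` whose entry (i, j) is the fraction of total tree depth that
species i and j share on the path from the root to their most recent common
ancestor.  Pagel's lambda mixes ``V`` with the identity,
``M = lam * V + (1 - lam) * I``, interpolating between full Brownian-expected
correlation (lam = 1) and phylogenetic independence (lam = 0).  The same
machinery provides phylogenetic generalized least squares (PGLS), used to
compute residual brain volume as the residuals of endocranial volume on body
mass under the Brownian correlation.

Trees are handled through dendropy; time units are Myr throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import statsmodels.api as sm

#: relative tolerance on root-to-tip depth spread before a tree is
#: considered non-ultrametric (warn + mean-normalize, never an error:
#: published supertrees carry rounding slack).
ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """A tree violates a structural invariant (duplicate tips, bad ages...)."""


class TreeParseError(ValueError):
    """The Newick text could not be parsed."""


@dataclass
class PhyloTree:
    """A rooted, (near-)ultrametric time tree over uniquely labelled tips."""

    tree: dendropy.Tree

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depths = _node_depths(self.tree)
        return {
            leaf.taxon.label: depths[leaf] for leaf in self.tree.leaf_node_iter()
        }

    @property
    def depth(self) -> float:
        """Mean root-to-tip depth (= tree age for an ultrametric tree)."""
        return float(np.mean(list(self.tip_depths().values())))

    def mrca_age(self, *tips: str) -> float:
        """Age (time before present) of the MRCA of the given tip labels."""
        leaves = {
            leaf.taxon.label: leaf for leaf in self.tree.leaf_node_iter()
        }
        for t in tips:
            if t not in leaves:
                raise KeyError(f"tip {t!r} not in tree")
        mrca = _mrca(*(leaves[t] for t in tips))
        depths = _node_depths(self.tree)
        return self.depth - depths[mrca]

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def _mrca(*nodes):
    """Most recent common ancestor by explicit ancestor-path intersection."""
    paths = []
    for node in nodes:
        path = []
        nd = node
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path)
    common = set(paths[0])
    for path in paths[1:]:
        common &= set(path)
    for nd in paths[0]:  # first hit walking rootward = most recent
        if nd in common:
            return nd
    raise ValueError("nodes share no ancestor")


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def load_tree(newick_text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths into a PhyloTree.

    Duplicate tip labels and negative branch lengths raise
    :class:`TreeValidationError`.  Root-to-tip depths differing by more than
    ``ULTRAMETRIC_RTOL`` (relative) trigger a warning and terminal branches
    are stretched so every tip sits at the mean depth.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError flavours
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise TreeParseError(f"could not parse Newick: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) < 1 or any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise TreeValidationError("tree has unlabelled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"duplicate tip labels: {dupes}")

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise TreeValidationError(
                f"missing branch length above {_describe(node)}"
            )
        if node.edge.length < 0:
            raise TreeValidationError(
                f"negative branch length above {_describe(node)}"
            )

    ptree = PhyloTree(tree)
    depths = ptree.tip_depths()
    vals = np.array(list(depths.values()))
    mean = vals.mean()
    if mean > 0 and (vals.max() - vals.min()) / mean > ULTRAMETRIC_RTOL:
        warnings.warn(
            "tree is not ultrametric (relative depth spread "
            f"{(vals.max() - vals.min()) / mean:.3g}); "
            "normalizing tip depths to their mean",
            stacklevel=2,
        )
        for leaf in tree.leaf_node_iter():
            leaf.edge.length += mean - depths[leaf.taxon.label]
    return ptree


def _describe(node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return "an internal node"


def graft_split(
    tree: PhyloTree, tip: str, new_tip: str, divergence_age: float
) -> PhyloTree:
    """Graft ``new_tip`` as the sister of ``tip``, splitting at ``divergence_age``.

    Used to add recent splits absent from the source supertree (e.g. the
    North/South Island robin split at 3 Myr, the dog/wolf split at
    0.015 Myr).  The input tree is not modified.  ``divergence_age`` must be
    strictly younger than the age of ``tip``'s parent node.
    """
    labels = tree.labels
    if tip not in labels:
        raise TreeValidationError(f"tip {tip!r} not in tree")
    if new_tip in labels:
        raise TreeValidationError(f"tip {new_tip!r} already in tree")
    if divergence_age <= 0:
        raise TreeValidationError("divergence_age must be positive")

    cloned = tree.tree.clone(depth=1)
    leaf = next(
        l for l in cloned.leaf_node_iter() if l.taxon.label == tip
    )
    parent = leaf.parent_node
    if parent is None:
        raise TreeValidationError("cannot graft onto the root tip")
    parent_age = leaf.edge.length  # tip age 0 on an ultrametric tree
    if divergence_age >= parent_age:
        raise TreeValidationError(
            f"divergence_age {divergence_age} must be younger than the "
            f"parent node age {parent_age}"
        )

    parent.remove_child(leaf)
    mid = parent.new_child(edge_length=parent_age - divergence_age)
    mid.add_child(leaf)
    leaf.edge.length = divergence_age
    taxon = cloned.taxon_namespace.require_taxon(label=new_tip)
    mid.new_child(taxon=taxon, edge_length=divergence_age)
    return PhyloTree(cloned)


@dataclass
class SpeciesCovariance:
    """Phylogenetic correlation matrix ``V`` over an ordered species list.

    ``M`` and ``lambda_value`` are populated by :func:`lambda_mix`.
    """

    labels: tuple[str, ...]
    V: np.ndarray
    M: np.ndarray | None = None
    lambda_value: float | None = None

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.V = np.asarray(self.V, dtype=float)
        n = len(self.labels)
        if self.V.shape != (n, n):
            raise ValueError("V shape does not match labels")
        if not np.allclose(self.V, self.V.T, atol=1e-12):
            raise ValueError("V must be symmetric")
        if not np.allclose(np.diag(self.V), 1.0, atol=1e-9):
            raise ValueError("V must have unit diagonal")

    def reorder(self, labels) -> "SpeciesCovariance":
        """Restrict/permute to the given labels (all must be present)."""
        idx = []
        pos = {l: i for i, l in enumerate(self.labels)}
        for l in labels:
            if l not in pos:
                raise KeyError(f"species {l!r} not in covariance")
            idx.append(pos[l])
        idx = np.array(idx)
        out = SpeciesCovariance(tuple(labels), self.V[np.ix_(idx, idx)])
        if self.M is not None:
            out.M = self.M[np.ix_(idx, idx)]
            out.lambda_value = self.lambda_value
        return out


def tree_to_correlation(
    tree: PhyloTree, labels: list[str] | None = None
) -> SpeciesCovariance:
    """Correlation matrix among species effects implied by the tree.

    ``V[i, j]`` is the root-to-MRCA shared path length of species i and j
    divided by total tree depth, so that the diagonal is exactly 1
    (correlation, not covariance: the Brownian-motion trait covariance
    divided by total depth).
    """
    tips = tree.labels
    if labels is None:
        labels = sorted(tips)
    missing = [l for l in labels if l not in tips]
    if missing:
        raise KeyError(f"species not in tree: {missing}")

    depth = tree.depth
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {
        leaf.taxon.label: leaf.taxon for leaf in tree.tree.leaf_node_iter()
    }
    n = len(labels)
    V = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            shared = max(0.0, depth - patristic / 2.0)
            V[i, j] = V[j, i] = shared / depth
    return SpeciesCovariance(tuple(labels), V)


def lambda_mix(cov: SpeciesCovariance, lam: float) -> SpeciesCovariance:
    """Pagel's lambda transform: ``M = lam * V + (1 - lam) * I``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = lam * cov.V + (1.0 - lam) * np.eye(len(cov.labels))
    return replace(cov, M=M, lambda_value=float(lam))


def pgls_residuals(
    y: np.ndarray, x: np.ndarray, cov: SpeciesCovariance
) -> np.ndarray:
    """Residuals of a phylogenetic (GLS) regression of y on x.

    Residual covariance is ``V`` (lambda fixed at 1, pure Brownian
    correlation).  With ``V = I`` this reduces exactly to OLS residuals.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(cov.labels)
    if y.shape != (n,) or x.shape != (n,):
        raise ValueError("y and x must align with cov labels")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values not allowed in PGLS")
    X = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(X) < 2:
        raise np.linalg.LinAlgError(
            "singular design: predictor is constant across species"
        )
    fit = sm.GLS(y, X, sigma=cov.V).fit()
    return y - fit.fittedvalues
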