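"""Host phylogeny utilities: Faith's PD and Pagel's lambda.

Trees are handled as :class:`dendropy.Tree` objects parsed from Newick.

Faith's phylogenetic diversity of a host set is the sum of branch lengths of
the minimal subtree spanning the set.  The convention here is
*root-exclusive*: the subtree is rooted at the set's most recent common
ancestor (MRCA), branches above the MRCA do not count, and a single host has
PD = 0, so PD is a pure among-host diversity measure.  An ``include_root``
switch adds the MRCA-to-root path for users of the other convention.

Pagel's lambda measures phylogenetic signal in a tip trait: the off-diagonal
entries of the Brownian-motion covariance matrix (shared root-to-MRCA branch
lengths) are multiplied by lambda in [0, 1] while the diagonal is kept;
lambda = 1 recovers pure Brownian motion, lambda = 0 removes all
phylogenetic covariance.  lambda is estimated by maximum likelihood with the
trait mean and rate sigma^2 profiled out in closed form and a bounded scalar
search over lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring branch lengths and unique tips."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in Newick tree")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    tree.is_rooted = True
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def faith_pd(tree: dendropy.Tree, tips: list[str], include_root: bool = False) -> float:
    """Faith's PD of a tip subset under the root-exclusive MRCA convention."""
    if len(tips) == 0:
        raise ValueError("need at least one tip")
    labels = set(tip_labels(tree))
    for t in tips:
        if t not in labels:
            raise KeyError(f"tip {t!r} not in tree")
    tip_set = set(tips)
    if len(tip_set) == 1 and not include_root:
        return 0.0
    mrca = tree.mrca(taxon_labels=list(tip_set))
    total = 0.0
    seen: set[int] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in tip_set:
            continue
        node = leaf
        while node is not mrca and node is not None:
            if id(node) not in seen:
                seen.add(id(node))
                total += node.edge.length or 0.0
            node = node.parent_node
    if include_root:
        node = mrca
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
    return total


def phylo_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: shared root-to-MRCA path lengths per tip pair.

    Returns tip labels (tree order) and the (n, n) matrix whose diagonal
    holds root-to-tip depths.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = {id(leaf): leaf.root_distance for leaf in leaves}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depth[id(leaves[i])]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            shared = 0.5 * (V[i, i] + depth[id(leaves[j])] - d)
            V[i, j] = V[j, i] = shared
    return labels, V


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal phylogenetic covariance by lambda, keep the diagonal."""
    W = lam * V
    np.fill_diagonal(W, np.diag(V))
    return W


@dataclass
class LambdaFit:
    lambda_hat: float
    log_likelihood: float
    sigma2_hat: float
    mu_hat: float


def _profile_loglik(lam: float, V: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = y.size
    W = lambda_transform(V, lam)
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0:
        return -np.inf, np.nan, np.nan
    Wi = np.linalg.inv(W)
    ones = np.ones(n)
    mu = float(ones @ Wi @ y / (ones @ Wi @ ones))
    r = y - mu
    s2 = float(r @ Wi @ r / n)
    if s2 <= 0:
        return -np.inf, mu, s2
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, mu, s2


def pagels_lambda(
    tree: dendropy.Tree, trait: dict[str, float] | "np.ndarray", tol: float = 1e-6
) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda of a tip trait, bounded to [0, 1].

    ``trait`` maps tip labels to values (a mapping or pandas Series).  The
    trait mean and Brownian rate are profiled out analytically; lambda is
    found by bounded scalar minimization of the negative profile likelihood,
    with the boundary values 0 and 1 checked explicitly.

    Raises
    ------
    ValueError
        For a constant trait (signal undefined) or a star tree (all shared
        branch lengths zero: lambda unidentifiable).
    """
    labels, V = phylo_vcv(tree)
    y = np.asarray([trait[lbl] for lbl in labels], dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 tips with trait values")
    if np.allclose(y, y[0]):
        raise ValueError("constant trait: lambda undefined")
    off = V[~np.eye(V.shape[0], dtype=bool)]
    if np.allclose(off, 0):
        raise ValueError("star tree: lambda unidentifiable")
    if np.any(np.diag(V) <= 0):
        raise ValueError("tree must have positive root-to-tip depths")

    res = minimize_scalar(
        lambda lam: -_profile_loglik(lam, V, y)[0],
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [0.0, 1.0, float(res.x)]
    best = max(candidates, key=lambda lam: _profile_loglik(lam, V, y)[0])
    ll, mu, s2 = _profile_loglik(best, V, y)
    return LambdaFit(lambda_hat=best, log_likelihood=ll, sigma2_hat=s2, mu_hat=mu)
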